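import numpy as np
import pytest

from hemoflow import (
    BoundaryConditions,
    GeneratorParams,
    RheologyParams,
    Segment,
    VesselNetwork,
    generate_network,
    render_confocal,
    solve_network,
    voxelize,
)

#: default confocal grid: 2.25 µm lateral pitch, 60 µm depth in 75 slices
DEFAULT_SPACING = (2.25, 2.25, 0.8)


@pytest.fixture(scope="session")
def rheo():
    return RheologyParams()


@pytest.fixture(scope="session")
def default_network():
    return generate_network(seed=1)


@pytest.fixture(scope="session")
def baseline_solution(default_network, rheo):
    bc = BoundaryConditions.from_preset(default_network, "baseline")
    return solve_network(default_network, bc, rheo)


@pytest.fixture(scope="session")
def mini_params():
    """Reduced-scale generator settings for voxel-level tests."""
    return GeneratorParams(
        extents=(800.0, 800.0, 60.0),
        trunk_inner_radius=60.0,
        trunk_outer_radius=320.0,
        trunk_step=65.0,
        branch_min_radius=110.0,
        branch_margin=60.0,
        branch_step=70.0,
        venule_radial_offset=30.0,
        rung_window=(15.0, 120.0),
        adapt_iterations=2,
        regression_threshold=0.0,
        angiogenesis_threshold=0.0,
    )


@pytest.fixture(scope="session")
def mini_network(mini_params):
    return generate_network(mini_params, seed=1)


@pytest.fixture(scope="session")
def crop_label(default_network):
    """Central 576 x 576 x 60 µm crop of the default network at confocal pitch."""
    return voxelize(default_network, DEFAULT_SPACING, origin=(574.0, 574.0, 0.0), size=(576.0, 576.0, 60.0))


@pytest.fixture(scope="session")
def crop_image(crop_label):
    return render_confocal(crop_label, seed=1)


def single_tube(radius_um=3.5, length_um=100.0):
    """One straight capillary between an arteriole inlet and a venule outlet."""
    return VesselNetwork(
        positions={0: (0.0, 0.0, 0.0), 1: (length_um, 0.0, 0.0)},
        segments=[Segment(0, 0, 1, radius_um)],
        roots={0: "arteriole_inlet", 1: "venule_outlet"},
    )


def random_network(n_nodes=30, n_segments=50, seed=42):
    """Random connected test network spanning one inlet and one outlet."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    while True:
        positions = {i: tuple(rng.uniform(0, 500, 3)) for i in range(n_nodes)}
        g = nx.Graph()
        segments = []
        sid = 0
        while sid < n_segments:
            a, b = rng.integers(0, n_nodes, 2)
            if a == b or g.has_edge(int(a), int(b)):
                continue
            g.add_edge(int(a), int(b))
            segments.append(Segment(sid, int(a), int(b), float(rng.uniform(2.0, 10.0)), "arteriole_2"))
            sid += 1
        if g.number_of_nodes() == n_nodes and nx.is_connected(g):
            return VesselNetwork(
                positions=positions,
                segments=segments,
                roots={0: "arteriole_inlet", 1: "venule_outlet"},
            )
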