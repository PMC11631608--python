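"""Synthetic rat-retina vasculature: ground-truth networks and confocal-like volumes.

The generator emulates the geometry of a perfused retinal field of view
centered on the optic disc: a slab 2300 x 2300 x 60 µm, with arteriole and
venule trees alternating radially around the center, each trunk shedding
fine terminal branches whose tips feed a dense capillary plexus laid on a
jittered 3D lattice.  Arterioles and their terminal branches carry most of
the driving pressure (they are the resistance vessels of real
microcirculation), while capillary lumen diameters stay at or below 7 µm.

Vessel calibres are a calibration: root diameters taper from 30 µm (order 1)
through ~12 µm terminal branches (order 2) to 4-7 µm capillaries, chosen so
that baseline wall shear stresses on the network land in the physiological
0-20 Pa range.

Every generated structure is a pure function of (parameters, seed).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .network import (
    ARTERIOLE_INLET,
    VENULE_OUTLET,
    NetworkError,
    Segment,
    VesselNetwork,
)

__all__ = [
    "GeneratorParams",
    "GenerationError",
    "ImageVolume",
    "LabelVolume",
    "generate_network",
    "voxelize",
    "render_confocal",
]


class GenerationError(RuntimeError):
    """The requested settings cannot produce a valid perfused network."""


# ---------------------------------------------------------------------------
# image containers
# ---------------------------------------------------------------------------

@dataclass
class ImageVolume:
    """3D grayscale stack.  ``data`` is indexed (z, y, x); ``spacing`` is
    (dx, dy, dz) in µm per voxel; voxel centers sit at origin + index*spacing."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D (z, y, x)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing components must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def sigma_voxels(self, sigma_um: float) -> tuple[float, float, float]:
        """Convert an isotropic physical scale to per-axis voxel sigmas (z, y, x)."""
        dx, dy, dz = self.spacing
        return (sigma_um / dz, sigma_um / dy, sigma_um / dx)


@dataclass
class LabelVolume(ImageVolume):
    """Binary vessel mask on the same grid conventions as :class:`ImageVolume`."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("label volume must be binary (0 background, 1 vessel)")
        self.data = self.data.astype(np.uint8)


# ---------------------------------------------------------------------------
# network generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorParams:
    """Settings for the synthetic vascular network.

    Distances and diameters in µm.  Defaults reproduce the rat-retina field
    of view (slab 2300 x 2300 x 60 µm): two arteriole and two venule trees
    alternate radially around the optic-disc proxy at the field center; each
    trunk sheds azimuthal terminal branches ("comb teeth") that interdigitate
    with the opposing comb at a small radial offset, and short capillary
    rungs bridge facing arteriole/venule teeth, as in ladder-like terminal
    microvascular units.  A sparse jittered lattice weaves an additional
    capillary mesh through the plexus.
    """

    extents: tuple[float, float, float] = (2300.0, 2300.0, 60.0)
    n_arteriole_trees: int = 3
    n_venule_trees: int = 3
    trunk_inner_radius: float = 150.0
    trunk_outer_radius: float = 1000.0
    trunk_step: float = 100.0
    #: radial stagger of the venule combs between consecutive arteriole combs
    venule_radial_offset: float = 50.0
    root_diameter: float = 28.0
    trunk_tip_diameter: float = 13.0
    branch_diameter: float = 5.8
    branch_tip_diameter: float = 5.8
    #: calibre of the short "neck" at each tooth base: the precapillary
    #: resistance element shared by all the tooth's capillary rungs
    neck_diameter: float = 5.8
    branch_min_diameter: float = 5.0
    branch_step: float = 150.0
    #: azimuthal fraction of the inter-trunk gap a tooth crosses
    branch_gap_fill: float = 0.85
    #: clearance kept between a tooth and the opposing trunk
    branch_margin: float = 100.0
    #: no teeth below this radius: short inner teeth would short-circuit the
    #: pressure ladder (their hydraulic resistance scales with their length)
    branch_min_radius: float = 400.0
    #: scale tooth calibre with length^(1/4) so teeth of different reach
    #: present similar hydraulic resistance (R_hyd ∝ L/d⁴)
    equalize_teeth: bool = True
    branches_per_trunk: int = 8
    #: capillary rungs bridge facing arteriole/venule tooth vertices whose
    #: distance falls in this window
    rung_window: tuple[float, float] = (25.0, 210.0)
    rung_fan: int = 2
    #: at most this many rungs may load one tooth (either side); keeps the
    #: teeth below the wall-shear ceiling (τ_tooth ≈ k·τ_rung·(R_rung/R_tooth)³)
    rungs_per_tooth: int = 4
    scale_rung_budget: bool = False
    rung_diameter_range: tuple[float, float] = (4.3, 4.7)
    #: sparse background capillary mesh (jittered lattice woven into the bed)
    mesh_spacing: float = 110.0
    mesh_z_layers: int = 2
    mesh_keep_prob: float = 0.0
    mesh_attach: int = 2
    mesh_diameter_range: tuple[float, float] = (4.0, 5.5)
    capillary_diameter_range: tuple[float, float] = (4.0, 7.0)
    #: restrict the plexus to an annulus around the disc (µm); None = whole slab
    lattice_annulus: tuple[float, float] | None = (220.0, 1480.0)
    jitter_frac: float = 0.25
    prune_dead_ends: bool = True
    #: shear-driven structural adaptation: vessels dilate toward a
    #: wall-shear-stress set point under baseline perfusion (within per-class
    #: calibre ranges), chronically low-shear capillaries regress, and
    #: maximally dilated capillaries under excess shear split into parallel
    #: lumens.  0 iterations disables adaptation entirely.
    adapt_iterations: int = 6
    wss_set_point: float = 16.0
    regression_threshold: float = 2.0
    branch_adapt_range: tuple[float, float] = (5.4, 6.0)
    trunk_adapt_range: tuple[float, float] = (13.0, 28.0)
    angiogenesis_threshold: float = 20.0

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extents):
            raise GenerationError("slab extents must be > 0")
        for lo, hi in (self.capillary_diameter_range, self.rung_diameter_range, self.mesh_diameter_range):
            if not (0 < lo <= hi <= 7.0):
                raise GenerationError("capillary diameters must lie in (0, 7] µm")
        if self.n_arteriole_trees < 1 or self.n_venule_trees < 1:
            raise GenerationError("need at least one arteriole and one venule tree")


def _clip_to_slab(p: np.ndarray, extents, margin: float = 1.0) -> np.ndarray:
    ext = np.asarray(extents, dtype=float)
    return np.clip(p, margin, ext - margin)


class _Builder:
    def __init__(self, extents):
        self.positions: dict[int, tuple[float, float, float]] = {}
        self.segments: list[Segment] = []
        self.roots: dict[int, str] = {}
        self.extents = extents
        self._next_node = 0
        self._next_seg = 0

    def add_node(self, p: np.ndarray) -> int:
        nid = self._next_node
        self._next_node += 1
        q = _clip_to_slab(np.asarray(p, dtype=float), self.extents)
        self.positions[nid] = (float(q[0]), float(q[1]), float(q[2]))
        return nid

    def add_segment(self, a: int, b: int, diameter: float, vclass: str) -> Segment:
        s = Segment(self._next_seg, a, b, diameter / 2.0, vclass)
        self._next_seg += 1
        self.segments.append(s)
        return s


def generate_network(params: GeneratorParams | None = None, seed: int = 0) -> VesselNetwork:
    """Generate a ground-truth vascular network.

    Raises :class:`GenerationError` if the settings cannot yield a connected
    network with at least one arteriole-inlet to venule-outlet path.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    b = _Builder(params.extents)
    ext = np.asarray(params.extents, dtype=float)
    center = ext / 2.0
    z_mid = center[2]

    n_trees = params.n_arteriole_trees + params.n_venule_trees
    kinds: list[str] = []
    na, nv = params.n_arteriole_trees, params.n_venule_trees
    while na or nv:
        if na:
            kinds.append("arteriole")
            na -= 1
        if nv:
            kinds.append("venule")
            nv -= 1

    tips: dict[str, list[int]] = {"arteriole": [], "venule": []}
    verts: dict[str, list[tuple[int, int]]] = {"arteriole": [], "venule": []}  # (node, tooth id)
    tooth_counter = [0]
    teeth_budget: dict[int, int] = {}
    for k, kind in enumerate(kinds):
        angle = 2.0 * math.pi * k / n_trees + rng.normal(0.0, 0.04)
        _grow_tree(b, params, rng, kind, angle, center, z_mid, n_trees, tips[kind], verts[kind], tooth_counter, teeth_budget)

    _bridge_combs(b, params, rng, verts, tips, teeth_budget)
    _weave_mesh(b, params, rng, ext, center, verts)

    net = VesselNetwork(
        positions=b.positions, segments=b.segments, roots=b.roots, extents=params.extents
    )
    net = _restrict_to_root_component(net)
    if params.prune_dead_ends:
        net = _prune_dead_ends(net)
    if params.adapt_iterations > 0:
        net = _adapt_to_shear(net, params)
    try:
        net.validate()
    except NetworkError as exc:
        raise GenerationError(f"generated network is invalid: {exc}") from exc
    return net


def _grow_tree(b, params, rng, kind, angle, center, z_mid, n_trees, tip_list, vert_list, tooth_counter, teeth_budget) -> None:
    """One radial trunk (order 1) with azimuthal terminal branches (order 2).

    The teeth of a comb run along circles of nearly constant radius into the
    gaps on either side of the trunk; venule combs are staggered radially so
    that arteriole and venule teeth interdigitate ~50 µm apart, ready to be
    bridged by capillary rungs.
    """
    order1 = f"{kind}_1"
    root_tag = ARTERIOLE_INLET if kind == "arteriole" else VENULE_OUTLET

    offset = params.venule_radial_offset if kind == "venule" else 0.0
    r0 = params.trunk_inner_radius + offset
    r1 = params.trunk_outer_radius + offset
    n_steps = max(0, int(round((r1 - r0) / params.trunk_step)))
    u = np.array([math.cos(angle), math.sin(angle), 0.0])

    root_p = center + u * r0
    root_p[2] = z_mid
    root = b.add_node(root_p)
    b.roots[root] = root_tag
    if n_steps == 0:
        tip_list.append(root)
        return

    branch_at = set()
    if params.branches_per_trunk > 0:
        idx = np.linspace(1, n_steps, min(params.branches_per_trunk, n_steps))
        branch_at = {int(round(i)) for i in idx}

    prev = root
    for i in range(1, n_steps + 1):
        r = r0 + i * params.trunk_step
        frac = i / n_steps
        dia = params.root_diameter + frac * (params.trunk_tip_diameter - params.root_diameter)
        p = center + u * r
        p[0] += rng.normal(0.0, params.jitter_frac * 20.0)
        p[1] += rng.normal(0.0, params.jitter_frac * 20.0)
        p[2] = z_mid + rng.normal(0.0, 3.0)
        node = b.add_node(p)
        b.add_segment(prev, node, dia, order1)
        if i in branch_at and r >= params.branch_min_radius:
            for side in (+1.0, -1.0):
                _grow_tooth(b, params, rng, kind, node, angle, r, side, center, n_trees, tip_list, vert_list, tooth_counter[0], teeth_budget)
                tooth_counter[0] += 1
        prev = node
    tip_list.append(prev)


def _grow_tooth(b, params, rng, kind, start, trunk_angle, r, side, center, n_trees, tip_list, vert_list, tooth_id, teeth_budget) -> None:
    gap_angle = 2.0 * math.pi / n_trees
    arc = max(0.0, (gap_angle * r - params.branch_margin) * params.branch_gap_fill)
    n_steps = int(arc / params.branch_step)
    if n_steps < 1:
        return
    arc_ref = max(1.0, (gap_angle * params.trunk_outer_radius - params.branch_margin) * params.branch_gap_fill)
    dia_scale = (arc / arc_ref) ** 0.25 if params.equalize_teeth else 1.0
    # short teeth take proportionally fewer rungs so every tooth runs at a
    # similar wall shear stress
    if params.scale_rung_budget:
        teeth_budget[tooth_id] = max(1, int(round(params.rungs_per_tooth * arc / arc_ref)))
    else:
        teeth_budget[tooth_id] = params.rungs_per_tooth
    prev = start
    z = float(b.positions[start][2])
    for i in range(1, n_steps + 1):
        frac = i / n_steps
        if i == 1:
            dia = max(params.branch_min_diameter, params.neck_diameter * dia_scale)
        else:
            dia = max(params.branch_min_diameter, dia_scale * (params.branch_diameter + frac * (params.branch_tip_diameter - params.branch_diameter)))
        phi = trunk_angle + side * (i * params.branch_step / r + rng.normal(0.0, 0.008))
        rr = r + rng.normal(0.0, params.jitter_frac * 20.0)
        z += rng.normal(0.0, 1.5)
        p = center + rr * np.array([math.cos(phi), math.sin(phi), 0.0])
        p[2] = z
        node = b.add_node(p)
        b.add_segment(prev, node, dia, f"{kind}_2")
        vert_list.append((node, tooth_id))
        prev = node
    tip_list.append(prev)


def _bridge_combs(b, params, rng, verts, tips, teeth_budget) -> None:
    """Capillary rungs between facing arteriole and venule tooth vertices."""
    from scipy.spatial import cKDTree

    a_ids = verts["arteriole"]
    v_ids = verts["venule"]
    if not a_ids or not v_ids:
        # degenerate settings: bridge arteriole tips straight to venule tips
        if not tips["arteriole"] or not tips["venule"]:
            raise GenerationError("no terminal branches or tips to bridge")
        vt = np.array([b.positions[t] for t in tips["venule"]])
        dhi = params.capillary_diameter_range[1]
        for tip in tips["arteriole"]:
            tp = np.asarray(b.positions[tip])
            j = int(np.argmin(np.sum((vt - tp) ** 2, axis=1)))
            b.add_segment(tip, tips["venule"][j], dhi, "capillary")
        return

    lo, hi = params.rung_window
    dlo, dhi = params.rung_diameter_range
    a_nodes = [n for n, _ in a_ids]
    a_tooth = {n: t for n, t in a_ids}
    v_nodes = [n for n, _ in v_ids]
    v_tooth = {n: t for n, t in v_ids}
    a_pos = np.array([b.positions[n] for n in a_nodes])
    v_pos = np.array([b.positions[n] for n in v_nodes])
    tree = cKDTree(v_pos)
    made = set()
    budget: dict[int, int] = {}
    order = rng.permutation(len(a_nodes))
    for i in order:
        n = a_nodes[i]
        if budget.get(a_tooth[n], 0) >= teeth_budget.get(a_tooth[n], params.rungs_per_tooth):
            continue
        dists, js = tree.query(a_pos[i], k=min(params.rung_fan + 4, len(v_nodes)))
        dists = np.atleast_1d(dists)
        js = np.atleast_1d(js)
        count = 0
        for d, j in zip(dists, js):
            if count >= params.rung_fan or d > hi:
                break
            if d < lo:
                continue
            m = v_nodes[int(j)]
            if budget.get(v_tooth[m], 0) >= teeth_budget.get(v_tooth[m], params.rungs_per_tooth):
                continue
            pair = (n, m)
            if pair in made:
                continue
            made.add(pair)
            b.add_segment(n, m, rng.uniform(dlo, dhi), "capillary")
            budget[a_tooth[n]] = budget.get(a_tooth[n], 0) + 1
            budget[v_tooth[m]] = budget.get(v_tooth[m], 0) + 1
            count += 1
            if budget[a_tooth[n]] >= teeth_budget.get(a_tooth[n], params.rungs_per_tooth):
                break


def _weave_mesh(b, params, rng, ext, center, verts) -> None:
    """Sparse jittered capillary lattice woven through the plexus, attached
    to nearby tooth vertices; adds mesh-like redundancy around the rungs."""
    if params.mesh_keep_prob <= 0 or params.mesh_spacing <= 0 or params.mesh_attach <= 0:
        return
    from scipy.spatial import cKDTree

    h = params.mesh_spacing
    nx_ = max(1, int(round(ext[0] / h)) - 1)
    ny_ = max(1, int(round(ext[1] / h)) - 1)
    nz_ = max(1, params.mesh_z_layers)
    jit = params.jitter_frac * h
    annulus = params.lattice_annulus
    nodes, index = [], {}
    for k in range(nz_):
        z0 = ext[2] * (k + 1) / (nz_ + 1)
        for j in range(ny_):
            for i in range(nx_):
                p = np.array(
                    [
                        (i + 1) * h + rng.normal(0.0, jit),
                        (j + 1) * h + rng.normal(0.0, jit),
                        z0 + rng.normal(0.0, 0.15 * ext[2] / (nz_ + 1)),
                    ]
                )
                if annulus is not None:
                    r = float(np.linalg.norm(p[:2] - center[:2]))
                    if not (annulus[0] <= r <= annulus[1]):
                        continue
                index[(i, j, k)] = len(nodes)
                nodes.append(_clip_to_slab(p, ext))
    if not nodes:
        return
    nodes = np.asarray(nodes)
    dlo, dhi = params.mesh_diameter_range
    node_of = {i: b.add_node(p) for i, p in enumerate(nodes)}
    for (i, j, k), a in index.items():
        for di, dj, dk in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            nb = (i + di, j + dj, k + dk)
            if nb in index and rng.random() < params.mesh_keep_prob:
                b.add_segment(node_of[a], node_of[index[nb]], rng.uniform(dlo, dhi), "capillary")
    # attach each mesh node to its nearest tooth vertices
    all_verts = [n for n, _ in verts["arteriole"]] + [n for n, _ in verts["venule"]]
    if not all_verts:
        return
    vpos = np.array([b.positions[n] for n in all_verts])
    tree = cKDTree(vpos)
    for i in range(nodes.shape[0]):
        dists, js = tree.query(nodes[i], k=min(params.mesh_attach, len(all_verts)))
        for d, j in zip(np.atleast_1d(dists), np.atleast_1d(js)):
            if d > 2.0 * h or d < 20.0:
                continue
            b.add_segment(node_of[i], all_verts[int(j)], rng.uniform(dlo, dhi), "capillary")


def _restrict_to_root_component(net: VesselNetwork) -> VesselNetwork:
    """Keep only the connected component(s) containing the roots; all roots
    must share one component, else generation has failed."""
    adj: dict[int, list[tuple[int, Segment]]] = {}
    for s in net.segments:
        adj.setdefault(s.a, []).append((s.b, s))
        adj.setdefault(s.b, []).append((s.a, s))
    roots = list(net.roots)
    start = roots[0]
    seen = {start}
    stack = [start]
    while stack:
        n = stack.pop()
        for m, _ in adj.get(n, ()):
            if m not in seen:
                seen.add(m)
                stack.append(m)
    missing = [r for r in roots if r not in seen]
    if missing:
        raise GenerationError(
            f"roots {missing} are disconnected from the main component; "
            "increase plexus density"
        )
    segments = [s for s in net.segments if s.a in seen]
    positions = {n: p for n, p in net.positions.items() if n in seen}
    return VesselNetwork(positions=positions, segments=segments, roots=dict(net.roots), extents=net.extents)


def _prune_dead_ends(net: VesselNetwork) -> VesselNetwork:
    """Iteratively remove degree-1 capillary stubs (they carry no flow).
    Root nodes and non-capillary segments are never pruned."""
    segments = list(net.segments)
    while True:
        degree: dict[int, int] = {}
        for s in segments:
            degree[s.a] = degree.get(s.a, 0) + 1
            degree[s.b] = degree.get(s.b, 0) + 1
        drop = [
            s
            for s in segments
            if s.vessel_class == "capillary"
            and (
                (degree[s.a] == 1 and s.a not in net.roots)
                or (degree[s.b] == 1 and s.b not in net.roots)
            )
        ]
        if not drop:
            break
        dropped = {s.id for s in drop}
        segments = [s for s in segments if s.id not in dropped]
    used = {s.a for s in segments} | {s.b for s in segments} | set(net.roots)
    positions = {n: p for n, p in net.positions.items() if n in used}
    return VesselNetwork(positions=positions, segments=segments, roots=dict(net.roots), extents=net.extents)


def _adapt_to_shear(net: VesselNetwork, params: GeneratorParams) -> VesselNetwork:
    """Structural adaptation of the plexus to wall shear stress.

    Vessels dilate toward a shear set point within per-class calibre ranges
    (τ_w ∝ Q/R³ at fixed flow); capillaries already at maximum calibre under
    excess shear split into two parallel lumens (intussusceptive
    angiogenesis); chronically under-perfused capillaries regress and are
    removed.  Narrowing is deliberately absent: in a pressure-driven bed it
    only starves cold vessels further.
    """
    from dataclasses import replace as _replace

    from .rheology import RheologyParams
    from .solver import BoundaryConditions, solve_network

    rheo = RheologyParams()
    cap_lo, cap_hi = (d / 2.0 for d in params.capillary_diameter_range)
    br_lo, br_hi = (d / 2.0 for d in params.branch_adapt_range)
    tr_lo, tr_hi = (d / 2.0 for d in params.trunk_adapt_range)
    adaptable = {
        "capillary": (cap_lo, cap_hi),
        "arteriole_2": (br_lo, br_hi),
        "venule_2": (br_lo, br_hi),
        "arteriole_1": (tr_lo, tr_hi),
        "venule_1": (tr_lo, tr_hi),
    }

    def remodel(net):
        sol = solve_network(net, BoundaryConditions.from_preset(net, "baseline"), rheo)
        segments = []
        positions = dict(net.positions)
        next_node = max(positions) + 1
        next_seg = max(s.id for s in net.segments) + 1
        for s, t in zip(net.segments, sol.wall_shear_stress):
            bounds = adaptable.get(s.vessel_class)
            if bounds is None or t <= params.wss_set_point:
                segments.append(s)
                continue
            r_new = s.radius * (t / params.wss_set_point) ** (1.0 / 3.0)
            r_new = float(min(max(r_new, s.radius), bounds[1]))
            if (
                s.vessel_class == "capillary"
                and params.angiogenesis_threshold > 0
                and t > params.angiogenesis_threshold
                and s.radius >= bounds[1] - 1e-9
            ):
                # intussusceptive splitting: a maximally dilated capillary
                # under excess shear divides into two parallel lumens
                pa = np.asarray(positions[s.a], dtype=float)
                pb = np.asarray(positions[s.b], dtype=float)
                axis = pb - pa
                perp = np.cross(axis, [0.0, 0.0, 1.0])
                nrm = np.linalg.norm(perp)
                perp = np.array([1.0, 0.0, 0.0]) if nrm < 1e-9 else perp / nrm
                offset = 0.25 * np.linalg.norm(axis)
                for sign in (+1.0, -1.0):
                    mid = 0.5 * (pa + pb) + sign * offset * perp
                    m = next_node
                    next_node += 1
                    positions[m] = tuple(_clip_to_slab(mid, net.extents))
                    segments.append(Segment(next_seg, s.a, m, s.radius, "capillary"))
                    segments.append(Segment(next_seg + 1, m, s.b, s.radius, "capillary"))
                    next_seg += 2
            else:
                segments.append(_replace(s, radius=r_new))
        out = VesselNetwork(positions=positions, segments=segments, roots=dict(net.roots), extents=net.extents)
        return out, sol

    def regress(net):
        sol = solve_network(net, BoundaryConditions.from_preset(net, "baseline"), rheo)
        keep = [
            s
            for s, t in zip(net.segments, sol.wall_shear_stress)
            if s.vessel_class != "capillary" or t >= params.regression_threshold
        ]
        pruned = net.copy()
        pruned.segments = keep
        try:
            pruned = _restrict_to_root_component(pruned)
            pruned = _prune_dead_ends(pruned)
            if pruned.has_inlet_outlet_path():
                return pruned
        except GenerationError:
            pass  # regression would sever the bed; keep the unpruned network
        return net

    # three phases of remodelling with regression between them; remodelling
    # always runs after the last regression so that flow concentrated onto
    # surviving vessels is relieved before the network is frozen
    third = max(1, params.adapt_iterations // 3)
    for phase in range(3):
        if phase and params.regression_threshold > 0:
            net = regress(net)
        n_pass = third if phase < 2 else params.adapt_iterations - 2 * third
        for _ in range(max(1, n_pass)):
            net, _ = remodel(net)
    return net


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def voxelize(
    network: VesselNetwork,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    size: tuple[float, float, float] | None = None,
) -> LabelVolume:
    """Rasterize a network: a voxel is labeled 1 iff its center lies within
    the segment radius of some segment axis.

    By default the grid covers the network's slab extents; pass ``origin``
    and ``size`` (µm) to rasterize a crop.  Emits a warning when the spacing
    is coarser than twice the smallest vessel radius (the network is then
    not resolvable on the grid).
    """
    dx, dy, dz = spacing
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError("voxel spacing must be > 0")
    if size is None:
        if network.extents is None:
            raise ValueError("network must carry slab extents to be voxelized")
        size = network.extents
    if network.segments:
        rmin = min(s.radius for s in network.segments)
        if min(spacing) > 2.0 * rmin:
            warnings.warn(
                f"voxel spacing {spacing} is coarser than twice the minimum radius "
                f"({rmin:.2f} µm); thin vessels will not be resolved",
                stacklevel=2,
            )
    ex, ey, ez = size
    shape = (int(round(ez / dz)), int(round(ey / dy)), int(round(ex / dx)))
    data = np.zeros(shape, dtype=np.uint8)
    sp = np.array([dx, dy, dz])
    org = np.asarray(origin, dtype=float)
    for s in network.segments:
        pa = np.asarray(network.positions[s.a], dtype=float) - org
        pb = np.asarray(network.positions[s.b], dtype=float) - org
        _rasterize_cylinder(data, pa, pb, s.radius, sp)
    return LabelVolume(data=data, spacing=(dx, dy, dz), origin=tuple(org))


def _rasterize_cylinder(data, pa, pb, radius, spacing) -> None:
    lo = np.minimum(pa, pb) - radius
    hi = np.maximum(pa, pb) + radius
    # voxel centers at index*spacing
    i_lo = np.maximum(np.floor(lo / spacing).astype(int), 0)
    i_hi = np.minimum(np.ceil(hi / spacing).astype(int), np.array(data.shape)[::-1] - 1)
    if np.any(i_hi < i_lo):
        return
    xs = np.arange(i_lo[0], i_hi[0] + 1) * spacing[0]
    ys = np.arange(i_lo[1], i_hi[1] + 1) * spacing[1]
    zs = np.arange(i_lo[2], i_hi[2] + 1) * spacing[2]
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    P = np.stack([X, Y, Z], axis=-1)
    ab = pb - pa
    denom = float(ab @ ab)
    if denom == 0.0:
        d2 = np.sum((P - pa) ** 2, axis=-1)
    else:
        t = np.clip(((P - pa) @ ab) / denom, 0.0, 1.0)
        proj = pa + t[..., None] * ab
        d2 = np.sum((P - proj) ** 2, axis=-1)
    inside = d2 <= radius * radius
    sub = data[i_lo[2]: i_hi[2] + 1, i_lo[1]: i_hi[1] + 1, i_lo[0]: i_hi[0] + 1]
    sub |= inside.astype(np.uint8)


# ---------------------------------------------------------------------------
# confocal rendering
# ---------------------------------------------------------------------------

def render_confocal(
    label: LabelVolume,
    psf_sigma_um: float = 2.0,
    signal: float = 150.0,
    background: float = 20.0,
    read_noise_sd: float = 8.0,
    shot_noise: bool = True,
    seed: int = 0,
) -> ImageVolume:
    """Render a labeled volume into a confocal-like grayscale stack.

    intensity = blur(label * signal) + background, then Poisson shot noise
    (photon-count statistics on the expected intensity) plus Gaussian read
    noise.  Deterministic for a fixed seed.
    """
    if psf_sigma_um < 0:
        raise ValueError("psf_sigma_um must be >= 0")
    if read_noise_sd < 0:
        raise ValueError("read noise level must be >= 0")
    rng = np.random.default_rng(seed)
    expected = label.data.astype(np.float64) * signal
    if psf_sigma_um > 0:
        expected = ndimage.gaussian_filter(expected, sigma=label.sigma_voxels(psf_sigma_um))
    expected += background
    img = rng.poisson(expected).astype(np.float64) if shot_noise else expected.copy()
    if read_noise_sd > 0:
        img += rng.normal(0.0, read_noise_sd, size=img.shape)
    return ImageVolume(data=img, spacing=label.spacing, origin=label.origin)
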