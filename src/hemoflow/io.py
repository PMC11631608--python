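"""File formats and reporting.

Volumes travel as multi-page TIFF with a JSON sidecar holding the voxel
spacing and origin (the TIFF itself is not trusted to carry physical units);
networks as JSON graph files; flow solutions and experiment summaries as CSV
and legacy-ASCII VTK polydata, one polyline per segment with per-segment
radius and field arrays.
"""
from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import tifffile

from .experiments import ExperimentResult, results_table
from .network import VesselNetwork
from .solver import FlowSolution
from .synthetic import ImageVolume, LabelVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_network",
    "write_network",
    "write_network_vtk",
    "write_solution_csv",
    "report",
]


class FormatError(ValueError):
    """A file could not be parsed; the message names the offending field."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume as multi-page TIFF plus a JSON spacing sidecar."""
    path = Path(path)
    data = volume.data
    if isinstance(volume, LabelVolume):
        data = data.astype(np.uint8)
    tifffile.imwrite(path, data)
    meta = {
        "spacing_um": list(volume.spacing),
        "origin_um": list(volume.origin),
        "kind": "label" if isinstance(volume, LabelVolume) else "image",
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_volume(path: str | Path) -> ImageVolume:
    """Read a TIFF volume; the spacing sidecar is required, never guessed."""
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FormatError(
            f"missing spacing sidecar {side.name}: voxel spacing is required metadata"
        )
    try:
        meta = json.loads(side.read_text())
        spacing = tuple(float(v) for v in meta["spacing_um"])
        origin = tuple(float(v) for v in meta.get("origin_um", (0.0, 0.0, 0.0)))
        kind = meta.get("kind", "image")
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed sidecar {side.name}: {exc}") from exc
    data = tifffile.imread(path)
    cls = LabelVolume if kind == "label" else ImageVolume
    return cls(data=data, spacing=spacing, origin=origin)


def write_network(network: VesselNetwork, path: str | Path) -> None:
    Path(path).write_text(network.to_json(indent=1))


def read_network(path: str | Path) -> VesselNetwork:
    return VesselNetwork.from_json(Path(path).read_text())


def write_network_vtk(
    network: VesselNetwork,
    path: str | Path,
    solution: FlowSolution | None = None,
) -> None:
    """Legacy-ASCII VTK polydata: one line cell per segment, with per-cell
    radius (µm) and, when a solution is given, wall shear stress (Pa),
    velocity (m/s) and flow (m³/s) arrays."""
    node_ids = sorted(network.positions)
    index = {n: i for i, n in enumerate(node_ids)}
    lines = [
        "# vtk DataFile Version 3.0",
        "vessel network",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(node_ids)} float",
    ]
    for n in node_ids:
        x, y, z = network.positions[n]
        lines.append(f"{x:.4f} {y:.4f} {z:.4f}")
    segs = network.segments
    lines.append(f"LINES {len(segs)} {3 * len(segs)}")
    for s in segs:
        lines.append(f"2 {index[s.a]} {index[s.b]}")
    lines.append(f"CELL_DATA {len(segs)}")
    arrays: list[tuple[str, list[float]]] = [("radius_um", [s.radius for s in segs])]
    if solution is not None:
        arrays += [
            ("wall_shear_stress_Pa", list(solution.wall_shear_stress)),
            ("velocity_m_s", list(solution.velocity)),
            ("flow_m3_s", list(solution.flow)),
        ]
    for name, vals in arrays:
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.6e}" for v in vals)
    Path(path).write_text("\n".join(lines) + "\n")


def write_solution_csv(network: VesselNetwork, solution: FlowSolution, path: str | Path) -> None:
    from .solver import wall_fields

    wall_fields(solution, network).to_csv(path, index=False)


def report(results: list[ExperimentResult], out_dir: str | Path) -> pd.DataFrame:
    """Summary table and figures for a scenario sweep.

    Writes ``summary.csv`` (one row per scenario), a bar chart of
    capillary-network mean wall shear stress by scenario, per-section bars,
    and a wall-shear-stress histogram (0-20+ Pa bins).  Returns the summary
    table.
    """
    if not results:
        raise ValueError("report requires at least one result")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = results_table(results)
    table.to_csv(out / "summary.csv", index=False)

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(table["scenario"], table["cap_mean_wss_Pa"], color="#8d1f1f")
    ax.set_ylabel("mean WSS, capillary network (Pa)")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(out / "mean_wss_by_scenario.png", dpi=120)
    plt.close(fig)

    sec_cols = [c for c in table.columns if c.startswith("section_")]
    if sec_cols:
        fig, ax = plt.subplots(figsize=(7, 4))
        width = 0.8 / len(sec_cols)
        xs = np.arange(len(table))
        for k, col in enumerate(sec_cols):
            ax.bar(xs + k * width, table[col], width, label=col.replace("_mean_wss_Pa", ""))
        ax.set_xticks(xs + 0.4, table["scenario"], rotation=45)
        ax.set_ylabel("mean WSS by radial section (Pa)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "mean_wss_by_section.png", dpi=120)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 4))
    bins = list(np.arange(0, 21, 2)) + [1e9]
    for r in results:
        if r.solution is None:
            continue
        counts, _ = np.histogram(r.solution.wall_shear_stress, bins=bins)
        ax.plot(np.arange(len(counts)) * 2 + 1, counts, marker="o", label=r.label)
    ax.set_xlabel("wall shear stress (Pa; last bin 20+)")
    ax.set_ylabel("segments")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "wss_histogram.png", dpi=120)
    plt.close(fig)
    return table
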