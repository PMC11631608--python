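"""Study design: pressure-scenario sweeps, capillary dropout, regional sectioning.

Capillary dropout emulates microvascular rarefaction: whole capillary
segments are removed at random until a target fraction of the baseline
capillary volume is gone, never severing the last arteriole-to-venule
pathway.  Scenarios pair a boundary-pressure preset with an optional dropout
and are summarised against the designated baseline (100/10 mmHg, intact
network).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import NetworkError, VesselNetwork, network_volume
from .rheology import RheologyParams
from .solver import (
    BoundaryConditions,
    ConvergenceError,
    FlowSolution,
    SolverOptions,
    solve_network,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DropoutSpec",
    "DropoutError",
    "Scenario",
    "ExperimentResult",
    "apply_dropout",
    "run_scenarios",
    "affected_area_stats",
    "AffectedAreaStats",
    "section_split",
]


class DropoutError(RuntimeError):
    """The requested dropout fraction cannot be reached without disconnecting
    every arteriole-to-venule pathway."""


@dataclass(frozen=True)
class DropoutSpec:
    """Volume-targeted random removal of capillary segments.

    ``fraction`` is the share of baseline capillary volume to remove;
    the achieved fraction is within ``tolerance`` of the target.
    """

    fraction: float
    seed: int = 0
    tolerance: float = 0.02
    vessel_class: str = "capillary"

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction < 1.0):
            raise ValueError("dropout fraction must lie in [0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


def _class_volume(network: VesselNetwork, vclass: str) -> float:
    return sum(
        math.pi * s.radius**2 * network.length(s)
        for s in network.segments
        if s.vessel_class == vclass
    )


def apply_dropout(network: VesselNetwork, spec: DropoutSpec) -> VesselNetwork:
    """Remove whole capillary segments at random until the target volume
    fraction is reached.

    A removal that would destroy all inlet-outlet connectivity is skipped and
    another candidate drawn.  Deterministic for a fixed (network, spec).
    Raises :class:`DropoutError` when the target is unreachable.
    """
    if spec.fraction == 0.0:
        return network.copy()
    base_volume = _class_volume(network, spec.vessel_class)
    if base_volume <= 0:
        raise DropoutError(f"network has no {spec.vessel_class} volume to remove")
    target = spec.fraction * base_volume
    tol_volume = spec.tolerance * base_volume

    rng = np.random.default_rng(spec.seed)
    candidates = [s for s in network.segments if s.vessel_class == spec.vessel_class]
    order = rng.permutation(len(candidates))

    # adjacency over segment ids for the connectivity guard
    adj: dict[int, set[int]] = {}
    seg_by_id = {s.id: s for s in network.segments}
    for s in network.segments:
        adj.setdefault(s.a, set()).add(s.id)
        adj.setdefault(s.b, set()).add(s.id)
    inlets = set(network.inlets())
    outlets = set(network.outlets())
    roots = inlets | outlets

    def survey(removed: set[int]) -> tuple[bool, set[int]]:
        """Nodes reachable from any root through surviving segments, plus
        whether some inlet still reaches some outlet."""
        stack = list(roots)
        seen = set(stack)
        while stack:
            n = stack.pop()
            for sid in adj.get(n, ()):
                if sid in removed:
                    continue
                s = seg_by_id[sid]
                m = s.b if s.a == n else s.a
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        stack = [n for n in inlets]
        seen_in = set(stack)
        ok = False
        while stack:
            n = stack.pop()
            if n in outlets:
                ok = True
                break
            for sid in adj.get(n, ()):
                if sid in removed:
                    continue
                s = seg_by_id[sid]
                m = s.b if s.a == n else s.a
                if m not in seen_in:
                    seen_in.add(m)
                    stack.append(m)
        return ok, seen

    def seg_volume(s) -> float:
        return math.pi * s.radius**2 * network.length(s)

    removed: set[int] = set()
    removed_volume = 0.0
    for idx in order:
        if removed_volume >= target - tol_volume:
            break
        s = candidates[idx]
        if s.id in removed:
            continue  # already stranded by an earlier removal
        v = seg_volume(s)
        if removed_volume + v > target + tol_volume:
            continue  # would overshoot; try a smaller candidate
        trial = removed | {s.id}
        ok, reachable = survey(trial)
        if not ok:
            continue  # guard: keep at least one perfusion path
        # capillaries stranded from every root are unperfused and count as
        # removed volume too
        islands = [
            t
            for t in candidates
            if t.id not in trial and t.a not in reachable and t.b not in reachable
        ]
        island_volume = sum(seg_volume(t) for t in islands)
        if removed_volume + v + island_volume > target + tol_volume:
            continue
        removed = trial | {t.id for t in islands}
        removed_volume += v + island_volume

    if removed_volume < target - tol_volume:
        raise DropoutError(
            f"could only remove {removed_volume / base_volume:.3f} of {spec.vessel_class} "
            f"volume (target {spec.fraction:.3f} ± {spec.tolerance}) without "
            "disconnecting all inlet-outlet paths"
        )

    out = network.copy()
    out.segments = [s for s in network.segments if s.id not in removed]
    used = {s.a for s in out.segments} | {s.b for s in out.segments} | set(out.roots)
    out.positions = {n: p for n, p in out.positions.items() if n in used}
    return out


def section_split(network: VesselNetwork, n_sections: int = 3) -> dict[int, int]:
    """Label every segment with a radial section 1..n from the field center.

    The optic-disc proxy sits at the in-plane center of the slab; sections
    are distance bands of equal width, section 1 innermost (closest to the
    disc).  Returns segment id -> section label.
    """
    if network.extents is None:
        raise NetworkError("section_split requires slab extents (optic-disc proxy at center)")
    cx, cy = network.extents[0] / 2.0, network.extents[1] / 2.0
    mids = {}
    for s in network.segments:
        pa = network.positions[s.a]
        pb = network.positions[s.b]
        mx = 0.5 * (pa[0] + pb[0]) - cx
        my = 0.5 * (pa[1] + pb[1]) - cy
        mids[s.id] = math.hypot(mx, my)
    if not mids:
        return {}
    r_min = min(mids.values())
    r_max = max(mids.values())
    if r_max == r_min:
        return {sid: 1 for sid in mids}
    width = (r_max - r_min) / n_sections
    return {
        sid: min(int((r - r_min) // width) + 1, n_sections)
        for sid, r in mids.items()
    }


@dataclass
class Scenario:
    """One experimental condition: a BC preset plus an optional dropout."""

    label: str
    bc_preset: str = "baseline"
    dropout: DropoutSpec | None = None


@dataclass
class ExperimentResult:
    """Per-scenario summary statistics and deltas versus the baseline."""

    label: str
    bc_preset: str
    dropout_fraction: float
    achieved_dropout_fraction: float
    n_segments: int
    mean_wss: float            # Pa, over all segments of this scenario's network
    max_wss: float             # Pa
    cap_mean_wss: float        # Pa, over the capillary network (paper's domain)
    cap_max_wss: float         # Pa
    mean_velocity: float       # m/s, mean |u|
    mean_pressure: float       # Pa, over nodes
    section_mean_wss: dict[int, float]
    pct_change_mean_wss: float | None = None    # vs baseline, surviving segments
    pct_change_mean_velocity: float | None = None
    delta_wss: dict[int, float] = field(default_factory=dict)  # per-segment Δτ_w (Pa)
    network: VesselNetwork | None = None
    solution: FlowSolution | None = None

    def summary_row(self) -> dict:
        return {
            "scenario": self.label,
            "bc_preset": self.bc_preset,
            "dropout_fraction": self.dropout_fraction,
            "achieved_dropout_fraction": self.achieved_dropout_fraction,
            "n_segments": self.n_segments,
            "mean_wss_Pa": self.mean_wss,
            "max_wss_Pa": self.max_wss,
            "cap_mean_wss_Pa": self.cap_mean_wss,
            "cap_max_wss_Pa": self.cap_max_wss,
            "mean_velocity_m_s": self.mean_velocity,
            "mean_pressure_Pa": self.mean_pressure,
            "pct_change_mean_wss": self.pct_change_mean_wss,
            "pct_change_mean_velocity": self.pct_change_mean_velocity,
            **{f"section_{k}_mean_wss_Pa": v for k, v in sorted(self.section_mean_wss.items())},
        }


def _percent_change(variant: float, baseline: float) -> float:
    return 100.0 * (variant - baseline) / baseline


def run_scenarios(
    network: VesselNetwork,
    scenarios: list[Scenario],
    params: RheologyParams | None = None,
    options: SolverOptions | None = None,
    n_sections: int = 3,
) -> list[ExperimentResult]:
    """Solve each scenario and summarise it against the designated baseline
    (baseline pressures, intact network).

    Percent changes are computed over the intersection of segments present in
    both scenario and baseline (for dropout variants: the surviving
    segments).  A solver failure aborts that scenario with a logged
    diagnostic; the others proceed.
    """
    params = params or RheologyParams()
    base_bc = BoundaryConditions.from_preset(network, "baseline")
    base_sol = solve_network(network, base_bc, params, options)
    base_wss = base_sol.wss_of()
    base_speed = {
        int(i): abs(float(u)) for i, u in zip(base_sol.segment_ids, base_sol.velocity)
    }
    base_cap_volume = _class_volume(network, "capillary")
    cap_class = {s.id: s.vessel_class == "capillary" for s in network.segments}

    results: list[ExperimentResult] = []
    for sc in scenarios:
        try:
            net = apply_dropout(network, sc.dropout) if sc.dropout else network
            bc = BoundaryConditions.from_preset(net, sc.bc_preset)
            sol = solve_network(net, bc, params, options)
        except (DropoutError, ConvergenceError, NetworkError) as exc:
            logger.error("scenario %r failed: %s", sc.label, exc)
            continue

        achieved = 0.0
        if sc.dropout:
            achieved = 1.0 - _class_volume(net, "capillary") / base_cap_volume

        wss = sol.wss_of()
        speed = {int(i): abs(float(u)) for i, u in zip(sol.segment_ids, sol.velocity)}
        # deltas vs baseline on the shared capillary bed: the paper's dropout
        # and pressure effects are reported for the capillary network, whose
        # WSS responds oppositely to the feeding arterioles under dropout
        common = sorted(i for i in set(wss) & set(base_wss) if cap_class.get(i))
        mean_wss_common = float(np.mean([wss[i] for i in common]))
        base_mean_wss_common = float(np.mean([base_wss[i] for i in common]))
        mean_u_common = float(np.mean([speed[i] for i in common]))
        base_mean_u_common = float(np.mean([base_speed[i] for i in common]))

        cap_ids = [s.id for s in net.segments if s.vessel_class == "capillary"]
        cap_wss = np.array([wss[i] for i in cap_ids])
        sections = section_split(net, n_sections)
        sec_means: dict[int, float] = {}
        for k in range(1, n_sections + 1):
            vals = [wss[i] for i in cap_ids if sections[i] == k]
            sec_means[k] = float(np.mean(vals)) if vals else float("nan")

        results.append(
            ExperimentResult(
                label=sc.label,
                bc_preset=sc.bc_preset,
                dropout_fraction=sc.dropout.fraction if sc.dropout else 0.0,
                achieved_dropout_fraction=achieved,
                n_segments=net.n_segments,
                mean_wss=sol.mean_wss,
                max_wss=sol.max_wss,
                cap_mean_wss=float(np.mean(cap_wss)) if cap_ids else float("nan"),
                cap_max_wss=float(np.max(cap_wss)) if cap_ids else float("nan"),
                mean_velocity=sol.mean_velocity,
                mean_pressure=float(np.mean(list(sol.node_pressure.values()))),
                section_mean_wss=sec_means,
                pct_change_mean_wss=_percent_change(mean_wss_common, base_mean_wss_common),
                pct_change_mean_velocity=_percent_change(mean_u_common, base_mean_u_common),
                delta_wss={i: wss[i] - base_wss[i] for i in common},
                network=net,
                solution=sol,
            )
        )
    return results


@dataclass
class AffectedAreaStats:
    """Wall-shear-stress disturbance among segments bordering a dropout."""

    affected_ids: list[int]
    pct_change: dict[int, float]   # per affected segment, 100*(variant-baseline)/baseline
    max_abs_pct_change: float      # 0.0 when the affected set is empty


def affected_area_stats(
    baseline_network: VesselNetwork,
    baseline_solution: FlowSolution,
    variant_network: VesselNetwork,
    variant_solution: FlowSolution,
) -> AffectedAreaStats:
    """Per-segment percent WSS change over the affected area of a dropout.

    Affected segments are the surviving segments that share a node with a
    removed segment (1-hop neighbors of the lesion).  An intact variant
    yields a defined empty result.
    """
    surviving = {s.id for s in variant_network.segments}
    removed = [s for s in baseline_network.segments if s.id not in surviving]
    removed_nodes = {n for s in removed for n in (s.a, s.b)}
    affected = sorted(
        s.id
        for s in variant_network.segments
        if s.a in removed_nodes or s.b in removed_nodes
    )
    base_wss = baseline_solution.wss_of()
    var_wss = variant_solution.wss_of()
    # floor: percent change is only meaningful where the baseline carried
    # appreciable shear (1% of the baseline network mean)
    floor = 0.01 * float(np.mean(list(base_wss.values())))
    pct = {
        i: _percent_change(var_wss[i], base_wss[i])
        for i in affected
        if base_wss.get(i, 0.0) > floor
    }
    max_abs = max((abs(v) for v in pct.values()), default=0.0)
    return AffectedAreaStats(affected_ids=affected, pct_change=pct, max_abs_pct_change=max_abs)


def results_table(results: list[ExperimentResult]) -> pd.DataFrame:
    """Tidy one-row-per-scenario summary."""
    return pd.DataFrame([r.summary_row() for r in results])
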