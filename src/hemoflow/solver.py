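"""Steady non-Newtonian flow on a vessel network.

Each segment is treated as a rigid tube in fully developed flow; nodal mass
conservation (Kirchhoff) with Dirichlet pressures at tagged terminals closes
the system.  The shear-thinning constitutive law couples viscosity to flow,
so segment conductances are updated by Picard iteration with under-relaxation
until the flow field is self-consistent.

Per-segment momentum balance makes the wall shear stress exact given the
converged pressure drop:  τ_w = |Δp|·R / (2L).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .network import ARTERIOLE_INLET, VENULE_OUTLET, NetworkError, VesselNetwork
from .rheology import FlowTable, RheologyParams, _shear_rate_many

__all__ = [
    "MMHG_TO_PA",
    "to_pascal",
    "BoundaryConditions",
    "SolverOptions",
    "FlowSolution",
    "ConvergenceError",
    "solve_network",
    "wall_fields",
    "BC_PRESETS_MMHG",
]

MMHG_TO_PA = 133.322

#: named arteriole/venule pressure scenarios (mmHg): baseline plus the
#: elevated-arteriole and elevated-venule sweeps.
BC_PRESETS_MMHG: dict[str, tuple[float, float]] = {
    "baseline": (100.0, 10.0),
    "elevated_arteriole_1": (130.0, 10.0),
    "elevated_arteriole_2": (150.0, 10.0),
    "elevated_venule_1": (100.0, 30.0),
    "elevated_venule_2": (100.0, 50.0),
}


def to_pascal(value: float, unit: str) -> float:
    """Convert a pressure to Pa.  Accepted units: ``mmHg``, ``Pa``."""
    if unit == "Pa":
        return float(value)
    if unit == "mmHg":
        return float(value) * MMHG_TO_PA
    raise ValueError(f"unknown pressure unit {unit!r}")


@dataclass(frozen=True)
class BoundaryConditions:
    """Dirichlet pressures (Pa) at terminal nodes."""

    pressures: dict[int, float]
    label: str = "custom"

    @classmethod
    def from_preset(cls, network: VesselNetwork, name: str) -> "BoundaryConditions":
        """Build BCs from a named preset: every arteriole inlet gets the
        arteriole pressure, every venule outlet the venule pressure."""
        try:
            p_art_mmhg, p_ven_mmhg = BC_PRESETS_MMHG[name]
        except KeyError:
            raise ValueError(
                f"unknown BC preset {name!r}; available: {sorted(BC_PRESETS_MMHG)}"
            ) from None
        if p_art_mmhg <= p_ven_mmhg:
            raise ValueError("arteriole pressure must exceed venule pressure")
        pressures: dict[int, float] = {}
        for node, tag in network.roots.items():
            if tag == ARTERIOLE_INLET:
                pressures[node] = to_pascal(p_art_mmhg, "mmHg")
            elif tag == VENULE_OUTLET:
                pressures[node] = to_pascal(p_ven_mmhg, "mmHg")
        return cls(pressures=pressures, label=name)

    def validate_against(self, network: VesselNetwork) -> None:
        for node in network.roots:
            if node not in self.pressures:
                raise ValueError(f"tagged terminal node {node} has no boundary pressure")
        for node in self.pressures:
            if node not in network.positions:
                raise ValueError(f"boundary node {node} is not in the network")


@dataclass(frozen=True)
class SolverOptions:
    tolerance: float = 1e-6      # relative change in segment flows
    relaxation: float = 0.5      # Picard under-relaxation on conductances
    max_iter: int = 200

    def __post_init__(self) -> None:
        if not (0 < self.relaxation <= 1):
            raise ValueError("relaxation must lie in (0, 1]")
        if self.tolerance <= 0 or self.max_iter < 1:
            raise ValueError("tolerance must be > 0 and max_iter >= 1")


class ConvergenceError(RuntimeError):
    """Picard iteration failed; carries the residual history."""

    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


@dataclass
class FlowSolution:
    """Converged flow field on a network.

    All per-segment arrays are aligned with ``network.segments`` order and
    SI-valued: pressures Pa, flows m³/s (positive a→b), velocities m/s,
    shear rates 1/s, stresses Pa, viscosities Pa·s.
    """

    node_pressure: dict[int, float]
    segment_ids: np.ndarray
    flow: np.ndarray
    velocity: np.ndarray
    wall_shear_rate: np.ndarray
    wall_shear_stress: np.ndarray
    effective_viscosity: np.ndarray
    reynolds: np.ndarray
    iterations: int
    residual: float
    converged: bool
    residual_history: list[float] = field(default_factory=list)
    bc_label: str = "custom"

    @property
    def mean_wss(self) -> float:
        return float(np.mean(self.wall_shear_stress))

    @property
    def max_wss(self) -> float:
        return float(np.max(self.wall_shear_stress))

    @property
    def mean_velocity(self) -> float:
        return float(np.mean(np.abs(self.velocity)))

    def wss_of(self) -> dict[int, float]:
        return {int(i): float(t) for i, t in zip(self.segment_ids, self.wall_shear_stress)}

    def total_inflow(self, network: VesselNetwork) -> float:
        """Net flow entering through arteriole inlets (m³/s)."""
        return self._net_root_flow(network, ARTERIOLE_INLET)

    def total_outflow(self, network: VesselNetwork) -> float:
        """Net flow leaving through venule outlets (m³/s)."""
        return -self._net_root_flow(network, VENULE_OUTLET)

    def _net_root_flow(self, network: VesselNetwork, tag: str) -> float:
        nodes = {n for n, t in network.roots.items() if t == tag}
        total = 0.0
        for s, q in zip(network.segments, self.flow):
            if s.a in nodes:
                total += q
            if s.b in nodes:
                total -= q
        return float(total)


def _check_terminals_connected(network: VesselNetwork, bc: BoundaryConditions) -> None:
    """Every node must be reachable from a boundary node, or the nodal system
    would be singular; report the offending node."""
    adj: dict[int, set[int]] = {}
    for s in network.segments:
        adj.setdefault(s.a, set()).add(s.b)
        adj.setdefault(s.b, set()).add(s.a)
    seen = set(bc.pressures)
    stack = list(seen)
    while stack:
        n = stack.pop()
        for m in adj.get(n, ()):
            if m not in seen:
                seen.add(m)
                stack.append(m)
    for n in bc.pressures:
        if n not in adj:
            raise NetworkError(f"boundary terminal node {n} is disconnected from the network")
    for n in adj:
        if n not in seen:
            raise NetworkError(
                f"node {n} is unreachable from every boundary terminal; "
                "the pressure field there is undefined"
            )


def solve_network(
    network: VesselNetwork,
    bc: BoundaryConditions,
    params: RheologyParams | None = None,
    options: SolverOptions | None = None,
) -> FlowSolution:
    """Solve steady network flow under Dirichlet pressure boundary conditions.

    Picard scheme: conductances start from Hagen–Poiseuille at the zero-shear
    viscosity η0; each sweep solves the sparse nodal system for interior
    pressures, recomputes segment flows from the full tube-flow law at the
    current pressure drops, and blends the implied conductances with
    under-relaxation.  Converged when the maximum change in segment flow,
    relative to the largest flow magnitude, falls below ``options.tolerance``.
    """
    params = params or RheologyParams()
    options = options or SolverOptions()
    if not network.segments:
        raise NetworkError("cannot solve an empty network")
    bc.validate_against(network)
    if len(bc.pressures) < 2:
        raise ValueError("need at least two boundary pressures to drive flow")
    _check_terminals_connected(network, bc)

    # position-only nodes (no incident segment) have no equation; exclude them
    used = {s.a for s in network.segments} | {s.b for s in network.segments}
    if used != set(network.positions):
        network = network.copy()
        network.positions = {n: p for n, p in network.positions.items() if n in used}
    node_ids, index_of, a_idx, b_idx, radius_um, length_um = network.arrays()
    n_nodes = len(node_ids)
    R = radius_um * 1e-6
    L = length_um * 1e-6

    dirichlet = np.zeros(n_nodes, dtype=bool)
    p_fixed = np.zeros(n_nodes)
    for node, p in bc.pressures.items():
        i = index_of[node]
        dirichlet[i] = True
        p_fixed[i] = p
    interior = ~dirichlet
    int_index = -np.ones(n_nodes, dtype=np.intp)
    int_index[interior] = np.arange(int(interior.sum()))

    table = FlowTable(params)
    G = np.pi * R**4 / (8.0 * params.eta0 * L)  # initial conductances at η0
    q_prev = np.zeros_like(G)
    p = p_fixed.copy()
    history: list[float] = []
    iterations = 0
    newtonian = params.is_newtonian

    for iterations in range(1, options.max_iter + 1):
        p = _solve_pressures(G, a_idx, b_idx, dirichlet, p_fixed, int_index, n_nodes)
        dp = p[a_idx] - p[b_idx]
        q_new = table.tube_flow_many(R, L, dp)
        scale = np.max(np.abs(q_new))
        if scale == 0.0:
            residual = 0.0
        else:
            residual = float(np.max(np.abs(q_new - q_prev)) / scale)
        history.append(residual)
        q_prev = q_new
        if residual < options.tolerance and iterations > 1:
            break
        if newtonian:
            # conductances are exact; one more sweep only confirms convergence
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            g_implied = np.where(np.abs(dp) > 0, np.abs(q_new) / np.abs(dp), G)
        G = (1.0 - options.relaxation) * G + options.relaxation * g_implied
    else:
        raise ConvergenceError(
            f"Picard iteration did not converge in {options.max_iter} sweeps "
            f"(last residual {history[-1]:.3e})",
            history,
        )

    # final consistent field: pressures from the last solve; flows from the
    # conductances of that solve so Kirchhoff holds to linear-solver precision
    dp = p[a_idx] - p[b_idx]
    Q = G * dp if not newtonian else q_prev
    tau_w = np.abs(dp) * R / (2.0 * L)
    gamma_w = _shear_rate_many(tau_w, params) if not newtonian else tau_w / params.eta0
    with np.errstate(divide="ignore", invalid="ignore"):
        eta_eff = np.where(gamma_w > 0, tau_w / gamma_w, params.eta0)
    u = Q / (np.pi * R**2)
    reynolds = params.rho * np.abs(u) * 2.0 * R / eta_eff

    return FlowSolution(
        node_pressure={n: float(p[index_of[n]]) for n in node_ids},
        segment_ids=np.array([s.id for s in network.segments], dtype=np.intp),
        flow=Q,
        velocity=u,
        wall_shear_rate=np.asarray(gamma_w, dtype=float),
        wall_shear_stress=tau_w,
        effective_viscosity=np.asarray(eta_eff, dtype=float),
        reynolds=reynolds,
        iterations=iterations,
        residual=history[-1],
        converged=True,
        residual_history=history,
        bc_label=bc.label,
    )


def _solve_pressures(G, a_idx, b_idx, dirichlet, p_fixed, int_index, n_nodes):
    """Assemble and solve the reduced symmetric nodal system for interior pressures."""
    n_int = int((~dirichlet).sum())
    p = p_fixed.copy()
    if n_int == 0:
        return p
    rows, cols, vals = [], [], []
    rhs = np.zeros(n_int)
    for i_end, j_end in ((a_idx, b_idx), (b_idx, a_idx)):
        m = ~dirichlet[i_end]
        im = int_index[i_end[m]]
        jm = j_end[m]
        gm = G[m]
        rows.append(im)
        cols.append(im)
        vals.append(gm)  # diagonal
        j_is_int = ~dirichlet[jm]
        rows.append(im[j_is_int])
        cols.append(int_index[jm[j_is_int]])
        vals.append(-gm[j_is_int])
        np.add.at(rhs, im[~j_is_int], gm[~j_is_int] * p_fixed[jm[~j_is_int]])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    A = sparse.coo_matrix((vals, (rows, cols)), shape=(n_int, n_int)).tocsr()
    p_int = spsolve(A, rhs)
    p[~dirichlet] = p_int
    return p


def wall_fields(solution: FlowSolution, network: VesselNetwork):
    """Per-segment wall quantities (τ_w Pa, γ̇_w 1/s, u m/s) as a DataFrame."""
    import pandas as pd

    if not solution.converged:
        raise ConvergenceError("wall_fields requires a converged solution", solution.residual_history)
    return pd.DataFrame(
        {
            "segment_id": solution.segment_ids,
            "vessel_class": [s.vessel_class for s in network.segments],
            "wall_shear_stress_Pa": solution.wall_shear_stress,
            "wall_shear_rate_per_s": solution.wall_shear_rate,
            "velocity_m_per_s": solution.velocity,
            "flow_m3_per_s": solution.flow,
            "effective_viscosity_Pa_s": solution.effective_viscosity,
        }
    )
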