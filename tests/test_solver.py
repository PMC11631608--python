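import math

import numpy as np
import pytest

from hemoflow.network import NetworkError, Segment, VesselNetwork
from hemoflow.rheology import RheologyParams
from hemoflow.solver import (
    MMHG_TO_PA,
    BoundaryConditions,
    ConvergenceError,
    SolverOptions,
    solve_network,
    to_pascal,
    wall_fields,
)

from conftest import random_network, single_tube

CY = RheologyParams()


class TestUnits:
    @pytest.mark.parametrize("mmhg,pa", [(100.0, 13332.2), (10.0, 1333.22), (0.0, 0.0)])
    def test_mmhg_conversion(self, mmhg, pa):
        assert to_pascal(mmhg, "mmHg") == pytest.approx(pa, abs=1e-9)

    def test_pascal_passthrough_and_unknown_unit(self):
        assert to_pascal(5.0, "Pa") == 5.0
        with pytest.raises(ValueError):
            to_pascal(5.0, "torr")

    def test_presets_require_positive_perfusion_pressure(self, default_network):
        with pytest.raises(ValueError):
            BoundaryConditions.from_preset(default_network, "no_such_preset")


class TestSingleTube:
    def test_hagen_poiseuille_at_baseline_pressures(self):
        net = single_tube(radius_um=3.5, length_um=100.0)
        bc = BoundaryConditions.from_preset(net, "baseline")
        eta = 0.0035
        sol = solve_network(net, bc, RheologyParams.newtonian(eta))
        dp = 90.0 * MMHG_TO_PA
        assert dp == pytest.approx(11998.98, abs=1e-6)
        q_expect = math.pi * (3.5e-6) ** 4 * dp / (8 * eta * 100e-6)
        assert sol.flow[0] == pytest.approx(q_expect, rel=1e-12)
        assert sol.wall_shear_stress[0] == pytest.approx(dp * 3.5e-6 / (2 * 100e-6), rel=1e-12)

    def test_two_parallel_tubes_split_evenly(self):
        net = VesselNetwork(
            positions={0: (0, 0, 0), 1: (100, 0, 0), 2: (50, 50, 0), 3: (50, -50, 0)},
            segments=[
                Segment(0, 0, 2, 3.0),
                Segment(1, 2, 1, 3.0),
                Segment(2, 0, 3, 3.0),
                Segment(3, 3, 1, 3.0),
            ],
            roots={0: "arteriole_inlet", 1: "venule_outlet"},
        )
        sol = solve_network(net, BoundaryConditions.from_preset(net, "baseline"), CY)
        assert sol.flow == pytest.approx(np.full(4, sol.flow[0]), rel=1e-9)
        assert sol.total_inflow(net) == pytest.approx(2 * sol.flow[0], rel=1e-9)


class TestNetworkSolve:
    def test_newtonian_matches_dense_linear_solve(self):
        net = random_network()
        eta = 0.004
        bc = BoundaryConditions.from_preset(net, "baseline")
        sol = solve_network(net, bc, RheologyParams.newtonian(eta))

        node_ids, index_of, a_idx, b_idx, r_um, l_um = net.arrays()
        R, L = r_um * 1e-6, l_um * 1e-6
        G = np.pi * R**4 / (8 * eta * L)
        n = len(node_ids)
        A = np.zeros((n, n))
        rhs = np.zeros(n)
        for k in range(len(net.segments)):
            i, j = a_idx[k], b_idx[k]
            A[i, i] += G[k]
            A[j, j] += G[k]
            A[i, j] -= G[k]
            A[j, i] -= G[k]
        for node, p_fix in bc.pressures.items():
            i = index_of[node]
            A[i, :] = 0.0
            A[i, i] = 1.0
            rhs[i] = p_fix
        p_dense = np.linalg.solve(A, rhs)
        for node in node_ids:
            assert sol.node_pressure[node] == pytest.approx(p_dense[index_of[node]], rel=1e-9)

    def test_interior_mass_conservation_and_global_balance(self):
        net = random_network(seed=5)
        bc = BoundaryConditions.from_preset(net, "baseline")
        sol = solve_network(net, bc, CY)
        residual = {}
        for k, s in enumerate(net.segments):
            residual[s.a] = residual.get(s.a, 0.0) - sol.flow[k]
            residual[s.b] = residual.get(s.b, 0.0) + sol.flow[k]
        q_scale = np.max(np.abs(sol.flow))
        for node, r in residual.items():
            if node not in bc.pressures:
                assert abs(r) < 1e-9 * q_scale
        assert sol.total_inflow(net) == pytest.approx(sol.total_outflow(net), rel=1e-9)

    def test_newtonian_linearity_in_driving_pressure(self):
        """Scaling all boundary pressure differences by α scales every field by α."""
        net = random_network(seed=11)
        eta = RheologyParams.newtonian(0.004)
        p_ref = 1000.0
        bc1 = BoundaryConditions({0: 2 * p_ref, 1: p_ref})
        bc2 = BoundaryConditions({0: 4 * p_ref, 1: p_ref})  # differences scaled by 3
        base = solve_network(net, bc1, eta)
        scaled = solve_network(net, bc2, eta)
        assert scaled.flow == pytest.approx(3.0 * base.flow, rel=1e-9)
        assert scaled.wall_shear_stress == pytest.approx(3.0 * base.wall_shear_stress, rel=1e-9)

    def test_cy_bracketing(self):
        """Total CY inflow lies strictly between the η0 and η∞ Newtonian inflows;
        per-segment flows are bracketed up to flow-split redistribution."""
        net = random_network(seed=21)
        bc = BoundaryConditions.from_preset(net, "baseline")
        cy = solve_network(net, bc, CY)
        lo = solve_network(net, bc, RheologyParams.newtonian(CY.eta0))
        hi = solve_network(net, bc, RheologyParams.newtonian(CY.eta_inf))
        assert lo.total_inflow(net) < cy.total_inflow(net) < hi.total_inflow(net)
        scale = np.max(np.abs(hi.flow))
        assert np.all(np.abs(cy.flow) <= np.abs(hi.flow) + 1e-3 * scale)
        assert np.all(np.abs(cy.flow) >= np.abs(lo.flow) - 1e-3 * scale)

    def test_venule_pressure_monotonicity(self, default_network):
        """Raising venule pressure at fixed arteriole pressure lowers every τ_w."""
        taus = []
        for preset in ("baseline", "elevated_venule_1", "elevated_venule_2"):
            bc = BoundaryConditions.from_preset(default_network, preset)
            taus.append(solve_network(default_network, bc, CY).wall_shear_stress)
        assert np.all(taus[1] <= taus[0] + 1e-12)
        assert np.all(taus[2] <= taus[1] + 1e-12)

    def test_nonconvergence_raises_with_history(self):
        net = random_network(seed=2)
        bc = BoundaryConditions.from_preset(net, "baseline")
        with pytest.raises(ConvergenceError) as exc:
            solve_network(net, bc, CY, SolverOptions(max_iter=1))
        assert exc.value.residual_history

    def test_disconnected_terminal_named_in_error(self):
        net = single_tube()
        net.positions[9] = (500.0, 0.0, 0.0)
        net.roots[9] = "venule_outlet"
        bc = BoundaryConditions.from_preset(net, "baseline")
        with pytest.raises(NetworkError, match="9"):
            solve_network(net, bc, CY)


class TestWallFields:
    def test_zero_drop_zero_fields(self):
        # a dangling side branch carries no flow: τ_w = 0, u = 0
        net = VesselNetwork(
            positions={0: (0, 0, 0), 1: (100, 0, 0), 2: (50, 0, 0), 3: (50, 60, 0)},
            segments=[Segment(0, 0, 2, 3.0), Segment(1, 2, 1, 3.0), Segment(2, 2, 3, 3.0)],
            roots={0: "arteriole_inlet", 1: "venule_outlet"},
        )
        sol = solve_network(net, BoundaryConditions.from_preset(net, "baseline"), CY)
        df = wall_fields(sol, net)
        side = df[df.segment_id == 2].iloc[0]
        assert abs(side.wall_shear_stress_Pa) < 1e-9
        assert abs(side.velocity_m_per_s) < 1e-12

    def test_momentum_balance_example(self):
        # Δp = 285.7 Pa over R = 3.5 µm, L = 100 µm gives τ_w = 5 Pa
        assert 285.7 * 3.5e-6 / (2 * 100e-6) == pytest.approx(5.0, abs=2e-3)
        net = single_tube(radius_um=3.5, length_um=100.0)
        bc = BoundaryConditions({0: 285.7, 1: 0.0})
        sol = solve_network(net, bc, CY)
        assert sol.wall_shear_stress[0] == pytest.approx(5.0, abs=2e-3)

    def test_newtonian_wall_shear_rate_formula(self):
        net = single_tube(radius_um=3.5, length_um=100.0)
        bc = BoundaryConditions.from_preset(net, "baseline")
        eta = RheologyParams.newtonian(0.0035)
        sol = solve_network(net, bc, eta)
        R = 3.5e-6
        assert sol.wall_shear_rate[0] == pytest.approx(4 * sol.flow[0] / (math.pi * R**3), rel=1e-6)

    def test_constitutive_consistency(self, default_network, baseline_solution):
        """τ_w equals η(γ̇_w)·γ̇_w for every segment of the converged solution."""
        from hemoflow.rheology import cy_viscosity

        tau = baseline_solution.wall_shear_stress
        gw = baseline_solution.wall_shear_rate
        recon = cy_viscosity(gw, CY) * gw
        assert recon == pytest.approx(tau, rel=1e-7, abs=1e-12)

    def test_unconverged_solution_rejected(self, default_network, baseline_solution):
        import dataclasses

        broken = dataclasses.replace(baseline_solution, converged=False)
        with pytest.raises(ConvergenceError):
            wall_fields(broken, default_network)
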