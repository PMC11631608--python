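import math

import numpy as np
import pytest

from hemoflow.experiments import (
    DropoutError,
    DropoutSpec,
    Scenario,
    affected_area_stats,
    apply_dropout,
    run_scenarios,
    section_split,
)
from hemoflow.network import Segment, VesselNetwork, network_volume
from hemoflow.rheology import RheologyParams
from hemoflow.solver import BoundaryConditions, solve_network


def _capillary_volume(net):
    return sum(
        math.pi * s.radius**2 * net.length(s)
        for s in net.segments
        if s.vessel_class == "capillary"
    )


class TestDropout:
    def test_zero_fraction_is_identity(self, default_network):
        out = apply_dropout(default_network, DropoutSpec(0.0, seed=1))
        assert out.to_json() == default_network.to_json()

    def test_target_volume_reached_within_tolerance(self, default_network):
        base = _capillary_volume(default_network)
        out = apply_dropout(default_network, DropoutSpec(0.30, seed=1))
        removed = 1.0 - _capillary_volume(out) / base
        assert removed == pytest.approx(0.30, abs=0.02)

    def test_deterministic(self, default_network):
        a = apply_dropout(default_network, DropoutSpec(0.30, seed=3))
        b = apply_dropout(default_network, DropoutSpec(0.30, seed=3))
        assert a.to_json() == b.to_json()

    def test_only_capillaries_removed_ids_stable(self, default_network):
        out = apply_dropout(default_network, DropoutSpec(0.30, seed=1))
        before = {s.id: s for s in default_network.segments}
        for s in out.segments:
            assert before[s.id] == s  # surviving segments unchanged, no new ones
        removed = set(before) - {s.id for s in out.segments}
        assert removed and all(before[i].vessel_class == "capillary" for i in removed)

    def test_perfusion_path_retained(self, default_network):
        out = apply_dropout(default_network, DropoutSpec(0.50, seed=1))
        assert out.has_inlet_outlet_path()

    def test_unreachable_target_fails(self):
        # one bridging capillary: any removal severs the only perfusion path
        net = VesselNetwork(
            positions={0: (0, 0, 0), 1: (100, 0, 0)},
            segments=[Segment(0, 0, 1, 3.0, "capillary")],
            roots={0: "arteriole_inlet", 1: "venule_outlet"},
        )
        with pytest.raises(DropoutError):
            apply_dropout(net, DropoutSpec(0.90, seed=1))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            DropoutSpec(1.0)

    def test_mean_capillary_wss_nondecreasing_in_dropout(self, default_network, rheo):
        """Rarefaction concentrates perfusion: the surviving capillary bed
        sees equal or higher mean wall shear stress as dropout deepens
        (ensemble over 5 seeds)."""
        fractions = (0.0, 0.10, 0.30, 0.50)
        means = {f: [] for f in fractions}
        bc0 = BoundaryConditions.from_preset(default_network, "baseline")
        base_sol = solve_network(default_network, bc0, rheo)
        for seed in range(1, 6):
            for f in fractions:
                net = (
                    default_network
                    if f == 0.0
                    else apply_dropout(default_network, DropoutSpec(f, seed=seed))
                )
                sol = (
                    base_sol
                    if f == 0.0
                    else solve_network(net, BoundaryConditions.from_preset(net, "baseline"), rheo)
                )
                caps = [k for k, s in enumerate(net.segments) if s.vessel_class == "capillary"]
                means[f].append(float(np.mean(sol.wall_shear_stress[caps])))
        ensemble = [float(np.mean(means[f])) for f in fractions]
        assert all(b >= a - 1e-9 for a, b in zip(ensemble, ensemble[1:]))


class TestSections:
    def test_partition_exhaustive_and_in_range(self, default_network):
        labels = section_split(default_network, 3)
        assert set(labels) == {s.id for s in default_network.segments}
        assert set(labels.values()) <= {1, 2, 3}
        assert set(labels.values()) == {1, 2, 3}

    def test_innermost_segment_closest_to_disc(self, default_network):
        labels = section_split(default_network, 3)
        cx, cy = 1150.0, 1150.0
        r_of = {}
        for s in default_network.segments:
            pa, pb = default_network.positions[s.a], default_network.positions[s.b]
            r_of[s.id] = math.hypot((pa[0] + pb[0]) / 2 - cx, (pa[1] + pb[1]) / 2 - cy)
        innermost = min(r_of, key=r_of.get)
        assert labels[innermost] == 1

    def test_uniform_plexus_band_counts_match_annulus_areas(self):
        """Segments spread uniformly over a disc fall into radial bands in
        proportion to the analytic annulus areas."""
        rng = np.random.default_rng(0)
        R_disc = 1000.0
        positions, segments = {}, []
        for i in range(4000):
            r = R_disc * math.sqrt(rng.uniform())
            t = rng.uniform(0, 2 * math.pi)
            x, y = 1150 + r * math.cos(t), 1150 + r * math.sin(t)
            positions[2 * i] = (x - 1, y, 30.0)
            positions[2 * i + 1] = (x + 1, y, 30.0)
            segments.append(Segment(i, 2 * i, 2 * i + 1, 2.0))
        net = VesselNetwork(
            positions=positions,
            segments=segments,
            roots={0: "arteriole_inlet", 3: "venule_outlet"},
            extents=(2300.0, 2300.0, 60.0),
        )
        labels = section_split(net, 3)
        counts = np.bincount(list(labels.values()))[1:]
        # bands are equal-width in radius: expected share ∝ annulus area
        edges = np.linspace(min(_all_radii(net)), max(_all_radii(net)), 4)
        areas = np.diff(edges**2)
        expected = areas / areas.sum() * counts.sum()
        assert counts == pytest.approx(expected, rel=0.10)


def _all_radii(net):
    cx, cy = 1150.0, 1150.0
    out = []
    for s in net.segments:
        pa, pb = net.positions[s.a], net.positions[s.b]
        out.append(math.hypot((pa[0] + pb[0]) / 2 - cx, (pa[1] + pb[1]) / 2 - cy))
    return out


def _radii(net, labels, k):
    cx, cy = 1150.0, 1150.0
    for s in net.segments:
        if labels[s.id] == k:
            pa, pb = net.positions[s.a], net.positions[s.b]
            yield math.hypot((pa[0] + pb[0]) / 2 - cx, (pa[1] + pb[1]) / 2 - cy)


class TestScenarios:
    def test_baseline_versus_itself_has_zero_deltas(self, default_network):
        results = run_scenarios(default_network, [Scenario(label="baseline")])
        r = results[0]
        assert r.pct_change_mean_wss == pytest.approx(0.0, abs=1e-9)
        assert r.pct_change_mean_velocity == pytest.approx(0.0, abs=1e-9)
        assert all(abs(d) < 1e-12 for d in r.delta_wss.values())

    def test_newtonian_pressure_sweeps_follow_linearity(self, default_network):
        """For a Newtonian fluid the percent change of mean WSS under a
        boundary-pressure change is exactly the perfusion-pressure ratio,
        independent of geometry: venule 10→30 mmHg gives -22.22%, arteriole
        100→130 mmHg gives +33.33%."""
        newton = RheologyParams.newtonian(0.004)
        results = run_scenarios(
            default_network,
            [
                Scenario(label="ven", bc_preset="elevated_venule_1"),
                Scenario(label="art", bc_preset="elevated_arteriole_1"),
            ],
            params=newton,
        )
        by_label = {r.label: r for r in results}
        assert by_label["ven"].pct_change_mean_wss == pytest.approx(-100 * 20 / 90, rel=1e-6)
        assert by_label["art"].pct_change_mean_wss == pytest.approx(+100 * 30 / 90, rel=1e-6)

    def test_summary_row_fields(self, default_network):
        r = run_scenarios(default_network, [Scenario(label="baseline")])[0]
        row = r.summary_row()
        assert row["n_segments"] == default_network.n_segments
        assert row["cap_mean_wss_Pa"] > 0
        assert {"section_1_mean_wss_Pa", "section_2_mean_wss_Pa", "section_3_mean_wss_Pa"} <= set(row)


class TestAffectedArea:
    def test_intact_variant_yields_empty_result(self, default_network, baseline_solution):
        stats = affected_area_stats(
            default_network, baseline_solution, default_network, baseline_solution
        )
        assert stats.affected_ids == []
        assert stats.max_abs_pct_change == 0.0

    def test_parallel_tube_removal_raises_survivor_wss(self):
        """With a shared feeding resistance, removing one of two parallel
        tubes strictly increases the survivor's wall shear stress."""
        positions = {0: (0, 0, 0), 1: (100, 0, 0), 2: (150, 40, 0), 3: (150, -40, 0), 4: (220, 0, 0)}
        segments = [
            Segment(0, 0, 1, 6.0, "arteriole_2"),
            Segment(1, 1, 2, 3.0, "capillary"),
            Segment(2, 1, 3, 3.0, "capillary"),
            Segment(3, 2, 4, 3.0, "capillary"),
            Segment(4, 3, 4, 3.0, "capillary"),
        ]
        net = VesselNetwork(positions=positions, segments=segments, roots={0: "arteriole_inlet", 4: "venule_outlet"})
        rheo = RheologyParams()
        bc = BoundaryConditions.from_preset(net, "baseline")
        base = solve_network(net, bc, rheo)
        variant = net.copy()
        variant.segments = [s for s in net.segments if s.id not in (2, 4)]
        bc2 = BoundaryConditions.from_preset(variant, "baseline")
        sol2 = solve_network(variant, bc2, rheo)
        stats = affected_area_stats(net, base, variant, sol2)
        assert stats.pct_change[1] > 0  # surviving branch sees higher τ_w
        assert stats.pct_change[3] > 0

    def test_max_matches_recomputation_from_raw_fields(self, default_network, baseline_solution, rheo):
        variant = apply_dropout(default_network, DropoutSpec(0.30, seed=1))
        sol = solve_network(variant, BoundaryConditions.from_preset(variant, "baseline"), rheo)
        stats = affected_area_stats(default_network, baseline_solution, variant, sol)
        base_wss = baseline_solution.wss_of()
        var_wss = sol.wss_of()
        floor = 0.01 * np.mean(list(base_wss.values()))
        manual = max(
            abs(100 * (var_wss[i] - base_wss[i]) / base_wss[i])
            for i in stats.affected_ids
            if base_wss[i] > floor
        )
        assert stats.max_abs_pct_change == pytest.approx(manual, rel=1e-12)
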