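"""Beam library, depth interpolation, SOBP optimization and plan fields."""

import numpy as np
import pytest

from fragrbe import (ALL_PARTICLES, DepthDoseSet, DepthGrid, EnergyGrid,
                     ExtrapolationError, InfeasiblePlanError, PRIMARIES,
                     PRIMARY_PROTON, SOBPPlan, TISSUES, depth_interpolate,
                     make_lq_table, mixed_field_profile, optimize_weights,
                     optimize_weights_biological, plan_field,
                     rbe_and_biodose_profile, scenario_dose_scale)
from fragrbe.sobp import BeamLibrary, _combine_spots


class TestDepthInterpolate:
    @pytest.fixture()
    def linear_ddd(self):
        grid = DepthGrid(10, 10.0)
        return DepthDoseSet(100.0, grid,
                            {PRIMARY_PROTON: 3.0 * grid.centers})

    def test_break_point_returns_row(self, linear_ddd):
        z = linear_ddd.depth_grid.centers[4]
        row = depth_interpolate(linear_ddd, z)
        assert row[PRIMARY_PROTON] == pytest.approx(3.0 * z, rel=1e-12)

    def test_midpoint_is_arithmetic_mean(self, linear_ddd):
        c = linear_ddd.depth_grid.centers
        mid = 0.5 * (c[2] + c[3])
        row = depth_interpolate(linear_ddd, mid)
        assert row[PRIMARY_PROTON] == pytest.approx(
            0.5 * (3 * c[2] + 3 * c[3]), rel=1e-12)

    def test_linear_profile_interpolated_exactly(self, linear_ddd):
        # D(z) = c*z is reproduced exactly at arbitrary interior depths
        for z in (1.234, 5.0, 8.77):
            row = depth_interpolate(linear_ddd, z)
            assert row[PRIMARY_PROTON] == pytest.approx(3.0 * z, rel=1e-12)

    def test_out_of_span_rejected(self, linear_ddd):
        with pytest.raises(ExtrapolationError):
            depth_interpolate(linear_ddd, 99.0)


class TestLibrary:
    def test_covers_energy_grid(self, library):
        assert library.energies[0] == 60.0
        assert library.energies[-1] == 230.0
        assert np.all(np.diff(library.energies) == 5.0)
        assert set(library.spc) == set(library.ddd)

    def test_entries_normalized(self, library):
        for e in (60.0, 150.0, 230.0):
            assert abs(library.spc[e].primary_normalization() - 1.0) <= 1e-12

    def test_virtual_spot_between_entries(self, library):
        zq = np.linspace(0.1, 20.0, 200)
        d_mid = library.spot_total_dose(102.5, zq)
        # peak of the interpolated spot sits between the neighbours' peaks
        p1 = zq[np.argmax(library.spot_total_dose(100.0, zq))]
        p2 = zq[np.argmax(library.spot_total_dose(105.0, zq))]
        pm = zq[np.argmax(d_mid)]
        assert p1 < pm < p2


class TestPhysicalOptimization:
    def test_single_energy_target_single_weight(self, library):
        # one narrow bin at one beam's peak: a single spot suffices
        plan = optimize_weights(library, target_center=bkpeak(library, 100.0),
                                target_width=0.1, spot_step=5.0)
        assert np.count_nonzero(plan.weights > 1e-9 * plan.weights.max()) <= 2

    def test_recovers_constructed_flat_combination(self):
        # two triangular profiles whose sum is exactly flat on the target;
        # the two spot energies have Bragg-Kleeman ranges inside the box
        grid = DepthGrid(100, 10.0)
        z = grid.centers
        up = np.clip(z - 4.0, 0, 2.0) / 2.0
        down = np.clip(6.0 - z, 0, 2.0) / 2.0

        class TwoTriangleLibrary:
            energies = np.array([80.0, 85.0])  # ranges ~5.1 and ~5.7 cm
            geom = None
            max_range = 10.0

            def spot_total_dose(self, e, zq):
                src = down if e == 80.0 else up
                return np.interp(zq, z, src)

        lib = TwoTriangleLibrary()
        plan = optimize_weights(lib, target_center=5.0, target_width=1.6,
                                spot_step=5.0, grid_dz=0.05)
        np.testing.assert_allclose(plan.weights, [1.0, 1.0], atol=1e-6)
        assert plan.achieved_flatness <= 1e-6

    def test_default_160mm_plan_flat_within_2pct(self, library):
        plan = optimize_weights(library, 16.0, 3.0)
        assert plan.achieved_flatness <= 0.02
        assert np.all(plan.weights >= 0)

    def test_deterministic(self, library):
        p1 = optimize_weights(library, 16.0, 3.0)
        p2 = optimize_weights(library, 16.0, 3.0)
        np.testing.assert_array_equal(p1.weights, p2.weights)

    def test_infeasible_target_rejected(self, library):
        with pytest.raises(InfeasiblePlanError):
            optimize_weights(library, 40.0, 3.0)


def bkpeak(library, e):
    from fragrbe import bk_range
    return bk_range(e, library.geom) - 0.05


class TestBiologicalOptimization:
    def test_photon_tables_reduce_to_physical(self, library, stopping):
        tissue = TISSUES["ab2"]
        lq0 = make_lq_table(tissue, list(library.energy_grids),
                            library.energy_grids, stopping, k=0.0)
        pb = optimize_weights_biological(library, tissue, lq0, 16.0, 3.0)
        pp = optimize_weights(library, 16.0, 3.0)
        zq = np.arange(14.525, 17.5, 0.05)
        a = np.column_stack([library.spot_total_dose(e, zq)
                             for e in pp.energies])
        prof_b = a @ pb.weights
        prof_p = a @ pp.weights
        # equal up to the optimizer's ridge regularization
        np.testing.assert_allclose(prof_b / prof_b.mean(),
                                   prof_p / prof_p.mean(), rtol=1e-3)

    def test_biological_dose_flat_within_3pct(self, library,
                                              lq_ab2_library):
        plan = optimize_weights_biological(library, TISSUES["ab2"],
                                           lq_ab2_library, 16.0, 3.0)
        assert plan.achieved_flatness <= 0.03
        assert plan.mode == "biological"

    def test_idempotent_from_converged_weights(self, library,
                                               lq_ab2_library):
        plan = optimize_weights_biological(library, TISSUES["ab2"],
                                           lq_ab2_library, 16.0, 3.0)
        again = optimize_weights_biological(
            library, TISSUES["ab2"], lq_ab2_library, 16.0, 3.0,
            initial_weights=plan.weights, max_iter=3)
        delta = np.abs(again.weights - plan.weights).max() / plan.weights.max()
        assert delta < 1e-4


class TestPlanField:
    def test_single_weight_scales_that_beam(self, library):
        spots = np.array([150.0])
        w = np.array([2.5])
        plan = SOBPPlan(spots, w, 15.0, 1.0, "physical")
        spc, ddd = plan_field(plan, library)
        zq = spc.depth_grid.centers
        n_one, d_one = library.spot_tables(150.0, zq)
        for t in d_one:
            np.testing.assert_allclose(ddd.dose[t], 2.5 * d_one[t],
                                       rtol=1e-12)
        np.testing.assert_allclose(spc.n[PRIMARY_PROTON],
                                   2.5 * n_one[PRIMARY_PROTON], rtol=1e-12)

    def test_doubling_weights_doubles_dose_keeps_alpha(self, library,
                                                       lq_ab2_library,
                                                       stopping):
        plan = optimize_weights(library, 16.0, 3.0)
        double = SOBPPlan(plan.energies, 2 * plan.weights, 16.0, 3.0,
                          "physical")
        spc1, d1 = plan_field(plan, library)
        spc2, d2 = plan_field(double, library)
        np.testing.assert_allclose(d2.total, 2 * d1.total, rtol=1e-12)
        a1, _, _ = mixed_field_profile(spc1, lq_ab2_library, stopping,
                                       ALL_PARTICLES)
        a2, _, _ = mixed_field_profile(spc2, lq_ab2_library, stopping,
                                       ALL_PARTICLES)
        ok = np.isfinite(a1)
        np.testing.assert_allclose(a1[ok], a2[ok], rtol=1e-10)

    def test_superposition_linearity(self, library):
        zq = np.linspace(0.1, 30.0, 120)
        wa = {100.0: 1.0, 150.0: 0.0}
        wb = {100.0: 0.0, 150.0: 2.0}
        spots = np.array([100.0, 150.0])
        na, da = _combine_spots(library, spots, np.array([1.0, 0.0]), zq)
        nb, db = _combine_spots(library, spots, np.array([0.0, 2.0]), zq)
        nab, dab = _combine_spots(library, spots, np.array([1.0, 2.0]), zq)
        for t in dab:
            np.testing.assert_allclose(
                dab[t], da.get(t, 0) + db.get(t, 0), rtol=1e-12)

    def test_deeper_target_larger_entrance_enhancement(self, library,
                                                       stopping,
                                                       lq_ab2_library):
        """The all-particle/primaries biological-dose ratio in the
        entrance channel grows with target depth."""
        tissue = TISSUES["ab2"]
        ratios = {}
        for center in (16.0, 28.0):
            plan = optimize_weights(library, center, 3.0)
            spc, _ = plan_field(plan, library)
            scale = scenario_dose_scale(spc, lq_ab2_library, stopping,
                                        ALL_PARTICLES)
            prof_all = rbe_and_biodose_profile(spc, lq_ab2_library, tissue,
                                               ALL_PARTICLES, stopping,
                                               dose_scale=scale)
            prof_p = rbe_and_biodose_profile(spc, lq_ab2_library, tissue,
                                             PRIMARIES, stopping,
                                             dose_scale=scale)
            z = spc.depth_grid.centers
            # matched relative depth: 30% of the target center
            i = int(np.argmin(np.abs(z - 0.3 * center)))
            ratios[center] = (prof_all.biological_dose[i]
                              / prof_p.biological_dose[i])
        assert ratios[28.0] >= ratios[16.0]

    def test_entrance_ratio_maximal_before_target(self, library, stopping,
                                                  lq_ab2_library):
        """For the 160 mm plan the fragment enhancement peaks in the
        entrance channel, not inside the target box."""
        tissue = TISSUES["ab2"]
        plan = optimize_weights(library, 16.0, 3.0)
        spc, _ = plan_field(plan, library)
        scale = scenario_dose_scale(spc, lq_ab2_library, stopping,
                                    ALL_PARTICLES)
        prof_all = rbe_and_biodose_profile(spc, lq_ab2_library, tissue,
                                           ALL_PARTICLES, stopping,
                                           dose_scale=scale)
        prof_p = rbe_and_biodose_profile(spc, lq_ab2_library, tissue,
                                         PRIMARIES, stopping,
                                         dose_scale=scale)
        z = spc.depth_grid.centers
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = prof_all.biological_dose / prof_p.biological_dose
        lo, hi = plan.target_interval
        entrance = (z > 1.0) & (z < lo)
        target = (z >= lo) & (z <= hi)
        assert np.nanmax(ratio[entrance]) > np.nanmax(ratio[target])
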