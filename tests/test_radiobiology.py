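"""LQL survival, ion LQ tables and the mixed-field dose averaging."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fragrbe import (ALL_PARTICLES, ALL_PROTONS, DepthGrid, EnergyGrid,
                     PRIMARIES, PRIMARY_PROTON, ConfigError, ParticleType,
                     SPCTable, TISSUES, TissueParams, lql_effect, lql_inverse,
                     lql_survival, make_lq_table, max_slope,
                     mixed_field_lq, mixed_field_profile,
                     photon_equivalent_dose, rbe_and_biodose_profile,
                     scenario_dose_scale)


class TestLQLSurvival:
    def test_zero_dose_full_survival(self):
        assert lql_survival(0.0, 0.1, 0.05, 8.0) == 1.0

    def test_quadratic_branch_value(self):
        # alpha=0.10, beta=0.05, D=Dt=8: effect = 0.8 + 3.2 = 4.0
        assert lql_survival(8.0, 0.10, 0.05, 8.0) == pytest.approx(
            np.exp(-4.0), rel=1e-12)

    def test_linear_branch_value(self):
        # Sm = 0.10 + 2*0.05*8 = 0.9; D=10: effect = 4.0 + 0.9*2
        assert lql_survival(10.0, 0.10, 0.05, 8.0) == pytest.approx(
            np.exp(-5.8), rel=1e-12)

    def test_strictly_decreasing(self):
        d = np.linspace(0.0, 30.0, 301)
        s = lql_survival(d, 0.10, 0.05, 8.0)
        assert np.all(np.diff(s) < 0)

    def test_negative_dose_rejected(self):
        with pytest.raises(ConfigError):
            lql_survival(-1.0, 0.1, 0.05, 8.0)

    def test_continuity_and_slope_continuity_at_threshold(self):
        alpha, beta, dt = 0.10, 0.05, 8.0
        h = 1e-7
        below = lql_effect(dt - h, alpha, beta, dt)
        above = lql_effect(dt + h, alpha, beta, dt)
        at = lql_effect(dt, alpha, beta, dt)
        assert abs(below - at) / at <= 1e-6
        assert abs(above - at) / at <= 1e-6
        slope_below = (at - lql_effect(dt - h, alpha, beta, dt)) / h
        sm = max_slope(alpha, beta, dt)
        assert abs(slope_below - sm) / sm <= 1e-6


class TestMaxSlope:
    def test_value(self):
        assert max_slope(0.10, 0.05, 8.0) == pytest.approx(0.9, rel=1e-12)

    def test_pure_linear_limit(self):
        assert max_slope(0.27, 0.0, 8.0) == pytest.approx(0.27)


class TestPhotonEquivalentDose:
    tissue = TissueParams(0.1, 0.05, 8.0)

    def test_zero_effect(self):
        assert photon_equivalent_dose(0.0, self.tissue) == 0.0

    def test_quadratic_root(self):
        # E = ln 2: Dx = (-0.1 + sqrt(0.01 + 0.2 ln 2)) / 0.1
        assert photon_equivalent_dose(np.log(2.0), self.tissue) == (
            pytest.approx(2.8552, abs=1e-4))

    @pytest.mark.parametrize("dose", [1.0, 8.0, 13.0])
    def test_inverse_round_trip(self, dose):
        s = lql_survival(dose, 0.1, 0.05, 8.0)
        back = photon_equivalent_dose(-np.log(s), self.tissue)
        assert back == pytest.approx(dose, rel=1e-10)

    def test_monotone_in_effect(self):
        e = np.linspace(0.0, 10.0, 200)
        d = photon_equivalent_dose(e, self.tissue)
        assert np.all(np.diff(d) > 0)

    def test_negative_effect_rejected(self):
        with pytest.raises(ConfigError):
            photon_equivalent_dose(-0.1, self.tissue)


class TestLQTable:
    def test_low_let_limit_recovers_photon_alpha(self, field150, stopping):
        cube = field150[0]
        lq = make_lq_table(TISSUES["ab2"], [PRIMARY_PROTON],
                           cube.energy_grids, stopping)
        # highest-energy proton bins: LET -> small, alpha -> alpha_x
        # (entrance-channel protons stay within ~1% of the photon value)
        assert lq.alpha[PRIMARY_PROTON][-1] == pytest.approx(
            TISSUES["ab2"].alpha_x, rel=2e-2)
        # and the amplification decreases monotonically towards high energy
        assert np.all(np.diff(lq.alpha[PRIMARY_PROTON][100:]) <= 0)
        assert np.all(lq.alpha[PRIMARY_PROTON]
                      >= TISSUES["ab2"].alpha_x * (1 - 1e-9))

    def test_k_zero_is_photon_everywhere(self, field150, stopping):
        cube = field150[0]
        lq = make_lq_table(TISSUES["ab2"], list(cube.fluence),
                           cube.energy_grids, stopping, k=0.0)
        for t in lq.alpha:
            np.testing.assert_allclose(lq.alpha[t], TISSUES["ab2"].alpha_x)
            np.testing.assert_allclose(lq.beta[t], TISSUES["ab2"].beta_x)

    def test_alpha_monotone_in_let_below_saturation(self, stopping):
        tissue = TISSUES["ab2"]
        let = np.linspace(0.1, 99.0, 500)
        boost = 0.4 * let ** 2 / (tissue.alpha_beta * (5.0 + let)
                                  * (1.0 + (let / 100.0) ** 2))
        assert np.all(np.diff(boost) > 0)


def toy_spc(weights, uppers=None):
    """Single-depth SPC with one species per weight, one bin each."""
    n_comp = len(weights)
    grid = DepthGrid(1, 1.0)
    species = [PRIMARY_PROTON, ParticleType(1, 1, 1), ParticleType(2, 1),
               ParticleType(3, 2), ParticleType(4, 2)][:n_comp]
    egrids = {t: EnergyGrid(1, (uppers or [100.0] * n_comp)[i])
              for i, t in enumerate(species)}
    n = {t: np.array([[w]]) for t, w in zip(species, weights)}
    return SPCTable(100.0, grid, egrids, n), species


class ConstStopping:
    """Per-species constant stopping powers for oracle tests."""

    rho = 1.0

    def __init__(self, table):
        self.table = table

    def __call__(self, t, e):
        return np.full(np.shape(e), self.table[t])

    def let(self, t, e):
        return self(t, e) / 10.0


def const_lq(tissue, species, egrids, alphas, betas=None):
    from fragrbe.radiobiology import LQTable
    return LQTable(tissue, dict(egrids),
                   {t: np.array([a]) for t, a in zip(species, alphas)},
                   {t: np.array([b]) for t, b in zip(
                       species, betas or [tissue.beta_x] * len(species))})


class TestMixedFieldLQ:
    tissue = TISSUES["ab2"]

    def test_single_component_returns_its_parameters(self):
        spc, species = toy_spc([0.7])
        lq = const_lq(self.tissue, species, spc.energy_grids, [0.23])
        stop = ConstStopping({species[0]: 5.0})
        abar, bbar, _ = mixed_field_lq(spc, lq, stop, ALL_PARTICLES, 0)
        assert abar == pytest.approx(0.23, rel=1e-12)
        assert bbar == pytest.approx(self.tissue.beta_x, rel=1e-12)

    def test_two_equal_dose_components_average(self):
        spc, species = toy_spc([1.0, 2.0])
        # equal w*S: w1*S1 = w2*S2
        stop = ConstStopping({species[0]: 6.0, species[1]: 3.0})
        lq = const_lq(self.tissue, species, spc.energy_grids, [0.1, 0.3])
        abar, _, _ = mixed_field_lq(spc, lq, stop, ALL_PARTICLES, 0)
        assert abar == pytest.approx(0.2, rel=1e-12)

    def test_brute_force_oracle_five_components(self):
        w = [0.4, 1.1, 0.2, 0.9, 0.05]
        s = [5.0, 3.0, 40.0, 25.0, 80.0]
        a = [0.10, 0.13, 0.5, 0.9, 0.3]
        b = [0.05, 0.05, 0.02, 0.06, 0.04]
        spc, species = toy_spc(w)
        stop = ConstStopping(dict(zip(species, s)))
        lq = const_lq(self.tissue, species, spc.energy_grids, a, b)
        abar, bbar, dose = mixed_field_lq(spc, lq, stop, ALL_PARTICLES, 0)
        ws = [wi * si for wi, si in zip(w, s)]
        assert abar == pytest.approx(
            sum(wsi * ai for wsi, ai in zip(ws, a)) / sum(ws), rel=1e-12)
        assert bbar == pytest.approx(
            sum(wsi * bi for wsi, bi in zip(ws, b)) / sum(ws), rel=1e-12)
        assert dose == pytest.approx(sum(ws) * 1.602176634e-10, rel=1e-9)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_weight_rescaling_invariance(self, c):
        w = [0.4, 1.1, 0.2]
        spc1, species = toy_spc(w)
        spc2, _ = toy_spc([wi * c for wi in w])
        stop = ConstStopping({t: 5.0 + 3 * i for i, t in enumerate(species)})
        lq = const_lq(self.tissue, species, spc1.energy_grids,
                      [0.1, 0.2, 0.4])
        a1, b1, _ = mixed_field_lq(spc1, lq, stop, ALL_PARTICLES, 0)
        a2, b2, _ = mixed_field_lq(spc2, lq, stop, ALL_PARTICLES, 0)
        assert a1 == pytest.approx(a2, rel=1e-10)
        assert b1 == pytest.approx(b2, rel=1e-10)

    def test_averages_bounded_by_component_extrema(self, spc150, lq_ab2,
                                                   stopping):
        abar, bbar, _ = mixed_field_profile(spc150, lq_ab2, stopping,
                                            ALL_PARTICLES)
        amin = min(a.min() for a in lq_ab2.alpha.values())
        amax = max(a.max() for a in lq_ab2.alpha.values())
        ok = np.isfinite(abar)
        assert np.all(abar[ok] >= amin - 1e-12)
        assert np.all(abar[ok] <= amax + 1e-12)


class TestRBEProfiles:
    def test_photon_field_has_unit_rbe_everywhere(self, spc150, stopping,
                                                  field150):
        cube = field150[0]
        tissue = TISSUES["ab2"]
        lq = make_lq_table(tissue, list(cube.fluence), cube.energy_grids,
                           stopping, k=0.0)
        prof = rbe_and_biodose_profile(spc150, lq, tissue, ALL_PARTICLES,
                                       stopping, prescribed_dose=2.0)
        ok = np.isfinite(prof.rbe)
        np.testing.assert_allclose(prof.rbe[ok], 1.0, rtol=1e-9)

    def test_effect_monotone_across_scenarios(self, spc150, lq_ab2, stopping):
        tissue = TISSUES["ab2"]
        scale = scenario_dose_scale(spc150, lq_ab2, stopping, ALL_PARTICLES)
        surv = {}
        for mask in (PRIMARIES, ALL_PROTONS, ALL_PARTICLES):
            prof = rbe_and_biodose_profile(spc150, lq_ab2, tissue, mask,
                                           stopping, dose_scale=scale)
            surv[mask.name] = prof.survival
        assert np.all(surv["all_protons"] <= surv["primaries"] + 1e-12)
        assert np.all(surv["all_particles"] <= surv["all_protons"] + 1e-12)

    def test_toy_two_depth_hand_calculation(self):
        tissue = TISSUES["ab2"]
        spc, species = toy_spc([1.0])
        stop = ConstStopping({species[0]: 5.0})
        lq = const_lq(tissue, species, spc.energy_grids, [0.2], [0.05])
        prof = rbe_and_biodose_profile(spc, lq, tissue, ALL_PARTICLES, stop,
                                       prescribed_dose=2.0)
        effect = 0.2 * 2.0 + 0.05 * 4.0
        dx = (-0.1 + np.sqrt(0.01 + 4 * 0.05 * effect)) / (2 * 0.05)
        assert prof.biological_dose[0] == pytest.approx(dx, rel=1e-10)
        assert prof.rbe[0] == pytest.approx(dx / 2.0, rel=1e-10)
        assert prof.survival[0] == pytest.approx(np.exp(-effect), rel=1e-10)

    def test_zero_dose_reported_missing_not_zero(self):
        # field with an empty second depth slice: RBE there is missing
        tissue = TISSUES["ab2"]
        grid = DepthGrid(2, 1.0)
        egrids = {PRIMARY_PROTON: EnergyGrid(1, 100.0)}
        spc = SPCTable(100.0, grid, egrids,
                       {PRIMARY_PROTON: np.array([[1.0], [0.0]])})
        stop = ConstStopping({PRIMARY_PROTON: 5.0})
        lq = const_lq(tissue, [PRIMARY_PROTON], egrids, [0.2])
        prof = rbe_and_biodose_profile(spc, lq, tissue, ALL_PARTICLES, stop)
        assert np.isfinite(prof.rbe[0])
        assert np.isnan(prof.rbe[1])


class TestParameterRecovery:
    def test_lq_refit_from_noisy_survival(self, rng):
        """Generating survival with 5% lognormal noise at n=8 doses and
        refitting (alpha, beta) by least squares recovers the truth to
        ~10% in the typical replicate."""
        alpha, beta, dt = 0.3, 0.05, 8.0
        doses = np.linspace(0.5, 7.5, 8)
        design = np.column_stack([doses, doses ** 2])
        errs = []
        for _ in range(51):
            s = lql_survival(doses, alpha, beta, dt)
            noisy = s * np.exp(rng.normal(0.0, 0.05, len(doses)))
            y = -np.log(noisy)
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            errs.append((abs(coef[0] - alpha) / alpha,
                         abs(coef[1] - beta) / beta))
        med = np.median(np.asarray(errs), axis=0)
        assert med[0] <= 0.10
        assert med[1] <= 0.10
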