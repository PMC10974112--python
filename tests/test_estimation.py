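"""Parameter recovery, shift-slope regression and solubility inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rheomelt import (
    CarreauArrheniusParams,
    DrugShiftParams,
    FitResult,
    ShiftObservation,
    SweepDesign,
    compare_zero_shear,
    drug_shift_factor,
    drug_shift_two_phase,
    estimate_drug_shifts,
    fit_carreau_arrhenius,
    fit_shift_slope,
    generate_mixture_series,
    generate_pure_polymer,
    solubility_from_shift,
)

from conftest import POLYMER_PARAMS, TREF_C, params_for

PARAM_NAMES = ("eta0", "gamma_c", "c", "EA")


def _fit_result_from_eta0s(eta0s, gamma_c=10.0, c=0.4, ea=1.3e5):
    reps = [
        CarreauArrheniusParams.from_values(e, gamma_c, c, ea, TREF_C) for e in eta0s
    ]
    arr = np.asarray(eta0s, float)
    mean = {"eta0": arr.mean(), "gamma_c": gamma_c, "c": c, "EA": ea}
    sd = {
        "eta0": arr.std(ddof=1) if arr.size > 1 else 0.0,
        "gamma_c": 0.0,
        "c": 0.0,
        "EA": 0.0,
    }
    return FitResult(reps[0], reps, mean, sd, 0.0)


class TestCarreauArrheniusFit:
    @pytest.mark.parametrize("system", sorted(POLYMER_PARAMS))
    def test_noise_free_recovery_within_one_percent(self, system):
        truth = POLYMER_PARAMS[system]
        p = params_for(system)
        curves = generate_pure_polymer(SweepDesign(noise_sigma=0.0, seed=2), p)
        fit = fit_carreau_arrhenius(curves, TREF_C, seed=2)
        for name, expected in zip(PARAM_NAMES, truth):
            assert fit.mean[name] == pytest.approx(expected, rel=0.01)
            assert getattr(fit.params, name) == pytest.approx(expected, rel=0.01)

    def test_recovery_across_parameter_grid(self):
        """Noise-free recovery < 1% over a grid spanning the realistic
        pure-polymer parameter ranges."""
        grid = [
            (7e2, 1.0, 0.3, 1.2e5),
            (2e4, 60.0, 0.6, 1.9e5),
            (5e3, 5.0, 0.45, 1.5e5),
        ]
        design = SweepDesign(noise_sigma=0.0, replicates=1)
        for eta0, gc, c, ea in grid:
            p = CarreauArrheniusParams.from_values(eta0, gc, c, ea, TREF_C)
            fit = fit_carreau_arrhenius(generate_pure_polymer(design, p), TREF_C)
            for name, expected in zip(PARAM_NAMES, (eta0, gc, c, ea)):
                assert fit.params and getattr(fit.params, name) == pytest.approx(
                    expected, rel=0.01
                ), (name, eta0, gc, c, ea)

    def test_stochastic_recovery_with_replicate_sd(self, bbma_params):
        curves = generate_pure_polymer(SweepDesign(noise_sigma=0.02, seed=4), bbma_params)
        fit = fit_carreau_arrhenius(curves, TREF_C, seed=4)
        for name, expected in zip(PARAM_NAMES, POLYMER_PARAMS["bBMA"]):
            assert fit.mean[name] == pytest.approx(expected, rel=0.05)
            assert fit.sd[name] > 0
        assert len(fit.per_replicate) == 3
        assert fit.residual > 0

    def test_single_temperature_unidentifiable(self, bbma_params):
        curves = generate_pure_polymer(
            SweepDesign(noise_sigma=0.0, temperatures_C=(160.0,)), bbma_params
        )
        with pytest.raises(ValueError, match="unidentifiable|temperature"):
            fit_carreau_arrhenius(curves, TREF_C)

    def test_mixed_compositions_rejected(self, sol_params, plasticizer):
        pure = generate_pure_polymer(SweepDesign(noise_sigma=0.0), sol_params)
        mix = generate_mixture_series(
            SweepDesign(noise_sigma=0.0), sol_params, plasticizer, None, [0.2]
        )
        with pytest.raises(ValueError, match="composition"):
            fit_carreau_arrhenius(pure + mix, TREF_C)

    def test_order_invariance(self, bbma_clean_curves):
        fwd = fit_carreau_arrhenius(bbma_clean_curves, TREF_C, seed=9)
        rev = fit_carreau_arrhenius(bbma_clean_curves[::-1], TREF_C, seed=9)
        for name in PARAM_NAMES:
            assert getattr(fwd.params, name) == pytest.approx(
                getattr(rev.params, name), rel=1e-9
            )


class TestDrugShiftFactor:
    def test_direct_ratio(self):
        assert drug_shift_factor(1000.0, 1000.0) == 1.0
        assert drug_shift_factor(500.0, 1000.0) == 0.5

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            drug_shift_factor(-1.0, 10.0)

    def test_fitted_series_reproduces_plasticizing_law(self, sol_params):
        """Shift factors estimated from a synthetic plasticized series follow
        exp(w * s_plast)."""
        d = DrugShiftParams(s_plast=-5.0)
        fractions = [0.1, 0.2, 0.3]
        mix = generate_mixture_series(
            SweepDesign(noise_sigma=0.0, replicates=1), sol_params, d, None, fractions
        )
        obs = estimate_drug_shifts(mix, sol_params)
        assert [o.w_drug for o in obs] == fractions
        for o in obs:
            assert o.a_drug == pytest.approx(math.exp(o.w_drug * -5.0), rel=1e-6)
        # fitted a_drug decreasing in w for a plasticizer
        a = [o.a_drug for o in obs]
        assert a == sorted(a, reverse=True)


class TestShiftSlope:
    def test_exact_line(self):
        obs = [ShiftObservation(w, math.exp(-5.0 * w)) for w in (0.0, 0.1, 0.2, 0.3)]
        res = fit_shift_slope(obs)
        assert res.slope == pytest.approx(-5.0, rel=1e-12)
        assert res.stderr == pytest.approx(0.0, abs=1e-10)

    def test_single_observation_through_origin(self):
        res = fit_shift_slope([ShiftObservation(0.2, math.exp(-1.0))])
        assert res.slope == pytest.approx(-5.0)
        assert res.stderr == 0.0

    def test_noisy_slope_within_two_se(self):
        rng = np.random.default_rng(6)
        w = np.repeat([0.05, 0.1, 0.2, 0.3], 3)
        obs = [
            ShiftObservation(float(x), math.exp(-4.0 * x + rng.normal(0, 0.05)))
            for x in w
        ]
        res = fit_shift_slope(obs)
        assert abs(res.slope - (-4.0)) < 2 * res.stderr

    def test_opaque_excluded_and_counted(self):
        obs = [
            ShiftObservation(0.1, math.exp(-0.5)),
            ShiftObservation(0.2, math.exp(-1.0)),
            ShiftObservation(0.3, 5.0, opaque=True),
        ]
        res = fit_shift_slope(obs)
        assert res.slope == pytest.approx(-5.0, rel=1e-12)
        assert res.n_excluded_opaque == 1

    def test_error_paths(self):
        with pytest.raises(ValueError, match="w_drug = 0"):
            fit_shift_slope([ShiftObservation(0.0, 1.0)])
        with pytest.raises(ValueError, match="opaque"):
            fit_shift_slope([ShiftObservation(0.2, 2.0, opaque=True)])
        with pytest.raises(ValueError):
            fit_shift_slope([])

    def test_filler_series_gives_positive_slope(self):
        obs = [ShiftObservation(w, math.exp(4.0 * w)) for w in (0.05, 0.1, 0.2)]
        assert fit_shift_slope(obs).slope == pytest.approx(4.0, rel=1e-12)


class TestSolubilityInversion:
    D = DrugShiftParams(s_plast=-6.0, s_filler=4.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        w_drug=st.floats(0.05, 0.6),
        frac=st.floats(0.0, 1.0),
    )
    def test_inverts_two_phase_factor_exactly(self, w_drug, frac):
        w_s = frac * w_drug
        a = drug_shift_two_phase(self.D, w_drug, w_s)
        assert solubility_from_shift(a, self.D, w_drug) == pytest.approx(
            w_s, abs=1e-12
        )

    def test_boundaries(self):
        w = 0.3
        fully_dissolved = math.exp(w * self.D.s_plast)
        fully_suspended = math.exp(w * self.D.s_filler)
        assert solubility_from_shift(fully_dissolved, self.D, w) == pytest.approx(w)
        assert solubility_from_shift(fully_suspended, self.D, w) == pytest.approx(0.0)

    def test_out_of_range_clamped(self):
        # shift factor above the pure-filler value implies w_s < 0: clamp to 0
        w = 0.3
        a = math.exp(w * self.D.s_filler + 0.5)
        assert solubility_from_shift(a, self.D, w) == 0.0

    def test_degenerate_slopes_rejected(self):
        d = DrugShiftParams(s_plast=2.0, s_filler=2.0)
        with pytest.raises(ValueError, match="parallel|undefined"):
            solubility_from_shift(1.0, d, 0.3)


class TestCompareZeroShear:
    def test_identical_sets_not_significant(self):
        f = _fit_result_from_eta0s([1000.0, 1001.0, 999.0])
        t, p, sig = compare_zero_shear(f, f)
        assert t == 0.0 and not sig

    def test_separated_sets_significant(self):
        a = _fit_result_from_eta0s([1000.0, 1001.0, 999.0])
        b = _fit_result_from_eta0s([2000.0, 2001.0, 1999.0])
        t, p, sig = compare_zero_shear(a, b, alpha=0.05)
        assert sig and p < 1e-4
        # matches the textbook Welch statistic computed independently
        t_ref, p_ref = stats.ttest_ind(
            [1000.0, 1001.0, 999.0], [2000.0, 2001.0, 1999.0], equal_var=False
        )
        assert t == pytest.approx(float(t_ref)) and p == pytest.approx(float(p_ref))

    def test_same_generator_matches_oracle(self):
        rng = np.random.default_rng(13)
        x = 1000 + rng.normal(0, 30, 5)
        y = 1000 + rng.normal(0, 30, 5)
        fa, fb = _fit_result_from_eta0s(x), _fit_result_from_eta0s(y)
        t, p, sig = compare_zero_shear(fa, fb)
        t_ref, p_ref = stats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(float(t_ref)) and p == pytest.approx(float(p_ref))

    def test_requires_two_replicates(self):
        a = _fit_result_from_eta0s([1000.0])
        b = _fit_result_from_eta0s([1000.0, 1010.0])
        with pytest.raises(ValueError):
            compare_zero_shear(a, b)
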