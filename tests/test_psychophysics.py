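"""Psychometric fitting, thresholds, cue weights, SRT analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from phaselock.psychophysics import (
    PsychometricModel,
    ThresholdResult,
    fit_psychometric,
    lateralization_judgments,
    perceptual_weight,
    sine_ild,
    srt,
    tfs_benefit,
    threshold,
    woodworth_itd,
)


class TestPsychometricFit:
    def test_parameter_recovery(self, rng):
        x = np.linspace(0.5, 3.5, 9)
        p = norm.cdf((x - 2.0) / 0.5)
        k = rng.binomial(200, p)
        fit = fit_psychometric(x, k, np.full(9, 200.0))
        assert fit.mu == pytest.approx(2.0, abs=3 * fit.cov_params()[0, 0] ** 0.5)
        assert fit.sigma == pytest.approx(0.5, rel=0.25)

    def test_symmetric_data_centered_mu(self):
        fit = fit_psychometric([1.0, 2.0, 3.0], [10, 50, 90], [100, 100, 100])
        assert fit.mu == pytest.approx(2.0, abs=1e-6)

    def test_cross_check_against_probit_glm(self, rng):
        # independent route: statsmodels binomial GLM with probit link
        import statsmodels.api as sm

        x = np.linspace(-1, 1, 7)
        p = norm.cdf((x - 0.1) / 0.4)
        k = rng.binomial(150, p)
        n = np.full(7, 150.0)
        fit = fit_psychometric(x, k, n)
        glm = sm.GLM(
            np.column_stack([k, n - k]),
            sm.add_constant(x),
            family=sm.families.Binomial(sm.families.links.Probit()),
        ).fit()
        b0, b1 = glm.params
        assert fit.mu == pytest.approx(-b0 / b1, abs=1e-4)
        assert fit.sigma == pytest.approx(1 / b1, rel=1e-3)

    def test_perfect_step_flags_nonconverged(self):
        # perfect separation: the scale is unidentified (sigma -> 0)
        fit = fit_psychometric([1.0, 2.0, 3.0], [0, 0, 100], [100, 100, 100])
        assert not fit.converged

    def test_degenerate_all_zero_or_one_raises(self):
        with pytest.raises(ValueError):
            fit_psychometric([1.0, 2.0, 3.0], [0, 0, 0], [50, 50, 50])
        with pytest.raises(ValueError):
            fit_psychometric([1.0, 2.0, 3.0], [50, 50, 50], [50, 50, 50])

    def test_chance_floor_2afc(self, rng):
        x = np.linspace(-3, 0, 8)
        p = 0.5 + 0.5 * norm.cdf((x + 1.5) / 0.4)
        k = rng.binomial(300, p)
        fit = fit_psychometric(x, k, np.full(8, 300.0), chance=0.5)
        assert fit.mu == pytest.approx(-1.5, abs=0.1)
        # 75% correct = chance midpoint = mu for a 0.5-floored curve
        res = threshold(fit, 0.75)
        assert res.threshold == pytest.approx(fit.mu)

    def test_summary_contains_estimates(self):
        fit = fit_psychometric([1.0, 2.0, 3.0], [10, 50, 90], [100, 100, 100])
        s = fit.summary()
        assert "location" in s and "scale" in s


class TestThreshold:
    def test_fit_method_quantile_formula(self):
        fit = fit_psychometric([1.0, 2.0, 3.0], [10, 50, 90], [100, 100, 100])
        res = threshold(fit, 0.707)
        assert res.threshold == pytest.approx(
            fit.mu + fit.sigma * norm.ppf(0.707), abs=1e-12
        )
        # 0.545 sigma above mu at the 70.7% criterion
        assert (res.threshold - fit.mu) / fit.sigma == pytest.approx(0.5446, abs=1e-3)

    def test_criterion_half_returns_mu(self):
        fit = fit_psychometric([1.0, 2.0, 3.0], [10, 50, 90], [100, 100, 100])
        assert threshold(fit, 0.5).threshold == pytest.approx(fit.mu)

    def test_interpolation_linear_crossing(self):
        res = threshold(
            [0.2, 0.4, 0.8], 0.6, method="interpolation", x=np.array([1.0, 2.0, 3.0])
        )
        assert res.threshold == pytest.approx(2.5)

    def test_never_crossing_unmeasurable(self):
        res = threshold(
            [0.45, 0.52, 0.48], 0.707, method="interpolation", x=np.array([1.0, 2.0, 3.0])
        )
        assert not res.measurable and np.isnan(res.threshold)

    def test_flat_at_chance_unmeasurable_via_fit(self, rng):
        # accuracy hovering at 0.5 regardless of x: the fitted curve never
        # reaches the criterion inside the tested range
        x = np.linspace(0, 1, 6)
        k = rng.binomial(100, np.full(6, 0.5))
        try:
            fit = fit_psychometric(x, k, np.full(6, 100.0))
            res = threshold(fit, 0.99)
        except ValueError:
            return  # exactly flat draws are degenerate, also acceptable
        assert not res.measurable


class TestLateralization:
    def test_all_shifted_right(self):
        assert lateralization_judgments([1.0, 2.0], [1.5, 2.5]) == 1.0

    def test_ties_near_half(self):
        est = np.zeros(10000)
        prop = lateralization_judgments(est, est, seed=0)
        assert prop == pytest.approx(0.5, abs=0.02)

    def test_mixed_pairs_exact_count(self):
        e1 = np.array([0.0, 0.0, 0.0, 5.0])
        e2 = np.array([1.0, -1.0, 2.0, 4.0])
        assert lateralization_judgments(e1, e2) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lateralization_judgments([], [])


class TestPerceptualWeight:
    def test_full_weight_when_shift_matches_bias(self):
        # response shift whose mapped cue change equals the imposed bias
        az_u, az_b = 10.0, 20.0
        bias = woodworth_itd(az_b) - woodworth_itd(az_u)
        w = perceptual_weight([az_u], [az_b], [bias], woodworth_itd)
        assert w == pytest.approx(1.0)

    def test_zero_weight_no_shift(self):
        assert perceptual_weight([15.0], [15.0], [300.0], woodworth_itd) == 0.0

    def test_linear_map_symbolic(self):
        c, daz, bias = 5.0, 4.0, 20.0
        w = perceptual_weight([10.0], [10.0 + daz], [bias], lambda a: c * np.asarray(a))
        assert w == pytest.approx(c * daz / bias)

    def test_rear_responses_reflected(self):
        # 170 deg reflects to 10 deg: same cue as a frontal response
        w_rear = perceptual_weight([10.0], [170.0], [100.0], sine_ild)
        assert w_rear == pytest.approx(0.0, abs=1e-12)

    def test_affine_reparameterization_invariance(self):
        # rescaling azimuth jointly with the cue map leaves the weight fixed
        az_u = np.array([5.0, 25.0])
        az_b = np.array([12.0, 31.0])
        bias = np.array([40.0, 40.0])
        w1 = perceptual_weight(az_u, az_b, bias, lambda a: 3.0 * np.asarray(a))
        w2 = perceptual_weight(az_u / 2, az_b / 2, bias, lambda a: 6.0 * np.asarray(a))
        assert w1 == pytest.approx(w2)


class TestSrt:
    def test_recovers_logistic_midpoint(self):
        snrs = np.arange(-15.0, 16.0, 3.0)
        acc = 0.8 / (1 + np.exp(-(snrs - (-3.0)) / 2.0))
        res = srt(acc, snrs)
        assert res.threshold == pytest.approx(-3.0, abs=0.05)

    def test_translation_equivariance(self):
        snrs = np.arange(-15.0, 16.0, 3.0)
        acc = 0.7 / (1 + np.exp(-(snrs + 5.0) / 2.0))
        acc_shift = 0.7 / (1 + np.exp(-(snrs + 3.0) / 2.0))
        d = srt(acc_shift, snrs).threshold - srt(acc, snrs).threshold
        assert d == pytest.approx(2.0, abs=0.1)

    def test_flat_accuracy_unmeasurable(self):
        snrs = np.arange(-15.0, 16.0, 3.0)
        res = srt(np.full(snrs.size, 0.95), snrs)
        assert not res.measurable

    def test_fixed_criterion_option(self):
        snrs = np.arange(-15.0, 16.0, 3.0)
        acc = 1.0 / (1 + np.exp(-(snrs - 1.0) / 2.0))
        res = srt(acc, snrs, criterion=0.5)
        assert res.threshold == pytest.approx(1.0, abs=0.05)


class TestTfsBenefit:
    def test_baseline_zero_and_arithmetic(self):
        tab = pd.DataFrame(
            {
                "cutoff_channel": [0, 24, 0, 24],
                "noise": ["stationary", "stationary", "modulated", "modulated"],
                "srt": [-2.0, -7.0, -1.0, -8.0],
            }
        )
        out = tfs_benefit(tab)
        b = out.set_index(["noise", "cutoff_channel"])["benefit_db"]
        assert b[("stationary", 0)] == 0.0
        assert b[("stationary", 24)] == pytest.approx(5.0)
        assert b[("modulated", 24)] == pytest.approx(7.0)

    def test_monotone_when_srts_monotone(self):
        tab = pd.DataFrame(
            {
                "cutoff_channel": [0, 8, 16, 24],
                "noise": ["m"] * 4,
                "srt": [-1.0, -2.0, -4.0, -6.5],
            }
        )
        out = tfs_benefit(tab)
        assert np.all(np.diff(out["benefit_db"]) > 0)

    def test_missing_baseline_rejected(self):
        tab = pd.DataFrame({"cutoff_channel": [8], "noise": ["m"], "srt": [-2.0]})
        with pytest.raises(ValueError):
            tfs_benefit(tab)
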