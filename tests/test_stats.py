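"""Descriptive behavioural statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import refrep as rr
from refrep.stats import (
    GammaMixtureHistogram,
    PsychometricCurve,
    estimate_sd_summary,
    fit_gamma_mixture_hist,
    fit_psychometric,
    relative_estimate,
    repulsive_bias_curve,
    select_correct_trials,
)


class TestRelativeEstimate:
    @pytest.mark.parametrize(
        "rep, ref, expected",
        [(50.0, 45.0, 5.0), (2.0, 165.0, 17.0), (45.0, 45.0, 0.0), (0.0, 90.0, 90.0)],
    )
    def test_examples(self, rep, ref, expected):
        assert relative_estimate(rep, ref) == pytest.approx(expected)

    def test_range_validation(self):
        with pytest.raises(ValueError):
            relative_estimate(190.0, 45.0)
        with pytest.raises(ValueError):
            relative_estimate(45.0, -1.0)

    @given(st.floats(-89.999, 90.0), st.floats(0.0, 179.999))
    @settings(max_examples=80, deadline=None)
    def test_wrap_roundtrip(self, delta, ref):
        """Composing with its inverse is the identity on (-90, 90]."""
        rep = (ref + delta) % 180.0
        if rep >= 180.0:  # float edge: tiny negative delta wraps to 180.0 exactly
            rep = 0.0
        assert relative_estimate(rep, ref) == pytest.approx(delta, abs=1e-9)


def _binomial_psych_data(pse, sd, lapse, guess, n_per=200, seed=0):
    rng = np.random.default_rng(seed)
    offsets = np.arange(-18.0, 19.0, 3.0)
    x, y = [], []
    for off in offsets:
        p = guess + (1 - guess - lapse) * norm.cdf((off - pse) / sd)
        k = rng.binomial(n_per, p)
        x += [off] * n_per
        y += [1] * k + [0] * (n_per - k)
    return np.array(x), np.array(y)


class TestPsychometric:
    def test_pse_recovery(self):
        x, y = _binomial_psych_data(1.5, 5.0, 0.02, 0.02, seed=1)
        fit = fit_psychometric(x, y, n_boot=50, seed=2)
        assert fit.pse == pytest.approx(1.5, abs=0.5)
        assert fit.slope_sd == pytest.approx(5.0, rel=0.25)
        assert np.isfinite(fit.se_pse) and fit.se_pse > 0
        assert 0 <= fit.lapse <= 0.1 and 0 <= fit.guess <= 0.1

    def test_symmetric_data_gives_zero_pse(self):
        offsets = np.arange(-18.0, 19.0, 3.0)
        # exactly symmetric aggregated counts
        k = np.array([2, 3, 5, 10, 20, 45, 100, 155, 180, 190, 195, 197, 198])
        n = np.full_like(k, 200)
        est = PsychometricCurve(n_boot=0).fit(offsets, np.column_stack([k, n]))
        assert est.pse_ == pytest.approx(0.0, abs=0.05)

    def test_steeper_slope_detected(self):
        wins = 0
        for seed in range(100):
            x3, y3 = _binomial_psych_data(0.0, 3.0, 0.02, 0.02, n_per=100, seed=seed)
            x6, y6 = _binomial_psych_data(0.0, 6.0, 0.02, 0.02, n_per=100, seed=seed + 1000)
            f3 = fit_psychometric(x3, y3, n_boot=0)
            f6 = fit_psychometric(x6, y6, n_boot=0)
            wins += f3.slope_sd < f6.slope_sd
        assert wins >= 95

    def test_degenerate_single_class(self):
        with pytest.raises(ValueError):
            fit_psychometric([0.0, 3.0, 6.0], [1, 1, 1])


def _mixture_draws(alpha, theta, delta, n, seed):
    rng = np.random.default_rng(seed)
    mags = rng.gamma(alpha, theta, size=n) + delta
    signs = rng.choice([-1.0, 1.0], size=n)
    return mags * signs


class TestGammaMixture:
    def test_recovery_with_shift(self):
        x = _mixture_draws(3.0, 2.0, 5.0, 100_000, seed=3)
        fit = fit_gamma_mixture_hist(x, bin_width=1.0, fit_delta=True, n_boot=0)
        assert fit.alpha == pytest.approx(3.0, rel=0.10)
        assert fit.theta == pytest.approx(2.0, rel=0.10)
        assert fit.delta == pytest.approx(5.0, abs=0.6)

    def test_derived_variance_definition(self):
        x = _mixture_draws(2.0, 3.0, 0.0, 5000, seed=4)
        fit = fit_gamma_mixture_hist(x, n_boot=30, seed=5)
        assert fit.derived_variance == fit.alpha * fit.theta**2
        if fit.ci95:
            lo, hi = fit.ci95["derived_variance"]
            assert lo <= hi

    def test_concentration_ordering(self):
        """A dual-task-like (concentrated) sample yields smaller fitted
        alpha*theta^2 than a single-task-like (broad) one at matched n."""
        broad = _mixture_draws(1.5, 8.0, 0.0, 20_000, seed=6)
        tight = _mixture_draws(4.0, 1.0, 4.0, 20_000, seed=7)
        v_broad = fit_gamma_mixture_hist(broad, n_boot=0).derived_variance
        v_tight = fit_gamma_mixture_hist(tight, n_boot=0).derived_variance
        assert v_tight < v_broad

    def test_too_few_estimates(self):
        with pytest.raises(ValueError):
            GammaMixtureHistogram().fit(np.zeros(10))


def _records(rows):
    return pd.DataFrame(rows, columns=["task", "noise_level", "offset_deg", "estimate_rel_deg"])


class TestSelection:
    def test_rule_application(self):
        df = _records(
            [
                ("single", "low", 6.0, 3.0),    # kept
                ("single", "low", -6.0, 2.0),   # dropped
                ("single", "low", 0.0, -4.0),   # kept by default
            ]
        )
        kept = select_correct_trials(df)
        assert len(kept) == 2
        assert select_correct_trials(df, zero_offset="drop").shape[0] == 1

    def test_explicit_classification_option(self):
        df = _records([("dual", "low", 6.0, -3.0)])
        df["discrimination"] = ["CW"]
        assert len(select_correct_trials(df)) == 0  # estimate on the wrong side
        assert len(select_correct_trials(df, use_explicit=True)) == 1  # choice correct


class TestBiasCurve:
    def test_sign_conventions(self):
        df = _records(
            [
                ("single", "low", 6.0, 10.0),   # +4 repulsion
                ("single", "low", -6.0, -10.0), # +4 repulsion (mirror side)
                ("single", "high", 6.0, 4.0),   # -2 attraction
                ("single", "high", 0.0, -4.0),  # |est| = 4 at alignment
            ]
        )
        bc = repulsive_bias_curve(df).set_index(["abs_offset_deg", "task", "noise_level"])
        assert bc.loc[(6.0, "single", "low"), "mean_bias_deg"] == pytest.approx(4.0)
        assert bc.loc[(6.0, "single", "high"), "mean_bias_deg"] == pytest.approx(-2.0)
        assert bc.loc[(0.0, "single", "high"), "mean_bias_deg"] == pytest.approx(4.0)
        assert bc.loc[(6.0, "single", "low"), "n"] == 2

    def test_end_to_end_pattern_on_model_predictions(self, paper_params, session_trials):
        """Model predictions analysed like data show the headline pattern:
        positive bias at small |offset|, and larger at 0 than at 18 deg."""
        pred = rr.predict_estimates(paper_params, session_trials, n_samples=300, seed=9)
        bc = repulsive_bias_curve(select_correct_trials(pred))
        for task in ("single", "dual"):
            sub = bc[bc.task == task]
            near = sub[sub.abs_offset_deg <= 3.0]["mean_bias_deg"]
            far = sub[sub.abs_offset_deg == 18.0]["mean_bias_deg"]
            assert (near > 0).all()
            assert near.mean() > far.mean()


class TestSdSummary:
    def test_identical_estimates_zero_sd(self):
        df = _records([("single", "low", 0.0, 5.0)] * 4)
        out = estimate_sd_summary(df)
        assert out.loc[0, "sd_deg"] == 0.0

    def test_design_spread_removed(self):
        # estimates exactly equal to offset in every cell: SD must be 0
        offs = list(np.arange(-18.0, 19.0, 3.0)) * 3
        df = _records([("single", "low", o, o) for o in offs])
        assert estimate_sd_summary(df)["sd_deg"].iloc[0] == pytest.approx(0.0)

    def test_noise_monotonicity(self, paper_params, session_trials):
        """Doubling the high-noise measurement SD inflates the high-noise
        estimate SDs."""
        from dataclasses import replace

        louder = replace(paper_params, sigma_high=2 * paper_params.sigma_high)
        base = rr.simulate_session(session_trials, paper_params, seed=31)
        loud = rr.simulate_session(session_trials, louder, seed=31)
        s_base = estimate_sd_summary(base).set_index(["task", "noise_level"])["sd_deg"]
        s_loud = estimate_sd_summary(loud).set_index(["task", "noise_level"])["sd_deg"]
        assert s_loud[("single", "high")] > s_base[("single", "high")]
        assert s_loud[("dual", "high")] > s_base[("dual", "high")]

    def test_single_broader_than_dual(self, pooled_data):
        s = estimate_sd_summary(pooled_data).set_index(["task", "noise_level"])["sd_deg"]
        for noise in ("low", "high"):
            assert s[("single", noise)] > s[("dual", noise)]
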