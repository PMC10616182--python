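"""Core densities, weighting function and likelihood."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import refrep as rr
from refrep.model import (
    DegenerateReadoutError,
    GridSpec,
    LikelihoodData,
    WeightingParams,
    gamma_density,
    log_likelihood,
    readout_density,
    weighting_function,
)

W_STRAT = st.builds(
    WeightingParams,
    alpha=st.floats(0.5, 8.0),
    theta=st.floats(0.5, 20.0),
    delta=st.floats(0.0, 15.0),
)


class TestGammaDensity:
    def test_closed_forms(self):
        assert gamma_density(0.0, WeightingParams(1, 1, 0)) == pytest.approx(1.0)
        assert gamma_density(1.0, WeightingParams(2, 1, 0)) == pytest.approx(np.exp(-1))
        assert gamma_density(2.0, WeightingParams(2, 1, 5)) == 0.0

    def test_mirrored_support(self):
        w = WeightingParams(2, 1, 5)
        assert gamma_density(-7.0, w, mirrored=True) == pytest.approx(
            gamma_density(7.0, w)
        )
        assert gamma_density(7.0, w, mirrored=True) == 0.0

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            WeightingParams(-1, 1, 0)
        with pytest.raises(ValueError):
            WeightingParams(1, 0, 0)


class TestWeightingFunction:
    def test_laplace_limit(self):
        w = WeightingParams(1, 1, 0)
        assert weighting_function(0.0, w) == pytest.approx(0.5)
        x = np.array([-3.0, -1.0, 2.0])
        assert np.allclose(weighting_function(x, w), 0.5 * np.exp(-np.abs(x)))

    @given(W_STRAT, st.floats(-50, 50))
    @settings(max_examples=60, deadline=None)
    def test_symmetry_exact(self, w, om):
        assert weighting_function(om, w) == weighting_function(-om, w)

    @given(W_STRAT, st.floats(-60.0, 60.0))
    @settings(max_examples=80, deadline=None)
    def test_components_match_scipy_gamma(self, w, om):
        """Each mixture component is exactly the (shifted, possibly
        reflected) normalised Gamma density."""
        from hypothesis import assume
        from scipy.stats import gamma as sp_gamma

        # the support-boundary points +/-delta are measure zero and carry a
        # deliberate one-sided convention (Laplace f(0) = 1/(2 theta))
        assume(om != w.delta and om != -w.delta)
        direct = sp_gamma.pdf(om, a=w.alpha, loc=w.delta, scale=w.theta)
        mirror = sp_gamma.pdf(-om, a=w.alpha, loc=w.delta, scale=w.theta)
        expected = 0.5 * direct + 0.5 * mirror
        assert weighting_function(om, w) == pytest.approx(expected, rel=1e-12, abs=1e-300)

    def test_quadrature_oracle_case(self):
        x = np.arange(-200.0, 200.0, 0.01)
        f = weighting_function(x, WeightingParams(2, 3, 7))
        assert np.trapezoid(f, x) == pytest.approx(1.0, abs=1e-6)

    def test_literal_shift_variant(self):
        w = WeightingParams(2, 3, 7)
        x = np.arange(-200.0, 200.0, 0.01)
        f = weighting_function(x, w, form="literal_shift")
        assert np.trapezoid(f, x) == pytest.approx(1.0, abs=1e-6)
        # the translated form is NOT symmetric about zero
        assert weighting_function(10.0, w, form="literal_shift") != pytest.approx(
            weighting_function(-10.0, w, form="literal_shift")
        )


class TestReadoutDensity:
    def test_flat_weighting_recovers_gaussian(self):
        w = WeightingParams(1.0, 1e6, 0.0)
        d = readout_density(6.0, 5.0, w, epsilon=2.0)
        assert d.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert d.mean() == pytest.approx(8.0, abs=0.05)
        assert d.sd() == pytest.approx(5.0, abs=0.05)

    def test_bimodal_modes_match_brute_force(self):
        w = WeightingParams(2.0, 2.0, 5.0)
        d = readout_density(0.0, 5.0, w)
        p = d.probs
        mid = len(p) // 2
        m_pos = d.grid_deg[mid + int(np.argmax(p[mid:]))]
        m_neg = d.grid_deg[int(np.argmax(p[:mid]))]
        assert m_pos == pytest.approx(-m_neg, abs=d.grid_deg[1] - d.grid_deg[0])
        # brute-force fine-grid argmax oracle
        xs = np.arange(0.0, 40.0, 0.01)
        dens = np.exp(-0.5 * (xs / 5.0) ** 2) * weighting_function(xs, w)
        assert m_pos == pytest.approx(xs[np.argmax(dens)], abs=0.06)

    def test_large_sigma_modes_at_weighting_peak(self):
        # flat-measurement limit: readout tends to the weighting profile,
        # whose components peak at +/- (delta + (alpha-1)*theta)
        w = WeightingParams(3.0, 2.0, 6.0)
        d = readout_density(0.0, 400.0, w, grid=GridSpec(-90, 90, 0.05))
        mid = d.probs.size // 2
        m_pos = d.grid_deg[mid + int(np.argmax(d.probs[mid:]))]
        assert m_pos == pytest.approx(w.mode, abs=0.1)

    def test_degenerate_product_raises(self):
        w = WeightingParams(2.0, 1.0, 60.0)
        with pytest.raises(DegenerateReadoutError):
            readout_density(0.0, 0.5, w)


def _toy_data(estimates, task="single", noise="low", offset=0.0):
    n = len(estimates)
    return pd.DataFrame(
        {
            "task": [task] * n,
            "noise_level": [noise] * n,
            "offset_deg": [offset] * n,
            "estimate_rel_deg": estimates,
        }
    )


class TestLogLikelihood:
    def test_density_monotonicity(self, paper_params):
        d = readout_density(0.0, 5.0, paper_params.weighting_dual)
        peak = d.grid_deg[np.argmax(d.probs)]
        ll_peak = log_likelihood(paper_params, _toy_data([peak], task="dual"))
        ll_tail = log_likelihood(paper_params, _toy_data([80.0], task="dual"))
        assert ll_peak > ll_tail

    def test_additivity_under_duplication(self, paper_params):
        est = [3.0, -7.5, 12.0, 0.4]
        ll1 = log_likelihood(paper_params, _toy_data(est))
        ll2 = log_likelihood(paper_params, _toy_data(est + est))
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_empty_data_errors(self, paper_params):
        with pytest.raises(ValueError):
            log_likelihood(paper_params, _toy_data([]))

    def test_outside_grid_floored(self, paper_params):
        ld = LikelihoodData(_toy_data([95.0]), grid=GridSpec(-90, 90, 0.1))
        assert ld.n_outside == 1
        assert ld.log_likelihood(paper_params) == pytest.approx(np.log(1e-12))

    def test_true_params_beat_perturbed_delta(self, paper_params):
        """Simulation oracle: on data from known parameters the likelihood at
        the truth exceeds the likelihood with the dual shift moved +10 deg in
        nearly all replicates."""
        from dataclasses import replace

        worse = replace(
            paper_params,
            weighting_dual=WeightingParams(
                paper_params.weighting_dual.alpha,
                paper_params.weighting_dual.theta,
                paper_params.weighting_dual.delta + 10.0,
            ),
        )
        design = rr.generate_session(1, 1, seed=5).sample(n=200, random_state=0)
        wins = 0
        for rep in range(100):
            data = rr.simulate_session(design, paper_params, seed=1000 + rep)
            ld = LikelihoodData(data)
            wins += ld.log_likelihood(paper_params) > ld.log_likelihood(worse)
        assert wins >= 95
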