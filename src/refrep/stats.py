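"""Descriptive analysis of reproduction and discrimination data.

Covers the behavioural summary layer: relative estimates (axial wrap of the
reproduced orientation to the reference), cumulative-Gaussian psychometric
fits with lapse/guess rates, Hartigan's dip test of unimodality with a
Monte-Carlo uniform null, symmetric Gamma-mixture fits to estimate
histograms, implicit-correctness trial selection, repulsive-bias curves and
per-condition SD summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import norm
from sklearn.base import BaseEstimator

from ._dip import dip_statistic
from .model import WeightingParams, weighting_function

__all__ = [
    "relative_estimate",
    "PsychFit",
    "PsychometricCurve",
    "fit_psychometric",
    "DipResult",
    "dip_test",
    "GammaMixFit",
    "GammaMixtureHistogram",
    "fit_gamma_mixture_hist",
    "select_correct_trials",
    "repulsive_bias_curve",
    "estimate_sd_summary",
]

RATE_MAX = 0.1  # upper bound on lapse and guess rates


def relative_estimate(reproduced_deg, reference_deg):
    """Reproduced orientation relative to the reference, wrapped to (-90, 90].

    Both inputs are axial orientations in [0, 180).  The wrap is modulo 180,
    so e.g. a report of 2 deg against a 165-deg reference is +17 deg.
    """
    rep = np.asarray(reproduced_deg, dtype=float)
    ref = np.asarray(reference_deg, dtype=float)
    for name, v in (("reproduced_deg", rep), ("reference_deg", ref)):
        if np.any((v < 0) | (v >= 180)):
            raise ValueError(f"{name} must lie in [0, 180)")
    d = (rep - ref + 90.0) % 180.0 - 90.0
    d = np.where(d == -90.0, 90.0, d)
    return d if d.shape else float(d)


# ---------------------------------------------------------------------------
# psychometric function
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsychFit:
    """Cumulative-Gaussian psychometric fit.

    P(CW | x) = guess + (1 - guess - lapse) * Phi((x - pse) / slope_sd).
    ``slope_sd`` is the SD of the cumulative Gaussian, i.e. the reciprocal
    slope; the discrimination threshold is identified with it.
    """

    pse: float
    slope_sd: float
    lapse: float
    guess: float
    se_pse: float
    loglik: float = float("nan")

    def predict(self, x):
        return self.guess + (1 - self.guess - self.lapse) * norm.cdf(
            (np.asarray(x, dtype=float) - self.pse) / self.slope_sd
        )


class PsychometricCurve(BaseEstimator):
    """Maximum-likelihood cumulative-Gaussian psychometric model.

    Parameters
    ----------
    n_boot : parametric-bootstrap replicates for the PSE standard error
        (0 disables).
    rate_max : bound on lapse and guess rates (default 0.1).
    random_state : seed for the bootstrap.

    Fitted attributes: ``pse_``, ``slope_sd_``, ``lapse_``, ``guess_``,
    ``se_pse_``, ``loglik_``, ``result_`` (a :class:`PsychFit`).
    """

    def __init__(self, n_boot: int = 200, rate_max: float = RATE_MAX,
                 random_state: int | None = None):
        self.n_boot = n_boot
        self.rate_max = rate_max
        self.random_state = random_state

    @staticmethod
    def _unpack(v, rate_max):
        pse, log_sd, u_guess, u_lapse = v
        return pse, np.exp(log_sd), rate_max * expit(u_guess), rate_max * expit(u_lapse)

    def _negll(self, v, x, k, n, rate_max):
        pse, sd, guess, lapse = self._unpack(v, rate_max)
        p = guess + (1 - guess - lapse) * norm.cdf((x - pse) / sd)
        p = np.clip(p, 1e-10, 1 - 1e-10)
        return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))

    def _mle(self, x, k, n, rng):
        spread = max(x.max() - x.min(), 1.0)
        p_emp = (k + 0.5) / (n + 1.0)
        pse0 = float(np.interp(0.5, p_emp, x)) if np.all(np.diff(p_emp) >= 0) else float(
            x[np.argmin(np.abs(p_emp - 0.5))]
        )
        best = None
        for jit in range(4):
            v0 = np.array([pse0, np.log(spread / 4.0), logit(0.2), logit(0.2)])
            if jit:
                v0 = v0 + rng.normal(0, [spread / 8, 0.5, 1, 1])
            res = optimize.minimize(
                self._negll, v0, args=(x, k, n, self.rate_max), method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-9},
            )
            if best is None or res.fun < best.fun:
                best = res
        return best

    def fit(self, X, y=None):
        """Fit to trial offsets X (degrees) and binary CW flags y.

        Aggregated input is also accepted: X = offsets, y = (k, n) columns via
        a 2-d y.  Requires >= 2 distinct offsets and both response classes.
        """
        x = np.asarray(X, dtype=float).ravel()
        yy = np.asarray(y)
        if yy.ndim == 2:
            k, n = yy[:, 0].astype(float), yy[:, 1].astype(float)
            xs = x
        else:
            flags = yy.astype(float).ravel()
            xs, inv = np.unique(x, return_inverse=True)
            k = np.bincount(inv, weights=flags)
            n = np.bincount(inv).astype(float)
        if len(xs) < 2:
            raise ValueError("need at least 2 distinct offsets")
        if k.sum() == 0 or k.sum() == n.sum():
            raise ValueError("degenerate data: only one response class present")
        rng = np.random.default_rng(self.random_state)
        res = self._mle(xs, k, n, rng)
        pse, sd, guess, lapse = self._unpack(res.x, self.rate_max)

        se = float("nan")
        if self.n_boot > 0:
            p_hat = np.clip(guess + (1 - guess - lapse) * norm.cdf((xs - pse) / sd), 1e-10, 1 - 1e-10)
            pses = []
            for _ in range(self.n_boot):
                kb = rng.binomial(n.astype(int), p_hat).astype(float)
                if kb.sum() == 0 or kb.sum() == n.sum():
                    continue
                rb = self._mle(xs, kb, n, rng)
                pses.append(self._unpack(rb.x, self.rate_max)[0])
            if len(pses) >= 2:
                se = float(np.std(pses, ddof=1))
        self.pse_, self.slope_sd_, self.guess_, self.lapse_ = pse, sd, guess, lapse
        self.se_pse_ = se
        self.loglik_ = -float(res.fun)
        self.result_ = PsychFit(pse, sd, lapse, guess, se, self.loglik_)
        return self

    def predict_proba(self, X):
        return self.result_.predict(X)


def fit_psychometric(offsets, cw_flags, n_boot: int = 200, seed: int | None = None) -> PsychFit:
    """MLE cumulative-Gaussian fit; see :class:`PsychometricCurve`."""
    est = PsychometricCurve(n_boot=n_boot, random_state=seed).fit(offsets, cw_flags)
    return est.result_


# ---------------------------------------------------------------------------
# dip test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DipResult:
    statistic: float
    p_value: float
    n: int
    degenerate: bool = False


_NULL_CACHE: dict = {}


def _null_dips(n: int, n_null: int, seed) -> np.ndarray:
    key = (n, n_null, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        _NULL_CACHE[key] = np.array(
            [dip_statistic(rng.uniform(size=n)) for _ in range(n_null)]
        )
        if len(_NULL_CACHE) > 16:
            _NULL_CACHE.pop(next(iter(_NULL_CACHE)))
    return _NULL_CACHE[key]


def dip_test(samples, n_null: int = 2000, seed: int | None = 0) -> DipResult:
    """Hartigan's dip test of unimodality.

    The statistic is the minimum sup-distance between the ECDF and any
    unimodal CDF; the p-value is the Monte-Carlo fraction of ``n_null``
    uniform samples of the same size whose dip is >= the observed one (the
    classical calibration against the uniform null).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 4:
        raise ValueError("dip test requires at least 4 observations")
    d = dip_statistic(x)
    if d == 0.0:  # point mass: perfectly unimodal, flagged degenerate
        return DipResult(statistic=0.0, p_value=1.0, n=x.size, degenerate=True)
    null = _null_dips(x.size, n_null, seed)
    p = float((np.sum(null >= d) + 1) / (len(null) + 1))
    return DipResult(statistic=float(d), p_value=p, n=int(x.size))


# ---------------------------------------------------------------------------
# symmetric Gamma-mixture histogram fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GammaMixFit:
    """Least-squares fit of the symmetric Gamma mixture to an estimate histogram.

    ``derived_variance`` is alpha * theta**2, the variance of each mixture
    component (about its own origin) - the spread summary compared across
    conditions.
    """

    alpha: float
    theta: float
    delta: float
    derived_variance: float
    sse: float
    ci95: dict = field(default_factory=dict)

    def density(self, x):
        w = WeightingParams(self.alpha, self.theta, self.delta)
        return weighting_function(x, w)


class GammaMixtureHistogram(BaseEstimator):
    """Histogram-based least-squares fit of the symmetric Gamma mixture.

    The sample of relative estimates is binned (default 2-degree bins over
    (-45, 45]), density-normalised, and the even mixture
    f(x) = [g(x; alpha, theta, delta) + g(-x; alpha, theta, delta)] / 2 is
    fitted by non-linear least squares with multi-start.  By default the
    shift is fixed at delta = 0 (two identical Gamma components reflected
    about the reference); ``fit_delta=True`` adds the shift as a third free
    parameter.  95% CIs come from a residual bootstrap.
    """

    def __init__(self, bin_width: float = 2.0, lo: float = -45.0, hi: float = 45.0,
                 fit_delta: bool = False, n_boot: int = 200,
                 random_state: int | None = None):
        self.bin_width = bin_width
        self.lo = lo
        self.hi = hi
        self.fit_delta = fit_delta
        self.n_boot = n_boot
        self.random_state = random_state

    def _model(self, centers, v):
        if self.fit_delta:
            la, lt, d = v
            delta = np.log1p(np.exp(d))
        else:
            la, lt = v
            delta = 0.0
        w = WeightingParams(np.exp(la), np.exp(lt), delta)
        return weighting_function(centers, w)

    def _ls(self, centers, dens, rng):
        m = np.abs(centers[np.argmax(dens)])
        inits = []
        for a0, t0 in ((2.0, max(m, 1.0) / 2), (1.5, 4.0), (4.0, max(m, 1.0) / 3), (1.1, 8.0)):
            v = [np.log(a0), np.log(t0)]
            if self.fit_delta:
                v.append(np.log(np.expm1(max(m / 2, 0.5))))
            inits.append(np.array(v))
        best = None
        for j, v0 in enumerate(inits):
            if j >= 2:
                v0 = v0 + rng.normal(0, 0.2, size=len(v0))
            res = optimize.least_squares(
                lambda v: self._model(centers, v) - dens, v0, method="lm", max_nfev=4000
            )
            if best is None or res.cost < best.cost:
                best = res
        return best

    def fit(self, X, y=None):
        est = np.asarray(X, dtype=float).ravel()
        if est.size < 50:
            raise ValueError("need at least 50 estimates for a histogram fit")
        nb = int(round((self.hi - self.lo) / self.bin_width))
        edges = self.lo + self.bin_width * np.arange(nb + 1)
        dens, _ = np.histogram(est, bins=edges, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        rng = np.random.default_rng(self.random_state)
        res = self._ls(centers, dens, rng)
        if not res.success and res.cost > 1e3:
            raise RuntimeError(f"gamma-mixture least squares failed: {res.message}")

        def unpack(v):
            if self.fit_delta:
                return np.exp(v[0]), np.exp(v[1]), float(np.log1p(np.exp(v[2])))
            return np.exp(v[0]), np.exp(v[1]), 0.0

        alpha, theta, delta = unpack(res.x)
        fitted = self._model(centers, res.x)
        resid = dens - fitted
        reps = []
        for _ in range(self.n_boot):
            dens_b = np.maximum(fitted + rng.choice(resid, size=len(resid), replace=True), 0.0)
            try:
                rb = self._ls(centers, dens_b, rng)
                reps.append(unpack(rb.x))
            except Exception:
                continue
        ci = {}
        if len(reps) >= 20:
            arr = np.asarray(reps)
            for i, name in enumerate(("alpha", "theta", "delta")):
                ci[name] = tuple(np.percentile(arr[:, i], [2.5, 97.5]))
            ci["derived_variance"] = tuple(
                np.percentile(arr[:, 0] * arr[:, 1] ** 2, [2.5, 97.5])
            )
        self.alpha_, self.theta_, self.delta_ = float(alpha), float(theta), float(delta)
        self.sse_ = float(np.sum(resid**2))
        self.ci95_ = ci
        self.result_ = GammaMixFit(
            alpha=self.alpha_, theta=self.theta_, delta=self.delta_,
            derived_variance=self.alpha_ * self.theta_**2, sse=self.sse_, ci95=ci,
        )
        return self


def fit_gamma_mixture_hist(
    estimates, bin_width: float = 2.0, fit_delta: bool = False,
    n_boot: int = 200, seed: int | None = None,
) -> GammaMixFit:
    """Least-squares symmetric Gamma-mixture fit; see :class:`GammaMixtureHistogram`."""
    est = GammaMixtureHistogram(
        bin_width=bin_width, fit_delta=fit_delta, n_boot=n_boot, random_state=seed
    ).fit(estimates)
    return est.result_


# ---------------------------------------------------------------------------
# implicit-correctness selection, bias curves, SD summaries
# ---------------------------------------------------------------------------


def select_correct_trials(
    records: pd.DataFrame, zero_offset: str = "keep", use_explicit: bool = False
) -> pd.DataFrame:
    """Keep trials whose response indicates the correct side of the reference.

    A trial is implicitly correct when the reproduction estimate falls on the
    same CW/CCW side of the reference as the true stimulus offset; this
    estimate-based rule is applied in both task conditions.  Zero-offset
    trials have no defined correct side: ``zero_offset="keep"`` (default)
    retains them with the side taken from the estimate's sign,
    ``zero_offset="drop"`` removes them.  ``use_explicit=True`` classifies
    dual-task trials by the recorded CW/CCW response instead.
    """
    if zero_offset not in ("keep", "drop"):
        raise ValueError("zero_offset must be 'keep' or 'drop'")
    off = records["offset_deg"].to_numpy(dtype=float)
    est = records["estimate_rel_deg"].to_numpy(dtype=float)
    correct = np.sign(est) == np.sign(off)
    if use_explicit and "discrimination" in records:
        resp = records["discrimination"].to_numpy()
        dual = records["task"].to_numpy() == "dual"
        explicit_ok = np.where(resp == "CW", off > 0, off < 0)
        correct = np.where(dual, explicit_ok, correct)
    if zero_offset == "keep":
        correct = correct | (off == 0)
    return records.loc[correct].copy()


def repulsive_bias_curve(records: pd.DataFrame) -> pd.DataFrame:
    """Mean repulsive bias +/- SEM per |offset| x task x noise cell.

    Per trial, bias = sign(offset) * (estimate - offset); positive values are
    estimates pushed away from the reference.  At zero offset the bias is
    |estimate| (always >= 0 under the keep-with-estimate-side convention).
    Returns a DataFrame with columns abs_offset_deg, task, noise_level,
    mean_bias_deg, sem_deg, n.
    """
    df = records.copy()
    off = df["offset_deg"].to_numpy(dtype=float)
    est = df["estimate_rel_deg"].to_numpy(dtype=float)
    bias = np.where(off == 0, np.abs(est), np.sign(off) * (est - off))
    df["_bias"] = bias
    df["abs_offset_deg"] = np.abs(off)
    rows = []
    for (a, task, noise), grp in df.groupby(["abs_offset_deg", "task", "noise_level"], sort=True):
        b = grp["_bias"].to_numpy()
        n = len(b)
        rows.append(
            {
                "abs_offset_deg": a,
                "task": task,
                "noise_level": noise,
                "mean_bias_deg": float(np.mean(b)) if n else float("nan"),
                "sem_deg": float(np.std(b, ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def estimate_sd_summary(records: pd.DataFrame) -> pd.DataFrame:
    """SD of relative estimates per task x noise cell.

    The per-(task, noise, offset) cell mean is subtracted before pooling
    across offsets, so the spread of the design itself does not inflate the
    summary.  Returns columns task, noise_level, sd_deg, n.
    """
    df = records.copy()
    centered = df.groupby(["task", "noise_level", "offset_deg"])["estimate_rel_deg"].transform(
        lambda v: v - v.mean()
    )
    df["_c"] = centered
    rows = []
    for (task, noise), grp in df.groupby(["task", "noise_level"], sort=True):
        v = grp["_c"].to_numpy()
        rows.append(
            {
                "task": task,
                "noise_level": noise,
                "sd_deg": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                "n": len(v),
            }
        )
    return pd.DataFrame(rows)
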