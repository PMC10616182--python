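"""Maximum-likelihood estimation of the observer parameters.

The nine parameters are fitted by Nelder-Mead on an unconstrained internal
scale (log for sigmas, alphas and thetas; softplus for the nonnegative
shifts; identity for the motor bias), with a jittered multi-start around a
data-driven initialisation and best-of selection.  Uncertainty comes from a
stratified nonparametric bootstrap (resampling trials with replacement
within each task x noise x offset design cell, so every replicate retains
the full design).  Model-based predictions draw a fixed number of estimates
per design cell through the synthetic observer so that predicted data can be
analysed exactly like measured data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .model import (
    GridSpec,
    LikelihoodData,
    ObserverParams,
    PARAM_NAMES,
    WeightingParams,
)
from .observer import simulate_session

__all__ = [
    "FitResult",
    "BootstrapResult",
    "ObserverModel",
    "fit_model",
    "bootstrap_fit",
    "predict_estimates",
    "recover_parameters",
    "profile_delta",
]

logger = logging.getLogger(__name__)

_SINGLE_PARAMS = ("alpha_single", "theta_single", "delta_single")
_DUAL_PARAMS = ("alpha_dual", "theta_dual", "delta_dual")


@dataclass(frozen=True)
class FitResult:
    params_hat: ObserverParams
    loglik: float
    n_trials: int
    converged: bool
    n_restarts_used: int
    fixed_params: tuple = ()

    def to_dict(self) -> dict:
        return {
            "params": self.params_hat.to_dict(),
            "loglik": self.loglik,
            "n_trials": self.n_trials,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "fixed_params": list(self.fixed_params),
        }


@dataclass(frozen=True)
class BootstrapResult:
    replicates: list
    summary: pd.DataFrame
    n_failures: int = 0

    def to_dict(self) -> dict:
        return {
            "replicates": [p.to_dict() for p in self.replicates],
            "summary": self.summary.to_dict(orient="records"),
            "n_failures": self.n_failures,
        }


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    y = max(float(y), 1e-8)
    return y + np.log(-np.expm1(-y))


_LOG_IDX = slice(0, 4)  # applies per-block below


def _pack(params: ObserverParams) -> np.ndarray:
    d = params.to_dict()
    return np.array(
        [
            np.log(d["sigma_low"]),
            np.log(d["sigma_high"]),
            np.log(d["alpha_single"]),
            np.log(d["theta_single"]),
            _softplus_inv(d["delta_single"]),
            np.log(d["alpha_dual"]),
            np.log(d["theta_dual"]),
            _softplus_inv(d["delta_dual"]),
            d["epsilon"],
        ]
    )


def _unpack(v: np.ndarray) -> ObserverParams:
    v = np.clip(v, -80.0, 80.0)  # keep exp() finite while NM explores
    return ObserverParams(
        sigma_low=float(np.exp(v[0])),
        sigma_high=float(np.exp(v[1])),
        weighting_single=WeightingParams(
            float(np.exp(v[2])), float(np.exp(v[3])), float(_softplus(v[4]))
        ),
        weighting_dual=WeightingParams(
            float(np.exp(v[5])), float(np.exp(v[6])), float(_softplus(v[7]))
        ),
        epsilon=float(v[8]),
    )


def _heuristic_init(data: pd.DataFrame) -> ObserverParams:
    """Moment-style starting point: sigmas from within-cell SDs, weighting
    location from the histogram peak of |estimate| at zero offset."""
    est = data["estimate_rel_deg"].to_numpy(dtype=float)
    eps0 = float(np.clip(np.mean(est), -5.0, 5.0))
    sig0 = {}
    for noise, grp in data.groupby("noise_level"):
        c = grp.groupby(["task", "offset_deg"])["estimate_rel_deg"].transform(
            lambda v: v - v.mean()
        )
        sig0[noise] = float(np.clip(np.std(c), 1.0, 25.0))
    weights = {}
    for task in ("single", "dual"):
        sub = data[(data["task"] == task) & (data["offset_deg"].abs() <= 3)]
        if len(sub) >= 20:
            a = np.abs(sub["estimate_rel_deg"].to_numpy() - eps0)
            hist, edges = np.histogram(a, bins=np.arange(0.0, 30.1, 2.0))
            peak = float(0.5 * (edges[:-1] + edges[1:])[np.argmax(hist)])
        else:
            peak = 6.0
        peak = max(peak, 2.0)
        weights[task] = WeightingParams(alpha=2.0, theta=peak / 4.0, delta=peak / 2.0)
    return ObserverParams(
        sigma_low=sig0.get("low", 5.0),
        sigma_high=sig0.get("high", 6.0),
        weighting_single=weights["single"],
        weighting_dual=weights["dual"],
        epsilon=eps0,
    )


class ObserverModel(BaseEstimator):
    """Sklearn-style estimator for the nine-parameter observer model.

    ``fit`` takes a trial table (DataFrame with columns task, noise_level,
    offset_deg, estimate_rel_deg) and maximises the gridded readout-density
    likelihood by multi-start Nelder-Mead.

    Parameters
    ----------
    init : optional ObserverParams used as the first start (and as the fixed
        value of parameters whose conditions are absent from the data).
    n_restarts : number of Nelder-Mead starts (first from ``init`` or a
        data-driven heuristic, the rest jittered).
    maxiter : Nelder-Mead iteration cap per start.
    fatol, xatol : Nelder-Mead convergence tolerances.
    jitter : SD of the start jitter on the unconstrained scale.
    grid, form, floor : likelihood evaluation settings (see ``refrep.model``).
    random_state : seed for start jitter.

    Fitted attributes: ``params_``, ``loglik_``, ``converged_``,
    ``n_restarts_used_``, ``fixed_params_``, ``result_`` (a :class:`FitResult`).
    """

    def __init__(self, init: ObserverParams | None = None, n_restarts: int = 8,
                 maxiter: int = 5000, fatol: float = 1e-6, xatol: float = 1e-4,
                 jitter: float = 0.3, grid: GridSpec | None = None,
                 form: str = "reflected", floor: float = 1e-12,
                 random_state: int | None = None):
        self.init = init
        self.n_restarts = n_restarts
        self.maxiter = maxiter
        self.fatol = fatol
        self.xatol = xatol
        self.jitter = jitter
        self.grid = grid
        self.form = form
        self.floor = floor
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        data = X
        if len(data) == 0:
            raise ValueError("no trials to fit")
        like = LikelihoodData(data, grid=self.grid, form=self.form, floor=self.floor)
        init = self.init if self.init is not None else _heuristic_init(data)

        fixed = []
        if "single" not in like.tasks:
            fixed += list(_SINGLE_PARAMS)
        if "dual" not in like.tasks:
            fixed += list(_DUAL_PARAMS)
        if "low" not in like.noise_levels:
            fixed.append("sigma_low")
        if "high" not in like.noise_levels:
            fixed.append("sigma_high")
        fixed_idx = np.array([PARAM_NAMES.index(p) for p in fixed], dtype=int)
        free = np.setdiff1d(np.arange(len(PARAM_NAMES)), fixed_idx)

        v_init = _pack(init)

        def objective(vf):
            v = v_init.copy()
            v[free] = vf
            return -like.log_likelihood(_unpack(v))

        rng = np.random.default_rng(self.random_state)
        best_v, best_nll = v_init[free].copy(), objective(v_init[free])
        init_nll = best_nll
        converged = False
        used = 0
        for start in range(max(self.n_restarts, 1)):
            v0 = v_init[free].copy()
            if start > 0:
                v0 = v0 + rng.normal(0.0, self.jitter, size=v0.size)
            res = optimize.minimize(
                objective, v0, method="Nelder-Mead",
                options={
                    "maxiter": self.maxiter, "maxfev": 4 * self.maxiter,
                    "fatol": self.fatol, "xatol": self.xatol, "adaptive": True,
                },
            )
            used += 1
            if res.fun < best_nll:
                best_nll, best_v = float(res.fun), res.x.copy()
            converged = converged or bool(res.success)
        v = v_init.copy()
        v[free] = best_v
        self.params_ = _unpack(v)
        self.loglik_ = -float(min(best_nll, init_nll))
        self.converged_ = converged
        self.n_restarts_used_ = used
        self.fixed_params_ = tuple(fixed)
        self.result_ = FitResult(
            params_hat=self.params_, loglik=self.loglik_, n_trials=like.n_trials,
            converged=converged, n_restarts_used=used, fixed_params=tuple(fixed),
        )
        if not converged:
            logger.warning("observer fit did not converge after %d starts", used)
        return self

    def score(self, X, y=None) -> float:
        """Log-likelihood of a trial table under the fitted parameters."""
        return LikelihoodData(X, grid=self.grid, form=self.form, floor=self.floor).log_likelihood(
            self.params_
        )

    def predict(self, X: pd.DataFrame, n_samples: int = 500, seed: int | None = 0) -> pd.DataFrame:
        """Model-predicted estimates for the design cells of X; see
        :func:`predict_estimates`."""
        return predict_estimates(self.params_, X, n_samples=n_samples, seed=seed,
                                 grid=self.grid, form=self.form)


def fit_model(data: pd.DataFrame, init: ObserverParams | None = None, **options) -> FitResult:
    """Fit the observer model; thin wrapper over :class:`ObserverModel`."""
    return ObserverModel(init=init, **options).fit(data).result_


def bootstrap_fit(
    data: pd.DataFrame,
    n_boot: int = 100,
    seed: int | None = 0,
    identity_resample: bool = False,
    **fit_options,
) -> BootstrapResult:
    """Stratified bootstrap of the observer fit.

    Trials are resampled with replacement within each task x noise x offset
    cell (so every replicate keeps the whole design), then refitted with the
    full-data estimate as starting point.  ``identity_resample=True`` is a
    test hook that skips resampling.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    full = ObserverModel(**fit_options).fit(data)
    refit_opts = dict(fit_options)
    refit_opts.setdefault("n_restarts", 2)
    reps, failures = [], 0
    for b in range(n_boot):
        if identity_resample:
            sample = data
        else:
            parts = [
                grp.sample(n=len(grp), replace=True, random_state=int(rng.integers(2**31 - 1)))
                for _, grp in data.groupby(["task", "noise_level", "offset_deg"], sort=True)
            ]
            sample = pd.concat(parts, ignore_index=True)
        try:
            fr = ObserverModel(init=full.params_, random_state=int(rng.integers(2**31 - 1)),
                               **refit_opts).fit(sample)
            reps.append(fr.params_)
        except Exception as exc:  # propagate nothing, record the failure
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            failures += 1
    mat = np.array([[p.to_dict()[k] for k in PARAM_NAMES] for p in reps])
    summary = pd.DataFrame(
        {
            "parameter": PARAM_NAMES,
            "mean": mat.mean(axis=0) if len(mat) else np.full(9, np.nan),
            "sd": mat.std(axis=0, ddof=1) if len(mat) > 1 else np.full(9, np.nan),
        }
    )
    return BootstrapResult(replicates=reps, summary=summary, n_failures=failures)


def predict_estimates(
    params: ObserverParams,
    design: pd.DataFrame,
    n_samples: int = 500,
    seed: int | None = 0,
    grid: GridSpec | None = None,
    form: str = "reflected",
) -> pd.DataFrame:
    """Model-predicted estimate samples, analysable like measured data.

    For each distinct (task, noise_level, offset_deg) cell of the design,
    ``n_samples`` estimates are drawn from the re-weighted readout through the
    synthetic observer; the output is a trial table with the same response
    columns as simulated data.
    """
    cells = (
        design[["task", "noise_level", "offset_deg"]]
        .drop_duplicates()
        .sort_values(["task", "noise_level", "offset_deg"])
        .reset_index(drop=True)
    )
    expanded = cells.loc[cells.index.repeat(n_samples)].reset_index(drop=True)
    expanded.insert(0, "trial_index", np.arange(len(expanded)))
    expanded.insert(0, "block_id", 0)
    expanded["reference_deg"] = np.nan
    return simulate_session(expanded, params, seed=seed, grid=grid, form=form)


def recover_parameters(
    true_params: ObserverParams,
    design: pd.DataFrame,
    n_replicates: int = 20,
    seed: int | None = 0,
    sim_kwargs: dict | None = None,
    **fit_options,
) -> pd.DataFrame:
    """Simulate -> fit -> tabulate recovery error per parameter.

    Returns one row per parameter with the truth, mean estimate, bias, RMSE
    and median absolute error over replicates (relative error columns for the
    positive-scale parameters).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    ests = []
    for r in range(n_replicates):
        data = simulate_session(design, true_params, seed=int(rng.integers(2**31 - 1)),
                                **(sim_kwargs or {}))
        fit = ObserverModel(random_state=int(rng.integers(2**31 - 1)), **fit_options).fit(data)
        ests.append([fit.params_.to_dict()[k] for k in PARAM_NAMES])
    mat = np.array(ests)
    truth = np.array([true_params.to_dict()[k] for k in PARAM_NAMES])
    err = mat - truth[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(err) / np.abs(truth[None, :])
    return pd.DataFrame(
        {
            "parameter": PARAM_NAMES,
            "true": truth,
            "mean_estimate": mat.mean(axis=0),
            "bias": err.mean(axis=0),
            "rmse": np.sqrt((err**2).mean(axis=0)),
            "median_abs_error": np.median(np.abs(err), axis=0),
            "median_rel_error": np.median(rel, axis=0),
        }
    )


def sampled_log_likelihood(
    params: ObserverParams,
    data: pd.DataFrame,
    n_samples: int = 500,
    seed: int | None = 0,
    bin_width: float = 2.0,
    floor: float = 1e-12,
    grid: GridSpec | None = None,
    form: str = "reflected",
) -> float:
    """Monte-Carlo alternative to the analytic gridded likelihood.

    For each design cell, ``n_samples`` model estimates are drawn through the
    observer and binned into a histogram density; each trial contributes the
    log of its bin's density mass (floored).  Noisier than
    :func:`refrep.model.log_likelihood` but independent of the analytic grid
    discretisation; provided for cross-checking.
    """
    rng = np.random.default_rng(seed)
    edges = np.arange(-90.0, 90.0 + bin_width / 2, bin_width)
    ll = 0.0
    for (task, noise, offset), grp in data.groupby(["task", "noise_level", "offset_deg"], sort=True):
        cell = grp.iloc[:1][["task", "noise_level", "offset_deg"]].copy()
        cell.insert(0, "trial_index", 0)
        cell.insert(0, "block_id", 0)
        sim = simulate_session(
            cell.loc[cell.index.repeat(n_samples)].reset_index(drop=True),
            params, seed=int(rng.integers(2**31 - 1)), grid=grid, form=form,
        )
        hist, _ = np.histogram(sim["estimate_rel_deg"], bins=edges)
        p = hist / hist.sum()
        idx = np.clip(np.digitize(grp["estimate_rel_deg"], edges) - 1, 0, len(p) - 1)
        ll += float(np.sum(np.log(np.maximum(p[idx], floor))))
    return ll


def profile_delta(
    data: pd.DataFrame, fitted: ObserverParams, task: str = "dual",
    delta_grid=None, grid: GridSpec | None = None, form: str = "reflected",
) -> pd.DataFrame:
    """Likelihood profile in the weighting shift delta at the fitted point.

    All other parameters are held at their fitted values; used as an
    identifiability guard (the fitted delta should sit within one grid step
    of the profile maximum).
    """
    if delta_grid is None:
        delta_grid = np.arange(0.0, 20.0 + 1e-9, 1.0)
    like = LikelihoodData(data, grid=grid, form=form)
    rows = []
    for d in delta_grid:
        w = fitted.weighting(task)
        p = replace(
            fitted,
            **{
                ("weighting_single" if task == "single" else "weighting_dual"): WeightingParams(
                    w.alpha, w.theta, float(d)
                )
            },
        )
        rows.append({"delta": float(d), "loglik": like.log_likelihood(p)})
    return pd.DataFrame(rows)
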