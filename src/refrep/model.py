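"""Encoding-decoding observer model: densities and likelihood.

The observer encodes the mean orientation of the ensemble as a noisy
measurement  m ~ N(mu, sigma^2)  where mu is the true stimulus orientation
relative to the reference and sigma depends on the ensemble noise level
(sigma_low for zero-noise displays, sigma_high for 9-degree-SD displays).
At decoding the measurement distribution is multiplied by a weighting
function centred on the reference,

    f(w) = 1/2 g(w; alpha, theta, delta) + 1/2 g(-w; alpha, theta, delta),

a symmetric mixture of two shifted Gamma densities

    g(w) = (theta^-alpha / Gamma(alpha)) (w - delta)^(alpha-1) e^-((w-delta)/theta),  w > delta,

with separate (alpha, theta, delta) for the single-task and dual-task
conditions.  The re-weighted, renormalised product is the readout density of
the reproduced orientation; a constant motor bias epsilon translates the
final estimate.  Altogether nine parameters:
sigma_low, sigma_high, (alpha, theta, delta) x 2 tasks, epsilon.

An alternative parameterisation translates the second component instead of
reflecting it, 1/2 g(w; .., delta) + 1/2 g(w; .., -delta); that form is a
pure translation of g and is not symmetric about the reference, so the
reflected (exactly even, bimodal) form above is the default, with the
translated variant available via ``form="literal_shift"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

__all__ = [
    "WeightingParams",
    "ObserverParams",
    "GridSpec",
    "ReadoutDensity",
    "DegenerateReadoutError",
    "gamma_density",
    "weighting_function",
    "readout_density",
    "log_likelihood",
    "PARAM_NAMES",
]

PARAM_NAMES = (
    "sigma_low",
    "sigma_high",
    "alpha_single",
    "theta_single",
    "delta_single",
    "alpha_dual",
    "theta_dual",
    "delta_dual",
    "epsilon",
)

DEFAULT_FLOOR = 1e-12


class DegenerateReadoutError(ValueError):
    """The measurement distribution and the weighting support do not overlap
    on the evaluation grid, so the re-weighted density has no mass."""


@dataclass(frozen=True)
class WeightingParams:
    """Shape/scale/shift of one task's symmetric Gamma-mixture weighting.

    alpha : Gamma shape (dimensionless, > 0)
    theta : Gamma scale (degrees, > 0)
    delta : shift of each mixture component away from the reference (degrees, >= 0)

    Each component peaks at delta + (alpha - 1) * theta degrees from the
    reference (for alpha > 1).
    """

    alpha: float
    theta: float
    delta: float = 0.0

    def __post_init__(self):
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not (self.theta > 0):
            raise ValueError(f"theta must be > 0, got {self.theta}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")

    @property
    def mode(self) -> float:
        """Location (degrees from reference) of each component's peak."""
        return self.delta + max(self.alpha - 1.0, 0.0) * self.theta


@dataclass(frozen=True)
class ObserverParams:
    """The nine-parameter observer.

    sigma_low, sigma_high : measurement SD (degrees) per ensemble noise level
    weighting_single, weighting_dual : decoding weights per task condition
    epsilon : constant motor bias (degrees), added to the final estimate
    """

    sigma_low: float
    sigma_high: float
    weighting_single: WeightingParams
    weighting_dual: WeightingParams
    epsilon: float = 0.0

    def __post_init__(self):
        if not (self.sigma_low > 0 and self.sigma_high > 0):
            raise ValueError("sigma_low and sigma_high must be > 0")

    def sigma(self, noise_level: str) -> float:
        if noise_level == "low":
            return self.sigma_low
        if noise_level == "high":
            return self.sigma_high
        raise ValueError(f"unknown noise level {noise_level!r}")

    def weighting(self, task: str) -> WeightingParams:
        if task == "single":
            return self.weighting_single
        if task == "dual":
            return self.weighting_dual
        raise ValueError(f"unknown task {task!r}")

    def to_dict(self) -> dict:
        return {
            "sigma_low": self.sigma_low,
            "sigma_high": self.sigma_high,
            "alpha_single": self.weighting_single.alpha,
            "theta_single": self.weighting_single.theta,
            "delta_single": self.weighting_single.delta,
            "alpha_dual": self.weighting_dual.alpha,
            "theta_dual": self.weighting_dual.theta,
            "delta_dual": self.weighting_dual.delta,
            "epsilon": self.epsilon,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverParams":
        return cls(
            sigma_low=float(d["sigma_low"]),
            sigma_high=float(d["sigma_high"]),
            weighting_single=WeightingParams(
                float(d["alpha_single"]), float(d["theta_single"]), float(d["delta_single"])
            ),
            weighting_dual=WeightingParams(
                float(d["alpha_dual"]), float(d["theta_dual"]), float(d["delta_dual"])
            ),
            epsilon=float(d["epsilon"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ObserverParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_vector(self) -> np.ndarray:
        return np.array([self.to_dict()[k] for k in PARAM_NAMES])

    @classmethod
    def from_vector(cls, v) -> "ObserverParams":
        return cls.from_dict(dict(zip(PARAM_NAMES, np.asarray(v, dtype=float))))


@dataclass(frozen=True)
class GridSpec:
    """Uniform evaluation grid of orientation offsets relative to the reference."""

    lo: float = -90.0
    hi: float = 90.0
    step: float = 0.1

    def __post_init__(self):
        if self.hi <= self.lo or self.step <= 0:
            raise ValueError("grid requires hi > lo and step > 0")

    @property
    def n(self) -> int:
        return int(round((self.hi - self.lo) / self.step)) + 1

    @property
    def points(self) -> np.ndarray:
        return _grid_points(self.lo, self.hi, self.step)

    def index_of(self, values) -> np.ndarray:
        """Nearest-cell index of each value; -1 for values outside the grid."""
        v = np.asarray(values, dtype=float)
        idx = np.round((v - self.lo) / self.step).astype(int)
        outside = (v < self.lo - self.step / 2) | (v > self.hi + self.step / 2)
        idx = np.clip(idx, 0, self.n - 1)
        return np.where(outside, -1, idx)


@lru_cache(maxsize=32)
def _grid_points(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    pts = lo + step * np.arange(n)
    pts.setflags(write=False)
    return pts


@dataclass
class ReadoutDensity:
    """Normalised probability mass over a uniform offset grid for one condition."""

    grid_deg: np.ndarray
    probs: np.ndarray
    stimulus_offset_deg: float
    task: str | None = None
    noise_level: str | None = None
    meta: dict = field(default_factory=dict)

    def mean(self) -> float:
        return float(np.sum(self.grid_deg * self.probs))

    def sd(self) -> float:
        mu = self.mean()
        return float(np.sqrt(np.sum((self.grid_deg - mu) ** 2 * self.probs)))

    def mode(self) -> float:
        return float(self.grid_deg[int(np.argmax(self.probs))])


def gamma_density(omega, w: WeightingParams, mirrored: bool = False) -> np.ndarray:
    """Shifted Gamma density g(omega; alpha, theta, delta) in 1/degrees.

    ``mirrored=True`` evaluates g at -omega (support omega < -delta), i.e. the
    counter-clockwise component of the weighting mixture.
    """
    om = np.asarray(omega, dtype=float)
    z = (-om if mirrored else om) - w.delta
    out = np.zeros_like(z, dtype=float)
    pos = z > 0
    zp = z[pos]
    out[pos] = np.exp(
        (w.alpha - 1.0) * np.log(zp) - zp / w.theta - w.alpha * np.log(w.theta) - gammaln(w.alpha)
    )
    if w.alpha == 1.0 and not mirrored:
        # the unit-shape component has a finite jump to 1/theta at its origin;
        # the mirrored component's support is strictly omega < -delta, so the
        # boundary point belongs to the non-mirrored branch only (this keeps
        # the alpha=1, delta=0 mixture at the Laplace value f(0) = 1/(2 theta))
        out[z == 0] = 1.0 / w.theta
    return out if out.shape else float(out)


def weighting_function(omega, w: WeightingParams, form: str = "reflected") -> np.ndarray:
    """Symmetric Gamma-mixture decoding weight f(omega), integrating to 1.

    ``form="reflected"`` (default): f(w) = [g(w) + g(-w)] / 2, exactly even.
    ``form="literal_shift"``: f(w) = [g(w; delta) + g(w; -delta)] / 2, the
    translated variant; not symmetric about 0.
    """
    if form == "reflected":
        om = np.asarray(omega, dtype=float)
        f = 0.5 * gamma_density(om, w) + 0.5 * gamma_density(om, w, mirrored=True)
        f = np.asarray(f, dtype=float)
        if w.alpha == 1.0 and w.delta > 0:
            # at the support boundaries +/-delta the unit-shape component
            # jumps; take the average of the one-sided limits there so that
            # f is exactly even (the boundary is measure zero either way)
            f = np.where(np.abs(om) == w.delta, 0.25 / w.theta, f)
        return f if f.shape else float(f)
    if form == "literal_shift":
        w_neg = WeightingParams(w.alpha, w.theta, 0.0)
        om = np.asarray(omega, dtype=float)
        return 0.5 * gamma_density(om, w) + 0.5 * gamma_density(om + w.delta, w_neg)
    raise ValueError(f"unknown weighting form {form!r}")


def readout_density(
    stimulus_offset: float,
    sigma: float,
    w: WeightingParams,
    epsilon: float = 0.0,
    grid: GridSpec | None = None,
    form: str = "reflected",
) -> ReadoutDensity:
    """Re-weighted readout density of the reproduced orientation offset.

    The measurement density N(stimulus_offset, sigma^2) is multiplied by the
    weighting function f and renormalised on the grid; the motor bias epsilon
    then translates the estimate axis, so the returned mass at grid point y is
    proportional to  N(y - epsilon; mu, sigma) * f(y - epsilon).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    grid = grid or GridSpec()
    y = grid.points
    z = y - epsilon
    q = np.exp(-0.5 * ((z - stimulus_offset) / sigma) ** 2) * weighting_function(z, w, form=form)
    total = q.sum()
    if not (total > 0) or not np.isfinite(total):
        raise DegenerateReadoutError(
            f"no overlap between N({stimulus_offset}, {sigma}) and the weighting "
            f"support on the grid [{grid.lo}, {grid.hi}]"
        )
    return ReadoutDensity(grid_deg=y, probs=q / total, stimulus_offset_deg=stimulus_offset)


def _condition_table(data):
    """Group trials by (task, noise_level, offset_deg); return conditions and
    per-condition estimate arrays.  ``data`` is a DataFrame with columns
    task, noise_level, offset_deg, estimate_rel_deg."""
    required = {"task", "noise_level", "offset_deg", "estimate_rel_deg"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"data is missing columns {sorted(missing)}")
    groups = data.groupby(["task", "noise_level", "offset_deg"], sort=True)
    return [(key, grp["estimate_rel_deg"].to_numpy(dtype=float)) for key, grp in groups]


class LikelihoodData:
    """Pre-binned trial data for fast repeated likelihood evaluation.

    Estimates are snapped to the nearest grid cell once; the log-likelihood of
    a parameter set is then a dot product of per-condition grid counts with
    per-condition log cell masses.
    """

    def __init__(self, data, grid: GridSpec | None = None, form: str = "reflected",
                 floor: float = DEFAULT_FLOOR):
        if len(data) == 0:
            raise ValueError("no trials supplied")
        self.grid = grid or GridSpec()
        self.form = form
        self.floor = floor
        self.n_trials = int(len(data))
        self.conditions = []  # (task, noise, offset)
        counts = []
        self.n_outside = 0
        for key, est in _condition_table(data):
            idx = self.grid.index_of(est)
            self.n_outside += int(np.sum(idx < 0))
            c = np.bincount(idx[idx >= 0], minlength=self.grid.n).astype(float)
            self.conditions.append(key)
            counts.append(c)
        self.counts = np.asarray(counts)
        self.tasks = sorted({c[0] for c in self.conditions})
        self.noise_levels = sorted({c[1] for c in self.conditions})

    def log_likelihood(self, params: ObserverParams) -> float:
        y = self.grid.points
        z = y - params.epsilon
        fw = {t: weighting_function(z, params.weighting(t), form=self.form) for t in self.tasks}
        ll = 0.0
        for (task, noise, offset), c in zip(self.conditions, self.counts):
            sigma = params.sigma(noise)
            q = np.exp(-0.5 * ((z - offset) / sigma) ** 2) * fw[task]
            tot = q.sum()
            if not (tot > 0) or not np.isfinite(tot):
                ll += c.sum() * np.log(self.floor)
                continue
            p = np.maximum(q / tot, self.floor)
            ll += float(c @ np.log(p))
        ll += self.n_outside * np.log(self.floor)
        return ll


def log_likelihood(
    params: ObserverParams,
    data,
    grid: GridSpec | None = None,
    form: str = "reflected",
    floor: float = DEFAULT_FLOOR,
) -> float:
    """Log-likelihood of trial-level estimates under the observer model.

    Each trial contributes the log of the readout-density cell mass nearest to
    its relative estimate; individual trial probabilities are floored at
    ``floor`` so the objective stays finite (estimates outside the grid count
    with floor probability).
    """
    return LikelihoodData(data, grid=grid, form=form, floor=floor).log_likelihood(params)
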