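"""Configuration, trial-table IO and the staged analysis pipeline.

One flat CSV schema is shared by designed and simulated (or re-exported
real) data: columns block_id, trial_index, task, reference_deg, offset_deg,
noise_level, plus estimate_rel_deg / discrimination / internal_sample_deg
once responses exist, and optionally bar_orientations (semicolon-joined
degrees of the 24 ensemble bars).  Every pipeline stage writes its outputs
together with a manifest recording the configuration hash and seeds, so a
re-run with the same config and seed reproduces the same files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import NOISE_LEVELS, OFFSETS_DEG, REFERENCES_DEG, generate_session
from .fitting import bootstrap_fit, fit_model, predict_estimates, recover_parameters
from .model import GridSpec, ObserverParams
from .observer import DEFAULT_OBSERVER, simulate_session
from .stats import (
    dip_test,
    estimate_sd_summary,
    fit_gamma_mixture_hist,
    fit_psychometric,
    repulsive_bias_curve,
    select_correct_trials,
)

__all__ = ["RunConfig", "read_trial_table", "write_trial_table", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("design", "simulate", "fit", "analyze", "recover", "report")

REQUIRED_COLUMNS = ["block_id", "trial_index", "task", "reference_deg", "offset_deg", "noise_level"]
RESPONSE_COLUMN = "estimate_rel_deg"


@dataclass
class RunConfig:
    """All pipeline settings; defaults reproduce the study design
    (6 references, +/-18 deg in 3-deg steps, noise SDs 0/9 deg, 5+5 blocks,
    100 bootstrap replicates, 500 prediction samples per design cell)."""

    references_deg: tuple = REFERENCES_DEG
    offset_step_deg: float = 3.0
    offset_max_deg: float = 18.0
    noise_sds_deg: tuple = (0.0, 9.0)
    n_single_blocks: int = 5
    n_dual_blocks: int = 5
    grid_lo: float = -90.0
    grid_hi: float = 90.0
    grid_step: float = 0.1
    weighting_form: str = "reflected"  # or "literal_shift"
    observer: dict = field(default_factory=lambda: DEFAULT_OBSERVER.to_dict())
    n_restarts: int = 8
    maxiter: int = 5000
    n_boot: int = 100
    n_pred_samples: int = 500
    n_recovery_replicates: int = 20
    dip_n_null: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.weighting_form not in ("reflected", "literal_shift"):
            raise ValueError("weighting_form must be 'reflected' or 'literal_shift'")

    @property
    def offsets_deg(self) -> tuple:
        k = int(round(self.offset_max_deg / self.offset_step_deg))
        return tuple(float(i) * self.offset_step_deg for i in range(-k, k + 1))

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.grid_lo, self.grid_hi, self.grid_step)

    @property
    def observer_params(self) -> ObserverParams:
        return ObserverParams.from_dict(self.observer)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["references_deg"] = list(self.references_deg)
        d["noise_sds_deg"] = list(self.noise_sds_deg)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for k in ("references_deg", "noise_sds_deg"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_trial_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial table CSV.

    Tables without an estimate column load in design-only mode.  Malformed
    degrees or unknown enum values fail hard with the offending row numbers
    (0-based data rows).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    def bad_rows(mask):
        return df.index[mask].tolist()[:10]

    for col in ("reference_deg", "offset_deg"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"{path}: non-numeric {col} at rows {bad_rows(vals.isna())}")
        df[col] = vals
    bad = (df["reference_deg"] < 0) | (df["reference_deg"] >= 180)
    if bad.any():
        raise ValueError(f"{path}: reference_deg outside [0, 180) at rows {bad_rows(bad)}")
    bad = ~df["task"].isin(["single", "dual"])
    if bad.any():
        raise ValueError(f"{path}: unknown task at rows {bad_rows(bad)}")
    bad = ~df["noise_level"].isin(list(NOISE_LEVELS))
    if bad.any():
        raise ValueError(f"{path}: unknown noise_level at rows {bad_rows(bad)}")
    if RESPONSE_COLUMN in df.columns:
        vals = pd.to_numeric(df[RESPONSE_COLUMN], errors="coerce")
        if vals.isna().any():
            raise ValueError(
                f"{path}: non-numeric {RESPONSE_COLUMN} at rows {bad_rows(vals.isna())}"
            )
        bad = (vals <= -90) | (vals > 90)
        if bad.any():
            raise ValueError(f"{path}: {RESPONSE_COLUMN} outside (-90, 90] at rows {bad_rows(bad)}")
    return df


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {path}; run the producing stage first or pass --data"
        )
    return path


def _analyze(data: pd.DataFrame, config: RunConfig, out: Path, seed: int) -> dict:
    """Descriptive analysis of a response table; writes the report files."""
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    psych = {}
    dual = data[data["task"] == "dual"]
    for noise, grp in dual.groupby("noise_level"):
        if grp["discrimination"].isin(["CW", "CCW"]).all() and len(grp) > 0:
            try:
                pf = fit_psychometric(
                    grp["offset_deg"], (grp["discrimination"] == "CW").astype(int),
                    n_boot=min(config.n_boot, 200), seed=seed,
                )
                psych[noise] = dataclasses.asdict(pf)
            except ValueError as exc:
                psych[noise] = {"error": str(exc)}
    (out / "psychfit.json").write_text(json.dumps(psych, indent=2))
    written["psychfit"] = "psychfit.json"

    dips, gammas = {}, {}
    for (task, noise), grp in data.groupby(["task", "noise_level"]):
        est = grp[RESPONSE_COLUMN].dropna().to_numpy()
        key = f"{task}_{noise}"
        if len(est) >= 4:
            d = dip_test(est, n_null=config.dip_n_null, seed=seed)
            dips[key] = dataclasses.asdict(d)
        if len(est) >= 50:
            gm = fit_gamma_mixture_hist(est, n_boot=min(config.n_boot, 200), seed=seed)
            gammas[key] = {
                "alpha": gm.alpha, "theta": gm.theta, "delta": gm.delta,
                "derived_variance": gm.derived_variance, "sse": gm.sse, "ci95": gm.ci95,
            }
    (out / "dip.json").write_text(json.dumps(dips, indent=2))
    (out / "gammamix.json").write_text(json.dumps(gammas, indent=2))
    written["dip"] = "dip.json"
    written["gammamix"] = "gammamix.json"

    selected = select_correct_trials(data.dropna(subset=[RESPONSE_COLUMN]))
    bias = repulsive_bias_curve(selected)
    bias.to_csv(out / "bias_curve.csv", index=False)
    estimate_sd_summary(data.dropna(subset=[RESPONSE_COLUMN])).to_csv(
        out / "sd_summary.csv", index=False
    )
    written["bias_curve"] = "bias_curve.csv"
    written["sd_summary"] = "sd_summary.csv"
    return written


def _report(data: pd.DataFrame, out: Path) -> dict:
    """Diagnostic figures: estimate histograms and bias curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for ax, ((task, noise), grp) in zip(
        axes.ravel(), data.groupby(["task", "noise_level"], sort=True)
    ):
        est = grp[RESPONSE_COLUMN].dropna().to_numpy()
        ax.hist(est, bins=np.arange(-45, 45.1, 2.0), density=True, color="#777", alpha=0.8)
        if len(est) >= 50:
            try:
                gm = fit_gamma_mixture_hist(est, n_boot=0)
                xs = np.linspace(-45, 45, 400)
                ax.plot(xs, gm.density(xs), "r-", lw=1.5)
            except Exception:
                pass
        ax.set_title(f"{task} / {noise} noise")
        ax.set_xlabel("estimate rel. reference (deg)")
    fig.tight_layout()
    fig.savefig(out / "histograms.png", dpi=120)
    plt.close(fig)

    selected = select_correct_trials(data.dropna(subset=[RESPONSE_COLUMN]))
    bias = repulsive_bias_curve(selected)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for (task, noise), grp in bias.groupby(["task", "noise_level"]):
        grp = grp.sort_values("abs_offset_deg")
        ax.errorbar(grp["abs_offset_deg"], grp["mean_bias_deg"], yerr=grp["sem_deg"],
                    label=f"{task}/{noise}", marker="o", capsize=2)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("|stimulus - reference| (deg)")
    ax.set_ylabel("repulsive bias (deg)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "bias_curves.png", dpi=120)
    plt.close(fig)
    return {"histograms": "histograms.png", "bias_curves": "bias_curves.png"}


def run_pipeline(
    config: RunConfig,
    stages=STAGES,
    out_dir="run",
    seed: int | None = None,
    data_path=None,
) -> Path:
    """Execute the requested pipeline stages into ``out_dir``.

    Stage outputs: design -> trials.csv; simulate -> data.csv (+ generating
    parameters); fit -> fit.json; analyze -> report files; recover ->
    recovery.csv; report -> figures.  A manifest.json records config hash,
    seed, package version and the files written.  Stages read their inputs
    from ``out_dir`` (or ``data_path`` for externally supplied data) and fail
    with the missing filename if an upstream product is absent.
    """
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages {bad}; valid stages are {STAGES}")
    stages = [s for s in STAGES if s in stages]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    stage_seeds = {s: int(v) for s, v in zip(STAGES, rng.integers(0, 2**31 - 1, len(STAGES)))}
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": seed,
        "stage_seeds": {s: stage_seeds[s] for s in stages},
        "outputs": {},
    }

    def data_file(stage):
        if data_path is not None:
            return _require(Path(data_path), stage)
        return _require(out / "data.csv", stage)

    for stage in stages:
        s_seed = stage_seeds[stage]
        logger.info("stage %s (seed %d)", stage, s_seed)
        if stage == "design":
            trials = generate_session(
                config.n_single_blocks, config.n_dual_blocks, seed=s_seed,
                references=config.references_deg, offsets=config.offsets_deg,
            )
            write_trial_table(trials, out / "trials.csv")
            manifest["outputs"]["design"] = "trials.csv"
        elif stage == "simulate":
            trials = read_trial_table(_require(out / "trials.csv", stage))
            data = simulate_session(
                trials, config.observer_params, seed=s_seed, grid=config.grid,
                form=config.weighting_form,
            )
            write_trial_table(data, out / "data.csv")
            sidecar = {"observer": config.observer, "seed": s_seed}
            (out / "data_params.json").write_text(json.dumps(sidecar, indent=2))
            manifest["outputs"]["simulate"] = "data.csv"
        elif stage == "fit":
            data = read_trial_table(data_file(stage))
            if RESPONSE_COLUMN not in data.columns:
                raise ValueError(f"fit stage needs responses ({RESPONSE_COLUMN}) in the data table")
            fr = fit_model(
                data, grid=config.grid, form=config.weighting_form,
                n_restarts=config.n_restarts, maxiter=config.maxiter, random_state=s_seed,
            )
            payload = fr.to_dict()
            if config.n_boot > 0:
                br = bootstrap_fit(
                    data, n_boot=config.n_boot, seed=s_seed, grid=config.grid,
                    form=config.weighting_form, n_restarts=min(config.n_restarts, 2),
                    maxiter=config.maxiter,
                )
                payload["bootstrap"] = br.to_dict()
            (out / "fit.json").write_text(json.dumps(payload, indent=2))
            manifest["outputs"]["fit"] = "fit.json"
        elif stage == "analyze":
            data = read_trial_table(data_file(stage))
            if RESPONSE_COLUMN not in data.columns:
                raise ValueError(f"analyze stage needs responses ({RESPONSE_COLUMN})")
            manifest["outputs"]["analyze"] = _analyze(data, config, out / "report", s_seed)
        elif stage == "recover":
            design = generate_session(
                config.n_single_blocks, config.n_dual_blocks, seed=s_seed,
                references=config.references_deg, offsets=config.offsets_deg,
            )
            rep = recover_parameters(
                config.observer_params, design, n_replicates=config.n_recovery_replicates,
                seed=s_seed, grid=config.grid, form=config.weighting_form,
                n_restarts=min(config.n_restarts, 2), maxiter=config.maxiter,
            )
            rep.to_csv(out / "recovery.csv", index=False)
            manifest["outputs"]["recover"] = "recovery.csv"
        elif stage == "report":
            data = read_trial_table(data_file(stage))
            manifest["outputs"]["report"] = _report(data, out / "report")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
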