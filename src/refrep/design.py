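"""Factorial experiment design for the ensemble-orientation reference task.

A block fully crosses 6 reference orientations x 13 stimulus-mean offsets
(-18..+18 degrees in 3-degree steps) x 2 ensemble noise levels (all bars
identical vs. bar orientations N(mean, 9 deg)), i.e. 156 trials, randomised
within the block.  A session is 5 single-task blocks followed by 5 dual-task
blocks (1560 trials); the explicit discrimination task is introduced only
after all single-task blocks.  Orientations are axial, i.e. arithmetic is
modulo 180 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "REFERENCES_DEG",
    "OFFSETS_DEG",
    "NOISE_LEVELS",
    "NOISE_SD_DEG",
    "N_BARS",
    "TrialSpec",
    "EnsembleSample",
    "generate_block",
    "generate_session",
    "sample_ensemble",
    "attach_ensembles",
]

REFERENCES_DEG = (15.0, 45.0, 75.0, 105.0, 135.0, 165.0)
OFFSETS_DEG = tuple(float(o) for o in range(-18, 19, 3))
NOISE_LEVELS = ("low", "high")
NOISE_SD_DEG = {"low": 0.0, "high": 9.0}
N_BARS = 24
TASKS = ("single", "dual")

TRIAL_COLUMNS = ["block_id", "trial_index", "task", "reference_deg", "offset_deg", "noise_level"]


@dataclass(frozen=True)
class TrialSpec:
    """One designed trial (no response)."""

    block_id: int
    trial_index: int
    task: str
    reference_deg: float
    offset_deg: float
    noise_level: str

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.noise_level not in NOISE_LEVELS:
            raise ValueError(f"noise_level must be one of {NOISE_LEVELS}")
        if self.block_id < 1:
            raise ValueError("block_id must be >= 1")

    @property
    def stimulus_mean_deg(self) -> float:
        """Nominal ensemble mean orientation, modulo 180."""
        return (self.reference_deg + self.offset_deg) % 180.0


@dataclass(frozen=True)
class EnsembleSample:
    """Realised bar orientations of one ensemble display."""

    orientations_deg: tuple
    nominal_mean_deg: float
    noise_sd_deg: float

    def __post_init__(self):
        if len(self.orientations_deg) != N_BARS:
            raise ValueError(f"an ensemble has exactly {N_BARS} bars")


def generate_block(
    block_id: int,
    task: str,
    seed: int,
    references=REFERENCES_DEG,
    offsets=OFFSETS_DEG,
    noise_levels=NOISE_LEVELS,
) -> pd.DataFrame:
    """One randomised full-factorial block.

    Returns a DataFrame of len(references) * len(offsets) * len(noise_levels)
    trials (156 under the default design), each combination exactly once, in
    a seeded Fisher-Yates order.
    """
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}, got {task!r}")
    cells = list(product(references, offsets, noise_levels))
    order = np.random.default_rng(seed).permutation(len(cells))
    rows = [cells[i] for i in order]
    df = pd.DataFrame(rows, columns=["reference_deg", "offset_deg", "noise_level"])
    df.insert(0, "task", task)
    df.insert(0, "trial_index", np.arange(len(df)))
    df.insert(0, "block_id", int(block_id))
    return df


def generate_session(n_single: int = 5, n_dual: int = 5, seed: int = 0, **block_kwargs) -> pd.DataFrame:
    """Concatenated session: all single-task blocks first, then dual-task.

    Per-block seeds are drawn deterministically from the session seed, so the
    whole trial table is reproducible from one integer.
    """
    if n_single < 0 or n_dual < 0:
        raise ValueError("block counts must be >= 0")
    n_blocks = n_single + n_dual
    if n_blocks == 0:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    block_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_blocks)
    blocks = []
    for b in range(n_blocks):
        task = "single" if b < n_single else "dual"
        blocks.append(generate_block(b + 1, task, int(block_seeds[b]), **block_kwargs))
    return pd.concat(blocks, ignore_index=True)


def sample_ensemble(nominal_mean_deg: float, noise_level: str, rng_seed: int) -> EnsembleSample:
    """Draw the 24 bar orientations of one ensemble display.

    Low noise: all bars share the nominal mean.  High noise: i.i.d. normal
    around it with SD 9 degrees, reduced modulo 180 (axial orientations).
    """
    if noise_level not in NOISE_LEVELS:
        raise ValueError(f"noise_level must be one of {NOISE_LEVELS}")
    sd = NOISE_SD_DEG[noise_level]
    if sd == 0:
        ori = np.full(N_BARS, nominal_mean_deg % 180.0)
    else:
        rng = np.random.default_rng(rng_seed)
        ori = rng.normal(nominal_mean_deg, sd, size=N_BARS) % 180.0
    return EnsembleSample(
        orientations_deg=tuple(float(v) for v in ori),
        nominal_mean_deg=float(nominal_mean_deg % 180.0),
        noise_sd_deg=sd,
    )


def attach_ensembles(trials: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Add realised bar orientations to a trial table.

    Draws one :func:`sample_ensemble` per trial around the nominal mean
    (reference + offset, mod 180) and stores ``bar_orientations`` (semicolon-
    joined degrees) and ``realized_mean_deg``.  The nominal mean remains the
    stimulus value used by the model (ensemble variability is absorbed into
    the high-noise measurement SD); the realised mean supports sensitivity
    analyses.
    """
    out = trials.copy().reset_index(drop=True)
    rng = np.random.default_rng(seed)
    bars, means = [], []
    for row in out.itertuples():
        nominal = (row.reference_deg + row.offset_deg) % 180.0
        ens = sample_ensemble(nominal, row.noise_level, int(rng.integers(2**31 - 1)))
        ori = np.asarray(ens.orientations_deg)
        bars.append(";".join(f"{v:.4f}" for v in ori))
        # axial mean via the doubled-angle resultant
        ang = np.deg2rad(ori * 2.0)
        means.append(float(np.rad2deg(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())) / 2.0) % 180.0)
    out["bar_orientations"] = bars
    out["realized_mean_deg"] = means
    return out
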