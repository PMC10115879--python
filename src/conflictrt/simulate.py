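"""Synthetic conflict-task sessions from a shifted-lognormal hierarchical model.

The generator is the inverse of the analysis model: on clean trials

    rt = shift + exp(mu + practice[superblock] + (theta + t_i) * x + u_i + eps)

with ``x = 1`` for incongruent trials and 0 for congruent, subject
intercepts ``u_i ~ N(0, sigma_I^2)``, subject conflict slopes
``t_i ~ N(0, sigma_T^2)`` and trial noise ``eps ~ N(0, sigma_N^2)``,
all on the log-seconds scale.  Contamination mimics the artefacts the
preprocessing rules target: anticipatory presses drawn below the 0.25 s
filter, and lapses recorded as missing RTs.

Sessions are organised as 12-trial blocks; four consecutive blocks form a
48-trial "superblock", the unit of the additive practice effect and of the
cumulative-aggregation analysis.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

TRIAL_COLUMNS = [
    "subject",
    "task",
    "block",
    "superblock",
    "trial",
    "condition",
    "double_shot",
    "rt",
    "correct",
]

#: Columns written to / read from disk (superblock is derived, not stored).
CSV_COLUMNS = ["subject", "task", "block", "trial", "condition", "double_shot", "rt", "correct"]

BLOCKS_PER_SUPERBLOCK = 4


@dataclass
class DesignSpec:
    """Layout of one simulated session per subject.

    Defaults mirror a full-length conflict-task session: 36 blocks of 12
    trials (432 trials), congruent and incongruent randomly intermixed
    50/50, and a double-shot requirement (second response based on the
    irrelevant attribute) on a random third of trials.
    """

    n_subjects: int = 30
    n_blocks: int = 36
    trials_per_block: int = 12
    congruent_fraction: float = 0.5
    double_shot_fraction: float = 1.0 / 3.0
    task_label: str = "flanker2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_blocks <= 0 or self.trials_per_block <= 0:
            raise ValueError("n_subjects, n_blocks and trials_per_block must be positive")
        if not 0.0 < self.congruent_fraction < 1.0:
            raise ValueError("congruent_fraction must lie in (0, 1)")
        if not 0.0 <= self.double_shot_fraction < 1.0:
            raise ValueError("double_shot_fraction must lie in [0, 1)")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @property
    def trials_per_subject(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def n_superblocks(self) -> int:
        return int(np.ceil(self.n_blocks / BLOCKS_PER_SUPERBLOCK))


def _default_practice() -> np.ndarray:
    # Monotone ~10% total speedup across 9 superblocks, sum-to-zero.
    return np.linspace(0.05, -0.05, 9)


@dataclass
class GenerativeParams:
    """Log-scale truth for simulation.

    ``mu`` is the log-seconds intercept of ``log(rt - shift)``; ``theta``
    the fixed conflict effect; ``practice`` one additive offset per
    48-trial superblock (sum-to-zero).  Default variance components place
    trait precision at sigma_T / sigma_N = 0.06 / 0.35 ~ 0.17, in the
    range reported for conflict tasks.  Error rates are free parameters of
    the generator, not estimates from any dataset.
    """

    mu: float = -0.7
    practice: np.ndarray = field(default_factory=_default_practice)
    theta: float = 0.10
    sigma_I: float = 0.30
    sigma_T: float = 0.06
    sigma_N: float = 0.35
    shift: float = 0.2
    p_anticipatory: float = 0.02
    p_lapse: float = 0.01
    error_rate_congruent: float = 0.03
    error_rate_incongruent: float = 0.07

    def __post_init__(self) -> None:
        self.practice = np.asarray(self.practice, dtype=float)
        if self.shift < 0:
            raise ValueError("shift must be non-negative")
        for name in ("sigma_I", "sigma_T", "sigma_N"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "p_anticipatory",
            "p_lapse",
            "error_rate_congruent",
            "error_rate_incongruent",
        ):
            val = getattr(self, name)
            if not 0.0 <= val < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.practice.size and abs(self.practice.sum()) > 1e-8 * max(1.0, np.abs(self.practice).max()):
            raise ValueError("practice offsets must sum to zero")

    @property
    def eta(self) -> float:
        """Trait precision sigma_T / sigma_N implied by the parameters."""
        if self.sigma_N == 0:
            raise ValueError("eta undefined when sigma_N = 0")
        return self.sigma_T / self.sigma_N


def _subject_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"s{i + 1:0{width}d}" for i in range(n)]


def build_schedule(spec: DesignSpec) -> pd.DataFrame:
    """Lay out trials for every subject; rt and correct left unset.

    Congruency is balanced per subject (incongruent count within one trial
    of ``(1 - congruent_fraction) * total``) and randomly intermixed;
    double-shot flags are assigned uniformly at random without replacement.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    total = spec.trials_per_subject
    n_incong = int(round((1.0 - spec.congruent_fraction) * total))
    n_double = int(round(spec.double_shot_fraction * total))

    blocks = np.repeat(np.arange(1, spec.n_blocks + 1), spec.trials_per_block)
    trials = np.tile(np.arange(1, spec.trials_per_block + 1), spec.n_blocks)
    frames = []
    for sid in _subject_ids(spec.n_subjects):
        incong = np.zeros(total, dtype=bool)
        incong[rng.choice(total, size=n_incong, replace=False)] = True
        double = np.zeros(total, dtype=bool)
        if n_double:
            double[rng.choice(total, size=n_double, replace=False)] = True
        frames.append(
            pd.DataFrame(
                {
                    "subject": sid,
                    "task": spec.task_label,
                    "block": blocks,
                    "superblock": (blocks - 1) // BLOCKS_PER_SUPERBLOCK + 1,
                    "trial": trials,
                    "condition": np.where(incong, "incongruent", "congruent"),
                    "double_shot": double,
                    "rt": np.nan,
                    "correct": pd.array([pd.NA] * total, dtype="boolean"),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(
    schedule: pd.DataFrame, params: GenerativeParams, seed: int
) -> pd.DataFrame:
    """Fill a schedule with shifted-lognormal RTs and correctness.

    Clean trials follow the hierarchical model in the module docstring.
    With probability ``p_anticipatory`` the RT is replaced by
    Uniform(0.05, 0.245) (below the 0.25 s anticipatory filter); with
    probability ``p_lapse`` the RT is missing (non-response).  Correctness
    is Bernoulli with the condition's error rate; lapses are marked
    incorrect.  All draws are reproducible from ``seed``.
    """
    if schedule["rt"].notna().any():
        raise ValueError("schedule already contains rt values")
    n_super = int(schedule["superblock"].max())
    if params.practice.size < n_super:
        raise ValueError(
            f"practice vector has {params.practice.size} offsets but the "
            f"schedule spans {n_super} superblocks"
        )

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = schedule.copy()
    subjects = out["subject"].to_numpy()
    uniq, subj_idx = np.unique(subjects, return_inverse=True)
    n_subj = uniq.size
    n = len(out)

    u = rng.normal(0.0, params.sigma_I, size=n_subj)
    t = rng.normal(0.0, params.sigma_T, size=n_subj)
    eps = rng.normal(0.0, params.sigma_N, size=n)
    x = (out["condition"].to_numpy() == "incongruent").astype(float)
    log_mean = (
        params.mu
        + params.practice[out["superblock"].to_numpy() - 1]
        + (params.theta + t[subj_idx]) * x
        + u[subj_idx]
    )
    rt = params.shift + np.exp(log_mean + eps)

    # Contamination: a single uniform per trial partitions lapse /
    # anticipatory / clean so the categories are mutually exclusive.
    mix = rng.uniform(size=n)
    lapse = mix < params.p_lapse
    anticip = (~lapse) & (mix < params.p_lapse + params.p_anticipatory)
    rt[anticip] = rng.uniform(0.05, 0.245, size=n)[anticip]
    rt[lapse] = np.nan

    err = np.where(x == 1.0, params.error_rate_incongruent, params.error_rate_congruent)
    correct = rng.uniform(size=n) >= err
    correct[lapse] = False

    out["rt"] = rt
    out["correct"] = pd.array(correct, dtype="boolean")
    return out


# ---------------------------------------------------------------------------
# CSV dialect and YAML configuration


def write_trials(table: pd.DataFrame, path: str | Path | io.IOBase) -> None:
    """Write a trial table; missing RTs serialize as empty fields."""
    out = table[CSV_COLUMNS].copy()
    out["double_shot"] = out["double_shot"].astype(bool).astype(int)
    out["correct"] = out["correct"].astype("boolean").astype("Int64")
    out.to_csv(path, index=False, float_format="%.6f")


def read_trials(
    path: str | Path | io.IOBase, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read the trial CSV dialect, re-deriving the superblock index.

    ``column_map`` renames incoming headers to the canonical ones
    (``{"participant": "subject", ...}``), for ingesting archival
    long-format exports with different naming conventions.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    df["subject"] = df["subject"].astype(str)
    if "task" in df.columns:
        df["task"] = df["task"].astype(str)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV missing columns: {missing}")
    df["double_shot"] = df["double_shot"].astype(bool)
    df["correct"] = df["correct"].astype("boolean")
    df["superblock"] = (df["block"].astype(int) - 1) // BLOCKS_PER_SUPERBLOCK + 1
    return df[TRIAL_COLUMNS]


def save_config(spec: DesignSpec, params: GenerativeParams, path: str | Path) -> None:
    """Persist design + generative parameters as a YAML key-value file."""
    payload = {
        "design": asdict(spec),
        "params": {**asdict(params), "practice": [float(v) for v in params.practice]},
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(path: str | Path) -> tuple[DesignSpec, GenerativeParams]:
    payload = yaml.safe_load(Path(path).read_text())
    return DesignSpec(**payload["design"]), GenerativeParams(**payload["params"])
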