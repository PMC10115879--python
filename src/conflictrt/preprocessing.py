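"""Participant exclusion, trial filtering, log-shift transform, aggregation.

Rules applied, in order:

1. Participant exclusion — a subject is dropped entirely when overall
   accuracy is below 60%, when more than 10% of trials are anticipatory
   (rt < 0.1 s), or when more than 10% of trials are non-responses
   (missing, or not completed within 4 s).  All inequalities are strict.
2. Trial filtering — trials with rt < 0.25 s are removed as anticipatory,
   missing RTs are removed, and (optionally) incorrect first responses.
3. Transform — y = log(rt - 0.2).  After the 0.25 s filter, rt - 0.2 is
   at least 0.05 s so the logarithm is always defined.
4. Cumulative aggregation — nested subsets by scheduled block membership:
   blocks 1-4 (48 scheduled trials), 1-8 (96), ... up to the full session.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import BLOCKS_PER_SUPERBLOCK

RT_FLOOR = 0.25  # anticipatory-response cutoff, seconds
DEFAULT_SHIFT = 0.2  # shifted-lognormal shift, seconds


@dataclass
class ExclusionThresholds:
    """Participant-level exclusion rules (strict inequalities)."""

    min_accuracy: float = 0.60
    max_anticipatory_fraction: float = 0.10
    max_nonresponse_fraction: float = 0.10
    anticipatory_cutoff: float = 0.1  # seconds
    response_deadline: float = 4.0  # seconds

    def __post_init__(self) -> None:
        for name in ("min_accuracy", "max_anticipatory_fraction", "max_nonresponse_fraction"):
            val = getattr(self, name)
            if not 0.0 < val < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


def exclude_participants(
    table: pd.DataFrame, thresholds: ExclusionThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects failing any exclusion rule.

    Returns the retained table and a report with one row per excluded
    subject: columns ``subject``, ``rule``, ``statistic``.  A subject
    triggering several rules appears once per rule.
    """
    if table.empty:
        raise ValueError("trial table is empty")
    thresholds = thresholds or ExclusionThresholds()

    rt = table["rt"].to_numpy(dtype=float)
    correct = table["correct"].fillna(False).to_numpy(dtype=bool)
    stats = pd.DataFrame(
        {
            "subject": table["subject"].to_numpy(),
            "correct": correct.astype(float),
            "anticipatory": ((rt < thresholds.anticipatory_cutoff) & ~np.isnan(rt)).astype(float),
            "nonresponse": (np.isnan(rt) | (rt > thresholds.response_deadline)).astype(float),
        }
    ).groupby("subject").mean()

    records = []
    for subject, row in stats.iterrows():
        if row["correct"] < thresholds.min_accuracy:
            records.append((subject, "low_accuracy", row["correct"]))
        if row["anticipatory"] > thresholds.max_anticipatory_fraction:
            records.append((subject, "anticipatory", row["anticipatory"]))
        if row["nonresponse"] > thresholds.max_nonresponse_fraction:
            records.append((subject, "nonresponse", row["nonresponse"]))
    report = pd.DataFrame(records, columns=["subject", "rule", "statistic"])
    kept = table[~table["subject"].isin(report["subject"])].reset_index(drop=True)
    return kept, report


def filter_trials(table: pd.DataFrame, correct_only: bool = True) -> pd.DataFrame:
    """Remove missing RTs, anticipatory trials (rt < 0.25 s), and
    optionally incorrect first responses."""
    rt = table["rt"].to_numpy(dtype=float)
    keep = ~np.isnan(rt) & (rt >= RT_FLOOR)
    if correct_only:
        keep &= table["correct"].fillna(False).to_numpy(dtype=bool)
    return table[keep].reset_index(drop=True)


def log_shift_transform(table: pd.DataFrame, shift: float = DEFAULT_SHIFT) -> pd.DataFrame:
    """Attach y = log(rt - shift); raw rt is preserved for seconds-scale
    reporting.

    Raises if any rt <= shift — a sign the anticipatory filter has not
    been applied.
    """
    rt = table["rt"].to_numpy(dtype=float)
    if np.isnan(rt).any():
        raise ValueError("table contains missing RTs; apply filter_trials first")
    if (rt <= shift).any():
        raise ValueError(f"all RTs must exceed the shift ({shift} s); filter trials first")
    out = table.copy()
    out["y"] = np.log(rt - shift)
    return out


def cumulative_subsets(
    table: pd.DataFrame,
    blocks_per_level: int = BLOCKS_PER_SUPERBLOCK,
    allow_partial: bool = False,
) -> list[pd.DataFrame]:
    """Nested cumulative subsets: blocks 1..4, 1..8, ... 1..n_blocks.

    Membership is by *scheduled* block index, so trial filtering may leave
    fewer retained rows than the nominal 48 per level per subject.
    """
    if "block" not in table.columns:
        raise ValueError("table lacks a block column")
    n_blocks = int(table["block"].max())
    if n_blocks % blocks_per_level and not allow_partial:
        raise ValueError(
            f"{n_blocks} blocks is not a whole number of {blocks_per_level}-block "
            "aggregation levels; pass allow_partial=True to keep the final partial level"
        )
    edges = list(range(blocks_per_level, n_blocks + 1, blocks_per_level))
    if allow_partial and (not edges or edges[-1] != n_blocks):
        edges.append(n_blocks)
    return [table[table["block"] <= e].reset_index(drop=True) for e in edges]


class TrialPreprocessor(BaseEstimator, TransformerMixin):
    """Transformer bundling exclusion, filtering and the log-shift map.

    ``fit`` evaluates the participant-exclusion rules on the supplied
    trial table (fitted attributes ``excluded_subjects_`` and ``report_``);
    ``transform`` drops those subjects, filters trials, and attaches the
    log-shifted response ``y``.

    Parameters
    ----------
    min_accuracy, max_anticipatory_fraction, max_nonresponse_fraction :
        Participant exclusion thresholds (strict inequalities).
    correct_only : bool
        Analyze correct first responses only (default True).
    shift : float
        Shift of the lognormal, seconds.
    """

    def __init__(
        self,
        min_accuracy: float = 0.60,
        max_anticipatory_fraction: float = 0.10,
        max_nonresponse_fraction: float = 0.10,
        correct_only: bool = True,
        shift: float = DEFAULT_SHIFT,
    ):
        self.min_accuracy = min_accuracy
        self.max_anticipatory_fraction = max_anticipatory_fraction
        self.max_nonresponse_fraction = max_nonresponse_fraction
        self.correct_only = correct_only
        self.shift = shift

    def _thresholds(self) -> ExclusionThresholds:
        return ExclusionThresholds(
            min_accuracy=self.min_accuracy,
            max_anticipatory_fraction=self.max_anticipatory_fraction,
            max_nonresponse_fraction=self.max_nonresponse_fraction,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "TrialPreprocessor":
        _, report = exclude_participants(X, self._thresholds())
        self.report_ = report
        self.excluded_subjects_ = sorted(report["subject"].unique().tolist())
        self.n_subjects_in_ = X["subject"].nunique()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "report_"):
            raise ValueError("TrialPreprocessor is not fitted")
        kept = X[~X["subject"].isin(self.excluded_subjects_)].reset_index(drop=True)
        if kept.empty:
            raise ValueError("all subjects excluded")
        kept = filter_trials(kept, correct_only=self.correct_only)
        return log_shift_transform(kept, shift=self.shift)
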