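"""Scoring of the four-test face-processing battery.

The battery comprises CFMT+ (face learning/memory, 0-102 correct), YBT
(age-invariant matching, 0-35), GFMT2-S (simultaneous matching, 0-40)
and J-BFFT (famous-face recognition, proportion 0-1).  Individual
ability is summarised as the participant's *mean rank* across tests:
within each test participants are ranked ascending by score (higher
score = higher rank = better), ties receive midranks, and the composite
is the mean of the available ranks.  Participants missing a test are
ranked on the remaining tests only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import BATTERY_TESTS


@dataclass
class CompositeResult:
    """Mean-rank composite scores plus per-test z-scores and an audit."""

    table: pd.DataFrame  # participant_id, mean_rank, n_tests_used, z_<test>...
    excluded: List[str] = field(default_factory=list)  # all tests missing

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.table)


def jbfft_score(known_count: int, identified_from_face_count: int) -> float:
    """Famous-face recognition score: identified-from-face / known.

    Returns NaN (participant flagged upstream) when no celebrity was
    known at all, since the proportion is then undefined.
    """
    if known_count < 0 or identified_from_face_count < 0:
        raise ValueError("counts must be non-negative")
    if identified_from_face_count > known_count:
        raise ValueError(
            "identified_from_face_count cannot exceed known_count"
        )
    if known_count == 0:
        return float("nan")
    return identified_from_face_count / known_count


def aggregate_score(
    battery: pd.DataFrame, tests: Sequence[str] = BATTERY_TESTS
) -> CompositeResult:
    """Compute mean-rank composites from a battery score table.

    Ranking is ascending in score (rank n = best of n), with midranks
    for ties, performed among the participants non-missing on each test;
    the composite averages the ranks of available tests.  Per-test
    z-scores (over non-missing participants) are appended for the
    exploratory single-test models.
    """
    if "participant_id" not in battery.columns:
        raise ValueError("battery table requires a participant_id column")
    if len(battery) < 2:
        raise ValueError("need at least two participants to rank")
    present = [t for t in tests if t in battery.columns]
    if not present:
        raise ValueError(f"battery table has none of the test columns {tests}")

    out = pd.DataFrame({"participant_id": battery["participant_id"].values})
    ranks = np.full((len(battery), len(present)), np.nan)
    for k, t in enumerate(present):
        scores = pd.to_numeric(battery[t], errors="coerce").to_numpy(float)
        mask = np.isfinite(scores)
        if mask.sum() >= 2:
            ranks[mask, k] = rankdata(scores[mask], method="average")
        elif mask.sum() == 1:  # a single observed score ranks 1 trivially
            ranks[mask, k] = 1.0
        zs = np.full(len(battery), np.nan)
        if mask.sum() >= 2 and np.nanstd(scores[mask], ddof=1) > 0:
            zs[mask] = (scores[mask] - scores[mask].mean()) / scores[
                mask
            ].std(ddof=1)
        elif mask.sum() >= 1:
            zs[mask] = 0.0
        out[f"z_{t}"] = zs

    n_used = np.isfinite(ranks).sum(axis=1)
    rank_sum = np.nansum(np.where(np.isfinite(ranks), ranks, 0.0), axis=1)
    mean_rank = np.where(n_used > 0, rank_sum / np.maximum(n_used, 1), np.nan)
    out.insert(1, "mean_rank", mean_rank)
    out.insert(2, "n_tests_used", n_used)

    excluded = out.loc[n_used == 0, "participant_id"].astype(str).tolist()
    out = out[n_used > 0].reset_index(drop=True)
    return CompositeResult(table=out, excluded=excluded)
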