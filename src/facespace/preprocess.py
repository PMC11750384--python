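"""Trial-level preprocessing: RT exclusion rules and signal detection.

Two exclusion rules are applied to hit RTs (go responses to upright
faces), in a fixed order: (1) a floor rule removing RTs shorter than
200 ms; (2) a per-participant +/-2 SD rule, with the mean and sample SD
computed once on the floor-surviving hit RTs and applied in a single
pass with a strict inequality.  Trials without an RT (misses, correct
rejections) and false-alarm RTs pass through untouched — RT analyses in
this package use hits only.

Signal detection indices are computed per participant on the raw trial
table: hits are go responses to upright faces, false alarms pool go
responses to inverted faces and chairs.  Rates of exactly 0 or 1 are
adjusted by the 1/(2N) rule before the z-transform, so d' and the
criterion stay finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

RT_FLOOR_MS = 200.0
SD_MULTIPLIER = 2.0


@dataclass
class CleanedTrials:
    """Retained trials plus a per-rule exclusion audit."""

    trials: pd.DataFrame
    excluded: pd.DataFrame  # excluded hit trials with an exclusion_reason
    audit: pd.DataFrame  # per participant: n_hits, below_floor, beyond_2sd
    warnings: List[str] = field(default_factory=list)

    def hits(self) -> pd.DataFrame:
        """Retained go responses to upright faces (the RT analysis set)."""
        t = self.trials
        return t[
            (t["stimulus_category"] == "upright_face")
            & (t["responded"] == "go")
        ]


def filter_rts(trials: pd.DataFrame) -> CleanedTrials:
    """Apply the floor rule then the per-participant 2 SD rule to hit RTs."""
    required = {"participant_id", "stimulus_category", "responded", "rt_ms"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")

    trials = trials.reset_index(drop=True)
    is_hit = (
        (trials["stimulus_category"] == "upright_face")
        & (trials["responded"] == "go")
        & trials["rt_ms"].notna()
    )
    rt = pd.to_numeric(trials["rt_ms"], errors="coerce").to_numpy(float)

    reason = np.full(len(trials), "", dtype=object)
    below_floor = is_hit.to_numpy() & (rt < RT_FLOOR_MS)
    reason[below_floor] = "below_floor"

    warns: List[str] = []
    beyond = np.zeros(len(trials), dtype=bool)
    for pid, idx in trials.groupby("participant_id").groups.items():
        idx = np.asarray(idx)
        cand = idx[is_hit.to_numpy()[idx] & ~below_floor[idx]]
        if len(cand) < 2:
            warns.append(
                f"participant {pid}: fewer than 2 floor-surviving hit RTs; "
                "SD rule skipped"
            )
            continue
        vals = rt[cand]
        mu = vals.mean()
        sd = vals.std(ddof=1)
        if sd > 0:
            beyond[cand] = np.abs(vals - mu) > SD_MULTIPLIER * sd
    reason[beyond] = "beyond_2sd"

    excluded_mask = below_floor | beyond
    retained = trials[~excluded_mask].reset_index(drop=True)
    excluded = trials[excluded_mask].copy()
    excluded["exclusion_reason"] = reason[excluded_mask]

    audit = (
        pd.DataFrame(
            {
                "participant_id": trials["participant_id"],
                "is_hit": is_hit,
                "below_floor": below_floor,
                "beyond_2sd": beyond,
            }
        )
        .groupby("participant_id", sort=True)
        .agg(
            n_hits=("is_hit", "sum"),
            below_floor=("below_floor", "sum"),
            beyond_2sd=("beyond_2sd", "sum"),
        )
        .reset_index()
    )
    audit["retained_hits"] = (
        audit["n_hits"] - audit["below_floor"] - audit["beyond_2sd"]
    )
    for w in warns:
        warnings.warn(w)
    return CleanedTrials(
        trials=retained, excluded=excluded, audit=audit, warnings=warns
    )


def adjust_rate(rate: float, n: int) -> float:
    """Clamp an observed rate of exactly 0 or 1 by the 1/(2N) rule."""
    if n <= 0:
        raise ValueError("rate adjustment requires n > 0")
    if rate <= 0.0:
        return 1.0 / (2 * n)
    if rate >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    return rate


def dprime(hit_rate: float, fa_rate: float) -> float:
    """Sensitivity: z(hit) - z(fa).  Rates must lie strictly in (0, 1)."""
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def criterion(hit_rate: float, fa_rate: float) -> float:
    """Response bias: -(z(hit) + z(fa)) / 2; negative = liberal."""
    return float(-(norm.ppf(hit_rate) + norm.ppf(fa_rate)) / 2.0)


def sdt_indices(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant hit rate, false-alarm rate, d' and criterion.

    Computed on the raw (unfiltered) trial table.  False alarms pool go
    responses to inverted faces and chairs.
    """
    rows = []
    for pid, g in trials.groupby("participant_id", sort=True):
        go = g[g["stimulus_category"] == "upright_face"]
        nogo = g[g["stimulus_category"].isin(["inverted_face", "chair"])]
        if len(nogo) == 0:
            raise ValueError(
                f"participant {pid}: no no-go trials; false-alarm rate undefined"
            )
        if len(go) == 0:
            raise ValueError(
                f"participant {pid}: no go trials; hit rate undefined"
            )
        hit_rate = (go["responded"] == "go").mean()
        fa_rate = (nogo["responded"] == "go").mean()
        h_adj = adjust_rate(hit_rate, len(go))
        f_adj = adjust_rate(fa_rate, len(nogo))
        rows.append(
            {
                "participant_id": pid,
                "hit_rate": hit_rate,
                "fa_rate": fa_rate,
                "hit_rate_adj": h_adj,
                "fa_rate_adj": f_adj,
                "d_prime": dprime(h_adj, f_adj),
                "criterion": criterion(h_adj, f_adj),
                "n_go": len(go),
                "n_nogo": len(nogo),
            }
        )
    return pd.DataFrame(rows)


def speed_accuracy_check(trials: pd.DataFrame):
    """Test for a speed-accuracy trade-off: RT ~ trial_index x correctness.

    Fit on all responded (RT-bearing) trials with a participant random
    intercept; `correct` distinguishes hits from false alarms.  Returns a
    :class:`facespace.mixed.ModelFit`; when correctness does not vary the
    interaction is inestimable and a flagged fit is returned instead of
    raising.
    """
    from .mixed import ModelFit, fit_lmm

    resp = trials[trials["rt_ms"].notna()].copy()
    resp["correct"] = resp["correct"].astype(int)
    resp["trial_index"] = resp["trial_index"].astype(float)
    if resp["correct"].nunique() < 2:
        return ModelFit.flagged_fit(
            outcome="rt_ms",
            note="correctness does not vary; trial_index x correct inestimable",
        )
    return fit_lmm(
        resp,
        outcome="rt_ms",
        fixed="trial_index * correct",
        groups="participant_id",
        random_slope=None,
    )
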