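"""Per-identity exponential learning rates from repeated detection RTs.

With repeated presentations of the same face identity, detection RTs are
modelled as an exponential approach to a fixed asymptote RT_inf (the
minimum meaningful RT, 200 ms):

    RT_n = RT_inf - (RT_inf - RT_0) * exp(-alpha * n)

Inverting for the n-th presentation yields the per-presentation learning
rate, the quantity analysed downstream:

    alpha = -log((RT_inf - RT_n) / (RT_inf - RT_0)) / n

where RT_0 is the RT of the first retained presentation of that identity
and n is the occurrence index of the later presentation.  alpha > 0
means RTs have dropped (learning), alpha = 0 no change, alpha < 0 a
slowdown.  RT_n values at or below the asymptote make the log argument
non-positive; such presentations yield an undefined alpha and are
excluded with an audit entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

RT_INF_MS = 200.0

LEARNING_COLUMNS = [
    "participant_id",
    "identity_id",
    "typicality",
    "occurrence",
    "rt0",
    "rtn",
    "rt_inf",
    "alpha",
]


def forward_rt(rt0: float, alpha: float, n, rt_inf: float = RT_INF_MS):
    """Exponential learning curve: RT at the n-th presentation."""
    n = np.asarray(n, dtype=float)
    return rt_inf - (rt_inf - rt0) * np.exp(-alpha * n)


def compute_alpha(rt0, rtn, n, rt_inf: float = RT_INF_MS):
    """Invert the learning curve for alpha; NaN where undefined.

    Vectorised over ``rtn`` and ``n``.  Raises when ``rt0 <= rt_inf``
    (the model requires the anchor to lie above the asymptote); returns
    NaN where ``rtn <= rt_inf`` (log of a non-positive ratio).
    """
    rt0 = float(rt0)
    if rt0 <= rt_inf:
        raise ValueError(
            f"rt0 must exceed rt_inf ({rt_inf} ms); got rt0={rt0}"
        )
    rtn = np.asarray(rtn, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("presentation index n must be >= 1")
    ratio = (rt_inf - rtn) / (rt_inf - rt0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(ratio > 0, -np.log(np.where(ratio > 0, ratio, 1.0)) / n, np.nan)
    if alpha.ndim == 0:
        return float(alpha)
    return alpha


@dataclass
class LearningRateResult:
    """Learning-rate table plus an audit of undefined/unusable entries."""

    table: pd.DataFrame
    audit: pd.DataFrame  # per participant: n_records, n_undefined_alpha,
    #                      n_identities_skipped


def learning_rate_table(
    cleaned_hits: pd.DataFrame, rt_inf: float = RT_INF_MS
) -> LearningRateResult:
    """Build the per-presentation learning-rate table.

    ``cleaned_hits`` are retained go responses to upright faces (see
    :meth:`facespace.preprocess.CleanedTrials.hits`), carrying
    ``participant_id``, ``identity_id``, ``typicality``, ``occurrence``
    and ``rt_ms``.  For each participant x identity, RT_0 is the RT at
    the first retained presentation; every later retained presentation
    contributes one record with n equal to its occurrence index.
    Identities with fewer than two retained presentations produce no
    records; presentations whose alpha is undefined (RT_n <= RT_inf, or
    an anchor RT_0 <= RT_inf) are excluded.  Both cases are audited.
    """
    required = {"participant_id", "identity_id", "occurrence", "rt_ms"}
    missing = required - set(cleaned_hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")

    records = []
    audit_rows = []
    grouped = cleaned_hits.groupby("participant_id", sort=True)
    for pid, g in grouped:
        n_records = 0
        n_undef = 0
        n_skipped = 0
        for ident, gi in g.groupby("identity_id", sort=True):
            gi = gi.sort_values("occurrence")
            if len(gi) < 2:
                n_skipped += 1
                continue
            occ = gi["occurrence"].to_numpy(float)
            rts = gi["rt_ms"].to_numpy(float)
            rt0 = rts[0]
            typ = gi["typicality"].iloc[0] if "typicality" in gi else None
            if rt0 <= rt_inf:
                # cannot anchor the curve; whole identity unusable
                n_skipped += 1
                n_undef += len(gi) - 1
                continue
            alphas = compute_alpha(rt0, rts[1:], occ[1:], rt_inf=rt_inf)
            alphas = np.atleast_1d(alphas)
            for k in range(len(alphas)):
                if not np.isfinite(alphas[k]):
                    n_undef += 1
                    continue
                records.append(
                    {
                        "participant_id": pid,
                        "identity_id": ident,
                        "typicality": typ,
                        "occurrence": int(occ[1 + k]),
                        "rt0": rt0,
                        "rtn": rts[1 + k],
                        "rt_inf": rt_inf,
                        "alpha": alphas[k],
                    }
                )
                n_records += 1
        audit_rows.append(
            {
                "participant_id": pid,
                "n_records": n_records,
                "n_undefined_alpha": n_undef,
                "n_identities_skipped": n_skipped,
            }
        )
    table = pd.DataFrame(records, columns=LEARNING_COLUMNS)
    audit = pd.DataFrame(audit_rows)
    return LearningRateResult(table=table, audit=audit)
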