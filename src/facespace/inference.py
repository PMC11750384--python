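"""Statistical layer: typicality contrasts, mixed models, Bayes factors.

The confirmatory questions are (i) whether distinctive faces are
detected more slowly than typical ones (paired contrast on participant
mean RTs, with a paired Cohen's d), and (ii) whether the typicality
effect on RTs or on learning rates scales with face-processing ability
(the typicality x composite-score interaction in linear mixed models
with participant random intercepts and, where convergent, random
typicality slopes; Satterthwaite t-tests).  Evidence for or against the
interaction is quantified by a BIC-approximated Bayes factor

    BF10 = exp((BIC_null - BIC_alt) / 2)

comparing the interaction model with the same model without the
interaction, both refit by maximum likelihood.  Learning-rate models
are fit twice, with the outcome on its original scale and on the log
scale (non-positive rates dropped, audited); the lower-BIC model wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import mannwhitneyu, nct, pearsonr
from scipy.stats import t as t_dist

from .battery import aggregate_score
from .config import BATTERY_TESTS, SimulationConfig
from .mixed import ModelFit, fit_lmm, holm_adjust
from .preprocess import CleanedTrials, filter_rts
from .simulate import simulate_dataset

INTERACTION_TERM = "distinctive:score"


# --------------------------------------------------------------------------
# paired typicality contrast
# --------------------------------------------------------------------------

@dataclass
class EffectSize:
    """Paired contrast distinctive - typical on participant mean RTs."""

    mean_diff_ms: float
    sd_diff_ms: float
    t: float
    df: int
    p: float
    cohens_d: float
    d_ci_low: float
    d_ci_high: float
    n_pairs: int
    n_dropped: int = 0
    ci_method: str = "noncentral-t"
    degenerate: bool = False


def _d_ci_noncentral(t_obs: float, n: int, level: float = 0.95):
    """CI for a paired Cohen's d by inverting the noncentral t CDF."""
    df = n - 1
    lo_q, hi_q = (1 + level) / 2, (1 - level) / 2
    scale = np.sqrt(n)

    def solve(target_q):
        f = lambda nc: nct.cdf(t_obs, df, nc) - target_q
        lo, hi = t_obs - 1.0, t_obs + 1.0
        for _ in range(60):
            if f(lo) > 0 > f(hi):
                break
            lo -= 2.0
            hi += 2.0
        else:  # pragma: no cover - bracket failure
            return np.nan
        return brentq(f, lo, hi, xtol=1e-10)

    return solve(lo_q) / scale, solve(hi_q) / scale


def typicality_contrast(hits: pd.DataFrame | CleanedTrials) -> EffectSize:
    """Paired test of the typicality detection advantage.

    ``hits`` is a table of retained go responses to upright faces (or a
    :class:`CleanedTrials`, whose hits are used).  Participant mean RTs
    are formed per typicality condition; the paired difference is
    distinctive - typical, tested with a paired t-test (df = n - 1) and
    summarised as Cohen's d on the paired differences with a 95% CI
    from the noncentral-t distribution.
    """
    if isinstance(hits, CleanedTrials):
        hits = hits.hits()
    means = (
        hits.groupby(["participant_id", "typicality"], observed=True)["rt_ms"]
        .mean()
        .unstack("typicality")
    )
    n_total = len(means)
    means = means.dropna(subset=["typical", "distinctive"])
    n = len(means)
    if n < 2:
        raise ValueError("need >= 2 participants with both conditions")
    diff = (means["distinctive"] - means["typical"]).to_numpy(float)
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    if sd_diff == 0.0:
        return EffectSize(
            mean_diff_ms=mean_diff,
            sd_diff_ms=0.0,
            t=np.inf if mean_diff != 0 else 0.0,
            df=n - 1,
            p=0.0 if mean_diff != 0 else 1.0,
            cohens_d=np.nan,
            d_ci_low=np.nan,
            d_ci_high=np.nan,
            n_pairs=n,
            n_dropped=n_total - n,
            degenerate=True,
        )
    d = mean_diff / sd_diff
    t_obs = d * np.sqrt(n)
    p = float(2.0 * t_dist.sf(abs(t_obs), n - 1))
    ci_lo, ci_hi = _d_ci_noncentral(t_obs, n)
    return EffectSize(
        mean_diff_ms=mean_diff,
        sd_diff_ms=sd_diff,
        t=float(t_obs),
        df=n - 1,
        p=p,
        cohens_d=float(d),
        d_ci_low=float(ci_lo),
        d_ci_high=float(ci_hi),
        n_pairs=n,
        n_dropped=n_total - n,
    )


# --------------------------------------------------------------------------
# Bayes factors
# --------------------------------------------------------------------------

@dataclass
class BayesFactorResult:
    bf10: float
    log_bf10: float
    bic_null: float
    bic_alt: float
    derivation: str = "BIC approximation"


def bic_bayes_factor(bic_null: float, bic_alt: float) -> BayesFactorResult:
    """BIC-approximated Bayes factor for the alternative over the null.

    ``log_bf10`` is exact for arbitrarily large BIC differences; ``bf10``
    itself overflows to inf (or underflows to 0) beyond ~|dBIC| = 1400.
    """
    if not (np.isfinite(bic_null) and np.isfinite(bic_alt)):
        raise ValueError("both BICs must be finite")
    log_bf = (bic_null - bic_alt) / 2.0
    with np.errstate(over="ignore"):
        bf = float(np.exp(log_bf))
    return BayesFactorResult(
        bf10=bf,
        log_bf10=float(log_bf),
        bic_null=float(bic_null),
        bic_alt=float(bic_alt),
    )


# --------------------------------------------------------------------------
# mixed models for RTs and learning rates
# --------------------------------------------------------------------------

@dataclass
class InteractionReport:
    """A fitted model plus the Bayes factor for its key interaction."""

    fit: ModelFit
    interaction_term: str = INTERACTION_TERM
    bf10: Optional[float] = None
    bic_null: Optional[float] = None

    def to_dict(self) -> Dict:
        out = self.fit.to_dict()
        out["interaction_term"] = self.interaction_term
        out["bf10_interaction"] = self.bf10
        out["bic_null"] = self.bic_null
        return out


def _prepare_model_frame(
    rows: pd.DataFrame,
    composites: pd.DataFrame,
    outcome: str,
    score_col: str = "mean_rank",
) -> Tuple[pd.DataFrame, List[str]]:
    """Join outcome rows with composite scores and numeric-code factors."""
    notes: List[str] = []
    comp = composites.rename(columns={score_col: "score"})[
        ["participant_id", "score"]
    ]
    df = rows.merge(comp, on="participant_id", how="inner")
    df = df.dropna(subset=[outcome, "score", "typicality"])
    df["distinctive"] = (df["typicality"] == "distinctive").astype(float)
    df["occurrence"] = pd.to_numeric(df["occurrence"]).astype(float)
    if "gender" in df.columns and df["gender"].notna().all():
        df["male"] = (df["gender"] == "male").astype(float)
        if df["male"].nunique() < 2:
            notes.append("gender does not vary; covariate dropped")
            df = df.drop(columns=["male"])
    else:
        notes.append("gender unavailable; covariate dropped")
    return df, notes


def _fixed_formulas(df: pd.DataFrame, occurrence_term: bool):
    gender = " + male" if "male" in df.columns else ""
    if occurrence_term:
        full = f"distinctive * score + distinctive * occurrence{gender}"
        null = f"distinctive * occurrence + score{gender}"
    else:
        full = f"distinctive * score{gender}"
        null = f"distinctive + score{gender}"
    return full, null


def _fit_with_bf(
    df: pd.DataFrame,
    outcome: str,
    occurrence_term: bool,
    random_slope: bool,
    outcome_scale: str,
    holm: bool,
    extra_notes: List[str],
) -> InteractionReport:
    full, null = _fixed_formulas(df, occurrence_term)
    slope = "distinctive" if random_slope else None
    fit = fit_lmm(
        df,
        outcome=outcome,
        fixed=full,
        groups="participant_id",
        random_slope=slope,
        outcome_scale=outcome_scale,
    )
    fit.notes = extra_notes + fit.notes
    if holm and len(fit.params):
        fit.params["p_holm"] = holm_adjust(fit.params["p"].to_numpy())
    bf10 = bic_null = None
    if not fit.flagged and np.isfinite(fit.bic):
        # refit the null with the structure the full model settled on
        null_slope = slope if "slope" in fit.re_structure else None
        null_fit = fit_lmm(
            df,
            outcome=outcome,
            fixed=null,
            groups="participant_id",
            random_slope=null_slope,
            outcome_scale=outcome_scale,
        )
        if np.isfinite(null_fit.bic):
            res = bic_bayes_factor(null_fit.bic, fit.bic)
            bf10, bic_null = res.bf10, res.bic_null
    return InteractionReport(fit=fit, bf10=bf10, bic_null=bic_null)


def fit_rt_model(
    cleaned: CleanedTrials | pd.DataFrame,
    composites: pd.DataFrame,
    random_slope: bool = True,
    occurrence_term: bool = True,
    score_col: str = "mean_rank",
    holm: bool = False,
) -> InteractionReport:
    """Mixed model of hit RTs on typicality x score (+ occurrence, gender).

    Fixed effects: typicality (distinctive indicator), composite score,
    identity occurrence, the typicality x score and typicality x
    occurrence interactions, and a gender covariate when available.
    Random effects: participant intercepts, plus a random typicality
    slope when it converges (deterministic downgrade otherwise).
    """
    hits = cleaned.hits() if isinstance(cleaned, CleanedTrials) else cleaned
    if "gender" in composites.columns and "gender" not in hits.columns:
        hits = hits.merge(
            composites[["participant_id", "gender"]], on="participant_id"
        )
    df, notes = _prepare_model_frame(hits, composites, "rt_ms", score_col)
    return _fit_with_bf(
        df, "rt_ms", occurrence_term, random_slope, "original", holm, notes
    )


@dataclass
class AlphaModelComparison:
    """Learning-rate models on the original and log outcome scale."""

    linear: InteractionReport
    log: InteractionReport
    best_scale: str
    n_dropped_log: int = 0

    def best(self) -> InteractionReport:
        return self.linear if self.best_scale == "original" else self.log

    def to_dict(self) -> Dict:
        return {
            "linear": self.linear.to_dict(),
            "log": self.log.to_dict(),
            "best_scale": self.best_scale,
            "n_dropped_log": self.n_dropped_log,
        }


def fit_alpha_model(
    lr_table: pd.DataFrame,
    composites: pd.DataFrame,
    random_slope: bool = True,
    occurrence_term: bool = True,
    score_col: str = "mean_rank",
    holm: bool = False,
) -> AlphaModelComparison:
    """Mixed models of learning rates, on linear and log outcome scales.

    Both models share the fixed/random structure of the RT model with
    the per-presentation learning rate as outcome.  The log model drops
    non-positive rates (audited in ``n_dropped_log``); the scale with
    the lower BIC is selected.
    """
    if lr_table["participant_id"].nunique() < 2:
        raise ValueError("learning-rate table needs >= 2 participants")
    rows = lr_table.copy()
    if "gender" in composites.columns:
        rows = rows.merge(
            composites[["participant_id", "gender"]], on="participant_id"
        )
    df, notes = _prepare_model_frame(rows, composites, "alpha", score_col)
    linear = _fit_with_bf(
        df, "alpha", occurrence_term, random_slope, "original", holm, notes
    )

    pos = df[df["alpha"] > 0].copy()
    n_dropped = len(df) - len(pos)
    if len(pos) == 0 or pos["participant_id"].nunique() < 2:
        log_rep = InteractionReport(
            fit=ModelFit.flagged_fit(
                "log_alpha", "all learning rates non-positive; log model inestimable"
            )
        )
    else:
        pos["log_alpha"] = np.log(pos["alpha"])
        log_rep = _fit_with_bf(
            pos, "log_alpha", occurrence_term, random_slope, "log", holm,
            notes + [f"dropped {n_dropped} non-positive rates for log scale"],
        )
    if log_rep.fit.flagged or not np.isfinite(log_rep.fit.bic):
        best = "original"
    else:
        best = "original" if linear.fit.bic <= log_rep.fit.bic else "log"
    return AlphaModelComparison(
        linear=linear, log=log_rep, best_scale=best, n_dropped_log=n_dropped
    )


# --------------------------------------------------------------------------
# rank-sum group comparison and battery correlations
# --------------------------------------------------------------------------

@dataclass
class RankSumResult:
    w: float
    p: float
    method: str
    n_a: int
    n_b: int


def group_compare_rank(scores_a, scores_b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison.

    W is the Mann-Whitney U statistic of the first group (the convention
    of R's ``wilcox.test``).  The exact null distribution is used for
    samples up to 50 without ties; otherwise the normal approximation
    with midranks, tie correction and continuity correction.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    exact_ok = not ties and max(len(a), len(b)) <= 50
    method = "exact" if exact_ok else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method,
                       use_continuity=True)
    return RankSumResult(
        w=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        method=method,
        n_a=len(a),
        n_b=len(b),
    )


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def battery_correlations(battery: pd.DataFrame) -> CorrelationResult:
    """Pairwise Pearson correlations between battery tests.

    Pairwise-complete observations; two-sided p per pair.  Requires at
    least three complete pairs per test pair.
    """
    tests = [t for t in BATTERY_TESTS if t in battery.columns]
    k = len(tests)
    r = pd.DataFrame(np.eye(k), index=tests, columns=tests)
    p = pd.DataFrame(np.zeros((k, k)), index=tests, columns=tests)
    n = pd.DataFrame(0, index=tests, columns=tests, dtype=int)
    for i, ti in enumerate(tests):
        n.loc[ti, ti] = battery[ti].notna().sum()
        for j in range(i + 1, k):
            tj = tests[j]
            pair = battery[[ti, tj]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"fewer than 3 complete pairs for {ti} vs {tj}"
                )
            rr, pp = pearsonr(pair[ti], pair[tj])
            r.loc[ti, tj] = r.loc[tj, ti] = rr
            p.loc[ti, tj] = p.loc[tj, ti] = pp
            n.loc[ti, tj] = n.loc[tj, ti] = len(pair)
    np.fill_diagonal(p.values, 0.0)
    return CorrelationResult(r=r, p=p, n=n)


# --------------------------------------------------------------------------
# Monte-Carlo calibration of the interaction test
# --------------------------------------------------------------------------

def simulate_interaction_pvalues(
    base_config: SimulationConfig,
    n_reps: int,
    seed: int = 0,
    random_slope: bool = False,
    occurrence_term: bool = True,
) -> np.ndarray:
    """p-values of the typicality x score interaction across replicate
    simulated datasets (used to check test calibration and power).

    Each replicate draws a fresh dataset from ``base_config`` with an
    independent seed, runs the RT preprocessing, composite scoring and
    the RT mixed model, and records the interaction p-value.  Under the
    generator's null (no ability coupling, equal learning-rate means)
    the typicality effect is homogeneous across participants, so the
    random-intercept model is correctly specified; ``random_slope``
    therefore defaults to off here.
    """
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    pvals = np.empty(n_reps)
    for r in range(n_reps):
        cfg = base_config.model_copy(update={"seed": int(rep_seeds[r])})
        data = simulate_dataset(cfg)
        cleaned = filter_rts(data.trials)
        comp = aggregate_score(data.battery).table
        comp = comp.merge(
            data.battery[["participant_id", "gender"]], on="participant_id"
        )
        report = fit_rt_model(
            cleaned,
            comp,
            random_slope=random_slope,
            occurrence_term=occurrence_term,
        )
        pvals[r] = report.fit.coef(INTERACTION_TERM)["p"]
    return pvals
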