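"""Linear mixed models with Satterthwaite t-tests.

Estimation is delegated to :class:`statsmodels` ``MixedLM`` (REML by
default).  On top of the fit, this module computes Satterthwaite
denominator degrees of freedom for each fixed-effect coefficient:

    df_j = 2 * f_j(theta)^2 / (grad f_j' A grad f_j)

where f_j(theta) = [ (X' V(theta)^-1 X)^-1 ]_jj is the sampling variance
of the j-th coefficient as a function of the variance parameters theta
(residual SD and the Cholesky factor of the random-effects covariance),
and A is the asymptotic covariance of theta_hat obtained from the
numerical Hessian of the REML deviance.  All quantities are evaluated
from per-group Gram matrices, so each deviance evaluation costs
O(groups * (p + q)^2) regardless of the number of rows.

Model comparison uses BIC from a maximum-likelihood refit of the same
structure (REML likelihoods are not comparable across fixed-effect
sets); the number of parameters counts fixed effects, the free elements
of the random-effects covariance, and the residual variance.

The random-effects structure follows a deterministic downgrade rule:
when a random slope is requested but the fit fails to converge or is
singular, the model is refit with a random intercept only and the
downgrade is recorded in the fit's notes — never silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import t as t_dist

import statsmodels.formula.api as smf

_SINGULAR_TOL = 1e-8


@dataclass
class ModelFit:
    """Result of a mixed-model fit.

    ``params`` has one row per fixed-effect term with columns
    ``estimate``, ``se``, ``df`` (Satterthwaite), ``t`` and ``p``.
    """

    outcome: str
    params: pd.DataFrame
    formula: str = ""
    outcome_scale: str = "original"
    re_structure: str = "intercept"
    converged: bool = True
    singular: bool = False
    loglik_reml: float = float("nan")
    bic: float = float("nan")
    n_obs: int = 0
    n_groups: int = 0
    notes: List[str] = field(default_factory=list)
    flagged: bool = False

    @classmethod
    def flagged_fit(cls, outcome: str, note: str) -> "ModelFit":
        return cls(
            outcome=outcome,
            params=pd.DataFrame(
                columns=["estimate", "se", "df", "t", "p"]
            ),
            converged=False,
            flagged=True,
            notes=[note],
        )

    def coef(self, term: str) -> pd.Series:
        """Row for a term, matched exactly or by substring."""
        if term in self.params.index:
            return self.params.loc[term]
        hits = [ix for ix in self.params.index if term in ix]
        if len(hits) != 1:
            raise KeyError(
                f"term {term!r} matches {hits} in {list(self.params.index)}"
            )
        return self.params.loc[hits[0]]

    def to_dict(self) -> Dict:
        return {
            "outcome": self.outcome,
            "outcome_scale": self.outcome_scale,
            "formula": self.formula,
            "re_structure": self.re_structure,
            "converged": self.converged,
            "singular": self.singular,
            "flagged": self.flagged,
            "loglik_reml": _json_float(self.loglik_reml),
            "bic": _json_float(self.bic),
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "notes": self.notes,
            "coefficients": {
                ix: {
                    k: _json_float(v)
                    for k, v in row.items()
                }
                for ix, row in self.params.to_dict(orient="index").items()
            },
        }


def _json_float(v):
    v = float(v)
    return None if not np.isfinite(v) else v


class _REMLWorkspace:
    """Per-group Gram matrices for fast REML deviance / beta-covariance
    evaluation as a function of the variance parameters."""

    def __init__(self, X, Z, y, group_rows: Sequence[np.ndarray]):
        self.p = X.shape[1]
        self.q = Z.shape[1]
        self.n = X.shape[0]
        self.groups = []
        for idx in group_rows:
            Xi, Zi, yi = X[idx], Z[idx], y[idx]
            self.groups.append(
                {
                    "ni": len(idx),
                    "XtX": Xi.T @ Xi,
                    "Xty": Xi.T @ yi,
                    "yty": float(yi @ yi),
                    "ZtZ": Zi.T @ Zi,
                    "ZtX": Zi.T @ Xi,
                    "Zty": Zi.T @ yi,
                }
            )

    # theta = [sigma, lower-triangular elements of L (row-major)] with
    # G = L L' the random-effects covariance.
    def n_theta(self) -> int:
        return 1 + self.q * (self.q + 1) // 2

    def pack(self, sigma: float, L: np.ndarray) -> np.ndarray:
        idx = np.tril_indices(self.q)
        return np.concatenate([[sigma], L[idx]])

    def unpack(self, theta: np.ndarray):
        sigma = theta[0]
        L = np.zeros((self.q, self.q))
        L[np.tril_indices(self.q)] = theta[1:]
        return sigma, L

    def _assemble(self, theta: np.ndarray):
        """Sum of X'V^-1 X, X'V^-1 y, log|V| and per-group solve pieces."""
        sigma, L = self.unpack(theta)
        s2 = max(sigma * sigma, 1e-12)
        p, q = self.p, self.q
        sum_XtViX = np.zeros((p, p))
        sum_XtViy = np.zeros(p)
        logdet_V = 0.0
        pieces = []
        for g in self.groups:
            M = np.eye(q) + (L.T @ g["ZtZ"] @ L) / s2
            cf = cho_factor(M, lower=True)
            logdet_V += g["ni"] * np.log(s2) + 2.0 * np.sum(
                np.log(np.diag(cf[0]))
            )
            LtZtX = L.T @ g["ZtX"]  # q x p
            LtZty = L.T @ g["Zty"]  # q
            MinvLtZtX = cho_solve(cf, LtZtX)
            MinvLtZty = cho_solve(cf, LtZty)
            XtViX = (g["XtX"] - LtZtX.T @ MinvLtZtX / s2) / s2
            XtViy = (g["Xty"] - LtZtX.T @ MinvLtZty / s2) / s2
            sum_XtViX += XtViX
            sum_XtViy += XtViy
            pieces.append((LtZtX, LtZty, MinvLtZtX, MinvLtZty))
        return s2, sum_XtViX, sum_XtViy, logdet_V, pieces

    def deviance(self, theta: np.ndarray) -> float:
        """-2 * REML log-likelihood at theta (beta profiled out)."""
        s2, SXX, SXy, logdet_V, pieces = self._assemble(theta)
        beta = np.linalg.solve(SXX, SXy)
        quad = 0.0
        for g, (LtZtX, LtZty, MinvLtZtX, MinvLtZty) in zip(
            self.groups, pieces
        ):
            ryy = (
                g["yty"]
                - 2.0 * beta @ g["Xty"]
                + beta @ g["XtX"] @ beta
            )
            w = LtZty - LtZtX @ beta
            Minvw = MinvLtZty - MinvLtZtX @ beta
            quad += (ryy - w @ Minvw / s2) / s2
        sign, logdet_XX = np.linalg.slogdet(SXX)
        return (
            logdet_V
            + logdet_XX
            + quad
            + (self.n - self.p) * np.log(2.0 * np.pi)
        )

    def beta_cov(self, theta: np.ndarray) -> np.ndarray:
        _, SXX, _, _, _ = self._assemble(theta)
        return np.linalg.inv(SXX)

    def gls_beta(self, theta: np.ndarray) -> np.ndarray:
        """Generalised least squares fixed effects at theta (equals the
        REML profile estimate; plain OLS when all variances vanish)."""
        _, SXX, SXy, _, _ = self._assemble(theta)
        return np.linalg.solve(SXX, SXy)

    def satterthwaite_df(self, theta: np.ndarray) -> np.ndarray:
        """Satterthwaite df for each fixed-effect coefficient."""
        m = len(theta)
        h = 1e-4 * (np.abs(theta) + 1e-2)

        # numerical Hessian of the deviance (central differences)
        H = np.zeros((m, m))
        d0 = self.deviance(theta)
        for k in range(m):
            ek = np.zeros(m)
            ek[k] = h[k]
            H[k, k] = (
                self.deviance(theta + ek)
                - 2.0 * d0
                + self.deviance(theta - ek)
            ) / h[k] ** 2
        for k in range(m):
            for l in range(k + 1, m):
                ek = np.zeros(m)
                el = np.zeros(m)
                ek[k] = h[k]
                el[l] = h[l]
                H[k, l] = H[l, k] = (
                    self.deviance(theta + ek + el)
                    - self.deviance(theta + ek - el)
                    - self.deviance(theta - ek + el)
                    + self.deviance(theta - ek - el)
                ) / (4.0 * h[k] * h[l])
        A = 2.0 * np.linalg.pinv(H)

        # gradient of f_j(theta) = Var(beta_j)(theta)
        f0 = np.diag(self.beta_cov(theta))
        grads = np.zeros((self.p, m))
        for k in range(m):
            ek = np.zeros(m)
            ek[k] = h[k]
            fp = np.diag(self.beta_cov(theta + ek))
            fm = np.diag(self.beta_cov(theta - ek))
            grads[:, k] = (fp - fm) / (2.0 * h[k])

        df = np.full(self.p, float(self.n - self.p))
        for j in range(self.p):
            denom = grads[j] @ A @ grads[j]
            if denom > 0 and np.isfinite(denom):
                df_j = 2.0 * f0[j] ** 2 / denom
                if np.isfinite(df_j) and df_j > 0:
                    df[j] = min(df_j, float(self.n - self.p))
        return df


def _safe_chol(G: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(G)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(G)
        w = np.clip(w, 1e-10, None)
        return np.linalg.cholesky((V * w) @ V.T)


def holm_adjust(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, ix in enumerate(order):
        running = max(running, (m - rank) * p[ix])
        adj[ix] = min(1.0, running)
    return adj


def _fit_once(data, formula, groups, re_formula, reml):
    md = smf.mixedlm(formula, data=data, groups=data[groups],
                     re_formula=re_formula)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = md.fit(reml=reml)
        except (np.linalg.LinAlgError, ValueError):
            return md, None
    return md, res


def fit_lmm(
    data: pd.DataFrame,
    outcome: str,
    fixed: str,
    groups: str,
    random_slope: Optional[str] = None,
    outcome_scale: str = "original",
    allow_downgrade: bool = True,
) -> ModelFit:
    """Fit a linear mixed model with Satterthwaite t-tests.

    Parameters
    ----------
    data : long-format table, one row per observation.
    outcome : outcome column name.
    fixed : patsy right-hand side for the fixed effects.
    groups : grouping (participant) column.
    random_slope : term with a per-group random slope in addition to the
        random intercept, or None for a random intercept only.  On
        convergence failure or a singular covariance the model is
        downgraded to an intercept-only structure (recorded in notes).
    """
    data = data.dropna(subset=[outcome]).copy()
    formula = f"{outcome} ~ {fixed}"
    notes: List[str] = []

    structure = "intercept"
    re_formula = None
    if random_slope is not None:
        structure = f"intercept+slope({random_slope})"
        re_formula = f"~{random_slope}"

    md, res = _fit_once(data, formula, groups, re_formula, reml=True)
    singular = False
    if res is not None:
        G = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
        eig = np.linalg.eigvalsh(G)
        singular = bool(eig.min() < _SINGULAR_TOL * max(res.scale, eig.max(), 1e-12))

    if random_slope is not None and allow_downgrade and (
        res is None or not res.converged or singular
    ):
        reason = (
            "did not converge" if (res is None or not res.converged)
            else "singular random-effects covariance"
        )
        notes.append(
            f"random slope for {random_slope!r} {reason}; "
            "downgraded to random intercept only"
        )
        structure = "intercept"
        re_formula = None
        md, res = _fit_once(data, formula, groups, None, reml=True)
        singular = False
        if res is not None:
            G = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
            eig = np.linalg.eigvalsh(G)
            singular = bool(
                eig.min() < _SINGULAR_TOL * max(res.scale, eig.max(), 1e-12)
            )

    if res is None:
        return ModelFit.flagged_fit(
            outcome, f"mixed model {formula!r} could not be fit"
        )
    if not res.converged:
        notes.append("optimizer did not report convergence")
    if singular:
        notes.append("random-effects covariance is singular")

    model = md
    X = np.asarray(model.exog, dtype=float)
    y = np.asarray(model.endog, dtype=float)
    Z = np.asarray(model.exog_re, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    group_rows = [np.asarray(model.row_indices[g]) for g in model.group_labels]
    ws = _REMLWorkspace(X, Z, y, group_rows)

    G = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
    sigma = float(np.sqrt(res.scale))
    theta = ws.pack(sigma, _safe_chol(G))
    try:
        df = ws.satterthwaite_df(theta)
    except np.linalg.LinAlgError:
        df = np.full(ws.p, float(ws.n - ws.p))
        notes.append("Satterthwaite failed; residual df fallback")

    # profile GLS estimate at theta-hat: identical to the optimizer's
    # fixed effects on healthy fits, and well-defined at variance
    # boundaries where the optimizer's report can degenerate
    beta = ws.gls_beta(theta)
    se = np.sqrt(np.diag(ws.beta_cov(theta)))
    tvals = beta / se
    pvals = 2.0 * t_dist.sf(np.abs(tvals), df)
    params = pd.DataFrame(
        {
            "estimate": beta,
            "se": se,
            "df": df,
            "t": tvals,
            "p": pvals,
        },
        index=model.exog_names,
    )

    # BIC from an ML refit of the same structure
    q = ws.q
    k = ws.p + q * (q + 1) // 2 + 1
    bic = float("nan")
    _, res_ml = _fit_once(data, formula, groups, re_formula, reml=False)
    if res_ml is not None:
        bic = float(-2.0 * res_ml.llf + k * np.log(ws.n))
    else:
        notes.append("ML refit for BIC failed")

    return ModelFit(
        outcome=outcome,
        params=params,
        formula=formula,
        outcome_scale=outcome_scale,
        re_structure=structure,
        converged=bool(res.converged),
        singular=singular,
        loglik_reml=float(res.llf),
        bic=bic,
        n_obs=ws.n,
        n_groups=len(group_rows),
        notes=notes,
    )
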