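"""Risk-factor regression machinery for log10 ISI.

Multivariate linear regression of log10 ISI on risk factors with
continuous predictors standardized to unit variance (coefficients are
"per 1 SD"), classical normal-approximation 95% CIs, variance inflation
factors for multicollinearity screening, moderator (ethnicity/sex)
interaction testing gated on significant marginal effects, and
age-adjusted two-group comparisons of means (linear) and proportions
(logistic).  Fitting is delegated to statsmodels; inference uses the
normal approximation consistent with large-sample reporting (t-based CIs
by option).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityWarning, ConvergenceError, DomainError, RankDeficiencyError

logger = logging.getLogger("ogttools")

ALPHA = 0.05  # two-sided significance threshold
VIF_BOUND = 3.5  # acceptance bound for multicollinearity
DEFAULT_LOG_VARIABLES = ("isi", "dio", "triglycerides")


@dataclass
class RegressionFit:
    """One fitted linear model: standardized betas with classical inference."""

    outcome: str
    terms: list
    beta: dict
    se: dict
    ci95: dict
    p: dict
    r2: float
    n: int
    vif: dict = field(default_factory=dict)
    interaction_p: dict = field(default_factory=dict)
    standardized: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n": self.n,
            "r2": self.r2,
            "terms": [
                {
                    "term": t,
                    "beta": self.beta[t],
                    "se": self.se[t],
                    "ci95": list(self.ci95[t]),
                    "p": self.p[t],
                    "standardized": self.standardized.get(t, False),
                    "vif": self.vif.get(t),
                    "interaction_p": self.interaction_p.get(t),
                }
                for t in self.terms
            ],
        }


def standardize(values) -> np.ndarray:
    """Divide by the sample SD (denominator n−1); no centering.

    Binary indicators are conventionally left unstandardized; this helper
    is applied only to continuous terms.
    """
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DomainError("standardize: zero variance")
    return v / sd


def _is_binary(v: np.ndarray) -> bool:
    u = np.unique(v[np.isfinite(v)])
    return len(u) <= 2 and set(u) <= {0.0, 1.0}


def build_design(
    data: pd.DataFrame, terms: Sequence[str], *, standardize_continuous: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Design matrix with continuous terms scaled to unit variance.

    Returns the design (without constant) and a map term → bool recording
    which terms were standardized.
    """
    cols, std_flags = {}, {}
    for t in terms:
        v = data[t].to_numpy(dtype=float)
        if standardize_continuous and not _is_binary(v):
            cols[t] = standardize(v)
            std_flags[t] = True
        else:
            cols[t] = v
            std_flags[t] = False
    return pd.DataFrame(cols, index=data.index), std_flags


def ols_fit(
    outcome,
    design: pd.DataFrame,
    *,
    outcome_name: str = "log10_isi",
    use_t: bool = False,
    compute_vif: bool = True,
    standardized: Optional[dict] = None,
) -> RegressionFit:
    """OLS with intercept: coefficients, classical SEs, 95% CIs, p-values, R².

    CIs and p-values use the normal approximation by default
    (``use_t=True`` switches to the t reference distribution).  A
    rank-deficient design raises listing the collinear terms.
    """
    y = np.asarray(outcome, dtype=float)
    X = sm.add_constant(design.astype(float), has_constant="add")
    if len(y) < design.shape[1] + 2:
        raise DomainError(f"ols_fit: need at least {design.shape[1] + 2} complete cases, got {len(y)}")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        collinear = _collinear_terms(design)
        raise RankDeficiencyError(collinear if collinear else list(design.columns))
    res = sm.OLS(y, X).fit()

    terms = list(design.columns)
    params, bse = res.params, res.bse
    if use_t:
        crit = stats.t.ppf(0.975, res.df_resid)
        pvals = res.pvalues
    else:
        crit = stats.norm.ppf(0.975)
        z = params / bse
        pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=params.index)
    fit = RegressionFit(
        outcome=outcome_name,
        terms=["const"] + terms,
        beta={t: float(params[t]) for t in params.index},
        se={t: float(bse[t]) for t in bse.index},
        ci95={t: (float(params[t] - crit * bse[t]), float(params[t] + crit * bse[t])) for t in params.index},
        p={t: float(pvals[t]) for t in pvals.index},
        r2=float(res.rsquared),
        n=int(res.nobs),
        standardized=dict(standardized or {}),
    )
    if compute_vif and len(terms) >= 2:
        fit.vif = vif(design)
    return fit


def _collinear_terms(design: pd.DataFrame) -> list:
    """Terms involved in an exact linear dependence (by incremental rank)."""
    out, kept = [], []
    for c in design.columns:
        trial = design[kept + [c]].to_numpy(dtype=float)
        if np.linalg.matrix_rank(trial) < len(kept) + 1:
            out.append(c)
        else:
            kept.append(c)
    return out


def vif(design: pd.DataFrame) -> dict:
    """Variance inflation factor per term: 1/(1−R²_j), R²_j from regressing
    term j on the remaining terms (with intercept).

    Perfect collinearity yields ``inf``; any VIF at or above
    :data:`VIF_BOUND` (3.5) emits a :class:`CollinearityWarning`.
    """
    out = {}
    cols = list(design.columns)
    for j, c in enumerate(cols):
        others = [t for t in cols if t != c]
        X = sm.add_constant(design[others].astype(float), has_constant="add")
        r2 = sm.OLS(design[c].astype(float), X).fit().rsquared
        out[c] = float("inf") if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
        if out[c] >= VIF_BOUND:
            warnings.warn(f"VIF for {c!r} is {out[c]:.2f} (>= {VIF_BOUND})", CollinearityWarning)
            logger.warning("VIF %.2f for term %r at/above bound %.1f", out[c], c, VIF_BOUND)
    return out


def interaction_scan(
    outcome,
    design: pd.DataFrame,
    moderator: str,
    *,
    alpha: float = ALPHA,
    use_t: bool = False,
) -> pd.DataFrame:
    """Moderator-interaction p-values with marginal-effect gating.

    Fits the base model ``outcome ~ const + design`` (which must include the
    ``moderator`` column).  To limit the multiple-testing burden, a
    term × moderator product is tested only for terms whose marginal effect
    is significant at ``alpha``; gated terms are reported with status
    ``"skipped (gated)"``.  Returns a frame (term, marginal_p,
    interaction_p, status).
    """
    if moderator not in design.columns:
        raise DomainError(f"moderator {moderator!r} must be a column of the design")
    mod = design[moderator].to_numpy(dtype=float)
    if np.ptp(mod) == 0:
        raise DomainError("interaction_scan: moderator is constant")
    base = ols_fit(outcome, design, use_t=use_t, compute_vif=False)
    rows = []
    for term in design.columns:
        if term == moderator:
            continue
        marginal_p = base.p[term]
        if marginal_p >= alpha:
            rows.append({"term": term, "marginal_p": marginal_p, "interaction_p": np.nan,
                         "status": "skipped (gated)"})
            logger.info("interaction for %r skipped (marginal p=%.3f >= %.2f)", term, marginal_p, alpha)
            continue
        prod_name = f"{term}:{moderator}"
        ext = design.copy()
        ext[prod_name] = design[term].to_numpy(dtype=float) * mod
        fit = ols_fit(outcome, ext, use_t=use_t, compute_vif=False)
        rows.append({"term": term, "marginal_p": marginal_p,
                     "interaction_p": fit.p[prod_name], "status": "tested"})
    return pd.DataFrame(rows)


def age_adjusted_comparison(
    values,
    group,
    ages,
    *,
    kind: str = "continuous",
    maxiter: int = 50,
    tol: float = 1e-8,
) -> dict:
    """Age-adjusted two-group comparison of a mean or a proportion.

    ``kind="continuous"``: OLS of the variable on a group indicator plus
    age; returns the adjusted difference and its p-value.
    ``kind="proportion"``: logistic regression (Newton/IRLS) of the binary
    variable on group plus age; returns the adjusted odds ratio and its
    p-value.  Complete separation raises :class:`ConvergenceError`.
    """
    v = np.asarray(values, dtype=float)
    glabels = pd.Series(group)
    levels = sorted(glabels.unique())
    if len(levels) != 2:
        raise DomainError(f"age_adjusted_comparison: need exactly 2 groups, got {levels}")
    ind = (glabels == levels[1]).astype(float).to_numpy()
    X = sm.add_constant(pd.DataFrame({"group": ind, "age": np.asarray(ages, dtype=float)}))
    if kind == "continuous":
        res = sm.OLS(v, X).fit()
        return {"contrast": f"{levels[1]} vs {levels[0]}", "difference": float(res.params["group"]),
                "p": float(res.pvalues["group"]), "n": int(res.nobs)}
    if kind == "proportion":
        if not set(np.unique(v)) <= {0.0, 1.0}:
            raise DomainError("proportion comparison requires a binary 0/1 outcome")
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            try:
                res = sm.Logit(v, X).fit(method="newton", maxiter=maxiter, tol=tol, disp=False)
            except Exception as exc:  # separation or non-convergence
                raise ConvergenceError(f"logistic fit failed: {exc}") from exc
        if not res.mle_retvals.get("converged", True):
            raise ConvergenceError("logistic fit did not converge "
                                   f"within {maxiter} iterations (tol={tol:g})")
        return {"contrast": f"{levels[1]} vs {levels[0]}",
                "odds_ratio": float(np.exp(res.params["group"])),
                "p": float(res.pvalues["group"]), "n": int(res.nobs)}
    raise DomainError(f"unknown comparison kind {kind!r}")


def log_transform_policy(
    table: pd.DataFrame, variables: Sequence[str] = DEFAULT_LOG_VARIABLES
) -> tuple[pd.DataFrame, list]:
    """log10-transform the configured right-skewed variables.

    Returns a copy with each listed (and present) column replaced by
    ``log10_<name>`` plus a provenance list of the transformations applied.
    A non-positive value in a listed variable is an error naming the
    subject.
    """
    out = table.copy()
    provenance = []
    for var in variables:
        if var not in out.columns:
            continue
        vals = out[var].to_numpy(dtype=float)
        bad = np.isfinite(vals) & (vals <= 0)
        if bad.any():
            sid = out["subject_id"].iloc[int(np.flatnonzero(bad)[0])] if "subject_id" in out else "?"
            raise DomainError(f"log_transform_policy: non-positive {var} for subject {sid!r}")
        out[f"log10_{var}"] = np.log10(vals)
        out = out.drop(columns=[var])
        provenance.append({"variable": var, "transform": "log10"})
    return out, provenance


def backward_eliminate(
    outcome, design: pd.DataFrame, *, alpha: float = ALPHA, use_t: bool = False,
    standardized: Optional[dict] = None,
) -> RegressionFit:
    """Drop the least-significant term (p ≥ alpha) one at a time, refit,
    and return the final model — emulates stratified published tables in
    which non-significant terms appear blank."""
    cols = list(design.columns)
    while len(cols) > 1:
        fit = ols_fit(outcome, design[cols], compute_vif=False, use_t=use_t,
                      standardized=standardized)
        worst, worst_p = None, alpha
        for t in cols:
            if fit.p[t] >= worst_p:
                worst, worst_p = t, fit.p[t]
        if worst is None:
            break
        cols.remove(worst)
        logger.info("backward elimination dropped %r (p=%.3f)", worst, worst_p)
    return ols_fit(outcome, design[cols], use_t=use_t, standardized=standardized)
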