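"""Group-specific anthropometric cut-offs at equivalent insulin sensitivity.

The question answered here: at what BMI (or waist circumference) does a
comparison population reach the same age-adjusted insulin-sensitivity level
that the reference population has at a standard obesity threshold
(BMI 25 or 30 kg/m²; waist 94 cm in men, 80 cm in women)?

Procedure, per sex × measure × outcome (ISI or DIo):

1. log10-transform the outcome (its distribution is right-skewed) and
   age-adjust it: residualize on age by least squares, pooled across groups
   within sex, adding back the pooled mean so the adjusted values keep the
   original scale and become uncorrelated with age.
2. Fit an ordinary least-squares line of the adjusted outcome on the
   anthropometric measure within each group.
3. Solve for the comparison-group measure value with the same fitted level
   as the reference group at its threshold::

       x_cmp = (a_ref + b_ref · x_ref − a_cmp) / b_cmp

   Cut-offs are reported raw and snapped to a reporting grid
   (0.5 kg/m² for BMI, 1 cm for waist).  An optional percentile bootstrap
   (resampling subjects with replacement within group) yields a CI.

Linearity of the adjusted log10 outcome in the measure is the functional
form; it is the minimal model under which "the same level" has a unique
crossing point.  A solved cut-off outside the comparison group's observed
measure range is flagged as extrapolated, not suppressed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import WAIST_THRESHOLDS, round_half_up
from .errors import AgeAdjustmentWarning, DomainError, ExtrapolationWarning, NonIdentifiableError

logger = logging.getLogger("ogttools")

BMI_THRESHOLDS = (25.0, 30.0)  # kg/m², overweight and obesity
ROUNDING_GRIDS = {"bmi": 0.5, "waist": 1.0}


@dataclass(frozen=True)
class GroupLineFit:
    """OLS line of age-adjusted log10 outcome vs an anthropometric measure."""

    group: str
    sex: str
    measure: str
    outcome: str
    slope: float
    intercept: float
    n: int
    residual_sd: float

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x


@dataclass(frozen=True)
class EquivalenceResult:
    """One solved cut-off: comparison-group measure value matching the
    reference group's age-adjusted outcome level at ``reference_threshold``."""

    group: str
    sex: str
    measure: str
    outcome: str
    reference_threshold: float
    reference_outcome_level: float
    cutoff_raw: float
    cutoff_rounded: float
    n_ref: int
    n_cmp: int
    reliable: bool = True
    extrapolated: bool = False
    ci: Optional[tuple] = None


@dataclass(frozen=True)
class CutoffConfig:
    """Thresholds, outcomes and numerical settings for the cut-off analysis."""

    bmi_thresholds: Sequence[float] = BMI_THRESHOLDS
    waist_thresholds: dict = field(default_factory=lambda: dict(WAIST_THRESHOLDS))
    outcomes: Sequence[str] = ("isi", "dio")
    measures: Sequence[str] = ("bmi", "waist")
    min_n: int = 30
    age_adjust: str = "pooled"  # or "per-group"
    rounding: dict = field(default_factory=lambda: dict(ROUNDING_GRIDS))
    slope_tol: float = 1e-8
    bootstrap_resamples: int = 0  # 0 disables the CI
    bootstrap_level: float = 0.95
    seed: Optional[int] = None


def _line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Simple-regression slope, intercept and residual SD (closed form)."""
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    sxx = dx @ dx
    if sxx == 0:
        raise DomainError("zero variance in the measure; cannot fit a line")
    slope = (dx @ (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    dof = max(len(x) - 2, 1)
    return float(slope), float(intercept), float(np.sqrt(resid @ resid / dof))


def age_adjust_outcome(values, ages, *, log_transform: bool = True) -> np.ndarray:
    """log10-transform and age-adjust an outcome (pooled least squares).

    Residualizes the (log10) outcome on age and adds back the sample mean,
    so the result is uncorrelated with age and preserves the mean.  With
    zero age variance the unadjusted log10 values are returned under an
    :class:`~ogttools.errors.AgeAdjustmentWarning`.
    """
    v = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if log_transform:
        if np.any(v <= 0):
            raise DomainError("age_adjust_outcome: non-positive outcome under log10")
        v = np.log10(v)
    da = a - a.mean()
    saa = da @ da
    if saa == 0:
        warnings.warn("zero age variance; returning unadjusted values", AgeAdjustmentWarning)
        return v
    slope = (da @ (v - v.mean())) / saa
    return v - slope * da


def fit_group_line(
    measure_values,
    adjusted_outcome,
    *,
    group: str = "",
    sex: str = "",
    measure: str = "bmi",
    outcome: str = "log10_isi",
) -> GroupLineFit:
    """OLS fit of the age-adjusted outcome on the measure within one stratum."""
    x = np.asarray(measure_values, dtype=float)
    y = np.asarray(adjusted_outcome, dtype=float)
    if len(x) < 3:
        raise DomainError(f"fit_group_line: need n >= 3, got {len(x)}")
    slope, intercept, resid_sd = _line(x, y)
    return GroupLineFit(
        group=group, sex=sex, measure=measure, outcome=outcome,
        slope=slope, intercept=intercept, n=len(x), residual_sd=resid_sd,
    )


def equivalence_cutoff(
    fit_ref: GroupLineFit,
    fit_cmp: GroupLineFit,
    x_ref: float,
    *,
    grid: Optional[float] = None,
    cmp_range: Optional[tuple] = None,
    slope_tol: float = 1e-8,
) -> EquivalenceResult:
    """Solve for the comparison measure value matching the reference level.

    ``grid`` snaps the reported cut-off (0.5 kg/m² for BMI, 1 cm for waist
    by default); the raw solution is always kept.  ``cmp_range`` (min, max of
    the comparison group's observed measure) triggers an
    :class:`~ogttools.errors.ExtrapolationWarning` when exceeded.
    """
    if (fit_ref.measure, fit_ref.outcome, fit_ref.sex) != (fit_cmp.measure, fit_cmp.outcome, fit_cmp.sex):
        raise DomainError("equivalence_cutoff: fits are not on the same sex/measure/outcome")
    if abs(fit_cmp.slope) < slope_tol:
        raise NonIdentifiableError(
            f"comparison slope {fit_cmp.slope:.3g} below tolerance {slope_tol:g}; "
            "no unique crossing point"
        )
    level = fit_ref.predict(x_ref)
    if fit_cmp.slope == fit_ref.slope and fit_cmp.intercept == fit_ref.intercept:
        x_cmp = float(x_ref)  # identical lines cross everywhere: exact identity
    else:
        x_cmp = (level - fit_cmp.intercept) / fit_cmp.slope
    if grid is None:
        grid = ROUNDING_GRIDS.get(fit_ref.measure, 0.1)
    rounded = round_half_up(x_cmp / grid, 0) * grid
    extrapolated = False
    if cmp_range is not None and not (cmp_range[0] <= x_cmp <= cmp_range[1]):
        extrapolated = True
        warnings.warn(
            f"cut-off {x_cmp:.2f} outside observed {fit_cmp.measure} range "
            f"[{cmp_range[0]:.1f}, {cmp_range[1]:.1f}] for group {fit_cmp.group!r}",
            ExtrapolationWarning,
        )
    return EquivalenceResult(
        group=fit_cmp.group, sex=fit_cmp.sex, measure=fit_cmp.measure, outcome=fit_cmp.outcome,
        reference_threshold=float(x_ref), reference_outcome_level=float(level),
        cutoff_raw=float(x_cmp), cutoff_rounded=float(rounded),
        n_ref=fit_ref.n, n_cmp=fit_cmp.n, extrapolated=extrapolated,
    )


def _adjusted_frame(df: pd.DataFrame, outcome: str, age_adjust: str) -> np.ndarray:
    if age_adjust == "pooled":
        return age_adjust_outcome(df[outcome], df["age"])
    adj = np.empty(len(df))
    for _, idx in df.groupby("group", observed=True).indices.items():
        adj[idx] = age_adjust_outcome(df[outcome].iloc[idx], df["age"].iloc[idx])
    return adj


def _solve_for_frame(
    df: pd.DataFrame,
    reference_group: str,
    cmp_group: str,
    sex: str,
    measure: str,
    outcome: str,
    thresholds: Sequence[float],
    config: CutoffConfig,
) -> list[EquivalenceResult]:
    adj = _adjusted_frame(df, outcome, config.age_adjust)
    sub_ref = df["group"] == reference_group
    sub_cmp = df["group"] == cmp_group
    out_label = f"log10_{outcome}"
    fit_ref = fit_group_line(
        df.loc[sub_ref, measure], adj[sub_ref.to_numpy()],
        group=reference_group, sex=sex, measure=measure, outcome=out_label,
    )
    fit_cmp = fit_group_line(
        df.loc[sub_cmp, measure], adj[sub_cmp.to_numpy()],
        group=cmp_group, sex=sex, measure=measure, outcome=out_label,
    )
    xs = df.loc[sub_cmp, measure].to_numpy(dtype=float)
    rng_cmp = (float(xs.min()), float(xs.max()))
    results = []
    for x_ref in thresholds:
        res = equivalence_cutoff(
            fit_ref, fit_cmp, x_ref,
            grid=config.rounding.get(measure), cmp_range=rng_cmp, slope_tol=config.slope_tol,
        )
        reliable = fit_ref.n >= config.min_n and fit_cmp.n >= config.min_n
        res = replace(res, reliable=reliable)
        results.append(res)
    return results


def _bootstrap_ci(
    df: pd.DataFrame,
    reference_group: str,
    cmp_group: str,
    sex: str,
    measure: str,
    outcome: str,
    x_ref: float,
    config: CutoffConfig,
    rng: np.random.Generator,
) -> Optional[tuple]:
    """Percentile CI by resampling subjects with replacement within group."""
    parts = {g: df.loc[df["group"] == g].reset_index(drop=True) for g in (reference_group, cmp_group)}
    draws = []
    for _ in range(config.bootstrap_resamples):
        resampled = pd.concat(
            [p.iloc[rng.integers(0, len(p), size=len(p))] for p in parts.values()],
            ignore_index=True,
        )
        try:
            res = _solve_for_frame(
                resampled, reference_group, cmp_group, sex, measure, outcome, [x_ref], config
            )
        except NonIdentifiableError:
            continue
        draws.append(res[0].cutoff_raw)
    if len(draws) < max(10, config.bootstrap_resamples // 2):
        return None
    alpha = 1.0 - config.bootstrap_level
    lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
    return (float(lo), float(hi))


def run_cutoff_analysis(
    cohort: pd.DataFrame,
    indices: pd.DataFrame,
    reference_group: str,
    config: CutoffConfig = CutoffConfig(),
) -> tuple[list[EquivalenceResult], dict]:
    """Full cut-off analysis: every sex × measure × outcome × threshold.

    ``cohort`` must have passed the diabetes exclusion; ``indices`` comes from
    :func:`ogttools.indices.compute_indices`.  Subjects with the outcome
    undefined are dropped per-outcome (complete case).  Returns the result
    list and a provenance dict with the per-stratum line fits.  When
    ``config.bootstrap_resamples > 0`` a seed must be set in the config.
    """
    if config.bootstrap_resamples > 0 and config.seed is None:
        raise DomainError("bootstrap requested but no seed configured")
    rng = np.random.default_rng(config.seed) if config.seed is not None else None

    merged = cohort.merge(indices, on="subject_id")
    if reference_group not in set(merged["group"]):
        raise DomainError(f"reference group {reference_group!r} not present in cohort")
    cmp_groups = sorted(set(merged["group"]) - {reference_group})

    results: list[EquivalenceResult] = []
    provenance: dict = {"fits": [], "config": config}
    for sex in sorted(set(merged["sex"])):
        sdf = merged.loc[merged["sex"] == sex]
        for outcome in config.outcomes:
            ok = np.isfinite(sdf[outcome]) & (sdf[outcome] > 0) & np.isfinite(sdf["age"])
            for measure in config.measures:
                thresholds = (
                    list(config.bmi_thresholds)
                    if measure == "bmi"
                    else [config.waist_thresholds[sex]]
                )
                okm = ok & np.isfinite(sdf[measure])
                df = sdf.loc[okm, ["group", measure, outcome, "age"]].reset_index(drop=True)
                for cmp_group in cmp_groups:
                    res_list = _solve_for_frame(
                        df, reference_group, cmp_group, sex, measure, outcome, thresholds, config
                    )
                    for res in res_list:
                        if rng is not None and config.bootstrap_resamples > 0:
                            ci = _bootstrap_ci(
                                df, reference_group, cmp_group, sex, measure, outcome,
                                res.reference_threshold, config, rng,
                            )
                            res = replace(res, ci=ci)
                        if not res.reliable:
                            logger.warning(
                                "unreliable cut-off (n_ref=%d, n_cmp=%d < %d): %s/%s/%s",
                                res.n_ref, res.n_cmp, config.min_n, sex, measure, outcome,
                            )
                        results.append(res)
                adj = _adjusted_frame(df, outcome, config.age_adjust)
                for g in [reference_group, *cmp_groups]:
                    m = (df["group"] == g).to_numpy()
                    if m.sum() >= 3:
                        fit = fit_group_line(
                            df.loc[m, measure], adj[m],
                            group=g, sex=sex, measure=measure, outcome=f"log10_{outcome}",
                        )
                        provenance["fits"].append(fit)
    return results, provenance


def results_frame(results: list[EquivalenceResult]) -> pd.DataFrame:
    """Tidy table of equivalence results for CSV export."""
    rows = []
    for r in results:
        rows.append(
            {
                "group": r.group, "sex": r.sex, "measure": r.measure, "outcome": r.outcome,
                "reference_threshold": r.reference_threshold,
                "reference_outcome_level": r.reference_outcome_level,
                "cutoff_raw": r.cutoff_raw, "cutoff_rounded": r.cutoff_rounded,
                "ci_lo": r.ci[0] if r.ci else np.nan, "ci_hi": r.ci[1] if r.ci else np.nan,
                "n_ref": r.n_ref, "n_cmp": r.n_cmp,
                "reliable": r.reliable, "extrapolated": r.extrapolated,
            }
        )
    return pd.DataFrame(rows)
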