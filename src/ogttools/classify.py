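"""Cohort exclusions, adiposity categories and insulin-resistance tertiles.

Subjects with a fasting glucose of 7.0 mmol/L or above (or a
diabetes-medication flag) are treated as having diabetes and excluded
before any index analysis.  Adiposity is categorised by BMI
(< 25 normal weight, 25–30 overweight, ≥ 30 obesity — no underweight
category) and by the WHO/IDF abdominal-obesity thresholds
(waist ≥ 94 cm in men, ≥ 80 cm in women).

Insulin resistance is defined relative to the designated reference
population: its ISI distribution is split into tertiles and every subject
(reference or comparison) is placed into "insulin resistant"
(ISI below the first boundary), "intermediate", or "insulin sensitive"
(ISI at or above the second boundary).  Boundary inclusion is strict "<"
for the lower category and "≥" for the upper ones; ties are assigned by
those inequalities, never split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .errors import DegenerateReferenceError, DomainError, MissingDataError

logger = logging.getLogger("ogttools")

DIABETES_FASTING_GLUCOSE = 7.0  # mmol/L, exclusion threshold (">=" excludes)
BMI_OVERWEIGHT = 25.0
BMI_OBESITY = 30.0
WAIST_THRESHOLDS = {"male": 94.0, "female": 80.0}  # cm

ISI_CATEGORIES = ["insulin resistant", "intermediate", "insulin sensitive"]
WEIGHT_CLASSES = ["normal weight", "overweight", "obesity"]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (reporting convention for percentages)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """A stratum percentage, rounded half-up to the reporting precision."""
    if total <= 0:
        raise DomainError("percentage: non-positive denominator")
    return round_half_up(100.0 * count / total, decimals)


@dataclass(frozen=True)
class TertileReference:
    """ISI tertile boundaries derived from the reference population only."""

    cut_lo: float
    cut_hi: float
    n_reference: int
    labels: tuple = tuple(ISI_CATEGORIES)

    def rounded(self, decimals: int = 1) -> tuple:
        """Boundaries at reporting precision (classification uses raw cuts)."""
        return (round_half_up(self.cut_lo, decimals), round_half_up(self.cut_hi, decimals))


def exclude_diabetes(
    cohort: pd.DataFrame,
    *,
    glucose_col: str = "glucose_0",
    threshold: float = DIABETES_FASTING_GLUCOSE,
    medication_col: str = "diabetes_medication",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects meeting the diabetes definition; return (retained, log).

    Retains subjects with fasting glucose strictly below ``threshold`` and no
    diabetes-medication flag.  A missing fasting glucose is itself grounds
    for exclusion (reason "missing fasting glucose").  The operation is
    idempotent.  The log has columns ``subject_id`` and ``reason``.
    """
    if glucose_col not in cohort.columns:
        raise MissingDataError("<cohort>", f"column {glucose_col}")
    g0 = pd.to_numeric(cohort[glucose_col], errors="coerce").to_numpy(dtype=float)
    missing = ~np.isfinite(g0)
    high = np.isfinite(g0) & (g0 >= threshold)
    if medication_col in cohort.columns:
        med = cohort[medication_col].eq(True).to_numpy()
    else:
        med = np.zeros(len(cohort), dtype=bool)

    reason = np.where(
        missing,
        "missing fasting glucose",
        np.where(high, f"fasting glucose >= {threshold} mmol/L", np.where(med, "diabetes medication", "")),
    )
    excluded = missing | high | med
    log = pd.DataFrame(
        {"subject_id": cohort.loc[excluded, "subject_id"].to_numpy(), "reason": reason[excluded]}
    )
    for _, row in log.iterrows():
        logger.info("excluded subject %s: %s", row["subject_id"], row["reason"])
    return cohort.loc[~excluded].reset_index(drop=True), log


def weight_class(bmi):
    """BMI category: normal weight (<25), overweight ([25, 30)), obesity (≥30)."""
    arr = np.asarray(bmi, dtype=float)
    if np.any(arr[np.isfinite(arr)] <= 0):
        raise DomainError("weight_class: non-positive BMI")
    cats = np.select(
        [arr < BMI_OVERWEIGHT, arr < BMI_OBESITY], WEIGHT_CLASSES[:2], default=WEIGHT_CLASSES[2]
    )
    return str(cats[()]) if arr.ndim == 0 else pd.Categorical(cats, categories=WEIGHT_CLASSES, ordered=True)


def abdominal_obesity(waist, sex):
    """True iff waist circumference meets the sex-specific WHO/IDF threshold."""
    warr = np.asarray(waist, dtype=float)
    if np.any(warr[np.isfinite(warr)] <= 0):
        raise DomainError("abdominal_obesity: non-positive waist circumference")
    sarr = np.asarray(sex, dtype=object)
    known = np.isin(sarr, list(WAIST_THRESHOLDS))
    if not known.all():
        bad = sorted(set(np.atleast_1d(sarr)[~np.atleast_1d(known)]))
        raise DomainError(f"abdominal_obesity: unknown sex value(s) {bad}")
    thr = np.vectorize(WAIST_THRESHOLDS.get, otypes=[float])(sarr)
    out = warr >= thr
    return bool(out[()]) if warr.ndim == 0 else out


def tertile_reference(reference_isi_values, *, method: str = "linear") -> TertileReference:
    """Tertile boundaries (1/3 and 2/3 quantiles) of the reference ISI sample.

    Quantiles interpolate linearly between order statistics at positions
    ``p·(n−1)+1`` (numpy's default rule); ``method="nearest-rank"`` uses the
    lower order statistic instead.  Requires at least three finite values
    with some spread.
    """
    vals = np.asarray(reference_isi_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 3:
        raise DegenerateReferenceError(f"need >= 3 finite reference ISI values, got {vals.size}")
    if np.ptp(vals) == 0:
        raise DegenerateReferenceError("all reference ISI values equal")
    interp = {"linear": "linear", "nearest-rank": "inverted_cdf"}[method]
    cut_lo, cut_hi = np.quantile(vals, [1 / 3, 2 / 3], method=interp)
    return TertileReference(cut_lo=float(cut_lo), cut_hi=float(cut_hi), n_reference=int(vals.size))


def classify_isi(isi, ref: TertileReference):
    """Place ISI values into the reference-derived tertile categories."""
    arr = np.asarray(isi, dtype=float)
    cats = np.select([arr < ref.cut_lo, arr < ref.cut_hi], ISI_CATEGORIES[:2], default=ISI_CATEGORIES[2])
    if arr.ndim == 0:
        return str(cats[()])
    return pd.Categorical(cats, categories=ISI_CATEGORIES, ordered=True)


def prevalence_crosstab(
    cohort: pd.DataFrame,
    indices: pd.DataFrame,
    ref: TertileReference,
    *,
    adiposity: str = "abdominal_obesity",
) -> pd.DataFrame:
    """Counts and percentages of each ISI category per (group, sex, adiposity) stratum.

    ``adiposity`` is ``"abdominal_obesity"`` or ``"weight_class"``.  Returns a
    tidy frame (group, sex, adiposity, isi_category, n, pct); percentages are
    half-up rounded to one decimal and sum to 100 ± rounding within a stratum.
    Strata with no classifiable subjects appear with n = 0 and NaN pct.
    """
    merged = cohort.merge(indices[["subject_id", "isi", "isi_defined"]], on="subject_id")
    merged = merged.loc[merged["isi_defined"]].copy()
    if adiposity == "weight_class":
        merged["adiposity"] = weight_class(merged["bmi"])
    elif adiposity == "abdominal_obesity":
        ab = abdominal_obesity(merged["waist"].to_numpy(), merged["sex"].to_numpy())
        merged["adiposity"] = pd.Categorical(
            np.where(ab, "abdominal obesity", "normal waist"),
            categories=["normal waist", "abdominal obesity"],
        )
    else:
        raise ValueError(f"unknown adiposity stratifier {adiposity!r}")
    merged["isi_category"] = classify_isi(merged["isi"].to_numpy(), ref)

    counts = (
        merged.groupby(["group", "sex", "adiposity", "isi_category"], observed=False)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = counts.groupby(["group", "sex", "adiposity"], observed=False)["n"].transform("sum")
    pct = np.full(len(counts), np.nan)
    nonzero = totals.to_numpy() > 0
    pct[nonzero] = [
        percentage(c, t) for c, t in zip(counts.loc[nonzero, "n"], totals[nonzero])
    ]
    counts["pct"] = pct
    return counts
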