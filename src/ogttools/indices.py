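"""Per-subject glycaemic and insulin indices from oral glucose tolerance tests.

A 75-g OGTT samples plasma glucose (mmol/L) and insulin (mIE/L) at
0, 30, 60, 90 and 120 minutes.  From these the module derives

* mean glucose / mean insulin — the unweighted arithmetic mean over the
  0/30/60/120-min samples (the 90-min sample, when drawn, is ignored);
* ISI — the Matsuda composite whole-body insulin sensitivity index,
  ``10000 / sqrt(G0 · I0 · Gmean · Imean)``, computed here with glucose in
  mmol/L and insulin in mIE/L so that population tertile boundaries land
  near 78/133 (the mg/dL convention of the original index gives values
  roughly 18× smaller; see :data:`MGDL_PER_MMOL`);
* CIR — the corrected insulin response, ``100·I30 / (G30·(G30 − 3.89))``,
  an index of beta-cell insulin secretion; undefined when the 30-min
  glucose does not exceed the 3.89 mmol/L (70 mg/dL) offset;
* DIo — the oral disposition index, ``CIR × ISI``, beta-cell function
  adjusted for insulin sensitivity.

All computations are pure, seed-free and double precision.  The policy for
incomplete records is complete-case per derived quantity: a subject missing
the 30-min insulin loses CIR and DIo but keeps ISI whenever the four ISI
inputs are present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, MissingDataError

#: Sampling times (minutes) that enter the mean glucose / mean insulin.
MEAN_TIMES = (0, 30, 60, 120)

#: All sampling times a cohort table may carry.
OGTT_TIMES = (0, 30, 60, 90, 120)

#: Numerator constant of the Matsuda composite index.
MATSUDA_CONSTANT = 10_000.0

#: Glucose offset (mmol/L) in the corrected insulin response denominator.
CIR_GLUCOSE_OFFSET = 3.89

#: Unit conversion for users whose glucose is recorded in mg/dL.
MGDL_PER_MMOL = 18.0182

INDEX_COLUMNS = ["mean_glucose", "mean_insulin", "isi", "cir", "dio"]


@dataclass(frozen=True)
class IndexSet:
    """Derived indices for one subject; undefined quantities are NaN."""

    mean_glucose: float
    mean_insulin: float
    isi: float
    cir: float
    dio: float


def mean_level(values: Mapping[int, float], *, subject_id="?", what: str = "value") -> float:
    """Arithmetic mean of the 0/30/60/120-min concentrations.

    Parameters
    ----------
    values
        Mapping from sampling time (minutes) to concentration.  The four
        times in :data:`MEAN_TIMES` must be present and finite; a 90-min
        entry is ignored.

    Raises
    ------
    MissingDataError
        If a required timepoint is absent or not finite.
    """
    total = 0.0
    for t in MEAN_TIMES:
        v = values.get(t)
        if v is None or not math.isfinite(v):
            raise MissingDataError(subject_id, f"{what} at {t} min")
        total += float(v)
    return total / len(MEAN_TIMES)


def matsuda_isi(g0, i0, gmean, imean, *, constant: float = MATSUDA_CONSTANT):
    """Matsuda composite insulin sensitivity index.

    ``constant / sqrt(g0 · i0 · gmean · imean)`` with glucose in mmol/L and
    insulin in mIE/L.  Accepts scalars or arrays; raises
    :class:`~ogttools.errors.DomainError` on any non-positive argument.
    """
    g0 = np.asarray(g0, dtype=float)
    i0 = np.asarray(i0, dtype=float)
    gmean = np.asarray(gmean, dtype=float)
    imean = np.asarray(imean, dtype=float)
    for name, arr in (("g0", g0), ("i0", i0), ("gmean", gmean), ("imean", imean)):
        if np.any(arr[np.isfinite(arr)] <= 0):
            raise DomainError(f"matsuda_isi: non-positive {name}")
    out = constant / np.sqrt(g0 * i0 * gmean * imean)
    return float(out) if out.ndim == 0 else out


def corrected_insulin_response(g30, i30, *, glucose_offset: float = CIR_GLUCOSE_OFFSET):
    """Corrected insulin response, ``100·i30 / (g30·(g30 − offset))``.

    Returns NaN (the "CIR undefined" flag) where ``g30 <= glucose_offset``,
    since the formula would otherwise yield a non-positive secretion index.
    Raises :class:`~ogttools.errors.DomainError` for non-positive ``i30``.
    """
    g30 = np.asarray(g30, dtype=float)
    i30 = np.asarray(i30, dtype=float)
    if np.any(i30[np.isfinite(i30)] <= 0):
        raise DomainError("corrected_insulin_response: non-positive i30")
    denom = g30 * (g30 - glucose_offset)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(g30 > glucose_offset, 100.0 * i30 / denom, np.nan)
    return float(out) if out.ndim == 0 else out


def disposition_index(cir, isi):
    """Oral disposition index: the exact product CIR × ISI.

    NaN (undefined) in either factor propagates to an undefined DIo.
    """
    out = np.asarray(cir, dtype=float) * np.asarray(isi, dtype=float)
    return float(out) if out.ndim == 0 else out


def _timed_columns(prefix: str, times=MEAN_TIMES) -> list[str]:
    return [f"{prefix}_{t}" for t in times]


def compute_indices(cohort: pd.DataFrame, *, glucose_offset: float = CIR_GLUCOSE_OFFSET) -> pd.DataFrame:
    """Derive :class:`IndexSet` columns for every subject of a cohort table.

    Expects ``glucose_0 … glucose_120`` / ``insulin_0 … insulin_120`` columns
    in mmol/L and mIE/L.  Undefined quantities are NaN with boolean
    ``*_defined`` flag columns; a textual ``index_note`` records why.  The
    computation is deterministic and row-wise independent: a subject with a
    missing 60-min glucose is flagged while every other subject is computed.
    """
    if len(cohort) == 0:
        raise MissingDataError("<cohort>", "any subjects (empty cohort)")
    gcols = _timed_columns("glucose")
    icols = _timed_columns("insulin")
    for col in gcols + icols:
        if col not in cohort.columns:
            cohort = cohort.assign(**{col: np.nan})

    g = cohort[gcols].to_numpy(dtype=float)
    ins = cohort[icols].to_numpy(dtype=float)
    g_ok = np.isfinite(g).all(axis=1) & (np.nan_to_num(g, nan=1.0) > 0).all(axis=1)
    i_ok = np.isfinite(ins).all(axis=1) & (np.nan_to_num(ins, nan=1.0) > 0).all(axis=1)

    mean_g = np.where(g_ok, g.mean(axis=1), np.nan)
    mean_i = np.where(i_ok, ins.mean(axis=1), np.nan)

    isi = np.full(len(cohort), np.nan)
    defined = g_ok & i_ok
    if defined.any():
        isi[defined] = matsuda_isi(g[defined, 0], ins[defined, 0], mean_g[defined], mean_i[defined])

    g30 = cohort["glucose_30"].to_numpy(dtype=float)
    i30 = cohort["insulin_30"].to_numpy(dtype=float)
    cir = np.full(len(cohort), np.nan)
    cir_inputs = np.isfinite(g30) & np.isfinite(i30) & (i30 > 0)
    if cir_inputs.any():
        cir[cir_inputs] = corrected_insulin_response(
            g30[cir_inputs], i30[cir_inputs], glucose_offset=glucose_offset
        )

    dio = disposition_index(cir, isi)

    notes = np.where(
        ~defined,
        "missing/invalid OGTT sample for ISI",
        np.where(~np.isfinite(cir), f"CIR undefined (g30 <= {glucose_offset} mmol/L or missing)", ""),
    )
    out = pd.DataFrame(
        {
            "subject_id": cohort["subject_id"].to_numpy(),
            "mean_glucose": mean_g,
            "mean_insulin": mean_i,
            "isi": isi,
            "cir": cir,
            "dio": dio,
            "isi_defined": np.isfinite(isi),
            "cir_defined": np.isfinite(cir),
            "dio_defined": np.isfinite(dio),
            "index_note": notes,
        }
    )
    return out
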