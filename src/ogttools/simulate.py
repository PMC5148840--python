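"""Synthetic two-group × two-sex OGTT cohorts.

The generator produces cohort tables carrying exactly the statistical
structure the downstream analysis assumes, so every pipeline stage is
testable without access to a real cohort:

* per stratum (group × sex): age ~ Normal truncated to [30, 75] by
  rejection; BMI ~ Normal; waist linear in BMI plus Gaussian noise;
* a latent log10 ISI from the stratum's linear model
  ``intercept + slope_bmi·(BMI − 25) + slope_age·(age − 50) + ε`` with
  Gaussian ε (log-normal ISI noise, matching the log10-transform rationale
  of the analysis);
* an OGTT glucose trajectory drawn from a per-stratum template with
  multiplicative log-normal noise (the 90-min sample is generated so the
  "ignore 90 min" rule is exercised, but carries no information);
* insulin values with response shape (1, a, 4, 3)·s at 0/30/60/120 min.
  The scale ``s`` is solved exactly from the latent ISI — the Matsuda
  index recomputed from the generated trajectory equals the latent ISI to
  machine precision — while the 30-min peak factor ``a`` is a per-subject
  beta-cell term (log-normal around 5 with its own negative BMI loading)
  so that CIR, and hence DIo, carries an identifiable adiposity signal
  instead of being a deterministic function of ISI.
* covariates linked to the latent sensitivity: triglycerides (negative
  loading, log-normal), HDL (positive loading), smoking / family-history
  prevalences, physical activity.

Scenarios: ``realistic`` (group- and sex-specific parameters calibrated to
magnitudes typical of published OGTT cohort studies of European-origin and
Middle-Eastern-origin adult populations), ``null`` (both groups identical),
and ``shift`` (the comparison group's ISI–BMI line displaced horizontally
by Δ kg/m², so the true equivalence cut-off at a reference threshold x is
x − Δ).  All randomness flows from a single integer seed via
``numpy.random.SeedSequence`` spawning, one substream per stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError
from .indices import MATSUDA_CONSTANT

AGE_RANGE = (30.0, 75.0)

#: Insulin response shape at 0/30/60/120 min, scaled per subject
#: (the 30-min entry is the default peak factor, varied per subject).
INSULIN_SHAPE = (1.0, 5.0, 4.0, 3.0)
#: 90-min insulin as a multiple of the same scale (uninformative).
INSULIN_SHAPE_90 = 3.5

GROUPS = ("reference", "comparison")
SEXES = ("male", "female")


@dataclass
class StratumParams:
    """Generative parameters for one group × sex stratum."""

    n: int
    age_mean: float = 48.0
    age_sd: float = 10.0
    bmi_mean: float = 27.0
    bmi_sd: float = 4.5
    waist_intercept: float = 35.0  # cm at BMI 0
    waist_slope: float = 2.0  # cm per kg/m²
    waist_sd: float = 6.0
    isi_intercept: float = 2.1  # log10 ISI at BMI 25, age 50
    isi_slope_bmi: float = -0.035  # log10 per kg/m²
    isi_slope_age: float = -0.004  # log10 per year
    isi_sd: float = 0.20  # residual SD, log10 scale
    glucose_template: tuple = (5.4, 8.6, 7.6, 6.5, 5.9)  # mmol/L at 0/30/60/90/120
    glucose_noise_sd: float = 0.06  # multiplicative, log scale
    insulin_peak_median: float = 5.0  # 30-min shape factor (beta-cell term)
    insulin_peak_slope_bmi: float = -0.015  # log10 peak per kg/m²
    insulin_peak_sd: float = 0.12  # log10 scale
    tg_median: float = 1.3  # mmol/L
    tg_loading: float = -0.5  # log10 TG per log10 ISI
    tg_sd: float = 0.12  # log10 scale
    hdl_mean: float = 1.35  # mmol/L
    hdl_loading: float = 0.4  # mmol/L per log10 ISI
    hdl_sd: float = 0.25
    smoker_prev: float = 0.25
    family_history_prev: float = 0.35
    activity_mean: float = 3.0  # hours/week
    activity_sd: float = 2.0

    def validate(self) -> None:
        if self.n < 1:
            raise DomainError("stratum n must be >= 1")
        for name in ("age_sd", "bmi_sd", "waist_sd", "isi_sd", "glucose_noise_sd",
                     "insulin_peak_sd", "tg_sd", "hdl_sd", "activity_sd"):
            if getattr(self, name) < 0:
                raise DomainError(f"negative SD: {name}")
        if any(g <= 0 for g in self.glucose_template):
            raise DomainError("glucose template must be strictly positive")
        if not 0 <= self.smoker_prev <= 1 or not 0 <= self.family_history_prev <= 1:
            raise DomainError("prevalences must lie in [0, 1]")


@dataclass
class SyntheticParams:
    """Full generator specification: one :class:`StratumParams` per
    (group, sex), plus the master seed."""

    strata: dict = field(default_factory=dict)  # (group, sex) -> StratumParams
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.seed is None:
            raise DomainError("an explicit seed is required")
        if not self.strata:
            raise DomainError("no strata configured")
        for sp in self.strata.values():
            sp.validate()

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "strata": {f"{g}/{s}": asdict(sp) for (g, s), sp in self.strata.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticParams":
        strata = {}
        for key, sub in d["strata"].items():
            g, s = key.split("/")
            strata[(g, s)] = StratumParams(**sub)
        return cls(strata=strata, seed=d.get("seed"))


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection sampling from Normal(mean, sd) restricted to [lo, hi]."""
    if sd == 0:
        if not lo <= mean <= hi:
            raise DomainError("degenerate truncated normal outside range")
        return np.full(size, float(mean))
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, size=todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _generate_stratum(sp: StratumParams, group, sex, rng, id_offset) -> pd.DataFrame:
    n = sp.n
    age = _truncated_normal(rng, sp.age_mean, sp.age_sd, *AGE_RANGE, size=n)
    bmi = np.maximum(rng.normal(sp.bmi_mean, sp.bmi_sd, size=n), 16.0)
    waist = np.maximum(sp.waist_intercept + sp.waist_slope * bmi + rng.normal(0, sp.waist_sd, size=n), 50.0)

    log_isi = (
        sp.isi_intercept
        + sp.isi_slope_bmi * (bmi - 25.0)
        + sp.isi_slope_age * (age - 50.0)
        + rng.normal(0, sp.isi_sd, size=n)
    )
    isi = 10.0 ** log_isi

    tmpl = np.asarray(sp.glucose_template, dtype=float)  # 0/30/60/90/120
    noise = np.exp(rng.normal(0, sp.glucose_noise_sd, size=(n, 5)))
    glucose = tmpl[None, :] * noise
    g_mean = glucose[:, [0, 1, 2, 4]].mean(axis=1)  # 90-min sample ignored

    # Per-subject 30-min peak factor: an independent beta-cell signal with
    # its own BMI loading, so DIo is not a deterministic function of ISI.
    peak = 10.0 ** (
        np.log10(sp.insulin_peak_median)
        + sp.insulin_peak_slope_bmi * (bmi - 25.0)
        + rng.normal(0, sp.insulin_peak_sd, size=n)
    )
    # Exact Matsuda inversion: with insulin (1, a, 4, 3)·s, I0 = s and
    # Imean = s·(8+a)/4; solve 10000/sqrt(G0·s·Gmean·s·(8+a)/4) = ISI for s.
    base = np.asarray(INSULIN_SHAPE)
    shape_mean = (base[0] + peak + base[2] + base[3]) / 4.0
    scale = MATSUDA_CONSTANT / (isi * np.sqrt(glucose[:, 0] * g_mean * shape_mean))
    if np.any(scale <= 0):
        raise DomainError("parameters imply non-positive insulin concentrations")
    insulin = np.column_stack(
        [scale * base[0], scale * peak, scale * base[2], scale * INSULIN_SHAPE_90, scale * base[3]]
    )

    log_tg = np.log10(sp.tg_median) + sp.tg_loading * (log_isi - sp.isi_intercept) + rng.normal(0, sp.tg_sd, size=n)
    hdl = np.maximum(
        sp.hdl_mean + sp.hdl_loading * (log_isi - sp.isi_intercept) + rng.normal(0, sp.hdl_sd, size=n), 0.4
    )
    smoker = rng.random(n) < sp.smoker_prev
    famhist = rng.random(n) < sp.family_history_prev
    activity = np.maximum(rng.normal(sp.activity_mean, sp.activity_sd, size=n), 0.0)

    return pd.DataFrame(
        {
            "subject_id": [f"S{ i + id_offset :06d}" for i in range(n)],
            "group": group,
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "waist": waist,
            "glucose_0": glucose[:, 0],
            "glucose_30": glucose[:, 1],
            "glucose_60": glucose[:, 2],
            "glucose_90": glucose[:, 3],
            "glucose_120": glucose[:, 4],
            "insulin_0": insulin[:, 0],
            "insulin_30": insulin[:, 1],
            "insulin_60": insulin[:, 2],
            "insulin_90": insulin[:, 3],
            "insulin_120": insulin[:, 4],
            "triglycerides": 10.0 ** log_tg,
            "hdl": hdl,
            "smoker": smoker,
            "physical_activity": activity,
            "family_history": famhist,
        }
    )


def generate_cohort(params: SyntheticParams) -> pd.DataFrame:
    """Generate a cohort table; bit-identical given identical params + seed."""
    params.validate()
    # One spawned substream per stratum, in sorted stratum order, so adding
    # or resizing one stratum does not disturb the draws of another.
    keys = sorted(params.strata)
    streams = np.random.SeedSequence(params.seed).spawn(len(keys))
    frames = []
    offset = 0
    for key, ss in zip(keys, streams):
        sp = params.strata[key]
        frames.append(_generate_stratum(sp, key[0], key[1], np.random.default_rng(ss), offset))
        offset += sp.n
    return pd.concat(frames, ignore_index=True)


# Defaults per stratum for the "realistic" scenario: sample sizes, ages,
# BMI and target median ISI chosen to match magnitudes reported for adult
# European-origin (reference) and Middle-Eastern-origin (comparison)
# OGTT cohorts (reference ISI medians ~90–111, comparison ~70–91; BMI
# means 26.8–29.4 kg/m²; ages 44–50 years).
_REALISTIC = {
    ("reference", "female"): dict(n=326, age_mean=49.7, age_sd=11.1, bmi_mean=26.8, bmi_sd=5.1,
                                  waist_intercept=34.8, waist_slope=2.0, isi_median=111.4,
                                  tg_median=1.1, hdl_mean=1.6, smoker_prev=0.26,
                                  family_history_prev=0.30, activity_mean=4.1),
    ("reference", "male"): dict(n=362, age_mean=48.9, age_sd=11.1, bmi_mean=27.2, bmi_sd=3.9,
                                waist_intercept=42.7, waist_slope=2.0, isi_median=90.1,
                                tg_median=1.4, hdl_mean=1.3, smoker_prev=0.25,
                                family_history_prev=0.24, activity_mean=4.1),
    ("comparison", "female"): dict(n=493, age_mean=44.3, age_sd=8.9, bmi_mean=29.4, bmi_sd=4.8,
                                   waist_intercept=33.2, waist_slope=2.0, isi_median=90.5,
                                   tg_median=1.3, hdl_mean=1.3, smoker_prev=0.12,
                                   family_history_prev=0.54, activity_mean=1.7),
    ("comparison", "male"): dict(n=683, age_mean=46.0, age_sd=9.5, bmi_mean=28.8, bmi_sd=4.0,
                                 waist_intercept=40.8, waist_slope=2.0, isi_median=70.1,
                                 tg_median=1.7, hdl_mean=1.1, smoker_prev=0.33,
                                 family_history_prev=0.47, activity_mean=2.0),
}


def _stratum_from_targets(spec: dict) -> StratumParams:
    spec = dict(spec)
    isi_median = spec.pop("isi_median")
    sp = StratumParams(**spec)
    # With symmetric noise the median latent log10 ISI sits on the line at
    # the stratum's mean BMI and age; back out the intercept at BMI 25 / age 50.
    sp.isi_intercept = (
        np.log10(isi_median)
        - sp.isi_slope_bmi * (sp.bmi_mean - 25.0)
        - sp.isi_slope_age * (sp.age_mean - 50.0)
    )
    return sp


def default_params(
    scenario: str,
    *,
    seed: int,
    n: Optional[int] = None,
    delta: float = 0.0,
) -> SyntheticParams:
    """Fully specified parameters for a named scenario.

    ``realistic``
        group- and sex-specific parameters (see module docstring);
        ``n`` overrides every stratum size when given.
    ``null``
        both groups share the reference parameters — statistically
        exchangeable (``n`` per stratum, default 1000).
    ``shift``
        like ``null`` but the comparison group's ISI–BMI line is displaced
        horizontally by ``delta`` kg/m² (its intercept moves by
        ``slope_bmi × delta``), so the true BMI cut-off equivalent to a
        reference threshold x is exactly ``x − delta``.
    """
    if scenario == "realistic":
        strata = {key: _stratum_from_targets(spec) for key, spec in _REALISTIC.items()}
        if n is not None:
            for sp in strata.values():
                sp.n = n
        return SyntheticParams(strata=strata, seed=seed)
    if scenario in ("null", "shift"):
        n = 1000 if n is None else n
        strata = {}
        for sex in SEXES:
            for group in GROUPS:
                sp = StratumParams(n=n)
                if group == "comparison" and scenario == "shift":
                    sp.isi_intercept = sp.isi_intercept + sp.isi_slope_bmi * delta
                strata[(group, sex)] = sp
        return SyntheticParams(strata=strata, seed=seed)
    raise DomainError(f"unknown scenario {scenario!r}")
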