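"""Cohort-table IO, schema validation, run configuration and the one-shot report.

Cohort files are comma-separated UTF-8 text with a mandatory header row,
"." as decimal separator and the empty string for missing values.  Glucose
columns are mmol/L, insulin columns mIE/L, waist cm, BMI kg/m².
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .classify import exclude_diabetes, prevalence_crosstab, tertile_reference
from .cutoffs import CutoffConfig, results_frame, run_cutoff_analysis
from .errors import DomainError, SchemaError
from .indices import compute_indices
from .regression import build_design, interaction_scan, log_transform_policy, ols_fit
from .simulate import default_params, generate_cohort

logger = logging.getLogger("ogttools")

SCHEMA_VERSION = "1"

REQUIRED_COLUMNS = (
    "subject_id", "group", "sex", "age", "bmi", "waist",
    "glucose_0", "glucose_30", "glucose_60", "glucose_120",
    "insulin_0", "insulin_30", "insulin_60", "insulin_120",
)
OPTIONAL_COLUMNS = (
    "glucose_90", "insulin_90", "triglycerides", "hdl",
    "smoker", "physical_activity", "family_history", "diabetes_medication",
)
NUMERIC_COLUMNS = tuple(
    c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS
    if c.startswith(("glucose", "insulin")) or c in ("age", "bmi", "waist", "triglycerides", "hdl", "physical_activity")
)
BOOLEAN_COLUMNS = ("smoker", "family_history", "diabetes_medication")
SEX_VALUES = ("male", "female")

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


@dataclass(frozen=True)
class CohortSchema:
    """Declared column set of a cohort table (units in the module docstring)."""

    required: tuple = REQUIRED_COLUMNS
    optional: tuple = OPTIONAL_COLUMNS
    version: str = SCHEMA_VERSION


DEFAULT_SCHEMA = CohortSchema()

#: Default multivariate-model term list (continuous terms standardized).
DEFAULT_MODEL_TERMS = (
    "group_indicator", "bmi", "waist", "log10_triglycerides", "hdl",
    "physical_activity", "smoker", "family_history",
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; the seed is mandatory for any
    stochastic step (simulation, bootstrap)."""

    seed: Optional[int] = None
    input: Optional[str] = None  # cohort CSV; when absent, simulate
    scenario: str = "realistic"
    n: Optional[int] = None
    delta: float = 0.0
    reference_group: str = "reference"
    log_variables: Sequence[str] = ("isi", "dio", "triglycerides")
    model_terms: Sequence[str] = DEFAULT_MODEL_TERMS
    moderator: str = "group_indicator"
    bootstrap_resamples: int = 0
    min_stratum_n: int = 30

    def require_seed(self) -> int:
        if self.seed is None:
            raise DomainError("this command is stochastic: a seed is required")
        return int(self.seed)


def load_config(path) -> RunConfig:
    """Load a YAML-or-JSON run configuration."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _parse_bool(raw: str):
    low = raw.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"not a boolean: {raw!r}")


def read_cohort(path, schema: CohortSchema = DEFAULT_SCHEMA) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a cohort CSV.

    Returns ``(cohort, row_errors)``.  A missing required column or an empty
    file raises :class:`SchemaError`.  Rows with malformed numerics, unknown
    sex, or unparseable booleans are dropped into ``row_errors`` (columns:
    line, subject_id, problem) while all other rows load normally.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    if len(raw) == 0:
        raise SchemaError(f"{path}: no data rows")
    missing = [c for c in schema.required if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    problems: dict[int, list] = {}

    def flag(i, msg):
        problems.setdefault(i, []).append(msg)

    out = pd.DataFrame(index=raw.index)
    out["subject_id"] = raw["subject_id"].str.strip()
    out["group"] = raw["group"].str.strip()
    sex = raw["sex"].str.strip().str.lower()
    for i in raw.index[~sex.isin(SEX_VALUES)]:
        flag(i, f"unknown sex {raw.loc[i, 'sex']!r}")
    out["sex"] = sex

    for col in NUMERIC_COLUMNS:
        if col not in raw.columns:
            continue
        txt = raw[col].str.strip()
        bad = pd.to_numeric(txt, errors="coerce").isna() & (txt != "")
        for i in raw.index[bad]:
            flag(i, f"malformed numeric in {col}: {raw.loc[i, col]!r}")
        # exact (correctly rounded) parse; to_numeric above only detects errors
        vals = np.full(len(raw), np.nan)
        ok = (~bad & (txt != "")).to_numpy()
        vals[ok] = txt.to_numpy()[ok].astype(float)
        out[col] = vals

    for col in BOOLEAN_COLUMNS:
        if col not in raw.columns:
            continue
        parsed = []
        for i, v in raw[col].items():
            if v.strip() == "":
                parsed.append(np.nan)
                continue
            try:
                parsed.append(_parse_bool(v))
            except ValueError:
                flag(i, f"malformed boolean in {col}: {v!r}")
                parsed.append(np.nan)
        out[col] = parsed

    bad_rows = sorted(problems)
    row_errors = pd.DataFrame(
        {
            "line": [i + 2 for i in bad_rows],  # header is line 1
            "subject_id": [raw.loc[i, "subject_id"] for i in bad_rows],
            "problem": ["; ".join(problems[i]) for i in bad_rows],
        }
    )
    for _, r in row_errors.iterrows():
        logger.warning("row %d (subject %s) rejected: %s", r["line"], r["subject_id"], r["problem"])
    cohort = out.drop(index=bad_rows).reset_index(drop=True)
    return cohort, row_errors


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic CSV export (shortest round-tripping float repr)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _regression_section(analysis_table: pd.DataFrame, config: RunConfig) -> dict:
    """Per-sex standardized regressions of log10 ISI with interaction scan."""
    fits = {}
    for sex in sorted(set(analysis_table["sex"])):
        sub = analysis_table.loc[analysis_table["sex"] == sex].copy()
        terms = [t for t in config.model_terms if t in sub.columns]
        cols = ["log10_isi"] + terms
        sub = sub.dropna(subset=[c for c in cols if c in sub.columns])
        if len(sub) < len(terms) + 2:
            continue
        design, std_flags = build_design(sub, terms)
        fit = ols_fit(sub["log10_isi"], design, standardized=std_flags)
        entry = fit.to_dict()
        if config.moderator in design.columns and design[config.moderator].nunique() > 1:
            scan = interaction_scan(sub["log10_isi"], design, config.moderator)
            entry["interaction_scan"] = scan.to_dict(orient="records")
        fits[sex] = entry
    return fits


def run_report(config: RunConfig, outdir) -> dict:
    """One-shot pipeline: simulate/read → exclude → indices → classify →
    cut-offs → regression; writes CSV/JSON results plus a structured log.

    Outputs are deterministic given the config (and its seed): rerunning
    with identical settings produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.write_text("")
    finally:
        if probe.exists():
            probe.unlink()

    log_lines = [f"config_hash={config_hash(config)}", f"schema_version={SCHEMA_VERSION}"]

    if config.input:
        cohort, row_errors = read_cohort(config.input)
        log_lines += [f"row_rejected line={r.line} subject={r.subject_id} problem={r.problem}"
                      for r in row_errors.itertuples()]
    else:
        seed = config.require_seed()
        params = default_params(config.scenario, seed=seed, n=config.n, delta=config.delta)
        cohort = generate_cohort(params)
        log_lines.append(f"simulated scenario={config.scenario} n_total={len(cohort)} seed={seed}")

    cohort, exclusions = exclude_diabetes(cohort)
    log_lines += [f"excluded subject={r.subject_id} reason={r.reason}" for r in exclusions.itertuples()]
    write_table(exclusions, outdir / "exclusions.csv")

    indices = compute_indices(cohort)
    write_table(indices, outdir / "indices.csv")
    n_cir_undef = int((~indices["cir_defined"]).sum())
    log_lines.append(f"cir_undefined n={n_cir_undef}")

    ref_isi = indices.loc[
        indices["subject_id"].isin(cohort.loc[cohort["group"] == config.reference_group, "subject_id"])
        & indices["isi_defined"],
        "isi",
    ]
    ref = tertile_reference(ref_isi)
    log_lines.append(f"tertile_cuts lo={ref.cut_lo!r} hi={ref.cut_hi!r} n_ref={ref.n_reference}")
    prev = pd.concat(
        [
            prevalence_crosstab(cohort, indices, ref, adiposity="abdominal_obesity"),
            prevalence_crosstab(cohort, indices, ref, adiposity="weight_class"),
        ],
        ignore_index=True,
    )
    write_table(prev, outdir / "prevalence.csv")

    cut_cfg = CutoffConfig(
        min_n=config.min_stratum_n,
        bootstrap_resamples=config.bootstrap_resamples,
        seed=config.seed if config.bootstrap_resamples else None,
    )
    results, provenance = run_cutoff_analysis(cohort, indices, config.reference_group, cut_cfg)
    write_table(results_frame(results), outdir / "cutoffs.csv")
    prov_json = {
        "config": dataclasses.asdict(config),
        "tertiles": {"cut_lo": ref.cut_lo, "cut_hi": ref.cut_hi, "n_reference": ref.n_reference},
        "fits": [dataclasses.asdict(f) for f in provenance["fits"]],
    }
    (outdir / "provenance.json").write_text(json.dumps(prov_json, indent=2, sort_keys=True, default=str))

    analysis = cohort.merge(indices[["subject_id", "isi", "isi_defined"]], on="subject_id")
    analysis = analysis.loc[analysis["isi_defined"]].copy()
    analysis["group_indicator"] = (analysis["group"] != config.reference_group).astype(float)
    for b in ("smoker", "family_history"):
        if b in analysis.columns:
            analysis[b] = analysis[b].astype(float)
    analysis, transforms = log_transform_policy(analysis, [v for v in config.log_variables if v in analysis.columns])
    log_lines += [f"log10_transform variable={t['variable']}" for t in transforms]
    fits = _regression_section(analysis, config)
    (outdir / "fits.json").write_text(json.dumps(fits, indent=2, sort_keys=True))

    (outdir / "report.log").write_text("\n".join(log_lines) + "\n")
    return {
        "cohort_n": int(len(cohort)),
        "excluded_n": int(len(exclusions)),
        "tertiles": (ref.cut_lo, ref.cut_hi),
        "n_cutoffs": len(results),
        "outdir": str(outdir),
    }
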