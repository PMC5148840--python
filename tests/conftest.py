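import numpy as np
import pandas as pd
import pytest


def make_cohort(rows):
    """Build a cohort frame from per-subject dicts, filling sane defaults."""
    defaults = dict(
        group="reference", sex="female", age=50.0, bmi=26.0, waist=85.0,
        glucose_0=5.0, glucose_30=8.0, glucose_60=7.0, glucose_90=6.5, glucose_120=6.0,
        insulin_0=8.0, insulin_30=40.0, insulin_60=32.0, insulin_90=28.0, insulin_120=24.0,
        triglycerides=1.2, hdl=1.4, smoker=False, physical_activity=3.0, family_history=False,
    )
    recs = []
    for i, row in enumerate(rows):
        rec = dict(defaults, subject_id=f"T{i:03d}")
        rec.update(row)
        recs.append(rec)
    return pd.DataFrame(recs)


@pytest.fixture
def tiny_cohort():
    """Three subjects: constant trajectories (ISI 100), a CIR-undefined
    30-min glucose, and a missing 60-min glucose."""
    return make_cohort(
        [
            dict(glucose_0=4.0, glucose_30=4.0, glucose_60=4.0, glucose_90=4.0, glucose_120=4.0,
                 insulin_0=25.0, insulin_30=25.0, insulin_60=25.0, insulin_90=25.0, insulin_120=25.0),
            dict(glucose_30=3.5),
            dict(glucose_60=np.nan),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
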