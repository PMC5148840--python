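"""Age adjustment, group line fits and the equivalence cut-off solver."""

import dataclasses
import warnings

import numpy as np
import pytest

from ogttools.cutoffs import (
    CutoffConfig,
    GroupLineFit,
    age_adjust_outcome,
    equivalence_cutoff,
    fit_group_line,
    run_cutoff_analysis,
)
from ogttools.errors import AgeAdjustmentWarning, DomainError, NonIdentifiableError, ExtrapolationWarning
from ogttools.indices import compute_indices
from ogttools.simulate import default_params, generate_cohort


def _fit(slope, intercept, **kw):
    base = dict(group="cmp", sex="male", measure="bmi", outcome="log10_isi",
                n=100, residual_sd=0.2)
    base.update(kw)
    return GroupLineFit(slope=slope, intercept=intercept, **base)


class TestAgeAdjustment:
    def test_residual_orthogonality_and_mean_preservation(self, rng):
        age = rng.uniform(30, 75, size=400)
        log_isi = 2.2 - 0.006 * age + rng.normal(0, 0.2, size=400)
        adj = age_adjust_outcome(10.0**log_isi, age)
        assert abs(np.corrcoef(adj, age)[0, 1]) < 1e-10
        assert adj.mean() == pytest.approx(log_isi.mean(), abs=1e-12)

    def test_no_age_effect_is_a_near_noop(self, rng):
        vals = 10.0 ** rng.normal(2.0, 0.2, size=2000)
        age = rng.uniform(30, 75, size=2000)
        adj = age_adjust_outcome(vals, age)
        assert np.allclose(adj, np.log10(vals), atol=0.02)

    def test_zero_age_variance_warns_and_returns_log10(self):
        vals = np.array([50.0, 100.0, 200.0])
        with pytest.warns(AgeAdjustmentWarning):
            adj = age_adjust_outcome(vals, np.full(3, 50.0))
        np.testing.assert_allclose(adj, np.log10(vals))

    def test_nonpositive_outcome_rejected(self):
        with pytest.raises(DomainError):
            age_adjust_outcome([10.0, -1.0], [40.0, 50.0])


class TestGroupLineFit:
    def test_collinear_points_recovered_exactly(self):
        x = np.array([20.0, 25.0, 30.0])
        y = 2.5 - 0.02 * x
        fit = fit_group_line(x, y)
        assert fit.slope == pytest.approx(-0.02, abs=1e-14)
        assert fit.intercept == pytest.approx(2.5, abs=1e-13)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(20, 35, size=5)
        y = rng.normal(2.0, 0.3, size=5)
        X = np.column_stack([np.ones(5), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)  # independent closed form
        fit = fit_group_line(x, y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_outcome_shift_moves_intercept_only(self, rng):
        x = rng.uniform(20, 35, size=30)
        y = rng.normal(2.0, 0.3, size=30)
        f0, f1 = fit_group_line(x, y), fit_group_line(x, y + 0.7)
        assert f1.slope == pytest.approx(f0.slope, abs=1e-12)
        assert f1.intercept == pytest.approx(f0.intercept + 0.7, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DomainError):
            fit_group_line([25.0, 25.0, 25.0], [2.0, 2.1, 2.2])
        with pytest.raises(DomainError):
            fit_group_line([25.0, 26.0], [2.0, 2.1])


class TestEquivalenceSolver:
    def test_identical_fits_return_the_threshold(self):
        f = _fit(-0.02, 2.6)
        res = equivalence_cutoff(f, f, 30.0)
        assert res.cutoff_raw == 30.0
        assert res.reference_outcome_level == pytest.approx(2.6 - 0.6)

    def test_parallel_lines_give_pure_horizontal_shift(self):
        b = -0.03
        ref = _fit(b, 2.6)
        cmp_ = _fit(b, 2.6 + 2 * b)  # intercept lower by 2|b| (b < 0)
        res = equivalence_cutoff(ref, cmp_, 30.0)
        assert res.cutoff_raw == pytest.approx(28.0, abs=1e-10)

    def test_hand_solved_example(self):
        res = equivalence_cutoff(_fit(-0.02, 2.6), _fit(-0.02, 2.5), 30.0)
        assert res.reference_outcome_level == pytest.approx(2.0)
        assert res.cutoff_raw == pytest.approx(25.0, abs=1e-10)
        assert res.cutoff_rounded == 25.0

    def test_rounding_grids(self):
        res = equivalence_cutoff(_fit(-0.02, 2.6), _fit(-0.019, 2.53), 30.0)
        assert res.cutoff_rounded == pytest.approx(round(res.cutoff_raw * 2) / 2, abs=0.26)
        assert res.cutoff_rounded % 0.5 == 0
        wres = equivalence_cutoff(
            _fit(-0.01, 2.9, measure="waist"), _fit(-0.011, 2.83, measure="waist"), 94.0
        )
        assert wres.cutoff_rounded == float(round(wres.cutoff_raw))

    def test_flat_comparison_slope_not_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            equivalence_cutoff(_fit(-0.02, 2.6), _fit(1e-12, 2.6), 30.0)

    def test_mismatched_fits_rejected(self):
        with pytest.raises(DomainError):
            equivalence_cutoff(_fit(-0.02, 2.6), _fit(-0.02, 2.5, measure="waist"), 30.0)

    def test_extrapolation_flagged(self):
        with pytest.warns(ExtrapolationWarning):
            res = equivalence_cutoff(_fit(-0.02, 2.6), _fit(-0.02, 2.2), 30.0, cmp_range=(18.0, 42.0))
        assert res.extrapolated

    def test_round_trip_identity_on_random_fits(self, rng):
        for _ in range(50):
            ref = _fit(rng.uniform(-0.06, -0.005), rng.uniform(2.0, 3.0))
            cmp_ = _fit(rng.uniform(-0.06, -0.005), rng.uniform(2.0, 3.0))
            x_ref = rng.uniform(24, 32)
            res = equivalence_cutoff(ref, cmp_, x_ref)
            assert cmp_.predict(res.cutoff_raw) == pytest.approx(ref.predict(x_ref), abs=1e-10)


def _bmi_isi_cutoffs(results, threshold=30.0):
    return {
        (r.sex): r.cutoff_raw
        for r in results
        if r.measure == "bmi" and r.outcome == "log10_isi" and r.reference_threshold == threshold
    }


class TestCutoffAnalysis:
    def _cohort_and_indices(self, scenario, seed, n, delta=0.0):
        cohort = generate_cohort(default_params(scenario, seed=seed, n=n, delta=delta))
        return cohort, compute_indices(cohort)

    def test_reference_vs_itself_reproduces_thresholds(self):
        cohort, idx = self._cohort_and_indices("null", seed=1, n=300)
        solo = cohort.loc[cohort["group"] == "reference"]
        twin = solo.assign(group="comparison", subject_id="c" + solo["subject_id"])
        twin_idx = idx.loc[idx["subject_id"].isin(solo["subject_id"])].assign(
            subject_id="c" + idx.loc[idx["subject_id"].isin(solo["subject_id"]), "subject_id"]
        )
        import pandas as pd

        results, _ = run_cutoff_analysis(
            pd.concat([solo, twin], ignore_index=True),
            pd.concat([idx, twin_idx], ignore_index=True),
            "reference",
        )
        for r in results:
            assert r.cutoff_raw == pytest.approx(r.reference_threshold, abs=1e-9)

    def test_planted_shift_recovered(self):
        errs = []
        for seed in (11, 12, 13):
            cohort, idx = self._cohort_and_indices("shift", seed=seed, n=1500, delta=2.0)
            results, _ = run_cutoff_analysis(cohort, idx, "reference")
            errs += [abs(c - 28.0) for c in _bmi_isi_cutoffs(results).values()]
        assert np.mean(errs) < 0.35

    def test_outcome_scale_equivariance(self):
        cohort, idx = self._cohort_and_indices("shift", seed=5, n=500, delta=1.0)
        res1, _ = run_cutoff_analysis(cohort, idx, "reference")
        scaled = idx.assign(isi=idx["isi"] * 10.0, dio=idx["dio"] * 10.0)
        res2, _ = run_cutoff_analysis(cohort, scaled, "reference")
        for a, b in zip(res1, res2):
            assert b.cutoff_raw == pytest.approx(a.cutoff_raw, abs=1e-9)

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_zero_comparison_slope_surfaces_error(self, rng):
        import pandas as pd

        n = 60
        rows = []
        for group in ("reference", "comparison"):
            bmi = rng.uniform(22, 34, size=n)
            for i in range(n):
                # constant age: the (skipped) age adjustment cannot perturb the
                # exactly flat comparison outcome
                rows.append(dict(subject_id=f"{group[:3]}{i}", group=group, sex="male",
                                 age=50.0, bmi=bmi[i], waist=60 + 1.0 * bmi[i]))
        cohort = pd.DataFrame(rows)
        idx = pd.DataFrame({
            "subject_id": cohort["subject_id"],
            "isi": np.concatenate([10 ** (2.5 - 0.03 * cohort["bmi"][:n]), np.full(n, 10**1.9)]),
            "dio": np.full(2 * n, 1e4),
        })
        with pytest.raises(NonIdentifiableError):
            run_cutoff_analysis(cohort, idx, "reference", CutoffConfig(outcomes=("isi",), measures=("bmi",)))

    def test_small_stratum_marked_unreliable(self):
        cohort, idx = self._cohort_and_indices("null", seed=3, n=20)
        results, _ = run_cutoff_analysis(cohort, idx, "reference", CutoffConfig(min_n=30))
        assert all(not r.reliable for r in results)

    def test_bootstrap_requires_seed(self):
        cohort, idx = self._cohort_and_indices("null", seed=3, n=50)
        with pytest.raises(DomainError, match="seed"):
            run_cutoff_analysis(cohort, idx, "reference", CutoffConfig(bootstrap_resamples=10))

    def test_bootstrap_ci_covers_planted_cutoff(self):
        """Percentile bootstrap CI coverage at nominal 95% stays >= 90%."""
        delta, covered, total = 2.0, 0, 0
        cfg = CutoffConfig(outcomes=("isi",), measures=("bmi",), bmi_thresholds=(30.0,),
                           bootstrap_resamples=200, seed=0)
        for seed in range(50):
            cohort = generate_cohort(default_params("shift", seed=100 + seed, n=500, delta=delta))
            cohort = cohort.loc[cohort["sex"] == "male"].reset_index(drop=True)
            idx = compute_indices(cohort)
            results, _ = run_cutoff_analysis(
                cohort, idx, "reference", dataclasses.replace(cfg, seed=seed)
            )
            (res,) = results
            if res.ci is not None:
                total += 1
                covered += res.ci[0] <= 30.0 - delta <= res.ci[1]
        assert total >= 45
        assert covered / total >= 0.90
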