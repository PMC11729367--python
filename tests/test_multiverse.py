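"""Multiverse machinery: the 48-specification grid, per-specification
analysis, curve assembly, permutation inference, and whole-brain testing."""

import numpy as np
import pandas as pd
import pytest

from specurve.multiverse import (
    PREREGISTERED,
    InsufficientDataError,
    Specification,
    StudyData,
    build_curve,
    compute_exponent_table,
    enumerate_specifications,
    infer_curve,
    permuted_cohort,
    run_specification,
    whole_brain_analysis,
)
from specurve.synthetic import EffectConfig, assign_ground_truth, generate_cohort


@pytest.fixture(scope="module")
def tiny_study():
    """8/8 cohort with 2 regions on reduced grids: fast but full-pipeline."""
    cohort = generate_cohort(8, 8, {"other": 8}, seed=31)
    truth = assign_ground_truth(cohort, EffectConfig(), seed=32)
    data = StudyData.from_truth_spectra(
        truth, cohort, regions=("mpfc-1", "mpfc-2"), seed=33,
        grid_resolution={2.0: 1.0, 5.0: 1.0},
    )
    return cohort, truth, data


@pytest.fixture(scope="module")
def tiny_table(tiny_study):
    cohort, _, data = tiny_study
    return compute_exponent_table(data, cohort, enumerate_specifications())


class TestSpecificationGrid:
    def test_exactly_48_unique_specifications(self):
        specs = enumerate_specifications()
        assert len(specs) == 48
        assert len(set(specs)) == 48

    def test_contains_preregistered_member(self):
        assert PREREGISTERED in enumerate_specifications()
        assert PREREGISTERED == Specification(2.0, "dpss", True, (2.0, 40.0), False)

    def test_dimension_cardinalities(self):
        specs = enumerate_specifications()
        assert {s.epoch_length for s in specs} == {2.0, 5.0}
        assert {s.taper for s in specs} == {"dpss", "hanning"}
        assert {s.avg_psd for s in specs} == {True, False}
        assert {s.fit_range for s in specs} == {(2.0, 40.0), (40.0, 60.0), (1.0, 100.0)}
        assert {s.knee for s in specs} == {False, True}


class TestPermutedCohort:
    def test_group_mode_preserves_label_counts(self, tiny_study):
        cohort, _, _ = tiny_study
        perm = permuted_cohort(cohort, "group", seed=5)
        assert perm["group"].value_counts().to_dict() == cohort["group"].value_counts().to_dict()
        assert (perm["age"] == cohort["age"]).all()

    def test_correlation_mode_permutes_ratings_only(self, tiny_study):
        cohort, _, _ = tiny_study
        perm = permuted_cohort(cohort, "correlation", seed=5)
        pain = cohort["group"] == "pain"
        assert sorted(perm.loc[pain, "pain_intensity"]) == sorted(
            cohort.loc[pain, "pain_intensity"]
        )
        assert (perm["group"] == cohort["group"]).all()
        assert perm.loc[~pain, "pain_intensity"].isna().all()

    def test_same_seed_same_permutation(self, tiny_study):
        cohort, _, _ = tiny_study
        a = permuted_cohort(cohort, "group", seed=9)
        b = permuted_cohort(cohort, "group", seed=9)
        assert (a["group"] == b["group"]).all()


class TestRunSpecification:
    def test_identical_groups_give_null_result(self, tiny_study):
        cohort, _, data = tiny_study
        cohort = cohort.copy()
        cohort["age"] = np.tile(np.arange(30, 38), 2)  # same ages in both groups
        vals = np.tile(np.linspace(1.0, 1.4, 8), 2)  # pain == healthy multiset
        chi = pd.Series(vals, index=cohort["subject_id"])
        res = run_specification(data, cohort, PREREGISTERED, "group", exponents=chi)
        assert res.effect.value == pytest.approx(0.0, abs=1e-12)
        assert res.bayes.bf10 < 1.0
        assert res.n_used == 16 and res.n_excluded == 0

    def test_nonconverged_subjects_are_excluded_and_counted(self, tiny_study):
        cohort, _, data = tiny_study
        rng = np.random.default_rng(0)
        vals = rng.normal(1.1, 0.2, len(cohort))
        vals[:3] = np.nan
        chi = pd.Series(vals, index=cohort["subject_id"])
        res = run_specification(data, cohort, PREREGISTERED, "group", exponents=chi)
        assert res.n_excluded == 3
        assert res.n_used == 13
        # correlation analysis drops a missing subject from BOTH variables
        res_c = run_specification(data, cohort, PREREGISTERED, "correlation", exponents=chi)
        assert res_c.n_used + res_c.n_excluded == 8  # pain subjects only
        assert res_c.bayes.n == res_c.n_used

    def test_too_few_usable_subjects_raise(self, tiny_study):
        cohort, _, data = tiny_study
        chi = pd.Series(np.nan, index=cohort["subject_id"])
        chi.iloc[:3] = 1.0
        with pytest.raises(InsufficientDataError):
            run_specification(data, cohort, PREREGISTERED, "group", exponents=chi)

    def test_injected_effect_is_detected(self):
        hits = 0
        for rep in range(20):
            cohort = generate_cohort(60, 60, {"other": 60}, seed=700 + rep)
            truth = assign_ground_truth(
                cohort, EffectConfig(group_d=1.2, age_slope=0.0), seed=800 + rep
            )
            data = StudyData.from_truth_spectra(
                truth, cohort, regions=("mpfc-1", "mpfc-2"), seed=900 + rep,
                epoch_lengths=(2.0,), grid_resolution={2.0: 1.0},
            )
            table = compute_exponent_table(data, cohort, [PREREGISTERED])
            res = run_specification(
                data, cohort, PREREGISTERED, "group", exponents=table[0]
            )
            hits += 0.8 <= res.effect.value <= 1.6 and res.bayes.bf10 > 3.0
        assert hits >= 18


class TestTimeseriesPath:
    def test_timeseries_study_data_runs_the_full_pipeline(self):
        cohort = generate_cohort(3, 3, {"other": 3}, seed=91)
        truth = assign_ground_truth(cohort, EffectConfig(), seed=92)
        data = StudyData.from_truth_timeseries(
            truth, cohort, regions=("mpfc-1",), duration=60.0, sampling_rate=250.0, seed=93
        )
        specs = [
            PREREGISTERED,
            Specification(2.0, "hanning", True, (2.0, 40.0), False),
        ]
        table = compute_exponent_table(data, cohort, specs)
        assert table.notna().all().all()
        truth_chi = truth.params.set_index("subject_id")["exponent"]
        # exponents estimated from 60 s of signal track the truth loosely
        assert np.all(np.abs(table[0] - truth_chi.loc[table.index]) < 0.35)
        # on real epoched signals the taper choice genuinely matters
        assert not np.allclose(table[0], table[1])
        # PSD cache makes the second pass cheap and identical
        table2 = compute_exponent_table(data, cohort, specs)
        pd.testing.assert_frame_equal(table, table2)


class TestCurve:
    def test_curve_is_sorted_permutation_of_grid(self, tiny_study, tiny_table):
        cohort, _, data = tiny_study
        curve = build_curve(data, cohort, "group", exponent_table=tiny_table)
        assert len(curve.results) == 48
        effects = curve.effects
        assert np.all(np.diff(effects) >= 0)
        assert {r.specification for r in curve.results} == set(enumerate_specifications())

    def test_preregistered_result_matches_direct_run(self, tiny_study, tiny_table):
        cohort, _, data = tiny_study
        specs = enumerate_specifications()
        j = specs.index(PREREGISTERED)
        direct = run_specification(data, cohort, PREREGISTERED, "group", exponents=tiny_table[j])
        curve = build_curve(data, cohort, "group", exponent_table=tiny_table)
        from_curve = next(
            r for r in curve.results if r.specification == PREREGISTERED
        )
        assert from_curve.effect.value == direct.effect.value
        assert from_curve.bayes.bf10 == direct.bayes.bf10
        assert from_curve.freq_p == direct.freq_p

    def test_taper_is_irrelevant_on_stored_spectra(self, tiny_study, tiny_table):
        # direct-synthesis spectra carry no taper information, so specs
        # differing only by taper must give identical exponents
        specs = enumerate_specifications()
        for j, spec in enumerate(specs):
            if spec.taper == "dpss":
                twin = Specification(
                    spec.epoch_length, "hanning", spec.avg_psd, spec.fit_range, spec.knee
                )
                k = specs.index(twin)
                pd.testing.assert_series_equal(tiny_table[j], tiny_table[k], check_names=False)


class TestInference:
    def test_reproducible_and_bounded_p_values(self, tiny_study, tiny_table):
        cohort, _, data = tiny_study
        a = infer_curve(data, cohort, "group", B=50, seed=3, exponent_table=tiny_table)
        b = infer_curve(data, cohort, "group", B=50, seed=3, exponent_table=tiny_table)
        assert a.to_dict() == b.to_dict()
        for p in (a.p_median, a.p_share, a.p_aggregate):
            assert 1.0 / 51.0 <= p <= 1.0

    def test_zero_share_gives_p_one(self, tiny_study, tiny_table):
        cohort, _, data = tiny_study
        inf = infer_curve(data, cohort, "group", B=50, seed=3, exponent_table=tiny_table)
        if inf.observed_share == 0.0:
            assert inf.p_share == 1.0

    def test_injected_effect_rejects(self):
        cohort = generate_cohort(50, 50, {"other": 50}, seed=41)
        truth = assign_ground_truth(cohort, EffectConfig(group_d=1.0, age_slope=0.0), seed=42)
        data = StudyData.from_truth_spectra(
            truth, cohort, regions=("mpfc-1", "mpfc-2"), seed=43,
            grid_resolution={2.0: 1.0, 5.0: 1.0},
        )
        table = compute_exponent_table(data, cohort, enumerate_specifications())
        inf = infer_curve(data, cohort, "group", B=100, seed=44, exponent_table=table)
        assert inf.p_median < 0.05
        assert inf.p_aggregate < 0.05
        assert inf.p_share < 0.05


class TestWholeBrain:
    @staticmethod
    def _exponent_matrix(cohort, n_regions, seed, spike_region=None, spike_d=0.0):
        rng = np.random.default_rng(seed)
        mat = rng.normal(1.1, 0.17, size=(len(cohort), n_regions))
        if spike_region is not None:
            pain = (cohort["group"] == "pain").to_numpy()
            mat[pain, spike_region] += spike_d * 0.17
        return pd.DataFrame(
            mat,
            index=pd.Index(cohort["subject_id"], name="subject_id"),
            columns=[f"region-{i:03d}" for i in range(n_regions)],
        )

    def test_identical_regions_get_identical_p(self):
        cohort = generate_cohort(20, 20, {"other": 20}, seed=51)
        rng = np.random.default_rng(0)
        col = rng.normal(1.1, 0.17, len(cohort))
        exponents = pd.DataFrame(
            {f"r{i}": col for i in range(5)},
            index=pd.Index(cohort["subject_id"], name="subject_id"),
        )
        out = whole_brain_analysis(exponents, cohort, "group", B_fdr=100, seed=1)
        assert out["p"].nunique() == 1

    def test_injected_region_survives_fdr(self):
        hits = 0
        for rep in range(10):
            cohort = generate_cohort(60, 60, {"other": 60}, seed=60 + rep)
            exponents = self._exponent_matrix(
                cohort, 100, seed=160 + rep, spike_region=0, spike_d=1.5
            )
            out = whole_brain_analysis(exponents, cohort, "group", B_fdr=200, seed=260 + rep)
            hits += out.loc[out["region_label"] == "region-000", "p_adj"].iloc[0] < 0.05
        assert hits >= 9

    def test_null_regions_rarely_reject(self):
        quiet = 0
        for rep in range(5):
            cohort = generate_cohort(40, 40, {"other": 40}, seed=70 + rep)
            exponents = self._exponent_matrix(cohort, 100, seed=170 + rep)
            out = whole_brain_analysis(exponents, cohort, "group", B_fdr=200, seed=270 + rep)
            quiet += (out["p_adj"] < 0.05).sum() <= 1
        assert quiet >= 4
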