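"""Statistical machinery: residualization, effect sizes, JZS Bayes factors
(against independent quadrature oracles and pingouin), frequentist tests,
Stouffer aggregation, sensitivity analysis, resampling FDR and matching."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats as sps

from specurve.stats import (
    MatchingFailureError,
    bf_correlation_from_r,
    bf_ttest_from_t,
    cohens_d,
    detectable_effect_size,
    evidence_category,
    match_controls,
    pearson_test,
    resampling_fdr,
    residualize,
    signed_z_from_p,
    stouffer_aggregate,
    two_sample_test,
)
from specurve.synthetic import generate_cohort


def oracle_bf_ttest(t, n1, n2, scale):
    """Brute-force JZS oracle: Cauchy prior on delta, noncentral-t likelihood."""
    nu = n1 + n2 - 2
    ne = math.sqrt(n1 * n2 / (n1 + n2))
    # the likelihood is concentrated near delta = t/ne; Cauchy-tail mass
    # beyond the bracket carries negligible likelihood
    b = abs(t) / ne + 10.0

    def integrand(d):
        val = sps.nct.pdf(t, nu, d * ne) * sps.cauchy.pdf(d, 0.0, scale)
        return val if np.isfinite(val) else 0.0  # deep-tail underflow artifacts

    num, _ = integrate.quad(integrand, -b, b, points=[0.0, t / ne], limit=400)
    return num / sps.t.pdf(t, nu)


def oracle_bf_correlation(r, n, width):
    """Fine-grid trapezoid oracle for the correlation Bayes factor."""
    a = 1.0 / width
    rho = np.linspace(-1 + 1e-9, 1 - 1e-9, 400_001)
    from scipy.special import betaln, hyp2f1

    h = hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0)
    h0 = hyp2f1(0.5, 0.5, n - 0.5, 0.5)
    log_lik = (
        0.5 * (n - 1) * np.log1p(-(rho**2))
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(h) - np.log(h0)
    )
    log_prior = (a - 1.0) * np.log1p(-(rho**2)) - (2 * a - 1) * np.log(2.0) - betaln(a, a)
    return float(np.trapezoid(np.exp(log_lik + log_prior), rho))


class TestResidualize:
    def test_hand_computed_ols_residuals(self):
        res = residualize([1.0, 2.0, 3.0, 5.0], [1.0, 2.0, 3.0, 4.0])
        assert res == pytest.approx([0.2, -0.1, -0.4, 0.3], abs=1e-12)

    def test_perfectly_explained_values(self):
        age = np.array([20.0, 30.0, 40.0, 55.0])
        assert residualize(2.0 * age, age) == pytest.approx(np.zeros(4), abs=1e-10)

    def test_orthogonal_covariate_just_centers(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0])
        v = np.array([1.0, 1.0, 2.0, 2.0])  # orthogonal to centered x
        assert residualize(v, x) == pytest.approx(v - v.mean(), abs=1e-12)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            residualize([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestEffectSizes:
    def test_identical_groups_have_zero_d(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).value == 0.0

    def test_hand_computed_d(self):
        assert cohens_d([1.0, 2.0, 3.0], [2.0, 3.0, 4.0]).value == pytest.approx(-1.0)

    def test_shift_by_one_sd_gives_unit_d(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(200_000)
        d = cohens_d(y + y.std(ddof=1), y).value
        assert d == pytest.approx(1.0, abs=0.01)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestEvidenceCategories:
    @pytest.mark.parametrize(
        "bf,cat",
        [
            (0.05, "strong_null"),
            (1 / 10, "moderate_null"),
            (0.2, "moderate_null"),
            (1 / 3, "inconclusive"),
            (1.0, "inconclusive"),
            (3.0, "inconclusive"),
            (3.0001, "moderate_alt"),
            (10.0, "moderate_alt"),
            (10.0001, "strong_alt"),
        ],
    )
    def test_boundaries(self, bf, cat):
        assert evidence_category(bf) == cat

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_partition_is_total_and_exclusive(self, bf):
        assert evidence_category(bf) in {
            "strong_null", "moderate_null", "inconclusive", "moderate_alt", "strong_alt"
        }


class TestBayesFactors:
    def test_null_t_gives_evidence_for_null(self):
        assert bf_ttest_from_t(0.0, 30, 30) < 1.0

    def test_bf_monotone_in_t(self):
        bfs = [bf_ttest_from_t(t, 40, 40) for t in (0.0, 0.5, 1.0, 2.0, 3.0, 5.0)]
        assert np.all(np.diff(bfs) > 0)

    @pytest.mark.parametrize("t,n1,n2", [(2.5, 50, 50), (1.0, 20, 30), (4.0, 100, 80)])
    def test_ttest_bf_matches_quadrature_oracle(self, t, n1, n2):
        scale = math.sqrt(2) / 2
        assert bf_ttest_from_t(t, n1, n2, scale) == pytest.approx(
            oracle_bf_ttest(t, n1, n2, scale), rel=1e-4
        )

    def test_ttest_bf_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        ours = bf_ttest_from_t(2.5, 50, 50)
        theirs = float(pg.bayesfactor_ttest(2.5, 50, 50))
        assert ours == pytest.approx(theirs, rel=1e-3)

    def test_null_r_gives_evidence_for_null(self):
        assert bf_correlation_from_r(0.0, 50) < 1.0

    def test_strong_r_gives_strong_evidence(self):
        assert bf_correlation_from_r(0.9, 100) > 10.0

    @pytest.mark.parametrize("r,n", [(0.5, 50), (0.1, 30), (-0.4, 120)])
    def test_correlation_bf_matches_trapezoid_oracle(self, r, n):
        assert bf_correlation_from_r(r, n, 1 / 3) == pytest.approx(
            oracle_bf_correlation(r, n, 1 / 3), rel=1e-3
        )

    def test_correlation_bf_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        ours = bf_correlation_from_r(0.5, 50, 1 / 3)
        theirs = float(pg.bayesfactor_pearson(0.5, 50, method="ly", kappa=1 / 3))
        assert ours == pytest.approx(theirs, rel=1e-3)


class TestFrequentistTests:
    def test_identical_groups(self):
        t, p = two_sample_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0
        assert signed_z_from_p(p, 0.0) == 0.0

    def test_textbook_t(self):
        t, p = two_sample_test([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert t == pytest.approx(-1.0)
        assert p == pytest.approx(2 * sps.t.sf(1.0, 8))

    def test_point_biserial_equivalence(self):
        # t-test p equals correlation-test p when the regressor is the
        # group indicator
        rng = np.random.default_rng(5)
        x = rng.standard_normal(30)
        y = rng.standard_normal(30) + 0.5
        vals = np.concatenate([x, y])
        indicator = np.concatenate([np.zeros(30), np.ones(30)])
        _, p_t = two_sample_test(x, y)
        _, p_r = pearson_test(vals, indicator)
        assert p_t == pytest.approx(p_r, rel=1e-10)


class TestStouffer:
    def test_equal_z_scaling(self):
        z0 = signed_z_from_p(0.05, 1.0)
        p = [0.05] * 4
        assert stouffer_aggregate(p, [1, 1, 1, 1]) == pytest.approx(z0 * 2.0)

    def test_sign_cancellation(self):
        assert stouffer_aggregate([0.1, 0.1], [1, -1]) == pytest.approx(0.0)

    def test_tabulated_value(self):
        z = stouffer_aggregate([0.05, 0.05, 0.05], [1, 1, 1])
        assert z == pytest.approx(3 * 1.959964 / math.sqrt(3), abs=1e-4)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            stouffer_aggregate([0.0, 0.5], [1, 1])


class TestSensitivity:
    def test_monotone_in_n_and_power(self):
        d1 = detectable_effect_size(50, 50, 0.05, 0.95)
        d2 = detectable_effect_size(100, 100, 0.05, 0.95)
        d3 = detectable_effect_size(50, 50, 0.05, 0.80)
        assert d2 < d1
        assert d3 < d1

    def test_power_at_zero_effect_is_alpha(self):
        df = 149 + 115 - 2
        tcrit = sps.t.isf(0.025, df)
        assert 2 * sps.t.sf(tcrit, df) == pytest.approx(0.05)

    def test_monte_carlo_power_at_returned_d(self):
        d = detectable_effect_size(149, 115, 0.05, 0.95)
        rng = np.random.default_rng(17)
        n_sim = 20_000
        x = rng.standard_normal((n_sim, 149)) + d
        y = rng.standard_normal((n_sim, 115))
        n1, n2 = 149, 115
        sp2 = ((n1 - 1) * x.var(axis=1, ddof=1) + (n2 - 1) * y.var(axis=1, ddof=1)) / (
            n1 + n2 - 2
        )
        t = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        tcrit = sps.t.isf(0.025, n1 + n2 - 2)
        assert np.mean(np.abs(t) > tcrit) == pytest.approx(0.95, abs=0.01)


class TestResamplingFdr:
    def test_all_ones_stay_ones(self):
        rng = np.random.default_rng(0)
        adj = resampling_fdr(np.ones(20), rng.uniform(size=(200, 20)))
        assert np.all(adj == 1.0)

    def test_adjusted_monotone_in_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        adj = resampling_fdr(p, rng.uniform(size=(300, 50)))
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_clear_signals_survive_correction(self):
        rng = np.random.default_rng(2)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            p = np.concatenate([np.full(5, 1e-6), rng.uniform(size=95)])
            adj = resampling_fdr(p, rng.uniform(size=(500, 100)))
            assert np.all(adj[:5] < 0.05)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            resampling_fdr(np.ones(3), np.ones((10, 4)))


class TestMatchControls:
    def test_matched_sample_sizes_and_datasets(self):
        cohort = generate_cohort(80, 200, {"CBP": 80}, seed=21)
        # confine the subgroup to datasets that have healthy pools
        rng = np.random.default_rng(0)
        pain = cohort["group"] == "pain"
        cohort.loc[pain, "dataset"] = rng.choice([1, 3], size=int(pain.sum()))
        sub_ids = cohort.loc[cohort["diagnosis"] == "CBP", "subject_id"]
        matched = match_controls(cohort, sub_ids, seed=1)
        assert len(matched) == 80
        m = cohort[cohort["subject_id"].isin(matched)]
        assert (m["group"] == "healthy").all()
        want = cohort[cohort["subject_id"].isin(sub_ids)]["dataset"].value_counts()
        got = m["dataset"].value_counts()
        assert want.to_dict() == got.to_dict()

    def test_infeasible_dataset_counts_are_reallocated(self):
        # the emulated study has no healthy participants in dataset 2, so a
        # subgroup drawn partly from dataset 2 is matched by reallocating the
        # deficit to datasets with spare healthy capacity
        cohort = generate_cohort(40, 120, {"CBP": 40}, seed=22)
        assert (cohort.loc[cohort["group"] == "healthy", "dataset"] != 2).all()
        sub_ids = cohort.loc[cohort["diagnosis"] == "CBP", "subject_id"]
        assert (cohort[cohort["subject_id"].isin(sub_ids)]["dataset"] == 2).any()
        matched = match_controls(cohort, sub_ids, seed=2)
        assert len(matched) == len(sub_ids)

    def test_null_populations_match_quickly(self):
        # same generating distribution: acceptance should take few draws
        iters = []
        for seed in range(50):
            cohort = generate_cohort(30, 60, {"other": 30}, seed=seed)
            cohort["dataset"] = 1  # one pool: pure null-population matching
            sub_ids = cohort.loc[cohort["group"] == "pain", "subject_id"]
            n_datasets = 1
            n_draws = [0]
            rng_cls = np.random.default_rng

            # count draws through a wrapping generator (one choice per dataset
            # per iteration)
            class Counting:
                def __init__(self, s):
                    self._g = rng_cls(s)

                def choice(self, *a, **k):
                    n_draws[0] += 1
                    return self._g.choice(*a, **k)

            import specurve.stats as ss

            orig = np.random.default_rng
            np.random.default_rng = lambda s: Counting(s)
            try:
                match_controls(cohort, sub_ids, seed=seed)
                iters.append(n_draws[0] / n_datasets)
            except MatchingFailureError:
                # an unlucky pool draw can be genuinely unmatchable; it
                # counts as a very slow seed for the median
                iters.append(np.inf)
            finally:
                np.random.default_rng = orig
        assert np.median(iters) <= 5

    def test_disjoint_age_supports_fail(self):
        cohort = generate_cohort(20, 40, {"other": 20}, seed=3)
        cohort["dataset"] = 1
        cohort.loc[cohort["group"] == "pain", "age"] = np.arange(20, 40)
        cohort.loc[cohort["group"] == "healthy", "age"] = np.arange(60, 100)
        sub_ids = cohort.loc[cohort["group"] == "pain", "subject_id"]
        # oracle: the age BF is enormous for any draw from the healthy pool
        assert bf_ttest_from_t(
            two_sample_test(
                cohort.loc[cohort["group"] == "pain", "age"],
                cohort.loc[cohort["group"] == "healthy", "age"].iloc[:20],
            )[0], 20, 20,
        ) > 1e6
        with pytest.raises(MatchingFailureError):
            match_controls(cohort, sub_ids, seed=4, max_iter=30)
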