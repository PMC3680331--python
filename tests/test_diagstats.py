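"""Diagnostic-accuracy and reproducibility statistics."""

import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from cardiofract import (
    bland_altman,
    exact_ci_proportion,
    evaluate_marker,
    fleiss_kappa,
    hanley_auc,
    icc_single,
    youden_threshold,
)


def all_pairs_auc(cases, controls):
    wins = ties = 0
    for x in cases:
        for y in controls:
            wins += x > y
            ties += x == y
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


class TestHanleyAUC:
    def test_perfect_separation(self):
        auc, se = hanley_auc([10, 11, 12], [1, 2, 3])
        assert auc == 1.0
        assert se == 0.0

    def test_identical_multisets_half(self):
        auc, _ = hanley_auc([1, 2, 3], [1, 2, 3])
        assert auc == pytest.approx(0.5)

    def test_toy_matches_all_pairs_oracle(self, rng):
        cases = rng.normal(1, 1, 5)
        controls = rng.normal(0, 1, 5)
        auc, _ = hanley_auc(cases, controls)
        assert auc == pytest.approx(all_pairs_auc(cases, controls), abs=1e-12)

    def test_rank_sum_equivalence_random_instances(self, rng):
        for _ in range(20):
            cases = np.round(rng.normal(1, 1, rng.integers(3, 30)), 1)
            controls = np.round(rng.normal(0, 1, rng.integers(3, 30)), 1)
            auc, _ = hanley_auc(cases, controls)
            u = sps.mannwhitneyu(cases, controls, alternative="two-sided").statistic
            assert auc == pytest.approx(u / (len(cases) * len(controls)), abs=1e-12)

    def test_hanley_se_formula(self):
        auc, se = hanley_auc([3, 4, 5, 6], [1, 2, 3, 4])
        a = auc
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        var = (a * (1 - a) + 3 * (q1 - a * a) + 3 * (q2 - a * a)) / 16
        assert se == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            hanley_auc([], [1.0])


class TestYoudenThreshold:
    def test_disjoint_supports(self):
        scores = [1.0, 1.1, 1.2, 2.0, 2.1, 2.2]
        labels = [0, 0, 0, 1, 1, 1]
        res = youden_threshold(scores, labels)
        assert res.j == pytest.approx(1.0)
        assert 1.2 < res.youden_threshold < 2.0
        assert res.auc == 1.0

    def test_matches_exhaustive_oracle(self, rng):
        scores = np.round(rng.normal(0, 1, 8), 2)
        labels = rng.integers(0, 2, 8)
        while labels.min() == labels.max():
            labels = rng.integers(0, 2, 8)
        res = youden_threshold(scores, labels)
        cases, controls = scores[labels == 1], scores[labels == 0]
        best_j = -np.inf
        for c in np.concatenate([scores - 1e-6, scores + 1e-6]):
            j = np.mean(cases >= c) + np.mean(controls < c) - 1
            best_j = max(best_j, j)
        assert res.j == pytest.approx(best_j, abs=1e-9)
        # returned threshold is never beaten by any tested candidate
        j_at = np.mean(cases >= res.youden_threshold) + np.mean(
            controls < res.youden_threshold
        ) - 1
        assert j_at == pytest.approx(res.j)

    def test_all_scores_equal_zero_j(self):
        res = youden_threshold([5.0] * 6, [0, 1, 0, 1, 0, 1])
        assert res.j == pytest.approx(0.0)

    def test_tie_broken_toward_specificity(self):
        # J = 0.5 both at c ~ 0.5 (sens 1, spec 0.5) and c ~ 2.5
        # (sens 0.5, spec 1); the higher-specificity threshold wins
        res = youden_threshold([0.0, 1.0, 2.0, 3.0], [0, 1, 0, 1])
        assert res.youden_threshold > 2.0
        assert res.spec_at_c == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold([1, 2, 3], [1, 1, 1])


class TestExactCI:
    @pytest.mark.parametrize(
        "x,n,lower_rounds_to", [(30, 30, 88), (105, 105, 97)]
    )
    def test_boundary_lower_bounds(self, x, n, lower_rounds_to):
        lo, hi = exact_ci_proportion(x, n)
        assert hi == 100.0
        assert round(lo) == lower_rounds_to

    def test_zero_of_one_closed_form(self):
        lo, hi = exact_ci_proportion(0, 1)
        assert lo == 0.0
        # upper bound solves (1-p)^1 = alpha/2 -> p = 0.975
        assert hi == pytest.approx(97.5)

    def test_matches_statsmodels_beta_method(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 60))
            x = int(rng.integers(0, n + 1))
            lo, hi = exact_ci_proportion(x, n)
            ref_lo, ref_hi = proportion_confint(x, n, method="beta")
            assert lo == pytest.approx(100 * np.nan_to_num(ref_lo), abs=1e-9)
            assert hi == pytest.approx(100 * (ref_hi if np.isfinite(ref_hi) else 1.0), abs=1e-9)

    def test_coverage_at_least_nominal(self, rng):
        p, n, reps = 0.7, 20, 2000
        draws = rng.binomial(n, p, reps)
        covered = 0
        for x in np.unique(draws):
            lo, hi = exact_ci_proportion(int(x), n)
            covered += ((draws == x).sum() if lo <= 100 * p <= hi else 0)
        assert covered / reps >= 0.95

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            exact_ci_proportion(5, 4)

    def test_cis_contain_point_estimates(self):
        res = evaluate_marker([1, 2, 3, 4], [0, 0, 1, 1], threshold=2.5)
        for name, value in (
            ("sensitivity", res.sensitivity),
            ("specificity", res.specificity),
            ("ppv", res.ppv),
            ("npv", res.npv),
        ):
            lo, hi = res.ci_95[name]
            assert lo <= value <= hi


class TestBlandAltman:
    def test_identical_pairs(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0.0 and res.rc == 0.0 and res.cov_pct == 0.0

    def test_repeatability_coefficient_hand_computed(self):
        # differences {0.1, 0.1}: RC = 1.96 sqrt(0.02/1) ~ 0.277
        res = bland_altman([1.1, 2.1], [1.0, 2.0])
        assert res.rc == pytest.approx(1.96 * np.sqrt(0.02), abs=1e-9)
        assert res.rc == pytest.approx(0.277, abs=5e-4)

    def test_matches_direct_formula_oracle(self, rng):
        a = rng.normal(10, 1, 30)
        b = a + rng.normal(0, 0.2, 30)
        res = bland_altman(a, b)
        d = a - b
        assert res.bias == pytest.approx(d.mean(), abs=1e-12)
        sd = d.std(ddof=1)
        assert res.loa_95[0] == pytest.approx(d.mean() - 1.96 * sd, abs=1e-12)
        assert res.loa_95[1] == pytest.approx(d.mean() + 1.96 * sd, abs=1e-12)
        assert res.rc == pytest.approx(1.96 * np.sqrt((d**2).sum() / 29), abs=1e-12)
        assert res.cov_pct == pytest.approx(
            100 * sd / np.concatenate([a, b]).mean(), abs=1e-12
        )
        assert res.rc >= 0 and res.cov_pct >= 0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])


class TestICC:
    def test_perfect_agreement(self, rng):
        col = rng.normal(0, 1, 30)
        icc, _ = icc_single(np.c_[col, col])
        assert icc == pytest.approx(1.0)

    def test_dominant_noise_destroys_agreement(self, rng):
        a = rng.normal(0, 1, 200)
        b = a + rng.normal(0, 5, 200)  # noise sd >> between-subject sd
        icc, _ = icc_single(np.c_[a, b])
        assert icc < 0.3

    def test_analytic_variance_ratio(self, rng):
        subj = rng.normal(0, 1, 500)
        a = subj + rng.normal(0, 0.5, 500)
        b = subj + rng.normal(0, 0.5, 500)
        icc, (lo, hi) = icc_single(np.c_[a, b])
        assert icc == pytest.approx(1.0 / 1.25, abs=0.05)  # sb2/(sb2+se2)
        assert lo <= icc <= hi

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, np.nan], [2.0, 2.0]])
        with pytest.raises(ValueError):
            icc_single(m)


class TestFleissKappa:
    def test_perfect_agreement(self, rng):
        ratings = np.repeat(rng.integers(0, 2, (40, 1)), 3, axis=1)
        kappa, _ = fleiss_kappa(ratings)
        assert kappa == pytest.approx(1.0)

    def test_random_ratings_near_zero(self, rng):
        ratings = rng.integers(0, 2, (500, 3))
        kappa, (lo, hi) = fleiss_kappa(ratings)
        assert abs(kappa) < 0.1
        assert lo <= kappa <= hi

    def test_three_rater_toy_table_matches_hand_computation(self):
        ratings = np.array(
            [[0, 0, 1], [1, 1, 1], [0, 0, 0], [1, 0, 1], [0, 1, 1]]
        )
        n, m = ratings.shape
        table = np.stack([(ratings == c).sum(1) for c in (0, 1)], axis=1)
        p_i = ((table**2).sum(1) - m) / (m * (m - 1))
        p_bar = p_i.mean()
        p_j = table.sum(0) / (n * m)
        p_e = (p_j**2).sum()
        expected = (p_bar - p_e) / (1 - p_e)
        kappa, _ = fleiss_kappa(ratings)
        assert kappa == pytest.approx(expected, abs=1e-12)

    def test_single_category_rejected(self):
        with pytest.raises(ValueError, match="single category"):
            fleiss_kappa(np.ones((10, 3), dtype=int))
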