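"""Statistical battery: oracles for every operation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fmdwi.stats import (
    StatsConfig,
    bh_fdr,
    combine_markers,
    partial_correlation,
    pool_summaries,
    roc_analysis,
    roi_mean,
    run_group_analysis,
    ttest_from_summary,
    two_sample_ttest,
    youden_threshold,
)
from fmdwi.synthetic_data import default_group_specs, generate_cohort, _subjects_dataframe


# --- independent oracles -------------------------------------------------

def auc_pair_counting(scores, labels):
    """Mann–Whitney concordant-pair fraction, ½ credit per tie."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def youden_exhaustive(scores, labels, higher=True):
    """Brute-force search over every candidate threshold."""
    s = scores if higher else -scores
    distinct = np.sort(np.unique(s))
    candidates = [-np.inf, np.inf] + list((distinct[:-1] + distinct[1:]) / 2)
    best = (-np.inf, None)
    for thr in sorted(candidates):
        pred = s >= thr
        sens = pred[labels == 1].mean()
        spec = (~pred)[labels == 0].mean()
        J = sens + spec - 1
        if J > best[0] + 1e-12:
            best = (J, thr)
    return best


def bh_stepup(p):
    """Literal BH step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


class TestRoiMean:
    def test_uniform_and_two_voxel(self):
        arr = np.array([[[1.0, 2.0], [5.0, 5.0]]])
        mask = np.array([[[True, True], [False, False]]])
        assert roi_mean(arr, mask) == 1.5
        assert roi_mean(np.full((2, 2, 2), 3.0), np.ones((2, 2, 2), bool)) == 3.0

    def test_nonfinite_excluded(self):
        arr = np.array([[[1.0, np.nan]]])
        assert roi_mean(arr, np.ones((1, 1, 2), bool)) == 1.0

    def test_empty_mask_raises_all_nan_gives_nan(self):
        with pytest.raises(ValueError):
            roi_mean(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool))
        assert math.isnan(roi_mean(np.full((1, 1, 1), np.nan), np.ones((1, 1, 1), bool)))


class TestTTests:
    def test_hand_computed_pooled_example(self):
        res = two_sample_ttest([1, 2, 3], [2, 3, 4], variant="pooled")
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == 4

    def test_identical_groups(self):
        res = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_zero_variance_equal_means_convention(self):
        res = two_sample_ttest([2.0, 2.0], [2.0, 2.0])
        assert res.p == 1.0

    def test_summary_matches_raw(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, rng.integers(3, 12))
            y = rng.normal(0.5, 2, rng.integers(3, 12))
            for variant in ("pooled", "welch"):
                raw = two_sample_ttest(x, y, variant)
                summ = ttest_from_summary(
                    x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y), variant
                )
                assert summ.statistic == pytest.approx(raw.statistic, rel=1e-10)
                assert summ.p == pytest.approx(raw.p, rel=1e-10)

    def test_summary_example(self):
        res = ttest_from_summary(1, 1, 3, 2, 1, 3, "pooled")
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)

    def test_pooling_identity_exact(self, rng):
        m, sd, n = pool_summaries(1.563, 0.030, 12, 1.531, 0.045, 12)
        assert m == pytest.approx(1.547, abs=1e-12)
        for _ in range(20):
            x = rng.normal(0, 1, 9)
            y = rng.normal(1, 2, 5)
            pm, psd, pn = pool_summaries(x.mean(), x.std(ddof=1), 9, y.mean(), y.std(ddof=1), 5)
            z = np.concatenate([x, y])
            assert pm == pytest.approx(z.mean(), rel=1e-12)
            assert psd == pytest.approx(z.std(ddof=1), rel=1e-10)
            assert pn == 14

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1.0], [1.0, 2.0])


class TestROC:
    def test_perfect_separation(self):
        roc = roc_analysis(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1]))
        assert roc.auc == 1.0
        assert roc.youden == 1.0 and roc.sensitivity == 1.0 and roc.specificity == 1.0

    def test_all_tied_scores(self):
        roc = roc_analysis(np.ones(6), np.array([0, 0, 0, 1, 1, 1]))
        assert roc.auc == 0.5

    def test_pair_counting_example(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        assert roc_analysis(scores, labels).auc == pytest.approx(0.75)

    def test_orientation_flips_inverted_marker(self):
        roc = roc_analysis(np.array([4, 3, 2, 1.0]), np.array([0, 0, 1, 1]))
        assert roc.auc == 1.0 and not roc.higher_is_positive

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(0, 1, 30)
        labels = (rng.random(30) < 0.5).astype(int)
        labels[:2] = [0, 1]
        roc = roc_analysis(scores, labels)
        assert roc.fpr[0] == 0 and roc.tpr[0] == 0
        assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.integers(0, 8), min_size=4, max_size=14), st.data())
    def test_auc_equals_mann_whitney(self, raw, data):
        scores = np.array(raw, float)
        labels = np.array(data.draw(st.lists(st.integers(0, 1), min_size=len(raw), max_size=len(raw))))
        if labels.sum() in (0, len(labels)):
            labels[0], labels[-1] = 0, 1
        expected = auc_pair_counting(scores, labels)
        roc = roc_analysis(scores, labels)
        assert roc.auc == pytest.approx(max(expected, 1 - expected), rel=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis(np.array([1.0, 2.0]), np.array([1, 1]))


class TestYouden:
    def test_interleaved_example_tie_breaks_low(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([0, 1, 0, 1])
        thr, sens, spec = youden_threshold(scores, labels)
        assert sens + spec - 1 == pytest.approx(0.5)
        assert thr == pytest.approx(1.5)

    def test_matches_exhaustive_search_on_random_instances(self, rng):
        for _ in range(100):
            n = rng.integers(4, 16)
            scores = np.round(rng.normal(0, 1, n), 1)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            thr, sens, spec = youden_threshold(scores, labels)
            J_best, thr_best = youden_exhaustive(scores, labels)
            assert sens + spec - 1 == pytest.approx(J_best, abs=1e-12)
            assert thr == pytest.approx(thr_best) or math.isinf(thr) == math.isinf(thr_best)


class TestCombineMarkers:
    def test_single_feature_preserves_auc(self, rng):
        x = rng.normal(0, 1, 30)
        y = (rng.random(30) < 0.5).astype(int)
        y[:2] = [0, 1]
        assert roc_analysis(combine_markers(x, y), y).auc == pytest.approx(
            roc_analysis(x, y).auc, rel=1e-10
        )

    def test_one_perfectly_separating_feature(self, rng):
        y = np.repeat([0, 1], 6)
        X = np.column_stack([np.where(y, 5.0, 0.0) + rng.normal(0, 0.1, 12), rng.normal(0, 1, 12)])
        scores = combine_markers(X, y)
        assert roc_analysis(scores, y).auc == 1.0

    def test_gaussian_two_feature_auc_matches_closed_form(self, rng):
        """For equal-covariance Gaussian classes the optimal linear rule has
        AUC = Φ(√(δᵀΣ⁻¹δ)/√2); the logistic combination should approach it."""
        from scipy.stats import norm

        delta = np.array([0.8, 0.5])
        cov = np.array([[1.0, 0.3], [0.3, 1.0]])
        n = 5000
        X0 = rng.multivariate_normal([0, 0], cov, n)
        X1 = rng.multivariate_normal(delta, cov, n)
        X = np.vstack([X0, X1])
        y = np.repeat([0, 1], n)
        auc = roc_analysis(combine_markers(X, y), y).auc
        expected = norm.cdf(math.sqrt(delta @ np.linalg.solve(cov, delta)) / math.sqrt(2))
        assert auc == pytest.approx(expected, abs=0.02)


class TestPartialCorrelation:
    def test_identical_variables(self, rng):
        x = rng.normal(0, 1, 20)
        z = rng.normal(0, 1, 20)
        res = partial_correlation(x, x, z)
        assert res.r == pytest.approx(1.0)

    def test_no_covariates_reduces_to_pearson(self, rng):
        from scipy.stats import pearsonr

        x, y = rng.normal(0, 1, 25), rng.normal(0, 1, 25)
        res = partial_correlation(x, y)
        r_ref, p_ref = pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-9)

    def test_single_covariate_closed_form_identity(self, rng):
        for _ in range(100):
            n = rng.integers(8, 30)
            z = rng.normal(0, 1, n)
            x = 0.5 * z + rng.normal(0, 1, n)
            y = -0.3 * z + rng.normal(0, 1, n)
            r_xy = np.corrcoef(x, y)[0, 1]
            r_xz = np.corrcoef(x, z)[0, 1]
            r_yz = np.corrcoef(y, z)[0, 1]
            expected = (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))
            assert partial_correlation(x, y, z).r == pytest.approx(expected, abs=1e-10)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = pd.DataFrame(
            {"x": rng.normal(0, 1, 40), "y": rng.normal(0, 1, 40), "z": rng.normal(0, 1, 40)}
        )
        df["y"] += 0.4 * df["x"] + 0.2 * df["z"]
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z")
        res = partial_correlation(df["x"], df["y"], df[["z"]])
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref[pcol].iloc[0]), rel=1e-6)

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            partial_correlation([1, 2, 3], [1, 2, 3], [[1], [2], [3]])


class TestFDR:
    def test_single_p_passthrough(self):
        np.testing.assert_allclose(bh_fdr([0.04]), [0.04])

    def test_stepup_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_bruteforce_on_random_sets(self, rng):
        for _ in range(100):
            p = rng.random(rng.integers(1, 25))
            np.testing.assert_allclose(bh_fdr(p), bh_stepup(p), rtol=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_sorted_inputs_give_monotone_q(self, ps):
        q = bh_fdr(np.sort(ps))
        assert np.all(np.diff(q) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


@pytest.fixture(scope="module")
def cohort_df():
    subs = generate_cohort(seed=42, with_phantoms=False)
    return _subjects_dataframe(subs)


class TestRunGroupAnalysis:
    def test_report_structure(self, cohort_df):
        rep = run_group_analysis(cohort_df)
        assert rep["n_subjects"] == 35
        assert len(rep["comparisons"]) == 2 * 2 * 4
        assert len(rep["roc"]) == 2 * 2 * 4
        assert len(rep["correlations"]) == 2 * 4 * 2
        assert all("q" in row for row in rep["correlations"])

    def test_missing_columns_reported(self, cohort_df):
        with pytest.raises(ValueError, match="alpha_left"):
            run_group_analysis(cohort_df.drop(columns=["alpha_left"]))

    def test_subject_order_invariance(self, cohort_df):
        rep1 = run_group_analysis(cohort_df)
        shuffled = cohort_df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        rep2 = run_group_analysis(shuffled)
        for section in ("comparisons", "roc", "correlations"):
            assert rep1[section] == rep2[section]

    def test_combined_markers_not_worse_than_alpha_alone(self, cohort_df):
        rep = run_group_analysis(cohort_df)
        roc = {(r["contrast"], r["roi"], r["marker"]): r["auc"] for r in rep["roc"]}
        for roi in ("left", "right"):
            key = ("AD_vs_controls", roi)
            assert roc[(*key, "alpha+adc")] >= roc[(*key, "alpha")] - 0.02
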