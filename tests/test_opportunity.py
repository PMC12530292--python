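import numpy as np
import pandas as pd
import pytest

from trophitv.opportunity import (
    SurveyTable,
    cohort_split,
    cv,
    habitat_summary,
    ln1p_transform,
    mean_bray_curtis,
    sample_metrics,
    standardise_by_permutation,
    validate_survey,
)


class TestSampleMetrics:
    def test_closed_form(self):
        richness, h = sample_metrics(np.array([3, 1, 0]))
        assert richness == 2
        assert h == pytest.approx(-(0.75 * np.log(0.75) + 0.25 * np.log(0.25)), abs=1e-12)
        assert h == pytest.approx(0.5623, abs=1e-4)

    def test_empty_sample(self):
        assert sample_metrics(np.zeros(4)) == (0, 0.0)

    def test_matches_brute_force_on_random_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            counts = rng.poisson(2, size=8)
            richness, h = sample_metrics(counts)
            assert richness == sum(1 for c in counts if c > 0)
            total = counts.sum()
            expected = -sum(
                (c / total) * np.log(c / total) for c in counts if c > 0
            ) if total else 0.0
            assert h == pytest.approx(expected, abs=1e-12)


class TestCV:
    def test_constant_vector_is_zero(self):
        assert cv(np.array([3.0, 3.0, 3.0])) == 0.0

    def test_hand_computation(self):
        assert cv(np.array([2.0, 4.0])) == pytest.approx(np.sqrt(2) / 3 * 100, abs=1e-10)
        assert cv(np.array([2.0, 4.0])) == pytest.approx(47.14, abs=0.01)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(1, 5, 20)
        assert cv(7.3 * x) == pytest.approx(cv(x), abs=1e-10)

    def test_zero_mean_flagged_as_nan(self):
        assert np.isnan(cv(np.array([-1.0, 1.0])))

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            cv(np.array([1.0]))


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        assert mean_bray_curtis(np.array([[1, 2], [1, 2]])) == 0.0

    def test_disjoint_samples_one(self):
        assert mean_bray_curtis(np.array([[3, 0], [0, 5]])) == 1.0

    def test_hand_computation(self):
        assert mean_bray_curtis(np.array([[1, 1], [0, 2]])) == pytest.approx(0.5)

    def test_empty_pairs_skipped(self):
        x = np.array([[0, 0], [0, 0], [1, 1]])
        # only the two pairs involving the non-empty sample are defined
        assert mean_bray_curtis(x) == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.poisson(2, size=(8, 5)).astype(float)
        vals = []
        for i in range(8):
            for j in range(i + 1, 8):
                denom = (x[i] + x[j]).sum()
                if denom > 0:
                    vals.append(np.abs(x[i] - x[j]).sum() / denom)
        assert mean_bray_curtis(x) == pytest.approx(np.mean(vals), abs=1e-12)


class TestCohortSplit:
    def _counts(self, rows):
        return pd.DataFrame(
            rows, columns=["campaign_id", "point_id", "taxon_id", "size_class", "count"]
        )

    def test_total_and_large_split(self):
        counts = self._counts(
            [
                ("c1", "p1", "Baetis", "small", 1),
                ("c1", "p1", "Baetis", "large", 2),
                ("c1", "p2", "Baetis", "small", 3),
            ]
        )
        out = cohort_split(counts)
        assert out.loc["p1", "MeanBae"] == 3
        assert out.loc["p1", "MeanBae5sup"] == 2
        assert out.loc["p2", "MeanBae5sup"] == 0

    def test_missing_size_class_counts_in_total_only(self):
        counts = self._counts([("c1", "p1", "Heptageniidae", "", 4)])
        out = cohort_split(counts)
        assert out.loc["p1", "MeanHep"] == 4
        assert out.loc["p1", "MeanHep5sup"] == 0


class TestLn1p:
    def test_closed_forms_and_monotonicity(self):
        assert ln1p_transform(np.array([0.0]))[0] == 0.0
        assert ln1p_transform(np.array([np.e - 1]))[0] == pytest.approx(1.0)
        x = np.sort(np.random.default_rng(0).uniform(0, 50, 20))
        assert (np.diff(ln1p_transform(x)) >= 0).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ln1p_transform(np.array([-0.5]))


class TestPermutationStandardisation:
    def _points(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"density": rng.poisson(5, n).astype(float)})

    def test_full_subsample_equals_plain_estimator(self):
        pts = self._points(45)
        est = lambda df: df["density"].mean()
        assert standardise_by_permutation(pts, est, n_sub=45, iters=3, seed=0) == est(pts)

    def test_linear_statistic_is_unbiased(self):
        pts = self._points(90, seed=1)
        est = lambda df: df["density"].mean()
        iters = 400
        val = standardise_by_permutation(pts, est, n_sub=45, iters=iters, seed=2)
        full = est(pts)
        # subsample means are unbiased for the full mean; allow 3 SE of MC error
        se = pts["density"].std(ddof=1) / np.sqrt(45) / np.sqrt(iters)
        assert abs(val - full) < 3 * se

    def test_set_richness_rarefaction_is_monotone(self):
        rng = np.random.default_rng(3)
        pts = pd.DataFrame(rng.poisson(0.3, size=(90, 12)), columns=[f"t{j}" for j in range(12)])
        total_richness = lambda df: float((df.sum(axis=0) > 0).sum())
        sub = standardise_by_permutation(pts, total_richness, n_sub=45, iters=100, seed=4)
        assert sub <= total_richness(pts)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="fewer than n_sub"):
            standardise_by_permutation(self._points(10), lambda df: 0.0, n_sub=45)


class TestHabitatSummary:
    def _habitat(self, depths):
        n = len(depths)
        return pd.DataFrame(
            {
                "campaign_id": ["c1"] * n,
                "point_id": [f"p{i}" for i in range(n)],
                "substrate_richness": [3] * n,
                "substrate_max": [5] * n,
                "velocity": [40.0] * n,
                "depth": depths,
                "clogging": [2] * n,
                "vegetal": [1] * n,
            }
        )

    def test_uniform_habitat_gives_zero_cvs(self):
        out = habitat_summary(self._habitat([20.0, 20.0])).iloc[0]
        assert all(out[f"cv-{code}"] == 0 for code in ["SbV", "SbG", "vs3", "Dep", "Clg", "VgD"])

    def test_depth_hand_computation(self):
        out = habitat_summary(self._habitat([10.0, 30.0])).iloc[0]
        assert out["Dep"] == pytest.approx(20.0)
        assert out["cv-Dep"] == pytest.approx(np.sqrt(200) / 20 * 100, abs=1e-10)
        assert out["cv-Dep"] == pytest.approx(70.71, abs=0.01)

    def test_ordinal_range_violations_reported(self):
        hab = self._habitat([20.0, 25.0])
        hab.loc[0, "clogging"] = 6
        counts = pd.DataFrame(
            [("c1", "p0", "Baetis", "", 1)],
            columns=["campaign_id", "point_id", "taxon_id", "size_class", "count"],
        )
        problems = validate_survey(SurveyTable(counts=counts, habitat=hab))
        assert any("clogging" in p for p in problems)


class TestCampaignOpportunity:
    def test_point_order_invariance_and_exact_effort(self, small_study):
        import trophitv as tv

        survey = small_study.survey
        base = tv.campaign_opportunity(survey, n_sub=45, iters=50, seed=9)
        shuffled = SurveyTable(
            counts=survey.counts.sample(frac=1, random_state=0),
            habitat=survey.habitat.sample(frac=1, random_state=0),
        )
        again = tv.campaign_opportunity(shuffled, n_sub=45, iters=50, seed=9)
        pd.testing.assert_frame_equal(
            base.sort_values("campaign_id").reset_index(drop=True),
            again.sort_values("campaign_id").reset_index(drop=True),
        )
        assert base["BrayCurtis"].between(0, 1).all()
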