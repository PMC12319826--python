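import numpy as np
import pytest
from scipy import stats as sps

from soundbrain.evaluation import (EvalTable, compare_models, make_null_model,
                                   percent_diff_map, r2_scores,
                                   signed_rank_test, transfer_matrix)
from soundbrain.protocols import by_stepup, enumerate_signed_rank_p


class TestR2:
    def test_perfect_prediction(self):
        y = np.random.default_rng(0).standard_normal((10, 3))
        np.testing.assert_allclose(r2_scores(y, y), 1.0)

    def test_column_mean_prediction_scores_zero(self):
        y = np.random.default_rng(1).standard_normal((12, 2))
        pred = np.tile(y.mean(axis=0), (12, 1))
        np.testing.assert_allclose(r2_scores(pred, y), 0.0, atol=1e-12)

    def test_worked_example(self):
        actual = np.array([[1.0], [2.0], [3.0]])
        pred = np.array([[1.0], [2.0], [4.0]])
        assert r2_scores(pred, actual)[0] == pytest.approx(0.5)

    def test_constant_column_is_nan_with_warning(self):
        actual = np.ones((5, 1))
        with pytest.warns(RuntimeWarning, match="constant"):
            out = r2_scores(np.zeros((5, 1)), actual)
        assert np.isnan(out[0])

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        pred = rng.standard_normal((20, 4))
        actual = rng.standard_normal((20, 4))
        np.testing.assert_allclose(r2_scores(pred, actual),
                                   r2_scores(pred + 3.0, actual + 3.0))

    def test_equals_squared_pearson_for_ls_fit(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(30)
        y = 2 * x + rng.standard_normal(30)
        slope, intercept, r, *_ = sps.linregress(x, y)
        fit = (slope * x + intercept)[:, None]
        assert r2_scores(fit, y[:, None])[0] == pytest.approx(r ** 2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            r2_scores(np.zeros((3, 1)), np.zeros((4, 1)))


class TestSignedRank:
    @pytest.mark.parametrize("n", range(3, 13))
    def test_exact_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(3):
            d = np.round(rng.standard_normal(n), 1)  # ties likely
            if not d.any():
                continue
            assert signed_rank_test(d, method="exact") == pytest.approx(
                enumerate_signed_rank_p(d), abs=1e-12)

    def test_five_positive_differences(self):
        assert signed_rank_test(np.ones(5)) == pytest.approx(0.0625)

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(5)
        d = rng.standard_normal(10)
        expected = sps.wilcoxon(d, method="exact").pvalue
        assert signed_rank_test(d, method="exact") == pytest.approx(expected)

    def test_matches_scipy_approximation_large_n(self):
        rng = np.random.default_rng(6)
        d = rng.standard_normal(60) + 0.3
        expected = sps.wilcoxon(d, method="approx", correction=False).pvalue
        assert signed_rank_test(d) == pytest.approx(expected, rel=1e-6)

    def test_zeros_dropped(self):
        d = np.array([0.0, 0.0, 1.0, -2.0, 3.0])
        assert signed_rank_test(d) == signed_rank_test(d[2:])

    def test_all_zero_differences_give_p_one(self):
        assert signed_rank_test(np.zeros(8)) == 1.0


class TestBenjaminiYekutieli:
    def test_worked_example(self):
        q = by_stepup(np.array([0.01, 0.02, 0.5]))
        np.testing.assert_allclose(q, [0.055, 0.055, 0.9167], atol=5e-5)

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = rng.uniform(size=int(rng.integers(2, 50)))
            _, q_sm, _, _ = multipletests(p, method="fdr_by")
            np.testing.assert_allclose(by_stepup(p), q_sm, atol=1e-12)

    def test_more_conservative_than_bh(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.uniform(size=15)
            _, q_bh, _, _ = multipletests(p, method="fdr_bh")
            assert (by_stepup(p) >= q_bh - 1e-12).all()


class TestCompareModels:
    def _tables(self, rng, n_runs=8, n_targets=6, shift=0.0):
        base = rng.standard_normal((n_runs, n_targets)) * 0.1
        a = EvalTable(base + shift, model_id="a")
        b = EvalTable(base * 1.0, model_id="b")
        return a, b

    def test_identical_tables_not_significant(self):
        a, b = self._tables(np.random.default_rng(0))
        res = compare_models(a, a)
        assert not res.significant.any()
        assert (res.p == 1.0).all()

    def test_q_at_least_p_and_flags_consistent(self):
        rng = np.random.default_rng(1)
        a, b = self._tables(rng)
        a.r2 = a.r2 + rng.uniform(0, 0.05, a.r2.shape)
        res = compare_models(a, b)
        assert (res.q >= res.p - 1e-12).all()
        np.testing.assert_array_equal(res.significant, res.q < 0.05)

    def test_strong_consistent_gain_detected(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal((30, 5)) * 0.05
        a = EvalTable(base + 0.1)
        b = EvalTable(base)
        res = compare_models(a, b)
        assert res.significant.all()
        assert (res.median_diff > 0).all()

    def test_run_mismatch_rejected(self):
        a = EvalTable(np.zeros((4, 2)))
        b = EvalTable(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            compare_models(a, b)


class TestPercentDiffMap:
    def _stats(self, significant):
        from soundbrain.evaluation import StatResult
        m = len(significant)
        return StatResult(p=np.zeros(m), q=np.zeros(m),
                          significant=np.array(significant),
                          median_diff=np.zeros(m))

    def test_arithmetic_and_masking(self):
        aligned = EvalTable(np.full((4, 3), 0.10))
        baseline = EvalTable(np.full((4, 3), 0.08))
        aligned.r2[:, 1] = 0.04        # below display threshold
        res = percent_diff_map(aligned, baseline,
                               self._stats([True, True, False]))
        assert res[0] == pytest.approx(25.0)
        assert np.isnan(res[1])        # |mean r2| < 0.05
        assert np.isnan(res[2])        # not significant

    def test_zero_baseline_reported_undefined(self):
        aligned = EvalTable(np.full((4, 1), 0.2))
        baseline = EvalTable(np.zeros((4, 1)))
        with pytest.warns(RuntimeWarning, match="zero baseline"):
            res = percent_diff_map(aligned, baseline, self._stats([True]))
        assert np.isnan(res[0])


class TestNullModel:
    def test_same_seed_identical_predictions(self, short_clip):
        a = make_null_model(4, kernel_size=2, seed=3)
        b = make_null_model(4, kernel_size=2, seed=3)
        np.testing.assert_array_equal(a.predict(short_clip, 1),
                                      b.predict(short_clip, 1))

    def test_different_seeds_differ(self, short_clip):
        a = make_null_model(4, kernel_size=2, seed=3)
        b = make_null_model(4, kernel_size=2, seed=4)
        assert not np.allclose(a.predict(short_clip, 1),
                               b.predict(short_clip, 1))


class TestTransferMatrix:
    def test_planted_subject_specific_mappings(self, monkeypatch):
        """With each subject's BOLD generated by its own kernels, the exact
        planted models give a diagonal-dominant transfer matrix with zero
        matched difference."""
        from soundbrain.encoding import EncodingModel, build_head
        from soundbrain.synthetic import SyntheticSpec, make_dataset

        spec = SyntheticSpec(n_subjects=2, seasons=1, episodes_per_season=1,
                             n_tr=20, n_targets=4, kernel_size=2,
                             noise_sigma=0.3, shared_mapping=False,
                             plant_rank=12, seed=13)
        ds = make_dataset(spec)
        models = {}
        for subject, kern in ds.kernels.items():
            head = build_head(1024, 4, 2)
            head.kernels.data[...] = kern
            head.bias.data[...] = ds.biases[subject]
            models[subject] = EncodingModel(ds.backbone, head)
        res = transfer_matrix(models, ds.runs_by_subject(), w=20)
        mat = res.max_r2.to_numpy()
        assert mat.shape == (2, 2)
        assert np.argmax(mat[0]) == 0 and np.argmax(mat[1]) == 1
        np.testing.assert_allclose(np.diag(res.diff_vs_matched.to_numpy()),
                                   0.0, atol=1e-12)

    def test_target_space_mismatch_rejected(self):
        from soundbrain.encoding import EncodingModel, build_head
        from soundbrain.backbone import build_backbone

        net = build_backbone(seed=0)
        models = {"a": EncodingModel(net, build_head(1024, 3, 1)),
                  "b": EncodingModel(net, build_head(1024, 4, 1))}
        with pytest.raises(ValueError, match="target space"):
            transfer_matrix(models, {"a": [], "b": []}, w=10)
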