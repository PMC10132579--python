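"""Metrics, split/fold plans and the cross-validated protocol mechanics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import novgmdeep as ng
from novgmdeep.evaluation import evaluate_on_test, make_folds, make_split


class TestPcc:
    def test_perfect_positive(self):
        assert ng.pcc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert ng.pcc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_definitional_recomputation(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        direct = np.cov(x, y, bias=True)[0, 1] / (x.std() * y.std())
        assert ng.pcc(x, y) == pytest.approx(direct, abs=1e-12)

    def test_constant_vector_is_an_error_not_zero(self):
        with pytest.raises(ValueError, match="constant"):
            ng.pcc([1.0, 1.0, 1.0], [1, 2, 3])


class TestMae:
    def test_perfect_prediction(self):
        assert ng.mae([1, 2], [1, 2]) == 0.0

    def test_hand_arithmetic(self):
        assert ng.mae([1, 3], [2, 5]) == pytest.approx(1.5)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        p, o = rng.normal(size=20), rng.normal(size=20)
        assert ng.mae(p, o) == pytest.approx(ng.mae(o, p), abs=1e-15)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ng.mae([1, 2], [1, 2, 3])


class TestSdPopulation:
    def test_constant_vector(self):
        assert ng.sd_population([4, 4, 4]) == 0.0

    def test_two_point_hand_value(self):
        # mean 2, deviations +/-1, divisor N=2
        assert ng.sd_population([1, 3]) == pytest.approx(1.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        assert ng.sd_population(x + 100) == pytest.approx(
            ng.sd_population(x), abs=1e-9
        )

    def test_population_divisor_not_sample(self):
        x = np.array([1.0, 2.0, 3.0, 6.0])
        assert ng.sd_population(x) == pytest.approx(np.std(x), abs=1e-12)
        assert ng.sd_population(x) != pytest.approx(np.std(x, ddof=1), abs=1e-6)


class TestMakeSplit:
    def test_80_20_counts(self):
        plan = make_split(10, ratio=0.8, seed=0)
        assert len(plan.train_indices) == 8 and len(plan.test_indices) == 2

    def test_round_half_up_boundary(self):
        # 0.8 * 13 = 10.4 -> 10; 0.8 * 15 = 12.0 -> 12; 0.5 boundary rounds up
        assert len(make_split(13, seed=0).train_indices) == 10
        assert len(make_split(15, seed=0).train_indices) == 12

    def test_deterministic(self):
        assert make_split(50, seed=9) == make_split(50, seed=9)

    @given(n=st.integers(min_value=5, max_value=200), seed=st.integers(0, 100))
    def test_partition_property(self, n, seed):
        plan = make_split(n, seed=seed)
        train, test = set(plan.train_indices), set(plan.test_indices)
        assert train | test == set(range(n))
        assert not train & test

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError):
            make_split(10, ratio=1.2, seed=0)


class TestMakeFolds:
    def test_balanced_9_in_3(self):
        plan = make_folds(range(9), k=3, seed=0)
        assert sorted(len(f) for f in plan.folds) == [3, 3, 3]

    def test_imbalance_at_most_one(self):
        plan = make_folds(range(10), k=3, seed=0)
        assert sorted(len(f) for f in plan.folds) == [3, 3, 4]

    @given(n=st.integers(min_value=6, max_value=100), seed=st.integers(0, 20))
    def test_partition_property(self, n, seed):
        idx = list(range(100, 100 + n))
        plan = make_folds(idx, k=3, seed=seed)
        flat = [i for f in plan.folds for i in f]
        assert sorted(flat) == sorted(idx)
        sizes = [len(f) for f in plan.folds]
        assert max(sizes) - min(sizes) <= 1

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            make_folds(range(10), k=1, seed=0)


class _StubModel:
    """Deterministic predictor for protocol tests (no training involved)."""

    def __init__(self, offset, best_val_mae):
        self.offset = offset
        self.best_val_mae = best_val_mae

    def predict(self, X):
        base = np.asarray(X).reshape(len(X), -1).sum(axis=1).astype(float)
        return base + self.offset


class TestEvaluateOnTest:
    def _test_data(self, n=10):
        rng = np.random.default_rng(0)
        X = rng.random((n, 4, 2))
        y = X.reshape(n, -1).sum(axis=1) + rng.normal(0, 0.1, n)
        return X, y

    def test_identical_models_mean_equals_single(self):
        X, y = self._test_data()
        models = [_StubModel(0.0, 1.0)] * 3
        rep = evaluate_on_test(models, (X, y))
        assert rep.mean_pcc == pytest.approx(rep.per_fold_pcc[0])

    def test_mean_is_arithmetic_mean_and_order_invariant(self):
        X, y = self._test_data()
        models = [_StubModel(o, v) for o, v in [(0, 3.0), (5, 1.0), (-2, 2.0)]]
        rep1 = evaluate_on_test(models, (X, y))
        rep2 = evaluate_on_test(models[::-1], (X, y))
        assert rep1.mean_pcc == pytest.approx(np.mean(rep1.per_fold_pcc))
        assert rep1.mean_pcc == pytest.approx(rep2.mean_pcc)

    def test_mae_comes_from_best_validation_model(self):
        X, y = self._test_data()
        # best-val model has offset 5 -> its test MAE ~ 5
        models = [_StubModel(0.0, 3.0), _StubModel(5.0, 1.0), _StubModel(-2.0, 2.0)]
        rep = evaluate_on_test(models, (X, y))
        assert rep.best_model_index == 1
        assert rep.test_mae == pytest.approx(
            np.abs(models[1].predict(X) - y).mean()
        )

    def test_perfect_models(self):
        X, y = self._test_data()

        class Perfect:
            best_val_mae = 0.0

            def predict(self, Xq):
                return y

        rep = evaluate_on_test([Perfect()] * 3, (X, y))
        assert rep.mean_pcc == pytest.approx(1.0)
        assert rep.test_mae == 0.0
        assert rep.test_sd_abs_err == 0.0

    def test_tiny_test_set_rejected(self):
        X, y = self._test_data(2)
        with pytest.raises(ValueError, match="at least 3"):
            evaluate_on_test([_StubModel(0, 1)], (X, y))


class TestCrossValidateProtocol:
    def test_three_models_with_disjoint_validation(self, small_tensor):
        tensor, y = small_tensor
        spec = ng.ModelSpec(conv_layers=((4, 3),), max_epochs=2, l1=0, l2=0)
        folds = make_folds(range(tensor.shape[0]), k=3, seed=0)
        models = ng.cross_validate(tensor.data, y, spec, folds, seed=0)
        assert len(models) == 3
        for a, b in [(0, 1), (0, 2), (1, 2)]:
            assert not set(folds.folds[a]) & set(folds.folds[b])

    def test_constant_phenotype_validation_mae_near_zero(self, small_tensor):
        tensor, _ = small_tensor
        y = np.full(tensor.shape[0], 3.0)
        spec = ng.ModelSpec(conv_layers=((4, 3),), dropout_rate=0.0,
                            max_epochs=150, l1=0, l2=0)
        folds = make_folds(range(tensor.shape[0]), k=3, seed=0)
        models = ng.cross_validate(tensor.data, y, spec, folds, seed=0)
        assert all(m.best_val_mae < 0.3 for m in models)

    def test_no_leak_between_test_and_training_folds(self, small_tensor):
        tensor, y = small_tensor
        n = tensor.shape[0]
        split = make_split(n, seed=1)
        folds = make_folds(split.train_indices, k=3, seed=1)
        test = set(split.test_indices)
        for f in range(3):
            training = {
                i for g, fold in enumerate(folds.folds) if g != f for i in fold
            }
            assert not training & test
            assert not set(folds.folds[f]) & test

    def test_run_protocol_end_to_end_small(self, small_tensor):
        tensor, y = small_tensor
        spec = ng.ModelSpec(conv_layers=((4, 3),), max_epochs=3, l1=0, l2=0)
        report, models = ng.run_protocol(
            tensor.data, y, spec, split_seed=0, fold_seed=0, model_seed=0
        )
        assert len(models) == 3
        assert len(report.per_fold_pcc) == 3
        assert report.mean_pcc == pytest.approx(np.mean(report.per_fold_pcc))
        assert report.test_mae >= 0 and report.test_sd_abs_err >= 0
        assert report.manifest["n_accessions"] == tensor.shape[0]
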