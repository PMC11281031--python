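import numpy as np
import pytest

from mixtox import featurize as fz
from mixtox.models import (
    HNNConfig,
    HNNModel,
    PredictionSet,
    Task,
    consensus_regression,
    ensemble_predict,
    train_baselines,
    train_hnn,
    predict_baseline,
)

FAST = dict(epochs=5, conv_filters=(8, 16), desc_dense=(16, 8),
            smiles_dense=16, merge_units=16)


def _tiny_data(task=Task.BINARY, n=40, seed=3):
    rng = np.random.default_rng(seed)
    strings = ["".join(rng.choice(list("CNO=#()"), size=12)) for _ in range(n)]
    vocab = fz.build_vocabulary(strings)
    tensor = fz.one_hot_encode(strings, vocab)
    X = rng.standard_normal((n, 6))
    if task is Task.BINARY:
        y = (X[:, 0] > 0).astype(int)
    elif task is Task.MULTICLASS:
        y = rng.integers(0, 5, size=n)
    else:
        y = X[:, 0] + 0.1 * rng.standard_normal(n)
    return tensor, X, y


class TestHNNContracts:
    def test_sigmoid_head_in_unit_interval(self):
        tensor, X, y = _tiny_data(Task.BINARY)
        model = train_hnn(tensor, X, y, HNNConfig(task=Task.BINARY, seed=0, **FAST))
        ps = model.predict(tensor, X)
        assert np.all((ps.scores >= 0) & (ps.scores <= 1))
        assert np.array_equal(ps.labels, (ps.scores >= 0.5).astype(int))

    def test_softmax_head_rows_sum_to_one(self):
        tensor, X, y = _tiny_data(Task.MULTICLASS)
        model = train_hnn(
            tensor, X, y, HNNConfig(task=Task.MULTICLASS, seed=0, **FAST)
        )
        ps = model.predict(tensor, X)
        assert ps.scores.shape == (40, 5)
        assert np.allclose(ps.scores.sum(axis=1), 1.0, atol=1e-6)
        assert np.array_equal(ps.labels, ps.scores.argmax(axis=1))

    def test_regression_head_finite(self):
        tensor, X, y = _tiny_data(Task.REGRESSION)
        model = train_hnn(
            tensor, X, y, HNNConfig(task=Task.REGRESSION, seed=0, **FAST)
        )
        assert np.all(np.isfinite(model.predict(tensor, X).scores))

    def test_constant_labels_learned(self):
        tensor, X, _ = _tiny_data(Task.BINARY)
        y = np.ones(40, dtype=int)
        model = train_hnn(
            tensor, X, y, HNNConfig(task=Task.BINARY, epochs=20, seed=0)
        )
        assert np.array_equal(model.predict(tensor, X).labels, y)

    def test_seed_determinism(self):
        tensor, X, y = _tiny_data(Task.BINARY)
        cfg = HNNConfig(task=Task.BINARY, seed=42, **FAST)
        s1 = train_hnn(tensor, X, y, cfg).predict(tensor, X).scores
        s2 = train_hnn(tensor, X, y, cfg).predict(tensor, X).scores
        assert np.array_equal(s1, s2)

    def test_shape_mismatch_rejected(self):
        tensor, X, y = _tiny_data(Task.BINARY)
        with pytest.raises(ValueError, match="mismatch"):
            train_hnn(tensor, X[:10], y, HNNConfig(task=Task.BINARY, **FAST))

    def test_non_finite_descriptors_rejected(self):
        tensor, X, y = _tiny_data(Task.BINARY)
        X = X.copy()
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            train_hnn(tensor, X, y, HNNConfig(task=Task.BINARY, **FAST))

    def test_vocabulary_mismatch_rejected_at_predict(self):
        tensor, X, y = _tiny_data(Task.BINARY)
        model = train_hnn(tensor, X, y, HNNConfig(task=Task.BINARY, **FAST))
        other_vocab = fz.build_vocabulary(["XYZW"])
        alien = fz.one_hot_encode(
            ["XYZW" * 3], other_vocab, L=tensor.L
        )
        with pytest.raises(ValueError):
            model.predict(alien, X[:1])

    def test_save_load_round_trip(self, tmp_path):
        tensor, X, y = _tiny_data(Task.BINARY)
        model = train_hnn(tensor, X, y, HNNConfig(task=Task.BINARY, seed=9, **FAST))
        model.save(tmp_path / "bundle")
        back = HNNModel.load(tmp_path / "bundle")
        assert np.array_equal(
            model.predict(tensor, X).scores, back.predict(tensor, X).scores
        )


class TestBaselines:
    def test_classifier_suite_names_and_determinism(self):
        _, X, y = _tiny_data(Task.BINARY)
        m1 = train_baselines(Task.BINARY, X, y, seed=7)
        m2 = train_baselines(Task.BINARY, X, y, seed=7)
        assert set(m1) == {"rf", "bagging", "adaboost"}
        p1 = predict_baseline(m1["rf"], Task.BINARY, X)
        p2 = predict_baseline(m2["rf"], Task.BINARY, X)
        assert np.array_equal(p1.scores, p2.scores)

    def test_regressor_suite_names(self):
        _, X, y = _tiny_data(Task.REGRESSION)
        models = train_baselines(Task.REGRESSION, X, y, seed=0)
        assert set(models) == {"rf", "svr", "gb", "kr", "dt", "kn"}
        for m in models.values():
            assert np.all(np.isfinite(predict_baseline(m, Task.REGRESSION, X).scores))


def _binary_ps(ids, scores):
    scores = np.asarray(scores, float)
    return PredictionSet(
        mixture_ids=np.asarray(ids), task=Task.BINARY,
        scores=scores, labels=(scores >= 0.5).astype(int),
    )


def _reg_ps(ids, scores):
    scores = np.asarray(scores, float)
    return PredictionSet(
        mixture_ids=np.asarray(ids), task=Task.REGRESSION,
        scores=scores, labels=scores,
    )


class TestEnsemble:
    ids = ["m1", "m2", "m3"]

    def test_soft_vote_mean_and_boundary(self):
        members = [
            _binary_ps(self.ids, s)
            for s in ([1, 0.9, 0], [1, 0.9, 0], [1, 0.1, 0], [1, 0.1, 0])
        ]
        out = ensemble_predict(members)
        assert np.allclose(out.scores, [1.0, 0.5, 0.0])
        assert out.labels.tolist() == [1, 1, 0]  # 0.5 labelled toxic

    def test_hard_vote(self):
        members = [
            _binary_ps(self.ids, s)
            for s in ([0.6, 0.6, 0.4], [0.7, 0.4, 0.4],
                      [0.8, 0.3, 0.4], [0.9, 0.2, 0.6])
        ]
        out = ensemble_predict(members, voting="hard")
        assert out.labels.tolist() == [1, 0, 0]

    def test_misaligned_ids_rejected(self):
        members = [_binary_ps(self.ids, [1, 1, 1]) for _ in range(3)]
        members.append(_binary_ps(["x", "y", "z"], [1, 1, 1]))
        with pytest.raises(ValueError, match="aligned"):
            ensemble_predict(members)

    def test_requires_four_members(self):
        with pytest.raises(ValueError, match="4"):
            ensemble_predict([_binary_ps(self.ids, [1, 1, 1])] * 3)


class TestConsensus:
    ids = ["m1", "m2"]

    def test_identical_predictions_pass_through(self):
        members = [_reg_ps(self.ids, [2.5, -1.0])] * 7
        assert np.allclose(consensus_regression(members).scores, [2.5, -1.0])

    def test_mean_and_permutation_invariance(self):
        vals = [[0, 0], [0, 0], [0, 0], [0, 0], [0, 0], [0, 0], [7, 14]]
        members = [_reg_ps(self.ids, v) for v in vals]
        out = consensus_regression(members)
        assert np.allclose(out.scores, [1.0, 2.0])
        shuffled = consensus_regression(members[::-1])
        assert np.allclose(out.scores, shuffled.scores)

    def test_matches_brute_force_mean_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((7, 5))
        members = [_reg_ps([f"i{k}" for k in range(5)], v) for v in vals]
        oracle = [sum(vals[m][i] for m in range(7)) / 7 for i in range(5)]
        assert np.allclose(consensus_regression(members).scores, oracle)

    def test_requires_seven_members(self):
        with pytest.raises(ValueError, match="7"):
            consensus_regression([_reg_ps(self.ids, [0, 0])] * 6)
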