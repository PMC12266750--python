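import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from polygero.chem import fingerprints_for
from polygero.mtl import (
    HeadConfig,
    MaskedMultiTaskClassifier,
    MultiTaskDataset,
    grid_search,
    load_model,
    masked_multitask_loss,
    mean_task_auc,
    save_model,
    split_by_butina,
    train_head,
)


def separable_problem(n=500, d=10, n_tasks=4, missing=0.3, seed=0):
    """Labels are thresholded linear functions of the descriptors."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    W = rng.normal(size=(d, n_tasks))
    Y = (X @ W > 0).astype(float)
    Y[rng.random((n, n_tasks)) < missing] = np.nan
    return X, Y


def task_aucs(Y_true, probs):
    out = []
    for t in range(Y_true.shape[1]):
        obs = ~np.isnan(Y_true[:, t])
        if obs.sum() and len(np.unique(Y_true[obs, t])) == 2:
            out.append(roc_auc_score(Y_true[obs, t], probs[obs, t]))
    return out


class TestMaskedLoss:
    def test_all_missing_flagged_zero(self):
        loss, degenerate = masked_multitask_loss(np.full((3, 2), 0.5),
                                                 np.full((3, 2), np.nan))
        assert loss == 0.0 and degenerate

    def test_perfect_confident_predictions_near_zero(self):
        labels = np.array([[1.0, 0.0], [0.0, 1.0]])
        loss, degenerate = masked_multitask_loss(labels, labels)
        assert not degenerate
        assert loss <= -math.log(1 - 1e-7) + 1e-12

    def test_two_observed_cells_hand_computed(self):
        # p=0.8 on a positive and p=0.4 on a negative; the other cells missing
        probs = np.array([[0.8, 0.123], [0.456, 0.4]])
        labels = np.array([[1.0, np.nan], [np.nan, 0.0]])
        loss, _ = masked_multitask_loss(probs, labels)
        assert loss == pytest.approx((-math.log(0.8) - math.log(0.6)) / 2)

    def test_masked_equals_unmasked_on_observed_subset(self, rng):
        """Exact algebraic identity between the masked loss and the plain
        mean BCE computed on only the observed cells."""
        for _ in range(20):
            probs = rng.uniform(0.01, 0.99, size=(15, 6))
            labels = rng.integers(0, 2, (15, 6)).astype(float)
            labels[rng.random((15, 6)) < 0.5] = np.nan
            if np.isnan(labels).all():
                continue
            masked, _ = masked_multitask_loss(probs, labels)
            obs = ~np.isnan(labels)
            p, y = probs[obs], labels[obs]
            unmasked = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
            assert masked == pytest.approx(unmasked, rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            masked_multitask_loss(np.zeros((2, 2)), np.zeros((3, 2)))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients of the masked loss through the skip-connected
        net agree with central finite differences."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(7, 4))
        Y = rng.integers(0, 2, (7, 3)).astype(float)
        Y[rng.random((7, 3)) < 0.3] = np.nan
        clf = MaskedMultiTaskClassifier(hidden_widths=(5, 4), seed=1)
        params = clf._init_params(4, 3, np.random.default_rng(1))

        def loss_at(params):
            probs, _ = clf._forward(X, params)
            return masked_multitask_loss(probs, Y)[0]

        probs, cache = clf._forward(X, params)
        grads = clf._backward(params, cache, probs, Y)
        eps = 1e-6
        for li, (W, b) in enumerate(params):
            for arr, g in ((W, grads[li][0]), (b, grads[li][1])):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in range(3):  # spot-check a few entries per tensor
                    idx = tuple(rng.integers(0, s) for s in arr.shape)
                    orig = arr[idx]
                    arr[idx] = orig + eps
                    up = loss_at(params)
                    arr[idx] = orig - eps
                    down = loss_at(params)
                    arr[idx] = orig
                    numeric = (up - down) / (2 * eps)
                    assert g[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7)


class TestTraining:
    def test_separable_tasks_reach_high_auc(self):
        X, Y = separable_problem(seed=3)
        clf = MaskedMultiTaskClassifier(epochs=150, seed=0).fit(X[:400], Y[:400])
        aucs = task_aucs(Y[400:], clf.predict_proba(X[400:]))
        assert len(aucs) == 4 and min(aucs) >= 0.9

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(4)
        aucs = []
        for seed in range(5):
            X, Y = separable_problem(seed=seed + 50)
            for t in range(Y.shape[1]):
                rng.shuffle(Y[:, t])
            clf = MaskedMultiTaskClassifier(epochs=100, seed=seed).fit(X[:400], Y[:400])
            aucs.extend(task_aucs(Y[400:], clf.predict_proba(X[400:])))
        assert 0.4 <= float(np.mean(aucs)) <= 0.6

    def test_zero_epochs_returns_initialization(self):
        X, Y = separable_problem(n=50, seed=5)
        clf = MaskedMultiTaskClassifier(epochs=0, seed=2).fit(X, Y)
        assert clf.training_log_ == []
        p1 = clf.predict_proba(X)
        p2 = clf.predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_training_reproducible_under_seed(self):
        X, Y = separable_problem(n=120, seed=6)
        p1 = MaskedMultiTaskClassifier(epochs=20, seed=7).fit(X, Y).predict_proba(X)
        p2 = MaskedMultiTaskClassifier(epochs=20, seed=7).fit(X, Y).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_descriptor_count_validated_at_predict(self):
        X, Y = separable_problem(n=60, seed=8)
        clf = MaskedMultiTaskClassifier(epochs=5, seed=0).fit(X, Y)
        with pytest.raises(ValueError, match="descriptor"):
            clf.predict_proba(X[:, :5])


def make_dataset(library, tasks=("drd2", "hrh1"), seed=0):
    rng = np.random.default_rng(seed)
    ids = [cid for cid, _ in library]
    desc = pd.DataFrame(rng.normal(size=(len(ids), 6)), index=ids,
                        columns=[f"d{i}" for i in range(6)])
    labels = pd.DataFrame(rng.integers(0, 2, (len(ids), len(tasks))).astype(float),
                          index=ids, columns=list(tasks))
    return MultiTaskDataset(desc, labels, dict(library))


class TestSplitByButina:
    def test_singletons_pack_to_exact_ratio(self):
        rng = np.random.default_rng(0)
        ids = [f"m{i}" for i in range(100)]
        from polygero.chem import Fingerprint
        fps = [Fingerprint(i, frozenset({10 * k + j for j in range(5)}))
               for k, i in enumerate(ids)]
        desc = pd.DataFrame(rng.normal(size=(100, 3)), index=ids)
        labels = pd.DataFrame(rng.integers(0, 2, (100, 2)).astype(float), index=ids)
        ds = MultiTaskDataset(desc, labels)
        split = split_by_butina(ds, fps, (0.8, 0.1, 0.1), 0.8, seed=1)
        counts = split.partition.value_counts()
        assert counts["train"] == 80 and counts["validation"] == 10 and counts["test"] == 10

    @pytest.mark.parametrize("seed", range(10))
    def test_cluster_integrity_across_seeds(self, toy_library, seed):
        ds = make_dataset(toy_library, seed=seed)
        fps = fingerprints_for(toy_library)
        split = split_by_butina(ds, fps, seed=seed)
        table = pd.DataFrame({"part": split.partition,
                              "cluster": split.butina_cluster_id})
        assert (table.groupby("cluster")["part"].nunique() == 1).all()

    def test_bad_ratio_rejected(self, toy_library):
        ds = make_dataset(toy_library)
        fps = fingerprints_for(toy_library)
        with pytest.raises(ValueError, match="ratio"):
            split_by_butina(ds, fps, (0.8, 0.3, 0.1))


class TestGridSearch:
    def test_single_config_returned(self, toy_library):
        ds = make_dataset(toy_library, seed=1)
        fps = fingerprints_for(toy_library)
        split = split_by_butina(ds, fps, seed=0)
        cfg = HeadConfig(epochs=5)
        best, model, board = grid_search(ds, split, [cfg])
        assert best is cfg and len(board) == 1

    def test_signal_config_beats_null(self):
        """A config trained long enough to learn a separable problem must
        outrank a zero-epoch (untrained) one."""
        rng = np.random.default_rng(2)
        n = 200
        ids = [f"m{i}" for i in range(n)]
        X = rng.normal(size=(n, 5))
        W = rng.normal(size=(5, 2))
        desc = pd.DataFrame(X, index=ids, columns=[f"d{i}" for i in range(5)])
        labels = pd.DataFrame((X @ W > 0).astype(float), index=ids,
                              columns=["t1", "t2"])
        ds = MultiTaskDataset(desc, labels)
        from polygero.chem import Fingerprint
        fps = [Fingerprint(i, frozenset({3 * k, 3 * k + 1})) for k, i in enumerate(ids)]
        split = split_by_butina(ds, fps, seed=3)
        grid = [HeadConfig(epochs=0, seed=0), HeadConfig(epochs=100, seed=0)]
        best, _, board = grid_search(ds, split, grid)
        assert best.epochs == 100
        assert len(board) == len(grid)


def test_model_save_load_roundtrip(tmp_path):
    X, Y = separable_problem(n=80, seed=9)
    clf = MaskedMultiTaskClassifier(epochs=10, seed=0).fit(X, Y)
    path = tmp_path / "model.npz"
    save_model(clf, path, [f"d{i}" for i in range(10)], [f"t{i}" for i in range(4)])
    clf2, feats, tasks = load_model(path)
    assert feats == [f"d{i}" for i in range(10)] and tasks == [f"t{i}" for i in range(4)]
    assert np.array_equal(clf.predict_proba(X), clf2.predict_proba(X))
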