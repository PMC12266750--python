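"""Masked multi-task binding classifier on molecular descriptors.

A feed-forward network with DenseNet-like skip connections (every hidden
layer sees the concatenation of the input and all preceding hidden layers)
maps a descriptor vector to per-target binding probabilities. Training
minimizes a masked binary cross-entropy: cells with no measured activity are
excluded from the loss, which is how sparse multi-target bioactivity panels
are handled without imputation.

The network is implemented directly in numpy (forward pass, manual
backpropagation, Adam); at desk scale (hundreds to thousands of compounds,
tens of descriptors and tasks) this trains in seconds and is exactly
reproducible from its seed. Externally computed molecular embeddings can be
concatenated to the descriptors before ``fit``.

Scaffold-aware data splitting (:func:`split_by_butina`) assigns whole Butina
clusters to train/validation/test so near-duplicate structures never straddle
partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score

from .chem import Fingerprint, butina_cluster

logger = logging.getLogger(__name__)

EPS_CLIP = 1e-7


@dataclass
class MultiTaskDataset:
    """Descriptor features plus a ternary (1/0/NaN) compound x task label matrix."""

    descriptors: pd.DataFrame          # rows: compound ids, columns: descriptor names
    labels: pd.DataFrame               # rows: compound ids, columns: task names; NaN = missing
    smiles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.descriptors.index.equals(self.labels.index):
            raise ValueError("descriptor and label rows must share the same compound index")
        vals = self.labels.to_numpy(dtype=float)
        observed = vals[~np.isnan(vals)]
        if not np.isin(observed, [0.0, 1.0]).all():
            raise ValueError("labels must be 0, 1 or NaN (missing)")
        if not np.isfinite(self.descriptors.to_numpy(dtype=float)).all():
            raise ValueError("descriptors contain non-finite values")

    @property
    def compound_ids(self) -> list[str]:
        return self.descriptors.index.tolist()

    @property
    def tasks(self) -> list[str]:
        return self.labels.columns.tolist()


@dataclass
class SplitAssignment:
    """Train/validation/test partition that keeps Butina clusters whole."""

    partition: pd.Series               # per-compound value in {train, validation, test}
    butina_cluster_id: pd.Series
    ratio: tuple[float, float, float]
    seed: int

    def ids(self, part: str) -> list[str]:
        return self.partition.index[self.partition == part].tolist()


def split_by_butina(
    dataset: MultiTaskDataset,
    fingerprints: Sequence[Fingerprint],
    ratio: tuple[float, float, float] = (0.8, 0.1, 0.1),
    cutoff: float = 0.8,
    seed: int = 0,
) -> SplitAssignment:
    """Scaffold-aware split: Butina clusters are assigned whole to partitions.

    Clusters are placed largest-first into whichever partition is furthest
    below its target compound count (random tie-break under ``seed``), so
    realized sizes track ``ratio`` as closely as cluster granularity allows.
    """
    if abs(sum(ratio) - 1.0) > 1e-9:
        raise ValueError(f"ratio must sum to 1, got {ratio}")
    ids = dataset.compound_ids
    if len(fingerprints) != len(ids):
        raise ValueError("one fingerprint per dataset compound required")
    if len(ids) < 10:
        logger.warning("dataset of %d compounds: 0.8/0.1/0.1 ratios are unrealizable", len(ids))
    assignment = butina_cluster(fingerprints, cutoff)
    rng = np.random.default_rng(seed)
    clusters: dict[int, list[int]] = {}
    for i, c in enumerate(assignment):
        clusters.setdefault(c, []).append(i)
    # largest first; random tie-break among equal sizes
    order = sorted(clusters, key=lambda c: (-len(clusters[c]), rng.random()))
    parts = ("train", "validation", "test")
    targets = np.array(ratio) * len(ids)
    counts = np.zeros(3)
    part_of = np.empty(len(ids), dtype=object)
    for c in order:
        deficit = targets - counts
        k = int(np.argmax(deficit + rng.random(3) * 1e-9))
        for i in clusters[c]:
            part_of[i] = parts[k]
        counts[k] += len(clusters[c])
    giant = max(len(v) for v in clusters.values())
    if giant > targets[0]:
        logger.warning("a Butina cluster of %d compounds exceeds the train target", giant)
    return SplitAssignment(
        partition=pd.Series(part_of, index=ids, name="partition"),
        butina_cluster_id=pd.Series(assignment, index=ids, name="butina_cluster_id"),
        ratio=tuple(ratio),
        seed=seed,
    )


def masked_multitask_loss(probabilities: np.ndarray, labels: np.ndarray) -> tuple[float, bool]:
    """Mean binary cross-entropy over observed (non-NaN) label cells.

    Returns ``(loss, degenerate)``; a matrix with zero observed cells yields
    loss 0.0 with the degenerate flag set. Probabilities are clipped to
    ``[EPS_CLIP, 1 - EPS_CLIP]`` before the logs.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if probabilities.shape != labels.shape:
        raise ValueError(
            f"shape mismatch: probabilities {probabilities.shape} vs labels {labels.shape}")
    mask = ~np.isnan(labels)
    if not mask.any():
        return 0.0, True
    p = np.clip(probabilities[mask], EPS_CLIP, 1 - EPS_CLIP)
    y = labels[mask]
    loss = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
    return float(loss), False


@dataclass
class HeadConfig:
    """Architecture and optimization settings for the skip-connected head."""

    hidden_widths: tuple[int, ...] = (64, 64)
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_widths) < 1:
            raise ValueError("need at least one hidden layer")
        if self.epochs < 0 or self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("invalid optimization settings")


class MaskedMultiTaskClassifier(BaseEstimator):
    """Skip-connected feed-forward multi-task classifier (scikit-learn style).

    ``fit(X, Y)`` takes a descriptor matrix and a float label matrix with
    NaN marking unmeasured cells; ``predict_proba`` returns per-task binding
    probabilities. Hidden layer k receives ``concat(x, h_1, ..., h_{k-1})``
    (DenseNet-like wiring); the output layer sees the input and every hidden
    layer. Standardization of inputs is learned on the training rows.
    """

    def __init__(self, hidden_widths: tuple[int, ...] = (64, 64),
                 learning_rate: float = 1e-3, epochs: int = 200,
                 batch_size: int = 128, seed: int = 0):
        self.hidden_widths = hidden_widths
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    # --- network internals -------------------------------------------------
    def _init_params(self, n_in: int, n_tasks: int, rng: np.random.Generator):
        widths = list(self.hidden_widths)
        params = []
        fan_in = n_in
        for w in widths:
            scale = np.sqrt(2.0 / fan_in)
            params.append([rng.normal(0, scale, size=(fan_in, w)), np.zeros(w)])
            fan_in += w  # dense wiring: next layer sees everything so far
        scale = np.sqrt(1.0 / fan_in)
        params.append([rng.normal(0, scale, size=(fan_in, n_tasks)), np.zeros(n_tasks)])
        return params

    def _forward(self, X: np.ndarray, params):
        acts = [X]
        cache = []
        for W, b in params[:-1]:
            inp = np.concatenate(acts, axis=1)
            z = inp @ W + b
            h = np.maximum(z, 0.0)
            cache.append((inp, z))
            acts.append(h)
        W, b = params[-1]
        inp = np.concatenate(acts, axis=1)
        logits = inp @ W + b
        cache.append((inp, logits))
        return 1.0 / (1.0 + np.exp(-logits)), cache

    def _backward(self, params, cache, probs, labels):
        """Gradients of the masked mean BCE w.r.t. every weight and bias."""
        mask = ~np.isnan(labels)
        n_obs = mask.sum()
        grads = [[np.zeros_like(W), np.zeros_like(b)] for W, b in params]
        # d(loss)/d(logits): (p - y) / n_observed on observed cells, else 0
        dlogits = np.zeros_like(probs)
        dlogits[mask] = (probs[mask] - labels[mask]) / n_obs
        inp, _ = cache[-1]
        grads[-1][0] = inp.T @ dlogits
        grads[-1][1] = dlogits.sum(axis=0)
        dinp = dlogits @ params[-1][0].T   # gradient w.r.t. final concat input
        n_in = cache[0][0].shape[1]
        widths = [p[0].shape[1] for p in params[:-1]]
        # walk hidden layers backwards, splitting the concat gradient
        dh = [dinp[:, n_in + sum(widths[:k]): n_in + sum(widths[:k + 1])]
              for k in range(len(widths))]
        for k in range(len(widths) - 1, -1, -1):
            inp_k, z_k = cache[k]
            dz = dh[k] * (z_k > 0)
            grads[k][0] += inp_k.T @ dz
            grads[k][1] += dz.sum(axis=0)
            dinp_k = dz @ params[k][0].T
            for j in range(k):
                lo = n_in + sum(widths[:j])
                dh[j] = dh[j] + dinp_k[:, lo:lo + widths[j]]
        return grads

    # --- estimator API -----------------------------------------------------
    def fit(self, X, Y, validation: tuple | None = None):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y row counts differ")
        if not (~np.isnan(Y)).any():
            raise ValueError("no observed labels to train on")
        rng = np.random.default_rng(self.seed)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        Xs = (X - self.mean_) / self.scale_
        self.n_features_in_ = X.shape[1]
        self.n_tasks_ = Y.shape[1]
        params = self._init_params(X.shape[1], Y.shape[1], rng)
        m = [[np.zeros_like(W), np.zeros_like(b)] for W, b in params]
        v = [[np.zeros_like(W), np.zeros_like(b)] for W, b in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        self.training_log_ = []
        n = X.shape[0]
        for epoch in range(self.epochs):
            idx = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                batch = idx[start:start + self.batch_size]
                if not (~np.isnan(Y[batch])).any():
                    continue
                probs, cache = self._forward(Xs[batch], params)
                grads = self._backward(params, cache, probs, Y[batch])
                step += 1
                for p, g, mm, vv in zip(params, grads, m, v):
                    for t in range(2):
                        mm[t] = beta1 * mm[t] + (1 - beta1) * g[t]
                        vv[t] = beta2 * vv[t] + (1 - beta2) * g[t] ** 2
                        mhat = mm[t] / (1 - beta1 ** step)
                        vhat = vv[t] / (1 - beta2 ** step)
                        p[t] -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            probs, _ = self._forward(Xs, params)
            train_loss, _ = masked_multitask_loss(probs, Y)
            if np.isnan(train_loss):
                raise FloatingPointError(f"training diverged (NaN loss) at epoch {epoch}")
            entry = {"epoch": epoch, "train_loss": train_loss}
            if validation is not None:
                Xv, Yv = validation
                pv, _ = self._forward((np.asarray(Xv, float) - self.mean_) / self.scale_, params)
                entry["val_loss"] = masked_multitask_loss(pv, np.asarray(Yv, float))[0]
            self.training_log_.append(entry)
        self.params_ = params
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} descriptor columns, got {X.shape[1]}")
        probs, _ = self._forward((X - self.mean_) / self.scale_, self.params_)
        return probs

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


def train_head(dataset: MultiTaskDataset, split: SplitAssignment,
               config: HeadConfig) -> MaskedMultiTaskClassifier:
    """Train on the split's train rows, logging validation loss per epoch."""
    clf = MaskedMultiTaskClassifier(
        hidden_widths=tuple(config.hidden_widths),
        learning_rate=config.learning_rate, epochs=config.epochs,
        batch_size=config.batch_size, seed=config.seed)
    tr = split.ids("train")
    va = split.ids("validation")
    if not tr:
        raise ValueError("train partition is empty")
    X = dataset.descriptors.loc[tr].to_numpy(float)
    Y = dataset.labels.loc[tr].to_numpy(float)
    val = None
    if va:
        val = (dataset.descriptors.loc[va].to_numpy(float),
               dataset.labels.loc[va].to_numpy(float))
    return clf.fit(X, Y, validation=val)


def mean_task_auc(clf: MaskedMultiTaskClassifier, dataset: MultiTaskDataset,
                  ids: Sequence[str]) -> tuple[float, list[str]]:
    """Mean ROC-AUC over tasks on the given compounds.

    Tasks with a single observed class among ``ids`` cannot be scored and are
    excluded from the mean; their names are returned alongside.
    """
    X = dataset.descriptors.loc[list(ids)].to_numpy(float)
    Y = dataset.labels.loc[list(ids)].to_numpy(float)
    probs = clf.predict_proba(X)
    aucs, skipped = [], []
    for t, task in enumerate(dataset.tasks):
        obs = ~np.isnan(Y[:, t])
        y = Y[obs, t]
        if obs.sum() == 0 or len(np.unique(y)) < 2:
            skipped.append(task)
            continue
        aucs.append(roc_auc_score(y, probs[obs, t]))
    if not aucs:
        raise ValueError("every task is single-class on the selection partition")
    return float(np.mean(aucs)), skipped


def grid_search(dataset: MultiTaskDataset, split: SplitAssignment,
                grid: Iterable[HeadConfig],
                selection_partition: str = "validation"
                ) -> tuple[HeadConfig, MaskedMultiTaskClassifier, pd.DataFrame]:
    """Train every config and pick the best by mean-over-tasks ROC-AUC.

    Selection on the validation partition by default; ``"test"`` reproduces
    selection on the held-out test scores (documented as leaking information
    from the test set into model choice).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty grid")
    if selection_partition not in ("validation", "test"):
        raise ValueError("selection_partition must be 'validation' or 'test'")
    sel_ids = split.ids(selection_partition)
    rows, models = [], []
    for i, cfg in enumerate(grid):
        clf = train_head(dataset, split, cfg)
        auc, skipped = mean_task_auc(clf, dataset, sel_ids)
        models.append(clf)
        rows.append({"config_index": i, "hidden_widths": str(cfg.hidden_widths),
                     "learning_rate": cfg.learning_rate, "epochs": cfg.epochs,
                     "mean_auc": auc, "n_tasks_skipped": len(skipped)})
    leaderboard = pd.DataFrame(rows).sort_values(
        "mean_auc", ascending=False, kind="mergesort").reset_index(drop=True)
    best_i = int(leaderboard.iloc[0]["config_index"])
    return grid[best_i], models[best_i], leaderboard


def save_model(clf: MaskedMultiTaskClassifier, path, feature_names: Sequence[str],
               tasks: Sequence[str]) -> None:
    """Persist weights plus the descriptor list, task list and seed."""
    arrays = {}
    for i, (W, b) in enumerate(clf.params_):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez(
        path, n_layers=len(clf.params_), mean=clf.mean_, scale=clf.scale_,
        hidden_widths=np.array(clf.hidden_widths), seed=clf.seed,
        feature_names=np.array(list(feature_names)), tasks=np.array(list(tasks)),
        **arrays)


def load_model(path) -> tuple[MaskedMultiTaskClassifier, list[str], list[str]]:
    data = np.load(path, allow_pickle=False)
    clf = MaskedMultiTaskClassifier(
        hidden_widths=tuple(int(w) for w in data["hidden_widths"]),
        seed=int(data["seed"]))
    n_layers = int(data["n_layers"])
    clf.params_ = [[data[f"W{i}"], data[f"b{i}"]] for i in range(n_layers)]
    clf.mean_ = data["mean"]
    clf.scale_ = data["scale"]
    clf.n_features_in_ = clf.params_[0][0].shape[0]
    clf.n_tasks_ = clf.params_[-1][0].shape[1]
    return clf, [str(f) for f in data["feature_names"]], [str(t) for t in data["tasks"]]


def predict_binding(clf: MaskedMultiTaskClassifier, descriptors: pd.DataFrame,
                    feature_names: Sequence[str], tasks: Sequence[str]) -> pd.DataFrame:
    """Per-(compound, task) probabilities with descriptor-name validation."""
    missing = [c for c in feature_names if c not in descriptors.columns]
    if missing:
        raise ValueError(f"missing descriptor columns: {missing}")
    probs = clf.predict_proba(descriptors[list(feature_names)].to_numpy(float))
    return pd.DataFrame(probs, index=descriptors.index, columns=list(tasks))
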