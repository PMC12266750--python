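"""Polypharmacology rule models linking target-cluster activity to lifespan.

Three predictor classes are evaluated against binary lifespan labels (LS+/LS-):

* single-cluster — a compound is called LS+ if it is active on one chosen
  cluster;
* count-threshold — LS+ if its total number of active clusters reaches N;
* combination ("m in M") — LS+ if it is active on at least m of a specific
  set of M clusters.

Models are scored by precision, recall and the Matthews correlation
coefficient (MCC), which is robust to the strong class imbalance of lifespan
screens; combination rules are searched exhaustively over a candidate cluster
set and ranked by MCC.

Estimators follow the scikit-learn protocol (``fit`` / ``predict`` /
``get_params``); the module-level functions are thin wrappers over them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .types import EvalMetrics, LifespanLabels, RuleSpec, labels_to_series

logger = logging.getLogger(__name__)

RANKING_COLUMNS = [
    "model_class", "rule", "clusters", "m", "M",
    "tp", "fp", "tn", "fn", "precision", "recall", "mcc", "degenerate",
]


def _as_binary_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        df = X
    else:
        arr = np.asarray(X)
        df = pd.DataFrame(arr, columns=[f"c{j}" for j in range(arr.shape[1])])
    vals = df.to_numpy()
    if not np.isin(vals, [0, 1]).all():
        raise ValueError("activity matrix must be binary (0/1); "
                         "collapse ternary matrices with matrix_to_binary first")
    return df


def align_labels(X: pd.DataFrame, labels: LifespanLabels | pd.Series):
    """Restrict the matrix to labeled compounds, in label order.

    Every labeled compound must appear in the matrix; unlabeled compounds are
    excluded from evaluation.
    """
    y = labels_to_series(labels) if not isinstance(labels, pd.Series) else labels
    missing = y.index.difference(X.index)
    if len(missing) > 0:
        raise ValueError(
            f"{len(missing)} labeled compound(s) absent from the activity "
            f"matrix, e.g. {list(missing[:5])}"
        )
    return X.loc[y.index], y.astype(int)


def evaluate(predictions: Sequence[int] | np.ndarray, labels) -> EvalMetrics:
    """Confusion counts and precision/recall/MCC for binary predictions.

    Metrics with a zero denominator are reported as 0 with the
    ``degenerate`` flag set.
    """
    pred = np.asarray(predictions).astype(int)
    y = np.asarray(labels if not isinstance(labels, pd.Series) else labels.to_numpy()).astype(int)
    if pred.shape != y.shape:
        raise ValueError(f"length mismatch: {pred.shape} predictions vs {y.shape} labels")
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return EvalMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


class MInMRuleClassifier(ClassifierMixin, BaseEstimator):
    """Predict LS+ when a compound is active on >= ``min_active_m`` of
    ``clusters``. With a single cluster and m=1 this is the single-cluster
    predictor."""

    def __init__(self, clusters: Sequence[str] = (), min_active_m: int = 1):
        self.clusters = clusters
        self.min_active_m = min_active_m

    @property
    def rule(self) -> RuleSpec:
        return RuleSpec(tuple(self.clusters), self.min_active_m)

    def fit(self, X, y=None):
        df = _as_binary_frame(X)
        self.rule_ = self.rule  # validates m <= M
        unknown = [c for c in self.rule_.clusters if c not in df.columns]
        if unknown:
            raise ValueError(f"unknown cluster(s) in rule: {unknown}")
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X) -> np.ndarray:
        df = _as_binary_frame(X)
        rule = getattr(self, "rule_", self.rule)
        unknown = [c for c in rule.clusters if c not in df.columns]
        if unknown:
            raise ValueError(f"unknown cluster(s) in rule: {unknown}")
        counts = df[list(rule.clusters)].to_numpy().sum(axis=1)
        return (counts >= rule.min_active_m).astype(int)


class SingleClusterClassifier(MInMRuleClassifier):
    """Predict LS+ from activity on one cluster (degenerate 1-in-1 rule)."""

    def __init__(self, cluster: str = ""):
        self.cluster = cluster
        super().__init__()

    # keep sklearn get_params happy: expose only `cluster`
    def get_params(self, deep=True):
        return {"cluster": self.cluster}

    def set_params(self, **params):
        if "cluster" in params:
            self.cluster = params.pop("cluster")
        return self

    @property
    def rule(self) -> RuleSpec:
        return RuleSpec((self.cluster,), 1)


class CountThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Predict LS+ when the number of active clusters reaches ``n_threshold``.

    The comparison is inclusive (>= N) by default; ``strict=True`` switches to
    the literal strictly-greater reading.
    """

    def __init__(self, n_threshold: int = 2, strict: bool = False):
        self.n_threshold = n_threshold
        self.strict = strict

    def fit(self, X, y=None):
        if self.n_threshold < 1:
            raise ValueError("n_threshold must be >= 1")
        _as_binary_frame(X)
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X) -> np.ndarray:
        df = _as_binary_frame(X)
        sums = df.to_numpy().sum(axis=1)
        if self.strict:
            return (sums > self.n_threshold).astype(int)
        return (sums >= self.n_threshold).astype(int)


def predict_single(X, cluster: str) -> np.ndarray:
    return SingleClusterClassifier(cluster).fit(X).predict(X)


def predict_count(X, n_threshold: int, strict: bool = False) -> np.ndarray:
    return CountThresholdClassifier(n_threshold, strict=strict).fit(X).predict(X)


def predict_rule(X, rule: RuleSpec) -> np.ndarray:
    return MInMRuleClassifier(rule.clusters, rule.min_active_m).fit(X).predict(X)


@dataclass
class SearchSpace:
    """The combinatorial model space to enumerate.

    ``M_range`` is the inclusive range of combination sizes (default 2..5);
    ``m_policy`` is ``"all"`` (every 1 <= m <= M) or ``"exact"`` (the
    conjunction m = M only). ``count_threshold_range`` drives the
    count-predictor sweep (default 2..20).
    """

    candidate_clusters: Sequence[str] = field(default_factory=list)
    M_range: tuple[int, int] = (2, 5)
    m_policy: str = "all"
    count_threshold_range: tuple[int, int] = (2, 20)
    budget: int = 200_000

    def __post_init__(self) -> None:
        if self.M_range[0] > self.M_range[1] or self.M_range[0] < 1:
            raise ValueError(f"invalid M_range {self.M_range}")
        if self.m_policy not in ("all", "exact"):
            raise ValueError(f"m_policy must be 'all' or 'exact', got {self.m_policy!r}")

    def n_rules(self) -> int:
        g = len(self.candidate_clusters)
        total = 0
        for M in range(self.M_range[0], min(self.M_range[1], g) + 1):
            total += comb(g, M) * (M if self.m_policy == "all" else 1)
        return total


def _metrics_row(model_class: str, rule_desc: str, clusters: tuple[str, ...],
                 m: int, M: int, em: EvalMetrics) -> dict:
    return {
        "model_class": model_class, "rule": rule_desc, "clusters": clusters,
        "m": m, "M": M, "tp": em.tp, "fp": em.fp, "tn": em.tn, "fn": em.fn,
        "precision": em.precision, "recall": em.recall, "mcc": em.mcc,
        "degenerate": em.degenerate,
    }


def _rank(df: pd.DataFrame) -> pd.DataFrame:
    # MCC desc, precision desc, recall desc, then lexicographic cluster tuple
    # and ascending m for full determinism.
    df = df.copy()
    df["_key"] = df["clusters"]
    df = df.sort_values(
        by=["mcc", "precision", "recall", "_key", "m"],
        ascending=[False, False, False, True, True],
        kind="mergesort",
    ).drop(columns="_key")
    return df.reset_index(drop=True)


def evaluate_single_clusters(X, labels) -> pd.DataFrame:
    """Score every cluster as a single-cluster predictor; ranked by MCC."""
    df = _as_binary_frame(X)
    Xa, y = align_labels(df, labels)
    arr, yv = Xa.to_numpy(), y.to_numpy()
    rows = []
    for j, cluster in enumerate(Xa.columns):
        em = evaluate(arr[:, j], yv)
        rows.append(_metrics_row("single", f"1 in 1: {{{cluster}}}",
                                 (cluster,), 1, 1, em))
    return _rank(pd.DataFrame(rows, columns=RANKING_COLUMNS))


def evaluate_count_thresholds(X, labels,
                              n_range: tuple[int, int] = (2, 20),
                              strict: bool = False) -> pd.DataFrame:
    """Score the count predictor for every N in the inclusive range."""
    df = _as_binary_frame(X)
    Xa, y = align_labels(df, labels)
    sums = Xa.to_numpy().sum(axis=1)
    yv = y.to_numpy()
    rows = []
    for n in range(n_range[0], n_range[1] + 1):
        pred = (sums > n) if strict else (sums >= n)
        em = evaluate(pred.astype(int), yv)
        rows.append(_metrics_row("count", f"sum >= {n}" if not strict else f"sum > {n}",
                                 (), n, 0, em))
    return pd.DataFrame(rows, columns=RANKING_COLUMNS)


def search_combinations(X, labels, space: SearchSpace, force: bool = False) -> pd.DataFrame:
    """Exhaustively evaluate every "m in M" rule in the search space.

    Returns all rules ranked by MCC descending (ties: precision, recall,
    lexicographic cluster tuple). The frame doubles as the recall/precision
    scatter table for the combination model class.
    """
    df = _as_binary_frame(X)
    Xa, y = align_labels(df, labels)
    candidates = list(space.candidate_clusters)
    if not candidates:
        raise ValueError("candidate_clusters is empty")
    unknown = [c for c in candidates if c not in Xa.columns]
    if unknown:
        raise ValueError(f"candidate cluster(s) not in matrix: {unknown}")
    n_rules = space.n_rules()
    if n_rules > space.budget and not force:
        raise ValueError(
            f"search space holds {n_rules} rules, over the budget of "
            f"{space.budget}; prune candidate_clusters (e.g. via "
            f"select_gt_clusters) or pass force=True"
        )
    arr = Xa[candidates].to_numpy()
    yv = y.to_numpy()
    n_pos, n_tot = int(yv.sum()), len(yv)
    rows = []
    idx = range(len(candidates))
    for M in range(space.M_range[0], min(space.M_range[1], len(candidates)) + 1):
        for combo in combinations(idx, M):
            clusters = tuple(sorted(candidates[j] for j in combo))
            counts = arr[:, combo].sum(axis=1)
            ms = range(1, M + 1) if space.m_policy == "all" else (M,)
            for m in ms:
                pred = counts >= m
                tp = int(np.sum(pred & (yv == 1)))
                fp = int(pred.sum()) - tp
                fn = n_pos - tp
                tn = n_tot - tp - fp - fn
                em = EvalMetrics(tp=tp, fp=fp, tn=tn, fn=fn)
                rows.append(_metrics_row(
                    "combination", f"{m} in {M}: {{{', '.join(clusters)}}}",
                    clusters, m, M, em))
    return _rank(pd.DataFrame(rows, columns=RANKING_COLUMNS))


def select_gt_clusters(X, labels, k: int = 10, min_support: int = 3) -> list[str]:
    """Pick the geroprotector-target (GT) clusters.

    Clusters are ranked by single-cluster MCC; clusters with fewer than
    ``min_support`` active LS+ compounds are excluded; the top ``k`` survive.
    Fewer than ``k`` eligible clusters returns them all with a warning.
    """
    if k < 1 or min_support < 1:
        raise ValueError("k and min_support must be >= 1")
    df = _as_binary_frame(X)
    Xa, y = align_labels(df, labels)
    support = Xa.loc[y == 1].sum(axis=0)
    ranking = evaluate_single_clusters(Xa, y)
    eligible = ranking[[support[c[0]] >= min_support for c in ranking["clusters"]]]
    picked = [c[0] for c in eligible["clusters"].head(k)]
    if len(picked) < k:
        warnings.warn(
            f"only {len(picked)} clusters have >= {min_support} active LS+ "
            f"compounds (requested top {k})", stacklevel=2)
    return picked


class RuleSearch(ClassifierMixin, BaseEstimator):
    """Combinatorial "m in M" rule search as a scikit-learn classifier.

    ``fit`` enumerates the search space against lifespan labels and keeps the
    full MCC-ranked leaderboard; ``predict`` applies the best rule. With
    ``candidate_clusters=None`` the candidates are narrowed first to the top
    GT clusters by single-cluster MCC, keeping the enumeration tractable on
    hundreds of clusters.

    Attributes
    ----------
    ranking_ : DataFrame — every evaluated rule with confusion counts and
        precision/recall/MCC, best first.
    best_rule_ : RuleSpec — the top-ranked rule.
    best_metrics_ : EvalMetrics — its training-label metrics.
    candidate_clusters_ : list of the clusters actually searched.
    """

    def __init__(self, M_range: tuple[int, int] = (2, 5), m_policy: str = "all",
                 candidate_clusters: Sequence[str] | None = None,
                 gt_top_k: int = 10, gt_min_support: int = 3,
                 budget: int = 200_000, force: bool = False):
        self.M_range = M_range
        self.m_policy = m_policy
        self.candidate_clusters = candidate_clusters
        self.gt_top_k = gt_top_k
        self.gt_min_support = gt_min_support
        self.budget = budget
        self.force = force

    def fit(self, X, y):
        df = _as_binary_frame(X)
        if self.candidate_clusters is None:
            candidates = select_gt_clusters(df, y, k=self.gt_top_k,
                                            min_support=self.gt_min_support)
        else:
            candidates = list(self.candidate_clusters)
        space = SearchSpace(candidate_clusters=candidates, M_range=tuple(self.M_range),
                            m_policy=self.m_policy, budget=self.budget)
        self.ranking_ = search_combinations(df, y, space, force=self.force)
        top = self.ranking_.iloc[0]
        self.best_rule_ = RuleSpec(tuple(top["clusters"]), int(top["m"]))
        self.best_metrics_ = EvalMetrics(tp=int(top["tp"]), fp=int(top["fp"]),
                                         tn=int(top["tn"]), fn=int(top["fn"]))
        self.candidate_clusters_ = candidates
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X) -> np.ndarray:
        return predict_rule(_as_binary_frame(X), self.best_rule_)


def ranking_to_tsv(ranking: pd.DataFrame, path) -> None:
    out = ranking.copy()
    out["clusters"] = [";".join(c) for c in out["clusters"]]
    out.to_csv(path, sep="\t", index=False)
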