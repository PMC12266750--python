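"""Virtual-screening funnel: binding calls -> polypharmacology rule ->
exclusions -> drug-likeness -> diversity selection.

Stages run in a fixed order on a candidate table and every stage records its
survivor count in a funnel ledger, so the accounting behind a selection
("N compounds passed the two-of-three rule, K survived the QED filter,
k were picked for diversity") is reproducible on any input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import (
    Fingerprint,
    butina_cluster_with_centroids,
    fingerprints_for,
    qed_score,
    smiles_to_inchikey,
)
from .types import inchikey_skeleton

logger = logging.getLogger(__name__)

DEFAULT_REQUIRED_CLUSTERS = ("drd2", "hrh1", "htr6")


@dataclass
class FunnelConfig:
    """Thresholds of the selection funnel, all exposed and serializable."""

    required_clusters: tuple[str, ...] = DEFAULT_REQUIRED_CLUSTERS
    min_hits: int = 2                 # polypharmacology: >= min_hits of required
    prob_threshold: float = 0.5       # probability -> activity bit, inclusive
    min_qed: float = 0.5              # drug-likeness floor
    k: int = 16                       # diversity picks
    diversity_cutoff: float = 0.8     # Butina Tanimoto cutoff
    task_to_cluster: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.prob_threshold < 1:
            raise ValueError("prob_threshold must be in (0, 1)")
        if self.min_hits > len(self.required_clusters):
            raise ValueError(
                f"min_hits={self.min_hits} exceeds the {len(self.required_clusters)} "
                f"required clusters")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def binarize_probabilities(probabilities: pd.DataFrame, threshold: float = 0.5,
                           task_to_cluster: Mapping[str, str] | None = None
                           ) -> pd.DataFrame:
    """Per-cluster activity bits from per-task probabilities.

    A task maps to a cluster via ``task_to_cluster`` (identity when omitted);
    the cluster bit is the max over its member tasks, comparing inclusively
    against ``threshold``.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if task_to_cluster is None:
        task_to_cluster = {t: t for t in probabilities.columns}
    missing = [t for t in probabilities.columns if t not in task_to_cluster]
    if missing:
        raise ValueError(f"task->cluster map missing task(s): {missing}")
    bits = (probabilities >= threshold).astype(int)
    return bits.T.groupby([task_to_cluster[t] for t in bits.columns]).max().T


def polypharm_filter(bits: pd.DataFrame,
                     required_clusters: Sequence[str] = DEFAULT_REQUIRED_CLUSTERS,
                     min_count: int = 2) -> pd.Series:
    """Pass iff active on at least ``min_count`` of the required clusters."""
    required = list(required_clusters)
    if min_count > len(required):
        raise ValueError(f"min_count={min_count} exceeds |required|={len(required)}")
    absent = [c for c in required if c not in bits.columns]
    if absent:
        raise ValueError(f"required cluster(s) not in bit matrix: {absent}")
    return (bits[required].sum(axis=1) >= min_count).rename("polypharm_pass")


def exclude_known(candidates: pd.DataFrame,
                  exclusion_keys: set[str] | frozenset[str]) -> pd.Series:
    """Flag candidates whose InChIKey connectivity skeleton is excluded.

    Matching on the 14-character skeleton makes the exclusion salt- and
    stereo-insensitive. InChIKeys are computed from SMILES when the table
    lacks an ``inchikey`` column.
    """
    skeletons = {inchikey_skeleton(k) for k in exclusion_keys}
    if "inchikey" in candidates.columns:
        keys = candidates["inchikey"]
    else:
        keys = candidates["smiles"].map(smiles_to_inchikey)
    return keys.map(lambda k: inchikey_skeleton(k) in skeletons).rename("excluded")


def diversity_select(candidates: pd.DataFrame, fps: Sequence[Fingerprint],
                     k: int = 16, cutoff: float = 0.8,
                     score_column: str | None = "mean_required_prob"
                     ) -> tuple[pd.Series, pd.Series]:
    """One representative per Butina cluster, larger clusters first.

    Within a cluster the representative is the member with the highest
    ``score_column`` (mean predicted probability over the required clusters),
    ties broken by compound id. Returns (selected flags, ranks); rank follows
    pick order, NaN for unselected. Fewer clusters than ``k`` selects them
    all with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(fps) != len(candidates):
        raise ValueError("one fingerprint per candidate required")
    assignment, _ = butina_cluster_with_centroids(fps, cutoff)
    df = candidates.copy()
    df["_cluster"] = assignment
    if score_column is not None and score_column in df.columns:
        score = df[score_column].astype(float)
    else:
        score = pd.Series(0.0, index=df.index)
    df["_score"] = score
    sizes = df["_cluster"].value_counts()
    cluster_order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    selected = pd.Series(False, index=candidates.index, name="selected")
    rank = pd.Series(np.nan, index=candidates.index, name="selection_rank")
    n_picked = 0
    for c in cluster_order:
        if n_picked >= k:
            break
        members = df[df["_cluster"] == c]
        rep = members.sort_values(["_score", "compound_id"],
                                  ascending=[False, True], kind="mergesort").index[0]
        selected.loc[rep] = True
        n_picked += 1
        rank.loc[rep] = n_picked
    if len(cluster_order) < k:
        logger.warning("only %d Butina clusters for k=%d picks", len(cluster_order), k)
    return selected, rank


def run_funnel(library: Sequence[tuple[str, str]],
               source,
               config: FunnelConfig = FunnelConfig(),
               exclusion_keys: set[str] | frozenset[str] = frozenset(),
               ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the full selection funnel over an (id, SMILES) library.

    ``source`` is either a per-task probability DataFrame (model predictions)
    or a per-cluster known-activity 0/1 DataFrame — downstream behavior is
    identical. Stages, in order: binarize -> exclude known -> polypharmacology
    rule -> QED floor -> Butina diversity selection. Returns the candidate
    table and the funnel ledger of survivor counts per stage.
    """
    ids = [cid for cid, _ in library]
    table = pd.DataFrame(
        {"compound_id": ids, "smiles": [smi for _, smi in library]},
        index=pd.Index(ids, name="id"))

    probs = source.reindex(ids)
    if probs.isna().any().any():
        raise ValueError("source table missing rows for some library compounds")
    # a known-activity 0/1 matrix passes through binarization unchanged
    bits = binarize_probabilities(probs.astype(float), config.prob_threshold,
                                  config.task_to_cluster)

    ledger: dict[str, int] = {"library": len(table)}

    required = [c for c in config.required_clusters if c in bits.columns]
    if len(required) < len(config.required_clusters):
        missing = set(config.required_clusters) - set(required)
        raise ValueError(f"required cluster(s) absent from source: {sorted(missing)}")
    table["mean_required_prob"] = probs[
        [t for t in probs.columns
         if (config.task_to_cluster or {t: t for t in probs.columns}).get(t, t)
         in config.required_clusters]
    ].mean(axis=1)
    for c in bits.columns:
        table[f"bit_{c}"] = bits[c]

    table["excluded"] = exclude_known(table, exclusion_keys)
    survivors = ~table["excluded"]
    ledger["not_excluded"] = int(survivors.sum())

    table["polypharm_pass"] = polypharm_filter(bits, config.required_clusters,
                                               config.min_hits) & survivors
    survivors = table["polypharm_pass"]
    ledger["polypharm"] = int(survivors.sum())

    table["qed"] = [qed_score(s) for s in table["smiles"]]
    table["qed_pass"] = (table["qed"] >= config.min_qed) & survivors
    survivors = table["qed_pass"]
    ledger["qed"] = int(survivors.sum())

    table["selected"] = False
    table["selection_rank"] = np.nan
    pool = table[survivors]
    if len(pool) > 0:
        fps = fingerprints_for([(c, pool.loc[c, "smiles"]) for c in pool.index])
        sel, rank = diversity_select(pool, fps, config.k, config.diversity_cutoff)
        table.loc[sel.index, "selected"] = sel
        table.loc[rank.index, "selection_rank"] = rank
    ledger["selected"] = int(table["selected"].sum())
    return table, ledger
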