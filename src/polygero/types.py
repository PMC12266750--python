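"""Shared domain types for the polypharmacology discovery pipeline.

The pipeline turns raw ChEMBL-style bioactivity records into a ternary
compound x target-cluster activity matrix, searches "m in M" polypharmacology
rules against lifespan labels, and screens compound libraries. The types here
are the currency passed between those stages.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# Ternary cell states of an activity matrix.
ACTIVE = 1
INACTIVE = 0
MISSING = -1

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


def is_valid_inchikey(key: str) -> bool:
    """True if ``key`` has the hyphenated 14-10-1 InChIKey shape."""
    return bool(_INCHIKEY_RE.match(key))


def inchikey_skeleton(key: str) -> str:
    """First 14 characters: the connectivity hash, salt/stereo-insensitive."""
    return key[:14]


@dataclass(frozen=True)
class ActivityRecord:
    """One assay measurement linking a compound to a protein target.

    ``pchembl_value`` is the negative base-10 log of a molar activity
    (IC50, Ki, Kd, EC50, ...); higher means more potent. ``assay_type`` is
    the single-letter ChEMBL assay class (B binding, F functional, A ADME,
    T toxicity, P physicochemical, U unassigned).
    """

    compound_id: str
    target_id: str
    pchembl_value: float | None
    assay_type: str
    standard_type: str
    inchikey: str | None = None
    smiles: str | None = None

    def __post_init__(self) -> None:
        if self.pchembl_value is not None and self.pchembl_value < 0:
            raise ValueError(
                f"pchembl_value must be non-negative, got {self.pchembl_value} "
                f"for compound {self.compound_id}"
            )
        if self.inchikey is not None and not is_valid_inchikey(self.inchikey):
            raise ValueError(
                f"malformed InChIKey {self.inchikey!r} for compound {self.compound_id}"
            )


@dataclass(frozen=True)
class CompoundRecord:
    """A library compound, optionally with a lifespan-screen label.

    ``parent_inchikey`` is the desalted parent's key for salt forms; it equals
    ``inchikey`` for parent compounds. ``ls_label`` is 1 for LS+ (significant
    positive lifespan effect) and 0 for LS-.
    """

    compound_id: str
    smiles: str | None = None
    inchikey: str | None = None
    parent_inchikey: str | None = None
    ls_label: int | None = None


@dataclass(frozen=True)
class RuleSpec:
    """An "m in M" polypharmacology predictor.

    A compound is called positive when it is active on at least
    ``min_active_m`` of the ``clusters``. ``M = len(clusters)``; ``m = M``
    is the conjunction (all clusters required), and a single cluster with
    ``m = 1`` degenerates to the single-cluster predictor.
    """

    clusters: tuple[str, ...]
    min_active_m: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "clusters", tuple(self.clusters))
        if len(set(self.clusters)) != len(self.clusters):
            raise ValueError(f"duplicate clusters in rule: {self.clusters}")
        if not 1 <= self.min_active_m <= len(self.clusters):
            raise ValueError(
                f"min_active_m={self.min_active_m} outside [1, {len(self.clusters)}]"
            )

    @property
    def M(self) -> int:
        return len(self.clusters)

    @property
    def description(self) -> str:
        return f"{self.min_active_m} in {self.M}"

    def __str__(self) -> str:
        return f"{self.description}: {{{', '.join(self.clusters)}}}"


@dataclass
class EvalMetrics:
    """Confusion counts plus precision / recall / MCC.

    Any metric whose denominator is zero is reported as 0.0 with
    ``degenerate`` set, so downstream ranking never sees NaN.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float = field(init=False)
    recall: float = field(init=False)
    mcc: float = field(init=False)
    degenerate: bool = field(init=False)

    def __post_init__(self) -> None:
        tp, fp, tn, fn = self.tp, self.fp, self.tn, self.fn
        degenerate = False
        if tp + fp > 0:
            self.precision = tp / (tp + fp)
        else:
            self.precision, degenerate = 0.0, True
        if tp + fn > 0:
            self.recall = tp / (tp + fn)
        else:
            self.recall, degenerate = 0.0, True
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if denom > 0:
            self.mcc = (tp * tn - fp * fn) / float(np.sqrt(float(denom)))
        else:
            self.mcc, degenerate = 0.0, True
        self.degenerate = degenerate


class TargetClusterSet:
    """A partition of protein targets into sequence-similarity clusters.

    Clusters carry a ``display_name`` following the field convention of the
    lowercase gene symbol of a key member (e.g. ``hrh1`` for the cluster
    containing HRH1). Membership is disjoint and exhaustive over the targets
    it was built from.
    """

    def __init__(self, clusters: Iterable[tuple[str, str, Sequence[str]]]):
        self.clusters: list[tuple[str, str, tuple[str, ...]]] = []
        seen_targets: dict[str, str] = {}
        seen_names: set[str] = set()
        for cluster_id, display_name, members in clusters:
            members = tuple(members)
            if not members:
                raise ValueError(f"cluster {cluster_id} has no members")
            if display_name in seen_names:
                raise ValueError(f"duplicate display_name {display_name!r}")
            seen_names.add(display_name)
            for t in members:
                if t in seen_targets:
                    raise ValueError(
                        f"target {t!r} belongs to both cluster "
                        f"{seen_targets[t]!r} and {cluster_id!r}"
                    )
                seen_targets[t] = cluster_id
            self.clusters.append((cluster_id, display_name, members))
        self._target_to_cluster = seen_targets

    @property
    def cluster_ids(self) -> list[str]:
        return [c[0] for c in self.clusters]

    @property
    def display_names(self) -> list[str]:
        return [c[1] for c in self.clusters]

    def members(self, cluster_id: str) -> tuple[str, ...]:
        for cid, _, mem in self.clusters:
            if cid == cluster_id:
                return mem
        raise KeyError(cluster_id)

    def cluster_of(self, target_id: str) -> str | None:
        return self._target_to_cluster.get(target_id)

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (cid, name, member)
            for cid, name, mem in self.clusters
            for member in mem
        ]
        return pd.DataFrame(rows, columns=["cluster_id", "display_name", "member"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TargetClusterSet":
        groups: dict[str, list[str]] = {}
        names: dict[str, str] = {}
        for _, row in df.iterrows():
            groups.setdefault(row["cluster_id"], []).append(row["member"])
            names[row["cluster_id"]] = row.get("display_name", row["cluster_id"])
        return cls((cid, names[cid], mem) for cid, mem in groups.items())


class ClusterActivityMatrix:
    """Compounds x target-clusters ternary activity matrix.

    Cells are ``ACTIVE`` (min pChEMBL over cluster-member records >= the
    binarization threshold), ``INACTIVE`` (records exist but min < threshold)
    or ``MISSING`` (no surviving records). ``aggregated_values`` optionally
    keeps the per-cell min pChEMBL (NaN where missing).
    """

    def __init__(
        self,
        compound_ids: Sequence[str],
        cluster_ids: Sequence[str],
        states: np.ndarray,
        binarize_threshold: float = 7.0,
        aggregated_values: np.ndarray | None = None,
    ):
        states = np.asarray(states, dtype=np.int8)
        if states.shape != (len(compound_ids), len(cluster_ids)):
            raise ValueError(
                f"states shape {states.shape} does not match "
                f"{len(compound_ids)} compounds x {len(cluster_ids)} clusters"
            )
        if not np.isin(states, [ACTIVE, INACTIVE, MISSING]).all():
            raise ValueError("states must be in {1, 0, -1}")
        self.compound_ids = list(compound_ids)
        self.cluster_ids = list(cluster_ids)
        self.states = states
        self.binarize_threshold = float(binarize_threshold)
        self.aggregated_values = aggregated_values
        if aggregated_values is not None:
            vals = np.asarray(aggregated_values, dtype=float)
            if vals.shape != states.shape:
                raise ValueError("aggregated_values shape mismatch")
            self.aggregated_values = vals

    @property
    def shape(self) -> tuple[int, int]:
        return self.states.shape

    def to_binary(self, missing_as: str = "inactive") -> pd.DataFrame:
        """Collapse to 0/1; ``missing_as`` maps MISSING cells ('inactive' -> 0,
        'active' -> 1). The mapping is recorded in ``DataFrame.attrs``."""
        if missing_as not in ("inactive", "active"):
            raise ValueError(f"missing_as must be 'inactive' or 'active', got {missing_as!r}")
        fill = 0 if missing_as == "inactive" else 1
        binary = np.where(self.states == MISSING, fill, self.states).astype(np.int8)
        df = pd.DataFrame(binary, index=self.compound_ids, columns=self.cluster_ids)
        df.attrs["missing_as"] = missing_as
        df.attrs["binarize_threshold"] = self.binarize_threshold
        return df

    def to_frame(self) -> pd.DataFrame:
        """Ternary view with NaN for missing cells (TSV-friendly)."""
        vals = self.states.astype(float)
        vals[self.states == MISSING] = np.nan
        return pd.DataFrame(vals, index=self.compound_ids, columns=self.cluster_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="NA", index_label="compound_id")

    @classmethod
    def from_tsv(cls, path, binarize_threshold: float = 7.0) -> "ClusterActivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col="compound_id", na_values=["NA"])
        states = df.to_numpy(dtype=float)
        out = np.full(states.shape, MISSING, dtype=np.int8)
        out[states == 1] = ACTIVE
        out[states == 0] = INACTIVE
        return cls(df.index.tolist(), df.columns.tolist(), out, binarize_threshold)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClusterActivityMatrix):
            return NotImplemented
        return (
            self.compound_ids == other.compound_ids
            and self.cluster_ids == other.cluster_ids
            and np.array_equal(self.states, other.states)
        )


LifespanLabels = Mapping[str, int]
"""Per-compound binary lifespan flag: 1 = LS+ (significant positive lifespan
effect in the screen), 0 = LS-. Compounds absent from the mapping are
unlabeled and excluded from evaluation."""


def labels_to_series(labels: LifespanLabels) -> pd.Series:
    s = pd.Series(dict(labels), dtype=int, name="ls_label")
    if not s.isin([0, 1]).all():
        raise ValueError("lifespan labels must be 0 or 1")
    return s
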