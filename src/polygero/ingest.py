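"""Activity ingestion: ChEMBL-style records -> binarized cluster activity matrix.

The pipeline is filter -> (optional InChIKey matching) -> aggregate-by-cluster
with the minimum pChEMBL -> binarize at pChEMBL >= 7. Potency filtering keeps
records with pChEMBL >= 5 from binding (B) and functional (F) assays whose
standard type is an inhibition-style measurement (Ki, IC50, Kd, ...).
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    ACTIVE,
    INACTIVE,
    MISSING,
    ActivityRecord,
    ClusterActivityMatrix,
    CompoundRecord,
    TargetClusterSet,
    inchikey_skeleton,
    is_valid_inchikey,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_PCHEMBL = 5.0
DEFAULT_BINARIZE_THRESHOLD = 7.0
DEFAULT_ASSAY_TYPES = frozenset({"B", "F"})
# Inhibition-style activity types; the trailing members resolve the open
# allow-list ("Ki, IC50, Kd, etc.") and are configurable at every call site.
DEFAULT_STANDARD_TYPES = frozenset({"Ki", "IC50", "Kd", "EC50", "Km", "pA2"})

RECORD_COLUMNS = [
    "compound_id",
    "inchikey",
    "smiles",
    "target_id",
    "pchembl_value",
    "assay_type",
    "standard_type",
]


def filter_records(
    records: Iterable[ActivityRecord],
    min_pchembl: float = DEFAULT_MIN_PCHEMBL,
    allowed_assay_types: frozenset[str] | set[str] = DEFAULT_ASSAY_TYPES,
    allowed_standard_types: frozenset[str] | set[str] = DEFAULT_STANDARD_TYPES,
) -> list[ActivityRecord]:
    """Keep records with pChEMBL >= ``min_pchembl`` from allowed assay and
    standard types; records lacking a pChEMBL value are dropped. Order is
    preserved and the operation is idempotent."""
    return [
        r
        for r in records
        if r.pchembl_value is not None
        and r.pchembl_value >= min_pchembl
        and r.assay_type in allowed_assay_types
        and r.standard_type in allowed_standard_types
    ]


class RecordIndex:
    """Activity records indexed by full InChIKey and by 14-character skeleton."""

    def __init__(self, records: Iterable[ActivityRecord]):
        self.by_full: dict[str, list[ActivityRecord]] = defaultdict(list)
        self.by_skeleton: dict[str, list[ActivityRecord]] = defaultdict(list)
        for r in records:
            if r.inchikey is None:
                continue
            self.by_full[r.inchikey].append(r)
            self.by_skeleton[inchikey_skeleton(r.inchikey)].append(r)


def match_compound(compound: CompoundRecord, index: RecordIndex) -> list[ActivityRecord]:
    """Match a compound to activity records by InChIKey.

    Full-key matches on the compound's own or parent key take precedence; only
    when neither yields anything is the relaxed search on the 14-character
    connectivity skeleton consulted. Returns [] when nothing matches.
    """
    keys = [k for k in (compound.inchikey, compound.parent_inchikey) if k]
    for k in keys:
        if not is_valid_inchikey(k):
            raise ValueError(
                f"malformed InChIKey {k!r} on compound {compound.compound_id}"
            )
    full: list[ActivityRecord] = []
    for k in keys:
        full.extend(index.by_full.get(k, []))
    if full:
        return full
    relaxed: list[ActivityRecord] = []
    seen: set[int] = set()
    for k in keys:
        for r in index.by_skeleton.get(inchikey_skeleton(k), []):
            if id(r) not in seen:
                seen.add(id(r))
                relaxed.append(r)
    return relaxed


def aggregate_to_matrix(
    records: Iterable[ActivityRecord],
    cluster_map: TargetClusterSet,
    threshold: float = DEFAULT_BINARIZE_THRESHOLD,
    compound_ids: Sequence[str] | None = None,
) -> ClusterActivityMatrix:
    """Aggregate records to a ternary compound x cluster matrix.

    Within each cluster the minimum pChEMBL over member-target records is
    taken, then binarized at ``threshold`` (inclusive). Cells with no records
    stay missing. Records on targets outside ``cluster_map`` are skipped with
    a warning. ``compound_ids`` optionally fixes the row set and order
    (compounds with no records then appear as all-missing rows).
    """
    if threshold <= 0:
        raise ValueError(f"binarization threshold must be positive, got {threshold}")
    records = list(records)
    unmapped: set[str] = set()
    cell_min: dict[tuple[str, str], float] = {}
    seen_compounds: list[str] = []
    seen_set: set[str] = set()
    for r in records:
        cluster = cluster_map.cluster_of(r.target_id)
        if cluster is None:
            unmapped.add(r.target_id)
            continue
        if r.pchembl_value is None:
            continue
        if r.compound_id not in seen_set:
            seen_set.add(r.compound_id)
            seen_compounds.append(r.compound_id)
        key = (r.compound_id, cluster)
        prev = cell_min.get(key)
        if prev is None or r.pchembl_value < prev:
            cell_min[key] = r.pchembl_value
    if unmapped:
        logger.warning(
            "skipped records on %d target(s) outside the cluster map: %s",
            len(unmapped),
            ", ".join(sorted(unmapped)[:10]),
        )
    if compound_ids is None:
        compound_ids = seen_compounds
    cluster_ids = cluster_map.cluster_ids
    row = {c: i for i, c in enumerate(compound_ids)}
    col = {c: j for j, c in enumerate(cluster_ids)}
    states = np.full((len(compound_ids), len(cluster_ids)), MISSING, dtype=np.int8)
    values = np.full(states.shape, np.nan)
    for (cid, cluster), v in cell_min.items():
        if cid not in row:
            continue
        i, j = row[cid], col[cluster]
        values[i, j] = v
        states[i, j] = ACTIVE if v >= threshold else INACTIVE
    return ClusterActivityMatrix(
        compound_ids, cluster_ids, states, threshold, aggregated_values=values
    )


def matrix_to_binary(
    matrix: ClusterActivityMatrix, missing_as: str = "inactive"
) -> pd.DataFrame:
    """Collapse the ternary matrix to 0/1 (missing treated as inactive by
    default); the policy is recorded in the output's metadata."""
    return matrix.to_binary(missing_as=missing_as)


def ingest_records(
    records: Iterable[ActivityRecord],
    cluster_map: TargetClusterSet,
    min_pchembl: float = DEFAULT_MIN_PCHEMBL,
    threshold: float = DEFAULT_BINARIZE_THRESHOLD,
    allowed_assay_types: frozenset[str] | set[str] = DEFAULT_ASSAY_TYPES,
    allowed_standard_types: frozenset[str] | set[str] = DEFAULT_STANDARD_TYPES,
    compound_ids: Sequence[str] | None = None,
) -> ClusterActivityMatrix:
    """Full ingest: filter -> aggregate -> binarize."""
    kept = filter_records(records, min_pchembl, allowed_assay_types, allowed_standard_types)
    return aggregate_to_matrix(kept, cluster_map, threshold, compound_ids=compound_ids)


def records_to_frame(records: Iterable[ActivityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.compound_id, r.inchikey, r.smiles, r.target_id, r.pchembl_value,
             r.assay_type, r.standard_type)
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )


def write_records_tsv(records: Iterable[ActivityRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_records_tsv(path, column_map: Mapping[str, str] | None = None) -> list[ActivityRecord]:
    """Read an activity TSV/CSV. ``column_map`` renames real-export column
    names onto the canonical ones (e.g. ``{"molecule_chembl_id": "compound_id"}``)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in ("compound_id", "target_id", "pchembl_value",
                           "assay_type", "standard_type") if c not in df.columns]
    if missing:
        raise ValueError(f"activity table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        pv = getattr(row, "pchembl_value")
        out.append(
            ActivityRecord(
                compound_id=str(row.compound_id),
                target_id=str(row.target_id),
                pchembl_value=None if pd.isna(pv) else float(pv),
                assay_type=str(row.assay_type),
                standard_type=str(row.standard_type),
                inchikey=(None if not hasattr(row, "inchikey") or pd.isna(row.inchikey)
                          else str(row.inchikey)),
                smiles=(None if not hasattr(row, "smiles") or pd.isna(row.smiles)
                        else str(row.smiles)),
            )
        )
    return out


def write_matrix(matrix: ClusterActivityMatrix, path, sidecar_path=None) -> None:
    """Write the ternary matrix as TSV plus a JSON sidecar with provenance."""
    matrix.to_tsv(path)
    if sidecar_path is not None:
        meta = {
            "binarize_threshold": matrix.binarize_threshold,
            "n_compounds": len(matrix.compound_ids),
            "n_clusters": len(matrix.cluster_ids),
            "states": {"active": ACTIVE, "inactive": INACTIVE, "missing": "NA"},
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)
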