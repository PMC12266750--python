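"""Synthetic inputs for every pipeline stage.

Real runs consume ChEMBL activity extracts, a lifespan screen, protein
sequences and a purchasable-compound library. The generators here emulate
each of those at desk scale — sparse ternary activity with missingness,
lifespan labels planted by a known "m in M" rule with label noise, raw
activity records whose ingestion reproduces a known matrix, sequence families
with controlled identity, and small template-built SMILES libraries — so the
whole pipeline builds and tests with no downloads. Every generator is a pure
function of its config and seed.
"""

from __future__ import annotations

import hashlib
import string
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np

from .types import (
    ACTIVE,
    INACTIVE,
    MISSING,
    ActivityRecord,
    ClusterActivityMatrix,
    RuleSpec,
    TargetClusterSet,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticConfig:
    """Conditions for the planted-rule labeled activity matrix.

    ``planted_rule`` drives the true lifespan labels: a compound's true label
    is the rule applied to its full (pre-masking) activity row, then flipped
    with probability ``label_noise_eps``. Activity on the rule's own clusters
    occurs with ``rule_active_prob``; on every other cluster with
    ``background_active_prob``. Each cell is observed (rather than missing)
    independently with probability ``observe_prob_rho``.
    """

    n_compounds: int = 800
    n_clusters: int = 30
    planted_rule: RuleSpec = field(
        default_factory=lambda: RuleSpec(("drd2", "hrh1", "htr6"), 2)
    )
    label_noise_eps: float = 0.05
    observe_prob_rho: float = 1.0
    background_active_prob: float = 0.1
    rule_active_prob: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("label_noise_eps", "observe_prob_rho",
                     "background_active_prob", "rule_active_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_clusters < self.planted_rule.M:
            raise ValueError(
                f"n_clusters={self.n_clusters} smaller than the planted rule's "
                f"{self.planted_rule.M} clusters"
            )
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")


def generate_labeled_matrix(
    config: SyntheticConfig,
) -> tuple[ClusterActivityMatrix, dict[str, int]]:
    """Draw an activity matrix and lifespan labels from a planted rule.

    Returns the (possibly masked) ternary matrix and per-compound labels.
    The labels are computed on the full pre-masking activity, so at
    ``observe_prob_rho < 1`` the observed matrix underestimates rule hits —
    exactly the incomplete-profiling regime of real bioactivity databases.
    """
    rng = np.random.default_rng(config.seed)
    n, g = config.n_compounds, config.n_clusters
    rule = config.planted_rule
    extra = [f"cl{i:03d}" for i in range(g - rule.M)]
    cluster_ids = list(rule.clusters) + extra
    perm = rng.permutation(g)
    cluster_ids = [cluster_ids[i] for i in perm]
    rule_cols = [cluster_ids.index(c) for c in rule.clusters]

    probs = np.full(g, config.background_active_prob)
    probs[rule_cols] = config.rule_active_prob
    activity = (rng.random((n, g)) < probs).astype(np.int8)

    hits = activity[:, rule_cols].sum(axis=1)
    true_labels = (hits >= rule.min_active_m).astype(int)
    flips = rng.random(n) < config.label_noise_eps
    labels = np.where(flips, 1 - true_labels, true_labels)

    observed = rng.random((n, g)) < config.observe_prob_rho
    states = np.where(observed, activity, np.int8(MISSING)).astype(np.int8)

    compound_ids = [f"CPD{i:05d}" for i in range(n)]
    matrix = ClusterActivityMatrix(compound_ids, cluster_ids, states)
    return matrix, dict(zip(compound_ids, labels.tolist()))


def synthetic_inchikey(compound_id: str) -> str:
    """Deterministic stand-in InChIKey with the 14-10-1 shape (synthetic:
    hashed from the compound id, not derived from a structure)."""
    digest = hashlib.sha256(compound_id.encode()).hexdigest().upper()
    letters = "".join(string.ascii_uppercase[int(c, 16) % 26] for c in digest)
    return f"{letters[:14]}-{letters[14:24]}-N"


def make_cluster_map(cluster_ids: Sequence[str], members_per_cluster: int = 2) -> TargetClusterSet:
    """A synthetic target->cluster map with ``members_per_cluster`` targets
    per cluster (target ids derived from the cluster id)."""
    return TargetClusterSet(
        (cid, cid, tuple(f"{cid.upper()}_T{j}" for j in range(members_per_cluster)))
        for cid in cluster_ids
    )


def generate_activity_records(
    matrix: ClusterActivityMatrix,
    cluster_map: TargetClusterSet,
    seed: int = 0,
    decoy_prob: float = 0.15,
) -> list[ActivityRecord]:
    """Emit raw activity records whose ingestion reconstructs ``matrix``.

    Active cells get one record with pChEMBL in [7, 10] on every member
    target; inactive cells get one record in [5, 7) on a random member (plus
    occasional extra member records in [5, 10), harmless under
    min-aggregation); missing cells get none. With probability ``decoy_prob``
    a cell also emits a record the potency/assay filters must drop
    (pChEMBL < 5 or a non-B/F assay type), exercising the filter stage.
    """
    rng = np.random.default_rng(seed)
    std_types = ["IC50", "Ki", "Kd", "EC50"]
    records: list[ActivityRecord] = []
    cluster_members = {cid: cluster_map.members(cid) for cid in matrix.cluster_ids}
    for cid in matrix.cluster_ids:
        if not cluster_members[cid]:
            raise ValueError(f"cluster {cid} has no member targets")

    def emit(compound: str, target: str, value: float, assay: str = "B") -> None:
        records.append(ActivityRecord(
            compound_id=compound, target_id=target,
            pchembl_value=round(float(value), 3), assay_type=assay,
            standard_type=str(rng.choice(std_types)),
            inchikey=synthetic_inchikey(compound),
        ))

    for i, compound in enumerate(matrix.compound_ids):
        for j, cid in enumerate(matrix.cluster_ids):
            state = matrix.states[i, j]
            members = cluster_members[cid]
            if state == ACTIVE:
                for t in members:
                    emit(compound, t, rng.uniform(7.0, 10.0))
            elif state == INACTIVE:
                low = rng.integers(len(members))
                emit(compound, members[low], rng.uniform(5.0, 6.999))
                for k, t in enumerate(members):
                    if k != low and rng.random() < 0.3:
                        emit(compound, t, rng.uniform(5.0, 10.0))
            if rng.random() < decoy_prob:
                t = members[rng.integers(len(members))]
                if rng.random() < 0.5:
                    emit(compound, t, rng.uniform(3.0, 4.999))  # below potency floor
                else:
                    emit(compound, t, rng.uniform(5.0, 10.0),
                         assay=str(rng.choice(["A", "T", "P", "U"])))
    return records


def generate_target_families(
    n_families: int,
    members_per_family: int,
    seq_len: int = 200,
    within_identity: float = 0.9,
    between_identity: float = 0.2,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, int]]:
    """Protein-like sequence families with controlled identity structure.

    One random ancestor is drawn per family; each member substitutes a random
    ``(1 - within_identity)`` fraction of positions (no indels, always to a
    different residue), so member-to-ancestor identity equals
    ``within_identity`` and pairwise within-family identity is at least
    ``2 * within_identity - 1``. Ancestors are independent, so between-family
    identity sits near the random-sequence baseline (far below 0.5 for
    realistic lengths). Returns (sequences, family index per sequence id).
    """
    if not within_identity > 0.5 > between_identity:
        raise ValueError(
            f"need within_identity > 0.5 > between_identity, got "
            f"{within_identity} / {between_identity}"
        )
    if seq_len < 20:
        raise ValueError(f"seq_len must be >= 20 to realize the identity gap, got {seq_len}")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    n_mut = int(round((1 - within_identity) * seq_len))
    sequences: dict[str, str] = {}
    families: dict[str, int] = {}
    for f in range(n_families):
        ancestor = rng.integers(len(aa), size=seq_len)
        for m in range(members_per_family):
            member = ancestor.copy()
            if n_mut > 0:
                pos = rng.choice(seq_len, size=n_mut, replace=False)
                shift = rng.integers(1, len(aa), size=n_mut)
                member[pos] = (member[pos] + shift) % len(aa)
            sid = f"F{f}_M{m}"
            sequences[sid] = "".join(aa[member])
            families[sid] = f
    return sequences, families


# SMILES assembly templates: each scaffold has one substitution slot, filled
# from the substituent list, optionally extended by a short alkyl tail.
_SCAFFOLDS = [
    "c1ccc({R})cc1",          # benzene
    "c1ccnc({R})c1",          # pyridine
    "C1CCN({R})CC1",          # piperidine
    "C1CN({R})CCN1C",         # N-methylpiperazine
    "c1ccc2c(c1)cccc2{R}",    # naphthalene
    "O=C(N{R})c1ccccc1",      # benzamide
    "c1csc({R})c1",           # thiophene
    "OC({R})c1ccccc1",        # benzylic alcohol
]
_SUBSTITUENTS = [
    "C", "CC", "CCC", "CC(C)C", "CCO", "CCN", "CCNC", "CCCN",
    "Cc1ccccc1", "CCOC", "CC(=O)C", "CCSC",
]
_TAILS = ["", "C", "CC", "CCC", "CCCC", "CCCCC"]


def generate_smiles_library(n: int, seed: int = 0) -> list[tuple[str, str]]:
    """A deterministic toy screening library of ``n`` (id, SMILES) pairs.

    Molecules are enumerated from scaffold x substituent x tail templates in
    a seed-shuffled order; all entries parse with RDKit (asserted at
    generation time). Raises when ``n`` exceeds the template space.
    """
    from rdkit import Chem

    if n < 1:
        raise ValueError("n must be >= 1")
    combos = list(product(range(len(_SCAFFOLDS)), range(len(_SUBSTITUENTS)),
                          range(len(_TAILS))))
    if n > len(combos):
        raise ValueError(
            f"template space holds {len(combos)} molecules, requested {n}")
    rng = np.random.default_rng(seed)
    rng.shuffle(combos)
    out: list[tuple[str, str]] = []
    for i, (s, r, t) in enumerate(combos[:n]):
        smi = _SCAFFOLDS[s].replace("{R}", _SUBSTITUENTS[r] + _TAILS[t])
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # template bug guard; never expected
            raise AssertionError(f"template produced invalid SMILES: {smi}")
        out.append((f"LIB{i:05d}", Chem.MolToSmiles(mol)))
    return out


def write_labels_tsv(labels: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("compound_id\tls_label\n")
        for cid, lab in labels.items():
            fh.write(f"{cid}\t{lab}\n")


def read_labels_tsv(path) -> dict[str, int]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["compound_id"].astype(str), df["ls_label"].astype(int)))
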