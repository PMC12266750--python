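"""Sequence-identity clustering of protein targets.

Targets are grouped at a global-alignment identity threshold (default 0.5),
mirroring the representative-based greedy strategy of fast sequence
clusterers: sequences are processed longest-first and each joins the first
cluster whose representative it matches at or above the threshold, otherwise
it founds a new cluster. Real cluster tables (e.g. an MMseqs2 export) can be
imported via :func:`load_cluster_map` instead.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd
from Bio import Align, SeqIO

from .types import TargetClusterSet

DEFAULT_IDENTITY_THRESHOLD = 0.5


def _make_aligner(match: float = 1.0, mismatch: float = 0.0, gap: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> float:
    """Global-alignment sequence identity in [0, 1].

    Identity is identical aligned positions divided by alignment length
    (gap columns included in the denominator), a single fixed convention
    recorded in output metadata. Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = _make_aligner(match, mismatch, gap)
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def cluster_by_identity(
    sequences: Mapping[str, str],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> TargetClusterSet:
    """Greedy representative-based clustering at an identity threshold.

    Sequences are processed in descending length order (lexicographic id
    tie-break, for determinism); each joins the first existing cluster whose
    representative it matches at >= ``threshold``, else founds a new cluster
    with itself as representative. Output is a partition.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    reps: list[str] = []  # representative ids, in founding order
    members: dict[str, list[str]] = {}
    for sid in order:
        seq = sequences[sid]
        for rep in reps:
            if pairwise_identity(seq, sequences[rep]) >= threshold:
                members[rep].append(sid)
                break
        else:
            reps.append(sid)
            members[sid] = [sid]
    return TargetClusterSet(
        (rep, rep.lower(), members[rep]) for rep in reps
    )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n{seq}\n")


def cluster_fasta(path, threshold: float = DEFAULT_IDENTITY_THRESHOLD) -> TargetClusterSet:
    return cluster_by_identity(read_fasta(path), threshold)


def load_cluster_map(path) -> TargetClusterSet:
    """Import a two-column (cluster_representative, member) TSV, e.g. an
    MMseqs2 cluster table. A member listed under two representatives is an
    error naming the member."""
    df = pd.read_csv(path, sep="\t", header=None, names=["representative", "member"],
                     dtype=str)
    seen: dict[str, str] = {}
    groups: dict[str, list[str]] = {}
    for rep, member in df.itertuples(index=False):
        if member in seen and seen[member] != rep:
            raise ValueError(
                f"target {member!r} listed under two representatives: "
                f"{seen[member]!r} and {rep!r}"
            )
        if member not in seen:
            seen[member] = rep
            groups.setdefault(rep, []).append(member)
    return TargetClusterSet((rep, rep.lower(), mem) for rep, mem in groups.items())


def write_cluster_map(clusters: TargetClusterSet, path) -> None:
    clusters.to_tsv(path)
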