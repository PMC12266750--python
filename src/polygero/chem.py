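"""Molecular utilities: fingerprints, Tanimoto, Butina clustering, QED,
descriptor computation and correlated-descriptor pruning.

The fingerprint default is a 2048-bit circular (Morgan) fingerprint of
radius 2; every fingerprint carries a scheme tag and comparisons across
schemes are refused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, QED, rdFingerprintGenerator
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

DEFAULT_FP_SCHEME = "morgan_r2_2048"


@dataclass(frozen=True)
class Fingerprint:
    """A binary molecular fingerprint: the set of on-bits plus a scheme tag."""

    compound_id: str
    bits: frozenset[int]
    scheme: str = DEFAULT_FP_SCHEME
    n_bits: int = 2048


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def morgan_fingerprint(smiles: str, compound_id: str | None = None,
                       radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(_parse(smiles))
    return Fingerprint(
        compound_id=compound_id if compound_id is not None else smiles,
        bits=frozenset(fp.GetOnBits()),
        scheme=f"morgan_r{radius}_{n_bits}",
        n_bits=n_bits,
    )


def fingerprints_for(smiles_list: Iterable[tuple[str, str]],
                     radius: int = 2, n_bits: int = 2048) -> list[Fingerprint]:
    """Fingerprints for an (id, SMILES) iterable."""
    return [morgan_fingerprint(smi, cid, radius, n_bits) for cid, smi in smiles_list]


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Intersection-over-union of on-bit sets; two empty fingerprints are
    defined as identical (1.0)."""
    if a.scheme != b.scheme:
        raise ValueError(f"fingerprint scheme mismatch: {a.scheme} vs {b.scheme}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def butina_cluster(fps: Sequence[Fingerprint], cutoff: float = 0.8) -> list[int]:
    """Sphere-exclusion (Butina) clustering at a Tanimoto cutoff.

    Neighbor lists at similarity >= cutoff are built, candidates sorted by
    neighbor count descending (ties by input order), and the largest
    unassigned neighborhoods taken as clusters in turn. Returns a cluster id
    per input fingerprint, ids numbered in pick order (0 = first/largest
    sphere); every non-centroid member has similarity >= cutoff to its
    centroid.
    """
    assignment, _ = butina_cluster_with_centroids(fps, cutoff)
    return assignment


def butina_cluster_with_centroids(
    fps: Sequence[Fingerprint], cutoff: float = 0.8
) -> tuple[list[int], list[int]]:
    """As :func:`butina_cluster`, also returning the centroid input index of
    each cluster id (the sphere center that founded it)."""
    if not fps:
        raise ValueError("need at least one fingerprint")
    if not 0 < cutoff <= 1:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    n = len(fps)
    neighbors = [
        [j for j in range(n) if j == i or tanimoto(fps[i], fps[j]) >= cutoff]
        for i in range(n)
    ]
    order = sorted(range(n), key=lambda i: (-len(neighbors[i]), i))
    assignment = [-1] * n
    centroids: list[int] = []
    for i in order:
        if assignment[i] != -1:
            continue
        cid = len(centroids)
        centroids.append(i)
        for j in neighbors[i]:
            if assignment[j] == -1:
                assignment[j] = cid
    return assignment, centroids


class ButinaClustering(ClusterMixin, BaseEstimator):
    """Butina sphere-exclusion clustering as a scikit-learn style clusterer.

    ``fit`` accepts a list of SMILES, of (id, SMILES) pairs, or of
    :class:`Fingerprint` objects; ``labels_`` holds the cluster id per input.
    """

    def __init__(self, cutoff: float = 0.8, radius: int = 2, n_bits: int = 2048):
        self.cutoff = cutoff
        self.radius = radius
        self.n_bits = n_bits

    def _to_fps(self, X) -> list[Fingerprint]:
        if all(isinstance(x, Fingerprint) for x in X):
            return list(X)
        if all(isinstance(x, str) for x in X):
            return [morgan_fingerprint(s, radius=self.radius, n_bits=self.n_bits)
                    for s in X]
        return [morgan_fingerprint(s, cid, self.radius, self.n_bits) for cid, s in X]

    def fit(self, X, y=None):
        fps = self._to_fps(X)
        self.labels_ = np.asarray(butina_cluster(fps, self.cutoff))
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@lru_cache(maxsize=65536)
def qed_score(smiles: str) -> float:
    """Quantitative Estimate of Druglikeness in [0, 1] (desirability-function
    aggregate of eight physicochemical properties); cached per SMILES."""
    return float(QED.qed(_parse(smiles)))


# Default physicochemical descriptor panel for the classifier head; compact
# but covers size, lipophilicity, polarity, flexibility and shape.
DEFAULT_DESCRIPTORS = [
    "MolWt", "MolLogP", "TPSA", "NumHAcceptors", "NumHDonors",
    "NumRotatableBonds", "NumAromaticRings", "RingCount", "FractionCSP3",
    "HeavyAtomCount", "NumSaturatedRings", "NOCount", "NHOHCount",
    "NumAliphaticRings", "LabuteASA", "BalabanJ", "BertzCT", "Chi0", "Chi1",
    "Kappa1", "Kappa2", "HallKierAlpha", "MaxPartialCharge", "MinPartialCharge",
]


def compute_descriptors(smiles_list: Iterable[tuple[str, str]],
                        names: Sequence[str] = DEFAULT_DESCRIPTORS) -> pd.DataFrame:
    """RDKit descriptor table (rows: compound ids, columns: descriptor names)."""
    fns = {name: getattr(Descriptors, name) for name in names}
    rows, ids = [], []
    for cid, smi in smiles_list:
        mol = _parse(smi)
        rows.append([float(fn(mol)) for fn in fns.values()])
        ids.append(cid)
    df = pd.DataFrame(rows, index=ids, columns=list(names))
    if not np.isfinite(df.to_numpy()).all():
        bad = df.columns[~np.isfinite(df).all(axis=0)].tolist()
        raise ValueError(f"non-finite descriptor values in: {bad}")
    return df


def prune_correlated(descriptors: pd.DataFrame, max_abs_corr: float = 0.95) -> list[str]:
    """Greedy removal of highly correlated descriptors.

    Zero-variance columns are dropped first (with a warning). Then descriptor
    pairs are scanned in column order and the later-listed member of any pair
    with |Pearson r| > ``max_abs_corr`` is dropped. The surviving list has no
    remaining pair above the threshold; re-running it is a no-op.
    """
    if len(descriptors) < 2:
        raise ValueError("need at least 2 compounds to estimate correlations")
    if not 0 < max_abs_corr <= 1:
        raise ValueError(f"max_abs_corr must be in (0, 1], got {max_abs_corr}")
    values = descriptors.to_numpy(dtype=float)
    variances = values.var(axis=0)
    constant = [c for c, v in zip(descriptors.columns, variances) if v == 0]
    if constant:
        warnings.warn(f"dropping zero-variance descriptors: {constant}", stacklevel=2)
    cols = [c for c in descriptors.columns if c not in constant]
    corr = descriptors[cols].corr().abs()
    kept: list[str] = []
    dropped: set[str] = set()
    for i, ci in enumerate(cols):
        if ci in dropped:
            continue
        kept.append(ci)
        for cj in cols[i + 1:]:
            if cj not in dropped and corr.loc[ci, cj] > max_abs_corr:
                dropped.add(cj)
    return kept


class CorrelationPruner(TransformerMixin, BaseEstimator):
    """Drop near-duplicate descriptor columns (|Pearson r| above threshold).

    scikit-learn transformer: ``fit`` learns the surviving column list
    (``kept_columns_``), ``transform`` subsets to it.
    """

    def __init__(self, max_abs_corr: float = 0.95):
        self.max_abs_corr = max_abs_corr

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
        self.kept_columns_ = prune_correlated(X, self.max_abs_corr)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
        missing = [c for c in self.kept_columns_ if c not in X.columns]
        if missing:
            raise ValueError(f"descriptor columns missing at transform: {missing}")
        return X[self.kept_columns_]


def smiles_to_inchikey(smiles: str) -> str:
    return Chem.MolToInchiKey(_parse(smiles))


def read_smiles(path) -> list[tuple[str, str]]:
    """Read an (id, SMILES) library from .smi (SMILES [whitespace] id) or
    CSV/TSV with compound_id and smiles columns."""
    path = str(path)
    if path.endswith(".smi"):
        out = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                parts = line.split()
                if not parts:
                    continue
                smi = parts[0]
                cid = parts[1] if len(parts) > 1 else f"mol{i}"
                out.append((cid, smi))
        return out
    sep = "," if path.endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    return list(zip(df["compound_id"].astype(str), df["smiles"].astype(str)))
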