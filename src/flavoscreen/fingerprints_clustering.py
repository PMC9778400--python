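"""Fingerprints, Tanimoto similarity and single-linkage clustering.

Two fingerprint kinds are exposed: Daylight-style hashed path fingerprints
(used for the reference-set clustering) and circular Morgan/ECFP-style
fingerprints (used for library screening, radius 2 = ECFP4-equivalent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.DataStructs.cDataStructs import ExplicitBitVect

from .compound_io import Compound, CompoundSet, ConfigurationError, mol_from_smiles

__all__ = [
    "FingerprintVector",
    "SimilarityMatrix",
    "ClusterAssignment",
    "path_fingerprint",
    "circular_fingerprint",
    "fingerprint",
    "tanimoto",
    "similarity_matrix",
    "single_linkage_cluster",
    "cluster_mean_similarity",
]


@dataclass(frozen=True)
class FingerprintVector:
    bits: frozenset[int]
    nbits: int
    kind: str  # "path" | "circular"
    params: tuple  # hashable param signature

    def __post_init__(self) -> None:
        if self.nbits <= 0 or self.nbits & (self.nbits - 1):
            raise ValueError(f"nbits must be a positive power of two, got {self.nbits}")
        if self.bits and max(self.bits) >= self.nbits:
            raise ValueError("bit index out of range")

    @property
    def popcount(self) -> int:
        return len(self.bits)


def _to_vector(bv: ExplicitBitVect, kind: str, params: tuple) -> FingerprintVector:
    return FingerprintVector(
        bits=frozenset(bv.GetOnBits()), nbits=bv.GetNumBits(), kind=kind, params=params
    )


def path_fingerprint(
    compound: Compound | str, nbits: int = 2048, min_path: int = 1, max_path: int = 7
) -> FingerprintVector:
    """Hashed topological (linear bond path) fingerprint."""
    mol = _as_mol(compound)
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(
        minPath=min_path, maxPath=max_path, fpSize=nbits
    )
    return _to_vector(gen.GetFingerprint(mol), "path", (min_path, max_path, nbits))


def circular_fingerprint(
    compound: Compound | str, radius: int = 2, nbits: int = 2048
) -> FingerprintVector:
    """Morgan circular-environment fingerprint (radius 2 ~ ECFP4)."""
    mol = _as_mol(compound)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    return _to_vector(gen.GetFingerprint(mol), "circular", (radius, nbits))


def fingerprint(compound: Compound | str, kind: str = "path", **params) -> FingerprintVector:
    if kind == "path":
        return path_fingerprint(compound, **params)
    if kind in ("circular", "ecfp4"):
        return circular_fingerprint(compound, **params)
    raise ConfigurationError(f"unknown fingerprint kind {kind!r}")


def _as_mol(compound: Compound | str) -> Chem.Mol:
    if isinstance(compound, Compound):
        return compound.mol()
    return mol_from_smiles(compound)


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    """|a & b| / |a | b|.  Both all-zero -> 1.0 (degenerate, warned)."""
    if (a.nbits, a.kind, a.params) != (b.nbits, b.kind, b.params):
        raise ConfigurationError(
            f"fingerprint parameter mismatch: {(a.kind, a.nbits, a.params)} "
            f"vs {(b.kind, b.nbits, b.params)}"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        warnings.warn("Tanimoto of two all-zero fingerprints defined as 1.0")
        return 1.0
    return len(a.bits & b.bits) / union


@dataclass
class SimilarityMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity matrix diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")
        self.values = v

    def at(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def to_csv(self, stream) -> None:
        stream.write("id," + ",".join(self.ids) + "\n")
        for i, rid in enumerate(self.ids):
            stream.write(rid + "," + ",".join(f"{x:.6f}" for x in self.values[i]) + "\n")


def similarity_matrix(compounds: CompoundSet, kind: str = "path", **params) -> SimilarityMatrix:
    failures = []
    fps = []
    for c in compounds:
        try:
            fps.append(fingerprint(c, kind=kind, **params))
        except Exception as exc:  # aggregate parse failures
            failures.append((c.id, str(exc)))
    if failures:
        raise ValueError(f"fingerprint failures for ids: {failures}")
    n = len(fps)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = tanimoto(fps[i], fps[j])
    return SimilarityMatrix(ids=list(compounds.ids), values=m)


@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    merge_heights: list[float]

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for cid, lab in self.labels.items():
            out.setdefault(lab, []).append(cid)
        return out

    def to_csv(self, stream) -> None:
        stream.write("id,cluster\n")
        for cid, lab in self.labels.items():
            stream.write(f"{cid},{lab}\n")


def single_linkage_cluster(matrix: SimilarityMatrix, n_clusters: int) -> ClusterAssignment:
    """Agglomerative single-linkage on distance = 1 - similarity.

    Equal-distance merges are broken deterministically by the
    lexicographically smallest (id, id) pair across the two clusters, so
    the result is invariant under input row permutation.
    """
    ids = matrix.ids
    n = len(ids)
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    dist = 1.0 - matrix.values
    # cluster -> member indices; keyed by sorted tuple of member ids for tie-breaks
    clusters: list[list[int]] = [[i] for i in range(n)]
    merge_heights: list[float] = []
    while len(clusters) > n_clusters:
        best: Optional[tuple[float, tuple[str, str], int, int]] = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(dist[i, j] for i in clusters[a] for j in clusters[b])
                ida = min(ids[i] for i in clusters[a])
                idb = min(ids[j] for j in clusters[b])
                key = (d, tuple(sorted((ida, idb))))
                if best is None or key < (best[0], best[1]):
                    best = (d, key[1], a, b)
        d, _, a, b = best
        merged = sorted(clusters[a] + clusters[b])
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
        merge_heights.append(d)
    # canonical labelling: clusters ordered by their smallest member id
    clusters.sort(key=lambda c: min(ids[i] for i in c))
    labels = {ids[i]: lab for lab, c in enumerate(clusters, start=1) for i in c}
    return ClusterAssignment(labels={i: labels[i] for i in ids}, merge_heights=merge_heights)


def cluster_mean_similarity(
    assignment: ClusterAssignment, matrix: SimilarityMatrix
) -> dict[int, float]:
    """Mean off-diagonal pairwise similarity per cluster; singletons omitted."""
    if set(assignment.labels) != set(matrix.ids):
        raise ConfigurationError("assignment and matrix ids differ")
    idx = {cid: i for i, cid in enumerate(matrix.ids)}
    out: dict[int, float] = {}
    for lab, members in assignment.clusters().items():
        if len(members) < 2:
            continue
        sims = [
            matrix.values[idx[a], idx[b]]
            for k, a in enumerate(members)
            for b in members[k + 1 :]
        ]
        out[lab] = float(np.mean(sims))
    return out
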