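"""2D molecular descriptors from the hydrogen-suppressed molecular graph.

Native engine for the five descriptors of the published 2D regression
equation: topological autocorrelations (ATS/AATS), neighborhood-symmetry
information content (IC/CIC/MIC) and Kier-Hall electrotopological state
(minimum over ssCH2 atoms).  Conventions:

* autocorrelations run over unordered heavy-atom pairs with raw atomic
  mass or Bondi van-der-Waals volume weights;
* IC_k uses iterative neighborhood refinement from (element, heavy degree)
  initial labels with bond orders on the edges; CIC_k = log2(N) - IC_k;
* MIC_k is the edge-multiplicity-augmented variant: the initial atom label
  additionally carries the sum of incident bond orders, so MIC_k >= IC_k;
* E-state: I = ((2/L)^2 * dv + 1) / d, S_i = I_i + sum (I_i - I_j)/(d_ij+1)^2.

External descriptor tables (e.g. for the published 3D equation) enter via
:func:`ingest_descriptor_table` and share the cleaning/correlation filter.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.sparse.csgraph import shortest_path

from .compound_io import Compound, ConfigurationError, mol_from_smiles

__all__ = [
    "MolecularGraph",
    "DescriptorTable",
    "build_graph",
    "ats",
    "aats",
    "neighborhood_classes",
    "ic",
    "cic",
    "mic",
    "estate_indices",
    "min_estate",
    "compute_descriptor_vector",
    "descriptor_table_for",
    "ingest_descriptor_table",
    "clean_descriptors",
    "correlation_filter",
    "MODEL_2D_DESCRIPTORS",
]

MODEL_2D_DESCRIPTORS = ("MIC1", "ATS4v", "AATS7m", "CIC3", "minssCH2")

# Bondi van der Waals radii (Angstrom); volume = 4/3 pi r^3
_BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}

_PERIOD_BOUNDS = (2, 10, 18, 36, 54, 86, 118)


def _period(z: int) -> int:
    for period, bound in enumerate(_PERIOD_BOUNDS, start=1):
        if z <= bound:
            return period
    raise ValueError(f"atomic number out of range: {z}")


def _vdw_volume(symbol: str, z: int) -> float:
    r = _BONDI_RADII.get(symbol)
    if r is None:
        r = Chem.GetPeriodicTable().GetRvdw(z)
    return 4.0 / 3.0 * math.pi * r**3


@dataclass(frozen=True)
class Atom:
    element: str
    period: int  # principal quantum number L
    degree: int  # heavy-neighbour count
    delta_v: int  # valence electrons minus attached hydrogens
    mass: float
    vdw_volume: float
    n_h: int


@dataclass
class MolecularGraph:
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]  # (i, j, order); aromatic = 1.5
    dist: np.ndarray  # topological distances, inf across fragments

    @property
    def n(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[tuple[int, float]]:
        out = []
        for a, b, order in self.bonds:
            if a == i:
                out.append((b, order))
            elif b == i:
                out.append((a, order))
        return out

    @property
    def diameter(self) -> int:
        finite = self.dist[np.isfinite(self.dist)]
        return int(finite.max()) if finite.size else 0


def build_graph(compound: Compound | str) -> MolecularGraph:
    """Hydrogen-suppressed labelled graph with a BFS topological distance matrix."""
    mol = compound.mol() if isinstance(compound, Compound) else mol_from_smiles(compound)
    pt = Chem.GetPeriodicTable()
    atoms = []
    for a in mol.GetAtoms():
        z = a.GetAtomicNum()
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                period=_period(z),
                degree=a.GetDegree(),
                delta_v=pt.GetNOuterElecs(z) - a.GetTotalNumHs(),
                mass=a.GetMass(),
                vdw_volume=_vdw_volume(a.GetSymbol(), z),
                n_h=a.GetTotalNumHs(),
            )
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), float(b.GetBondTypeAsDouble()))
        for b in mol.GetBonds()
    ]
    n = len(atoms)
    adj = np.zeros((n, n))
    for i, j, _ in bonds:
        adj[i, j] = adj[j, i] = 1
    if n:
        dist = shortest_path(adj, method="BF", unweighted=True, directed=False)
    else:
        dist = np.zeros((0, 0))
    return MolecularGraph(atoms=atoms, bonds=bonds, dist=dist)


_WEIGHTS = {"mass": "mass", "vdw_volume": "vdw_volume", "m": "mass", "v": "vdw_volume"}


def _weights(graph: MolecularGraph, weight: str) -> np.ndarray:
    attr = _WEIGHTS.get(weight)
    if attr is None:
        raise ConfigurationError(f"unknown autocorrelation weight {weight!r}")
    return np.array([getattr(a, attr) for a in graph.atoms])


def _pairs_at_lag(graph: MolecularGraph, k: int) -> np.ndarray:
    iu, ju = np.triu_indices(graph.n, k=1)
    if iu.size == 0:
        return np.zeros((0, 2), dtype=int)
    at_k = graph.dist[iu, ju] == k
    return np.column_stack([iu[at_k], ju[at_k]])


def ats(graph: MolecularGraph, k: int, weight: str = "mass") -> float:
    """Moreau-Broto autocorrelation: sum of w_i * w_j over pairs at lag k."""
    if k < 1:
        raise ValueError(f"lag must be >= 1, got {k}")
    w = _weights(graph, weight)
    pairs = _pairs_at_lag(graph, k)
    if pairs.size == 0:
        return 0.0
    return float(np.sum(w[pairs[:, 0]] * w[pairs[:, 1]]))


def aats(graph: MolecularGraph, k: int, weight: str = "mass") -> float:
    """Averaged autocorrelation; NaN when no pair exists at lag k."""
    if k < 1:
        raise ValueError(f"lag must be >= 1, got {k}")
    npairs = len(_pairs_at_lag(graph, k))
    if npairs == 0:
        return float("nan")
    return ats(graph, k, weight) / npairs


def _refine(graph: MolecularGraph, initial: Sequence, k: int) -> list[int]:
    """k rounds of Weisfeiler-Lehman-style relabelling; returns class ids."""
    canon: dict = {}
    labels = [canon.setdefault(lab, len(canon)) for lab in initial]
    for _ in range(k):
        canon = {}
        new = []
        for i in range(graph.n):
            env = tuple(sorted((order, labels[j]) for j, order in graph.neighbors(i)))
            new.append(canon.setdefault((labels[i], env), len(canon)))
        if new == labels:
            break
        labels = new
    return labels


def neighborhood_classes(graph: MolecularGraph, k: int) -> list[list[int]]:
    """Partition of heavy atoms by k-neighborhood equivalence."""
    if k < 0:
        raise ValueError("neighborhood order must be >= 0")
    labels = _refine(graph, [(a.element, a.degree) for a in graph.atoms], k)
    classes: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        classes.setdefault(lab, []).append(i)
    return sorted(classes.values())


def _entropy(class_sizes: Iterable[int], n: int) -> float:
    return -sum((s / n) * math.log2(s / n) for s in class_sizes)


def ic(graph: MolecularGraph, k: int) -> float:
    """Information content of the order-k neighborhood partition (bits)."""
    if graph.n == 0:
        raise ValueError("graph has no heavy atoms")
    return _entropy((len(c) for c in neighborhood_classes(graph, k)), graph.n)


def cic(graph: MolecularGraph, k: int) -> float:
    """Complementary information content: log2(N) - IC_k."""
    return math.log2(graph.n) - ic(graph, k)


def mic(graph: MolecularGraph, k: int) -> float:
    """Edge-multiplicity-augmented information content (>= IC_k)."""
    if graph.n == 0:
        raise ValueError("graph has no heavy atoms")
    bond_order_sum = [0.0] * graph.n
    for i, j, order in graph.bonds:
        bond_order_sum[i] += order
        bond_order_sum[j] += order
    initial = [
        (a.element, a.degree, bond_order_sum[i]) for i, a in enumerate(graph.atoms)
    ]
    labels = _refine(graph, initial, k)
    sizes: dict[int, int] = {}
    for lab in labels:
        sizes[lab] = sizes.get(lab, 0) + 1
    return _entropy(sizes.values(), graph.n)


def intrinsic_states(graph: MolecularGraph) -> np.ndarray:
    out = np.empty(graph.n)
    for i, a in enumerate(graph.atoms):
        if a.degree == 0:
            raise ValueError(f"intrinsic state undefined for isolated atom {i}")
        out[i] = ((2.0 / a.period) ** 2 * a.delta_v + 1.0) / a.degree
    return out


def estate_indices(graph: MolecularGraph) -> np.ndarray:
    """Kier-Hall E-state values S_i (intrinsic state + field perturbations)."""
    I = intrinsic_states(graph)
    S = I.copy()
    for i in range(graph.n):
        for j in range(graph.n):
            if i == j or not np.isfinite(graph.dist[i, j]):
                continue
            S[i] += (I[i] - I[j]) / (graph.dist[i, j] + 1.0) ** 2
    return S


def _matches_ssch2(graph: MolecularGraph, i: int) -> bool:
    a = graph.atoms[i]
    if a.element != "C" or a.degree != 2 or a.n_h != 2:
        return False
    return all(order == 1.0 for _, order in graph.neighbors(i))


_ATOM_TYPES = {"ssCH2": _matches_ssch2}


def min_estate(graph: MolecularGraph, atom_type: str = "ssCH2") -> float:
    """Minimum E-state over atoms of the given Kier-Hall type; NaN if none."""
    try:
        matcher = _ATOM_TYPES[atom_type]
    except KeyError:
        raise ConfigurationError(f"unknown E-state atom type {atom_type!r}") from None
    matched = [i for i in range(graph.n) if matcher(graph, i)]
    if not matched:
        return float("nan")
    return float(estate_indices(graph)[matched].min())


def compute_descriptor_vector(compound: Compound | str) -> dict[str, float]:
    """The five descriptors of the published 2D equation.

    Molecules without an ssCH2 atom get minssCH2 = 0 (with a warning); a
    topological diameter below 7 leaves AATS7m as NaN.
    """
    graph = build_graph(compound)
    values = {
        "MIC1": mic(graph, 1),
        "ATS4v": ats(graph, 4, "vdw_volume"),
        "AATS7m": aats(graph, 7, "mass"),
        "CIC3": cic(graph, 3),
        "minssCH2": min_estate(graph, "ssCH2"),
    }
    if math.isnan(values["minssCH2"]):
        name = compound.id if isinstance(compound, Compound) else compound
        warnings.warn(f"no ssCH2 atom in {name}; minssCH2 imputed as 0")
        values["minssCH2"] = 0.0
    return values


@dataclass
class DescriptorTable:
    """Compounds x named numeric descriptors (NaN marks missing cells)."""

    frame: pd.DataFrame

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.frame.index]

    @property
    def names(self) -> list[str]:
        return [str(c) for c in self.frame.columns]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def select(self, names: Sequence[str]) -> "DescriptorTable":
        missing = [n for n in names if n not in self.frame.columns]
        if missing:
            raise KeyError(f"descriptors not in table: {missing}")
        return DescriptorTable(self.frame[list(names)].copy())

    def to_csv(self, stream) -> None:
        self.frame.to_csv(stream, index_label="id")


def descriptor_table_for(compounds) -> DescriptorTable:
    """Native five-descriptor table for a compound set."""
    rows = {c.id: compute_descriptor_vector(c) for c in compounds}
    return DescriptorTable(pd.DataFrame.from_dict(rows, orient="index"))


def ingest_descriptor_table(stream: io.TextIOBase | str) -> DescriptorTable:
    """Read an externally computed descriptor CSV (first column = id)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    frame = pd.read_csv(stream, index_col=0, dtype=str)
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()].tolist()
        raise ValueError(f"duplicate compound ids: {dupes}")
    numeric = frame.apply(lambda col: pd.to_numeric(col.str.strip(), errors="coerce"))
    bad = numeric.isna() & frame.notna() & (frame.apply(lambda c: c.str.strip()) != "")
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {frame.index[r]!r}, column {frame.columns[c]!r}: "
            f"{frame.iat[r, c]!r}"
        )
    return DescriptorTable(numeric)


def clean_descriptors(table: DescriptorTable) -> tuple[DescriptorTable, dict[str, str]]:
    """Drop degenerate columns/rows; returns (table, {dropped name: reason}).

    Columns that are entirely missing, all zero or constant are removed, as
    are columns with residual missing cells (so the result has no NaN) and
    rows that are fully missing.
    """
    frame = table.frame.copy()
    dropped: dict[str, str] = {}
    full_missing_rows = frame.index[frame.isna().all(axis=1)]
    for rid in full_missing_rows:
        dropped[str(rid)] = "row fully missing"
    frame = frame.drop(index=full_missing_rows)
    for col in list(frame.columns):
        series = frame[col]
        if series.isna().all():
            dropped[str(col)] = "blank column"
        elif (series.fillna(0) == 0).all():
            dropped[str(col)] = "all zeros"
        elif series.dropna().nunique() <= 1:
            dropped[str(col)] = "constant column"
        elif series.isna().any():
            dropped[str(col)] = "missing values"
        else:
            continue
        frame = frame.drop(columns=[col])
    if frame.shape[1] == 0:
        raise ValueError("degenerate table: all descriptor columns dropped")
    return DescriptorTable(frame), dropped


def correlation_filter(
    table: DescriptorTable, threshold: float = 0.9
) -> tuple[DescriptorTable, list[str]]:
    """Greedy elimination until no descriptor pair has |r| > threshold.

    At each step the worst (largest |r|) offending pair is located and the
    member with the larger mean absolute correlation to the remaining
    columns is dropped; ties drop the later column in input order.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    frame = table.frame.copy()
    dropped: list[str] = []
    while frame.shape[1] > 1:
        corr = frame.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = np.nanmax(corr.to_numpy())
        if worst <= threshold or math.isnan(worst):
            break
        i, j = np.unravel_index(np.nanargmax(corr.to_numpy()), corr.shape)
        mean_i = corr.iloc[i].mean()
        mean_j = corr.iloc[j].mean()
        if mean_i > mean_j:
            victim = i
        elif mean_j > mean_i:
            victim = j
        else:
            victim = max(i, j)  # later input-order column
        dropped.append(str(frame.columns[victim]))
        frame = frame.drop(columns=[frame.columns[victim]])
    return DescriptorTable(frame), dropped
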