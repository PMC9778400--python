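"""Seeded generators for every input the pipeline needs offline.

Two generators: correlated descriptor/activity datasets with a known
linear truth (for fitting, filtering and GA-recovery experiments), and
flavonoid-like compound libraries built by decorating a chromen-4-one
scaffold, with planted single-edit variants of seed compounds (for
screening-enrichment experiments).  Both are pure functions of their spec,
seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import RWMol

from .compound_io import Compound, CompoundSet, mol_from_smiles
from .descriptors_2d import DescriptorTable
from .fingerprints_clustering import circular_fingerprint, tanimoto

__all__ = [
    "SyntheticLinearSpec",
    "LibrarySpec",
    "synth_linear_dataset",
    "synth_library",
    "FLAVONE_SCAFFOLD",
    "DEFAULT_FRAGMENTS",
]

FLAVONE_SCAFFOLD = "O=c1cc(-c2ccccc2)oc2ccccc12"  # 2-phenyl-4H-chromen-4-one

# CHO-only substituents; atom 0 is the attachment point
DEFAULT_FRAGMENTS = {
    "hydroxy": "O",
    "methoxy": "OC",
    "glucosyloxy": "OC1OC(CO)C(O)C(O)C1O",
    "rutinosyloxy": "OC1OC(COC2OC(C)C(O)C(O)C2O)C(O)C(O)C1O",
    "galloyl": "OC(=O)c1cc(O)c(O)c(O)c1",
}


@dataclass(frozen=True)
class SyntheticLinearSpec:
    n: int = 60
    p_total: int = 40
    k_true: int = 5
    true_coefficients: Optional[dict[str, float]] = None
    intercept: float = 4.0
    noise_sd: float = 0.1
    descriptor_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.descriptor_correlation < 1.0:
            raise ValueError("descriptor_correlation must be in [0, 1)")
        if self.k_true > self.p_total:
            raise ValueError("k_true cannot exceed p_total")
        if self.true_coefficients is not None and len(self.true_coefficients) != self.k_true:
            raise ValueError("true_coefficients must have k_true entries")


def synth_linear_dataset(
    spec: SyntheticLinearSpec,
) -> tuple[DescriptorTable, np.ndarray, dict]:
    """Descriptor matrix with a common-factor correlation structure and a
    response with known linear truth.  Returns (table, y, truth)."""
    rng = np.random.default_rng(spec.seed)
    names = [f"D{i+1:03d}" for i in range(spec.p_total)]
    rho = spec.descriptor_correlation
    latent = rng.standard_normal(spec.n)
    X = np.sqrt(rho) * latent[:, None] + np.sqrt(1.0 - rho) * rng.standard_normal(
        (spec.n, spec.p_total)
    )
    if spec.true_coefficients is None:
        true_names = names[: spec.k_true]
        signs = rng.choice([-1.0, 1.0], size=spec.k_true)
        magnitudes = rng.uniform(2.0, 5.0, size=spec.k_true)
        coefficients = dict(zip(true_names, signs * magnitudes))
    else:
        coefficients = dict(spec.true_coefficients)
        unknown = set(coefficients) - set(names)
        if unknown:
            raise ValueError(f"true coefficient names not in table: {sorted(unknown)}")
    beta = np.array([coefficients.get(name, 0.0) for name in names])
    y = spec.intercept + X @ beta + spec.noise_sd * rng.standard_normal(spec.n)
    ids = [f"mol{i+1:03d}" for i in range(spec.n)]
    table = DescriptorTable(pd.DataFrame(X, index=ids, columns=names))
    truth = {"intercept": spec.intercept, "coefficients": coefficients}
    return table, y, truth


@dataclass(frozen=True)
class LibrarySpec:
    n_molecules: int = 100
    scaffold: str = FLAVONE_SCAFFOLD
    substituent_vocabulary: tuple[str, ...] = tuple(DEFAULT_FRAGMENTS.values())
    planted_seed_variants: int = 1
    max_substituents: int = 4
    seed: int = 0


def _decoration_sites(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIsAromatic() and a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    ]


def _attach(mol: Chem.Mol, site: int, fragment: Chem.Mol) -> Optional[Chem.Mol]:
    combined = RWMol(Chem.CombineMols(mol, fragment))
    combined.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        out = combined.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _decorate_scaffold(
    scaffold: Chem.Mol, fragments: list[Chem.Mol], rng: np.random.Generator, max_subs: int
) -> Optional[str]:
    mol = scaffold
    for _ in range(int(rng.integers(1, max_subs + 1))):
        sites = _decoration_sites(mol)
        if not sites:
            break
        site = int(rng.choice(sites))
        fragment = fragments[int(rng.integers(0, len(fragments)))]
        nxt = _attach(mol, site, fragment)
        if nxt is None:
            continue
        mol = nxt
    smiles = Chem.MolToSmiles(mol)
    return smiles if Chem.MolFromSmiles(smiles) is not None else None


def _single_edits(mol: Chem.Mol, rng: np.random.Generator) -> list[Chem.Mol]:
    """Candidate single-site edits: add an OH/OMe, or delete a terminal
    hydroxyl; order shuffled by the rng."""
    edits: list[Chem.Mol] = []
    for site in _decoration_sites(mol):
        for frag_smiles in ("O", "OC"):
            edited = _attach(mol, site, Chem.MolFromSmiles(frag_smiles))
            if edited is not None:
                edits.append(edited)
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "O" and atom.GetDegree() == 1 and atom.GetTotalNumHs() == 1:
            editable = RWMol(mol)
            editable.RemoveAtom(atom.GetIdx())
            try:
                out = editable.GetMol()
                Chem.SanitizeMol(out)
                edits.append(out)
            except Exception:
                continue
    order = rng.permutation(len(edits))
    return [edits[i] for i in order]


def synth_library(spec: LibrarySpec, seeds: Optional[CompoundSet] = None) -> CompoundSet:
    """Generate a screening library plus planted near-duplicates of seeds.

    Planted variants differ from their seed by one substituent edit chosen
    so the circular-fingerprint Tanimoto to the seed stays above 0.8; a
    seed with no passing edit falls back to an exact copy (warned via name).
    """
    rng = np.random.default_rng(spec.seed)
    scaffold = mol_from_smiles(spec.scaffold)
    fragments = [mol_from_smiles(f) for f in spec.substituent_vocabulary]
    compounds: list[Compound] = []
    made = 0
    while made < spec.n_molecules:
        smiles = _decorate_scaffold(scaffold, fragments, rng, spec.max_substituents)
        if smiles is None:
            continue
        made += 1
        compounds.append(
            Compound(id=f"lib-{made:05d}", smiles=smiles, name="scaffold-decorated")
        )
    for seed_compound in seeds or []:
        seed_fp = circular_fingerprint(seed_compound)
        planted = 0
        for edited in _single_edits(seed_compound.mol(), rng):
            if planted >= spec.planted_seed_variants:
                break
            smiles = Chem.MolToSmiles(edited)
            if Chem.MolFromSmiles(smiles) is None:
                continue
            if tanimoto(seed_fp, circular_fingerprint(smiles)) <= 0.8:
                continue
            planted += 1
            compounds.append(
                Compound(
                    id=f"planted-{seed_compound.id}-{planted}",
                    smiles=smiles,
                    name=f"planted variant of {seed_compound.id}",
                )
            )
        while planted < spec.planted_seed_variants:
            planted += 1
            compounds.append(
                Compound(
                    id=f"planted-{seed_compound.id}-{planted}",
                    smiles=seed_compound.smiles,
                    name=f"planted copy of {seed_compound.id} (no passing edit)",
                )
            )
    return CompoundSet(compounds, provenance=f"synthetic library (seed={spec.seed})")
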