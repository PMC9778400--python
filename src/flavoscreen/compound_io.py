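"""Molecule table I/O, canonicalization and the embedded reference dataset.

The reference dataset is a fixture of 27 dietary flavonoids with measured
alpha-glucosidase pIC50 values plus the table-predicted values of the two
published regression models; the five screened candidate molecules are a
second, smaller fixture.  Structures were transcribed from the PubChem
records for the listed CIDs (hydroxylation/glycosylation patterns; stereo
descriptors are deliberately omitted because every downstream computation
is 2D).  See the ``provenance`` note on each loaded set.
"""

from __future__ import annotations

import csv
import importlib.resources
import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "Compound",
    "CompoundSet",
    "ParseFailure",
    "ParseError",
    "ConfigurationError",
    "read_smiles_table",
    "read_smi_file",
    "read_sdf",
    "write_smiles_table",
    "canonicalize",
    "mol_from_smiles",
    "load_reference_dataset",
    "load_candidates",
    "pic50_from_ic50",
    "ic50_from_pic50",
    "element_set",
]


class ParseError(ValueError):
    """A SMILES string could not be parsed into a valid molecule."""


class ConfigurationError(ValueError):
    """Invalid column mapping, parameters or otherwise malformed request."""


@dataclass(frozen=True)
class Compound:
    """A single identified molecule.

    ``pic50`` is always on the molar scale (-log10 of IC50 in mol/L).
    """

    id: str
    smiles: str
    name: str = ""
    cid: Optional[int] = None
    pic50: Optional[float] = None
    source: str = "library"

    def __post_init__(self) -> None:
        if self.cid is not None and self.cid <= 0:
            raise ValueError(f"cid must be positive, got {self.cid}")
        if self.pic50 is not None and not (0.0 < self.pic50 < 15.0):
            raise ValueError(f"pic50 out of plausible range (0, 15): {self.pic50}")

    def mol(self) -> Chem.Mol:
        return mol_from_smiles(self.smiles, context=self.id)


@dataclass(frozen=True)
class ParseFailure:
    row: int
    id: str
    smiles: str
    reason: str


class CompoundSet:
    """An ordered collection of compounds with unique ids."""

    def __init__(self, compounds: Iterable[Compound], provenance: str = "") -> None:
        self._compounds = list(compounds)
        self.provenance = provenance
        seen: set[str] = set()
        for c in self._compounds:
            if c.id in seen:
                raise ValueError(f"duplicate compound id: {c.id!r}")
            seen.add(c.id)
        self._by_id = {c.id: c for c in self._compounds}

    def __len__(self) -> int:
        return len(self._compounds)

    def __iter__(self) -> Iterator[Compound]:
        return iter(self._compounds)

    def __getitem__(self, key: str | int) -> Compound:
        if isinstance(key, int):
            return self._compounds[key]
        return self._by_id[key]

    def __contains__(self, cid: str) -> bool:
        return cid in self._by_id

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self._compounds]

    def by_cid(self, cid: int) -> Compound:
        for c in self._compounds:
            if c.cid == cid:
                return c
        raise KeyError(f"no compound with CID {cid}")

    def by_name(self, name: str) -> Compound:
        matches = [c for c in self._compounds if c.name == name]
        if not matches:
            raise KeyError(f"no compound named {name!r}")
        if len(matches) > 1:
            raise KeyError(
                f"name {name!r} is ambiguous (CIDs {[c.cid for c in matches]}); "
                "look up by CID instead"
            )
        return matches[0]

    def subset(self, ids: Sequence[str], provenance: str = "") -> "CompoundSet":
        return CompoundSet([self._by_id[i] for i in ids], provenance or self.provenance)


def mol_from_smiles(smiles: str, context: str = "") -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        where = f" (compound {context})" if context else ""
        raise ParseError(f"unparseable SMILES{where}: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Canonical SMILES; invariant under input atom ordering and idempotent."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def read_smiles_table(
    stream: io.TextIOBase | str,
    *,
    smiles_col: str = "smiles",
    id_col: Optional[str] = "id",
    name_col: Optional[str] = "name",
    pic50_col: Optional[str] = "pic50",
    source: str = "library",
    delimiter: str = ",",
) -> tuple[CompoundSet, list[ParseFailure]]:
    """Read a delimited compound table.

    Returns the parsed set together with a report of rows whose SMILES did
    not parse; bad rows are never silently dropped.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.DictReader(stream, delimiter=delimiter)
    if reader.fieldnames is None:
        raise ConfigurationError("empty file: no header row")
    if smiles_col not in reader.fieldnames:
        raise ConfigurationError(
            f"missing SMILES column {smiles_col!r}; found {reader.fieldnames}"
        )
    compounds: list[Compound] = []
    failures: list[ParseFailure] = []
    nrows = 0
    for i, row in enumerate(reader, start=1):
        nrows += 1
        smiles = (row.get(smiles_col) or "").strip()
        rid = (row.get(id_col) or "").strip() if id_col else ""
        rid = rid or f"row{i}"
        if Chem.MolFromSmiles(smiles) is None:
            failures.append(ParseFailure(i, rid, smiles, "unparseable SMILES"))
            continue
        pic50 = None
        if pic50_col and row.get(pic50_col, "").strip():
            pic50 = float(row[pic50_col])
        compounds.append(
            Compound(
                id=rid,
                smiles=smiles,
                name=(row.get(name_col) or "").strip() if name_col else "",
                pic50=pic50,
                source=source,
            )
        )
    if nrows == 0:
        raise ConfigurationError("empty file: no data rows")
    return CompoundSet(compounds), failures


def read_smi_file(stream: io.TextIOBase | str, source: str = "library") -> tuple[CompoundSet, list[ParseFailure]]:
    """Read a ``.smi`` file: one record per line, ``SMILES<ws>id``."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    compounds: list[Compound] = []
    failures: list[ParseFailure] = []
    for i, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        rid = parts[1].strip() if len(parts) > 1 else f"line{i}"
        if Chem.MolFromSmiles(smiles) is None:
            failures.append(ParseFailure(i, rid, smiles, "unparseable SMILES"))
            continue
        compounds.append(Compound(id=rid, smiles=smiles, source=source))
    return CompoundSet(compounds), failures


def read_sdf(stream: io.TextIOBase | str, id_prop: Optional[str] = None, source: str = "library") -> CompoundSet:
    """Read a V2000 SDF; the title line is the id unless ``id_prop`` is given."""
    if not isinstance(stream, str):
        stream = stream.read()
    supplier = Chem.SDMolSupplier()
    supplier.SetData(stream)
    compounds = []
    for i, mol in enumerate(supplier, start=1):
        if mol is None:
            continue
        if id_prop and mol.HasProp(id_prop):
            rid = mol.GetProp(id_prop)
        else:
            rid = mol.GetProp("_Name") if mol.GetProp("_Name") else f"mol{i}"
        compounds.append(Compound(id=rid, smiles=Chem.MolToSmiles(mol), source=source))
    return CompoundSet(compounds)


def write_smiles_table(compounds: CompoundSet, stream: io.TextIOBase) -> None:
    writer = csv.writer(stream)
    writer.writerow(["id", "name", "smiles", "pic50"])
    for c in compounds:
        writer.writerow([c.id, c.name, c.smiles, "" if c.pic50 is None else repr(c.pic50)])


def _data_text(filename: str) -> str:
    return importlib.resources.files("flavoscreen.data").joinpath(filename).read_text()


def _load_fixture_rows(filename: str) -> list[dict[str, str]]:
    return list(csv.DictReader(io.StringIO(_data_text(filename))))


def load_reference_dataset() -> CompoundSet:
    """The 27-flavonoid reference set with experimental pIC50 values.

    CID is the primary key: two rows print the display name "Myricetin"
    (CIDs 5281672 and 5281673); the latter is myricitrin per its CID and
    carries that as ``alt_name`` in the raw fixture.  Use :meth:`CompoundSet.by_cid`.
    """
    compounds = [
        Compound(
            id=f"CID{row['cid']}",
            cid=int(row["cid"]),
            name=row["name"],
            smiles=row["smiles"],
            pic50=float(row["pic50"]),
            source="reference",
        )
        for row in _load_fixture_rows("reference_flavonoids.csv")
    ]
    return CompoundSet(
        compounds,
        provenance="27 dietary flavonoids with experimental alpha-glucosidase pIC50; "
        "structures transcribed from PubChem records for the listed CIDs (2D, no stereo)",
    )


def load_reference_predictions() -> list[dict]:
    """Raw fixture rows including the table-predicted pIC50 of both models."""
    rows = []
    for row in _load_fixture_rows("reference_flavonoids.csv"):
        rows.append(
            {
                "cid": int(row["cid"]),
                "name": row["name"],
                "alt_name": row["alt_name"],
                "pic50": float(row["pic50"]),
                "pic50_pred_2d": float(row["pic50_pred_2d"]),
                "residual_2d": float(row["residual_2d"]),
                "pic50_pred_3d": float(row["pic50_pred_3d"]),
                "residual_3d": float(row["residual_3d"]),
            }
        )
    return rows


def load_candidates() -> CompoundSet:
    """The five screened candidate natural products.

    Four structures follow directly from their systematic chromen-4-one
    names; the morelosin structure is an approximate flavone transcription
    and is not used in any numeric check.
    """
    compounds = [
        Compound(id=row["id"], name=row["name"], smiles=row["smiles"], source="candidate")
        for row in _load_fixture_rows("candidates.csv")
    ]
    return CompoundSet(compounds, provenance="screened candidate inhibitors")


def pic50_from_ic50(ic50: float, unit: str = "molar") -> float:
    """-log10 of an IC50; ``unit`` is ``molar`` or ``micromolar``."""
    if ic50 <= 0:
        raise ValueError(f"ic50 must be positive, got {ic50}")
    if unit == "micromolar":
        ic50 = ic50 * 1e-6
    elif unit != "molar":
        raise ConfigurationError(f"unknown unit {unit!r}")
    return -math.log10(ic50)


def ic50_from_pic50(pic50: float, unit: str = "molar") -> float:
    ic50_molar = 10.0 ** (-pic50)
    if unit == "micromolar":
        return ic50_molar * 1e6
    if unit != "molar":
        raise ConfigurationError(f"unknown unit {unit!r}")
    return ic50_molar


def element_set(compound: Compound | str) -> frozenset[str]:
    """Distinct element symbols in the molecule, hydrogens included."""
    smiles = compound.smiles if isinstance(compound, Compound) else compound
    mol = mol_from_smiles(smiles)
    symbols = {a.GetSymbol() for a in mol.GetAtoms()}
    if any(a.GetTotalNumHs() > 0 for a in mol.GetAtoms()) or "H" in symbols:
        symbols.add("H")
    return frozenset(symbols)
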