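"""MMGBSA decomposition-table bookkeeping.

Parses per-complex energy-component tables (cells optionally "value ±
uncertainty"), aggregates the decomposition identities

    g_gas  = e_vdw + e_ele
    g_sol  = g_pol + g_nonpol
    g_bind = g_gas + g_sol

and audits printed aggregate rows against the component arithmetic.  The
gas-phase term is defined as vdW + electrostatics only: that is the
identity the embedded fixture's printed values satisfy exactly.  Units are
passed through unchanged.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from typing import Optional

from .compound_io import _data_text

__all__ = [
    "Measurement",
    "EnergyDecomposition",
    "AuditFinding",
    "parse_energy_table",
    "load_reference_energy_table",
    "aggregate",
    "audit",
]

_PM_RE = re.compile(r"^\s*([^\s±]+)\s*(?:±\s*([^\s±]+))?\s*$")

_COMPONENTS = ("e_vdw", "e_ele", "g_pol", "g_nonpol")
_AGGREGATES = ("g_gas", "g_sol", "g_bind")


@dataclass(frozen=True)
class Measurement:
    value: float
    uncertainty: Optional[float] = None


def _parse_cell(text: str, where: str) -> Optional[Measurement]:
    text = text.strip()
    if not text:
        return None
    m = _PM_RE.match(text)
    if not m:
        raise ValueError(f"malformed cell {where}: {text!r}")
    try:
        # tolerate the typographic minus sign used in print
        value = float(m.group(1).replace("−", "-"))
        unc = float(m.group(2).replace("−", "-")) if m.group(2) else None
    except ValueError as exc:
        raise ValueError(f"malformed cell {where}: {text!r}") from exc
    return Measurement(value, unc)


@dataclass(frozen=True)
class EnergyDecomposition:
    complex_id: str
    e_vdw: Measurement
    e_ele: Measurement
    g_pol: Measurement
    g_nonpol: Measurement
    g_gas: Optional[Measurement] = None
    g_sol: Optional[Measurement] = None
    g_bind: Optional[Measurement] = None
    unit: str = "kcal_per_mol"


def parse_energy_table(stream: io.TextIOBase | str, unit: str = "kcal_per_mol") -> list[EnergyDecomposition]:
    """Read a per-complex component CSV; '±' cells split into value and
    uncertainty.  Required columns: complex, e_vdw, e_ele, g_pol, g_nonpol;
    aggregate columns are optional."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.DictReader(stream)
    required = {"complex", *_COMPONENTS}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise ValueError(
            f"energy table must have columns {sorted(required)}; "
            f"found {reader.fieldnames}"
        )
    records = []
    for row in reader:
        cid = row["complex"]
        fields = {}
        for col in _COMPONENTS + _AGGREGATES:
            cell = row.get(col) or ""
            fields[col] = _parse_cell(cell, f"({cid}, {col})")
        missing = [c for c in _COMPONENTS if fields[c] is None]
        if missing:
            raise ValueError(f"complex {cid!r} missing components: {missing}")
        records.append(EnergyDecomposition(complex_id=cid, unit=unit, **fields))
    return records


def load_reference_energy_table() -> list[EnergyDecomposition]:
    """The embedded five-complex MMGBSA fixture (as printed, typos included)."""
    return parse_energy_table(_data_text("mmgbsa_decomposition.csv"))


def aggregate(record: EnergyDecomposition) -> tuple[float, float, float]:
    """(g_gas, g_sol, g_bind) recomputed from the four base components."""
    g_gas = record.e_vdw.value + record.e_ele.value
    g_sol = record.g_pol.value + record.g_nonpol.value
    return g_gas, g_sol, g_gas + g_sol


@dataclass(frozen=True)
class AuditFinding:
    complex_id: str
    field: str
    printed: float
    computed: float

    @property
    def discrepancy(self) -> float:
        return self.printed - self.computed


def audit(
    records: list[EnergyDecomposition], tolerance: float = 0.015
) -> list[AuditFinding]:
    """Compare printed aggregate rows against component sums.

    Returns the findings whose |printed - computed| exceeds the tolerance
    (default: last-printed-digit rounding).  Never raises on inconsistency.
    """
    findings = []
    for record in records:
        g_gas, g_sol, g_bind = aggregate(record)
        for name, computed in (("g_gas", g_gas), ("g_sol", g_sol), ("g_bind", g_bind)):
            printed = getattr(record, name)
            if printed is None:
                continue
            if abs(printed.value - computed) > tolerance:
                findings.append(
                    AuditFinding(record.complex_id, name, printed.value, computed)
                )
    return findings
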