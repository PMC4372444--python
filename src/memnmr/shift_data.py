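"""Experimental chemical-shift tables: I/O, restraint selection, shift index.

Shift tables are flat per-residue/per-atom records in ppm.  The module also
ships a random-coil reference set (Wishart-style values) used by the
secondary chemical-shift index, and turns a table into the restraint set
consumed by the ensemble-selection objective.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "ATOM_NAMES",
    "CARBON_ATOMS",
    "PROTON_ATOMS",
    "ShiftEntry",
    "ShiftTable",
    "RestraintSet",
    "RandomCoilReference",
    "CSIRecord",
    "read_shift_table",
    "write_shift_table",
    "select_restraints",
    "chemical_shift_index",
    "load_random_coil_reference",
    "packaged_shift_table_path",
]

ATOM_NAMES = ("CO", "CA", "CB", "CG", "CD", "HA", "HB", "HG", "HD")
CARBON_ATOMS = frozenset({"CO", "CA", "CB", "CG", "CD"})
PROTON_ATOMS = frozenset({"HA", "HB", "HG", "HD"})

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_THREE_TO_ONE = {v: k for k, v in _ONE_TO_THREE.items()}


def one_to_three(letter: str) -> str:
    """Map a 1-letter residue code to its 3-letter code."""
    try:
        return _ONE_TO_THREE[letter.upper()]
    except KeyError:
        raise ValueError(f"unknown residue letter {letter!r}") from None


def three_to_one(name: str) -> str:
    try:
        return _THREE_TO_ONE[name.upper()]
    except KeyError:
        raise ValueError(f"unknown residue name {name!r}") from None


@dataclass(frozen=True)
class ShiftEntry:
    """One measured shift: residue (1-based), 3-letter name, atom, ppm."""

    residue_number: int
    residue_name: str
    atom: str
    shift: float
    uncertainty: Optional[float] = None

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValueError(f"residue_number must be >= 1, got {self.residue_number}")
        if self.atom not in ATOM_NAMES:
            raise ValueError(f"unknown atom {self.atom!r}; expected one of {ATOM_NAMES}")
        if not _finite(self.shift):
            raise ValueError(f"non-finite shift for residue {self.residue_number} {self.atom}")
        if self.uncertainty is not None and not (self.uncertainty >= 0):
            raise ValueError("uncertainty must be >= 0 when present")


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


class ShiftTable:
    """Collection of shift entries with at most one entry per (residue, atom)."""

    def __init__(self, entries: Iterable[ShiftEntry]):
        self.entries: list[ShiftEntry] = list(entries)
        self._index: dict[tuple[int, str], ShiftEntry] = {}
        for e in self.entries:
            key = (e.residue_number, e.atom)
            if key in self._index:
                raise ValueError(f"duplicate entry for residue {key[0]} atom {key[1]}")
            self._index[key] = e

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ShiftTable):
            return NotImplemented
        return self.entries == other.entries

    def get(self, residue_number: int, atom: str) -> Optional[float]:
        e = self._index.get((residue_number, atom))
        return None if e is None else e.shift

    def entry(self, residue_number: int, atom: str) -> Optional[ShiftEntry]:
        return self._index.get((residue_number, atom))

    def residues(self) -> list[int]:
        """Sorted residue numbers present in the table."""
        return sorted({e.residue_number for e in self.entries})

    def residue_name(self, residue_number: int) -> str:
        for e in self.entries:
            if e.residue_number == residue_number:
                return e.residue_name
        raise KeyError(residue_number)


@dataclass(frozen=True)
class Restraint:
    residue_number: int
    atom: str
    shift: float

    @property
    def atom_class(self) -> str:
        return "carbon" if self.atom in CARBON_ATOMS else "proton"


@dataclass
class RestraintSet:
    """Subset of a shift table used as the selection objective target."""

    restraints: list[Restraint]

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    @property
    def atom_classes(self) -> list[str]:
        return [r.atom_class for r in self.restraints]

    def keys(self) -> list[tuple[int, str]]:
        return [(r.residue_number, r.atom) for r in self.restraints]


@dataclass
class RandomCoilReference:
    """Per (residue_name, atom) random-coil shift in ppm, with provenance."""

    values: dict[tuple[str, str], float]
    provenance: str = "unspecified"

    def get(self, residue_name: str, atom: str) -> float:
        key = (residue_name.upper(), atom)
        try:
            return self.values[key]
        except KeyError:
            raise KeyError(
                f"no random-coil reference for residue {residue_name!r} atom {atom!r}"
            ) from None

    def has(self, residue_name: str, atom: str) -> bool:
        return (residue_name.upper(), atom) in self.values


@dataclass(frozen=True)
class CSIRecord:
    """Secondary-shift index for one residue: (dCA_obs-dCA_ref)-(dCB_obs-dCB_ref)."""

    residue_number: int
    residue_name: str
    value: float
    label: str  # "helix" | "sheet" | "none"


def _parse_float(text: str, line_no: int, column: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"non-numeric {column} {text!r} on line {line_no}") from None


def read_shift_table(path: str | Path) -> ShiftTable:
    """Read a shift CSV (residue_number,residue_name,atom,shift_ppm,uncertainty_ppm).

    The uncertainty column may be empty.  Duplicate (residue, atom) pairs are
    rejected with both offending line numbers.
    """
    path = Path(path)
    entries: list[ShiftEntry] = []
    seen: dict[tuple[int, str], int] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"residue_number", "residue_name", "atom", "shift_ppm"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: header must contain {sorted(required)}, got {reader.fieldnames}"
            )
        for line_no, row in enumerate(reader, start=2):
            resnum = int(row["residue_number"])
            atom = row["atom"].strip()
            key = (resnum, atom)
            if key in seen:
                raise ValueError(
                    f"{path}: duplicate entry for residue {resnum} atom {atom} "
                    f"(lines {seen[key]} and {line_no})"
                )
            seen[key] = line_no
            unc_text = (row.get("uncertainty_ppm") or "").strip()
            entries.append(
                ShiftEntry(
                    residue_number=resnum,
                    residue_name=row["residue_name"].strip().upper(),
                    atom=atom,
                    shift=_parse_float(row["shift_ppm"], line_no, "shift"),
                    uncertainty=None if not unc_text else _parse_float(unc_text, line_no, "uncertainty"),
                )
            )
    return ShiftTable(entries)


def write_shift_table(table: ShiftTable, path: str | Path) -> None:
    """Write a shift table as CSV; round-trips exactly through read_shift_table."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["residue_number", "residue_name", "atom", "shift_ppm", "uncertainty_ppm"])
        for e in table.entries:
            writer.writerow(
                [
                    e.residue_number,
                    e.residue_name,
                    e.atom,
                    repr(e.shift),
                    "" if e.uncertainty is None else repr(e.uncertainty),
                ]
            )


def select_restraints(
    table: ShiftTable,
    atoms: Iterable[str],
    excluded_residues: Iterable[int] = (),
) -> RestraintSet:
    """Keep table entries whose atom is in `atoms` and residue not excluded.

    An empty atom set yields an empty (legal) restraint set.
    """
    atom_set = frozenset(atoms)
    excluded = frozenset(excluded_residues)
    restraints = [
        Restraint(e.residue_number, e.atom, e.shift)
        for e in table.entries
        if e.atom in atom_set and e.residue_number not in excluded
    ]
    return RestraintSet(restraints)


def chemical_shift_index(
    table: ShiftTable,
    reference: RandomCoilReference,
    threshold: float = 1.0,
) -> list[CSIRecord]:
    """Secondary-shift index per residue with both CA and CB measured.

    value = (dCA_obs - dCA_ref) - (dCB_obs - dCB_ref); labelled "helix" above
    +threshold, "sheet" below -threshold, "none" otherwise.  Glycine (no CB)
    and residues missing either observation are skipped.  A residue with both
    observations but no reference pair raises KeyError naming the gap.
    """
    records: list[CSIRecord] = []
    for resnum in table.residues():
        ca = table.get(resnum, "CA")
        cb = table.get(resnum, "CB")
        if ca is None or cb is None:
            continue  # Gly has no CB; partially assigned residues are skipped
        name = table.residue_name(resnum)
        value = (ca - reference.get(name, "CA")) - (cb - reference.get(name, "CB"))
        if value > threshold:
            label = "helix"
        elif value < -threshold:
            label = "sheet"
        else:
            label = "none"
        records.append(CSIRecord(resnum, name, value, label))
    return records


def load_random_coil_reference(path: str | Path | None = None) -> RandomCoilReference:
    """Load the random-coil reference; defaults to the packaged Wishart-style set."""
    if path is None:
        source = resources.files("memnmr.data") / "random_coil_wishart.csv"
        provenance = "packaged Wishart-style random-coil values"
        text = source.read_text()
    else:
        text = Path(path).read_text()
        provenance = str(path)
    values: dict[tuple[str, str], float] = {}
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    reader = csv.DictReader(lines)
    for row in reader:
        values[(row["residue_name"].upper(), row["atom"])] = float(row["shift_ppm"])
    return RandomCoilReference(values=values, provenance=provenance)


def packaged_shift_table_path() -> Path:
    """Path of the packaged experimental ghrelin shift table."""
    return Path(str(resources.files("memnmr.data") / "ghrelin_shifts.csv"))
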