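"""PPII-aware secondary structure: overlay on DSSP strings, ensemble composition.

DSSP itself is not re-implemented; assignments come either from classic .dssp
output files or from a documented torsion-only fallback for synthetic pools
that carry backbone atoms only.  The overlay relabels coil residues ('-') as
polyproline II ('P') when their phi/psi fall in the PPII window and the same
holds for at least one sequence neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SS_SYMBOLS",
    "PPIIRule",
    "SSAssignment",
    "ppii_overlay",
    "ss_composition",
    "ramachandran_export",
    "torsion_ss",
    "read_dssp",
]

SS_SYMBOLS = frozenset("HGIEBTS-P")


@dataclass
class PPIIRule:
    """PPII torsion windows (degrees) and minimum run length."""

    phi_center: float = -75.0
    phi_halfwidth: float = 29.0
    psi_center: float = 145.0
    psi_halfwidth: float = 29.0
    min_run: int = 2

    def __post_init__(self) -> None:
        if self.phi_halfwidth <= 0 or self.psi_halfwidth <= 0:
            raise ValueError("halfwidths must be > 0")
        if self.min_run < 2:
            raise ValueError("min_run must be >= 2")

    def in_window(self, phi: float, psi: float) -> bool:
        if not (np.isfinite(phi) and np.isfinite(psi)):
            return False
        return (
            abs(phi - self.phi_center) <= self.phi_halfwidth
            and abs(psi - self.psi_center) <= self.psi_halfwidth
        )


@dataclass
class SSAssignment:
    symbols: str
    source: str = "torsion-only"  # or "external-dssp"

    def __post_init__(self) -> None:
        bad = set(self.symbols) - SS_SYMBOLS
        if bad:
            raise ValueError(f"unknown secondary-structure symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.symbols)


def ppii_overlay(
    assignment: SSAssignment | str,
    phi: Sequence[float],
    psi: Sequence[float],
    rule: PPIIRule | None = None,
) -> SSAssignment:
    """Relabel coil residues as 'P' where the PPII conditions hold pairwise.

    A residue becomes 'P' iff it is '-' with phi/psi inside the windows AND at
    least one neighbour (i-1 or i+1) also satisfies all three conditions.
    Residues with undefined (NaN) torsions are never eligible; every other
    symbol is left untouched.  Idempotent.
    """
    rule = rule or PPIIRule()
    symbols = assignment.symbols if isinstance(assignment, SSAssignment) else assignment
    source = assignment.source if isinstance(assignment, SSAssignment) else "torsion-only"
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n = len(symbols)
    if phi.shape != (n,) or psi.shape != (n,):
        raise ValueError("torsion arrays must match assignment length")
    eligible = [
        (symbols[i] in "-P") and rule.in_window(phi[i], psi[i]) for i in range(n)
    ]
    out = []
    for i, sym in enumerate(symbols):
        left = eligible[i - 1] if i > 0 else False
        right = eligible[i + 1] if i < n - 1 else False
        if eligible[i] and (left or right):
            out.append("P")
        elif sym == "P":
            out.append("-")  # a lone 'P' from an earlier overlay would no longer qualify
        else:
            out.append(sym)
    return SSAssignment("".join(out), source=source)


_CLASSES = {
    "coil": frozenset("-"),
    "turn_bend": frozenset("TS"),
    "helix": frozenset("HGP"),
    "other": frozenset("IEB"),
}


def ss_composition(assignments: Sequence[SSAssignment | str]) -> pd.DataFrame:
    """Per-position class frequencies over an ensemble of assignments.

    Classes: coil ('-'), turn_bend ('T'/'S'), helix ('H'/'G'/'P'), other.
    Fractions sum to 1 at every position.
    """
    if not assignments:
        raise ValueError("no assignments given")
    strings = [a.symbols if isinstance(a, SSAssignment) else a for a in assignments]
    n = len(strings[0])
    if any(len(s) != n for s in strings):
        raise ValueError("assignments differ in length")
    rows = []
    for pos in range(n):
        counts = {name: 0 for name in _CLASSES}
        for s in strings:
            for name, members in _CLASSES.items():
                if s[pos] in members:
                    counts[name] += 1
                    break
        row = {"position": pos + 1}
        row.update({name: counts[name] / len(strings) for name in _CLASSES})
        rows.append(row)
    return pd.DataFrame(rows)


def ramachandran_export(
    models: Iterable, residue_ranges: Sequence[tuple[int, int]]
) -> pd.DataFrame:
    """Flat (range label, model_id, residue, phi, psi) table for plotting.

    Ranges are inclusive 1-based (start, end) pairs; undefined terminal
    torsions are exported as NaN.
    """
    models = list(models)
    rows = []
    for lo, hi in residue_ranges:
        if lo > hi:
            raise ValueError(f"empty residue range ({lo}, {hi})")
        label = f"{lo}-{hi}"
        for m in models:
            if hi > m.n_residues or lo < 1:
                raise ValueError(f"range ({lo}, {hi}) outside model of {m.n_residues} residues")
            for i in range(lo - 1, hi):
                rows.append(
                    {
                        "range": label,
                        "model_id": m.model_id,
                        "residue": i + 1,
                        "phi": float(m.torsions[i, 0]),
                        "psi": float(m.torsions[i, 1]),
                    }
                )
    if not rows:
        raise ValueError("no residues exported")
    return pd.DataFrame(rows)


def torsion_ss(phi: Sequence[float], psi: Sequence[float]) -> SSAssignment:
    """Coarse torsion-only assignment: 'H' in the alpha basin, 'E' for clear
    beta-strand torsions, '-' elsewhere.

    The strand window deliberately excludes the PPII region (phi around -75)
    so the PPII overlay sees those residues as coil.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    out = []
    for f, s in zip(phi, psi):
        if not (np.isfinite(f) and np.isfinite(s)):
            out.append("-")
        elif -100.0 <= f <= -30.0 and -77.0 <= s <= -17.0:
            out.append("H")
        elif -170.0 <= f <= -110.0 and 110.0 <= s <= 180.0:
            out.append("E")
        else:
            out.append("-")
    return SSAssignment("".join(out), source="torsion-only")


def read_dssp(path: str | Path) -> SSAssignment:
    """Read per-residue symbols from a classic DSSP output file.

    Parses the fixed-column data block (symbol at column 17); blank symbols
    become '-'.  Chain breaks ('!') are skipped.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if ln.lstrip().startswith("#  RESIDUE"))
    except StopIteration:
        raise ValueError(f"{path}: no DSSP data header found") from None
    symbols = []
    for ln in lines[start + 1:]:
        if len(ln) < 17 or ln[13] == "!":
            continue
        ss = ln[16]
        symbols.append("-" if ss == " " else ss)
    return SSAssignment("".join(symbols), source="external-dssp")
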