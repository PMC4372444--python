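"""Conformer pools: backbone construction from torsions, pool I/O, filters.

Coordinates live in a membrane frame: +z is the bilayer normal and z=0 the
bilayer center.  Models carry backbone N/CA/C atoms only, a scalar energy
(lower is better) and per-(residue, atom) predicted shifts.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .shift_data import one_to_three, three_to_one

__all__ = [
    "IDEAL_GEOMETRY",
    "ConformerModel",
    "ModelPool",
    "FilterConfig",
    "build_backbone",
    "measure_torsions",
    "filter_membrane_contact",
    "filter_receptor_distance",
    "filter_energy_percentile",
    "write_pool",
    "read_pool",
]

# Ideal backbone geometry (lengths in Angstrom, angles in degrees).
IDEAL_GEOMETRY = {
    "N_CA": 1.458,
    "CA_C": 1.525,
    "C_N": 1.329,
    "N_CA_C": 111.2,
    "CA_C_N": 116.2,
    "C_N_CA": 121.7,
}


@dataclass
class ConformerModel:
    """One backbone conformer: torsions, N/CA/C coordinates, energy, shifts.

    torsions: (n_res, 3) array of phi/psi/omega in degrees; phi of the first
    and psi/omega entries that reference absent neighbours are carried but
    ignored by the builder.  coords: (n_res, 3, 3) with axis 1 = (N, CA, C).
    """

    model_id: int
    torsions: np.ndarray
    coords: np.ndarray
    energy: float
    predicted_shifts: dict[tuple[int, str], float] = field(default_factory=dict)
    ss_class: Optional[str] = None

    @property
    def n_residues(self) -> int:
        return self.torsions.shape[0]

    def ca_coords(self) -> np.ndarray:
        return self.coords[:, 1, :]


@dataclass
class ModelPool:
    models: list[ConformerModel]
    sequence: str
    provenance: str = ""

    def __post_init__(self) -> None:
        n = len(self.sequence)
        ids = [m.model_id for m in self.models]
        if len(set(ids)) != len(ids):
            raise ValueError("model_ids must be unique within a pool")
        for m in self.models:
            if m.n_residues != n:
                raise ValueError(
                    f"model {m.model_id} has {m.n_residues} residues, sequence has {n}"
                )

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def energies(self) -> np.ndarray:
        return np.array([m.energy for m in self.models], dtype=float)

    def subset(self, models: Sequence[ConformerModel], note: str) -> "ModelPool":
        provenance = f"{self.provenance}; {note}" if self.provenance else note
        return ModelPool(list(models), self.sequence, provenance)


@dataclass
class FilterConfig:
    """Thresholds for the three pool filters."""

    anchor_residue: int = 3
    slab_zmin: float = 12.0
    slab_zmax: float = 18.0
    receptor_min_distance: float = 5.0
    energy_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.slab_zmin < self.slab_zmax):
            raise ValueError("require 0 < slab_zmin < slab_zmax")
        if self.receptor_min_distance <= 0:
            raise ValueError("receptor_min_distance must be > 0")


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement of atom d given chain a-b-c, |cd|, angle(b,c,d), dihedral(a,b,c,d)."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(dihedral),
            bond * math.sin(angle) * math.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(torsions: np.ndarray, n_residues: Optional[int] = None) -> np.ndarray:
    """Build N/CA/C coordinates from per-residue (phi, psi, omega) degrees.

    Ideal bond lengths/angles; the first residue is placed at the origin with
    CA on +x.  phi[0] is undefined and ignored, as are psi/omega entries that
    would place atoms of a non-existent next residue.  Returns (n, 3, 3).
    """
    torsions = np.asarray(torsions, dtype=float)
    if torsions.ndim != 2 or torsions.shape[1] != 3:
        raise ValueError("torsions must have shape (n_residues, 3)")
    # Only torsions that place atoms are checked: phi[0], psi[-1], omega[0]
    # reference absent neighbours and may be NaN (e.g. from measure_torsions).
    used = np.concatenate([torsions[1:, 0], torsions[:-1, 1], torsions[1:, 2]])
    if not np.all(np.isfinite(used)):
        raise ValueError("non-finite torsion angle")
    n = torsions.shape[0] if n_residues is None else n_residues
    if n != torsions.shape[0]:
        raise ValueError("n_residues does not match torsion count")
    g = IDEAL_GEOMETRY
    coords = np.zeros((n, 3, 3))
    # First residue: N at origin, CA on +x, C in the xy-plane.
    coords[0, 0] = np.array([0.0, 0.0, 0.0])
    coords[0, 1] = np.array([g["N_CA"], 0.0, 0.0])
    theta = math.radians(180.0 - g["N_CA_C"])
    coords[0, 2] = coords[0, 1] + g["CA_C"] * np.array(
        [math.cos(theta), math.sin(theta), 0.0]
    )
    for i in range(1, n):
        phi_i = torsions[i, 0]
        psi_prev = torsions[i - 1, 1]
        omega_i = torsions[i, 2]
        n_prev, ca_prev, c_prev = coords[i - 1]
        # N(i): dihedral psi(i-1) about N(i-1)-CA(i-1)-C(i-1)
        coords[i, 0] = _place_atom(n_prev, ca_prev, c_prev, g["C_N"], g["CA_C_N"], psi_prev)
        # CA(i): dihedral omega(i) about CA(i-1)-C(i-1)-N(i)
        coords[i, 1] = _place_atom(ca_prev, c_prev, coords[i, 0], g["N_CA"], g["C_N_CA"], omega_i)
        # C(i): dihedral phi(i) about C(i-1)-N(i)-CA(i)
        coords[i, 2] = _place_atom(c_prev, coords[i, 0], coords[i, 1], g["CA_C"], g["N_CA_C"], phi_i)
    return coords


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def measure_torsions(coords: np.ndarray) -> np.ndarray:
    """Recover (phi, psi, omega) degrees from N/CA/C coordinates; NaN where undefined."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    out = np.full((n, 3), np.nan)
    for i in range(n):
        n_i, ca_i, c_i = coords[i]
        if i > 0:
            c_prev = coords[i - 1, 2]
            ca_prev = coords[i - 1, 1]
            out[i, 0] = _dihedral(c_prev, n_i, ca_i, c_i)  # phi
            out[i, 2] = _dihedral(ca_prev, c_prev, n_i, ca_i)  # omega
        if i < n - 1:
            n_next = coords[i + 1, 0]
            out[i, 1] = _dihedral(n_i, ca_i, c_i, n_next)  # psi
    return out


def filter_membrane_contact(pool: ModelPool, cfg: FilterConfig) -> ModelPool:
    """Keep models whose anchor-residue CA depth satisfies zmin <= |z| <= zmax."""
    idx = cfg.anchor_residue - 1
    if not (0 <= idx < len(pool.sequence)):
        raise ValueError(f"anchor residue {cfg.anchor_residue} outside sequence")
    kept = []
    for m in pool.models:
        z = abs(float(m.coords[idx, 1, 2]))
        if cfg.slab_zmin <= z <= cfg.slab_zmax:
            kept.append(m)
    return pool.subset(kept, f"membrane slab [{cfg.slab_zmin}, {cfg.slab_zmax}] A")


def filter_receptor_distance(
    pool: ModelPool, receptor_coordinates: np.ndarray, cfg: FilterConfig
) -> ModelPool:
    """Keep models with min peptide-atom-to-receptor-atom distance >= threshold."""
    receptor = np.asarray(receptor_coordinates, dtype=float).reshape(-1, 3)
    if receptor.size == 0:
        raise ValueError("receptor coordinate set is empty; filter undefined")
    kept = []
    for m in pool.models:
        atoms = m.coords.reshape(-1, 3)
        d2 = np.sum((atoms[:, None, :] - receptor[None, :, :]) ** 2, axis=-1)
        if math.sqrt(float(d2.min())) >= cfg.receptor_min_distance:
            kept.append(m)
    return pool.subset(kept, f"receptor clearance >= {cfg.receptor_min_distance} A")


def filter_energy_percentile(
    pool: ModelPool, cfg: FilterConfig, reference_pool: Optional[ModelPool] = None
) -> ModelPool:
    """Keep models within the lowest-energy fraction of the reference pool.

    Threshold is the energy at the ceil(fraction*N)-th lowest position of the
    reference energies; ties at the threshold are kept.
    """
    if not (0 < cfg.energy_fraction <= 1):
        raise ValueError("energy_fraction must be in (0, 1]")
    reference = reference_pool if reference_pool is not None else pool
    if len(reference) == 0:
        raise ValueError("reference pool is empty")
    energies = np.sort(reference.energies())
    k = math.ceil(cfg.energy_fraction * len(energies))
    threshold = energies[k - 1]
    kept = [m for m in pool.models if m.energy <= threshold]
    return pool.subset(kept, f"energy <= {threshold:.6g} (lowest {cfg.energy_fraction:.0%})")


# ---------------------------------------------------------------------------
# Pool I/O: multi-model PDB + energies TSV + predicted-shifts CSV


def write_pool(pool: ModelPool, pdb_path: str | Path,
               energies_path: str | Path | None = None,
               shifts_path: str | Path | None = None) -> None:
    """Write a pool as multi-model PDB plus optional energy TSV / shifts CSV."""
    pdb_path = Path(pdb_path)
    atom_names = ("N", "CA", "C")
    with pdb_path.open("w") as fh:
        fh.write(f"REMARK   6 memnmr pool sequence={pool.sequence}\n")
        for m in pool.models:
            fh.write(f"MODEL     {m.model_id:4d}\n")
            serial = 1
            for i, letter in enumerate(pool.sequence):
                resname = one_to_three(letter)
                for j, aname in enumerate(atom_names):
                    x, y, z = m.coords[i, j]
                    element = aname[0]
                    name_field = (" " + aname).ljust(4)  # short names start in column 14
                    fh.write(
                        f"ATOM  {serial:5d} {name_field} {resname:>3s} A{i + 1:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {element:>2s}\n"
                    )
                    serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")
    if energies_path is not None:
        with Path(energies_path).open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["model_id", "energy"])
            for m in pool.models:
                writer.writerow([m.model_id, repr(m.energy)])
    if shifts_path is not None:
        with Path(shifts_path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["model_id", "residue_number", "residue_name", "atom", "shift_ppm"])
            for m in pool.models:
                for (resnum, atom), value in sorted(m.predicted_shifts.items()):
                    resname = one_to_three(pool.sequence[resnum - 1])
                    writer.writerow([m.model_id, resnum, resname, atom, repr(value)])


def read_pool(pdb_path: str | Path,
              energies_path: str | Path | None = None,
              shifts_path: str | Path | None = None) -> ModelPool:
    """Read a pool written by write_pool (or any backbone multi-model PDB)."""
    from Bio.PDB import PDBParser

    pdb_path = Path(pdb_path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("pool", str(pdb_path))
    energies: dict[int, float] = {}
    if energies_path is not None:
        with Path(energies_path).open(newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                energies[int(row["model_id"])] = float(row["energy"])
    shifts: dict[int, dict[tuple[int, str], float]] = {}
    if shifts_path is not None:
        with Path(shifts_path).open(newline="") as fh:
            for row in csv.DictReader(fh):
                mid = int(row["model_id"])
                shifts.setdefault(mid, {})[(int(row["residue_number"]), row["atom"])] = float(
                    row["shift_ppm"]
                )
    models: list[ConformerModel] = []
    sequence = ""
    for bio_model in structure:
        chain = next(iter(bio_model))
        residues = [r for r in chain]
        letters = [three_to_one(r.get_resname()) for r in residues]
        sequence = "".join(letters)
        coords = np.zeros((len(residues), 3, 3))
        for i, res in enumerate(residues):
            for j, aname in enumerate(("N", "CA", "C")):
                coords[i, j] = res[aname].get_coord()
        serial = bio_model.serial_num if bio_model.serial_num else bio_model.id + 1
        models.append(
            ConformerModel(
                model_id=serial,
                torsions=measure_torsions(coords),
                coords=coords,
                energy=energies.get(serial, float("nan")),
                predicted_shifts=shifts.get(serial, {}),
            )
        )
    return ModelPool(models, sequence, provenance=str(pdb_path))
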