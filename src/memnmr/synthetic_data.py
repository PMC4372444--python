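"""Seeded generators standing in for the external folding/prediction tools.

Everything here is a pure function of its arguments plus a seed, so every
downstream stage (filters, ensemble selection, isotherm fitting, spin
diffusion) can be exercised offline with known ground truth.  The toy shift
predictor is deliberately linear: random-coil base value + secondary-
structure-class offset + Gaussian noise, which gives ensemble-selection
recovery tests an analytically known optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import conformers
from .conformers import ConformerModel, ModelPool
from .membrane_binding import BindingMeasurement, ThermoConfig
from .nmr_dynamics import BuildupCurve, LatticeSpec, simulate_lattice
from .shift_data import (
    RandomCoilReference,
    ShiftEntry,
    ShiftTable,
    load_random_coil_reference,
    one_to_three,
)

__all__ = [
    "GHRELIN_SEQUENCE",
    "PoolRecipe",
    "ToyShiftModel",
    "gen_pool",
    "gen_experimental_shifts",
    "gen_binding_data",
    "gen_buildup",
]

GHRELIN_SEQUENCE = "GSSFLSPEHQRVQQRKESKKPPAKLQPR"

# Ideal-basin torsions per class (phi, psi); omega is always trans.
_CLASS_TORSIONS = {"helix": (-57.0, -47.0), "ppii": (-75.0, 145.0)}
_CLASSES = ("helix", "ppii", "coil")


@dataclass
class PoolRecipe:
    n_models: int
    sequence: str = GHRELIN_SEQUENCE
    class_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)  # helix, ppii, coil
    torsion_sigma: float = 8.0  # degrees
    shift_sigma: float = 0.3  # ppm
    anchor_residue: int = 3
    z_range: tuple[float, float] = (0.0, 30.0)  # Angstrom, uniform |z| draw
    energy_model: dict = field(
        default_factory=lambda: {
            "helix": (-50.0, 5.0),
            "ppii": (-45.0, 5.0),
            "coil": (-40.0, 5.0),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix fractions must sum to 1")
        if any(f < 0 for f in self.class_mix):
            raise ValueError("class_mix fractions must be >= 0")


@dataclass
class ToyShiftModel:
    """Linear toy predictor: random-coil base + class offset + noise."""

    reference: RandomCoilReference = field(default_factory=load_random_coil_reference)
    helix_offsets: dict = field(default_factory=lambda: {"CA": 2.5, "CB": -0.5})
    ppii_offsets: dict = field(default_factory=dict)
    coil_offsets: dict = field(default_factory=dict)
    noise_sigma: float = 0.3
    atoms: tuple[str, ...] = ("CO", "CA", "CB", "HA")

    def offsets_for(self, ss_class: str) -> dict:
        return {"helix": self.helix_offsets, "ppii": self.ppii_offsets}.get(
            ss_class, self.coil_offsets
        )

    def predict(
        self, sequence: str, ss_class: str, rng: np.random.Generator
    ) -> dict[tuple[int, str], float]:
        offsets = self.offsets_for(ss_class)
        shifts: dict[tuple[int, str], float] = {}
        for i, letter in enumerate(sequence, start=1):
            resname = one_to_three(letter)
            for atom in self.atoms:
                if not self.reference.has(resname, atom):
                    continue  # e.g. Gly CB
                base = self.reference.get(resname, atom)
                value = base + offsets.get(atom, 0.0)
                if self.noise_sigma > 0:
                    value += rng.normal(0.0, self.noise_sigma)
                shifts[(i, atom)] = value
        return shifts


def gen_pool(recipe: PoolRecipe, shift_model: Optional[ToyShiftModel] = None) -> ModelPool:
    """Generate a seeded conformer pool with coordinates, energies and shifts.

    Per model: a class is drawn from the mix; torsions are the class basin
    plus Gaussian noise (coil draws broadly); the backbone is built with
    ideal geometry and rigidly translated so the anchor CA sits at a z drawn
    uniformly from z_range.  Identical recipes give identical pools.
    """
    rng = np.random.default_rng(recipe.seed)
    if shift_model is None:
        shift_model = ToyShiftModel(noise_sigma=recipe.shift_sigma)
    n_res = len(recipe.sequence)
    anchor = recipe.anchor_residue - 1
    if not (0 <= anchor < n_res):
        raise ValueError("anchor residue outside the sequence")
    models = []
    for model_id in range(1, recipe.n_models + 1):
        ss_class = _CLASSES[rng.choice(3, p=recipe.class_mix)]
        torsions = np.empty((n_res, 3))
        if ss_class == "coil":
            torsions[:, 0] = rng.uniform(-160.0, -50.0, size=n_res)
            torsions[:, 1] = rng.uniform(-60.0, 170.0, size=n_res)
        else:
            phi0, psi0 = _CLASS_TORSIONS[ss_class]
            torsions[:, 0] = phi0
            torsions[:, 1] = psi0
        torsions[:, 2] = 180.0
        if recipe.torsion_sigma > 0:
            torsions[:, :2] += rng.normal(0.0, recipe.torsion_sigma, size=(n_res, 2))
        torsions[:, :2] = ((torsions[:, :2] + 180.0) % 360.0) - 180.0
        coords = conformers.build_backbone(torsions)
        z_target = rng.uniform(*recipe.z_range)
        coords = coords + np.array([0.0, 0.0, z_target - coords[anchor, 1, 2]])
        mean, sigma = recipe.energy_model[ss_class]
        energy = float(rng.normal(mean, sigma))
        shifts = shift_model.predict(recipe.sequence, ss_class, rng)
        models.append(
            ConformerModel(
                model_id=model_id,
                torsions=torsions,
                coords=coords,
                energy=energy,
                predicted_shifts=shifts,
                ss_class=ss_class,
            )
        )
    return ModelPool(models, recipe.sequence, provenance=f"synthetic pool seed={recipe.seed}")


def gen_experimental_shifts(
    models: Sequence[ConformerModel],
    sequence: str,
    atoms: Sequence[str] = ("CO", "CA", "CB", "HA"),
    noise_sigma: float = 0.1,
    seed: int = 0,
    excluded_residues: Sequence[int] = (),
) -> ShiftTable:
    """Ground-truth table: per-atom mean over a model subset plus noise.

    Only keys predicted by every model in the subset are emitted; a key
    present in some but not all models raises.
    """
    if not models:
        raise ValueError("model subset is empty")
    rng = np.random.default_rng(seed)
    excluded = set(excluded_residues)
    keys = []
    for i in range(1, len(sequence) + 1):
        if i in excluded:
            continue
        for atom in atoms:
            present = [(i, atom) in m.predicted_shifts for m in models]
            if all(present):
                keys.append((i, atom))
            elif any(present):
                raise KeyError(
                    f"residue {i} atom {atom} predicted by only part of the subset"
                )
    entries = []
    for resnum, atom in keys:
        mean = sum(m.predicted_shifts[(resnum, atom)] for m in models) / len(models)
        value = mean + (rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0)
        entries.append(
            ShiftEntry(
                residue_number=resnum,
                residue_name=one_to_three(sequence[resnum - 1]),
                atom=atom,
                shift=value,
                uncertainty=noise_sigma if noise_sigma > 0 else None,
            )
        )
    return ShiftTable(entries)


def gen_binding_data(
    kd_mm: float,
    bmax: float,
    lipid_concs_mm: Sequence[float],
    noise_sigma: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
    cfg: Optional[ThermoConfig] = None,
) -> list[BindingMeasurement]:
    """Synthetic assay: hyperbolic isotherm on the effective-lipid scale.

    kd_mm is the dissociation constant against effective lipid (mM).  The
    bound fraction (plus noise, clipped to [0, 1]) is converted to
    supernatant/pellet intensities with I_sup + I_pel = 1.
    """
    if kd_mm <= 0:
        raise ValueError("K_D must be > 0")
    cfg = cfg or ThermoConfig()
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(1, replicates + 1):
        for lipid in lipid_concs_mm:
            l_eff = lipid * cfg.effective_lipid_factor
            frac = bmax * l_eff / (kd_mm + l_eff)
            if noise_sigma > 0:
                frac += rng.normal(0.0, noise_sigma)
            frac = min(max(frac, 0.0), 1.0)
            out.append(
                BindingMeasurement(
                    lipid_total=float(lipid),
                    i_supernatant=1.0 - frac,
                    i_pellet=frac,
                    replicate=rep,
                )
            )
    return out


def gen_buildup(
    steps: int,
    omega: float,
    t_list: Sequence[float],
    noise_sigma: float = 0.0,
    t1: float = math.inf,
    seed: int = 0,
    n_pad: int = 2,
    normalization_time: float = 0.900,
) -> BuildupCurve:
    """Synthetic site-n buildup trace with T1 decay and noise re-applied.

    This is the inverse of correct_and_normalize: the clean lattice trace is
    multiplied by exp(-t/T1) and Gaussian noise is added.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    t = np.asarray(t_list, dtype=float)
    spec = LatticeSpec(n_sites=steps + n_pad, omega=omega)
    sim = simulate_lattice(spec, t)[:, steps]
    intensities = sim * np.exp(-t / t1)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensities = intensities + rng.normal(0.0, noise_sigma, size=t.shape)
    return BuildupCurve(
        mixing_times=t,
        intensities=intensities,
        t1=t1,
        normalization_time=normalization_time,
    )
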