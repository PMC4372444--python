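"""Membrane-binding assay analysis: %bound, isotherm fit, thermodynamics, charge.

The fraction of bound peptide comes from supernatant/pellet fluorescence;
lipid concentrations are reduced to the peptide-accessible pool by a fixed
effective-lipid factor.  The dissociation constant is converted to a standard
binding free energy on the mole-fraction scale ([W] = 55.5 M), the convention
under which a hyperbolic isotherm and a simple partition model are mutually
consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BindingMeasurement",
    "IsothermFit",
    "ThermoConfig",
    "ChargeConfig",
    "percent_bound",
    "effective_lipid",
    "fit_isotherm",
    "delta_g_from_kd",
    "partition_fraction",
    "net_charge",
    "binding_energy_total",
]

GAS_CONSTANT = 8.314  # J/(mol K)
WATER_MOLARITY = 55.5  # mol/L


@dataclass(frozen=True)
class BindingMeasurement:
    """One assay point: total lipid (mM) and the two fluorescence readings."""

    lipid_total: float
    i_supernatant: float
    i_pellet: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.lipid_total < 0:
            raise ValueError("lipid_total must be >= 0")
        if self.i_supernatant < 0 or self.i_pellet < 0:
            raise ValueError("intensities must be >= 0")


@dataclass
class ThermoConfig:
    temperature: float = 310.15  # K
    water_molarity: float = WATER_MOLARITY  # M
    gas_constant: float = GAS_CONSTANT  # J/(mol K)
    effective_lipid_factor: float = 0.45

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


# Conventional side-chain and terminal pKa values; user-overridable.
DEFAULT_PKA = {
    "R": 12.5,
    "K": 10.5,
    "H": 6.5,
    "E": 4.25,
    "D": 3.65,
    "Y": 10.1,
    "C": 8.3,
}
BASIC_GROUPS = frozenset("RKH")
ACIDIC_GROUPS = frozenset("EDYC")


@dataclass
class ChargeConfig:
    pka: dict = field(default_factory=lambda: dict(DEFAULT_PKA))
    pka_nterm: float = 9.0
    pka_cterm: float = 3.6
    ph: float = 7.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ph <= 14.0):
            raise ValueError("pH must be in [0, 14]")


def percent_bound(m: BindingMeasurement) -> float:
    """Bound peptide percentage: (1 - I_sup / (I_sup + I_pel)) * 100."""
    total = m.i_supernatant + m.i_pellet
    if total <= 0:
        raise ValueError("supernatant and pellet intensities are both zero")
    return (1.0 - m.i_supernatant / total) * 100.0


def effective_lipid(lipid_total: float, cfg: ThermoConfig | None = None) -> float:
    """Peptide-accessible lipid concentration: total times the 0.45 factor."""
    cfg = cfg or ThermoConfig()
    if lipid_total < 0:
        raise ValueError("lipid_total must be >= 0")
    return lipid_total * cfg.effective_lipid_factor


@dataclass
class IsothermFit:
    """Hyperbolic single-site fit f(L) = Bmax * L / (K_D + L)."""

    kd: float  # same units as the input L (mM)
    kd_se: float
    bmax: float
    bmax_se: float
    sse: float
    n_points: int

    @property
    def kd_uM(self) -> float:
        return self.kd * 1000.0


def _hyperbola(L, bmax, kd):
    return bmax * L / (kd + L)


def fit_isotherm(points: Sequence[tuple[float, float]]) -> IsothermFit:
    """Nonlinear least squares of fraction bound vs effective lipid (mM).

    Requires at least 4 distinct lipid concentrations; Bmax is constrained to
    (0, 1] and K_D to positive values.  Standard errors come from the fit
    covariance.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (L, fraction) pairs")
    L, f = pts[:, 0], pts[:, 1]
    if len(np.unique(L)) < 4:
        raise ValueError("need >= 4 distinct lipid concentrations to identify the fit")
    if np.allclose(f, 0.0):
        raise ValueError("all fractions are zero; nothing to fit")
    p0 = (min(max(float(f.max()), 0.05), 1.0), max(float(np.median(L[L > 0])), 1e-6))
    try:
        popt, pcov = curve_fit(
            _hyperbola,
            L,
            f,
            p0=p0,
            bounds=([1e-12, 1e-12], [1.0, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"isotherm fit failed to converge: {err}") from err
    bmax, kd = popt
    perr = np.sqrt(np.diag(pcov))
    residuals = f - _hyperbola(L, *popt)
    return IsothermFit(
        kd=float(kd),
        kd_se=float(perr[1]),
        bmax=float(bmax),
        bmax_se=float(perr[0]),
        sse=float(residuals @ residuals),
        n_points=len(L),
    )


def delta_g_from_kd(kd_molar: float, cfg: ThermoConfig | None = None) -> float:
    """Standard binding free energy in kJ/mol, mole-fraction standard state.

    dG0 = R * T * ln(K_D / [W]) with [W] = 55.5 M, so K_D = 55.5 M gives 0.
    """
    cfg = cfg or ThermoConfig()
    if kd_molar <= 0:
        raise ValueError("K_D must be > 0")
    return cfg.gas_constant * cfg.temperature * math.log(kd_molar / cfg.water_molarity) / 1000.0


def partition_fraction(
    delta_g_kj_mol: float, l_eff_mm: float, cfg: ThermoConfig | None = None
) -> float:
    """Fraction bound from a mole-fraction partition coefficient.

    K_x = exp(-dG/(R T)); X_L = L_eff / (L_eff + [W]); f = K_x X_L / (1 + K_x X_L).
    """
    cfg = cfg or ThermoConfig()
    if l_eff_mm < 0:
        raise ValueError("effective lipid concentration must be >= 0")
    kx = math.exp(-delta_g_kj_mol * 1000.0 / (cfg.gas_constant * cfg.temperature))
    xl = (l_eff_mm / 1000.0) / (l_eff_mm / 1000.0 + cfg.water_molarity)
    return kx * xl / (1.0 + kx * xl)


def net_charge(sequence: str, cfg: ChargeConfig | None = None) -> float:
    """Henderson-Hasselbalch net charge of a peptide, termini included.

    Basic groups contribute +1/(1 + 10^(pH - pKa)), acidic groups
    -1/(1 + 10^(pKa - pH)).
    """
    cfg = cfg or ChargeConfig()
    if not sequence:
        raise ValueError("sequence is empty")
    seq = sequence.upper()
    standard = set("ACDEFGHIKLMNPQRSTVWY")
    unknown = set(seq) - standard
    if unknown:
        raise ValueError(f"unknown residue letters {sorted(unknown)}")
    ph = cfg.ph

    def basic(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pka))

    def acidic(pka: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pka - ph))

    charge = basic(cfg.pka_nterm) + acidic(cfg.pka_cterm)
    for letter in seq:
        if letter in BASIC_GROUPS:
            charge += basic(cfg.pka[letter])
        elif letter in ACIDIC_GROUPS:
            charge += acidic(cfg.pka[letter])
    return charge


def binding_energy_total(components: Sequence[float]) -> float:
    """Sum of binding-energy contributions (kJ/mol); empty list sums to 0."""
    comps = [float(c) for c in components]
    if any(not math.isfinite(c) for c in comps):
        raise ValueError("components must be finite")
    return float(sum(comps))
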