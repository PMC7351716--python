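"""Polymer conformation and capacity calculations.

Field-flow fractionation with light scattering yields, per polymer, a
weight-average molecular weight M_w, hydrodynamic radius R_h and gyration
radius R_g.  From these the module derives:

* the apparent hydrodynamic volume  V_app,h = (4/3)·π·R_h³,
* the apparent density              ρ_app,h = M_w / (V_app,h · N_A),
* the water mass fraction inside the coil, 1 − ρ_app,h/ρ_solution,
* the conformation scaling exponent ν of R_g = K·M^ν (log-log least
  squares over a fractionation series; ν ≈ 0.33 for a hard sphere,
  0.5 for a statistical chain in a theta solvent),
* the anchor-strand capacity in nmol hybridization sites per mg polymer
  and its utilization against a measured binding capacity.

Canonical units: radii in nm, volumes in µm³, M_w in g/mol, densities in
g/cm³ — explicit conversions, since source data mix nm, µm³ and MDa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence as _Seq

import numpy as np
from scipy import constants, stats

__all__ = [
    "N_A",
    "PolymerSpec",
    "ScalingSeries",
    "ScalingFit",
    "apparent_volume",
    "radius_from_volume",
    "apparent_density",
    "water_fraction",
    "fit_scaling_exponent",
    "theoretical_capacity",
    "capacity_utilization",
    "characterize",
]

N_A = constants.Avogadro  # 1/mol

_UM3_TO_CM3 = 1e-12  # 1 µm³ = 1e-12 cm³
_NM_TO_UM = 1e-3


@dataclass
class PolymerSpec:
    """Composition and measured conformation of one polymer variant.

    m/n/o are acrylate, acrylamide and anchor-strand units per chain; the
    remaining fields are fractionation-derived.  A scaling exponent
    outside (0.2, 0.8) is physically implausible and triggers a warning.
    """

    name: str
    m: "float | None" = None
    n: "float | None" = None
    o: "float | None" = None
    M_w: "float | None" = None  # g/mol
    R_h: "float | None" = None  # nm
    R_g: "float | None" = None  # nm
    nu: "float | None" = None
    K: "float | None" = None

    def __post_init__(self) -> None:
        for name in ("m", "n", "o", "M_w", "R_h", "R_g", "K"):
            v = getattr(self, name)
            if v is not None and v <= 0 and not (name == "o" and v == 0):
                raise ValueError(f"{self.name}: {name} must be positive, got {v}")
        if self.nu is not None and not 0.2 < self.nu < 0.8:
            warnings.warn(
                f"{self.name}: scaling exponent nu={self.nu} outside the plausible "
                "(0.2, 0.8) range",
                stacklevel=2,
            )


def apparent_volume(r_h_nm: float) -> float:
    """Apparent hydrodynamic volume in µm³ from R_h in nm: (4/3)·π·R_h³."""
    if r_h_nm <= 0:
        raise ValueError(f"hydrodynamic radius must be positive, got {r_h_nm}")
    return (4.0 / 3.0) * np.pi * (r_h_nm * _NM_TO_UM) ** 3


def radius_from_volume(v_um3: float) -> float:
    """Inverse of :func:`apparent_volume`: R_h in nm from V in µm³."""
    if v_um3 <= 0:
        raise ValueError(f"volume must be positive, got {v_um3}")
    return float((3.0 * v_um3 / (4.0 * np.pi)) ** (1.0 / 3.0) / _NM_TO_UM)


def apparent_density(m_w: float, v_um3: float) -> float:
    """Apparent density in g/cm³: ρ_app,h = M_w / (V_app,h · N_A)."""
    if m_w <= 0 or v_um3 <= 0:
        raise ValueError("M_w and V_app,h must be positive")
    return m_w / (v_um3 * _UM3_TO_CM3 * N_A)


def water_fraction(rho_app: float, rho_solution: float = 1.0) -> float:
    """Water mass percentage inside the coil: 100·(1 − ρ_app,h/ρ_solution)."""
    if rho_app <= 0:
        raise ValueError("apparent density must be positive")
    if rho_app >= rho_solution:
        raise ValueError(
            f"apparent density {rho_app} g/cm³ is not below the solution density "
            f"{rho_solution} g/cm³ — check units"
        )
    return 100.0 * (1.0 - rho_app / rho_solution)


@dataclass
class ScalingSeries:
    """(M, R_g) pairs from one fractionation run, masses strictly increasing."""

    masses: np.ndarray  # g/mol
    radii: np.ndarray  # nm

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if len(self.masses) != len(self.radii):
            raise ValueError("masses and radii must have equal length")
        if len(self.masses) < 3:
            raise ValueError("scaling series needs at least 3 points")
        if (self.masses <= 0).any() or (self.radii <= 0).any():
            raise ValueError("masses and radii must be positive")
        if not (np.diff(self.masses) > 0).all():
            raise ValueError("masses must be strictly increasing")


class ScalingFit(NamedTuple):
    nu: float
    K: float
    nu_stderr: float


def fit_scaling_exponent(series: ScalingSeries) -> ScalingFit:
    """Ordinary least squares on log R_g vs log M: slope = ν, exp(intercept) = K."""
    log_m = np.log(series.masses)
    log_r = np.log(series.radii)
    if np.ptp(log_m) == 0:
        raise ValueError("degenerate series: all masses equal")
    fit = stats.linregress(log_m, log_r)
    return ScalingFit(float(fit.slope), float(np.exp(fit.intercept)), float(fit.stderr))


def theoretical_capacity(o: float, chain_mass: float) -> float:
    """Anchor capacity in nmol hybridization sites per mg polymer.

    o anchors per chain of ``chain_mass`` g/mol give o/chain_mass mol/g,
    i.e. (o/chain_mass)·1e6 nmol/mg.
    """
    if o < 0:
        raise ValueError("anchor count must be >= 0")
    if chain_mass <= 0:
        raise ValueError("chain mass must be positive")
    return o / chain_mass * 1e6


def capacity_utilization(measured: float, theoretical: float) -> float:
    """Measured binding capacity as a percentage of the theoretical limit."""
    if theoretical <= 0:
        raise ValueError("theoretical capacity must be positive")
    return 100.0 * measured / theoretical


def characterize(spec: PolymerSpec, measured_capacity: "float | None" = None) -> dict:
    """Derive every quantity computable from the fields set on ``spec``."""
    report: dict = {"name": spec.name}
    v = None
    if spec.R_h is not None:
        v = apparent_volume(spec.R_h)
        report["V_app_h_um3"] = v
    if spec.M_w is not None and v is not None:
        rho = apparent_density(spec.M_w, v)
        report["rho_app_h_g_cm3"] = rho
        report["water_fraction_pct"] = water_fraction(rho)
    if spec.o is not None and spec.M_w is not None:
        cap = theoretical_capacity(spec.o, spec.M_w)
        report["theoretical_capacity_nmol_mg"] = cap
        if measured_capacity is not None:
            report["capacity_utilization_pct"] = capacity_utilization(measured_capacity, cap)
    if spec.nu is not None:
        report["nu"] = spec.nu
    return report
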