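"""Closed-form dielectrophoresis (DEP) force estimators and polarizability.

A polarizable particle in a non-uniform AC field experiences a
dielectrophoretic force whose sign and magnitude are set by the real part
of the Clausius-Mossotti (CM) factor, the frequency-dependent
polarizability contrast between particle and suspending medium.  This
module provides the homogeneous-sphere CM factor, its pDEP/nDEP crossover
frequency, and two closed-form force estimators:

* the equivalent-dipole-moment (EDM) force, proportional to the gradient
  of the squared field magnitude, and
* the parallel-plate ("simplified") tip-to-tip approximation, which takes
  the field as U/d over the electrode gap and the integration surface as
  the cell surface.

All quantities are strict SI; nanonewton/micrometre conversion happens
only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# Physical constants
# ---------------------------------------------------------------------------

#: Vacuum permittivity, F/m.
EPS0: float = 8.854e-12

#: Boltzmann constant, J/K.
KB: float = 1.380649e-23


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DielectricMaterial:
    """A linear, isotropic, lossy dielectric.

    Parameters
    ----------
    rel_permittivity : float
        Relative permittivity (dimensionless), >= 1 for physical media.
    conductivity : float
        Ohmic conductivity, S/m, >= 0.
    """

    rel_permittivity: float
    conductivity: float

    def __post_init__(self) -> None:
        if self.rel_permittivity < 1.0:
            raise ValueError(
                f"rel_permittivity must be >= 1, got {self.rel_permittivity}"
            )
        if self.conductivity < 0.0:
            raise ValueError(f"conductivity must be >= 0, got {self.conductivity}")


#: Low-conductivity isotonic stretching buffer (sucrose/dextrose).
DEFAULT_MEDIUM = DielectricMaterial(rel_permittivity=78.0, conductivity=5.29e-3)

#: Cytoplasm-like defaults for a leukaemia cell; configuration, not constants.
DEFAULT_CYTOPLASM = DielectricMaterial(rel_permittivity=60.0, conductivity=0.2)


@dataclass(frozen=True)
class CellDielectric:
    """Spherical cell approximated as a homogeneous dielectric sphere."""

    radius: float = 7e-6  # m
    cytoplasm: DielectricMaterial = field(default_factory=lambda: DEFAULT_CYTOPLASM)

    def __post_init__(self) -> None:
        if self.radius <= 0.0:
            raise ValueError(f"radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class Drive:
    """Sinusoidal drive: voltage amplitude (not peak-to-peak) and frequency."""

    voltage_amplitude: float  # V
    frequency: float  # Hz

    def __post_init__(self) -> None:
        if self.frequency <= 0.0:
            raise ValueError(f"frequency must be > 0, got {self.frequency}")

    @property
    def angular_frequency(self) -> float:
        """omega = 2*pi*f, rad/s."""
        return 2.0 * math.pi * self.frequency

    @classmethod
    def from_vpp(cls, v_pp: float, frequency: float) -> "Drive":
        """Build from a peak-to-peak voltage (amplitude = V_pp / 2)."""
        return cls(voltage_amplitude=v_pp / 2.0, frequency=frequency)

    @property
    def v_pp(self) -> float:
        return 2.0 * self.voltage_amplitude


@dataclass(frozen=True)
class CMResult:
    """Clausius-Mossotti factor K(omega) and its real part."""

    value: complex

    @property
    def real_part(self) -> float:
        return self.value.real


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def complex_conductivity(material: DielectricMaterial, omega: float) -> complex:
    """Complex conductivity sigma* = sigma + j*omega*eps0*eps_r, S/m.

    This is the coefficient of the quasi-electrostatic potential equation
    -div(sigma* grad phi) = 0.  The equivalent complex-permittivity
    convention eps* = eps0*eps_r - j*sigma/omega relates to it by
    sigma* = j*omega*eps*; this package uses sigma* for field solving and
    eps* for the CM factor, consistently.
    """
    if omega <= 0.0:
        raise ValueError(f"omega must be > 0, got {omega}")
    return material.conductivity + 1j * omega * EPS0 * material.rel_permittivity


def complex_permittivity(material: DielectricMaterial, omega: float) -> complex:
    """Complex permittivity eps* = eps0*eps_r - j*sigma/omega, F/m."""
    if omega <= 0.0:
        raise ValueError(f"omega must be > 0, got {omega}")
    return EPS0 * material.rel_permittivity - 1j * material.conductivity / omega


def clausius_mossotti(
    cell: CellDielectric, medium: DielectricMaterial, omega: float
) -> CMResult:
    """Homogeneous-sphere Clausius-Mossotti factor.

    K = (eps*_c - eps*_m) / (eps*_c + 2 eps*_m), with eps* the complex
    permittivity of cytoplasm (c) and medium (m).  Re[K] is bounded in
    [-0.5, 1] for physical inputs; positive Re[K] means pDEP (attraction
    toward field maxima), negative means nDEP.
    """
    eps_c = complex_permittivity(cell.cytoplasm, omega)
    eps_m = complex_permittivity(medium, omega)
    denom = eps_c + 2.0 * eps_m
    if denom == 0:
        raise ValueError("degenerate CM denominator: eps*_c + 2 eps*_m = 0")
    return CMResult(value=(eps_c - eps_m) / denom)


def crossover_frequency(
    cell: CellDielectric,
    medium: DielectricMaterial,
    f_lo: float,
    f_hi: float,
    tol: float = 1e-6,
) -> float | None:
    """Frequency in [f_lo, f_hi] where Re[K] changes sign, or None.

    Found by bisection on Re[K(2*pi*f)]; absence of a sign change between
    the bracket ends is a valid outcome (returns None).  ``tol`` bounds
    |Re[K]| at the returned frequency.
    """
    if not f_lo < f_hi:
        raise ValueError(f"need f_lo < f_hi, got {f_lo} >= {f_hi}")

    def re_k(f: float) -> float:
        return clausius_mossotti(cell, medium, 2.0 * math.pi * f).real_part

    a, b = f_lo, f_hi
    fa, fb = re_k(a), re_k(b)
    if fa == 0.0:
        return a
    if fb == 0.0:
        return b
    if fa * fb > 0.0:
        return None
    # bisection in log-frequency: Re[K] varies on decade scales
    la, lb = math.log(a), math.log(b)
    for _ in range(200):
        lm = 0.5 * (la + lb)
        fm = re_k(math.exp(lm))
        if abs(fm) < tol:
            return math.exp(lm)
        if fa * fm < 0.0:
            lb = lm
        else:
            la, fa = lm, fm
    return math.exp(0.5 * (la + lb))


def dep_force_edm(
    cell: CellDielectric,
    medium: DielectricMaterial,
    re_k: float,
    grad_e2: np.ndarray,
) -> np.ndarray:
    """Equivalent-dipole-moment DEP force, N.

    F = 2*pi*r^3*eps0*eps_m*Re[K]*grad(E^2), componentwise.  ``grad_e2``
    is the gradient of the mean-square field; when working with phasor
    amplitudes E0 the mean square is |E0|^2 / 2 (see
    :func:`cytostretch.field_solver.dep_force_edm_from_solution`).
    """
    grad_e2 = np.asarray(grad_e2, dtype=float)
    if not np.all(np.isfinite(grad_e2)) or not math.isfinite(re_k):
        raise ValueError("non-finite input to dep_force_edm")
    pref = 2.0 * math.pi * cell.radius**3 * EPS0 * medium.rel_permittivity * re_k
    return pref * grad_e2


def dep_force_simplified(
    drive: Drive,
    gap: float,
    cell: CellDielectric,
    medium: DielectricMaterial,
) -> float:
    """Tip-to-tip parallel-plate approximation of the DEP force, N.

    F = (1/4) eps0 eps_m (U/d)^2 A with U the voltage amplitude, d the
    electrode gap and A = 4*pi*r^2 the cell surface area.  Assumes the
    field inside the cell is negligible; frequency-independent, scales
    exactly as U^2.
    """
    if gap <= 0.0:
        raise ValueError(f"gap must be > 0, got {gap}")
    e_mag = drive.voltage_amplitude / gap
    area = 4.0 * math.pi * cell.radius**2
    return 0.25 * EPS0 * medium.rel_permittivity * e_mag**2 * area
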