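"""Quasi-electrostatic phasor field solver for the 2D side-view chip.

Solves -div((sigma + j*omega*eps0*eps) grad phi) = 0 on a uniform
Cartesian grid over the channel cross-section, with Dirichlet potentials
on the electrode segments, zero normal flux (insulation) on all other
boundaries, and an optional circular dielectric inclusion (the cell)
whose interface continuity is built into the conservative finite-volume
discretization via harmonic face averaging of the complex coefficient.

Post-processing provides the two field-based DEP force routes:

* ``grad_e2_at`` / ``dep_force_edm_from_solution`` -- the gradient of the
  mean-square field for the equivalent-dipole-moment estimate, probed at
  the cell centre of the particle-free solution;
* ``integrate_mst`` -- the time-averaged Maxwell stress tensor integrated
  over a circular contour on the medium side of the cell interface and
  multiplied by the out-of-plane thickness.

The solve is linear in the drive, so phi and E scale as U and both force
routes scale as U^2; :class:`ForceEstimator` exploits this to price a
whole voltage protocol from two factorized solves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .electrokinetics import (
    EPS0,
    CellDielectric,
    DielectricMaterial,
    Drive,
    clausius_mossotti,
    complex_conductivity,
    dep_force_edm,
    dep_force_simplified,
)


class ConfigurationError(ValueError):
    """Ill-posed chip or solver setup (e.g. no Dirichlet electrode)."""


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElectrodeSegment:
    """A zero-thickness electrode interval on the bottom or top wall."""

    wall: str  # "bottom" | "top"
    start: float  # m, along x
    end: float  # m
    potential: float  # V

    def __post_init__(self) -> None:
        if self.wall not in ("bottom", "top"):
            raise ConfigurationError(f"wall must be bottom/top, got {self.wall!r}")
        if not self.end > self.start:
            raise ConfigurationError("electrode segment must have end > start")


@dataclass(frozen=True)
class ChipModel:
    """2D side-view chip cross-section with two coplanar electrodes.

    The default geometry is a 100 x 50 um window of the channel with two
    30 um electrodes on the bottom wall separated by the 20 um gap; the
    full 5000 um channel length is unnecessary because the field decays
    within a few gap widths of the electrodes.
    """

    domain_width: float = 100e-6  # m
    domain_height: float = 50e-6  # m (channel height)
    electrodes: tuple[ElectrodeSegment, ...] = ()
    gap: float = 20e-6  # m, electrode gap d
    grid_spacing: float = 0.25e-6  # m
    out_of_plane_thickness: float = 14e-6  # m, default = cell diameter

    def __post_init__(self) -> None:
        if self.gap <= 0:
            raise ConfigurationError(f"gap must be > 0, got {self.gap}")
        if self.grid_spacing <= 0:
            raise ConfigurationError("grid_spacing must be > 0")
        for el in self.electrodes:
            if el.start < -1e-12 or el.end > self.domain_width + 1e-12:
                raise ConfigurationError("electrode outside domain")
        bottoms = sorted(
            (e for e in self.electrodes if e.wall == "bottom"), key=lambda e: e.start
        )
        for a, b in zip(bottoms, bottoms[1:]):
            if b.start < a.end:
                raise ConfigurationError("overlapping electrode segments")

    @property
    def driven_potential(self) -> float:
        """Largest electrode potential (the drive amplitude U)."""
        if not self.electrodes:
            raise ConfigurationError("chip has no electrodes")
        return max(e.potential for e in self.electrodes)

    def with_drive(self, voltage_amplitude: float) -> "ChipModel":
        """Rescale every electrode potential so the drive is the given U."""
        u0 = self.driven_potential
        if u0 == 0:
            raise ConfigurationError("cannot rescale a chip with all-ground electrodes")
        scale = voltage_amplitude / u0
        return replace(
            self,
            electrodes=tuple(
                replace(e, potential=e.potential * scale) for e in self.electrodes
            ),
        )


def default_chip(
    voltage_amplitude: float = 2.0,
    gap: float = 20e-6,
    grid_spacing: float = 0.25e-6,
    electrode_length: float = 30e-6,
    out_of_plane_thickness: float = 14e-6,
) -> ChipModel:
    """Default tip-to-tip chip: two coplanar bottom electrodes.

    The driven electrode ends at the domain centre minus gap/2; the cell
    is captured at its inner edge (see :func:`default_cell_center`).
    """
    width = 100e-6
    x_left_end = width / 2 - gap / 2
    x_right_start = width / 2 + gap / 2
    return ChipModel(
        domain_width=width,
        domain_height=50e-6,
        electrodes=(
            ElectrodeSegment("bottom", x_left_end - electrode_length, x_left_end,
                             voltage_amplitude),
            ElectrodeSegment("bottom", x_right_start, x_right_start + electrode_length,
                             0.0),
        ),
        gap=gap,
        grid_spacing=grid_spacing,
        out_of_plane_thickness=out_of_plane_thickness,
    )


def default_cell_center(
    chip: ChipModel, radius: float = 7e-6, standoff: float = 1e-6
) -> tuple[float, float]:
    """Capture position of the cell: inner edge of the driven electrode.

    The centre sits at the driven electrode's gap-side edge, one radius
    plus a small standoff above the wall so the cell surface clears the
    insulating boundary (cells rest on the substrate; the standoff keeps
    a medium layer under the interface for the stress contour).
    """
    driven = max(chip.electrodes, key=lambda e: e.potential)
    edge = driven.end if driven.wall == "bottom" else driven.start
    return (edge, radius + standoff)


@dataclass(frozen=True)
class ParticleInclusion:
    """Circular dielectric inclusion (the cell cross-section)."""

    center: tuple[float, float]  # m
    radius: float  # m
    material: DielectricMaterial

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("particle radius must be > 0")


# ---------------------------------------------------------------------------
# Solution container
# ---------------------------------------------------------------------------


@dataclass
class FieldSolution:
    """Discrete phasor solution: potential and field on the node grid."""

    phi: np.ndarray  # complex, shape (ny+1, nx+1)
    ex: np.ndarray  # complex, V/m
    ey: np.ndarray  # complex, V/m
    x: np.ndarray  # node coordinates, m
    y: np.ndarray
    chip: ChipModel
    medium: DielectricMaterial
    omega: float
    particle: ParticleInclusion | None = None
    _grad_cache: tuple | None = field(default=None, repr=False)

    @property
    def grid_spacing(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def e2(self) -> np.ndarray:
        """Mean |E0|^2 = |Ex|^2 + |Ey|^2 of the amplitude phasor, V^2/m^2."""
        return (np.abs(self.ex) ** 2 + np.abs(self.ey) ** 2).real

    def _bilinear(self, grid: np.ndarray, px: np.ndarray, py: np.ndarray) -> np.ndarray:
        """Vectorized bilinear interpolation of a node grid at points."""
        h = self.grid_spacing
        fx = np.clip(px / h, 0, len(self.x) - 1 - 1e-12)
        fy = np.clip(py / h, 0, len(self.y) - 1 - 1e-12)
        j0 = fx.astype(int)
        i0 = fy.astype(int)
        tx = fx - j0
        ty = fy - i0
        return (
            grid[i0, j0] * (1 - tx) * (1 - ty)
            + grid[i0, j0 + 1] * tx * (1 - ty)
            + grid[i0 + 1, j0] * (1 - tx) * ty
            + grid[i0 + 1, j0 + 1] * tx * ty
        )

    def e_at(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Complex (Ex, Ey) at (n, 2) points, bilinear interpolation."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (
            self._bilinear(self.ex, points[:, 0], points[:, 1]),
            self._bilinear(self.ey, points[:, 0], points[:, 1]),
        )


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------


def _node_grid(chip: ChipModel) -> tuple[np.ndarray, np.ndarray]:
    h = chip.grid_spacing
    nx = int(round(chip.domain_width / h))
    ny = int(round(chip.domain_height / h))
    if abs(nx * h - chip.domain_width) > 1e-9 * chip.domain_width or abs(
        ny * h - chip.domain_height
    ) > 1e-9 * chip.domain_height:
        raise ConfigurationError("grid_spacing must divide the domain dimensions")
    return np.linspace(0, chip.domain_width, nx + 1), np.linspace(
        0, chip.domain_height, ny + 1
    )


def solve_potential(
    chip: ChipModel,
    medium: DielectricMaterial,
    omega: float,
    particle: ParticleInclusion | None = None,
) -> FieldSolution:
    """Solve the variable-coefficient complex Laplace problem on the chip.

    Conservative five-point finite-volume scheme; the complex coefficient
    sigma* = sigma + j*omega*eps0*eps is assigned per node by material
    (cell-centre rasterization of the particle disc) and harmonically
    averaged on faces, which enforces flux continuity at the interface.
    Dirichlet values are imposed on electrode nodes; all other boundary
    nodes carry the natural zero-flux condition.  Direct sparse solve.
    """
    x, y = _node_grid(chip)
    nx1, ny1 = len(x), len(y)
    h = chip.grid_spacing

    sig_m = complex_conductivity(medium, omega)
    coef = np.full((ny1, nx1), sig_m, dtype=complex)
    if particle is not None:
        cx, cy = particle.center
        if (
            cx - particle.radius <= 0
            or cx + particle.radius >= chip.domain_width
            or cy - particle.radius <= 0
            or cy + particle.radius >= chip.domain_height
        ):
            raise ConfigurationError("particle disc must lie strictly inside domain")
        xx, yy = np.meshgrid(x, y)
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 < particle.radius**2
        coef[inside] = complex_conductivity(particle.material, omega)
    coef = coef / sig_m  # normalize for conditioning; equation is homogeneous

    # Dirichlet mask/value from electrode segments
    dirichlet = np.zeros((ny1, nx1), dtype=bool)
    dval = np.zeros((ny1, nx1), dtype=complex)
    for el in chip.electrodes:
        row = 0 if el.wall == "bottom" else ny1 - 1
        cols = (x >= el.start - 0.5 * h) & (x <= el.end + 0.5 * h)
        dirichlet[row, cols] = True
        dval[row, cols] = el.potential
    if not dirichlet.any():
        raise ConfigurationError("no electrode (Dirichlet) nodes: problem is singular")

    n = ny1 * nx1
    idx = np.arange(n).reshape(ny1, nx1)

    # face conductances (harmonic mean), horizontal then vertical
    ch = 2.0 * coef[:, :-1] * coef[:, 1:] / (coef[:, :-1] + coef[:, 1:])
    cv = 2.0 * coef[:-1, :] * coef[1:, :] / (coef[:-1, :] + coef[1:, :])

    rows, cols, vals = [], [], []

    def add_faces(p: np.ndarray, q: np.ndarray, c: np.ndarray) -> None:
        p, q, c = p.ravel(), q.ravel(), c.ravel()
        rows.append(p)
        cols.append(q)
        vals.append(c)
        rows.append(q)
        cols.append(p)
        vals.append(c)
        rows.append(p)
        cols.append(p)
        vals.append(-c)
        rows.append(q)
        cols.append(q)
        vals.append(-c)

    add_faces(idx[:, :-1], idx[:, 1:], ch)
    add_faces(idx[:-1, :], idx[1:, :], cv)

    a = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    # replace Dirichlet rows with identity
    dmask = dirichlet.ravel()
    keep = sp.diags((~dmask).astype(float))
    a = keep @ a + sp.diags(dmask.astype(float))
    b = np.where(dmask, dval.ravel(), 0.0 + 0.0j)

    phi = spla.spsolve(a.tocsc(), b).reshape(ny1, nx1)

    gy, gx = np.gradient(phi, h)
    return FieldSolution(
        phi=phi, ex=-gx, ey=-gy, x=x, y=y, chip=chip, medium=medium,
        omega=omega, particle=particle,
    )


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------


def grad_e2_at(solution: FieldSolution, point: tuple[float, float]) -> np.ndarray:
    """Gradient of mean |E0|^2 at a point, V^2/m^3.

    Central differences of the nodal |E0|^2 grid, bilinearly interpolated
    at the probe.  The probe must sit at least two grid cells from every
    boundary.
    """
    h = solution.grid_spacing
    px, py = point
    if not (
        2 * h <= px <= solution.chip.domain_width - 2 * h
        and 2 * h <= py <= solution.chip.domain_height - 2 * h
    ):
        raise ValueError("probe point outside domain interior (>= 2 cells from wall)")
    if solution._grad_cache is None:
        g = solution.e2
        gy, gx = np.gradient(g, h)
        solution._grad_cache = (gx, gy)
    gx, gy = solution._grad_cache
    return np.array(
        [
            float(solution._bilinear(gx, np.array([px]), np.array([py]))[0]),
            float(solution._bilinear(gy, np.array([px]), np.array([py]))[0]),
        ]
    )


def dep_force_edm_from_solution(
    solution: FieldSolution,
    cell: CellDielectric,
    medium: DielectricMaterial,
    point: tuple[float, float],
) -> np.ndarray:
    """Time-averaged EDM force at a probe of the particle-free solution, N.

    Uses Re[K] at the solve frequency and the gradient of the mean-square
    field; for amplitude phasors the mean square is |E0|^2 / 2, hence the
    factor 1/2 applied to the nodal |E0|^2 gradient.
    """
    re_k = clausius_mossotti(cell, medium, solution.omega).real_part
    return dep_force_edm(cell, medium, re_k, 0.5 * grad_e2_at(solution, point))


def integrate_mst(
    solution: FieldSolution,
    contour: ParticleInclusion,
    medium: DielectricMaterial,
    thickness: float,
    n_points: int = 720,
    offset: float | None = None,
) -> np.ndarray:
    """Time-averaged Maxwell-stress force on the particle, N, as (Fx, Fy).

    The 2D time-averaged stress tensor

        T_xx = (eps0 eps_m / 4) (|Ex|^2 - |Ey|^2)
        T_yy = -T_xx
        T_xy = (eps0 eps_m / 2) Re(Ex Ey*)

    is sampled at ``n_points`` uniformly spaced points on a circle of
    radius r + offset (medium side of the interface; default offset
    1.5 grid cells keeps the quadrature off the rasterized interface),
    contracted with outward normals, integrated by the trapezoid rule,
    and multiplied by the out-of-plane ``thickness``.  In the homogeneous
    source-free medium the integral is contour-independent, so a small
    outward offset changes only discretization error.
    """
    h = solution.grid_spacing
    if offset is None:
        offset = 1.5 * h
    rc = contour.radius + offset
    cx, cy = contour.center
    if (
        cx - rc <= 0
        or cx + rc >= solution.chip.domain_width
        or cy - rc <= 0
        or cy + rc >= solution.chip.domain_height
    ):
        raise ValueError("MST contour intersects the domain boundary")

    theta = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
    pts = np.column_stack([cx + rc * np.cos(theta), cy + rc * np.sin(theta)])
    ex, ey = solution.e_at(pts)

    pref = 0.25 * EPS0 * medium.rel_permittivity
    txx = pref * (np.abs(ex) ** 2 - np.abs(ey) ** 2)
    tyy = -txx
    txy = 2.0 * pref * np.real(ex * np.conj(ey))

    nx_, ny_ = np.cos(theta), np.sin(theta)
    ds = 2.0 * math.pi * rc / n_points
    fx = np.sum(txx * nx_ + txy * ny_) * ds
    fy = np.sum(txy * nx_ + tyy * ny_) * ds
    return np.array([fx, fy]) * thickness


# ---------------------------------------------------------------------------
# Three-way force pipeline
# ---------------------------------------------------------------------------


class ForceEstimator:
    """Three DEP force estimates on one chip, factorized over voltage.

    Solves the chip field once without and once with the cell at unit
    drive, then prices any voltage protocol by the exact U^2 scaling of
    both field-based estimates.  Forces are magnitudes in newtons.
    """

    def __init__(
        self,
        chip: ChipModel,
        cell: CellDielectric,
        medium: DielectricMaterial,
        frequency: float = 1e6,
        standoff: float = 1e-6,
    ) -> None:
        self.chip = chip
        self.cell = cell
        self.medium = medium
        self.frequency = frequency
        omega = 2.0 * math.pi * frequency
        self.center = default_cell_center(chip, cell.radius, standoff)
        base = chip.with_drive(1.0)
        self._free = solve_potential(base, medium, omega)
        self._particle = ParticleInclusion(self.center, cell.radius, cell.cytoplasm)
        self._loaded = solve_potential(base, medium, omega, self._particle)

        f_edm = dep_force_edm_from_solution(self._free, cell, medium, self.center)
        self._edm_unit = float(np.linalg.norm(f_edm))
        f_mst = integrate_mst(
            self._loaded, self._particle, medium, chip.out_of_plane_thickness
        )
        self._mst_unit = float(np.linalg.norm(f_mst))

    def edm(self, voltage_amplitude: float) -> float:
        return self._edm_unit * voltage_amplitude**2

    def mst(self, voltage_amplitude: float) -> float:
        return self._mst_unit * voltage_amplitude**2

    def simplified(self, voltage_amplitude: float) -> float:
        drive = Drive(voltage_amplitude=voltage_amplitude, frequency=self.frequency)
        return dep_force_simplified(drive, self.chip.gap, self.cell, self.medium)

    def table(self, voltages: list[float]) -> dict[str, list[float]]:
        """Force table (N) for a list of voltage amplitudes."""
        return {
            "voltage_V": list(voltages),
            "edm_N": [self.edm(u) for u in voltages],
            "mst_N": [self.mst(u) for u in voltages],
            "simplified_N": [self.simplified(u) for u in voltages],
        }
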