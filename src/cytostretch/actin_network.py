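"""Coarse-grained actin cytoskeleton: WLC filaments + Hookean crosslinks.

The cortical actin network of a suspended cell is modelled as N_AF
straight filament segments of contour length L_c placed randomly in a
spherical shell [R_I, R_E], their ends connected by actin-binding
proteins (ABPs) represented as linear springs of stiffness k_c.  Each
filament obeys the MacKintosh semiflexible-polymer (worm-like chain)
force-extension law

    f_a = 81 kB T Lp^2 Lc^2 (dr + dr0)
          / ((Lc^2 - 6 Lp (dr+dr0))^2 (Lc^2 + 3 Lp (dr+dr0)))

which is linear near zero extension and diverges at the finite extension
limit Lc^2/(6 Lp) - dr0; dr0 is a built-in pre-extension representing
resting cytoskeletal tension.  The contour length follows from crosslink
density R, filament diameter d_Actin and F-actin concentration C_AF:

    L_c = kappa * (R^0.2 * d_Actin / 2) * sqrt(pi / C_AF)

with a single documented unit-bridging constant kappa (see
``NetworkParams.length_scale``).

A stretching load is distributed over polar caps of vertices and the
network is relaxed to mechanical force balance (overdamped dynamics
eta*dr/dt = F_i; the default relaxer minimizes the total elastic energy,
whose gradient is exactly the negative vertex force, with explicit-Euler
and inertial damped-dynamics integrators available).  The strain readout
is (r - r0)/r0 along the stretch axis.

Positions and forces are strict SI (metres, newtons) internally;
parameter fields use the conventional units stated on each field.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .electrokinetics import KB

logger = logging.getLogger(__name__)

_UM = 1e-6  # metres per micrometre


class RelaxationError(RuntimeError):
    """Relaxation diverged (non-finite positions or WLC domain breach)."""


class NetworkBuildError(ValueError):
    """Requested network is geometrically infeasible."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkParams:
    """Structural and material parameters of the coarse-grained network.

    Shell radii follow the fitted scale of a ~7 um leukaemia cell; the
    filament count default is a computational reduction of the
    physiological count (hundreds of thousands) that preserves the
    shell geometry and connectivity statistics at tractable cost.
    """

    R_E: float = 7.02  # um, external shell radius
    R_I: float = 6.21  # um, internal shell radius
    C_AF: float = 15.0  # uM, F-actin concentration
    R: float = 10.0  # crosslinks per filament (dimensionless density)
    N_AF: int = 500  # number of filaments
    L_p: float = 10.0  # um, persistence length
    d_Actin: float = 7.0  # nm, filament diameter
    k_c: float = 1e-3  # N/m, ABP spring stiffness
    delta_r0: float = 0.015  # um, filament pre-extension (prestress)
    T: float = 300.0  # K
    eta: float = 1e-3  # Pa*s, cytoplasm viscosity
    # --- modelling constants (config-visible, not physics inputs) ---
    length_scale: float = 800.0  # kappa: unit bridge in the L_c relation
    capture_radius: float = 2.5  # um, ABP endpoint-pairing reach
    cap_half_angle_deg: float = 30.0  # polar-cap half angle for load
    drag_radius: float = 0.05  # um, Stokes radius per vertex (Euler mode)

    def __post_init__(self) -> None:
        if not 0 < self.R_I < self.R_E:
            raise ValueError("need 0 < R_I < R_E")
        if self.C_AF <= 0 or self.R <= 0 or self.L_p <= 0 or self.d_Actin <= 0:
            raise ValueError("C_AF, R, L_p, d_Actin must be > 0")
        if self.N_AF < 1:
            raise ValueError("N_AF must be >= 1")
        if self.contour_length_um <= 0:
            raise ValueError("derived contour length must be > 0")

    @property
    def contour_length_um(self) -> float:
        return contour_length(self.R, self.d_Actin, self.C_AF, self.length_scale)


def contour_length(
    R: float, d_actin: float, C_AF: float, length_scale: float = 800.0
) -> float:
    """Filament contour length L_c in micrometres.

    L_c = kappa * (R^0.2 * d_Actin/2) * sqrt(pi / C_AF) with d_Actin in
    nanometres and C_AF in micromolar.  The dimensionless constant kappa
    (``length_scale``, default 800) bridges the mixed-unit convention so
    that cortical-scale parameters (C_AF ~ 15 uM, d_Actin = 7 nm,
    R in [1, 100]) give L_c in the 0.1-3 um range typical of crosslinked
    cortical actin.
    """
    if R <= 0 or d_actin <= 0 or C_AF <= 0:
        raise ValueError("contour_length inputs must be > 0")
    d_um = d_actin * 1e-3
    return length_scale * (R**0.2) * (d_um / 2.0) * math.sqrt(math.pi / C_AF)


# ---------------------------------------------------------------------------
# Network container
# ---------------------------------------------------------------------------


@dataclass
class ActinNetwork:
    """Vertices and edges of one realized network (positions in metres)."""

    vertices: np.ndarray  # (n, 3) m
    filament_edges: np.ndarray  # (m_f, 2) int
    filament_rest: np.ndarray  # (m_f,) m
    abp_edges: np.ndarray  # (m_c, 2) int
    abp_rest: np.ndarray  # (m_c,) m
    pole_plus: np.ndarray  # int indices, +axis cap
    pole_minus: np.ndarray
    params: NetworkParams
    rng_seed: int
    core: np.ndarray  # indices of the largest connected component
    axis: int = 2  # stretch axis (z)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def realized_crosslink_density(self) -> float:
        """Realized crosslinks per filament."""
        return len(self.abp_edges) / max(len(self.filament_edges), 1)

    def same_topology(self, other: "ActinNetwork") -> bool:
        return (
            self.n_vertices == other.n_vertices
            and np.array_equal(self.filament_edges, other.filament_edges)
            and np.array_equal(self.abp_edges, other.abp_edges)
        )


@dataclass(frozen=True)
class LoadSpec:
    """External stretching load: per-vertex force vectors, N.

    ``forces`` sums to zero over the whole network (force balance);
    ``total_force`` is the pulling magnitude applied at each pole.
    """

    total_force: float
    forces: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        net = np.abs(self.forces.sum(axis=0)).max()
        if net > 1e-9 * max(abs(self.total_force), 1e-30) + 1e-30:
            raise ValueError("load does not balance: nonzero net force")


def make_load(network: ActinNetwork, total_force: float) -> LoadSpec:
    """Distribute +/- ``total_force`` equally over the two polar caps.

    The plus cap is pulled along +axis with total magnitude
    ``total_force`` and the minus cap along -axis with the same
    magnitude, emulating the distributed pole traction of DEP
    stretching.
    """
    forces = np.zeros_like(network.vertices)
    if total_force != 0.0:
        if len(network.pole_plus) == 0 or len(network.pole_minus) == 0:
            raise NetworkBuildError("empty pole cap: cannot apply load")
        forces[network.pole_plus, network.axis] = total_force / len(network.pole_plus)
        forces[network.pole_minus, network.axis] = -total_force / len(
            network.pole_minus
        )
    return LoadSpec(total_force=total_force, forces=forces)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finalizer: stable pseudo-random uint64 per input."""
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x = ((x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    x = ((x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    return x ^ (x >> np.uint64(31))


def build_network(params: NetworkParams, seed: int) -> ActinNetwork:
    """Place N_AF filaments in the shell and wire ABP crosslinks.

    Segment midpoints are uniform in the shell volume and orientations
    uniform on the sphere; a candidate is rejected unless both endpoints
    have radii in [R_I, R_E] (bounded retries).  Crosslinks connect
    endpoint pairs of different filaments lying within the absolute
    capture radius, added until the target density R (crosslinks per
    filament) is met, in the order of a stable per-pair pseudo-random
    priority.  Pole caps (half-angle ``cap_half_angle_deg`` about the
    +/- stretch axis) are restricted to the largest connected component
    so the applied load always acts on a percolating cluster.

    Each filament draws from its own random substream and each candidate
    crosslink has a priority that depends only on (seed, endpoint ids),
    so the realized network is deterministic for a fixed seed and,
    crucially, varies *continuously* with the structural parameters up
    to rare local flips: a small change in L_c re-draws only the few
    filaments whose candidates cross the shell boundary and re-ranks
    only the pairs entering or leaving the capture radius.  This keeps
    simulation-based loss surfaces quasi-smooth under common random
    numbers, which derivative-free fitting relies on.
    """
    lc = params.contour_length_um * _UM
    r_i, r_e = params.R_I * _UM, params.R_E * _UM

    n = params.N_AF
    pos = np.empty((2 * n, 3))
    max_tries = 10_000
    # one independent substream per filament
    fil_seeds = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    batch = 32
    for i in range(n):
        rng_i = np.random.default_rng(fil_seeds[i])
        placed = False
        for _ in range(max_tries // batch + 1):
            u = rng_i.random(batch)
            rad = (r_i**3 + u * (r_e**3 - r_i**3)) ** (1.0 / 3.0)
            mid_dir = rng_i.normal(size=(batch, 3))
            mid_dir /= np.linalg.norm(mid_dir, axis=1, keepdims=True)
            mids = rad[:, None] * mid_dir
            ori = rng_i.normal(size=(batch, 3))
            ori /= np.linalg.norm(ori, axis=1, keepdims=True)
            e0 = mids - 0.5 * lc * ori
            e1 = mids + 0.5 * lc * ori
            ok = (
                (np.linalg.norm(e0, axis=1) >= r_i)
                & (np.linalg.norm(e0, axis=1) <= r_e)
                & (np.linalg.norm(e1, axis=1) >= r_i)
                & (np.linalg.norm(e1, axis=1) <= r_e)
            )
            hit = np.flatnonzero(ok)
            if len(hit):
                pos[2 * i] = e0[hit[0]]
                pos[2 * i + 1] = e1[hit[0]]
                placed = True
                break
        if not placed:
            raise NetworkBuildError(
                f"cannot place filament of L_c={lc / _UM:.3g} um "
                f"in shell [{params.R_I}, {params.R_E}] um"
            )

    filament_edges = np.column_stack(
        [np.arange(0, 2 * n, 2), np.arange(1, 2 * n, 2)]
    ).astype(np.int64)
    filament_rest = np.full(n, lc)

    # ABP wiring: endpoint pairs of distinct filaments within capture radius
    abp_edges = np.empty((0, 2), dtype=np.int64)
    if n > 1:
        from scipy.spatial import cKDTree

        capture = params.capture_radius * _UM
        tree = cKDTree(pos)
        pairs = np.array(sorted(tree.query_pairs(capture)), dtype=np.int64)
        if len(pairs):
            diff_fil = (pairs[:, 0] // 2) != (pairs[:, 1] // 2)
            pairs = pairs[diff_fil]
        target = int(round(params.R * n))
        if len(pairs):
            seed_mix = np.uint64((int(seed) * 0xD6E8FEB86659FD93) % (1 << 64))
            with np.errstate(over="ignore"):
                key = (
                    pairs[:, 0].astype(np.uint64) * np.uint64(0xC2B2AE3D27D4EB4F)
                    + pairs[:, 1].astype(np.uint64)
                    + seed_mix
                )
            priority = _splitmix64(key)
            order = np.argsort(priority, kind="stable")
            pairs = pairs[order[: min(target, len(pairs))]]
            if len(pairs) < target:
                logger.warning(
                    "crosslink density target %d not reachable; realized %d",
                    target,
                    len(pairs),
                )
            abp_edges = pairs
    abp_rest = np.linalg.norm(pos[abp_edges[:, 0]] - pos[abp_edges[:, 1]], axis=1) if len(abp_edges) else np.empty(0)

    core = _largest_component(2 * n, filament_edges, abp_edges)

    # polar caps about the stretch axis, restricted to the core
    axis = 2
    radii = np.linalg.norm(pos, axis=1)
    cosang = np.divide(pos[:, axis], radii, out=np.zeros(2 * n), where=radii > 0)
    in_core = np.zeros(2 * n, dtype=bool)
    in_core[core] = True
    # widen the cap for unlucky small realizations so a load can always
    # be applied; the default half-angle is kept whenever it is populated
    half_angle = params.cap_half_angle_deg
    while True:
        cos_cap = math.cos(math.radians(half_angle))
        pole_plus = np.flatnonzero((cosang >= cos_cap) & in_core)
        pole_minus = np.flatnonzero((cosang <= -cos_cap) & in_core)
        if (len(pole_plus) and len(pole_minus)) or half_angle >= 85.0:
            break
        half_angle += 5.0
    if half_angle != params.cap_half_angle_deg:
        logger.warning(
            "pole cap widened from %.0f to %.0f deg to find load vertices",
            params.cap_half_angle_deg,
            half_angle,
        )

    return ActinNetwork(
        vertices=pos,
        filament_edges=filament_edges,
        filament_rest=filament_rest,
        abp_edges=abp_edges,
        abp_rest=abp_rest,
        pole_plus=pole_plus,
        pole_minus=pole_minus,
        params=params,
        rng_seed=int(seed),
        core=core,
        axis=axis,
    )


def _largest_component(
    n: int, filament_edges: np.ndarray, abp_edges: np.ndarray
) -> np.ndarray:
    edges = (
        np.vstack([filament_edges, abp_edges]) if len(abp_edges) else filament_edges
    )
    adj = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    return np.flatnonzero(labels == sizes.argmax())


# ---------------------------------------------------------------------------
# Force laws
# ---------------------------------------------------------------------------


def wlc_force(
    delta_r: float, delta_r0: float, L_p: float, L_c: float, T: float = 300.0
) -> float:
    """MacKintosh WLC force, N, for extensions given in micrometres.

    Raises a domain error at or beyond the finite extension limit
    L_c^2/(6 L_p) - delta_r0 (and at the compression root
    -L_c^2/(3 L_p) - delta_r0).
    """
    lp, lc = L_p * _UM, L_c * _UM
    x = (delta_r + delta_r0) * _UM
    a = lc * lc
    if a - 6.0 * lp * x <= 0.0 or a + 3.0 * lp * x <= 0.0:
        limit = L_c**2 / (6.0 * L_p) - delta_r0
        raise ValueError(
            f"WLC extension out of domain: delta_r={delta_r} um; "
            f"extension limit is {limit:.6g} um"
        )
    return float(
        81.0 * KB * T * lp**2 * a * x / ((a - 6.0 * lp * x) ** 2 * (a + 3.0 * lp * x))
    )


def abp_force(extension: float, k_c: float) -> float:
    """Hookean ABP force, N (extension in micrometres, signed)."""
    return k_c * extension * _UM


def _wlc_terms(params: NetworkParams) -> tuple[float, float, float, float]:
    """(a, p, q, pref) of the SI WLC law f = pref * x / ((a-px)^2 (a+qx))."""
    lp = params.L_p * _UM
    lc = params.contour_length_um * _UM
    a = lc * lc
    return a, 6.0 * lp, 3.0 * lp, 81.0 * KB * params.T * lp**2 * a


def _wlc_f_and_e(
    x: np.ndarray, params: NetworkParams, frac: float = 0.999
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Vectorized WLC force and potential energy at extension x (SI).

    Beyond ``frac`` of either domain limit the law is continued linearly
    in force (quadratically in energy).  On the extension side this lets
    the minimizer recover from trial steps that overshoot the divergence:
    the continuation force at 0.999 of the limit exceeds any
    physiological load by orders of magnitude, so converged equilibria
    lie inside the true domain, and any equilibrium in the extension
    continuation is reported as unconverged (clean=False).  On the
    compression side the algebraic root of the force law at
    -L_c^2/(3 L_p) is not physical -- a compressed semiflexible filament
    buckles -- so the linear continuation there acts as an explicit
    buckling regularization and does not block convergence.
    Returns (force, energy, clean).
    """
    a, p, q, pref = _wlc_terms(params)
    x_hi = frac * a / p
    x_lo = -frac * a / q
    xc = np.clip(x, x_lo, x_hi)

    dm = a - p * xc
    dp_ = a + q * xc
    f = pref * xc / (dm**2 * dp_)

    # closed-form potential: E' = f (partial fractions in x)
    A = -2.0 / (27.0 * a * (p / 6.0))  # = -2/(27 a Lp)
    B = 1.0 / (9.0 * (p / 6.0))  # = 1/(9 Lp)
    C = -1.0 / (27.0 * a * (p / 6.0))  # = -1/(27 a Lp)
    e = pref * (
        (-A / p) * np.log(dm / a) + (B / p) * (1.0 / dm - 1.0 / a)
        + (C / q) * np.log(dp_ / a)
    )

    over = x > x_hi
    under = x < x_lo
    clean = not over.any()
    if over.any() or under.any():
        # linear force continuation: f(xc) + f'(xc) (x - xc)
        dfdx = pref * (dm * dp_ + xc * (2.0 * p * dp_ - q * dm)) / (dm**3 * dp_**2)
        ext = np.where(over | under, x - xc, 0.0)
        e = e + np.where(over | under, f * ext + 0.5 * dfdx * ext**2, 0.0)
        f = np.where(over | under, f + dfdx * ext, f)
    return f, e, clean


def network_forces(
    network: ActinNetwork, load: LoadSpec | None = None
) -> np.ndarray:
    """Force F_i on every vertex, N: WLC + ABP + external load."""
    f, _, _ = _forces_energy(network, network.vertices, load)
    return f


def vertex_force(
    network: ActinNetwork, i: int, load: LoadSpec | None = None
) -> np.ndarray:
    """Force on vertex i, N (sum of incident WLC, ABP and load terms)."""
    if not 0 <= i < network.n_vertices:
        raise IndexError(f"vertex index {i} out of range")
    return network_forces(network, load)[i]


def _accumulate(forces: np.ndarray, edges: np.ndarray, fv: np.ndarray) -> None:
    """Add +fv to edges[:,0] rows and -fv to edges[:,1] rows of forces."""
    n = len(forces)
    for k in range(forces.shape[1]):
        forces[:, k] += np.bincount(edges[:, 0], weights=fv[:, k], minlength=n)
        forces[:, k] -= np.bincount(edges[:, 1], weights=fv[:, k], minlength=n)


def _forces_energy(
    network: ActinNetwork,
    pos: np.ndarray,
    load: LoadSpec | None,
) -> tuple[np.ndarray, float, bool]:
    """(forces, total energy, wlc_domain_clean) at candidate positions."""
    params = network.params
    forces = np.zeros_like(pos)
    energy = 0.0
    clean = True
    dr0 = params.delta_r0 * _UM

    fe = network.filament_edges
    if len(fe):
        d = pos[fe[:, 1]] - pos[fe[:, 0]]
        length = np.linalg.norm(d, axis=1)
        length = np.maximum(length, 1e-30)
        x = (length - network.filament_rest) + dr0
        fmag, e, ok = _wlc_f_and_e(x, params)
        clean &= ok
        energy += float(e.sum())
        fv = (fmag / length)[:, None] * d  # tension pulls 0 toward 1
        _accumulate(forces, fe, fv)

    ae = network.abp_edges
    if len(ae):
        d = pos[ae[:, 1]] - pos[ae[:, 0]]
        length = np.linalg.norm(d, axis=1)
        length = np.maximum(length, 1e-30)
        ext = length - network.abp_rest
        energy += float(0.5 * params.k_c * np.sum(ext**2))
        fv = (params.k_c * ext / length)[:, None] * d
        _accumulate(forces, ae, fv)

    if load is not None:
        forces = forces + load.forces
        energy -= float(np.sum(load.forces * pos))
    return forces, energy, clean


# ---------------------------------------------------------------------------
# Relaxation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RelaxConfig:
    """Relaxation settings.

    ``method`` selects the relaxer: "lbfgs" (energy minimization, the
    default; the energy gradient is exactly -F_i so the converged state
    is the overdamped fixed point), "euler" (explicit overdamped
    integration of eta*dr/dt = F with adaptive step halving), or
    "inertial" (semi-implicit damped dynamics m*r'' + gamma*r' = F using
    the fictitious mass; default mass keeps the motion overdamped by
    >= 10x so inertia is negligible).
    """

    fictitious_mass: float = 1e-17  # kg
    time_step: float = 1e-6  # s (euler / inertial)
    max_iterations: int = 20_000
    force_tolerance: float = 1e-12  # N, on max_i |F_i|
    method: str = "lbfgs"

    def __post_init__(self) -> None:
        if self.time_step <= 0 or self.force_tolerance <= 0:
            raise ValueError("time_step and force_tolerance must be > 0")
        if self.method not in ("lbfgs", "euler", "inertial"):
            raise ValueError(f"unknown relaxation method {self.method!r}")


@dataclass
class RelaxResult:
    """Equilibrated network plus convergence diagnostics."""

    network: ActinNetwork
    converged: bool
    max_residual: float  # N
    n_iterations: int


_L0 = 1e-6  # optimization length unit, m (um)
_F0 = 1e-9  # force unit, N (nN)
_E0 = _L0 * _F0  # energy unit, J


def relax_network(
    network: ActinNetwork,
    load: LoadSpec | None = None,
    config: RelaxConfig | None = None,
) -> RelaxResult:
    """Relax vertex positions to force balance under the given load."""
    config = config or RelaxConfig()
    if config.method == "lbfgs":
        return _relax_lbfgs(network, load, config)
    return _relax_dynamics(network, load, config)


def _max_residual(forces: np.ndarray) -> float:
    return float(np.linalg.norm(forces, axis=1).max()) if len(forces) else 0.0


def _relax_lbfgs(
    network: ActinNetwork, load: LoadSpec | None, config: RelaxConfig
) -> RelaxResult:
    from scipy.optimize import minimize

    n = network.n_vertices

    def fun(xflat: np.ndarray):
        pos = xflat.reshape(n, 3) * _L0
        forces, energy, _ = _forces_energy(network, pos, load)
        return energy / _E0, -(forces / _F0).ravel()

    x0 = (network.vertices / _L0).ravel()
    best = x0
    total_it = 0
    for _ in range(3):
        res = minimize(
            fun,
            best,
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": config.max_iterations,
                "maxfun": 2 * config.max_iterations,
                "gtol": 0.3 * config.force_tolerance / _F0,
                "ftol": 1e-16,
                "maxls": 60,
            },
        )
        best = res.x
        total_it += int(res.nit)
        pos = best.reshape(n, 3) * _L0
        if not np.all(np.isfinite(pos)):
            raise RelaxationError("relaxation produced non-finite positions")
        forces, _, clean = _forces_energy(network, pos, load)
        resid = _max_residual(forces)
        if resid <= config.force_tolerance and clean:
            break
        if not res.success:
            break  # iteration budget exhausted; report state as-is
    return RelaxResult(
        network=replace_positions(network, pos),
        converged=bool(resid <= config.force_tolerance and clean),
        max_residual=resid,
        n_iterations=total_it,
    )


def _relax_dynamics(
    network: ActinNetwork, load: LoadSpec | None, config: RelaxConfig
) -> RelaxResult:
    """Explicit overdamped Euler, or damped inertial dynamics.

    Per-vertex Stokes drag gamma = 6*pi*eta*a with the configured drag
    radius.  The step is halved when a trial step breaches the WLC
    domain or grows the residual; it is gently re-grown after successes.
    """
    params = network.params
    gamma = 6.0 * math.pi * params.eta * params.drag_radius * _UM
    inertial = config.method == "inertial"
    m = config.fictitious_mass

    pos = network.vertices.copy()
    vel = np.zeros_like(pos)
    dt = config.time_step
    forces, _, clean = _forces_energy(network, pos, load)
    if not clean:
        raise RelaxationError("initial state breaches the WLC domain")
    resid = _max_residual(forces)
    it = 0
    while resid > config.force_tolerance and it < config.max_iterations:
        if inertial:
            new_vel = (vel + dt * forces / m) / (1.0 + dt * gamma / m)
            trial = pos + dt * new_vel
        else:
            trial = pos + dt * forces / gamma
        tf, _, clean = _forces_energy(network, trial, load)
        new_resid = _max_residual(tf)
        if not clean or not np.isfinite(new_resid) or new_resid > 4.0 * resid:
            dt *= 0.5
            if dt < 1e-18:
                raise RelaxationError(
                    f"relaxation step collapsed (dt={dt:.3g}) at iteration {it}"
                )
            if inertial:
                vel[:] = 0.0
            it += 1
            continue
        pos, forces, resid = trial, tf, new_resid
        if inertial:
            vel = new_vel
        dt = min(dt * 1.1, config.time_step * 100)
        it += 1
    if not np.all(np.isfinite(pos)):
        raise RelaxationError("relaxation produced non-finite positions")
    return RelaxResult(
        network=replace_positions(network, pos),
        converged=bool(resid <= config.force_tolerance),
        max_residual=resid,
        n_iterations=it,
    )


def replace_positions(network: ActinNetwork, pos: np.ndarray) -> ActinNetwork:
    return replace(network, vertices=pos)


# ---------------------------------------------------------------------------
# Readouts
# ---------------------------------------------------------------------------


def strain_of(deformed: ActinNetwork, reference: ActinNetwork) -> float:
    """Axial strain (r - r0)/r0 from half-extents along the stretch axis.

    The half-extent is measured over the load-bearing (largest connected)
    component; disconnected fragments do not move under load and would
    otherwise dilute the readout.
    """
    if not deformed.same_topology(reference):
        raise ValueError("strain_of requires networks with identical topology")
    idx = deformed.core if len(deformed.core) else np.arange(deformed.n_vertices)
    ax = deformed.axis

    def half_extent(net: ActinNetwork) -> float:
        z = net.vertices[idx, ax]
        return 0.5 * float(z.max() - z.min())

    r0 = half_extent(reference)
    if r0 <= 0:
        raise ValueError("degenerate reference: zero extent along stretch axis")
    return (half_extent(deformed) - r0) / r0


# ---------------------------------------------------------------------------
# Strain-force curves
# ---------------------------------------------------------------------------


@dataclass
class StrainForceCurve:
    """Paired applied-force / strain observations (mean +/- SE per level)."""

    force: np.ndarray  # N, strictly increasing
    strain_mean: np.ndarray
    strain_se: np.ndarray | None = None
    n: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        self.strain_mean = np.asarray(self.strain_mean, dtype=float)
        if len(self.force) != len(self.strain_mean):
            raise ValueError("force and strain columns differ in length")
        if np.any(np.diff(self.force) <= 0):
            raise ValueError("forces must be strictly increasing")
        if self.strain_se is not None:
            self.strain_se = np.asarray(self.strain_se, dtype=float)
            if len(self.strain_se) != len(self.force):
                raise ValueError("strain_se column length mismatch")
            if np.any(self.strain_se < 0):
                raise ValueError("strain_se must be >= 0")
        if self.n is not None:
            self.n = np.asarray(self.n, dtype=int)
            if len(self.n) != len(self.force):
                raise ValueError("n column length mismatch")


def strain_matrix(
    params: NetworkParams,
    forces: np.ndarray,
    replicates: int,
    seed: int,
    config: RelaxConfig | None = None,
) -> np.ndarray:
    """Strain of each replicate network at each force level.

    One fresh network per replicate (seeds spawned deterministically from
    ``seed``); each is first relaxed under zero load to its reference
    state, then relaxed at each force level in ascending order with warm
    starts (quasi-static continuation).  Returns shape
    (len(forces), replicates).
    """
    forces = np.asarray(forces, dtype=float)
    if np.any(forces < 0) or np.any(np.diff(forces) < 0):
        raise ValueError("forces must be nonnegative and non-decreasing")
    config = config or RelaxConfig()
    child_seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2**31)
    out = np.empty((len(forces), replicates))
    for rep in range(replicates):
        net = build_network(params, int(child_seeds[rep]))
        ref = relax_network(net, make_load(net, 0.0), config).network
        state = ref
        for li, f in enumerate(forces):
            try:
                state = relax_network(state, make_load(ref, float(f)), config).network
            except RelaxationError as err:
                raise RelaxationError(
                    f"relaxation failed at force level {li} (f={f:.3g} N), "
                    f"replicate {rep}: {err}"
                ) from err
            out[li, rep] = strain_of(state, ref)
    return out


def simulate_stretch_curve(
    params: NetworkParams,
    forces: np.ndarray,
    replicates: int = 5,
    seed: int = 0,
    config: RelaxConfig | None = None,
    label: str = "",
) -> StrainForceCurve:
    """Mean +/- SE strain-force curve over replicate network realizations."""
    mat = strain_matrix(params, forces, replicates, seed, config)
    se = (
        mat.std(axis=1, ddof=1) / math.sqrt(replicates)
        if replicates > 1
        else np.zeros(len(mat))
    )
    return StrainForceCurve(
        force=np.asarray(forces, dtype=float),
        strain_mean=mat.mean(axis=1),
        strain_se=se,
        n=np.full(len(mat), replicates),
        label=label,
    )
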