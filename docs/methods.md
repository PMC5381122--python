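# Methods

`cytostretch` characterises cell biomechanics from dielectrophoresis
(DEP) cell-stretching: it estimates the stretching force a microfluidic
chip applies to a captured cell, simulates the cell's deformation with a
coarse-grained actin-cytoskeleton model, and inverts measured
strain–force curves for cytoskeletal structural parameters.  This note
records the models, the numerical choices, and the limits of what the
synthetic-data experiments demonstrate.

## DEP force estimation

A polarizable cell in a non-uniform AC field experiences a
dielectrophoretic force.  Three estimators of increasing fidelity are
implemented, all reported as time averages for sinusoidal drive of
amplitude `U` (peak-to-peak voltage = 2U).

**Clausius–Mossotti factor.**  The cell is a homogeneous dielectric
sphere: `K = (ε*_c − ε*_m)/(ε*_c + 2 ε*_m)` with `ε* = ε0 ε_r − jσ/ω`.
Defaults: medium ε = 78, σ_m = 5.29 mS/m (low-conductivity
sucrose/dextrose stretching buffer); cytoplasm ε_c = 60, σ_c = 0.2 S/m.
These give Re[K] ≈ +0.92 at the 1 MHz operating frequency (pDEP,
consistent with cells being attracted to and captured at the electrode
edge) and a pDEP→nDEP crossover near 60 MHz from the permittivity
contrast.  A homogeneous sphere cannot show the low-frequency nDEP that
real cells display below ~25 kHz — that behaviour comes from the
insulating membrane of a shelled particle, and shell models are out of
scope here.  `crossover_frequency` therefore correctly returns "none"
over the experimentally scanned 100 Hz–5 MHz band for the default cell.

**Simplified (parallel-plate) estimate.**  `F = ¼ ε0 ε (U/d)² · 4πr²`
with `d` the electrode gap (20 μm) and `r` the cell radius (7 μm).
Exact in `U²`, frequency-independent, and an overestimate because the
actual field at the cell is weaker than `U/d`.  With ε = 80 this
reproduces the published six-voltage reference table to 0.01 nN; with
the ε = 78 stated for the medium elsewhere, all values shift by −2.5%.
Both values are plain configuration.

**Field-based estimates.**  The chip cross-section (side view) is
solved as a quasi-electrostatic phasor problem
`−∇·((σ + jωε0ε)∇φ) = 0` on a uniform Cartesian grid: conservative
finite-volume five-point stencil, complex coefficient assigned per node
by material and harmonically averaged on faces (this builds flux
continuity at the cell–medium interface into the discretization),
Dirichlet potentials on two zero-thickness electrode segments on the
bottom wall, zero normal flux elsewhere, direct sparse LU solve.
Default geometry: 100 × 50 μm window of the channel (the full 5 mm
channel is unnecessary — the field decays within a few gap widths), two
30 μm electrodes separated by the 20 μm gap, grid spacing 0.25 μm.  The
cell is captured at the inner edge of the driven electrode; its centre
sits one radius plus a 1 μm standoff above the wall so a medium layer
separates the interface from the insulating boundary (a tangent contact
would leave no room for the stress contour).

*Equivalent dipole moment (EDM):* `F = 2πr³ ε0 ε_m Re[K] ∇⟨E²⟩`, with
`⟨E²⟩ = |E0|²/2` for amplitude phasors, probed at the cell centre of the
particle-free solution (central differences of the nodal `|E0|²` grid,
bilinear interpolation).

*Maxwell stress tensor (MST):* the time-averaged 2D stress tensor
`T = ¼ ε0 ε_m (E E* + E* E − |E|² I)` is sampled at 720 points on a
circle 1.5 grid cells outside the rasterized cell interface (medium
side; in the homogeneous source-free medium the integral is
contour-independent, so the small outward offset only reduces staircase
error), contracted with outward normals, integrated by the trapezoid
rule, and multiplied by the out-of-plane thickness.

**Out-of-plane thickness.**  The 2D solver computes force per unit
length of an infinite cylinder; multiplying by a thickness equal to the
particle's own diameter makes the slab force agree with the 3D sphere
dipole force in the small-particle limit (the ratio of cylinder to
sphere polarizability is ≈1 for these materials).  The default
thickness is therefore the cell diameter, 14 μm, and the dipole-limit
verification (radius gap/20 = 1 μm, thickness 2 μm, 0.125 μm grid)
shows MST within 7% of EDM.  At the physical cell size (r comparable to
the gap and to the field's length scale) the dipole approximation is
genuinely poor, and the solver reproduces the expected ordering
`F_EDM < F_MST < F_simplified` at every protocol voltage, with all
values in 0.1–10 nN.  The published EDM/MST columns themselves are not
reproduction targets: the authors' exact electrode lengths, cell
standoff and meshing are unpublished, so only range and ordering are
asserted (our 2 V values, 0.25/0.51 nN, sit near the published
0.28/0.72 nN).

## Actin-network model

The cytoskeleton is `N_AF` straight filament segments of contour length
`L_c` in a spherical shell `[R_I, R_E]`, ends crosslinked by
actin-binding proteins (ABPs) modelled as linear springs `f_c = k_c Δx`.
Filaments follow the MacKintosh worm-like-chain (WLC) law

    f_a = 81 kB T Lp² Lc² x / ((Lc² − 6 Lp x)² (Lc² + 3 Lp x)),
    x = Δr + δr0,

linear near `x = 0`, divergent at the extension limit
`x = Lc²/(6 Lp)`; `δr0` is a pre-extension representing resting
cytoskeletal tension.  The contour length is tied to crosslink density
`R`, filament diameter `d_Actin` and F-actin concentration `C_AF` by
`L_c = κ (R^0.2 d_Actin/2) √(π/C_AF)`, where κ (config field
`length_scale`, default 800, dimensionless) bridges the mixed unit
convention (nm, μM → μm).

**Coarse-graining.**  A physiological network has ~10⁵–10⁶ filaments;
simulating that is not practical per relaxation, so the default
`N_AF = 500` is a computational reduction.  κ = 800 was chosen so that
the reduced network still percolates across the shell: with fewer
filaments, longer ones (L_c ≈ 1.5–2.3 μm for C_AF = 15–30 μM) are the
down-scaling that preserves connectivity.  The ABP capture radius is an
absolute length (default 2.5 μm) rather than a multiple of L_c: a
L_c-proportional radius makes the crosslink count collapse as C_AF
rises, which would invert the concentration-stiffening direction.  With
the absolute radius, raising C_AF shortens filaments and shrinks their
extension window, and the network stiffens — the physically expected
direction — in the well-connected regime (N_AF ≳ 400).  At much smaller
filament counts the connectivity loss dominates and the direction can
invert; property tests therefore probe stiffening at the full default
count.

**Construction randomness.**  Each filament draws midpoint (uniform in
shell volume) and orientation (uniform on the sphere) from its own
seeded substream, with rejection until both endpoints lie in the shell
(bounded retries); candidate crosslinks (endpoint pairs of distinct
filaments within the capture radius) are ranked by a stable per-pair
hash priority and taken until the target `R·N_AF` is met.  Beyond
reproducibility, the local substreams make the realized network vary
*quasi-continuously* with the structural parameters — a small parameter
change re-draws only the filaments and pairs it actually affects —
which is what makes simulation-based fitting with common random numbers
workable.  Pole caps (half-angle 30° about the stretch axis) are
restricted to the largest connected component so the load always acts
on a percolating cluster, and are widened in 5° steps if a small
realization leaves a cap empty.

**Loading and relaxation.**  The stretching force is split equally over
the cap vertices: +F·ẑ distributed over the plus cap, −F·ẑ over the
minus cap (a distributed pull emulating DEP pole traction; a two-point
mode can be built by hand for tweezer-like loading).  Mechanical
equilibrium solves the overdamped force balance `η ṙ_i = F_i`.  The
default relaxer minimizes the total elastic energy (closed-form WLC
potential obtained by partial fractions, plus harmonic ABP terms, minus
load work) with L-BFGS; its gradient is exactly `−F_i`, so the
minimum is the overdamped fixed point, reached orders of magnitude
faster than explicit integration through the stiff WLC divergence.
Explicit overdamped Euler and a damped inertial mode (fictitious mass
`m_i = 10⁻¹⁷ kg`, overdamped by ≥10× at the default per-vertex Stokes
drag) are kept as alternatives and agree with the minimizer on oracle
problems.  Numerical safeguards: beyond 99.9% of the WLC extension
limit the force law is continued linearly so trial steps can recover
(an equilibrium in that region is reported as unconverged); beyond the
*compression* root `−Lc²/(3Lp)` — where the algebraic formula, not the
physics, diverges — the same continuation acts as an explicit buckling
regularization and does not block convergence.

**Strain readout.**  `(r − r0)/r0` where `r` is the half-extent of the
load-bearing component's vertex cloud along the stretch axis, after
relaxing the freshly built network to its unloaded reference state
(with prestress the network first contracts).  Force levels are swept
in ascending order with warm starts (quasi-static continuation).

**Defaults as study conditions.**  R = 10 crosslinks/filament,
k_c = 10⁻³ N/m, δr0 = 0.015 μm, L_p = 10 μm, d_Actin = 7 nm, T = 300 K,
shell radii 6.21/7.02 μm (the fitted scale of a ~7 μm leukaemia cell).
These were calibrated so that the default network's strain–force
response spans ~0.08–0.21 over 0.5–2.9 nN — the range reported for
DEP-stretched leukaemia cells (mean strain 0.23 at 2.9 nN) — and so
that the concentration-stiffening direction holds at full equilibrium:
at weaker prestress the coverage-loss softening of shorter filaments
outweighs their extension-window stiffening and doubling C_AF softens
the network, which paired 10-replicate equilibrium runs made clear
(truncated fit-mode relaxations mask the effect because stiffer
networks converge faster).

## Synthetic data

`generate_strain_force_data` emulates mean ± SE strain–force curves:
one network realization per "cell" (default n = 50 cells per level,
mirroring the n > 50 of the study design), additive zero-mean Gaussian
observation noise (default sd 0.03 strain units) on every cell × level
reading, aggregation to mean, SE = sd/√n, and n.  What it does *not*
emulate: cell-to-cell size variation, membrane and non-actin mechanics,
viscoelastic (time-dependent) response, electric-field-induced
cytoskeletal remodelling, or measurement outliers.  Passing tests
therefore demonstrate that the inversion machinery recovers the
parameters of data *generated by this model family*, not that the model
is an adequate description of any particular real cell.

## Inference

**Loss.**  Weighted SSE of mean strains, weights `1/SE²` (unit weights
when SE is absent), model strains from a fixed set of network seeds
shared across all trial parameter vectors (common random numbers), so
the loss surface is deterministic.  Inside the fitting loop,
relaxations use a bounded iteration budget (`FIT_RELAX`,
100 L-BFGS iterations) — a ~0.5% strain bias common to every trial
point, cancelling in the misfit — for an order-of-magnitude speedup.

**Search.**  Nelder–Mead within box bounds, seeded from the best of a
small deterministic Sobol presearch (the quasi-smooth loss has local
jumps from discrete topology flips, so a single distant start is
unreliable).  `N_AF` is rounded inside the loss; infeasible or failing
trial points get +∞ loss and are logged, not fatal.  The returned
optimum is the best point actually evaluated.

**Correlated parameters.**  Concentration and prestress trade off along
a stiffness ridge (prestress is weakly identified: its mechanical
leverage only appears when filament pre-tension is comparable to the
per-vertex load, hence the low-force protocol used in the joint
recovery study, and truths placed at δr0 ≈ 2/3 of the extension
window).  `fit_parameters_iterative` fits one parameter at a time with
the others at their current estimates, sweeps the free set twice, and
returns the best point evaluated in any stage — losses are comparable
across stages because curve, weights, seeds and relaxation settings are
shared.  Fitting more than three parameters on a single curve emits an
identifiability warning.  Recovery accuracy varies with the seed of the
synthetic dataset: at 5 replicates per evaluation the loss landscape
occasionally contains remote quasi-degenerate pockets (a distant
parameter value whose 5-network mean mimics the curve), so recovery
errors are typically 1–5% but can reach ~20% for unlucky seed/replicate
combinations; more replicates per evaluation shrink the pockets at
proportional cost.

**Modulus.**  Stress = force/area with the midplane cross-section
`πr0²` by default (the full surface `4πr0²` alternative rescales the
modulus by exactly 4 and is carried as metadata); ordinary least
squares through the origin (zero force ⇒ zero strain by the strain
definition); R² computed on the through-origin fit.  The absolute
moduli of the source study are not reproduction targets — they derive
from an area convention in an external reference — but modulus *ratios*
between groups are convention-independent, which is what the group
comparison uses.

## Problem sizes and verification scales

Field solves: 0.25 μm grid (80k unknowns, ~2 s) by default; 0.125 μm
(320k, ~25 s) for the grid-refinement and dipole-limit checks.
Recovery studies: N_AF = 500, 5 force levels, 5 replicates per loss
evaluation, ~30–40 evaluations per 1D stage.  Group comparison:
5 replicates per group at four force levels.  These sizes are the
package's standard verification configuration; all are configurable.

## Known limitations

- Homogeneous-sphere CM factor: no membrane dispersion, hence no
  low-frequency nDEP; single-shell models are deliberately excluded.
- 2D side-view field model: the out-of-plane thickness constant is a
  geometric approximation whose error grows when the field varies
  strongly across the cell.
- The network model has no thermal fluctuations, no filament turnover,
  no microtubules/intermediate filaments, no membrane; strain is purely
  quasi-static.
- δr0 and R are weakly identified from a single mean curve;
  multi-parameter fits on one curve should be treated as descriptive.
- Equilibria of floppy networks are not unique; warm-started
  continuation makes the reported strain the quasi-static path's
  equilibrium, which is reproducible under fixed seeds but can differ
  from other load paths by ~1–2% strain.
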