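# Methods

## Model

A protein (or synthetic stand-in) is reduced to one bead per residue at
the Cα position of a *reference* conformation.  Beads strictly closer
than a cutoff `r_c` are connected by identical Hookean springs whose
natural lengths equal the reference distances, so the reference is the
global energy minimum with E = 0.  Torsional terms, distance-dependent
stiffnesses, and the scalar (Gaussian-network) variant are deliberately
out of scope.  The elastic energy is quadratic in the inter-bead
*distances*; because distances are nonlinear functions of coordinates,
the forces — and therefore the relaxation dynamics — are nonlinear.

Motion is overdamped: bead velocity equals the force on it, with the
spring constant κ and the (uniform) mobility absorbed into the energy
and time units.  Hydrodynamic coupling between beads and explicit
thermal (Langevin) forcing are not modeled; fluctuations enter only
through random initial conditions.  Consequently every unforced
trajectory is a gradient-flow descent, `dE/dt = −Σᵢ|Ṙᵢ|² ≤ 0`, ending
at the reference state or a metastable minimum.

### Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `r_c` | contact cutoff (Å) | 10.0 | strict `<`; 8–10 Å is the usual Cα-ENM range and is an ordinary config choice for sensitivity checks.  10 Å reproduces the mean contact degree (≈17) implied by the published motor-protein network sizes. |
| κ | spring constant | 1 (rescaled) | sets the energy unit |
| `f0`, `t0` | random-static-force modulus and duration | **required, no default** | protein-specific; the hinge experiments use 0.5 and 30 (see below) |
| `a` | RMS perturbation amplitude (Å) | **required, no default** | hinge experiments use 0.4 Å |
| `force_tol` | convergence: max per-bead force | 1e-8 | |
| `rmsd_tol` | endpoint classification radius (Å) | 1.0 | Kabsch-superposed |
| `max_stretch` | unfolding guard (× d⁰) | 2.0 | checked on force-prepared states |

## Numerical integration

The gradient flow is integrated with an adaptive embedded Runge–Kutta
4(5) scheme (`scipy.integrate.solve_ivp`, RK45).  Spring networks mix
fast local modes and slow collective ones (eigenvalues spread over ~3
orders of magnitude), so the controller takes small steps through the
initial transient and stability-limited steps along the exponential
tail.  Convergence is a terminal event: largest per-bead force below
`force_tol`.

Tolerances: `rtol = 1e-10`, `atol = 1e-12`.  The error controller's
noise floor near a minimum leaves residual forces of order
`rtol · |R| · λ_max`; at `rtol = 1e-8` that floor (~1e-7) sits *above*
the convergence threshold and the event can never fire, while at
`rtol = 1e-10` the tail remains stability-limited, so the tighter
setting costs almost nothing and terminates cleanly.  An energy increase
beyond the integrator tolerance on an unforced trajectory raises an
error naming the offending step.

Frames are recorded on a log-spaced schedule anchored at `t_max·1e-7`:
the initial fast transient carries most of the configuration-space path
length and must be resolved by the frame grid, not only by the internal
steps.  The mechanical coordinate is discretized two independent ways —
summed frame-to-frame chord length in the full 3N-dimensional space, and
the midpoint quadrature `Δs = √(−ΔE·Δt)` — which agree to <0.1% on the
recorded grids (points with `s` below 1% of the total path are excluded
from the comparison: both estimators lose relative accuracy inside the
convergence noise floor).

Endpoint identity uses RMSD after optimal *proper-rotation* (Kabsch)
superposition; the dynamics is invariant under rigid motion, and
force-prepared starts generally carry net drift.  Proper rotations only:
a mirror-image minimum (see the bistable fixture) must count as
distinct.

## Initial-condition protocols

*Force-prepared random deformations.*  Each bead receives an independent
random force of exactly modulus `f0` with uniform direction on the
sphere (normalized Gaussian draw); the forced dynamics runs for `t0`,
the forces are released instantaneously, and the reached conformation is
the start.  The unfolding guard rejects preparations stretching any link
beyond `max_stretch·d⁰`.  `f0` and `t0` are protein-specific and
deliberately have no defaults.  For the 28-bead hinge, `f0 = 0.5`,
`t0 = 30` produce mean deformations of ≈1 Å superposed RMSD with maximum
link stretch ≈1.15 — large relative to the harmonic domain, far from
unfolding.

*RMS displacements.*  Isotropic Gaussian offsets rescaled post hoc so
the realized per-bead RMS displacement equals `a` exactly, making the
amplitude a controlled variable.  `a = 0.4` Å for the hinge robustness
bundle: comparable to thermal fluctuation amplitudes, well below the
deformation scale of the transition itself.

*Crystallographic second conformation.*  Coordinates of the residues
paired between the two structures, ordered as the network's beads; no
superposition is applied.

All randomness flows through numpy's PCG64 generator with explicit
seeds; outputs record the seed and a hash of the scientific
configuration.

## Trajectory reduction and bundle statistics

The harmonic fit `E = k·s²` is least squares through the origin over
`s < s_window`; the *harmonic radius* is the largest `s` up to which the
profile deviates <10% from the fitted parabola (points below a 1e-9
relative energy floor are ignored — they are integrator noise).  The 10%
threshold is this package's own convention.  For the acceptance
comparison with λ₁/2 the window is 0.05 Å, safely inside the hinge's
harmonic domain.

Bundle dispersion is computed against *progress* — each trace's own
remaining arc length in the (l_AB, l_BC) label plane, since traces have
different total lengths — as the RMS distance to the bundle medoid of
the cross-section at each progress value.

Branch detection is this package's formalization of a visually obvious
phenomenon, and it is deliberately conservative.  A cross-section is
bimodal when a 2-means split (scikit-learn) yields (i) cluster centers
separated by more than 3× the within-cluster spread, (ii) an empty
margin: the closest inter-cluster pair farther apart than the
within-cluster spread (an elongated unimodal cloud fails this), and
(iii) non-antipodal approach directions: the angle at the endpoint
between the two cluster directions below 150° — the two arms of the
*same* soft-mode line through the endpoint are one undirected path, not
two valleys.  A bundle is *branched* when bimodality persists over at
least 4 consecutive progress-grid points (isolated flags are unstable
splits of one tight arm); the merge progress is the smallest value in
that run.  The 3× factor, margin rule, angle, and run length are
config-exposed.

## Synthetic structures

The generators emulate exactly the geometric facts the analysis relies
on, with Cα-like 3.8 Å bead spacing:

* **chain / helix** — analytic geometries with closed-form link counts
  and (for the 3-bead chain) hand-diagonalizable Hessians.
* **two-domain hinge** — two FCC-packed blobs (compact, non-planar →
  exactly six zero modes) joined by a short helical linker (straight
  linkers add floppy transverse zero modes).  The "deformed" state
  rotates one side rigidly about the hinge by 12° — about z for the
  primary opening, about y for a qualitatively different second valley
  used in the branching experiment.  Contact-topology preservation
  between all states is guaranteed *by construction*: per bead pair, the
  interval between its minimum and maximum distance across the
  conformations is forbidden to the cutoff; an admissible cutoff value
  near the requested one is located and the geometry rescaled by the
  small ratio (≲10%), so the requested cutoff classifies every pair
  identically in every state.  Among admissible candidates the one
  giving the stiffest hinge with exactly six zero modes is preferred —
  soft hinges relax impractically slowly.  The standard 28-bead hinge
  has 201 links, λ₁ ≈ 0.054, spectral gap λ₂/λ₁ ≈ 2.8.
* **bistable pyramid** — a scalene triangle base plus off-center apex,
  fully spring-connected.  Reflecting the apex through the base plane
  preserves every link length, so the mirror conformation is a second
  zero-energy minimum that no proper rotation can superpose on the
  reference (the geometry is chiral); crossing between basins compresses
  the apex springs, creating a barrier.  Bistability is confirmed at
  generation time by the exhaustive multi-start descent oracle (48
  random 3.5 Å-RMS starts relaxed to convergence, endpoints deduplicated
  by superposed RMSD); the large search amplitude is needed because the
  mirror basin is entered only when the apex crosses the base plane.

What the fixtures do **not** emulate: amino-acid sequence, realistic
packing heterogeneity, the size (hundreds of residues) and spectral
density of real motor domains, or crystallographic noise.  Passing tests
therefore demonstrate the correctness of the machinery and the
qualitative phenomenology (single attractive valley, branching,
harmonic-domain smallness), not quantitative predictions for any real
protein; real structures enter through the same `ExperimentConfig`
interface with a PDB pair.

## Problem sizes

The study systems are sized for desk-scale, exactly reproducible runs:
28-bead hinge networks, 100 random-deformation trajectories, 50
perturbed-functional trajectories, 24 two-valley trajectories, 400-frame
functional relaxations, and a 2-bead spring for the closed-form checks.

## Known limitations

* Dense Hessians and eigendecompositions only (3N up to a few thousand);
  adequate here, not for ribosome-scale networks.
* Identifier-based residue pairing; structures whose chains/numbering
  disagree need an explicit chain map, and no sequence alignment
  fallback exists.
* The branch detector assumes two valleys; three-way branching would be
  reported as a single split.
* Explicit RK integration is stability-limited on the stiff tail; very
  soft systems (λ₁ ≪ 0.01 in rescaled units) converge slowly.
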