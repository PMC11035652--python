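# Methods

`condnet` implements the computational workflow used to characterize the
internal structure and dynamics of biomolecular condensates formed by
pentameric scaffold proteins (the N-terminal region of nucleophosmin,
"N130", whose pentamerization domain we abbreviate PD) complexed with
arginine-rich peptides (rpL5), together with the simple-liquid
(Lennard-Jones) reference calculations and the wet-lab-side fits (FRAP,
small-angle scattering, phase maps) that frame those results.

## Coarse-grained potential

The configurational energy is a five-term decomposition

    W = W_LJ + W_el + W_b + W_theta + W_phi

* **W_LJ** — truncated 12-6 Lennard-Jones between all bead pairs,
  `4 eps_ij [(sig_ij/r)^12 − (sig_ij/r)^6]` for `r < r_c`, with
  Lorentz–Berthelot mixing `sig_ij = (sig_i + sig_j)/2`,
  `eps_ij = sqrt(eps_i eps_j)` and `r_c = 2.5 sig_ij` by default.  The
  potential is truncated without shift, matching the conventional
  pair-style behavior; a shifted variant is switchable (`lj_shift`) and
  is what the NVE conservation test uses, since an unshifted cutoff
  injects energy whenever a pair crosses it.
* **W_el** — Debye–Hückel screened Coulomb
  `C q_i q_j exp(−kappa r)/(eps r)`, with dielectric 80.0 and
  `kappa = 0.1 Å⁻¹` in real units.  The Coulomb prefactor is
  332.0637 kcal·Å/(mol·e²) in real units and 1 in reduced units.  Two
  electrostatic cutoffs (24.1 Å default, 15.0 Å optional) are exposed as
  per-bead-group values; a pair uses the larger of its two groups'
  cutoffs.  Which beads the shorter cutoff applies to is a free choice
  of the configuration.
* **W_b, W_theta** — harmonic bonds `K (b − b0)²` and angles
  `K (θ − θ0)²`.
* **W_phi** — a three-term Fourier series
  `Σ_{n=1..3} K_n (1 − cos(n φ − φ_n))` in the instantaneous dihedral φ,
  plus a quadratic variant `K (φ − φ0)²` (wrapped to (−π, π]) used to
  constrain rigid arm anchors.

Charges are integer: +1 for Arg/Lys-type beads, −1 for Asp/Glu-type
beads, 0 otherwise (including the PD bead).  Beads separated by one or
two bonds are excluded from the nonbonded terms (1-2/1-3 exclusion, the
common bead-spring convention; the policy depth is configurable).
Analytic forces are the exact negative gradients of every term; the test
suite verifies them against central finite differences at 1e-6 relative
on random bonded configurations, and the angle/dihedral gradients use
the standard geometric formulas with degenerate-geometry floors
(sin θ ≥ 1e-8).

Overlapping beads (r below 5% of sig_ij) are evaluated at a clamped
separation and flagged, so a pathological configuration yields a large
finite energy rather than an overflow.

## Simulation engine

Two NVT integrators share one interface:

* a compiled (numba) path for single-type reduced-unit LJ systems — half
  Verlet neighbor lists built from linked cells with a 13-offset half
  stencil, displacement-triggered rebuilds (skin/2 criterion),
  cell-sorted particle order for cache locality, and a BAOAB Langevin
  splitting whose O-step noise is pre-generated per block by a seeded
  PCG64 generator.  With the friction set to zero the scheme reduces to
  velocity Verlet (NVE).
* a generic NumPy path for bonded, multi-type, charged systems (the
  condensate replicas), with a skin-buffered nonbonded pair cache
  refreshed every `nlist_every` steps.  Bead types whose interaction
  range approaches the minimum-image radius (the 53 Å PD bead in a
  reduced box) are paired explicitly against all beads; the remaining
  types go through a periodic KD-tree query.  The tree and brute-force
  paths agree to round-off and both are exercised in the tests.

The default thermostat is Langevin with the damping time constant
mapped to friction `gamma = 1/damping`; a single Nose–Hoover variant is
provided in the generic path for protocol parity.  Structural
observables (g(r), coordination numbers, degree distributions) are
ensemble averages and insensitive to this choice, which is why the
fast path only implements Langevin.

LJ state points follow the standard pure-phase reference conditions:
vapor at reduced density 0.01 and temperature 1.0, liquid at 0.8/1.0,
solid at 1.5/0.758, integrated at dt = 0.005 τ with damping 0.5 τ.  The
desk-scale defaults are N = 2000 particles (2048 for the solid, the
nearest perfect FCC filling), 10⁴ settling steps and 2×10⁵ production
steps with frames every 2×10³ steps, of which the last 50 frames enter
the analysis — a proportional scaling of the convention of analyzing
only the final portion of much longer runs.  These sizes were chosen
once as the smallest at which the three phases separate cleanly in
their degree statistics; the vapor/liquid/solid signatures (mode 0,
mean ≈ 13, mode 12) are flat in N and steps well below this scale.

Initial configurations are either simple-cubic lattices, FCC lattices
(solid), or random sequential addition with a minimum-separation floor
(0.85 σ default); stalled placement raises an error reporting the
achieved density rather than silently densifying.

## Radial distribution functions and coordination

g(r) uses half-open bins [r, r+dr) with centers at r + dr/2, exact
dual-tree pair counting on the periodic box, and normalization by the
global number density of the partner selection (the condensate fills
its box as a single dense phase; a droplet-in-box local-density variant
is out of scope).  Identical selections exclude self-pairs; disjoint
composite selections (all acidic beads of a tract vs all basic peptide
beads) pool every cross pair, i.e. a linear superposition of pair
distributions; partially overlapping selections are rejected.  Bin
widths default to 0.5 Å for condensate-scale systems and 0.025 σ for
reduced-unit LJ systems.

The first minimum of g(r) — the edge cutoff for the network analysis —
is located on a moving-average-smoothed curve (window 5 bins): the first
maximum must be a genuine structural peak (prominence ≥ 0.05), while
the following minimum needs only a small prominence (0.005), so a
dilute vapor whose g(r) decays almost monotonically after its contact
peak still yields a cutoff at its first dip.  A structureless profile
raises an explicit no-minimum error; nothing defaults silently.

Coordination numbers integrate `4 pi rho g(r) r²` by trapezoid to the
cutoff; for the ideal gas this matches (4/3) π ρ r³ to quadrature
error.  Potentials of mean force are the Boltzmann inversion
`w = −kT ln g`, NaN-masked where g = 0.

## Graph construction and degrees

Given two bead selections and the first-minimum cutoff, an edge joins
two beads when their minimum-image distance is strictly below the
cutoff (the strict/non-strict distinction is measure-zero and
documented).  The bead adjacency is block-summed to molecules: two
molecules are adjacent when any selected bead pair is in contact, and
the weighted variant stores the block contact count.  The production
path finds unique molecule-id pairs of the contacting beads; an
explicit block-reduction of the full bead matrix is retained as an
independent oracle and the two are asserted identical on randomized
fixtures.  Self-loops are excluded by construction, and bipartite
selections can have no within-class edges.  Degrees are row sums of the
unweighted adjacency; distributions are normalized per snapshot and
then averaged over frames (histogram mean, not graph union), with SEM
across independent replicates.

For atomic systems every particle is its own molecule, which makes the
same pipeline produce the LJ contact graphs: the vapor's modal degree
is 0, the liquid's mean lands at ~12–13, and the solid is sharply
peaked at exactly 12 — the close-packed reference (coordination 12 in
any close-packed lattice; the FCC fixture ships that ground truth).
Against this baseline the pentamer-scaffold coordination of ~4 reads as
a specific-crosslink network fluid rather than a packed liquid.

## Mean squared displacements

MSD(m) is doubly averaged: over all (T − m) start frames for each
window length m, then over the selected particles.  The printed form of
the window-average normalization reuses one symbol for both particle
and frame counts; we normalize the inner sum by the number of windows
(T − m).  A naive triple-loop implementation is kept as the exact
oracle.  Trajectories must carry image flags (unwrapped coordinates);
wrapped-only input is refused rather than silently aliased.

Regime exponents are least-squares slopes of log MSD vs log t.  Default
windows take the first ~7% of lag times (early, super-diffusive in the
condensate) and the last 50% (late, sub-diffusive), scaled from the
fixed windows used on picosecond-resolved trajectories.  The diffusive
window scans sliding windows spanning a factor 1.5 in lag time and
scores each by the R² of a through-origin MSD ∝ t fit (threshold 0.99);
the through-origin constraint is what makes locally-linear but
non-proportional curves (ballistic t²) fail.  The contiguous run of
passing windows containing the best one defines the diffusive region;
t_D is its median lag time.  Per-molecule exponent histograms fit each
molecule's own window-averaged MSD; failures are recorded as NaN and
negative exponents are kept — they reflect the statistical uncertainty
of single-molecule window averages at long lags, not physics.

## Experimental-side analyses

* **FRAP** — the single-species hyperbolic recovery
  `I(t) = (I0 + I_inf t/t_half)/(1 + t/t_half)` (so
  `I(t_half) = (I0 + I_inf)/2`), fitted by Levenberg–Marquardt with
  per-replicate amplitudes and a shared half-time (grouped fit across
  bleached droplets), optional division by a global-photobleaching
  reference trace, and standard errors from the Jacobian (t_half is
  fitted in log space; its SE is delta-method transformed).  No
  immobile-fraction term, by design.
* **Form factors** — the orientationally averaged Debye sum with unit
  cross-sections, `P(q) = (1/N²) Σ sin(q r_ij)/(q r_ij)`, normalized so
  P(q→0) = 1.
* **Scattering peaks** — the derivative method resamples log I on a
  uniform log q grid, Savitzky–Golay smooths (window ~3% of the grid,
  polynomial order 3), and detects prominent minima of the second
  derivative; the prominence floor adapts to the curvature noise level
  (8× the MAD) so a pure power law returns an empty peak set.  Because
  the extreme-curvature point of a q-space Gaussian is displaced on a
  log grid, each detection is refined to the bump apex: the bracket of
  negative curvature is extended downhill to the surrounding valley
  floors and the apex is located by a parabolic vertex fit (chord-
  subtracted residual for weak shoulders).  The multi-Gaussian method
  fits a power-law background plus Gaussian components seeded by the
  derivative detections; it is an explicit stand-in for multi-peak
  fitting protocols whose details are not public, and is validated only
  on synthetic profiles.  Peak positions map to real-space lengths by
  the Bragg-like relation d = 2π/q.
* **Phase maps** — the index of dispersion (variance/mean of pixel
  intensities) averaged over a well's images; a well is called
  phase-separated when its mean exceeds 10% of the grid maximum (ties
  at the maximum are positive; single-well grids are flagged
  degenerate).

## Synthetic data

Every fixture is generated programmatically, bit-reproducible from its
seed, and carries its ground truth:

* LJ state-point configurations and FCC lattices (nearest-neighbor
  distance a/√2, coordination 12 — we use FCC as the close-packed
  reference; the testable claim, twelve first-shell neighbors, is
  shared by all close-packed stackings).
* The toy condensate: each pentamer is one 53 Å excluded-volume PD bead
  (mass 47544.8 amu) carrying five 13-bead arms with three 3-bead
  acidic tracts (A0/A1/A2, charge −1 each) separated by neutral
  linkers; peptides are 10-bead chains with four +1 beads.  The default
  composition is 12 pentamers : 180 peptides (the 1:15 stoichiometry of
  the full 108:1620 system) in a box scaled as (12/108)^(1/3) × 338.6 Å
  so the PD number density is preserved.  The interaction strengths are
  package-chosen placeholders tuned only to produce association at
  300 K — the systematically optimized per-type parameters are not
  public — and the exact arm sequences are a documented approximation.
  The PD–PD LJ cutoff is capped at 75 Å because 2.5 σ_PD would exceed
  the reduced box's minimum-image radius.  Assembled configurations are
  made integrable by displacement-capped steepest descent before
  dynamics.
* Stochastic walks: static, ballistic, Brownian (Gaussian increments
  with stated D), and fractional-Gaussian-noise walkers (circulant-
  embedding synthesis) for sub-diffusion with exponent 2H.
* Noisy hyperbolic FRAP curves, multi-peak scattering profiles on
  power-law backgrounds, and droplet/uniform well images.

What the synthetic fixtures do *not* emulate: atomistic conformational
ensembles, real SANS noise and instrument resolution, optical PSFs, or
the slow (multi-10⁷-step) relaxation of a real dense phase.  Passing
tests therefore demonstrate that the estimators recover known answers
under their stated models, not that the toy condensate is quantitatively
converged.

## Scaled-down condensate replica

The 12:180 replica has only 66 pentamer pairs per frame, so its
g_PD-PD(r) is shot-noise dominated at any desk-scale run length, and
with the placeholder interaction strengths the pentamers associate more
loosely than in the systematically optimized model: the smoothed
contact peak lands between ~1.1 and ~1.4 σ_PD run to run, with a
first-shell coordination of ~2.  The replica analyses therefore assert
(and the analysis script reports) the robust signatures only: hard-core
exclusion below ~0.8 σ_PD, a contact peak within the first shell of the
pentamer diameter, and a coordination far below the ~12 of a packed
liquid.  The full-scale values (contact peak 53 Å
with higher-order peaks at 95/144 Å, coordination ≈ 4) require the
50k-bead, 10⁸-step runs of the original study and are out of desk
scope by design.

## Numerical choices and limitations

* Reduced units: k_B = 1, C = 1, masses 1; real units: Å, fs, kcal/mol,
  amu, e (kinetic-energy conversion 2390.057 kcal/mol per amu·Å²/fs²).
* RDF pair counting uses `<=` at bin edges (measure-zero vs the
  half-open convention); adjacency uses strict `<`.
* The LJ engine's `fastmath` compilation reorders floating-point
  reductions; runs are bit-reproducible for a fixed seed on one build
  but only statistically identical across compilers.
* The Nose–Hoover variant is a single-thermostat integrator intended
  for protocol parity, not a reference implementation of thermostat
  chains.
* The generic engine is NumPy-vectorized and comfortable to ~3×10³
  beads × 10⁴ steps on one core; larger condensate replicas need the
  compiled path to be generalized (not done — the reduced replica is
  the target use).
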