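# Model and methods

`fibrocell` couples three submodels of a single contractile cell on a
fibrous extracellular matrix (ECM): a cellular Potts model (CPM) for the
cell shape, an overdamped bead–spring network for the fiber gel, and an
ordinary differential equation per focal adhesion (FA) for its
integrin-cluster size. The three are advanced by operator splitting —
each submodel is stepped with the others frozen — so every coupled step
tracks a quasi-steady state of the slower physics.

## Cell: cellular Potts model

The cell is the set of spin-1 sites of a square lattice (spin 0 =
medium). Its energy is

    H = λ A² + J Σ_x Σ_{x'∈NB(x)} 1[σ(x) ≠ σ(x')] − λc·A_um/(A_um + A_h)

with A the cell area, NB the Moore (second-order) stencil, and the last
term a saturating, non-integrin substrate adhesion (A_um in µm²). The
double sum counts every unordered mismatched pair twice; J is calibrated
under that convention. Copy attempts pick a random site and a random
Moore neighbor and are accepted with the Metropolis rule P = 1 for
ΔH ≤ 0 and exp(−ΔH/T) otherwise; one Monte Carlo step is one sweep of
`lattice size` attempts. Retraction over a site holding adhesions pays

    ΔH_FA = λ_FA · X/(X + N_h),   X = max(0, Σ_site (N − N0)),

so matured adhesions anchor the membrane; the numerator is clamped at
zero so a shrunken cluster never *rewards* retraction. Accepted
retractions delete the adhesions left outside; accepted extensions over
a free fiber bead create a nascent adhesion (N = N0) bound to the bead
nearest the site center (ties broken by bead id). Copies into the
outermost lattice ring are rejected, keeping the cell away from the
clamped gel boundary. Cell connectivity is not enforced.

The CPM coefficients are dimensionless. The published physical values of
λ, J and λc do not reduce to a single coherent dimensionless set under
one energy scale together with the 0.25 µm lattice spacing, so this
sector follows the calibration procedure instead: with the defaults
(λ = 0.01, J = 5, λc = 1.33e5, A_h = 50 µm², T = 50) a cell of the
standard initial radius (20 sites = 5 µm) is stationary in the absence
of a gel — the marginal contractility cost of one site equals the
marginal adhesion gain — and shows lively boundary fluctuations at
T = 50. Every area change beyond that baseline is then attributable to
the focal-adhesion feedback. λ_FA = 800 and T = 50 are the published
dimensionless values.

## Gel: cross-linked bead–spring fibers

Fibers are chains of `n_beads = 31` beads at rest spacing
`r_polymer = 0.4 µm` (contour 12 µm ≈ one cell length), joined by
harmonic springs U = (k/2)(r0 − |b_i − b_j|)² and straightened by a
harmonic angle potential U = (K_bend/2)(θ − θ0)², θ0 = π, at every
consecutive triple. A linear-in-Δθ variant of this energy is dimensionally inconsistent
with K_bend's units (N·m·rad⁻²); the standard quadratic form is used. Internally the package works in µm/nN/s/fJ, in
which the published stiffnesses are K = 31 nN/µm (3.1e-2 N/m, the value
the cylindrical-rod conversion K = Y·πd²/4L reproduces for collagen with
Y = 1 MPa, d = 0.125 µm, L = 0.4 µm) and K_bend = 3.88 fJ/rad²
(3.88e-15 N·m·rad⁻²).

Random gels drop `0.48 per µm² × domain area` fibers with uniform
midpoints and von Mises orientations (κ = 0 isotropic, κ = 10 aligned);
cross-link candidates are bead pairs of distinct fibers within a 0.5 µm
capture radius, shuffled and accepted up to `crosslink_density × area`
links. Cross-links are born unstrained — their rest length is the pair's
initial separation — so cross-linking adds connectivity and stiffness
without pre-loading the gel; pre-tensioned variants make densely linked
gels contract on their own, a drift that masks the cell-driven
displacement signal. The regular grid scenario likewise cross-links the
nearest bead pair at every strand intersection at its initial
separation. Beads created outside the domain are
clamped and anchor the gel.

Free beads follow the overdamped Langevin update b ← b + (dt/γ)(F + W)
with ⟨W²⟩ = 2γT_ecm/dt per component and T_ecm = 0.001 (near-
deterministic). The timestep is chosen automatically as
dt = 0.4·γ / max_i k_i, where k_i sums the spring constants and
~4K_bend/r² bending contributions meeting at bead i; summing at shared
beads keeps the explicit update stable at heavily cross-linked junctions
while allowing a larger step than the single-stiffest-bond rule.
Relaxation stops when the maximum free-bead force drops below
`force_tol` or at `max_steps`; non-convergence is logged and tolerated —
within operator splitting each relaxation merely tracks the
quasi-steady state from a warm start.

## Adhesions: catch–slip integrin clusters

Each FA binds one lattice site to one bead and carries a continuous
integrin count N with

    dN/dt = γ_b (N_tot − N) − d0 · d(f* Φ / N) · N,
    d(φ) = e^(φ−φs) + e^(φc−φ),

with the published rates (γ_b = 2.88 s⁻¹, d0 = 0.0288 s⁻¹,
f* = 12.9 nN⁻¹, φs = 4.02, φc = 7.76, N_tot = 390). d(φ) is large at
zero load, minimal at (φs+φc)/2 = 5.89 and divergent in slip, so the
steady-state cluster size N*(φ) is unimodal: adhesions persist only in a
band of per-integrin tension (~0.3–0.7 nN). The ODE is advanced per
coupling step (τ = 2.88 s) by an exponential integrator that freezes
d within adaptive sub-steps (halved until one step changes N by <10%):
the frozen-d update is exact for the then-linear equation, is
unconditionally stable in the stiff catch regime (d(0) ≈ 2.3e3 makes the
plain explicit map oscillate at this τ), and recovers the analytic fixed
points N*(0) ≈ 15.95 and N*(5.89) ≈ 345.2 to machine precision. N is
clamped to [1, N_tot].

The tension Φ on an adhesion is, by default, the magnitude of the net
elastic force of the gel on its pinned bead (`tension_source: ecm`).
This is the two-spring reading: pulling an adhesion across a stiff gel
builds force quickly, across a soft one slowly, and along a fiber more
than across it (stretching vs bending) — the three ingredients behind
stiffness-dependent spreading, the slip-induced downturn on very stiff
gels, and elongation along aligned fibers. The alternative
`cytoskeletal` convention (Φ = K_cyto × distance to the cell centroid,
K_cyto = 0.31 nN/µm) coincides with it where the greedy displacement has
stalled, but is independent of gel stiffness and direction and therefore
cannot produce the slip regime or directional maturation; it is retained
as a config option. Contractility enters through the displacement rule:
once per coupled step, each FA (ascending id) attempts to move one
lattice site toward the cell centroid — restricted to sites under the
cell — and moves, together with its pinned bead, iff the cytoskeletal
spring energy (K_cyto/2)·dist² plus the energy of the springs directly
attached to the bead strictly decreases. FAs move independently and may
share a site.

N0 = 25 and N_h = 100 are not published: N0 sits slightly above the
zero-tension steady state (≈16) so nascent adhesions decay unless
loaded, and N_h spans the observed cluster-size range up to N_tot so the
retraction penalty discriminates soft from stiff conditions. Both are
config-exposed.

## Coupled step and units

One coupled step (= 2.88 s; 0.25 µm per lattice site; 1e4 steps ≈ 8 h)
executes: (1) one CPM Monte Carlo step with FA creation/removal; (2)
centroid refresh; (3) one greedy displacement attempt per FA; (4) gel
relaxation with FA beads pinned (every `relax_every` steps, default 1);
(5) tension recomputation; (6) the integrin ODE for every FA. A
consistency audit (FA ↔ bead bijection, FA sites inside the mask,
clamped beads immobile) runs each step. Randomness flows from one master
seed through separate streams for the CPM, network generation and gel
noise, so runs are bit-reproducible and toggling gel noise does not
perturb the cell's draw sequence.

## Measurement statistics

* Nematic order S = |⟨e^{2iθ}⟩| over fiber segments, length-weighted
  (resultant form; S = 0 isotropic, 1 aligned).
* Cell eccentricity e = sqrt(1 − λ₂/λ₁) from the covariance eigenvalues
  of the occupied site centers; a single site is 0 by convention.
* FA angles: acute signed angle between the centroid→FA direction and a
  reference axis, folded to (−π/2, π/2].
* Remodeling onsets: 5×5-site bins; per-bin order S_i(t) (segments
  assigned by midpoint, length-weighted) and occupancy C_i(t), both
  smoothed by a trailing 10-step mean, fitted with L/(1+e^{−k(t−t0)})
  (initialization: L = max, t0 = half-max crossing, k = 4/rise; k > 0
  bounded; flat or non-converged series are flagged and excluded). The
  lag t0_cell − t0_S is reported over bins where the cell actually
  arrives (occupancy rise ≥ 0.2) and the order signal moves (≥ 0.05).
* Annulus alignment: unweighted mean of final-time S_i over bins whose
  centers satisfy r < |x_i − c| < 1.5r, with r the mask's major-axis
  length (4σ convention).
* Gel displacement: mean Euclidean displacement of non-clamped beads.
* Percolation: a gel percolates if one connected component of the
  bead graph (fiber springs + cross-links) touches two opposite domain
  boundaries along either axis.

## Problem scales

`full_config()` mirrors the study conditions: 200×200 sites (50×50 µm),
cell radius 20 sites, 1e4 steps, relaxation capped at 1e4 sub-steps.
`desk_config()` keeps the same cell, physics and parameters but shrinks
the arena to 100×100 sites (25×25 µm; fiber count scales with area),
runs a few hundred steps and caps each relaxation at 300 sub-steps
(force tolerance 0.05 nN, initial settle 1500 sub-steps). These sizes
were chosen so a full qualitative experiment — a stiffness sweep, an
isotropy comparison — completes in minutes on one core while preserving
every mechanism: adhesion maturation, the slip downturn and directional
tension differences are all local-stiffness effects that do not require
the full arena. What the reduced scale does *not* reproduce are the
absolute spread areas and tension magnitudes of 8-hour runs; tests
therefore assert orderings and signs (biphasic shape, anisotropic vs
isotropic medians, majority-positive onset lags), not absolute figure
values.

## Known limitations

* The soft end of the stiffness sweep relaxes slowly relative to the
  bending-dominated timestep; with the desk relaxation cap the softest
  gels carry some residual (transient) tension, which makes soft–stiff
  contrasts conservative rather than exaggerated.
* Single cell only; no Act/polarity migration, no fiber plasticity or
  degradation, no excluded volume between fibers, 2-D only.
* Quasi-steady-state detection is not automated; runs have a fixed
  number of steps.
* The synthetic gels emulate homogeneous in-vitro networks: fiber length
  is monodisperse and cross-linking spatially uniform, unlike real
  collagen's bundling and heterogeneity, so passing tests demonstrate
  the mechanisms, not quantitative agreement with any particular gel.
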