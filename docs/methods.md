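# Methods

`sasamc` couples a coarse-grained, implicit-water/implicit-salt Monte
Carlo simulator for small associating solutes (caffeine by default) to
the analysis layers that turn its output into full ternary
(water–solute–salt) solution thermodynamics: Kirkwood–Buff (KB)
inversion and a vapor-pressure-osmometry (VPO) style residual-osmolality
analysis.  This note records the model, the numerical choices, what the
synthetic generators emulate, and the limitations a user should know
about before trusting a number.

## The energy model

A molecule is a rigid body of spherical beads, one per chemical group.
The configurational energy of N molecules in a periodic cubic box is

    U = Σ_{a<b} u_WCA(r_ab) + Σ_{a<b} (γ_ab + ε_ab,TFE·c_s)·ΔA_ab(r_ab)
        + N·c_s·Σ_i ε_i,TFE·A_i^ref

with the sums over intermolecular bead pairs.

* `u_WCA` is the Weeks–Chandler–Andersen potential (Lennard-Jones
  truncated at 2^(1/6)σ and shifted), ϵ = 0.5 kJ/mol on every bead.
* `ΔA_ab(r)` is the change in the exposed area of two probe-inflated
  spheres relative to non-overlapping separation.  For radii R ≥ r at
  separation d the lens cap heights are h_R = (r−R+d)(r+R−d)/2d and
  h_r = (R−r+d)(R+r−d)/2d, giving the exposed area
  4π(R²+r²) − 2π(R·h_R + r·h_r); the engulfed regime d ≤ R−r is clamped
  to 4πR² so the potential stays finite and continuous everywhere (the
  WCA core makes deep overlap astronomically improbable, but
  virtual-volume perturbations must never see a discontinuity).
* γ_ab and ε_ab,TFE are arithmetic means of per-bead values.  γ_i is a
  microscopic surface tension describing short-range attraction in neat
  water (hydrophobic/van-der-Waals); ε_i,TFE is a cosolute-specific
  transfer free energy per unit area and molar cosolute concentration.
  Only the product ε_TFE·c_s enters the pair term, so one scalar
  describes a salt at a concentration.
* The one-body term transfers each molecule's reference (monomer)
  surface from water into the cosolute solution.  It is a constant in
  canonical sampling and matters for grand-canonical insertion/deletion
  and Widom insertion, where it is included in ΔU.

Electrostatics are implicit in ε_TFE; the model targets high-salt
conditions where screening lengths are short.

## The caffeine template and its conventions

Eight beads: the two fused heterocyclic rings (the stacking sites, the
only beads carrying γ = 0.0572 kJ/mol/Å²), the three N-methyl carbons,
the two carbonyl oxygens, and the −N=CH− imine group.  Bead positions
are heavy-atom group centroids of an embedded MMFF94-optimized caffeine
geometry (a frozen text fixture; any atom set and group mapping can be
supplied instead).  Each heavy atom belongs to exactly one group; the
fused carbons C4/C5 are assigned to the five-ring bead.

Three numerical conventions close gaps that the group decomposition
alone does not fix.  All of them are exposed as arguments of
`build_caffeine_template` and recorded here with their rationale:

* **Group radius** (`radius_convention="rms"`): bare radius =
  √(⟨|r−c|²⟩ + ⟨r_vdW²⟩) over the group's heavy atoms.  With the
  default 1.4 Å water probe this reproduces the atomistic
  Shrake–Rupley solvent-accessible surface of the same geometry almost
  exactly (CG union surface 338 Å² vs 337 Å² atomistic), which is the
  physical meaning the SASA radii must carry.
* **Reference areas** A_i^ref: exact per-bead union-surface exposures on
  a deterministic Fibonacci spherical quadrature (8192 points,
  relative error ~10⁻³).  A pairwise lens subtraction — natural as it
  would be for consistency with the pair potential — clamps every bead
  of this heavily fused template to zero area (centroid separations of
  1.4–2.5 Å against radii of ~3–3.5 Å over-count the buried surface
  many times), which would eliminate the one-body transfer term
  entirely.  The intermolecular *pair* term keeps the lens form, where
  a single overlap dominates at a time.
* **WCA core size**: σ_i = 1.08 · 2·(R_i − r_probe).  The scale factor
  controls how deeply beads may interpenetrate the probe-inflated SASA
  spheres and thereby the depth and softness of the stacking
  attraction.  It is the one free parameter of the geometry and was
  fixed once against the reference salt-free structural observable of
  the calibrated model, a caffeine–caffeine KB integral plateau
  G22 ≈ 20×10³ Å³ at ~21 mM (this package measures 2.1–2.3×10⁴ Å³ at
  that setting, seeds 2/7/42).

TFE sites default to the five hydrophobic beads (rings + methyls, equal
strength): atomistic simulation evidence places the salt-specific
binding on the hydrophobic surface, the methyl groups above all, and in
this template the ring beads alone expose only 38 Å² of reference area
(the peripheral groups own most of the union surface), which would make
the monomer transfer term ~5× weaker than the reference caffeine–salt
interaction coefficients imply.  The two-site variant remains available
via `tfe_sites=("RC6", "RC5")`.

### A limitation that matters: the two reference anchors conflict

The calibrated reference model is characterized by two published salt-
free observables: the structural anchor G22 ≈ 20×10³ Å³ and a
grand-canonical reference state (molar activity 0.026 ↔ 69 mM total
caffeine in pure water).  Under this package's geometry these are
mutually exclusive: scanning the core-size scale (and independently the
probe radius) maps G22 = 2×10⁴ Å³ to ρ(a = 0.026) ≈ 38–41 mM, and
ρ = 69 mM to G22 ≈ 3.7×10⁴ Å³ — at pair level the two anchors imply
effective association constants of roughly 6 and 15 L/mol respectively.
The shipped default keeps the structural anchor.  Consequences:

* the grand-canonical reference density computed by
  `scripts/acceptance.py` comes out near 40 mM, not 69 mM;
* the model sits further from its aggregation instability than the
  density-matched variant, which keeps the salt-response machinery
  well behaved in the dilute regime;
* near and above ~25 mM activity the ε_TFE-modulation of the *pair*
  attraction (ε-weighted buried area of a stacking contact:
  ~650–1150 Å²) outweighs the one-body monomer term (213 Å²), so the
  net sign of the simulated salt effect inverts at high caffeine
  concentration.  TFE calibration and sign conventions are therefore
  validated at dilute activities (≈ 0.008 M), where the one-body term
  controls the response; the analytic thermodynamic layers (below) are
  sign-correct by construction at all compositions.

## Sampling

Metropolis–Hastings with single-molecule translations (uniform
direction, magnitude uniform in [0, Δ]) and rotations (axis uniform on
the sphere, angle uniform in [−Δθ, Δθ]), a COM-distance-threshold
cluster move, and grand-canonical insertion/deletion at fixed molar
activity with acceptance min(1, zV/(N+1)·e^(−βΔU)) and
min(1, N/zV·e^(−βΔU)); z is the activity converted to number density
and ΔU includes the one-body term.  One "iteration" is a sweep of N
attempted moves, with the sweep length frozen at run start — a
state-dependent chunk length would oversample low-N states between
observer calls in grand-canonical runs (this bias was measured at ~20%
of the mean before being designed out).

The cluster move takes the transitive closure of COM distances below
the threshold (default 6.5 Å), moves it rigidly (rotation about the
seed molecule), and rejects outright when (i) the post-move cluster
membership differs from the pre-move one (detailed-balance guard),
(ii) the cluster percolates through the periodic boundary, or (iii) any
member lies further than L/4 from the seed — condition (iii) guarantees
that every member-pair minimum-image distance equals the true distance,
so rigid motion preserves the internal energy exactly.  A cluster
containing every molecule degenerates to a global translation.

Default move parameters: canonical 2.5 Å / 0.5 rad with a 7.5 Å /
1.0 rad cluster move; grand canonical 10 Å / 1 rad plus
insertion/deletion.  Kernels are Numba-compiled; a single kernel RNG
stream is seeded once per run, so runs are bit-reproducible from the
protocol seed.  Energy bookkeeping is validated by requiring the
accumulated per-move ΔU to match a fresh total-energy evaluation to
10⁻⁶ kJ/mol over a run.

## Estimators

* **RDF**: COM–COM, default 0.25 Å bins, normalized with the exact
  per-frame N and V (grand-canonical safe).
* **KB integrals**: G(R) = ∫₀^R [g(r)−1]4πr²dr by trapezoid; plateau =
  mean over R ∈ [16, 20] Å (configurable).
* **Preferential binding**: Γ₂₃ = ρ₃(G₂₃ − G₂₁) from KB integrals, or
  Γ₂₃(r) = N₂₃(r) − (N₃⁰/N₁⁰)N₂₁(r) from running coordination numbers
  (the latter accepts externally supplied tables).  In a finite bath
  the counts route carries a small analytic excess-volume slope; the
  tests compare each route against its own direct-counting expectation.
* **Pressure**: virtual-volume perturbation,
  p = (kT/ΔV)·ln⟨(1+ΔV/V)^N·e^(−βΔU)⟩ with COM-scaled rigid molecules,
  ΔV = 5 Å³ by default (50 Å³ supported); p^ex subtracts ⟨N⟩kT/V, and
  φ = (p^id+p^ex)/p^id.  The estimator has an O(ΔV/V) discretization
  bias (~NkTΔV/2V²), visible only in ideal-gas tests.
* **Widom**: μ^ex = −ln⟨e^(−βΔU_insert)⟩ with random poses, one-body
  term included.  In the associating fluid the average is dominated by
  rare low-energy insertions; the defaults for activity-model grids use
  200 insertions every 5 sweeps.
* **Δμ^ex** between two grand-canonical runs at equal activity:
  ln(ρ^water/ρ^salt).
* Uncertainties: block averaging with doubling block length, taking the
  largest plateau estimate (conservative for short correlated series).

## Solution thermodynamics

The ternary activity model (1 = water, 2 = solute, 3 = salt):

    ln γ₂ = A₂m₂ + B₂m₂² + (C₁ + C₂m₂)m₃
    ln γ₃± = A₃m₃ + B₃m₃² + (C₁m₂ + C₂m₂²/2)/ν₃
    ln a₁ = −M₁·[m₂ + ν₃m₃ + m₂g₂ + m₃g₃ − g]

where g(m₂, m₃) is the excess Gibbs energy per kg of water in RT units
whose gradients are (ln γ₂, ν₃ ln γ₃).  The caffeine cross-term in
ln γ₃± is forced by the Maxwell relation ∂lnγ₂/∂m₃ = ν₃·∂lnγ₃±/∂m₂, and
ln a₁ follows exactly from Gibbs–Duhem — the residual osmolality of the
model surface is *identically* (C₁ + C₂m₂)·m₂m₃ and the salting-out
constant is k_s(m₂) = C₁ + C₂m₂.  Consistency is enforced by tests that
integrate the Gibbs–Duhem differential along random composition paths
(pointwise residual < 10⁻⁸ with central-difference chemical potentials).

**KB inversion** goes through the grand-canonical fluctuation matrix
B_ij = ρ_iδ_ij + ρ_iρ_jG_ij: the analytic constant-pressure chemical-
potential derivatives are combined with infinite-dilution partial molar
volumes and the water compressibility,
A_ij = βV·∂μ_i/∂N_j|_{T,P} + V̄_iV̄_j/(kTκ_T), and inverted, G following
from B = A⁻¹.  Because the batch volume is built from the same V̄_i,
Σρ_iV̄_i = 1 holds exactly and the forward map recovers the input
derivatives, κ_T and V̄_i to machine precision (round-trip tested at
10⁻⁸).  Compositions with a zero molality are evaluated with a 10⁻⁸
molal floor.  Defaults: T = 310.15 K, κ_T = 4.48×10⁻¹⁰ Pa⁻¹,
V̄ = (18.14, 145.9, salt-specific) cm³/mol.

**Two-stage activity fit**: (A₂, B₂) by weighted least squares on the
salt-free slice of a μ₂^ex grid (μ₂^ex = RT ln γ₂, molality ≈ molarity
in this dilute regime), then (C₁, C₂) on the ternary points with the
binary coefficients frozen; the stage-1 parameter covariance is
propagated into the stage-2 errors (without it, nominal 95% intervals
covered only ~80% in Monte-Carlo recovery studies).

**VPO analysis**: ΔOsm = Osm(m₂,m₃) − Osm(m₂,0) − Osm(0,m₃) with binary
curves smoothed by low-order polynomials through the origin
(quadratic default for noisy tables, cubic for model-generated
surfaces, which the model form makes exact); extrapolation beyond the
binary coverage is refused.  The k_s fit is generalized least squares
using the full ΔOsm covariance — the shared binary fits correlate every
residual point, and ignoring that correlation shrinks the confidence
intervals by ~2× (measured coverage 0.70 vs 0.95).  The in-silico
path (model → osmolality surface → residuals → k_s) shares this code
path verbatim with the experimental-table path.

The k_s ↔ Γ₂₃ relation, with Γ₂₃ counting cosolute ions,

    k_s = −(Γ₂₃/m₃)·(1 + ∂ln γ₃±/∂ln m₃)

is validated as a round trip through KB inversion in the dilute regime
(it is a leading-order relation; agreement is ~10% at m₂ = 5 mmol/kg,
m₃ = 20 mmol/kg).

## Calibration workflows

Stage 1 fits γ to a salt-free osmotic-coefficient curve φ(c) by a
deterministic grid scan plus golden-section refinement, each objective
evaluation being canonical simulations with fixed seeds (the 1D
objective is noisy; a stochastic optimizer would add nothing).  Stage 2
fits a salt's ε_TFE to a Δμ^ex(c_s) curve at fixed solute activity; the
model's exact linearity of Δμ^ex in ε_TFE·c_s admits a slope-matching
shortcut (one probe simulation fixes the response slope, the
least-squares ε_TFE follows in closed form), with a scan fallback.
Targets with sign changes along c_s are flagged as inconsistent with a
single ε_TFE.  Reference curves are user-supplied; shipped named
defaults: γ = 0.0572 kJ/mol/Å², ϵ_WCA = 0.5 kJ/mol and per-salt ε_TFE
values (Na₂SO₄ 0.0178, NaCl 0.003, NaBr −0.001, NaSCN −0.008, NaClO₄
−0.0125 kJ/mol/Å²/M).

## Synthetic data

* `generate_synthetic_osm_table` builds osmolality tables from the
  Gibbs–Duhem surface of an activity model plus Gaussian read noise,
  on the experimental design grid (fixed solute molalities 10, 25, 50,
  75 mmol/kg; salt molalities to 0.5 mol/kg).  It emulates the residual
  structure ΔOsm = (C₁+C₂m₂)m₂m₃ and uncorrelated instrument noise; it
  does *not* emulate drift, calibration error, or composition
  uncertainty, so passing recovery tests demonstrate estimator
  correctness, not robustness to systematic experimental error.
* `generate_toy_system` builds ideal-gas, single-bead WCA and fixed
  dimer states used by the statistical-mechanics limit tests.

## Problem sizes used by the test suite

Tests and the acceptance script run reduced protocols chosen to keep
the default suite interactive: geometry oracle 100 triples × 10⁶
surface points; ideal-gas limits ~6×10³–6×10⁴ sweeps; self-association
KB integral 200 molecules, 250 Å box, 5×10³ + 4×10⁴ sweeps;
grand-canonical reference density 100 Å box, 1.5–2×10⁵ equilibration
and 0.7–1.2×10⁶ production sweeps; activity-model grid 12 state points,
60 molecules, 3×10⁴ sweeps with 200 insertions per 5 sweeps.
Production-quality studies should scale these up (the study-scale
protocols are the config defaults: 250 Å canonical box, 10⁶ iterations,
150 Å grand-canonical box).

## Known limitations

* The pairwise lens approximation over-counts buried area for
  many-bead contacts; with this template a stacking contact buries an
  ε-weighted area larger than the monomer reference surface, which is
  the root of the salt-response sign inversion at high solute
  concentration described above.
* The two reference anchors (G22, grand-canonical reference density)
  cannot be met simultaneously; the structural anchor is shipped.
* k_s from Γ₂₃ is a dilute-regime relation here; no exact association
  correction is applied.
* Widom insertion degrades in strongly clustered configurations;
  grand-canonical Δμ^ex is the more robust route at high density.
* The isothermal compressibility and partial molar volumes are treated
  as composition-independent in the KB inversion.
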