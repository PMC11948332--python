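# Methods

## The geometrical route

The binding constant of a receptor–ligand association is decomposed into
contributions from conformational (c), orientational (o) and positional (a)
restraints imposed in the bound state (site) and released in the unbound
state (bulk), plus a restrained separation PMF.  With the ligand's external
degrees of freedom expressed in Boresch coordinates (r, θ_A, θ_B, φ_A, φ_B,
φ_C over six anchor atoms), the positional angular release at the bulk
reference distance r* becomes the surface integral

    S* = (r*)² ∫∫ exp(−β u_a) sinθ_A dθ_A dφ_A ,

the orientational release the triple integral

    Ω_o = ∫∫∫ exp(−β u_o) sinθ_B dθ_B dφ_B dφ_C      (8π² unrestrained),

and the radial release the separation integral

    I* = ∫_site exp(−β [W(r) − W(r*)]) dr

over the separation PMF computed with all angular restraints active.  The
assembled standard free energy of one dissociation step is

    ΔG° = −kT ln(S* I* C°) − ΣΔG_imposed^site + ΣΔG_released^bulk − kT ln σ,

where every restraint component is defined as the free energy of *imposing*
that restraint in the named state.  The derivation follows from factorising
the bound-state configurational integral: the PMF along r carries the full
Jacobian of its ensemble, e^{−βW(r*)} ∝ r*² Ω_a Ω_o, so S*·I* is exactly
the restrained site volume and dividing by V° = 1/C° references it to 1 M.
A useful consistency check implemented in the tests: with no restraints and
S*·I* = V° the expression vanishes identically, and for a non-interacting
pair it reduces to −kT ln(V_site/V°).

Sign conventions are locked by the end-to-end toy oracle test rather than
by bookkeeping: the assembled total must reproduce a brute-force
configurational integral, which leaves no freedom.

### Analytic closed forms and their residual

For stiff harmonic restraints the angular integrals reduce to Gaussian
closed forms with sinθ frozen at its equilibrium value,

    S* ≈ (r*)² sinθ_A,0 · 2πkT / √(K_θA K_φA),
    Ω_o ≈ sinθ_B,0 · (2πkT)^{3/2} / √(K_θB K_φB K_φC).

The freezing of sinθ carries an exact, derivable residual: averaging
sin(θ₀+δ) over the Gaussian fluctuation of variance kT/K gives
sinθ₀·e^{−kT/2K}, i.e. a free-energy gap of kT²/(2K) per polar angle
(0.0035 kcal/mol at K = 50 kcal·mol⁻¹·rad⁻², 298.15 K), independent of θ₀.
The unit tests pin this law; closed form and quadrature agree to better
than 10⁻³ kcal/mol only for K ≳ 180 (single polar angle) or K ≳ 350 (the
combined angular correction with two polar angles).  Numerical quadrature
(adaptive scipy routines on the separable 1-D factors, relative tolerance
10⁻¹⁰, 201-point Gauss–Legendre fallback) is therefore the default route.

### Symmetry correction

For a homomultimer of n identical chains the labelled, restrained
calculation measures one permutation sector of the bound configurational
integral.  Counting label assignments (n! in total, of which g are
connected to the reference sector by a proper rotation of the complex)
gives the physical binding constant as σ = 1/g times the labelled one;
for a cyclic Cₙ bundle g = n, hence the default rule σ = 1/n and the
correction −kT ln σ = +kT ln n (≈ +0.41 kcal/mol for a homodimer at
298.15 K: indistinguishability makes association *less* favourable than
the labelled estimate).  A brute-force oracle enumerates the permutations
realizable by proper rotations (Kabsch superposition with reflections
excluded) on the bound toy complexes and validates the rule for parallel
dimers/trimers and an antiparallel dimer.  The rule is exposed as an
override for complexes with other point groups, and heteromultimers take
σ = 1.

## Restraints

All restraint potentials are ≥ 0, zero at their reference, and continuous
in value and first derivative at flat-bottom boundaries: the harmonic
Boresch set (dihedral deviations by minimum image), flat-bottom φ/ψ
torsion restraints preserving helicity (width 0 = pure harmonic; the
functional form is configurable because production protocols differ),
flat-bottom restraints on the optimal-superposition RMSD to a reference
(selection is an explicit required parameter — backbone-only vs all-atom
is a user decision), and a cone-plus-cylinder funnel wall whose boundary
radius follows the cone law before the switch distance and the cylinder
radius after it, meeting continuously.

Anchor selection searches CA triples on each side exhaustively (optionally
strided), excludes collinear candidates, and applies hard criteria on
circular statistics over the supplied frames: circular means of the five
restrained DOFs plus the two unrestrained angles c–b–a and A–B–C at least
30° from 0/180°, circular SD ≤ 20°, pairwise anchor separation ≥ 5 Å.
These thresholds are package defaults (the guiding principle is only that
angles stay away from 0/180°, where the sinθ factors vanish and dihedrals
become ill-conditioned); the score is the worst angular margin minus the
mean circular SD, with deterministic lexicographic tie-breaking.

## Toy systems and samplers

The validation systems are rigid three-bead "helices" (centre bead = the
separation anchor at the body origin, an axis bead, and a side bead that
breaks axial symmetry), interacting through smooth Gaussian pair wells
(matched beads, ε = 3 kcal/mol, width 0.8 Å, contact 4 Å) plus a soft
Gaussian repulsion between all bead pairs.  The wells produce a single
dominant docking pose (centre separation, parallel registry, roll), plus a
physically meaningful weakly-bound shell that any correct estimator must
integrate over.  The constructed dimer is exactly C₂-symmetric and the
trimer exactly C₃-symmetric, which the symmetry-counting oracle exploits.
What the toys deliberately do not emulate: internal flexibility, solvent,
rugged energy landscapes, or the sub-kcal/mol per-residue energetics of
real coiled coils — passing the oracle tests validates the free-energy
bookkeeping and the samplers, not any force field.

Samplers:

* **BAOAB Langevin** for point-particle systems (2 fs default step,
  1 ps⁻¹ friction, 298.15 K), deterministic per seed; used for the 1-D
  well-tempered metadynamics benchmarks.
* **Seeded Metropolis Monte Carlo rigid moves** (Gaussian translations and
  rotations about the body centre) for rigid-body systems.  Rigid bodies
  are parameterised by centre + orientation matrix; no constraint solver.
  Langevin dynamics of rigid bodies would require orientational equations
  of motion that add nothing to the validation, so MC is the rigid-body
  sampler by design.

### Well-tempered metadynamics

Gaussian hills with the well-tempered height rule
h = h₀·exp(−V(s)/((γ−1)kT)) accumulate on a grid (periodic for dihedral
CVs); out-of-bounds depositions are rejected and counted, never silent.
The free energy is *not* read from −γ/(γ−1)·V alone: the run freezes the
bias for the final 40% of the steps and recovers
F(s) = −kT ln H(s) − V(s) by umbrella reweighting of the frozen-window
histogram, with block errors from four consecutive sub-histograms.  This
estimator is free of hill-kernel smoothing and of the tempering transient;
with h₀ = 0 it degenerates gracefully to Boltzmann inversion of plain
sampling.  The instantaneous −γ/(γ−1)·V estimate remains available from
the bias state.

### Estimators used by the toy protocol

Desk-scale budgets make two of the textbook estimators fragile, so the
protocol driver defaults to more robust equivalents (the PMF-based
variants remain available via options and are validated separately):

* **Restraint impositions** (ΔG_o^site, ΔG_a^site, receptor conformational
  terms): staircase free-energy perturbation over a geometric
  force-constant schedule (0, 1/128, …, 1/2, 1)·K, each stage sampled by
  plain MC, combining −kT ln⟨e^{−βΔu}⟩ per stage.  Adjacent stages overlap
  well because each doubling perturbs the restrained fluctuations by
  ~kT/2; the two weakest stages get twice the move budget since they
  sample the widest ensembles.  Errors from 5-block spreads per stage,
  combined in quadrature.
* **Separation PMF**: a ladder of harmonic umbrella windows (spacing
  0.5 Å, K = 20 kcal·mol⁻¹·Å⁻², seeded sequentially as a drag along r)
  combined with WHAM; replicate ladders are averaged.  Trimer removal
  steps separate a helix from a roughly twice-deeper well, so their
  ladder defaults to denser, stiffer windows (0.35 Å, K = 30), which cuts
  the replicate scatter by an order of magnitude.  The ladder only
  spans the interacting region: beyond it the PMF follows the exact bulk
  law W(r) = −2kT ln r + c (the spherical-shell Jacobian with
  r-independent angular restraints), so W(r*) is taken from a fit of that
  law over an interaction-free window — far more robust than a single
  noisy endpoint value.  For the stock toys, interactions are < 10⁻⁴
  kcal/mol beyond r ≈ 8 Å under the orientational restraints; r* = 10 Å.

The site is defined identically everywhere as r ≤ 7 Å (a flat-bottom wall
during bound-state sampling, the upper bound of the I* integral, and the
radial cut of the oracle's quadrature), so protocol and oracle compute the
same thermodynamic quantity.

A cautionary observation the toys reproduce: when the two-body receptor of
the trimer step is held together only by a loose species wall instead of a
compensated conformational restraint, the free receptor body rearranges
and transiently follows the leaving helix during the separation PMF, and
the step free energy stops converging at desk-scale budgets — precisely
the receptor-rearrangement failure mode that motivates conformational
restraints in the first place.  The invariance tests therefore compare
different *compensated* restraint parameterisations, whose totals agree
because the imposition terms absorb the difference.

### Brute-force oracle

For two rigid bodies the binding constant is evaluated by direct
deterministic quadrature: positions in spherical coordinates about the
receptor centre (Gauss–Legendre radial and polar nodes, periodic
trapezoidal azimuth — the site boundary is resolved exactly) and
orientations over Euler angles with the Haar measure (Gauss–Legendre in
cosβ, periodic trapezoid in α, γ).  Default resolution (36, 16, 24) ×
(16, 12, 16); the convergence estimate compares against a grid coarsened
by one third and is ≈ 5·10⁻⁴ kcal/mol for the stock dimer.  Systems with
more than two bodies (more than six external DOFs) are refused.  The true
ΔG° contains no restraints, so the oracle takes none.

## Problem sizes and tolerances

The validation suite runs the toy dimer protocol with 30 000 MC moves per
staircase stage and 60 000 moves per umbrella window (≈ 3·10⁶ moves and
about a minute per protocol replicate), two to three replicates per
condition, and 10⁶ Langevin steps for the double-well benchmark.  At these
sizes replicate means reproduce the oracle to ≲ 0.1 kcal/mol with ~0.1
kcal/mol standard errors, against a 0.3 kcal/mol acceptance band; the
trimer's removal-order comparison is assessed as two-sigma consistency of
the replicate totals, the standard statistical meaning of "equal within
uncertainty".  Statistical-test seeds are fixed in the suite.

## Numerical choices and edge cases

* Internal angular unit is radians; every interface and file uses degrees.
  Dihedral sign follows the IUPAC convention (order reversal leaves a
  dihedral invariant; mirror reflection negates it).
* Degenerate geometries (coincident points, collinear dihedral frames)
  raise instead of returning NaN — a silent NaN would poison the PMF
  assembly downstream.
* Superposition uses the closed-form Kabsch rotation with the determinant
  forced positive: reflections are never counted as superposable.
* k_B = 1.987204259·10⁻³ kcal·mol⁻¹·K⁻¹; V° defaults to the rounded
  1661 Å³ (the unrounded 10²⁷/N_A is available by flag).
* PMF text files: `#` metadata lines, four whitespace-separated columns
  (cv name, grid value, free energy, error), point grids not bins.
  Replicate profiles are averaged on a common linearly-interpolated grid.
* Uncertainty propagation assumes independent components (quadrature sum)
  — a documented simplification; step replicates are combined as
  mean ± max(spread SE, propagated SE).
* Window free energies default to Boltzmann averages over the window
  (robust to grid noise); a min-to-min convention is available.
* The I* site upper bound defaults to r* and is configurable; the
  site/bulk boundary is a required modelling input.

## Known limitations

* The toy engine is a validation instrument, not a production MD engine;
  an adapter to a full MD package would map the restraint definitions and
  consume its PMFs through the same assembly interface (PMF files are the
  exchange format).
* WHAM/staircase error bars are block estimates; strongly correlated
  samplers can underestimate them, which is why acceptance comparisons use
  replicate means.
* The Crick builder is a minimal fixture generator (CA traces, classic
  parametrisation, bundle axis on z) — not a design tool: no scoring, no
  register assignment, no parameter optimisation, no mmCIF.
* Euler/polar-angle (quaternion) restraint variants are not implemented;
  the Boresch coordinates cover the same physics and are the route's
  native frame.
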