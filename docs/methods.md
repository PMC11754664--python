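# Methods

This note documents the models implemented in `paibind`, the choices made
where conventions were genuinely open, what the synthetic-data generators do
and do not emulate, and the known limitations.

## Binding isotherms

Dose-response curves (MST F_norm, anisotropy, or intensity-weighted
lifetime vs titrant concentration) are modelled as a sum of Hill terms,

    F(c) = baseline + Σ_m ΔF_m · c^{n_m} / (K_{D,m}^{n_m} + c^{n_m}).

The biphasic form is an *additive* two-site model rather than a sequential
one: the two transitions in transposase titrations are attributed to
distinct specific and nonspecific binding modes, not to ordered occupancy
of coupled sites.  Fits are weighted least squares with weights 1/SEM when
replicate SEMs exist; K_D is optimized on a log scale (guaranteeing
positivity and scale-free steps) with multistart over log-spaced initial
values spanning the sampled concentration range.  The Hill coefficient is
free by default, bounded to [0.5, 4] — a loose band around non-cooperative
binding — with an option to fix n = 1.  Mode count is chosen by AICc (not
an F-test, which is unreliable at the 16-24 point counts typical of these
titrations) with a 2-unit margin resolving ties toward the simpler model.

A K_D is reported as `unbounded` when the fitted value sits at the edge of
the sampled range or when the Hill model does not beat a constant
(no-binding) model on AICc; in either case the data do not constrain it.
Zero-concentration points are retained as baseline anchors.  Baseline
subtraction (`normalize_baseline`) is a display convention; K_D estimates
are invariant to affine transforms of the observable because the model
carries free baseline and amplitude.

Resolving a biphasic curve requires adequate sampling of both transitions.
At ~25-fold K_D separation with 2% noise and 16-24 points, the two-mode fit
with free exponents is weakly identified; the analysis driver therefore
samples the first transition densely (40 points from 0.5 nM), mirroring how
nanomolar constants are determined experimentally.

## CD pH-folding

Mean residue ellipticity is computed in the standard path-length form,

    [θ] = θ_mdeg / (10 · l_cm · C_M · N_res)    [deg·cm²·dmol⁻¹],

with θ in millidegrees, l the cuvette path in cm, C the molar protein
concentration and N_res the residue count.  A strict `as_printed` mode
evaluating M₀·θ/(100·C·λ) (wavelength in the denominator) is provided for
auditing against sources that typeset the formula that way; it is not used
in analysis.

The folded fraction from [θ]₂₂₂ is a linear two-state interpolation between
folded and unfolded reference values — justified when the spectral family
shows an isodichroic point, which `find_isodichroic` locates as the
wavelength minimizing across-spectra variance (flagging degenerate or
crossing-free families).  This replaces basis-set secondary-structure
deconvolution, which is out of scope.

The pH transition is fit to

    f_h(pH) = (f_basic + f_acid·10^{n(pKa−pH)}) / (1 + 10^{n(pKa−pH)}),

with all four parameters free and multistart over a pKa grid from 4 to 9.
Parameters are named by their plateau role: `f_acid` is the low-pH plateau
and `f_basic` the high-pH plateau (the algebraic limits of the printed form
of this equation invert the letter labels; naming by role removes the
ambiguity).  The parameterization is canonicalized to n > 0 — the (f_a↔f_b,
n→−n) mirror generates the identical curve.  A fit whose pKa lands at the
search boundary (sampled pH range ± 1, also the validity band of the
result type) is raised as "no inflection in range" rather than returned.

**Precision note.**  With plateaus 0.10/0.35, nine pH points and noise
σ = 0.02, the replicate SD of the fitted pKa is ≈ 0.18, matching the
fit-covariance SE (≈ 0.15): the estimator is near-efficient and the spread
is information-limited.  Tighter pKa uncertainties require a larger folded-
fraction amplitude or error-weighted raw ellipticity fits.

## Time-resolved fluorescence

Decays are modelled as a two-exponential convolved with the measured IRF.
The discrete convolution uses the IRF normalized to unit sum, so a
delta-function IRF reproduces the biexponential samples exactly; a sub-bin
IRF time shift (free nuisance parameter, bounded to ±1 bin) absorbs
instrument alignment drift.  Weights are Poisson, 1/√counts with counts
floored at one.  In a linked (global) fit the two lifetimes are shared
across all waveforms of a titration while amplitudes float per waveform —
the standard linked-reconvolution workflow — and lifetimes are reported in
canonical order τ₁ < τ₂.  When the fitted A₂ is within one standard error
of zero the result is flagged for a single-exponential interpretation.
The default fit window is 50 ns, within which these dyes decay completely.

Summary statistics follow the printed conventions: intensity-weighted
lifetime τ = (A₁τ₁² + A₂τ₂²)/(A₁τ₁ + A₂τ₂) and integral intensity
A₁τ₁ + A₂τ₂.  Steady-state anisotropy uses the g-factor of the detection
train (1.03 for the emulated setup).

The FLT titration generator mixes free- and bound-state amplitude pairs
linearly in the bound fraction with the *integral intensity conserved*
(defaults: free (0.8, 0.3), bound (0.2, 0.45) at τ₁ = 1 ns, τ₂ = 4 ns, both
giving A₁τ₁ + A₂τ₂ = 2).  Under intensity conservation the intensity-
weighted lifetime is exactly linear in bound fraction and the Hill fit of
τ(c) is unbiased; if binding changes the total fluorescence intensity, the
lifetime-weighted average over species introduces a bias in the apparent
K_D of order the fractional intensity change.  This is a property of the
method, not of the implementation, and is why the generator models the
intensity-conserving (ideal) experiment.

## NMR titrations

Chemical-shift perturbations use the weighted combined shift
√(Δδ_H² + 0.15·Δδ_N²); the 0.15 weight compresses the ~5× wider ¹⁵N scale
onto the ¹H scale.  The profile SD is computed over all residues with both
peaks present, with no iterative trimming.  Residues whose bound-state peak
is broadened beyond detection are a distinct "missing" category — never
Δδ = 0, which would dilute the statistics.  Active residues for docking
restraints are those with Δδ > mean + 2 SD *and* relative SASA > 50%; the
threshold is relative to the profile mean (the conventional reading) and
both cutoffs are parameters.  Selection is monotone: raising either
threshold never adds residues.

PFG diffusion uses the Stejskal–Tanner attenuation
I(g) = I₀·exp(−D(γgδ)²(Δ − δ/3)) with γ the ¹H gyromagnetic ratio.
Acquisition defaults match the emulated experiment: 32 gradient amplitudes
spanning 2–98% of 0.53 T/m and Δ = 60 ms; the gradient pulse length δ is
not a published constant, so the generator defaults to 4 ms and always
records it in the output — fits read it from there and never assume it.
The generator and fitter share one attenuation convention, so noiseless
round-trips are exact; any bipolar-pair timing correction would enter both
identically as an effective Δ.  The nonlinear fit is seeded by, and
cross-checked against, the linearized ln I vs g² regression.  Oligomeric
state is called by relative proximity of the fitted D to externally
predicted monomer/dimer values (consumed as inputs), with calls more than
3 SE from even the nearer reference, or exactly midway, returned as
ambiguous.

## Docking engine

The interaction energy is a sum over residue–base pairs of a binned
knowledge-based table E⁰_ij(r, φ).  Geometric definitions, where no
published convention exists, are: r is the distance from the residue's
sidechain heavy-atom centroid (Cα for glycine) to the base's aromatic-ring
centroid; φ ∈ [0°, 90°] is the angle between the Cα→sidechain-centroid
vector and the least-squares plane of the ring atoms (glycine, with no
direction vector, scores at φ = 0).  All reference points are swappable via
the scorer.  Default bins are r ∈ [0, 15] Å in 1 Å steps and φ in 15°
steps; beyond the distance cutoff the contribution is exactly zero.

The potential is derived by inverse-Boltzmann statistics,
E = −ln[(N_obs + p)/(N_ref + p)] with pseudo-count p (default 0.5), against
an *angle-uniform, distance-marginal* reference: N_ref(i,j,r,φ) =
N_obs(i,j,r,·)/n_φ.  Energies therefore encode angular preference at each
separation while the radial contact-frequency profile cancels; the table is
invariant to duplicating the training set.  This is a documented,
simplified variant of statistical protein–DNA potentials and makes no
claim of numeric equality with any published table.

Docking runs independent Metropolis searches (default 200 runs, 5000 steps)
over rigid 6-DOF moves: translations up to 1 Å and rotations up to 5° about
the protein centroid, under geometric cooling from T = 5 to 0.1 in the
table's arbitrary energy units.  Starts are random orientations on a sphere
enclosing both molecules; starts with unresolvable steric overlap are
re-drawn.  Because the statistical potential has no excluded-volume term, a
soft-core penalty — quadratic in the overlap below 2.5 Å heavy-atom
distance — is added during the search only and reported separately from the
statistical energy.  The best-visited pose per run is returned (elitism),
and run k uses seed+k, so a fixed seed reproduces the pose list exactly.

Poses are clustered by complete-linkage hierarchical clustering of pairwise
protein-Cα RMSD (the DNA frame is common to all poses, so DNA superposition
is the identity; all shared Cα atoms enter the RMSD).  Cutting the
dendrogram at 3 Å bounds every cluster's diameter by 3 Å.  Clusters are
ranked by the energy of their lowest-energy member; mean-of-top-10 ranking
is available for the restraint-driven workflow convention.  Interface atoms
are those within 5 Å of the partner; hydrogen bonds are donor–acceptor
heavy-atom pairs ≤ 3.5 Å with an antecedent–donor–acceptor angle ≥ 120°
(conventional geometric criteria), with donors/acceptors from a bundled
table.  SASA is Shrake–Rupley with a deterministic 960-point Fibonacci
sphere and Bondi radii; relative per-residue accessibility divides by
Gly-X-Gly maximum areas (theoretical values), so absolute agreement with
other SASA programs is not claimed.

## Synthetic data: what it does and does not emulate

Generators are pure functions of (parameters, seed) and default to the
study conditions of the assays they stand in for: 16 log-spaced titration
points averaged over 3 replicate curves with Gaussian noise of 2% of the
response amplitude; pH 4.5–8.5 in 0.5 steps with σ_f = 0.02; photon-
counting decays at 10⁴ peak counts with Poisson noise and a Gaussian IRF
(center 2 ns, σ 0.2 ns) on a 0.05 ns grid; 1% intensity noise on gradient
attenuation.  The MST noise magnitude is not a published quantity; 2% of
amplitude makes the recovered standard errors plausible but is not
calibrated to any instrument.

Not emulated: thermophoresis physics (only the dose-response shape),
exchange line shapes (peak broadening is missing-at-random bound peaks),
rotational-diffusion anisotropy decays, sequence-dependent DNA geometry
(the duplex is fiber-model B-DNA with idealized planar rings), and real
sidechains (the toy protein is poly-alanine).  Passing recovery tests
therefore demonstrate that the estimators are correct and efficient under
the assumed noise models, not that those noise models capture every
systematic effect of the instruments.

## Problem sizes

Recovery studies use 100 noise realizations per binding/pKa/diffusion
target and 50 for the end-to-end lifetime chain; the docking property
checks run a reduced search (8–12 runs of a few thousand steps on a
12-residue/10-bp toy) against an exhaustive translation-grid oracle.  These
sizes give sub-percent Monte Carlo error on the recovered means while the
full suite completes in minutes on one CPU.

## Known limitations

- The binned potential is piecewise-constant, so docking energies are
  plateau-valued and gradient-free; the Monte Carlo kernel relies on
  temperature, not local gradients.
- Biphasic Hill decomposition below ~10-fold K_D separation is flagged as
  unresolvable rather than attempted.
- The hydrogen-bond detector uses heavy atoms only (no protons are built),
  so donor angles are measured at the antecedent atom.
- Relative SASA can slightly exceed 1 for extended termini; values are
  reported unclipped.
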