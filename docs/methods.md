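# Models, conventions and parameter choices

This note documents the science implemented in `sitekit`: the models and
estimators, their assumptions, the defaults that matter, what the
synthetic-data generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

Units throughout: nm (length), kJ/mol (energy), eV (excitation energy),
degrees (angles), kelvin (temperature).  Constants:
k_B = 0.0083144626 kJ/(mol K), hc = 1239.84193 eV nm, default
temperature 300 K.

## Helical fibril model

Amyloid fibrils stack protofilament layers under approximate screw
symmetry.  A single generating operation maps layer *k* to *k+1*: a
right-handed rotation by `360°/s + twist` about the fibril axis plus a
translation by the rise, where *s* is the screw order (2 for the 2₁ axis
relating the two C-shaped protofilaments of the tau paired helical
filament).  The reported per-layer `twist` is thus the deviation from
perfect `360/s` staggering.  A forced-periodic cell of *n* layers closes
when `n · twist · s ≡ 0 (mod 360°)`; `twist_from_layers` inverts this,
giving 0.973° ≈ 0.97° for the 185-layer tau cell at a rise of 0.48 nm.

Choices:

* The builder imposes geometry only — no relaxation, no stress or kink
  remediation, and no scan over twist angles.  `verify_symmetry` reports
  the atom-wise 3-D RMSD between the screw image of layer *k* and stored
  layer *k+1* (for i.i.d. Gaussian coordinate noise of sd σ on both
  layers this tends to σ√6); freshly built models verify to machine
  precision.
* The fibril axis is estimated from data, not taken on faith: the
  principal component of the layer centroids when ≥ 3 layers exist,
  otherwise the template's smallest-inertia direction.  This makes every
  downstream frame (density maps, mode classification) equivariant under
  rigid motions of the whole system.
* Coordinates are nm internally; PDB I/O (via biotite) converts to Å.
  Residue numbers are offset by 1000 per layer.  Chain identifiers cycle
  through the 62 single characters A–Z, 0–9, a–z (the PDB chain column
  is one character wide, so two-letter codes are not used); residue
  offsets keep identities unambiguous beyond 62 layers.

## Ligand representation and binding-mode taxonomy

The ligand is reduced to six labelled reference points: bi-thiophene
centroid (BTC), vinylene midpoint (VIN), benzothiazole centroid (BZT),
thiazole-ring centroid (THI), terminal ethyl carbon (ETH), and the
charge center (CHG, the 0.44/0.56 charge-weighted mean of the
bi-thiophene and benzothiazole centroids, matching the cationic charge
split between the moieties).  This is the minimal set that supports site
membership, major-mode orientation and minor-mode torsions.

* **Site membership**: CHG within 0.7 nm (configurable) of the site
  triad's C-alpha centroid — a first-contact-shell distance.
* **Major modes**: the ethyl vector e = ETH − THI in the site frame
  (ẑ = fibril axis; x̂ = in-plane His→Ile anchor direction; ŷ = ẑ × x̂):
  U/D by the sign of e·ẑ, L/R by the sign of e·ŷ.  Exact ties (|·| <
  1e-6) resolve deterministically to U and R — a measure-zero case where
  determinism beats physical meaning.
* **Minor modes**: the thiazole–ethyl and bi-thiophene inter-ring
  torsions, each binned by the sign of its cosine (near-cis vs
  near-trans), giving indices 0–3 as `2·bit(first) + bit(second)`.
* **Planarity**: Σᵢ|cos θᵢ| over a supplied set of conjugated-backbone
  dihedrals; 4 planar dihedrals score 4.0, all-orthogonal scores 0.
  This Σ|cos| form is an interpretation: it reproduces the observed
  ~3.4–3.5 range on four backbone dihedrals, but scores from the
  six-point toy ligand (two resolvable torsions) are not comparable to
  full-molecule values beyond order of magnitude.
* Density maps collapse the trajectory along the fibril axis: each
  reference point is assigned its nearest layer `k = round(z/rise)` and,
  with untwisting ON (default), rotated by −k times the per-layer screw
  rotation so all symmetry-equivalent sites superpose before binning on
  the cross-section plane.
* Energy aggregation consumes per-frame LJ/Coulomb records (it never
  computes them from force-field parameters).  Site totals are exactly
  the sums of per-residue means; spreads are population (ddof = 0)
  standard deviations, the large-sample MD convention.  Note that the
  reference per-residue site-A LJ means, being rounded to 0.1, sum to
  −92.0 while the quoted total is −91.9.

## WHAM and Boltzmann populations

The 1-D weighted-histogram estimator recombines umbrella windows
(harmonic biases `k/2 (x−c)²`) into the unbiased density by
self-consistent iteration of the window free energies, performed in log
space (log-sum-exp) for stability.  Defaults: bin width 0.02 nm,
tolerance 1e-8 kJ/mol on the shifts, at most 100 000 direct iterations.
Non-convergence raises an error carrying the iteration count and last
shift change.

* **Support**: the histogram is restricted to the contiguous nonempty
  run of bins containing the most populated bin; stray extreme-tail
  samples outside it are dropped (they would otherwise masquerade as
  coverage gaps).  If any window has more than half its samples outside
  that run the windows genuinely fail to overlap and a coverage error is
  raised.
* **Reference convention**: bulk-zero by default — the mean over the
  last 0.5 nm of the coordinate is set to zero, matching profiles with
  flat solvated tails; min-zero by flag.
* **Binding energy**: mean PMF over a stated bulk interval minus the
  global minimum; non-negative by construction.
* **Populations**: `pᵢ ∝ exp(Eᵢ/kT)` on the positive binding energies,
  so stronger binding means larger population; invariant under a common
  shift of all energies.
* **Uncertainty** (optional): block bootstrap over window samples
  (blocks of n/20, 50 resamples by default), honest about sample
  autocorrelation within windows.
* Intermediate minima along the exit path (e.g. transient contacts with
  a secondary site) are reported as local PMF minima above a prominence
  threshold, excluding the global minimum.

## Absorption spectra

Condensed-phase spectra are snapshot averages over vertical excitation
energies from decorrelated configurations.  Two broadening routes:

* **Gaussian**: each snapshot contributes a normal of width σ
  (default 0.15 eV).
* **Vibronic**: each snapshot contributes a fixed low-temperature line
  shape anchored with its 0-0 line at the snapshot energy (the 0-0
  transition dominates for this ligand family, making it the natural
  anchor; centroid anchoring is available by flag).  The default profile
  places three progression lines at 1300/1400/1600 cm⁻¹
  (0.161/0.174/0.198 eV) above the 0-0 line — the stretching and
  angle-bending modes relevant for this chromophore — with geometrically
  decaying intensities (ratio 0.45) and a 0.02 eV intrinsic width.  The
  exact line-by-line profile of the reference calculation is not
  published, so this fixture emulates its structure; absolute curve
  shapes built from it are illustrative, not reproductions.

λmax is the intensity argmax on the energy grid (default 1.5–4.0 eV at
1 meV) converted to nm, with grid ties broken toward lower energy
(longer wavelength) and flagged.  No dλ/dE Jacobian reweighting is
applied, because band maxima are compared directly between theory and
experiment in this field.  Both operators preserve unit area to < 1e-6
on a grid covering the snapshot range ± several σ.  Snapshot spectra are
unweighted by default; a per-snapshot weight column (e.g. oscillator
strengths) is accepted.

## Synthetic data: what it emulates, and what it does not

All pipeline inputs are generated with planted ground truth from a
single integer seed feeding a splittable `SeedSequence` (one independent
stream per sub-task), so identical seeds give identical outputs.

* **Toy layer**: an open 270° arc of pseudo-residues (4 atoms each) in a
  plane — the C-shaped protofilament cross-section — with triads
  labelled for sites A (Ile/Thr/His, ids 360–362) and B (Arg/Val/Gln,
  349–351) when the id range covers them.
* **Trajectories**: each (frame, ligand) configuration is independently
  bulk (probability `bulk_fraction`) or bound at site A with a major
  mode drawn from `mode_weights` (default 47/30/19/4 %, the equilibrium
  mode distribution of the studied system, assigned in the fixed order
  UL/UR/DL/DR) and a minor mode from per-major weights (default
  uniform).  Bound geometry: torsions set near 0°/180° per minor bit
  (wrapped-normal noise, sd 20°), ethyl vector rotated into the planted
  quadrant, charge center scattered isotropically about the site
  centroid (sd 0.1 nm).  Frames are 20 ps apart, reflecting the
  decorrelation spacing used for snapshot extraction.  *Not* emulated:
  real binding/unbinding kinetics (frames are independent, so residence
  times only sanity-check the bookkeeping), ligand internal dynamics,
  solvent, and any force field.  Recovery tests therefore demonstrate
  estimator correctness, not MD realism.
* **Umbrella windows**: Metropolis sampling of the exact biased
  Boltzmann density of an analytic potential (Gaussian proposals of
  0.05 nm, 1000-step burn-in, 10× thinning; proposals outside the
  domain are rejected, i.e. the density is truncated there).  Thinned
  samples retain a small autocorrelation (integrated time ≈ 2 thinned
  steps), which matters for i.i.d.-assuming tests — the
  distributional KS check uses heavier thinning for that reason.
* **Energies**: i.i.d. normal draws about stated per-residue or
  per-snapshot means — no correlation structure across frames or
  residues.

## Problem sizes and accuracy of the recovery demonstrations

The canonical WHAM oracle is a tilted double well (barrier 3 kJ/mol ≈
1.2 kT, minima ±0.35 nm, tilt 1 kJ/mol/nm) on ±0.44 nm, sampled by 25
windows × 5000 samples at k = 600 kJ/mol/nm².  Two deliberate choices
make this a clean validation: the spring constant exceeds the barrier
curvature (|U''| ≈ 98 kJ/mol/nm²), keeping every biased density
unimodal so chains mix; and window centers span the closed domain
inclusive of the endpoints so edge bins are sampled.  Under these
conditions the maximum absolute PMF error after constant alignment is
typically 0.1–0.25 kJ/mol (per-bin statistical noise ~kT/√n_eff).

The end-to-end population demonstration plants per-mode Gaussian wells
of depth 26.9–33.0 kJ/mol (spaced kT·ln pᵢ/pⱼ so the planted Boltzmann
populations are 47/30/19/4 %) on a 0–2.2 nm coordinate, samples 25 ×
5000 per mode, and recovers populations via WHAM → binding energy →
Boltzmann weights.  Typical recovery error is 2–4 percentage points,
dominated by the ~0.2 kJ/mol statistical noise of each binding energy;
occasional seeds reach ~5 points.

Mode-weight recovery by the classifier uses 20 000 frames (binomial
3σ ≈ 1 percentage point).  All demonstrations together run in well
under a minute on one CPU.

## Known limitations

* WHAM is direct-iteration 1-D only; no MBAR generalisation, no 2-D
  profiles.
* The builder does not reproduce the stress-based selection among
  candidate twist angles that motivates the 185-layer cell; twist is an
  input.
* The vibronic profile is an emulation (see above), and the planarity
  score's exact reference formula is interpreted as Σ|cos|.
* Binding energies from the PMF use the raw bin minimum, which carries
  the minimum bin's statistical noise; a quadrature over the well would
  be smoother but is not what band-vs-plateau comparisons report.
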