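# Methods

## Model

The package treats a cryo-EM map as evidence about the statistical weights
of a fixed structural ensemble.  Bayes' rule combines a Gaussian voxel
likelihood with an entropic prior over weights:

* **Prior** `P(w) ∝ exp(−θ S_KL)` with `S_KL = Σᵢ wᵢ ln(wᵢ/w⁰ᵢ)` (natural
  log, so S_KL is in nats).  θ ≥ 0 expresses confidence in the prior
  ensemble; θ → ∞ pins w at w⁰, θ = 0 is a pure likelihood fit.
* **Likelihood** `P(D|w) ∝ exp(−Σₙ [ρ⁰ₙ − α Σᵢ wᵢ ρⁱₙ(σ)]² / (2σ_L²))` over
  the selected voxels n = 1…N.

The negative log-posterior is minimised over log-weight coordinates
`wᵢ = w⁰ᵢ e^{gᵢ} / Σⱼ w⁰ⱼ e^{gⱼ}` with the last member's g pinned at 0 to
remove the normalisation gauge.  This parameterisation keeps weights
strictly positive — standard-mode weights are never exactly zero (a floor
of 1e−300 absorbs floating-point underflow of strongly down-weighted
members; the KL term treats w → 0 by the limit x ln x → 0).

Two χ² conventions coexist deliberately: the *reported* misfit is
`χ² = Σ r²/σ_L²` while the posterior's data term carries the Gaussian ½.
Doubling σ_L² therefore halves the reported χ².

## Nuisance parameters

* **α (map scale)** is profiled analytically at every objective evaluation:
  `α* = (ρ⁰·ρ̄)/(ρ̄·ρ̄)` with `ρ̄ = Σᵢ wᵢ ρⁱ`.  By the envelope theorem the
  gradient of the profiled objective needs no dα/dw term, which both tests
  and the finite-difference oracle confirm.  α is unconstrained in sign; a
  non-positive α (reference anti-correlated with the model) only triggers a
  warning, since it signals an alignment or threshold problem upstream.
* **σ (kernel width)** is handled by a discrete scan (default
  {0.2, 0.225, 0.25, 0.3} × nominal resolution) because the N×M density
  matrix must be rebuilt per candidate; the σ with the lowest knee-selected
  χ² wins, ties to the smaller width.  Gradient-based σ optimisation was
  rejected for cost.
* **σ_L² (noise variance)** is the variance of reference density over
  voxels where *every* model map stays below its own 3σ_map threshold (the
  region outside the molecular density).  It is estimated once, against the
  full prior ensemble, and reused across σ candidates and iterative rounds:
  the error scale of the data should not drift while candidates compete.
  A floor of 1e−6 × (max ρ)² protects noiseless synthetic maps.

## Forward model

Each atom contributes a normalised isotropic 3-D Gaussian; the amplitude is
the element's integrated electron scattering power (the sum of the standard
five-Gaussian scattering-factor coefficients for H, C, N, O, P, S; unlisted
elements fall back to atomic number scaled to carbon).  A single shared
width is used: 0.225 × resolution for reference synthesis (the molmap
convention) and the nuisance σ for model maps.  The per-element intrinsic
widths of the scattering-factor fits are tabulated for reference but do not
modulate σ (whether σ_e² = σ² + b_e² would be more faithful is an open
modelling question; a shared σ matches the likelihood's single-σ form).
Gaussians are truncated at 4σ (≤ 0.4 % of an atom's mass) and accumulated
separably per axis, so map synthesis is O(atoms × local box).  Total
simulated density equals the summed amplitudes to within the truncation
error — the mass-conservation property test.

## Voxel selection and map processing

Maps are normalised by zeroing negative voxels and dividing by the maximum
("molecular density value of 1" is read as max → 1; rescaling to a contour
level of 1 would be the alternative reading).  Noise is injected *after*
normalisation with sd = fraction × max of the clean map, which is the only
order under which the stated 3σ_noise reference threshold matches the 1 %
and 10 % noise fractions.  The reweighting dataset is the **union** of
reference voxels above 3σ_noise and model voxels above that model's
3σ_map: the union keeps voxels where models predict density the map lacks,
which the likelihood must be able to penalise.  For experimental maps with
unknown noise, σ_noise is estimated as sqrt(σ_L²) from the outside region,
or an explicit contour threshold overrides both.

## θ selection

θ is scanned over {0} ∪ 10^{−2…7} (11 points, warm-started from high θ
downward).  Across the scan S_KL is non-increasing and χ² non-decreasing in
θ, so the points trace a proper trade-off curve.  Selection works on the
(S_KL, χ²) plane, both axes min-max normalised:

1. **Kneedle knee** — the point maximising the height below the descending
   diagonal, equivalent to maximal perpendicular distance to the chord.
   θ = 0 is barred from candidacy when its Neff < 1/M (degenerate overfit).
2. **Agreement guard** — on coarse logarithmic grids whose χ² spans orders
   of magnitude, the raw difference maximum can land well up the misfit
   cliff (χ² several times the scan minimum) even though a wide plateau of
   near-minimal χ² exists at smaller θ.  A knee whose χ² exceeds the scan
   minimum by more than 5 % is therefore demoted to the maximal-Neff point
   of that plateau — the selected θ must *both* fit the data and guard
   against overfitting.  The guard is waived when the only near-minimal
   point is the unregularised low-θ endpoint, where demotion would defeat
   regularisation (this keeps the selection faithful on smooth analytic
   curves such as y = 1/x, where the geometric knee is the right answer).
3. **Fallback** — if the curve has no knee at all (straight or degenerate),
   the θ with χ² within 5 % of the minimum and maximal Neff is returned,
   flagged as such.

## Iterative mode

Round 0 is a standard run on the full ensemble.  Each later round keeps the
ceil(Neff·M) highest-weight members (ties to lower index, never fewer than
2), resets them to a **uniform** prior — each sub-ensemble is a fresh prior,
not a carry-over of the posterior — re-selects voxels against the kept
models and reruns the full θ scan.  Rounds stop when χ² at the knee
increases (the previous round is returned), when the selection stops
shrinking, or at the 2-member floor; a failed round returns the last good
round, flagged in the trace.  Stopping compares knee-selected χ² rather
than θ = 0 χ², because the unregularised fit ignores the overfitting
control that motivates the iteration.  Neff for the selection is computed
against that round's uniform prior.  exp(−S_KL) is used for Neff throughout
— the effective-fraction convention in (0, 1] that makes "keep Neff·M
members" a contraction.

## Metrics

* **CC** — Pearson correlation over the reweighting voxel selection (so the
  reported value matches the fitted objective's support); whole-box and
  about-zero overlap variants are also available.  Reweighting minimises
  χ², so posterior CC can tie with the prior only up to optimiser noise
  when the prior already matches the truth.
* **SMOC** — per-residue Manders overlap between reference and simulated
  density over voxels within 5 Å of the residue's atoms; empty or
  zero-density zones score 0 with a warning.
* **Ensemble JS divergence** — weighted histograms of a scalar feature
  (default: Kabsch RMSD to a fixed reference member, Freedman–Diaconis
  bins) compared by Jensen–Shannon divergence (natural log, bounded by
  ln 2).  The feature space is a package choice, declared rather than
  canonical.
* **Weighted RMSF / PCA** — members' representative atoms (Cα when present,
  else residue centroid) are superposed onto the weighted mean (iterated
  weighted least squares, two passes, permutation-invariant initialisation);
  RMSF is the weighted root-mean-square deviation per residue, PCA the
  eigendecomposition of the weighted coordinate covariance with a
  largest-entry-positive sign convention.  With global superposition a
  strictly local displacement partially redistributes into the fitted
  translation; `superpose=False` trusts the input alignment and makes the
  closed-form small cases exact.

## Synthetic benchmarks

The generators are pure functions of their seeds and carry ground truth
(member weights plus the clean pre-noise map, which the truth weights
reproduce exactly).

* **Two-state (discrete)** — a 40-residue two-arm pseudo-atomic polymer
  (3.8 Å spacing, one atom per residue, cycled C/N/O/S elements); closing
  the hinge by 30° separates the end states by ≈ 8 Å Cα RMSD, the magnitude
  of a large domain closure such as adenylate kinase's 7.16 Å open/closed
  transition.  Members jitter around each end state (0.3 Å coordinate sd,
  3° hinge wobble).  References mix the two state-mean maps at populations
  0–1; the canonical grid is 11 populations × 3 resolutions (3/6/10 Å) × 2
  noise levels (1 %/10 %) = 66 maps, with a 3 × 2 × 1 quick grid as the
  test-suite default.
* **Continuous subset** — members deform the chain by 3 smooth sinusoidal
  modes (amplitude ~ N(0, 6 Å/k)), giving pairwise RMSDs from a few to
  ~20 Å, a flexible tethered-domain regime; a seeded random 10-of-100
  subset averages into the reference map.
* **Compositional** — species B adds a rigid 12-atom companion blob at a
  fixed offset; the reference mixes the species-mean maps at a known
  fraction.

What these emulate — and what they do not: maps are synthesised by the same
Gaussian forward model that fits them, noise is iid Gaussian, structures
are pre-aligned, pseudo-atoms stand in for all-atom chemistry, and there is
no CTF, B-factor variation, masking artefact or resolution anisotropy.
Passing benchmarks therefore demonstrates the statistical machinery
(population recovery, member identification, fit improvement, minimal
ensembles) under controlled heterogeneity, not robustness to experimental
map pathologies.

## Numerical choices

* Optimiser: L-BFGS-B on the gauge-fixed log-weights with the analytic
  gradient, started at g = 0 (or warm-started along the θ scan), gradient
  tolerance 1e−8, max 10⁴ iterations.  Because the data term scales with
  N/σ_L², convergence is additionally accepted when the gradient norm is
  below 1e−4 × the objective magnitude — on near-degenerate landscapes
  (many members at vanishing weight) the line search stalls at first-order
  residuals that are negligible relative to the objective.
* Problem sizes in the test suite and acceptance script — M = 100 members,
  ~40 pseudo-atoms, 6 Å maps on ~2 Å voxels, ~10⁴ selected voxels — were
  chosen so a full standard run takes seconds on one CPU while keeping the
  benchmark regimes (state separation, ensemble spread, noise fractions)
  at the stated values.
* Anisotropic voxels are rejected at read time rather than resampled; axis
  permutations in MRC headers are resolved on read so flat voxel indices
  are always C-order over the logical (x, y, z) array.
* Rigid fitting is a deliberately coarse convenience (integer-voxel
  translation grid × small rotation set, ties to the earliest candidate):
  ensembles are expected to arrive aligned to the map frame.

## Known limitations

* One global σ and per-element amplitudes; no B-factors, no multi-Gaussian
  scattering profiles, no Fourier-space synthesis.
* Per-voxel errors are homoscedastic (a single σ_L²); local-resolution
  weighting must happen upstream by map filtering.
* The minimal-ensemble search is greedy (top-weight pruning), not a global
  subset optimisation.
* The ensemble-JS feature space and binning are package conventions; other
  choices will give different absolute divergences (comparisons within one
  convention remain meaningful).
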