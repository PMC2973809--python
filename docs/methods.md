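# Methods

This note documents the models, numerical choices and limitations behind
`fishdyn`, in the spirit of the model documentation of packages like
`statsmodels` or `msprime`.

## Setting and observables

Every observation is one fixed cell hybridized for a pair of genes (i, j),
yielding two non-negative counts. The cell's position in the underlying
dynamics — its cycle time t, its switch state s, and its global
transcription factor G — is hidden and is drawn independently per cell.
Counts of the two genes are conditionally independent given (t, s, G); all
between-gene correlation is induced by the shared hidden variables. Pairs
are independent data sets: no cell contributes to more than one pair.

Two consequences shape everything downstream:

1. **Time scale and direction are unidentifiable.** Snapshots carry no clock,
   so the period is fixed by convention (T = 1) and every likelihood is
   exactly invariant under a global phase shift and under time reflection.
   Both reconstruction-error metrics quotient these symmetries out before
   comparing models.
2. **The covariance diagonal is unobservable.** Same-gene coincidences are
   never measured, so data-derived moment sets flag the diagonal as missing;
   exact model moments carry the model-implied dynamical variance on the
   diagonal (which is what the diagonal-completion PCA reconstructs), not
   the Bernoulli indicator variance.

## Model families and closed-form moments

*Continuous cycle*: mu_i(t) = mu0_i + A_i cos(2πt/T + φ_i), Gaussian noise
sd σ_i. Cycle-averaged mean mu0_i; between-gene covariance
½ A_i A_j cos(φ_i − φ_j); same-gene variance ½A_i² + σ_i².

*Bursty cycle*: burst probability p_i(t) = p̄_i + Σ_h a_{i,h}
cos(2πht/T + φ_{i,h}), clipped to [0,1] when evaluated (a predicted
probability above one generates a burst with probability one). With a global
factor G of mean 1 and variance σ_G² multiplying all probabilities,

    c_ij = σ_G² p̄_i p̄_j + (1 + σ_G²) · ½ Σ_h a_{i,h} a_{j,h} cos(φ_{i,h} − φ_{j,h}).

Distinct harmonics average to zero against each other, so each harmonic
contributes an independent rank-2 sheet; the global-noise term adds one
rank-1 sheet. The closed forms ignore clipping (as the algebra requires);
the quadrature path (`exact_moments(..., method="quadrature")`, uniform time
grid plus generalized Gauss–Laguerre nodes for the gamma-distributed G)
honors clipping and agrees with the closed forms to ~1e-12 whenever clipping
is inactive. The gamma quadrature needs σ_G ≳ 0.08; below that the
generalized-Laguerre weights overflow and the closed form (exact there
anyway, since clipping vanishes as σ_G → 0) should be used.

The *amplitude-locked* cycle, p_i(t) = p̄_i (1 + cos(2πt/T + φ_i)), models
genes whose expression collapses to near zero once per cycle (the metabolic-
cycle phenotype); it has a single free parameter per gene (the phase) once
the means are pinned to the data.

*Switch*: S states with probabilities P_s, per-gene per-state burst
probabilities q_{i,s}; mean Σ_s P_s q_{i,s} and covariance
Σ_s P_s q_{i,s} q_{j,s} − p̄_i p̄_j = Σ_s P_s δ_s δ_sᵀ (δ_s = q_{·,s} − p̄),
rank S−1 because Σ_s P_s δ_s = 0.

All moment formulas are validated in the test suite against brute-force
Monte-Carlo time/state sampling, and the identifiability counts against the
numerical rank of the parameters-to-moments Jacobian at generic points.

## Identifiability accounting

For a cycle with H harmonics there are N(1+2H) − 1 parameters (one overall
phase removed). The observables supply N means plus the degrees of freedom
of a rank-r symmetric matrix, rN − r(r−1)/2 with r = 2H (+1 with global
noise), capped at the N(N−1)/2 observable off-diagonal entries for small
gene sets; `dof_report` reports which branch applied. The unconstrained
remainder is H(2H−1) − 1 for large N — zero for one harmonic, five for two —
and S(S−1)/2 for switches (1 for S=2, 3 for S=3). `fit_cycle_bursty`
refuses free-amplitude configurations whose report shows unconstrained
parameters (with the cap this requires N ≥ 5 genes for H = 1) rather than
returning one arbitrary member of a solution family; the amplitude-locked
model is exempt. Pairwise data also cannot distinguish a rank-2k covariance
produced by a k-harmonic cycle from a (2k+1)-state switch, nor resolve the
harmonic-mixing degeneracy at H ≥ 2; those choices are prior knowledge, and
`infer_complexity` reports the ambiguous alternatives explicitly.

## Estimation

**Continuous regime.** The per-snapshot likelihood is a cycle average of a
product of two Gaussians, computed on a uniform midpoint grid (default 128
points) with log-sum-exp stabilization; for a periodic integrand this
trapezoid-equivalent rule converges spectrally. The default resolves
integrands whose sharpest time-scale σ_i/(A_i ω) is ≳ 1/128; the exact
shift-invariance of the continuum integral holds on the grid only to
quadrature accuracy, so invariance checks use 512 points. Optimization is
L-BFGS-B with analytic gradients (posterior-weighted per-quadrature-point
score functions, verified against central differences at 1e-8), bounds
A ≥ 0, σ ≥ 1e-3, phases wrapped after convergence. Starting points follow
two heuristics built on the per-pair Pearson matrix ρ̂ (≈ cos of phase
differences): method (a) fixes a reference gene and assigns phase magnitudes
arccos ρ̂ (two reference-gene variants; signs unresolved), method (b)
maximizes Σ ρ̂_ij cos(φ_i − φ_j) from a top-two-eigenvector seed with local
refinement. Baselines start at sample means; amplitude and noise at half the
sample standard deviation. The benchmark in the test suite (20 paired
replicates over n_genes ∈ {2,4,8} × M ∈ {30,100,300}, common random numbers
across cells) checks that the heuristic starts match true-parameter starts
to within 10% in mean reconstruction error.

The continuous reconstruction error is
Δ² = (1/N) Σ_i ⟨(μ̂_i − μ_i)²⟩_t / ⟨μ_i⟩², minimized over the global shift
and reflection. For harmonic trajectories the time average is analytic and
the optimal shift reduces to the modulus of a weighted phase resultant, so Δ
is computed in closed form (validated against a grid search). Normalizing
by the squared mean (rather than the trajectory variance) makes Δ
dimensionless and insensitive to the unidentifiable overall scale of
"interesting" amplitude; this is a documented package choice — it affects
absolute Δ values, not orderings.

**Bursty regime.** Counts are binarized at per-gene thresholds (pooled
median by default; the lower median for even sample sizes). Burst
frequencies p̂ pool all observations of a gene weighted by pair sample
sizes; covariances use within-pair means so each pair's estimate is
self-contained. The sampling variance of ĉ_ij is the Bernoulli-coincidence
leading term r̂(1−r̂)/M (r̂ = coincidence frequency), floored at ε/M with
ε = 0.25 coincidences so zero-coincidence pairs keep a finite likelihood;
the neglected corrections from mean estimation are O(p_i + p_j) relative
and the approximation is validated by re-simulation in the rare-coincidence
regime it targets (p̄ ≲ 0.05 gives agreement within 20%; at p̄ ~ 0.2 the
correction is visible). The covariance likelihood is then a product of
Gaussians over pairs, maximized with means pinned to p̂ exactly. Free
parameters: phases; amplitudes in [0, min(p̄, 1−p̄)] (keeping the closed-form
objective consistent with the clipped simulation) unless locked; σ_G on a
log scale (s ∈ [−10, 1.5], i.e. an effective lower bound of 0). Each fit
runs n_restarts = 10 starts: one deterministic spectral start that reads
phases and amplitudes off the rank-2 diagonal-completed covariance
(c = ½ZZᵀ with Z_i = a_i(cos φ_i, sin φ_i)), plus uniform-random restarts;
the locked model's landscape is effectively unimodal (restart agreement
≥ 80–100%), while the free-amplitude landscape needs the spectral start.

The 2-state switch fit takes P1 as known, optimizes q_{·,1} within the
interval that keeps q_{·,2} = (p̂ − P1 q_{·,1})/(1−P1) inside [0,1] (so the
means stay pinned without clamping), and reports the state labeling with the
larger mean burst probability first. The switch error Δ² averages
Σ_s P_s (q̂ − q)² / Σ_s P_s (q − p̄)² over genes, minimized over state
relabelings; genes with no state-to-state variation are excluded with a
warning.

**PCA.** Starting from a zero diagonal, eigendecompose, rebuild the diagonal
from the top-r eigenpairs, iterate until the diagonal moves less than 1e-10
(max 500 iterations; non-convergence is reported, not raised). Off-diagonal
entries are never modified; missing pairs are imputed as 0 (unbiased under
no signal) and reported. The complexity heuristic counts eigenvalues above
5× a noise scale; absent a user-supplied noise level the scale is the median
absolute eigenvalue of the *lower half* of the spectrum (robust when signal
eigenvalues are not a small minority, as with few genes) plus a
1e-10·max|λ| floor for exact inputs.

## Cluster synchrony

For amplitude-locked cycles the cluster activity
Q_j(t) = (1/N_j) Σ_{i∈j} p_i(t)/p̄_i = (1/N_j) Σ (1 + cos(ωt + φ_i)) is
non-negative, averages to 1 over a period for any phases, and reaches 0 iff
the cluster is perfectly synchronized — which makes its minimum a synchrony
statistic comparable across clusters of fixed size. The minimum is evaluated
on a 512-point grid; since the sum of unit cosines is a single sinusoid,
the grid minimum is computed exactly from the phase resultant (bias vs the
continuum minimum < 2e-5, identical for observed and null values). The
p-value Monte-Carlo draws i.i.d. uniform phases (default 1e5 draws),
applies the same grid minimum, and reports the add-one-corrected fraction
(k+1)/(n+1); a calibration test confirms null p-values are uniform.

## Synthetic-data generators

The generators define the benchmark conditions and are first-class, tested
code:

* Continuous cycles: A_i = 5(1+u_i), μ0_i = A_i(1+u′_i) with u, u′ ~ U(0,1)
  — positivity and significant amplitudes by construction; phases uniform;
  σ_i ~ U(0, noise_max] with noise_max = 2 (≈ 20% relative noise at the
  mean baseline of ~11), a regime where reconstruction is good at a few
  hundred observations per pair. Gaussian noise is floored at zero counts;
  at these baselines the flooring is essentially never active (the small
  low-mean bias is ignored by the Gaussian likelihood, a documented
  approximation).
* Bursty cycles: p̄_i ~ U(0.1, 0.4), a_i = p̄_i·U(0.5, 1) — positive burst
  probabilities with substantial cyclic variation and no clipping.
  Amplitude-locked sampling uses p̄_i ~ U(0.1, 0.25) so the peak probability
  stays ≤ 0.5 and clipping remains rare even under ~2-fold global noise.
* Global noise: one gamma factor per cell (mean 1, sd σ_G) shared by both
  probed genes — per-cell sharing is what generates between-gene covariance.
  The observable moments depend only on the factor's mean and variance, so
  the gamma choice (vs. any positive distribution) affects only simulation
  tails.
* Switches: q_{i,s} ~ U(0,1), optionally resampled until each gene's
  per-state spread exceeds a floor (default 0.3 in the benchmarks) so every
  gene is informative about the hidden state.
* Burst-size dressing: indicator × geometric size (mean 8), used only to
  exercise thresholding; the information content remains binary.

What the generators deliberately do not emulate: measurement noise and
spot-calling ambiguity, false positives/negatives, nascent transcripts,
per-cell count reuse across pairs (each observation draws a fresh time), and
cell-cycle-correlated sampling. Passing recovery tests therefore demonstrate
the estimators' correctness under the stated generative models, not
robustness to those real-data artifacts.

## Problem sizes and numerical defaults

The recovery benchmarks run at reduced scale chosen as the package's own
benchmark design: continuous grid n_genes ∈ {2,4,8} × M ∈ {30,100,300} with
20 paired replicates; bursty switch benchmark 6 genes × M = 10⁴ × 20
replicates; global-noise inference 8 genes × M = 10⁴ × 20 replicates at
σ_G = 0.55. Quadrature 128 points (fits), 512 (symmetry checks), 1024 time ×
48 gamma nodes (moment quadrature); optimizer tolerances ftol 1e-10,
gtol 1e-8; rank tolerance 1e-8 relative; PCA tolerance 1e-10; variance floor
ε = 0.25 coincidences; eigenvalue noise factor 5.

## Known limitations

* Continuous fits are single-harmonic; higher harmonics would need the
  model container extended to per-harmonic amplitude/phase matrices.
* The bursty likelihood treats covariance estimates as independent
  Gaussians; at very small M or very common bursts the Gaussian and
  independence approximations degrade together with the variance formula.
* Free-amplitude bursty fits with H ≥ 2 are refused as under-identified
  (by construction of pairwise data, not an implementation gap); resolving
  them requires triplet measurements, which the package does not model.
* `fit_switch` supports S = 2 with known P1; higher S is blocked pending
  the extra constraints the identifiability accounting demands.
* The threshold choice (median) is a heuristic; the package does not model
  probabilistic presence/absence calls for ambiguous spots.
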