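# fishdyn

Reconstructing real-time gene-expression dynamics from pairwise single-cell
RNA-FISH snapshots.

RNA FISH counts individual mRNA molecules in fixed cells with high accuracy,
but fixation means every cell is a single *snapshot* of its expression
trajectory at an unknown time. `fishdyn` implements a maximum-likelihood
framework that turns collections of such snapshots, measured for *pairs* of
genes, back into dynamics: cycles of gene expression (cell cycle, metabolic
cycle) or stochastic switches between discrete expression states. It is aimed
at quantitative biologists analyzing multiplexed FISH (or immunofluorescence
/ single-cell sequencing) data, and at method developers who need a
reference implementation with honest identifiability accounting.

## The models and the statistics

**Continuous regime** (many transcription bursts per count): counts fluctuate
around a smooth periodic mean,

    x_i = mu_i(t) + eta_i,    mu_i(t) = mu0_i + A_i cos(2*pi*t/T + phi_i),
    eta_i ~ N(0, sigma_i),

and each pairwise snapshot (x_i, x_j), taken at an unknown uniform time, has
likelihood (1/T) ∫ N(x_i; mu_i(t), sigma_i) N(x_j; mu_j(t), sigma_j) dt.
Maximizing the product over all observations reconstructs the trajectories up
to two fundamentally unidentifiable symmetries: the global time shift and the
direction of time.

**Bursty regime** (counts dominated by at most one recent burst): data are
binarized (count strictly above a per-gene threshold, the pooled median by
default), and everything measurable is the per-gene burst frequency p̂_i and
the per-pair indicator covariance ĉ_ij. For a cyclic burst probability
p_i(t) = p̄_i + Σ_h a_{i,h} cos(2*pi*h*t/T + φ_{i,h}), the cycle-averaged
covariance is c_ij = ½ Σ_h a_{i,h} a_{j,h} cos(φ_{i,h} − φ_{j,h}) — a matrix
of rank 2H.  A cell-wide transcription factor G (mean 1, sd σ_G) adds
σ_G² p̄_i p̄_j and multiplies the harmonic part by (1+σ_G²), raising the rank
to 2H+1.  An S-state synchronous switch gives c = Σ_s P_s δ_s δ_sᵀ of rank
S−1.  Fitting maximizes a Gaussian likelihood of the observed ĉ_ij with
sampling variances r̂(1−r̂)/M, with the means pinned to p̂ exactly.

The package also provides:

* **Degrees-of-freedom accounting** (`dof_report`): how many parameters a
  model family has, how many constraints pairwise means + covariances
  supply, and how many extra constraints (e.g. triplet-FISH data sets) are
  needed. A single-harmonic cycle over 25 genes has 74 parameters and is
  fully constrained; a two-harmonic cycle needs 5 extra constraints; 2- and
  3-state switches need 1 and 3.
* **Diagonal-completion PCA** (`pca_complete`): the same-gene covariance
  diagonal is unmeasurable, so it is imputed iteratively from a low-rank
  eigenreconstruction; the spectrum reveals the dynamical complexity and,
  for a 2-state switch, the principal eigenvector directly yields the
  between-state burst-probability differences.
* **Cluster-synchrony statistics** (`cluster_activity`,
  `min_activity_pvalue`): the mean-normalized cluster activity
  Q_j(t) = (1/N_j) Σ_{i∈j} (1 + cos(2πt/T + φ_i)) dips to zero for
  phase-coherent clusters; significance of a low minimum is assessed by
  phase randomization.
* **Synthetic-data generators** for all three model families, first-class
  and tested, including burst-size dressing, global noise, and TSV export
  with true-model sidecars for recovery experiments.

## Worked example

Simulate a 2-state switch probed for all pairs of 6 genes, binarize,
and reconstruct it by MLE and by PCA:

```python
import numpy as np
import fishdyn as fd

true = fd.sample_switch_params(6, 2, rng_seed=100, min_separation=0.3)
data = fd.simulate_switch(true, fd.all_pairs(6), 10_000, rng_seed=200)
est  = fd.estimate_moments(data)

mle = fd.fit_switch(est, P1=0.5, n_restarts=10, rng_seed=0)
pca = fd.switch_from_pca(fd.pca_complete(est, rank=1), est.p_hat, 0.5)

print("Delta(MLE) =", round(fd.reconstruction_error_switch(true, mle.model), 4))
print("Delta(PCA) =", round(fd.reconstruction_error_switch(true, pca), 4))
print("restart agreement =", mle.restart_agreement)
```

Output:

```
Delta(MLE) = 0.0141
Delta(PCA) = 0.0133
restart agreement = 1.0
```

`Delta` is the switch reconstruction error: the per-gene squared deviation
of reconstructed from true burst probabilities, normalized by the
state-to-state variation, weighted by the state probabilities, averaged over
genes, and minimized over state relabelings. Values near 0.01 mean the
per-state burst probabilities are recovered to about 1% of their
between-state spread; both estimators perform comparably, with MLE ahead by
a few percent at most. `restart agreement = 1.0` records that all 10 random
optimization restarts reached the same maximum.

The same workflow is available from the shell:

```sh
fishdyn simulate --regime switch --genes 6 --n-obs 10000 --seed 1 --out d.tsv
fishdyn binarize --in d.tsv --moments mom
fishdyn fit-switch --moments mom --p1 0.5 --out fit.json
fishdyn dof --family cycle --genes 25 --harmonics 1   # prints n_parameters: 74
```

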