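# Methods

## The model family

A gene's expression is observed as log2 FPKM in `n_j` biological replicates
per species `j` on a rooted, ultrametric phylogeny with branch lengths in
million years (MY). All six models share the within-species layer
`X_ij ~ Normal(mu_j, delta2_j)`: each species has its own replicate variance
`delta2_j` (log2² units). Treating the `delta2_j` as free per-species
nuisance parameters is deliberate — per-gene replicate variances are
heterogeneous and essentially uncorrelated across species, so pooling them
(as equal-variance comparative methods do) risks inflated type-I error.

The species means `mu_j` arise from one of six processes: a single shared
mean; free unrelated means; Brownian motion (BM) with drift rate `sigma2`
(log2²·MY⁻¹); BM with one foreground branch at its own rate `sigma2_F`;
an Ornstein–Uhlenbeck (OU) process with attraction `alpha` (MY⁻¹) toward an
optimum `theta`; and OU with a foreground branch carrying its own rate and
optimum (`alpha` shared across regimes — the shift model has five free
parameters beyond the five `delta2_j`).

### Likelihood evaluation

The latent species means are integrated out analytically. Writing `xbar_j`
and `SS_j` for the species sample means and within-species sums of squares,
the likelihood factorizes into independent within-species scatter terms and
a multivariate normal in `xbar` with covariance `V + diag(delta2_j / n_j)`,
where `V` is the model's phylogenetic covariance:

* BM: `V_ij = sigma2 * (shared root-to-MRCA path length)`; with per-edge
  rates the contribution of each edge is `rate_k * length_k`.
* OU (stationary root): `V_ij = sigma2/(2 alpha) * exp(-alpha * d_ij)` with
  `d_ij` the tree distance between tips; the mean vector blends optima
  exponentially along each root-to-tip path.

**Root treatment.** BM-family models use REML — the likelihood of contrasts,
which is invariant to adding a constant to all observations and removes the
unknown root state without making it a parameter. The implementation uses
the closed-form identity for the density of orthonormal individual-level
contrasts (verified against a dense per-individual MVN oracle to 1e-8 in the
tests). OU-family models instead draw the root from the stationary law
`Normal(theta, sigma2/(2 alpha))`: an OU model with an attracting optimum is
not translation-invariant, and the stationary root both removes the root
nuisance and makes the tip variance exactly `sigma2/(2 alpha)`, independent
of tree depth.

A consequence worth knowing: as `alpha -> 0` the *raw* OU covariance
diverges like `sigma2/(2 alpha)`, while its translation-invariant part —
pairwise difference variances, equivalently the contrast covariance —
converges entrywise to BM. Limit checks are therefore stated on
`Var(x_i − x_j)`. `alpha` below 1e−12 is rejected outright; callers needing
the drift limit use the BM covariance. `(1 − exp(−2 alpha t))/(2 alpha)` is
computed via `expm1`, which is stable for small `alpha * t`.

### Simulation

`simulate_gene` is exact (no time discretization): each child node's latent
mean is drawn from its exact conditional normal given the parent — BM:
`Normal(parent, sigma2_k * t)`; OU: `Normal(theta_k + e^{-alpha t}(parent −
theta_k), sigma2_k (1 − e^{−2 alpha t})/(2 alpha))` — and replicates add
`delta2_j` noise. The OU root is stationary; the BM root state is a
simulation-only input (default 0) that the REML likelihood never sees.

## Inference

### MCMC

Random-walk Metropolis with one scalar proposal per parameter: a sliding
window reflecting at the prior bounds, applied on the log scale for positive
parameters (a multiplicative scaling move). Priors are uniform on the
sampling scale — `Uniform(−20, 20)` for means and optima (log2 units),
log-uniform on `[1e−5, 1e5]` for `sigma2`-type rates, `alpha` and
`delta2_j` — so the tempered target is just `beta * loglik` up to a
constant and a chain at `beta = 0` samples the prior exactly.

Schedule (defaults): 2000 burn-in iterations with proposal auto-tuning every
100 iterations toward 0.44 acceptance per scalar move, then 50,000 main
iterations thinned by 10 → 5000 retained samples; every free parameter is
updated twice per iteration in an order re-randomized each iteration.
Tuning is frozen after burn-in so the main chain is a valid Markov chain.
Initialization draws from the prior, retrying (bounded) until the likelihood
is finite; means/optima can optionally start at the grand sample mean.
Everything is bit-reproducible from the settings seed.

All chain arithmetic carries a leading batch axis. The public single-gene
functions run a batch of size one; the calibration studies
(`conserved_calibration`, `branch_shift_probability_batch`,
`phylo_signal_batch`) run hundreds to tens of thousands of independent
chains in lockstep, which is what makes a 200-repetition calibration of a
test that itself needs 101 MCMC fits per repetition run in minutes on one
core. The batched and scalar paths share one likelihood kernel.

### Stepping-stone marginal likelihoods

`stones` power posteriors (default 128) at powers `beta_k = (k/K)^{1/0.3}`,
the quantiles of Beta(0.3, 1) at equally spaced probabilities — the small
shape parameter concentrates stones near `beta = 0`, where the integrand
varies fastest. Stone `k` samples at `beta_{k−1}` (with `beta_0 = 0`),
contributes `log mean L^{beta_k − beta_{k−1}}`, re-runs the burn-in/tuning
schedule, and warm-starts the next stone. A model with all parameters fixed
yields its log likelihood exactly. Model probabilities are softmax of log
marginals under equal prior model weights; `p/(1−p)` converts a two-model
probability to a Bayes factor (0.75 ⇔ 3, 0.95 ⇔ 19 — the conventional
"BF > 20" label for 0.95 is a rounding of that convention; thresholds are
applied on the probability scale).

## Study-level procedures

**Phylogenetic signal.** BM vs the two nonphylogenetic models, pairwise.
Note a structural asymmetry: under these priors the independent-means model
pays ≈ 5·ln(40/posterior width) ≈ 26 nats for its five means while REML-BM
has none, so BM wins against UNEQUAL_MEANS even on data with no (or
adversarially negative) phylogenetic structure. That asymmetry, not a
property of real transcriptomes alone, is part of why near-universal
phylogenetic signal should be expected from this test on this model family.

**Conserved expression (sigma2 = 0).** Marginal likelihoods are prior
sensitive, so conservation is tested by Monte Carlo instead: fit the
identical-means model (only `mu` and the `delta2_j`), simulate `n_sim`
(default 1000) datasets from its posterior with the gene's replicate layout,
estimate the BM posterior-mean `sigma2` for each simulated dataset and for
the gene, and call the gene conserved unless its estimate exceeds 95% of the
simulated ones. "Exceeds 95% of" is a count, implemented as the
order-statistic quantile (`method="higher"`), giving an exchangeability
conserved rate of `(0.95 n + 1)/(n + 1)` — 0.9505 at `n_sim = 100`. For a
study of `G` genes the procedure costs `G (n_sim + 1)` MCMC analyses
(2,395,393 at `G = 2393`, `n_sim = 1000`).

**Branch shifts.** One tip at a time, shift vs no-shift marginal
likelihoods (BM_SHIFT vs BM, or OU_SHIFT vs OU), significant at model
probability > 0.75 (0.95 available). Direction: BM family compares the
foreground species' sample mean with the mean of background species' means
(BM has no optimum to compare); OU family uses the posterior mean of
`theta_F − theta_B`; exact ties are called "down" with a flag. No
multiple-testing correction is applied across tips or genes — calls are
Bayes-factor statements, not frequentist discoveries. Follow-ups: exact
two-sided binomial sign test on up/down counts; two-sided Wilcoxon rank-sum
on the within-species variances of up- vs down-shifted gene sets (exact for
tie-free samples up to 20 per side).

A power fact, established here by exact quadrature over the rate priors: a
*rate-only* tip shift is weakly identified on a 5-taxon tree. For one
shifted tip contrast `z`, the integrated `Normal(0, v)` marginal under a
10-decade log-uniform prior on `v` scales like `1/|z|`, which nearly cancels
the likelihood gain, so a 20-fold foreground rate yields Bayes factors near
1 and ~30–40% detection at the 0.75 threshold regardless of the base rate
(the comparison is scale-free). Optimum shifts (OU_SHIFT) are first-order in
the mean and are detected far more easily — a 3-to-4 log2-unit optimum shift
is recovered with high probability. This asymmetry is intrinsic to the
model/prior combination, not a sampler limitation.

## Divergence analytics and the OU bias study

Under BM, two species separated `T` MY have expression difference
`Normal(0, 2 sigma2 T)`, so the expected absolute divergence is the
half-normal mean `2 sigma sqrt(T/pi)`; under stationary OU the difference
variance saturates at `(sigma2/alpha)(1 − e^{−2 alpha T})` and the curve
flattens. `divergence_curve` pits Monte-Carlo means (default 10,000
simulated genes) against these closed forms per species pair. The
sum-of-squares estimator averages `(xbar_i − xbar_j)² / (2 T_ij)` over
pairs, then over genes; it is exactly unbiased for BM with noise-free
species means and is shift-invariant.

The bias study simulates stationary-OU tip values (one per tip, no replicate
layer) on pure-birth trees and refits `(alpha, sigma2)` by profile maximum
likelihood: for fixed `alpha` the optimum and the scale have closed-form
GLS/quadratic estimates, leaving a 1-D search over `log alpha` (coarse
49-point grid to dodge the profile's multimodality, then a bounded local
refine; search bounds default `[1e−3, 1e3]`). Relative bias is
`(mean estimate − truth)/truth`; optimizer failures are dropped and counted,
never imputed. ML rather than full MCMC keeps 1000-replicate grids
tractable and isolates the likelihood-surface pathology being measured.

Two numerical/design points. First, `exp(−alpha d)` correlation matrices
lose positive definiteness numerically on large trees; a small escalating
diagonal jitter (up to 1e−8·n) restores the Cholesky factorization. Second,
the trees are *not* rescaled to unit root height: a Yule(birth = 1) tree's
depth grows like `log n`, and that growth carries most of the extra
information about `alpha` that larger phylogenies provide. Measured on
unit-height trees, `alpha = 0.1` is unidentifiable at every size (`alpha ×
depth ≤ 0.2`) and the bias does not improve with taxa; on unscaled trees the
relative bias collapses between 10 and 50 taxa — small phylogenies
drastically overestimate attraction strength, which is precisely why the
conserved-expression question on a 5-species tree is better asked through
the `sigma2 = 0` Monte-Carlo test than through an OU fit. Unit-height
rescaling remains available as `BiasStudyConfig(unit_height=True)`.

## The synthetic-data generator

`generate_dataset` emulates the motivating study's structure: the five-taxon
fixture tree (root 11.8 MY, youngest split 5.5 MY, intermediate node ages
8.5 and 9.0 MY — within the published range, configurable since only the
range endpoints are pinned down); per-species replicate totals
(12, 11, 6, 12, 8) = 49 samples, generated as two sex groups per species to
match the design but pooled in analysis; and a regime mixture defaulting to
3% conserved / 81% drift / 16% tip shifts (half up, half down), mirroring
the proportions such analyses report. Baseline expression is
`Uniform(2, 8)` log2 FPKM; drift rates are log-uniform on `[0.05, 2]`
(matching the ~0–9 range of estimated rates); directed shifts are OU_SHIFT
genes with an optimum displaced 2–5 log2 units so that the direction label
is part of the ground truth; `delta2_j` is log-normal
(`meanlog = log 0.2`, `sdlog = 0.8`), drawn independently per gene and
species so variance vectors are uncorrelated across species by
construction.

What the generator does *not* emulate: count-level measurement noise and the
FPKM normalization pipeline, mean–variance coupling, sex-biased expression,
orthology-assignment errors, and correlated expression between genes.
Passing calibration tests on these data therefore demonstrate correctness of
the inference machinery under the model's own assumptions, not robustness to
those real-data features.

## Problem sizes used in the checked claims

The test suite and `scripts/acceptance.py` run shortened-but-honest
versions of the expensive procedures, sizes chosen as the smallest that
leave the assertions statistically meaningful: conserved-test calibration
over 200 sigma2 = 0 genes with `n_sim = 100` and 650-iteration chains
(batched: 20,300 BM fits); shift recovery over 30 shifted + 50 plain genes
with 16 stones; the bias contrast at 200 replicates per cell; divergence
laws at 10,000 simulated genes. The full study schedule (2000 + 50,000/10
iterations, 128 stones) is exercised live once, on a two-tip gene.

## Known limitations

* Single foreground branch per fit; no multi-regime OU, no joint multi-tip
  model (tips are scanned one at a time).
* Non-ultrametric trees are rejected rather than handled.
* The stepping-stone estimator's accuracy degrades if a stone's power
  posterior is poorly mixed; the stability checks (64 vs 128 stones within
  0.2 log units) are run on toy posteriors, not on every gene.
* The conserved test's threshold is a per-gene parametric bootstrap; no
  cross-gene FDR control is attempted.
* Rate-only tip shifts on 5 taxa sit at the Bayes-factor detection boundary
  (see above); detected shift sets will under-represent them.
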