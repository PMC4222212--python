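# Methods

## Model and procedure

### Center-point synthesis

Reference samples for each group (wild, farm) are equalized by sampling
`n_per_pop` individuals without replacement from every source population —
by default the size of the smallest population, so no single large sample
dominates — and pooled.  A center point is then synthesized by
frequency-conditional random mating: at each locus, each of an offspring's
two allele copies is an independent Bernoulli draw with the pooled A-allele
frequency.  This reproduces what gamete-shuffling programs such as HybridLab
do and yields, by construction, Hardy–Weinberg genotype proportions and
linkage equilibrium; a heterogeneous pool of diverged populations used
directly as a cluster anchor would violate both and bias the admixture
model.  The default center-point size is 100 individuals: large enough that
the synthetic sample frequencies track the pooled frequencies (binomial SE
≤ 0.035 per locus), small enough that per-individual MCMC runs stay cheap.
Missing genotypes are excluded from pooled frequencies, never imputed; a
locus with no non-missing alleles in the pool is an error.

### Two-cluster admixture model

Each query individual is stacked with all center-point individuals
(1 + 100 + 100 rows) and analyzed under the standard admixture model with
K = 2 clusters, no sampling-location priors, and independent cluster allele
frequencies:

* allele-copy origins: z_{ilc} ∈ {wild, farm} with
  P(z = k) ∝ q_{ik} p_{kl} for an A copy (1 − p_{kl} for B);
* cluster frequencies: p_{kl} ~ Beta(λ + n_A, λ + n_B), λ = 1 (uniform
  prior);
* admixture proportions: q_i ~ Beta(α + c_{i,wild}, α + c_{i,farm});
* one concentration α shared by both clusters and all individuals, updated
  by a Gaussian-proposal Metropolis step (SD 0.05) under a uniform(0, 10)
  prior.

Missing genotypes drop out of the likelihood.  *P*(wild) is the running
posterior mean of the query's q over post-burn-in sweeps.  Defaults are
50,000 burn-in and 100,000 retained sweeps; the test suite and the
acceptance script use 2,000 / 5,000, which the recovery suite shows is
already accurate to well under 0.05 on diverged panels.  Cluster labels are
arbitrary during sampling and are aligned afterwards by comparing the mean
posterior membership of the wild- versus farm-center-point individuals; with
100 anchors per cluster the ordering is unambiguous and label switching
within a run is, in practice, absent.  The reported Monte-Carlo standard
error is the naive √(var/n) of the per-sweep q draws and ignores
autocorrelation; it is a lower bound meant for rough convergence checking,
not a calibrated posterior-mean SE.

Analyzing individuals one by one (rather than a whole sample jointly) is a
deliberate design point of the method: joint analysis makes every estimate
depend on the composition of the rest of the sample, which biases membership
probabilities when group sizes are unbalanced or heterogeneous.  Per-query
chain seeds are derived from (base seed, CRC-32 of the individual id), so
batch results are independent of batch composition and order.

### Fixed-frequency ML engine

`ml_admixture` maximizes the same likelihood with cluster frequencies pinned
at the center-point values: the log-likelihood Σ_copies log(q·p_w + (1−q)·p_f)
is concave in q, maximized by bounded scalar optimization to 10⁻⁹ (grid
agreement verified to 10⁻³).  Frequencies are clipped to [10⁻⁶, 1 − 10⁻⁶] so
fully diagnostic loci keep the likelihood finite.  The ML engine is both a
fast alternative (`mode="ml"`, milliseconds per individual) and an
independent cross-check on the sampler; it reports a point estimate, not a
posterior, so its SE is returned as 0.

`AdmixtureAssigner` exposes both engines as a scikit-learn estimator: `fit`
on labeled reference genotypes, `predict_proba` → membership probabilities,
composable with sklearn model selection.

### Reference distributions and testing

*P*(wild) values are summarized with linearly interpolated (inclusive)
percentiles and logit-transformed before any mean comparison — proportions
near the boundaries otherwise have strongly mean-dependent variance.  The
clamp ε = 0.001 bounds |logit| by ~6.9 and matches the granularity of
membership estimates from 10⁵ sweeps; it is configurable.

The introgression test is one-sided (the alternative is always a *lower*
mean *P*(wild)) at level 0.05, as a z-test: the within-population variance
σ²_w of logit *P*(wild) is pooled across all wild reference populations, so
its degrees of freedom are in the hundreds and a t correction would change
critical values in the third decimal.  With a historical sample from the
same population, the null mean is the historical mean and
Var = σ²_w (1/n_hist + 1/n_cont).  Without one, the null mean is the grand
mean of wild population means and Var = σ²_b + σ²_w / n_cont, where σ²_b is
the between-population variance of mean logits estimated by method of
moments (sample variance of population means minus the mean sampling
contribution σ²_w·mean(1/n_j), floored at 0).  The critical-value curve is
the inverse of the test, back-transformed to the *P*(wild) scale; as
n_cont → ∞ the without-reference curve tends to
inv_logit(grand_mean − z₀.₉₅ √σ²_b), so without a historical sample there is
an irreducible detection floor set by how much wild populations differ among
themselves.

### Calibration and uncertainty

Because wild references average below 1 and farm references above 0, the raw
admixed mean is rescaled between the two anchors:
W = (P̄_adm − Farm_ref)/(Wild_ref − Farm_ref).  Values outside [0, 1] are
possible under sampling noise and are flagged, not clipped.  Uncertainty is
a percentile bootstrap over individuals (default 1,000 resamples); plain
percentile rather than BCa because the resampled statistic is a nearly
unbiased smooth mean.  Simulated coverage of the 95% interval at n = 30 is
within 3 points of nominal.

### Simulators

*Crosses* are gamete-level: one allele sampled uniformly per locus per
parent; a missing parental locus propagates missingness rather than imputing.
Group expectations follow the pedigree: F1 (H) and F1×F1 (2GH) carry an
expected wild-genome fraction of 0.5, backcrosses BCW/BCF 0.75/0.25.
"All-pairs" pairing iterates over *population* pairs (with random parents
within each), matching designs that draw a fixed number of hybrids per
population pair; individual-level all-pairs would be combinatorial overkill.

*Scenario resampling* consumes externally supplied cross-group proportions
(e.g. from demographic/fitness projections of repeated escapee spawning) and
per-group *P*(wild) pools: each replicate draws a multinomial group
composition, samples pool values with replacement, and calibrates the
replicate mean.

*Synthetic panels* use the Balding–Nichols model: ancestral frequency π ~
U(0.05, 0.95) per locus, group frequencies ~ Beta(π(1−F)/F, (1−π)(1−F)/F)
independently for wild and farm, individuals drawn in HW proportions.  The
default panel — L = 59 loci, F = 0.3, 100 individuals per group — emulates a
diagnostic SNP panel whose markers separate the groups collectively rather
than individually: single-individual admixture estimates on it have an SD of
roughly 0.11, so individual F1 hybrids span nearly the whole unit interval
while cohort means are accurate to ~0.02.  "Strong divergence" in the
recovery and MCMC-vs-ML suites means F = 0.8, where per-individual SD drops
to ~0.05.  Multi-population groups (`n_wild_pops`, `n_farm_pops`) share
their group frequency; they model sampling structure, not within-group
divergence.

## What the synthetic data does and does not show

The generator reproduces the features the method's statistics rely on:
two diverged gene pools, HW-equilibrium populations, unlinked loci, and
pedigree-faithful hybrid genotypes.  It does **not** model linkage,
genotyping error, allele dropout, within-group population substructure
(unless configured), selection during introgression, or ascertainment bias
in marker choice.  Passing tests therefore demonstrate correctness of the
algorithms and calibration of the statistics under the model's own
assumptions — not robustness of the marker panel on any particular real
species.

## Numerical choices and degenerate inputs

* q is clipped to [10⁻¹², 1 − 10⁻¹²] inside the sampler so the α
  log-posterior stays finite; p draws with λ ≥ 1 cannot degenerate.
* An α proposal outside (0, α_max) is rejected with the uniform draw still
  consumed, keeping the chain's draw count — and hence reproducibility —
  independent of the acceptance pattern.
* Weir–Cockerham F_ST skips loci with fewer than two genotyped individuals
  in either population, sums variance components over loci before taking the
  ratio, and may legitimately be negative for undifferentiated pairs;
  distances for PCoA are floored at 0.  PCoA is classical metric scaling
  (scikit-bio), with variance explained computed over positive eigenvalues.
* Percentiles: numpy's default linear interpolation between order
  statistics.
* The STRUCTURE-style text format does not carry locus names (the reader
  synthesizes `locus_1…locus_L`) nor allele orientation at loci where only
  one allele is observed; the default dialect treats labels {1, 2} as the
  canonical A/B coding, which makes write-then-read the identity.
  Half-missing genotypes collapse to fully missing with a warning, because
  the admixture likelihood treats a genotype's two copies jointly.

## Problem sizes

Unit and acceptance suites run the sampler at 2,000 burn-in / 5,000 retained
sweeps against 100-individual center points (about 0.4 ms per sweep), with
cohort sizes of 20–30 queries; simulation-calibration checks (type-I error,
bootstrap coverage) run 500–1,000 replicates directly on the logit scale.
These sizes were chosen so the whole battery completes in a few minutes
while leaving every tolerance comfortably tighter than the Monte-Carlo noise
floor it checks against.

## Known limitations

* One shared α and independent cluster frequencies; the correlated-
  frequencies admixture variant is not implemented.
* No convergence diagnostics beyond the naive running-mean SE.
* K is fixed at 2 by design — the method's question is binary.
* The without-reference test treats the available wild populations as a
  random sample of all wild populations; a non-representative panel shifts
  both the null mean and σ²_b.
* Scenario group proportions are inputs; the package does not derive them
  from fitness or demographic parameters.
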