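# Methods

`kelpabc` implements coalescent-based approximate Bayesian computation (ABC)
for a three-group phylogeographic system — two diverged kelp lineages (H,
along Japan; P, along Primorye) and a putatively admixed group (A, Sakhalin)
— typed at unlinked microsatellite loci and one non-recombining
mitochondrial sequence locus. This note records the models, estimators,
numerical choices and known limitations.

## Demographic model

A scenario is a backward-in-time event schedule over demes of constant
diploid effective size. Sampled lineages coalesce within a deme of
gene-copy size *M* at rate k(k−1)/(2M) per generation (continuous-time
approximation; waiting times are exponential). *M* = 2N for autosomal loci
and 0.5N for the mitochondrial locus (haploid, maternal, even sex ratio;
the 0.5 coefficient is configurable). Events are instantaneous:

* **Merge** — all lineages of one deme move into another. The sentence
  "X merged with Y at t" is always read as X's lineages moving into Y,
  with Y persisting at its own size; this convention fixes which effective
  size applies between events and is applied uniformly to all presets.
* **Admixture** — each lineage of the derived deme moves independently to
  the first source with probability *r*, else to the second. *r* is the
  proportion of A's ancestry tracing to H (the first-listed source).
* **SizeChange** — a deme takes a new size looking further back.

Seven presets encode the competing histories: four hierarchical split
orders (scenarios 1–4), isolation-with-admixture (scenario 5: A founded at
t1 from H and P, H/P divergence at t2), and two constrained variants of
scenario 5 placing the H/P divergence before (scenario 6) or after
(scenario 7) the Last Glacial Maximum. The LGM boundary is set at 10,500
generations — 21 kyr at 2 years/generation, the older edge of the usual
18–21 kya dating — and is configurable. In scenarios 6/7 the ancestral
size parameter `N_anc` doubles as the pre-expansion (bottleneck) size of
the lineage older than t2; no separate expansion time is modelled, since
only a single pre-expansion size is identifiable from these data.

Generation time defaults to 2 years/generation, the value implied by the
study system's reported generation-to-year conversions; `generations_to_years`
multiplies by it.

### Priors

Defaults (all configurable): effective sizes `N_H, N_P, N_A, N_anc` ~
Uniform(100; 100,000) diploids; `t2` ~ Uniform(1,000; 30,000) generations;
`t1` ~ Uniform(100; t2); `r` ~ Uniform(0.001; 0.999). Dependent bounds are
honored by drawing parameters in declaration order; cross-parameter
conditions (t1 < t2; the scenario 6/7 LGM constraints) are enforced by
rejection with a cap of 10^5 consecutive rejections. These bounds bracket
all posterior medians and intervals the study system reported; the exact
priors of the original analysis live in an inaccessible supplement, so the
defaults are package choices, not reproduced values.

## Mutation models

**Microsatellites** follow a generalized stepwise model (GSM). Per-branch
mutation counts are Poisson(rate × branch length); each mutation steps the
repeat count by ±s with s geometric on {1, 2, ...} (parameter `p_geom`,
default 0.22; `p_geom = 0` is the strict single-step model). Allele states
live on a window of `k_states` = 40 contiguous repeat counts, the root
starts mid-window, and steps that would leave the window are redrawn
(equivalently, the step distribution is truncated given the current
state). Per-locus rates are Gamma with shape 2 and mean `msat_mu_mean` =
5×10⁻⁴ mutations/locus/generation, the centre of the conventional
10⁻⁴–10⁻³ prior. The implementation reproduces the Ohta–Kimura equilibrium
gene diversity 1 − 1/√(1 + 8Nμ) under the strict model (tested).

**Sequence** evolution is Kimura two-parameter: substitution counts are
Poisson(μ_seq × L × branch length), sites uniform, transition:transversion
odds `kappa`:1 (default 2), the two transversions equiprobable. μ_seq
defaults to 2×10⁻⁸/site/generation, which at the inferred effective sizes
yields nucleotide diversities of order 10⁻³ — the order observed in the
real mitochondrial data. The root sequence is uniform random; only
substitution differences matter downstream. Multiple hits are allowed; no
rate heterogeneity across sites.

## Summary statistics

One code path serves observed and simulated data. Per group: mean alleles
per locus, mean gene diversity (1 − Σp²), mean allele-size variance
(unbiased, ddof = 1); per group pair: multi-allelic Weir–Cockerham θ with
variance components summed over alleles and loci before the ratio, the
mean individual assignment log-likelihood averaged over both directions
("classification index": per locus the Hardy–Weinberg genotype probability
under the target group's frequencies, leave-one-out for self-assignment,
unseen alleles at frequency 1/(2N+1)), and Goldstein's (δμ)². With a
sequence locus, per group: haplotype count, segregating sites, mean
pairwise differences; per pair: haplotype-frequency F_ST (distance-free,
Nei–Chesser correction) and mean between-group pairwise differences.
Statistics undefined on a dataset (e.g. F_ST of a monomorphic pair) are
imputed as 0 and flagged; the flag column is excluded from distances.

Other estimator conventions: haplotype diversity uses the n/(n−1)
correction; nucleotide diversity is the mean pairwise mismatch per
compared site with pairwise deletion of gaps/Ns; H_E is plain 1 − Σp² by
default (matching the spreadsheet convention common in this literature)
with the unbiased correction behind a flag; rarefied allelic richness uses
the hypergeometric formula at 2g gene copies, skipping under-sampled loci
with a warning; AMOVA uses squared pairwise distances (mismatch counts for
sequences, allele-sharing counts for microsatellites) with the standard
unequal-size coefficients, collapsing to two levels without groups, and
reports percentages that sum to 100 with the all-monomorphic case defined
as (0, 0, 100). Negative F_ST estimates are reported as computed; a
clamp-to-zero flag exists for pipelines that need non-negative inputs.

## ABC machinery

**Rejection** standardizes each statistic by the reference-table standard
deviation (SD, not MAD — deterministic and matching common practice),
excludes zero-variance columns, and retains the ⌈tolerance × n⌉ closest
rows by Euclidean distance, ties broken by row order.

**Model choice** fits a multinomial logistic regression of scenario index
on the standardized statistics over the retained set, centred at the
observed point so the fitted intercepts are the linear predictors at the
data. The fit is ridge-penalized (λ = 10⁻⁶) Newton iteration with step
halving; the 95% CIs propagate the intercepts' covariance (inverse
observed information) through the softmax by the delta method. The
original analysis does not state its CI construction; this is the package's
choice. Direct rejection proportions are reported alongside. The retained
fraction is pooled across scenarios, not per scenario.

**Parameter estimation** runs rejection within the chosen scenario's rows,
weights retained draws with the Epanechnikov kernel 1 − (d/d_max)², and
adjusts each parameter by a weighted local-linear regression on the
standardized statistics transported to the observed point. Sizes and times
are log-transformed, the admixture proportion logit-transformed, and
back-transformed after adjustment; a singular regression falls back to the
unadjusted weighted sample with a warning. Summaries are weighted median
and 2.5/97.5% weighted quantiles. At reduced table sizes the retained
fraction should be chosen so the regression stays clearly overdetermined
(retained rows ≫ number of statistics); the calibration experiments retain
500 rows for estimation rather than the 1% used for model choice.

**Posterior predictive error** simulates datasets under the chosen
scenario with parameters resampled from the fitted posterior (draws
violating the event-time ordering are resampled, then nudged as a last
resort), re-runs model choice against the existing table, and reports the
fraction not re-selecting the scenario. Drawing from the posterior rather
than the prior matches the "confidence in the selected scenario" usage; a
prior-based variant is a straightforward caller-side change.

**PCA check** projects the observed vector into the PCA of the
standardized table statistics; an observed point inside the simulated
cloud indicates the scenarios can generate data resembling the
observations.

## Synthetic data and calibration design

The full study template is 16 populations in groups H:8/P:3/A:5, 352
diploids total (22 per population — only the total is published, so
near-equal sizes are assumed), 24 microsatellite loci and a 1,890-bp
sequence. Populations within a group are drawn from the same deme: the
generator does not model within-group structure, genotyping error, null
alleles or missing-data patterns, so passing tests demonstrate correctness
of the inference machinery under the stated model, not robustness to those
real-data artefacts.

Calibration experiments (model-choice accuracy, parameter recovery,
posterior predictive error) need thousands of simulations, so they run on
a reduced design: one population per group with 16/6/10 diploids (roughly
proportional to the study's 176/66/110), the study's full 24 loci and
1,890-bp sequence. Problem sizes for these experiments — 5,000 simulations
per scenario, 1% tolerance for model choice, 500 retained rows for
estimation, 20 replicate pseudo-observed datasets — were chosen as the
largest the package's own test suite runs routinely. Pseudo-observed data
for calibration are generated at a fixed, study-scale parameter point
(N_H = 63,600, N_P = 6,910, N_A = 34,500, N_anc = 3,310, t2 = 13,500,
t1 = 3,590 generations, r = 0.5): prior-drawn pseudo-observations are
dominated by no-signal corners of the prior (recent divergence, very large
sizes) where no method can separate the scenarios, so they measure
prior-predictive overlap rather than pipeline correctness. Replicate
randomness comes from the coalescent and mutation processes.

## Numerical notes

* All randomness flows through `numpy.random.Generator`; fixed seeds give
  bitwise-identical datasets and tables. The stepwise-mutation walk runs
  in a numba kernel seeded from the caller's generator.
* The coalescent draws each deme-epoch's whole ladder of waiting times at
  once; by memorylessness, restarting the exponential clock at epoch
  boundaries is exact.
* Weir–Cockerham θ is undefined (NaN) for pairs monomorphic at every
  usable locus; haplotype-frequency F_ST is defined as 0 there. Small
  identical samples give mildly negative unbiased F_ST estimates — this is
  a property of the estimators, not a bug.
* GenePop codes are read as repeat counts directly (identity motif
  mapping); 2- and 3-digit dialects are supported, `0000`/`000000` is
  missing, half-missing genotypes are rejected.

## Limitations

* No continuous migration, recombination, selection, or growth other than
  instantaneous size changes.
* Sequence statistics treat haplotypes by exact identity; no substitution
  distances in F_ST (the distance-free estimator), no Φ_ST.
* The multinomial logistic CI is asymptotic; with few retained rows per
  scenario it can be optimistic.
* Microsatellite saturation: at the default mutation rate and large
  effective sizes, gene diversity approaches the k-state bound and
  between-group signal compresses; this mirrors the generalized stepwise
  model itself, but narrows the scenarios' separability at small sample
  sizes.
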