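# Methods

`invadem` re-implements, as one tested pipeline, the model-based
inference workflow used in invasion genomics surveys of recently
introduced plant populations: coalescent simulation of invasion
scenarios, SNP panel filtering and diversity statistics, LD-based
contemporary Ne, folded-SFS demographic model fitting, and ABC
random-forest scenario choice. This note records the models, the
parameter conventions, and the design decisions that were genuinely
open.

## Coalescent simulator

The core is a continuous-time structured coalescent over demes with
piecewise-constant diploid sizes. A deme of size `N` coalesces `k`
lineages at rate `k(k-1)/(4N)` per generation. Backward-time events are
instantaneous: a *split* moves every lineage of a deme into its source
deme; an *admixture* pulse moves each lineage of a deme independently
into donor A with probability `r`, else donor B; a *size change* resets
a deme's size. Events with equal times apply in list order. There is no
recombination within a locus, no migration between events, no selection,
and no growth curves (the size histories modelled here are all step
functions). One generation equals one year (the species flowers
annually; introduction-time posteriors of ~48 generations are read as
"within the last ~50 years"); this is configurable.

Mutations are infinite-sites with per-site rate 7e-9 per generation (a
plant rate estimated in *Arabidopsis*), over a default 150 bp RAD locus.
Two locus regimes exist:

- **`ascertainment="none"`** — Poisson mutations at rate mu*L per branch
  generation; a locus can carry 0, 1 or several SNPs. Used for
  Watterson/pi-style checks.
- **`ascertainment="segregating"` (or a MAF float)** — exactly one SNP
  per locus, simulated *conditional on segregating*: a genealogy is
  accepted with probability `1 - exp(-lambda * L_tree)` and a single
  mutation is then placed uniformly on its branches. This equals
  length-biased genealogy sampling up to a relative error of order
  `lambda * L_tree`; the intensity is auto-scaled so the expected number
  of mutations per genealogy is `snp_intensity` (default 0.1, giving a
  bias well below Monte-Carlo noise at the locus counts used anywhere in
  the package; throughput-critical ABC table construction uses 0.4,
  where only self-consistency between reference and pseudo-observed
  simulations matters). A MAF float additionally rejects SNPs at or
  below that pooled minor-allele frequency, emulating a filtered panel.

The nine invasion-scenario topologies (three sampled demes, up to three
unsampled "ghost" sources, one native ancestor; times `ti > td > td1`
plus a native divergence `ta`) are encoded in `data/scenarios.yaml`.
Scenario sets like this one are usually communicated as diagrams, so the exact
branching orders within each family are explicit, revisable defaults:
scenarios 1–5 funnel everything through a single introduced deme
(simultaneous split; two stepwise orders; the two stepwise orders with
the third deme replaced by a recent admixture of the other two), and
scenarios 6–9 use multiple sources (three independent introductions;
two sources with a post-introduction split; two sources with
post-introduction admixture; a single introduction drawn from an
admixed pool of two ghosts). Scenario 6 assigns the three ordered times
to the three introductions, oldest first. The admixture proportion `r`
has no conventional value; its prior is U(0.05, 0.95).

Priors are independent uniforms — sizes 100–100,000 diploids, ordered
times 10–60 generations, `ta` 101–10,000 — with order constraints
enforced by rejection, which preserves each parameter's marginal bounds
(sorting would not).

## Expected folded SFS

For a single population with piecewise-constant history, the expected
folded spectrum is computed exactly: in rescaled time the lineage count
is a homogeneous pure-death chain, so per-epoch occupancies come from
`expm` of a bidiagonal generator plus one linear solve, giving expected
times `E[T_k]` at each lineage count; the unfolded class expectations
follow from the classical subtending probabilities
`C(n-i-1, k-2)/C(n-1, k-1)`, then folding and renormalization over
segregating classes. For a constant-size history this reduces to the
folded `1/i` spectrum (e.g. proportions `(8/11, 3/11) = (0.7273,
0.2727)` at `n = 4`). A Monte-Carlo mode averages simulated spectra and
serves as an internal cross-check; the test suite additionally checks
both against msprime branch-length spectra.

## Filtering and diversity statistics

Filtering is a fixed four-step sequence mirroring a Stacks → Plink →
Tassel pipeline: (1) locus presence ≥ 80% of individuals within each of
≥ 12 populations (degrading to "all populations" when fewer exist);
(2) pooled exact Hardy–Weinberg test, removing loci with p < 1e-6 (the
exact conditional test over heterozygote counts; pooled because the
original pipeline filtered globally — a per-population option exists);
(3) individuals with > 30% missing calls removed; (4) pooled MAF ≤ 0.05
removed. An audit object proves `input = retained + removed-by-step`.

He uses the plain `1 - p^2 - q^2` form (the GENALEX convention; an
unbiased `2n/(2n-1)` variant sits behind a flag). Allelic richness is
rarefied hypergeometrically:
`Na(g) = sum_alleles [1 - C(N-N_i, g)/C(N, g)]`. Pairwise FST is
multi-locus Weir–Cockerham theta (ratio of summed variance components),
with a one-sided permutation test over individual relabelings and the
`(b+1)/(m+1)` p-value estimator. Negative theta estimates are reported
as-is and clamped at 1e-6 only when linearizing `F/(1-F)` for the
Mantel test, whose geographic predictor is log great-circle kilometres
(haversine; a planar option exists for strict tool emulation).
Population-level Nei (1972) standard distance feeds PCoA via
scikit-bio's Gower double-centering; an individual-level variant is also
provided since the original analysis was reported at genotype level.

## LD-based contemporary Ne

The estimator is the Burrows composite-disequilibrium method: for every
qualifying locus pair (within-population MAF ≥ 0.05, pairwise-complete
individuals), `Delta = (1/2S) sum x_i y_i - 2 p q` and Weir's composite
correlation `r^2 = Delta^2 S^2 / ((S-1)^2 (p(1-p)+D_p)(q(1-q)+D_q))`,
where `D` is the within-locus Hardy–Weinberg disequilibrium. The
`(p(1-p)+D)` denominators matter: the Waples sampling expectation
`E(r^2|S) = 0.0018 + 0.907/S + 4.44/S^2` (S < 30; `1/S + 3.19/S^2`
otherwise) is calibrated for exactly this estimator, and the package's
Wright–Fisher recovery tests fail with the plain `p(1-p)` product.
The drift signal `r2' = mean r^2 - E(r^2|S)` inverts to
`Ne = (0.308 + sqrt(0.308^2 - 2.08 r2'))/(2 r2')` for S < 30 (1/3 and
2.76 coefficients otherwise); non-positive `r2'` reports an infinite
estimate rather than an error. Pairs are weighted by their own S; the
harmonic-mean S over pairs selects the correction regime. Loci are
assumed unlinked (sparse RAD panels), random mating is assumed (the
species is self-incompatible), and confidence intervals are either
parametric (chi-square with the locus-pair count as degrees of freedom)
or delete-one-locus jackknife. "Rarefaction" of Ne to a common sample
size is implemented as explicit subsample-and-re-estimate (median point
estimate and median CI bounds over replicates, infinite estimates
tracked separately) — an explicit construction, since NeEstimator-style
implementations expose no such feature.

## Folded-SFS demographic fitting

Three single-population models are fitted to per-population folded
spectra by maximizing the multinomial composite log-likelihood over the
renormalized segregating classes (SNP-only data carry no invariant-site
count, so the monomorphic class is excluded). Consequences worth
stating plainly:

- the constant model's renormalized spectrum does not depend on its
  size, so with the contemporary size fixed it has zero free parameters
  and a closed-form likelihood;
- a bottleneck-plus-rebound history is nearly unidentifiable from a
  single size change at these sample sizes: the best two-parameter
  approximation of the three-epoch spectrum sits within KL ~ 1e-5,
  so AIC essentially never prefers the richer model even when it is
  true. The package reports this honestly rather than papering over it;
  the richer model's *size-ratio* (ancient/bottleneck) remains
  recoverable.

The contemporary size is fixed to an externally supplied value by
default (e.g. the LD-based Ne), matching the protocol of fixing Ne at
the present; a flag frees it. Optimization is cyclic coordinate ascent
("ECM-like"): one bounded Brent line search per parameter per cycle on
log10 scale, bounds sizes [1, 1e7] and times [1, 1e4], the ordering
`T_BOT < T_ENDBOT` enforced by a `(T_BOT, dT)` reparameterization,
multi-started from uniform random points (default 8 restarts; the
100-run convention of cluster-scale analyses is configuration,
not default), stopping at
a per-cycle lnL improvement < 0.001. Model choice is by AIC
(`2k - 2 lnL`, natural logs) with ties toward fewer parameters.
Confidence intervals come from refitting 50 multinomial resamples of
the observed spectrum (percentile 2.5/97.5), warm-started at the MLE.

## ABC random forest

The reference table simulates each scenario under the priors, computes
a fixed-schema 33-entry summary vector (per population: proportion
polymorphic, mean/variance of He, mean MAF; per pair: Weir–Cockerham
FST, Nei distance, bias-corrected f2; per target: bias-corrected f3 and
the least-squares two-source admixture coefficient
`alpha = sum (p_t - p_B)(p_A - p_B) / sum (p_A - p_B)^2`, clamped to
[-0.5, 1.5]; degenerate entries imputed as 0 with paired indicator
flags), and shuffles rows with a recorded permutation. The "AML"
admixture summaries named in this literature are interpreted as these
least-squares coefficients — the nearest well-defined construct.

Scenario choice trains a 500-tree classification forest (sqrt features
per split, unlimited depth); votes are per-tree predictions at the
observed vector; the global error is the OOB misclassification rate;
the local error is the prediction, at the observed vector, of a
regression forest trained on the per-row OOB misclassification
indicator, and the posterior probability of the selected scenario is
`1 - local error` by construction. The error-regression forest is
capped at 200 smoothed trees (min leaf 5) since it estimates a scalar
rate, not votes. Rows are canonically sorted before any forest fit, so
all outputs are invariant to reference-table row order. The default
forest size is 500 trees (so vote tables sum to 500), configurable.
Parameter estimation uses one 500-tree regression forest per parameter;
leaf co-occurrence weights with the observed vector give the posterior
median and 5–95% quantiles plus the locally weighted NMAE, and OOB
predictions give the global NMAE. LDA projection onto the first two
discriminant axes provides the usual visual diagnostic.

## Synthetic study generator

`synthetic_study.generate_study` emulates the survey end-to-end: 22
populations with the survey's sample sizes (9–16 diploids, 283 total)
and coordinates, assigned to three introduced lineages under scenario 6
by default (`ti = 48`, `td = 28`, `td1 = 15` — an introduction within
the last ~50 generations with later secondary divergences), eight populations admixed between two lineages, each
population founded from its lineage deme 5–12 generations ago with a
contemporary size U(40, 220) and a recent decline to U(15, 90) ending
U(2, 5) generations ago, uniform missing calls at 5%, then the standard
filter. The deep-divergence parameters (`ta = 2500`, source sizes
8000, lineage sizes 2000) were calibrated once so that the filtered
matrix spans the surveyed pairwise-FST range (~0.03–0.26, mean ~0.1)
and He range (~0.17–0.25), and then frozen. What the generator does
*not* emulate: RAD assembly artifacts, linked SNPs, non-uniform
missingness (a block-missingness option would be the first extension),
gene flow after founding, selection — and, importantly, pedigree LD:
because every locus is an independent genealogy, the generated matrices
carry no drift LD at all, so the LD-based Ne estimator is structurally
infinite on them. LD-Ne recovery is therefore validated on forward
Wright-Fisher simulations, where unlinked loci share a pedigree. Passing tests on this
generator therefore demonstrate internal consistency of the inference
chain under the stated model, not robustness to real-data artifacts.

The `generate_worked_micro` fixture (3 populations x 6 individuals x 50
SNPs) runs in seconds and backs the tutorial and most tests.

## Problem sizes used in tests and the acceptance script

Scaled once, as package defaults, from the cluster-scale settings
such analyses use in production: reference tables of 2,000 simulations per
scenario at 200 SNP loci (tests) and 600 per scenario (acceptance
script), 500 trees; SFS fits with 5–8 restarts on 1,000-locus spectra;
Wright–Fisher Ne recovery with 50 replicates of 500 loci; the full
synthetic study at 1,200–3,563 loci. The bottleneck-rebound recovery
condition uses a contemporary size of 1,000 (a pronounced rebound),
chosen by the identifiability analysis above.

## Known limitations

- The length-biased SNP acceptance is exact only as `snp_intensity -> 0`;
  the documented default keeps the bias an order of magnitude below
  sampling noise, but it is a knowing approximation.
- The composite likelihood ignores linkage between SNPs from the same
  RAD locus (one SNP per locus makes this mild) and treats loci as
  independent draws.
- RF posterior probabilities inherit the known optimism/pessimism of
  OOB-based local error regression at small table sizes.
- No canonical summary-statistic set exists for this analysis;
  the implemented registry is a documented, fixed superset candidate.
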