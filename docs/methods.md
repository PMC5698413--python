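# Methods

This note records the models behind each module, the defaults and why
they are set where they are, what the synthetic data do and do not
emulate, and the numerical choices a maintainer would want written down.

## Genealogy and mutation models

**Genealogies.** Three topologies are supported, all parameterised
directly in years. `star` attaches every tip to the root with a branch
of length equal to the TMRCA — the idealised model of an instantaneous
radiation, and the regime in which the rho standard error is exact.
`coalescent_const` is a Kingman coalescent: inter-coalescence waiting
times for *k* lineages are exponential with rate C(k,2)/scale, where the
scale is the product of haploid effective size and a generation time of
30 years. `coalescent_growth` shrinks the population backwards in time
at a user rate (per year), drawing waiting times by inverting the
cumulative coalescent intensity; strong growth produces star-like trees.
Because downstream validation needs a known truth, coalescent trees are
conditioned on their root age: the realised tree is linearly rescaled so
the TMRCA equals the requested value exactly. The raw (unconditioned)
intervals are exposed as `coalescent_intervals` and are checked against
their closed-form mean and against msprime in the test suite.

**SNPs.** Infinite-sites: each branch receives
Poisson(rate × callable length × branch years) mutations, each at a
distinct position in the callable region, carried by all descendant
tips. Defaults are the two whole-Y calibrations in common use — a fast
rate of 1e-9 and a slow rate of 6.17e-10 substitutions/site/year — over
4.88 Mb of unique, high-quality Y sequence. No back mutation and no
recombination, which is the standard approximation for the male-specific
region and is what makes the perfect-phylogeny builder applicable.

**STRs.** Mutations arrive per haplotype as Poisson(rate × years) with
the YHRD-derived default of one mutation per haplotype per 858 years for
the 13 single-copy YFiler loci; each mutation picks a locus (uniform
weights by default; the published rate is per-haplotype, so any per-locus
split is a modelling choice) and steps the repeat count ±1 with equal
probability. Repeat counts cannot drop below one: a step that would do
so reflects to +1. Multi-step mutations and locus-specific published
rates are deliberately out of scope.

**What the simulator does not emulate.** Genotyping error, locus
dropout, duplicated loci (DYS385a/b), population admixture and
migration, and ascertainment of the SNP panel. Passing tests therefore
show estimator correctness under the stated models, not robustness to
those artefacts.

## Filtering

The cascade runs mask → callable filter → heterozygote removal → sample
QC, in that order, and is idempotent. Depth-failing genotypes become
missing, never ancestral — coercing them to the reference state would
deflate every downstream mutation count and bias rho towards the
present. "Mean depth < 10X" is interpreted as the per-sample mean over
the sites retained at the QC stage (the natural reading when upstream
stages have already restricted the site set); the QC report records the
value used. The 5% missingness boundary is exclusive-fail: exactly 5%
is removed. After sample removal, sites left without any derived call
are dropped so the output contains variable sites only.

## Perfect phylogeny and haplogroup assignment

Y-SNP matrices are effectively homoplasy-free, so the sample tree is the
unique perfect phylogeny: identical site columns are merged into clades,
clades are ordered by size and nested (Gusfield's construction), and any
overlap-without-nesting raises an error naming a representative site
pair rather than resolving the conflict heuristically. Edge mutation
counts and descendant-tip counts feed the rho estimator directly.
Missing genotypes are either refused or imputed by per-site majority
(ties to ancestral), with a warning; heuristic parsimony search,
bootstrap supports and branch-length optimisation are non-goals.

Assignment walks the defining-SNP hierarchy from the root: an edge is
derived only if at least one defining variant is called derived and none
ancestral; mixed calls on one edge, a derived call below an ancestral
edge, and derived sibling edges are all hard inconsistency errors. An
edge whose defining variants are all missing blocks descent — the sample
keeps the shallower (starred) label and the event is logged — a
conservative choice; the alternative (descend on downstream evidence)
would assign deeper but can silently mask genotyping failures.

Frequency tables print percentages to two decimals with round-half-up,
matching the convention of published haplogroup tables. Subclade shares
within the clade are flagged (warning + NaN) for populations with no
clade members instead of dividing by zero.

## Rho dating

rho is computed branch-wise, Σ (n_b/n)·l_b, which equals the tip-wise
mean mutation count to the ancestor (both routes are implemented and
cross-checked). The standard error is the Saillard estimator
σ² = Σ (n_b/n)²·l_b. Conversion to years divides by μ = rate × callable
length (SNP mode) or by the per-haplotype STR rate (STR mode, i.e.
multiply by 858 under the default). Confidence intervals are T ± zσ_T
with z = 1.96 by default and a `ci_multiplier` override, since symmetric
intervals at an unstated multiplier are the convention in rho tables.

For STR rho the founder defaults to the per-locus modal haplotype, the
common founder-age convention. Its standard error uses the star
approximation σ = √(ρ/n), which is exact on a star genealogy and
optimistic otherwise; wiring the Saillard estimator to a spanning tree
of the median-joining network was considered and not done, because the
MJN is unrooted and the choice of spanning tree would add an arbitrary
degree of freedom.

Two caveats are worth stating because they are easy to miss:

- The per-locus **modal** haplotype is not guaranteed to minimise the
  mean stepwise distance — the componentwise **median** is the L1
  minimiser. On peaked, star-like data the two coincide (asserted in the
  tests); on flat allele distributions they can differ.
- **Saturation bias:** the stepwise distance to the founder undercounts
  mutations when a locus is hit more than once (±1 steps can cancel).
  At a depth of 2000 years over 13 loci the shortfall is ≈ 8%, so STR
  rho mildly underestimates deep TMRCAs. The simulator tests therefore
  compare the observed mean distance to an exact single-step
  random-walk expectation rather than to the raw mutation count.

`effective_rate_per_variable_site` implements the bookkeeping needed
when an external clock-based tool is fed a variable-sites-only
alignment: rate × callable length / number of variable sites (e.g.
1e-9 × 4,880,000 / 4,269 = 1.1431e-6 per site per year). Bayesian MCMC
dating itself is out of scope.

## Diversity statistics

Gene diversity is the unbiased D = n/(n−1)(1 − Σp²) over exact
multi-locus haplotype identities, with Nei's sampling variance.
Per-locus heterozygosity applies the same estimator to allele
frequencies; allele-size variance uses the n−1 denominator. These match
the conventions of the standard population-genetics packages, which the
source literature relies on without stating the formulas. Longitude
associations use Spearman rank correlation with midranks for ties; for
n ≤ 8 units the two-sided P-value is computed by full enumeration of the
n! rank permutations (at n = 6, ρ = 0.8857 gives exactly P = 24/720 =
0.033), because the large-sample approximation is invalid for a handful
of populations.

## AMOVA

Variance components follow the Excoffier partition of sums of squared
deviations computed from a pairwise distance matrix, with the standard
unequal-n coefficients, for one-level (populations) and two-level
(groups of populations) designs. The default distance is the count of
differing loci — the F_ST-style haplotype distance — with the squared
stepwise distance available for R_ST-style sensitivity analysis.
Negative components are reported as computed, not truncated. Populations
with a single sample are excluded with a warning (they carry no
within-population information). A two-level design with one group
collapses to the one-level analysis. P-values permute the labels
appropriate to each statistic (samples among populations for Φ_ST,
populations among groups for Φ_CT, samples within groups for Φ_SC) with
p = (hits + 1)/(n_perm + 1); the default 10,000 permutations trades the
resolution of very small P-values for desk-scale runtime and is a flag.
A coastal-vs-inland style grouping is supplied as configuration (a
`population → group` mapping in the pipeline YAML or a CSV on the CLI),
never hard-coded, e.g.:

```yaml
groups:
  WesternSahara: inland
  Reguibates: inland
  Morocco: coastal
  Algeria: coastal
  Tunisia: coastal
  Libya: coastal
```

The test suite checks the components against an independent oracle that
embeds haplotypes in coordinates (repeat vectors for the squared
stepwise metric; scaled one-hot allele indicators for the
loci-differing metric, whose Hamming distance is half a squared
Euclidean distance), computes classical ANOVA sums of squares about
means, and solves the expected-mean-square equations numerically.

## Median-joining networks

Stage 1 is the minimum spanning network: an edge joins two haplotypes
when its weighted stepwise distance is within ε of the minimax
(bottleneck) connection cost between them; at ε = 0 this is exactly the
union of all minimum spanning trees. Stage 2 proposes per-locus medians
of triplets connected in the current MSN, keeps a candidate only if
adding it alone shortens the minimum spanning tree, recomputes, and
stops at a fixed point (iteration cap 50, raising with diagnostics if
hit); medians whose removal leaves the tree cost unchanged are pruned.
Identical haplotypes collapse into one node with their count as
frequency and a per-population composition attribute. Locus weights
default to uniform and are a parameter, as is the locus set itself —
published panels vary between 12 and 13 YFiler loci, so no set is baked
in.

Two containment caveats: once a median is inserted, a direct
observed–observed MSN edge may legitimately disappear from the final
graph (replaced by finer steps through the median), so the invariant
that survives is bottleneck containment — every MSN edge is realised as
a path whose largest step does not exceed the edge weight — and that is
what the tests assert.

`star_index` is the fraction of observed haplotypes exactly one
mutational step from the highest-frequency node (ties broken towards the
lexicographically smallest haplotype). It quantifies the one-step halo
of a recent radiation and is depth-dependent: at ~1 expected STR
mutation per lineage star genealogies clearly outscore constant-size
coalescents, while at 2–3 mutations per lineage the halo of a true star
disperses outward and the index loses discrimination. The simulation
property test runs at the shallow depth where the signature is
well-defined.

## Pipeline and reproducibility

The `ylineage run` pipeline takes one YAML config validated by schema
(unknown keys rejected, field-path errors, thresholds bounded). Omitted
fields get the filter defaults (min reads 5, max missingness 5%, min
mean depth 10X), rate presets (1e-9 / 6.17e-10 / 1 per 858 years) and
ε = 0. A master seed is mandatory whenever a stochastic stage
(simulation, AMOVA permutations) is configured; each stage receives a
derived sub-seed, so a rerun with the same config produces a
byte-identical report (timestamps go to the log only). A failing stage
aborts with the stage name while keeping partial outputs.

## Problem sizes and external-data checks

The test suite and `scripts/acceptance.py` size their simulations for a
single desktop core: the rho-recovery experiment uses 200 star panels of
50 tips (enough for a 5% tolerance on the mean and a stable coverage
estimate), AMOVA oracle checks use ≤ 13 samples where exhaustive
verification is feasible, MST enumeration uses ≤ 7 haplotypes, and the
synthetic pipeline panel has six populations of 15–30 samples.

Two further reproduction targets from the source study require external
downloads and are documented here rather than run: (i) applying the
filter cascade and SNP rho dating to the published North African whole-Y
VCF (figshare "North_African_Ychromosome_dataset_vcf") should recover an
E-M183 TMRCA of 1730 [1481, 1979] years at the fast rate; (ii) the
supplementary 12-locus STR table with subclade assignments should
reproduce AMOVA percentages of 8.1 (populations), 16.5 (coastal vs
inland) and 8.6 (subclades), DYS458*17 frequencies of 71% vs 31%, and an
STR rho TMRCA of 2012 [1583, 2441] years. The entry points are
`run_filter_cascade` + `rho_snp` and `amova_with_pvalues` +
`allele_split` + `rho_str` respectively; no code changes are needed,
only the input files.

## Known limitations

- Perfect phylogeny requires conflict-free data; real panels with
  recurrent mutation or genotyping error need upstream cleaning (the
  error message names the offending site pair to make that tractable).
- STR rho inherits the saturation bias described above and the star
  approximation for its standard error; both make deep STR dates mildly
  optimistic in precision and low in expectation.
- The AMOVA permutation engine is pure Python/NumPy; at tens of
  thousands of permutations on panels of thousands of samples it is
  minutes, not seconds.
- The median-joining implementation targets panel sizes typical of
  haplogroup studies (hundreds of samples, tens of distinct haplotypes);
  it recomputes minimum spanning trees per candidate median and scales
  accordingly.
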