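# Methods

`oefit` analyses pooled gene-overexpression (OE) screens: a barcoded
high-copy plasmid library (one gene per plasmid, each with a unique DNA
barcode) is transformed into one or more yeast strains and grown
competitively under a stress condition. Barcode abundance before and after
outgrowth measures the relative fitness effect of each gene's dosage
increase; companion RNA-seq and DNA-seq data characterize strain-specific
expression responses and natural copy-number variation. This note records
the models, the tunable parameters, and the design decisions behind each
stage.

## Barcode fitness scoring

**Normalization with jackpot exclusion.** Some barcodes balloon to extreme
read counts during competition. If they entered the library-size factor
they would deflate everyone else's normalized abundance, so each sample's
size factor is the total read count over genes at or below
`high_count_threshold` (default 50,000 reads) *in that sample*; every
count, including the excluded ones, is divided by that factor. The
exclusion is evaluated per sample on raw counts: the threshold is an
absolute read count, so a gene may be excluded from one sample's factor and
not another's.

**Scaling.** Normalized values (which are proportions on the order of
1e-6) are multiplied by `scale` (default 1,000,000) and rounded to the
nearest integer, half away from zero. This returns the data to a count-like
scale on which both the imputation floor and the NB model operate.

**Dropout imputation.** Highly deleterious genes can disappear from the
pool entirely. A gene that was well measured at the start — scaled value
above `impute_min_start` (default 20) in *all* start replicates of a
strain — and is zero in an end replicate gets that cell set to
`pseudocount` (default 1, on the scaled integer scale). The threshold is
applied after scaling because the >20 floor is only meaningful on the
count-like scale; applying the pseudocount on the same scale keeps it
commensurate with the NB model's count units. Two interpretations of
"missing" are selectable: per end replicate (`impute_mode="replicate"`,
default) or only when the gene is zero in every end replicate (`"all"`).

**Scores.** The relative fitness score of a gene in a replicate is
log2(end / start) of the scaled values, pairing start and end samples by
replicate index; the per-gene score is the mean over replicates with finite
scores. log2(x/0) is treated as undefined and excluded, never ±inf:
imputation is the mechanism for true dropouts, and what remains unmeasured
stays unmeasured (NA with a `low_coverage` flag).

**Expected scores in the simulator.** With deterministic exponential
growth, gene g's abundance after t doublings is
a_g(t) = a_g(0)·2^(t(1+s_g)), and its expected centered score is

    score_g = t·s_g − log2( Σ_h a_h(0)·2^(t(1+s_h)) / Σ_h a_h(0)·2^t ),

the log2 change of its *relative* abundance. The centering term is the
pool's abundance-weighted growth in excess of neutral doubling; by
construction Σ_g p_g(0)·2^(score_g) = 1.

## NB testing machinery

The differential-abundance stack is implemented here rather than delegated:
log-link negative-binomial GLMs (Var = μ + αμ²) fitted by IRLS, vectorized
across genes sharing a design matrix (convergence: relative deviance change
< 1e-8, max 100 iterations; non-converged genes get NA p-values).
Coefficients are reported in log2 to match fitness scores and fold changes.

Dispersion is estimated by Cox–Reid adjusted profile likelihood (the
per-gene log-likelihood at the fitted means minus ½·log det XᵀWX) on a
log-spaced grid with parabolic refinement. The common value maximizes the
APL summed over genes; per-gene values are shrunk toward the common one by
weighted-likelihood empirical Bayes — maximizing
APL_g(α) + (prior_df / residual_df)·mean_g APL_g(α) — and clipped to lie
between the raw per-gene and common estimates. `prior_df` defaults to 10;
prior_df → ∞ collapses every gene to the common value. A single common
shrinkage target is used (no abundance trend): the simplest defensible
estimator, with trend fitting deliberately out of scope. Tests are
likelihood-ratio chi-square tests of nested designs (not quasi-likelihood
F-tests), chosen because the LRT is fully specifiable from the model above
with no extra moderation machinery. BH step-up FDR is computed within each
testing family (e.g. within strain for fitness tests).

TMM normalization factors for RNA-seq follow the standard trimmed-mean-of-
M-values recipe: per-gene log2 expression ratios against a reference sample
(the one whose 75th-percentile count fraction is closest to the mean),
trimmed 30% two-sided on M and 5% two-sided on A, precision-weighted mean,
factors normalized to geometric mean 1. Genes zero in either sample are
excluded from the pair's factor.

## Gene calls

A gene is *beneficial* in a strain when FDR < 0.05 and its mean score is at
or above a magnitude threshold; *deleterious* when FDR < 0.05 with negative
mean score (no magnitude gate — the magnitude rule exists because strains
with mild phenotypes produce many significant-but-tiny positive effects).
The threshold can be derived from the data as the smallest significant
positive mean score among a named strain set (the stress-sensitive
strains); ties at the threshold are included, since a derived threshold is
itself the score of an included gene. Cross-strain overlap tables are exact
partitions over the 2^k − 1 strain combinations.

## Strain-by-environment expression contrasts

"Different from the mean of all strains" is implemented as sum-to-zero
(deviation) coding of the strain factor, which makes the question a direct
coefficient test and guarantees the reported per-gene deviations are
mean-zero across strains. The interaction test fits, per gene, an NB GLM
with replicate block, strain (deviation-coded), timepoint, and
strain×timepoint terms, and drops all interaction terms jointly in the LRT:
the two post-shift timepoints are tested jointly, with per-timepoint
deviations reported. The replicate block encodes the paired design (all
strains grown in parallel within a replicate). The basal contrast is the
same model on time-0 samples with replicate block and strain only.
Display fold changes are computed on TMM-and-depth-normalized counts,
paired within replicate, with a +0.5 pseudocount in numerator and
denominator; the pseudocount never enters the GLM, which handles zeros
through the likelihood.

## Copy number from read depth

Depth tracks are normalized to the genome-wide median, references are k=3
single-copy genes whose median depth lies within ±5% of the genome median
on distinct contigs (chosen uniformly at random, seeded, when not supplied),
and every base is divided by the pooled reference median to give copies per
haploid genome. The copy call for a target is the median of the *raw* ratio
over its bases; the 500-bp centered running average (windows truncated at
interval edges; even windows take one extra base to the right) is produced
for display only. All medians use the lower-median convention for even
counts, applied consistently. A partial duplication shows up as a bimodal
per-base ratio; rather than calling breakpoints, the call is flagged
heterogeneous when the interquartile range of the ratio exceeds 0.5.

## Enrichment and clustering

Gene-set enrichment is the upper-tail hypergeometric test
P(X ≥ overlap) with population = universe, successes = category size,
draws = query size, against a fixed significance cutoff (default 1e-4, no
multiplicity correction; BH available via flag — fidelity to the fixed-
cutoff convention first, rigor as an option). Hierarchical clustering
defaults to uncentered Pearson correlation distance (1 − Σxy/√(Σx²Σy²),
no centering) with average linkage — the Eisen/Cluster 3.0 convention,
adopted as a documented assumption since tools in this lineage rarely
record their settings — and exports CDT/GTR files in the Cluster 3.0
dialect (GID/ORF/NAME/GWEIGHT columns, EWEIGHT row, GTR heights written as
1 − distance). Rows that are entirely missing are excluded and reported;
missing values are pairwise-excluded from distances.

## Synthetic data: what it emulates and what it does not

`simulate_pool_growth` draws per-gene selection coefficients from a
three-part mixture — a point mass near zero (weight 0.45, sd 0.003), a
gamma-tailed deleterious component (weight 0.51, shape 1.3, scale 0.09,
clipped at s = −1), and a small beneficial component (weight 0.04, shape
2.0, scale 0.07) — chosen to reproduce the qualitative shape of an OE
screen under stress: a long deleterious tail, a spike at zero, a few
percent beneficial. Initial abundances are log-normal (sd 0.5); a
`jackpot_fraction` (0.002) of barcodes get a 50× initial-abundance boost,
implementing jackpots as abundance outliers since no mechanism is
established. Growth is deterministic exponential; sequencing is a
multinomial draw of fixed total depth per sample (default 1e7 reads, an
artifact choice — per-sample depth is not a published quantity), which
induces the compositional coupling the normalization must handle. Not
emulated: genetic drift, plasmid copy-number suppression dynamics (absorbed
into s), PCR amplification noise.

`simulate_coverage` draws per-base depth as Poisson(copy ×
mean_haploid_depth), optionally overdispersed by a gamma multiplier.
`simulate_expression` draws NB counts with log-normal baselines, per-gene
per-strain log2 fold changes at each timepoint, a log-normal replicate
effect (sd 0.1) shared across strains within a replicate to emulate paired
growth, and NB dispersion defaulting to 0.05 — a typical value for
biological triplicates in yeast bulk RNA-seq, and the default used wherever
a test needs "realistic" expression noise. Passing tests on these
generators demonstrates correctness of the estimators under the stated
models, not robustness to artifacts the generators omit (mapping bias, GC
effects, batch structure).

## Numerical choices and degenerate inputs

* IRLS linear predictors are clipped to ±30 to keep exp() finite; a 1e-10
  ridge keeps all-zero genes solvable (they are excluded from testing).
* Rounding is half away from zero (not banker's rounding).
* The LRT of identical designs is degenerate by construction: statistic 0,
  p = 1.
* BH propagates NaN p-values without ranking them.
* Depth tracks absent from a file are dense zeros; overlapping bedGraph
  intervals are an error, not a merge.
* All stochastic stages require explicit seeds; nothing seeds from the
  clock.

## Problem sizes

Tests and the acceptance script run on reduced problem sizes chosen so the
properties they probe are already stable: 1,000-gene pools at depth 1e7 for
score recovery, 2,000-gene null simulations for calibration, 400-gene
expression experiments for interaction recovery, 4-kb targets at 50×
haploid depth for copy calls. The analysis drivers under `analysis/` run
the same stages at study scale (4,133 genes).

## Known limitations

* The generation-effect test treats the scaled matrix's columns as NB
  counts; the scaling step makes their magnitudes comparable across
  samples, so offsets are near-constant by construction.
* Fitness scores and calls are relative to the pool: a uniformly beneficial
  dosage change is unobservable by design.
* The dispersion estimator has no abundance trend; strongly
  abundance-dependent overdispersion will be averaged over.
* The CNV caller reports median ratios, not integer genotypes, and does not
  resolve tandem paralogs or breakpoints; the heterogeneity flag is a
  screen, not a segmentation.
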