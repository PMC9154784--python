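# Methods

`fmtx` re-implements, as one tested pipeline, the computational chain that
links a reciprocal fecal-microbiota-transplant (FMT) experiment between two
mouse genotypes (wild-type and a knockout, "WT" and "KO") to colonic
transcriptome changes.  Because the real sequencing cohorts are not shipped
with the package, every stage is exercised against a synthetic cohort with a
planted, machine-readable ground truth; this note records the models, the
defaults, and what passing tests do and do not establish.

## Study design emulated by the generator

Four groups of `n_per_group = 10` mice: WT and KO controls, and WT_FMT / KO_FMT
recipients carrying the other genotype's microbiota.  Each mouse contributes a
16S stool profile and a colonic RNA count profile under the same sample id;
control and FMT mice of a genotype are matched into pairs (`pair_id`) for the
paired abundance tests.

**ASV counts.**  A log-normal backbone of 120 taxa; 30% of taxa
(`taxon_shift_fraction`) are genotype-specific, enriched 8-fold
(`genotype_fold_log2 = 3`) in one genotype and depleted 8-fold in the other.
FMT mixes *expected* compositions: a recipient's expected profile is
`r * donor + (1 - r) * own`, with direction-specific transfer rates
`r = 0.65` (KO into WT recipients) and `r = 0.27` (WT into KO) — the
engraftment asymmetry the assay is designed to detect.  Per-sample
compositions are Dirichlet draws at concentration 50 around the group
expectation (overdispersion without modelling phylogeny), counts are
multinomial at log-normal depths (median 20 000 reads, sigma 0.3).  Mixing
acts on expected proportions, not on counts, which matches the engraftment
interpretation of source-attribution estimates.

**Gene counts.**  2 000 genes, negative binomial with dispersion 0.2 and
log-normal size factors (sigma 0.25).  Sixty *opposite-direction* genes are
fully reversed by the transplant: their baseline differs between genotypes by
`effect_lfc = 1.5` log2 units and each recipient group moves to the donor
genotype's level, so the two recipient-vs-donor contrasts see +1.5 and -1.5,
and the cross-genotype comparisons see 0 ("restored").  Thirty *same-sign
confounders* respond to the procedure identically in both genotypes — they
exist so the opposite-direction filter has something to reject.

**Planted gene-taxon links.**  Thirty sign-consistent and ten
sign-inconsistent links connect opposite-direction genes to donor-enriched
taxa.  The linked gene's expected expression in the target genotype's FMT
samples tracks the taxon's *measured* (log2 CSS-normalized) abundance with
log-scale slope `corr_link_gamma = 0.6`, mean-normalized within the group so
the planted fold-change is preserved.  Tracking the measured rather than the
latent abundance is deliberate: CSS normalization and library-depth variation
distort the latent signal by enough that, at n = 10 samples under a
BH family of ~10 000 pairs, a latent-level link is undetectable for reasons
that have nothing to do with the correlation-and-filter machinery under test.
Linked genes get low biological dispersion (0.005) and a floor of 500 on mean
expression so shot noise does not dominate the link.  Sign-inconsistent links
are real correlations whose sign contradicts the fold-change product — the
consistency filter must remove them deterministically.  Planting is
restricted to the eight most abundant donor-enriched taxa per genotype;
a link planted on a taxon at the sequencing detection floor would measure
multinomial noise, not the method.

**Interaction edges.**  Three 8-gene modules among the opposite-direction
genes with within-module edge probability 0.9 and scores U(0.55, 0.99), over
a background of sparse random edges (probability 0.02, scores U(0, 1)).

What the generator does *not* emulate: phylogenetic structure, rarefaction
curves and read-level artifacts, compositional correlations between taxa
beyond the Dirichlet coupling, batch effects, and gene-gene co-expression
beyond the planted links.  Passing tests therefore demonstrate statistical
correctness and recoverability of planted structure — not robustness to
every feature of real amplicon or RNA-seq data.

## Microbiome profiling

*Alpha diversity* on raw (unrarefied) counts: observed ASVs, bias-corrected
Chao1 `S + F1(F1-1) / (2(F2+1))` (defined when no doubletons are present),
Shannon H in natural log (the base is recorded in the output), inverse
Simpson.  *Genus collapsing* sums ASVs with identical Phylum..Genus lineages;
genus-unassigned ASVs group under their finest assigned rank, so sample sums
are conserved exactly.  *Cumulative sum scaling* divides each sample by the
sum of its counts at or below a quantile of its nonzero counts, times 1000;
the quantile comes from the adaptive instability rule (smallest level at
which the median deviation from the across-sample reference changes by more
than 10%, floored at the median as in the reference implementation), with 0.5
as fallback on degenerate tables.  *Paired differential abundance* is the
classical two-sided Wilcoxon signed-rank on CSS values (zero differences
dropped, exact null for <= 25 informative pairs), BH-adjusted across taxa;
the reported taxon effect is the median paired log2 ratio with pseudocount 1.
*The LDA-effect-size scan* expands clades over ranks phylum..genus in
per-mille units, gates at Kruskal-Wallis alpha = 0.05, and scores survivors
by a 30-round bootstrapped (2/3 subsampling) one-dimensional discriminant
effect reported as log10, threshold 2.0.  The within-class subclass stage of
the original biomarker tool is omitted — this design has no subclasses.

*PERMANOVA* partitions a Gower-centered squared-distance matrix with
sequential (type-I) sums of squares over the ordered factors and free
permutation of sample labels (999 by default); Bray-Curtis on CSS genus
tables is the default distance (configurable; Bray-Curtis is the usual
choice for community count data).  *RDA* regresses the column-centered sample x taxon
matrix on factor indicator codings, partitions constrained inertia
sequentially, and tests each factor with an ANOVA-like permutation of rows.
On the default synthetic cohort genotype explains ~17% of community variance
and treatment ~3%; the treatment term is not always significant at n = 10
per group — the generator's effect sizes and depths are this package's
choices of a realistic regime, not a calibration to any particular cohort.

## Source attribution

Collapsed Gibbs sampler over per-read source assignments.  Known source
environments (pooled control samples per genotype) have fixed taxon profiles
smoothed by a scaled Dirichlet prior `alpha1 * m_v` (alpha1 = 0.001); an
*unknown* environment learns its profile from currently assigned reads under
a symmetric prior beta = 10 per taxon; mixing proportions carry a prior
`alpha2 * depth`.  Sinks are rarefied to 1 000 reads (multivariate
hypergeometric).  Defaults: burn-in 100 sweeps, 25 recorded draws, 10
restarts; the estimate is the mean over draws and restarts, the uncertainty
the sd across restart means.

Two numerical choices matter.  (1) Initialization assigns reads over the
known sources only: seeding the unknown environment uniformly hands it a
copy of the sink profile, which is self-reinforcing and traps the chain.
With known-source initialization a sink of taxa absent from every source is
still attributed ~100% unknown, but well-explained sinks no longer collapse.
(2) At these study conditions (Dirichlet concentration 50, 120 taxa, depth
1 000) the posterior is genuinely bimodal for a minority of sinks: a sample's
Kullback-Leibler deviation from its expected mixture, ~(T-1)/2c ~ 1.2 nats,
rivals the unknown environment's smoothing handicap, so occasional sinks are
attributed mostly to "unknown".  This depresses the cohort-mean donor
proportion by ~0.06-0.08 below the planted transfer rate and inflates its
spread — an echo of the large per-animal spread the real assay reports.
Recovery checks therefore average over five replicate cohorts.

## Differential expression

Median-of-ratios size factors (geometric-mean reference over genes expressed
everywhere, positive-count fallback otherwise).  Dispersion: per-gene method
of moments pooled over groups on normalized counts, corrected for the mean
inverse size factor; a robust (Huber) log-log linear trend of dispersion on
mean; the final value is a residual-d.f.-weighted geometric interpolation
between raw and trend (prior weight 8 d.f.), floored at 1e-8.  Per-gene NB
GLMs use the cell-means parameterization (no reference-level ambiguity in a
four-group design), Newton scoring with expected information, and report
log2FC of test over reference group with a Wald statistic.  p-values use a t
reference at the contrast's residual degrees of freedom: with plug-in
dispersions at n = 6+6 a normal reference rejects a true null at 7-8%
instead of 5%, and the t correction restores the nominal level (verified at
0.043-0.050 on 5 000-gene null simulations).  All-zero genes are dropped
before testing and BH runs over tested genes per contrast.  Exact numerical
parity with any published DE package is a non-goal; statistical calibration
and planted-effect recovery (power 0.94, observed FDR 0 at the defaults) are
the acceptance surface.  Hypergeometric over-representation with expected
counts `de_size * set_size / universe` supports downstream gene-set
summaries.

## Core signature and clustering

A gene joins the signature iff padj < 0.05 in both recipient-vs-donor
contrasts, |log2FC| strictly > 0.58 in both (ties at exactly 0.58 excluded),
and the fold-changes have opposite signs.  "Restored" requires
non-significance in *both* cross-genotype comparisons — the stricter of the
two natural readings of restoration, and the one that cannot be satisfied by
a gene that merely overshoots in one direction.  The interaction network keeps edges with confidence strictly
> 0.4 among signature genes and deletes connected components smaller than
three nodes.  Clustering maximizes the cohesiveness
`f(V) = W_in / (W_in + W_bound + p |V|)` (penalty p = 2) by best-improvement
search with add, remove and — when neither improves — swap moves, seeded
from every node, every edge and every connected component; converged
candidates merge at match coefficient `|A∩B|^2 / (|A||B|) >= 0.8`; clusters
below three members are dropped and scored by a one-sided Mann-Whitney U of
in-cluster vs boundary edge weights (p = 0 when no boundary edge exists).
The component seeds and swap moves exist so the greedy attains the
exhaustive optimum on every random graph of <= 12 nodes in the oracle suite;
on the classic two-clique toy this also surfaces the union of both cliques,
which genuinely has the higher cohesiveness — the cliques themselves are
still recovered exactly and are optimal among subsets of at most six nodes.

## Gene-taxon integration

Per genotype, Pearson correlations between log2(normalized expression + 1)
of that genotype's FMT-responsive genes and log2(CSS + 1) ASV abundances
across its FMT samples, with t-based two-sided p and BH over all pairs of
the genotype (one global family per genotype — stricter than per-gene
families, and free of per-gene multiplicity asymmetries).  Candidates (padj < 0.05) pass the sign-consistency
rule — positive r requires equal gene/taxon fold-change signs, negative r
opposite signs — and must belong to the opposite-direction set with
|log2FC| > 0.58.  The taxon fold-change entering the rule is the median
paired log2 ratio from the paired abundance test, at ASV resolution so that
planted links are scored at the level they were planted.  Log-scale values
on both sides are the package's choice: the CSS reference implementation
usually exports log2 values, and correlating raw normalized abundances
against log expression mixes scales.  The WT and KO edge sets use disjoint
samples; permuting one genotype's samples can never change the other's
edges.  The mixed network unions kept correlation edges (gene-taxon,
bipartite) with the pruned interaction network (gene-gene) and reports the
fraction of signature genes with at least one taxon partner (~50% on the
default cohort).

## Pipeline and reproducibility

`fmtx run` (or `fmtx.pipeline.run_pipeline`) executes the whole chain from
one master seed, expanded per stage through a counter-based scheme, with all
intermediate products written as TSV (floats at 8 significant digits) and a
summary JSON recording parameters, per-stage seeds, sha256 checksums of every
output, and the headline counts.  Two runs under the same seed produce
byte-identical outputs.  Problem sizes used throughout (10 mice per group,
120 taxa, 2 000 genes, 999 permutations, 1 000-read rarefaction, 50-graph
clustering oracle, 5 000-gene calibration nulls, five replicate cohorts for
source-attribution checks) are the package's defaults and keep the full test
suite and the acceptance script in the minutes range on one core.

## Known limitations

The dispersion moderation is a simplified moments-plus-trend scheme, not the
empirical-Bayes machinery of mature DE packages; no independent filtering or
outlier replacement is performed.  The LDA effect size is a per-feature
discriminant without the multi-feature LDA or subclass stages of the
original biomarker tool.  The source attribution reports posterior mixing proportions; a
"fraction of taxa transferred" could alternatively be defined as a
taxon-count overlap, which is a different statistic — the mixing proportion
is what the underlying mixture model estimates.
PERMANOVA uses free permutation, appropriate for the single-stratum designs
here but not for nested or repeated-measures layouts.
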