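# Methods

This note documents the models, defaults and numerical choices behind
`mtexpress`, and what the synthetic-cohort validation does and does not
demonstrate about real data.

## Consensus calling and variants

A sample's mtDNA sequence is reconstructed from its base-count pileup by a
majority rule: position *i* is called as the most frequent base iff
depth(i) ≥ `min_depth` and that base's fraction of the depth is at least
`min_major_fraction`; otherwise it is N. Exact ties for the top count are
N — no heteroplasmy model is in scope, so an ambiguous position carries no
defensible call. Defaults are `min_depth = 5` and
`min_major_fraction = 0.7`, chosen so that both error-free and 1%-error
pileups at typical mitochondrial RNA-seq depths (tens to hundreds of
reads per base) reconstruct the underlying haplotype exactly: at depth
100 and a 1% per-read error rate, the probability that errors reach the
30% minority needed to disturb a call is below 1e-20 per site (binomial
tail), i.e. negligible genome-wide.

Variants are substitutions of the consensus against the reference on the
linear 1-based rCRS frame of 16,569 positions; circularity is ignored
because pileups are positional. Indels are out of scope — the analysis
downstream is SNP-based. Universal RNA–DNA difference (RDD) positions are
masked from variant lists: an allele that every individual's RNA carries
regardless of DNA haplotype is a transcriptome artifact for genotyping
purposes. The RDD list is a required input with no default; the package
does not hard-code a catalogue of human RDD sites.

The cohort site matrix keeps positions where at least one non-major
allele has ≥ `min_carriers` carriers (default 10) and retains at most the
three most frequent alleles per site (rarer alleles recoded N), matching
the at-most-triallelic structure of population mtDNA data.

## Haplogroup assignment

A haplogroup definition is a rooted clade tree with per-branch defining
(position, allele) variants; the same variant may recur on independent
branches. A sample is scored per clade as (observed cumulative defining
variants) / (cumulative path length). Private variants carry no penalty —
singletons are expected in real cohorts. Selection rules: when one or
more clades are fully supported (score 1.0), the deepest such clade wins
(its ancestors are fully supported by construction); among partially
supported clades tied at the maximal score, the shallowest wins, which
avoids overcalling depth from incomplete matches; the root is the vacuous
assignment only when no defining variant matches at all. A sample whose
consensus is N at every defining position is flagged unassigned rather
than scored. This scorer is a deliberate simplification of
database-driven haplogroup callers, adequate for defined clade trees; it
is not a drop-in replacement for full phylogenetic nomenclature.

## Trees

Distances are uncorrected p-distances with pairwise deletion of N sites
(a pair with zero comparable sites is an error, not a zero). Neighbor
joining follows the standard Q-matrix agglomeration with the usual
branch-length formulas; ties in Q are broken toward the lexicographically
smallest label pair so merge order is deterministic; negative branch
lengths are clamped to zero with the residual moved to the sibling (the
standard fix). Branch lengths serialize to 6 decimals, so patristic
distances recomputed from newick differ from exact values by up to a few
1e-6. On additive matrices the generating topology and path distances are
recovered (verified to 1e-9 before serialization rounding). Bootstrap
support is out of scope.

## Normalization

Size factors are classic median-of-ratios: the reference is the per-gene
geometric mean (computed in log space) over genes with strictly positive
counts in every sample; a sample's factor is its median count/reference
ratio. Genes with any zero are excluded from the reference set. Long-RNA
and tRNA matrices are distinct libraries and must be normalized
separately. The gene-presence filter retains genes with reads in strictly
more than `min_presence_fraction` (default 0.9) of samples; presence
means count > 0 — a depth-based notion of "sufficient reads" is exposed
only through the caller pre-thresholding counts.

One scale caveat: rescaling a sample's column rescales the geometric
reference by a global constant, so individual factors are identified only
up to that constant; all downstream quantities depend on factor ratios,
which are invariant.

## Association model

Associations are ordinary least squares of normalized expression on an
allele predictor plus covariates, with two-sided p-values from the t
distribution on residual degrees of freedom. Haploid mtDNA sites
contribute one 0/1 indicator per tested minor allele (each minor with
≥ `min_carriers` carriers, tested one-vs-rest); this keeps a 1-df
interpretable effect per allele at multi-allelic sites, rather than a
joint ANOVA. Diploid SNPs enter as additive 0/1/2 dosages. Covariates are
sex, lab of origin (indicator-coded with a dropped reference level) and
mtDNA copy number entered untransformed (a log option is available);
indicator levels that become constant after per-test missing-data removal
are dropped automatically, and rank-deficient designs raise an error
naming the collinear columns. Population identity is deliberately *not* a
default covariate in the pooled scan — the pooled analysis is meant to
discover population-correlated structure, not condition on it.

Site filters require a minor allele with ≥ 10 carriers and a major-allele
frequency of at most 95% (missing calls excluded from denominators).
Multiple testing is Bonferroni within each scan family, and the family
size always equals the number of emitted tests for that family — no test
is counted that is not reported. Stratified scans re-run filters,
scan and family bookkeeping independently per stratum (default minimum
stratum size 30).

The background-masking contrast reports the pooled allele effect, each
background's own effect, and a heterogeneity statistic — Cochran's Q over
inverse-variance-weighted per-background effects, which for two
backgrounds reduces to the Wald test on the effect difference. Opposing
effects of similar magnitude across backgrounds produce the diagnostic
signature: each background significant, pooled near-null, heterogeneity
significant.

## Split-replication consistency

Each replicate deals samples round-robin within sex × ethnicity cells
into two groups (per-stratum group sizes differ by at most one), then
*recomputes from scratch inside each half*: size factors, site filters,
the scan, and the half's own Bonferroni threshold. An association
replicates when significant in both halves ("both" is the default; an
"either" mode exists and reports label it). Defaults are 500 replicates
and a strict >60% certification cutoff. Halves that cannot be normalized
or fit are skipped with the denominator adjusted. The degenerate level
`alpha ≥ 1` disables the significance filter (every emitted test counts),
which is useful for exercising the bookkeeping. Under a global null the
both-halves requirement makes certification essentially impossible
(empirically zero passes in the packaged simulations).

## Copy number

Copy number is mean DNA coverage over mtDNA positions 1–16,499 divided by
the mean of 22 autosomal window means. Windows are the inclusive-start
100,000-base stretches at position 20,100,000 of each autosome; because
they are equal length, the unweighted mean of window means equals the
pooled per-base mean. Group comparisons use the tie-corrected
Kruskal–Wallis H referred to chi-squared with (groups − 1) df, with a
label-permutation option preferable below ~20 observations per group. H,
df and n are always reported separately.

## Co-expression and enrichment

The Pearson screen tests all (mt gene × nuclear gene) pairs with p from
t = r√((n−2)/(1−r²)); the Bonferroni family is the full cross product.
Stage two refits the association model with the macro-group indicator and
covariates; its family size defaults to the number of stage-1 survivors —
the corrected thresholds this produces imply a survivor-sized family, not
a genome-wide one. Enrichment uses the hypergeometric upper tail
P(X ≥ observed) with expected = |set|·|term∩background|/|background|;
fold enrichment is observed/expected and is model-independent. The
annotation and the background set are explicit user inputs; no ontology
database is bundled, and the choice of background (all annotated vs all
expressed genes) materially affects expected counts, so it is never
defaulted.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with defaults matching a two-clade bulk RNA-seq cohort: 400 samples, 20%
in the African-like L clade (the approximate African fraction of public
LCL panels), three defining SNPs per clade on a star phylogeny over a
random 16,569-base reference, seven labs assigned independently of clade,
sex balanced, copy number uniform in [50, 500], log-normal library-size
factors (σ = 0.3), negative-binomial counts parameterized by mean and
dispersion α with variance μ + αμ² (α defaults to 0.1, a typical bulk
RNA-seq value; α = 0 gives the Poisson limit), pileup depth
Poisson-distributed with mean 100 and a 1% per-read error rate. Baseline
means are 10,000 (rRNA), 2,000 (mRNA), 500 (tRNA) and 100 (nuclear)
counts; per-gene depth profiles are uniform and configurable, as no
canonical empirical profile is assumed. RDD sites are planted at 100%
RNA-allele penetrance in every sample, the defining property of a
universal RDD. Planted effects multiply the count mean by exp(lfc ·
predictor); predictors may be clade/macro-group indicators, nuclear SNP
dosages, sex/lab levels, or standardized log copy number. Sex and lab are
independent of clade by default; `confound_lab_with_clade` pushes L
samples toward one lab to exercise covariate adjustment under
confounding. One global seed feeds fixed per-generator substreams, so
adding a simulation step never perturbs another's draws.

What the generator does *not* emulate: read-level artifacts (mapping
bias, duplicates, NUMT misassignment), batch correlation structure beyond
a single lab indicator, linkage between nuclear SNPs, heteroplasmy, and
gene-length or GC effects. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under its
assumed model, not robustness to every artifact of real sequencing data.

## Validation problem sizes

The acceptance run uses desk-scale analogues of the study conditions: the
association and replication checks use n = 400 with a −0.5 log-fold
change planted on 10 of the 15 mtDNA mRNA/rRNA genes, dispersion 0.1, and
a 500-gene nuclear null panel. The null panel is deliberately large
because median-of-ratios size factors are estimated from all genes: with
only a handful of null genes the ten planted genes would shift the
per-sample median and leak a spurious group effect into every normalized
null gene, whereas at a few hundred genes (and, in real data, tens of
thousands) the median is robust to ten shifted genes. Replication uses 50
re-divisions; null calibration uses 550 independent gene-level nulls at a
single biallelic site; the sequence round trip uses 60 samples at full
genome length with error-free depth-50 pileups; copy-number recovery uses
436 samples at 30× nuclear depth; the masking demonstration uses 100
cohorts of 240 samples with ±1.0 effects. All sizes are set in
`scripts/acceptance.py` and scale linearly if larger runs are wanted.

## Known limitations

- The haplogroup scorer assumes the provided clade tree is correct and
  complete; it does not rescue samples whose defining positions are
  uncalled beyond flagging them.
- OLS on normalized counts is the study-design model family; it is not a
  count-likelihood method, and very low-expression genes (tRNA-scale
  counts at shallow depth) inherit its normal-approximation behavior.
- The split-replication fraction is reported descriptively; no standard
  error or permutation p-value is attached to the fraction itself.
- Enrichment p-values assume genes are exchangeable within the
  background; co-expression-selected sets violate independence, so the
  tail probabilities are best treated as rankings.
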