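# mtexpress

Haplogroup-aware analysis of mitochondrial gene expression from bulk
RNA-seq cohorts.

Human mtDNA is transcribed as strand-wide polycistrons, so standard RNA-seq
covers essentially the entire 16,569-base mitochondrial genome. This makes
it possible to (i) reconstruct each donor's mtDNA sequence directly from
the transcriptome, (ii) assign each donor to a mitochondrial haplogroup —
a maternally inherited clade defined by a set of diagnostic variants, such
as the deep African macro-haplogroup L versus the out-of-Africa lineages —
and (iii) ask whether mtDNA variants behave as expression quantitative
trait loci (eQTLs) for the mitochondrial transcriptome itself, and which
nuclear factors travel with those expression differences.

`mtexpress` implements that full pipeline as a tested library plus CLI, and
ships a synthetic-cohort generator so every stage can be validated against
planted ground truth.

## What the package computes

- **Consensus calling** (`mtconsensus`): majority-rule consensus over
  per-position base-count pileups (call iff depth ≥ `min_depth` and the top
  base's fraction ≥ `min_major_fraction`, else N), variant extraction
  against the reference with universal RNA–DNA difference (RDD) sites
  masked, and a cohort site matrix keeping sites whose minor allele has at
  least `min_carriers` carriers (≤ 3 alleles per site).
- **Haplogroups and trees** (`phylo`): clade assignment scored as the
  fraction of cumulative root-to-clade defining variants observed;
  p-distances with pairwise deletion; neighbor joining
  (Q-matrix minimization, `Q(i,j) = (n−2)d(i,j) − r(i) − r(j)`) with
  deterministic tie-breaks; bipartition-based monophyly checks.
- **Normalization** (`expression`): median-of-ratios size factors
  `s_j = median_g ( k_gj / (∏_j k_gj)^{1/m} )` over genes positive in all
  samples, plus a strict "reads in more than 90% of samples" gene-presence
  filter.
- **eQTL scans** (`eqtl`): ordinary least squares of normalized expression
  on an allele predictor (haploid minor alleles one-vs-rest; diploid
  additive dosage) with sex, lab and mtDNA copy-number covariates;
  Bonferroni correction per scan family; per-population stratified scans;
  and a pooled-vs-per-background masking contrast with a Cochran/Wald
  heterogeneity test.
- **Split replication** (`replication`): the cohort is re-divided (default
  500×) into two halves with sex and ethnicity proportions preserved; size
  factors, site filters, scans and Bonferroni thresholds are recomputed
  inside each half; an association "replicates" when significant in both
  halves, and is certified when it replicates in more than 60% of
  divisions.
- **Copy number** (`copynumber`): mtDNA copy number as the ratio of mean
  DNA coverage over mtDNA positions 1–16,499 to the mean of 22 autosomal
  100-kb window coverages, compared across groups by Kruskal–Wallis.
- **Co-expression** (`coexpr`): all-pairs Pearson screen of nuclear genes
  against the 15 mtDNA mRNA/rRNA genes (p from the t transform with n−2
  df), a second-stage macro-group differential filter, L/non-L direction
  summaries, and hypergeometric term enrichment
  (fold = observed/expected).
- **Synthetic cohorts** (`synthdata`): clade-structured haplotypes,
  negative-binomial counts (variance μ + αμ²) with planted haplogroup /
  nuclear-SNP / covariate effects, pileups with sequencing error and RDD
  sites, Hardy–Weinberg nuclear genotypes, and copy-number-linked DNA
  coverage — all bit-reproducible from one seed.

## Worked example

```python
from mtexpress import synthdata, mtconsensus, phylo, expression, eqtl

config = synthdata.SimulationConfig(
    n_samples=100, depth_mean=60.0, error_rate=0.01,
    planted_effects=(("MT-ND2", "L", -0.5),), seed=4,
)
reference = synthdata.simulate_reference(config)
hapdef, haplotypes = synthdata.simulate_haplotypes(config, reference)
samples = synthdata.simulate_cohort(config, haplotypes)

# RNA-side reconstruction and haplogrouping
pileups = synthdata.simulate_pileups(samples, haplotypes, config, hapdef)
correct = 0
for sample_id, pileup in pileups.items():
    consensus = mtconsensus.call_consensus(pileup)
    variants = [(v.position, v.observed)
                for v in mtconsensus.call_variants(consensus, reference)]
    call = phylo.assign_haplogroup(variants, hapdef)
    correct += call.clade == samples.loc[sample_id, "clade"]
print(f"haplogroups recovered: {correct}/{len(pileups)}")

# association of the L-defining sites with expression
counts = synthdata.simulate_counts(samples, config)
normalized = expression.normalize(counts, expression.size_factors(counts))
genotypes = synthdata.true_site_matrix(samples, hapdef, haplotypes)
covariates = samples[["sex", "lab", "true_copy_number"]].rename(
    columns={"true_copy_number": "copy_number"})
results = eqtl.scan(normalized, genotypes, covariates)
top = results.iloc[0]
print(f"top hit: {top.gene} at site {top.site} "
      f"(effect {top.effect:.1f}, p = {top.p:.2e})")
```

Output:

```
haplogroups recovered: 100/100
top hit: MT-ND2 at site 566 (effect -755.9, p = 6.49e-07)
```

All 100 samples are assigned their planted clade, and the scan's top
association is the planted gene at an L-defining site: the effect of
−755.9 normalized counts per allele matches the planted 0.61-fold change
(e^−0.5, i.e. about −780 counts) on MT-ND2's baseline of 2,000 counts, and
its p-value clears the Bonferroni threshold for this scan family
(0.05 / 222 tests ≈ 2.3e-4).

The same stages are available from the shell:

```bash
mtexpress simulate --config cohort.yaml --out cohort/
mtexpress consensus --pileups cohort/pileups --reference cohort/reference.fasta --out calls/
mtexpress normalize --counts cohort/counts.tsv --out norm/
mtexpress eqtl --expression norm/normalized.tsv --genotypes calls/mtdna_sites.tsv --out scan.tsv
mtexpress replicate --counts cohort/counts.tsv --genotypes calls/mtdna_sites.tsv \
    --samples cohort/samples.tsv --n-reps 500 --cutoff 0.6 --out replication.tsv
```

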