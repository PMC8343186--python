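# quadhet

Family-based compound-heterozygous variant prioritization for quad
pedigrees (two parents, two affected children), with quartile-stratified
gene-set enrichment on expression counts and a fully synthetic fixture
generator so every stage is testable offline.

## What it does

- **core I/O** (`quadhet.io`): data model plus readers/writers for 6-column
  PED, multi-sample VCF (GT, with multiallelic decomposition), an
  annotation sidecar TSV (gene, consequence class, allele frequencies from
  multiple sources, four pathogenicity predictor calls), gene lists, GMT
  gene sets, and gene x sample count matrices.
- **segregation** (`quadhet.segregation`): parental-origin inheritance
  labelling from unphased dosages; an ordered branch filter cascade
  (shared-in-children + single-parent origin → MAF < 0.01 across all
  available frequency sources → exonic consequence whitelist → cancer-driver
  gene screen) with per-step survivor counts; the two-hit
  compound-heterozygous gene intersection (one allele from each parent at
  distinct sites, trans guaranteed by opposite single-parent origin);
  majority-vote predictor consensus; protein-domain truncation/localization
  mapping (default table: the six BRCA2 functional domains).
- **enrichment** (`quadhet.enrichment`): thresholded differential-expression
  selection (|fold change| > 2 and BH FDR < 0.05 on library-size-normalized
  counts with a rank-sum test — a deliberate, documented stand-in for a
  negative-binomial model fit), single- and joint-gene quartile sample
  grouping (floor(0.25·n) per tail), and hypergeometric over-representation
  with Benjamini–Hochberg adjustment.
- **synthetic data** (`quadhet.simulate`): deterministic fixture bundles —
  Hardy–Weinberg parents, Mendelian transmission with optional de novo
  flips, a planted causal gene carrying a rare maternal stop-gain and a
  common paternal missense allele, annotation records with enriched
  damaging calls on loss-of-function sites, and negative-binomial counts
  with a planted pathway-level group effect. Identical config + seed gives
  a byte-identical bundle.

## CLI

```sh
# write a synthetic bundle (PED, VCF, annotations, drivers, GMT, counts, truth)
quadhet simulate --seed 1 --out bundle/

# run both branch cascades and the compound-het intersection
quadhet segregate --vcf bundle/variants.vcf --ped bundle/family.ped \
    --annotations bundle/annotations.tsv --drivers bundle/drivers.txt \
    --maf-threshold 0.01 --mode paper --out results/

# DE selection + gene-set over-representation (explicit groups or quartiles)
quadhet enrich --counts bundle/counts.tsv --gmt bundle/gene_sets.gmt \
    --groups bundle/sample_groups.tsv --out results/
quadhet enrich --counts bundle/counts.tsv --gmt bundle/gene_sets.gmt \
    --quartile-gene BRCA2 --out results/

# end-to-end report over a bundle
quadhet report --bundle bundle/ --out results/
```

Exit codes: 0 success, 2 config error, 3 input-format error, 4 stage
failure. Logs go to stderr; results go to files only, so repeated runs are
byte-identical.

## Conventions and caveats

- VCF 1-based coordinates are kept end to end; multiallelic records are
  decomposed but indels are assumed pre-normalized (no left-alignment).
- The annotation join key is `chrom:pos:ref:alt` with uppercased alleles.
- A site with a missing dosage in any member required by a filter fails
  that filter (conservative default; `missing_policy="permissive"` flips
  this).
- Variants whose configured allele-frequency sources are all missing pass
  the rare-MAF filter (novel variants are by definition rare); this is
  logged.
- Bundles can flag samples whose genotypes derive from tumor-tissue DNA
  used as a germline proxy; the report repeats this caveat.
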