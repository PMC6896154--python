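# methint

Coupled DNA-methylation / gene-expression two-group analysis, built as a
tested, reusable pipeline:

1. **core_io** — beta-value computation from probe intensities
   (`M / (M + U + 100)`), logit2 beta/M conversion, TSV readers/writers for
   beta matrices, Illumina-manifest-style CpG annotations, log2 expression
   matrices, sample sheets and drug-target tables, with sample-intersection
   alignment.
2. **region_methylation** — geometric-mean aggregation of CpG betas to
   (gene, region) level for TSS1500 / TSS200 / gene body (other manifest
   regions selectable), and case-minus-control delta-beta.
3. **differential** — empirical-Bayes moderated two-sample t on M-values /
   log2 expression (prior estimated by digamma/trigamma moments matching),
   Benjamini-Hochberg adjustment, and strict-threshold calling of
   differentially methylated sites/regions/genes (adj p < 0.05,
   |delta-beta| > 0.2) and expressed genes (adj p < 0.05, |log2FC| > 2).
4. **integration** — intersection of methylation and expression calls into
   DMEG records classified into HypoUp / HypoDown / HyperUp / HyperDown
   quadrants, per-region pattern proportions, and the promoter DMS set
   inside DMEGs.
5. **evaluation** — leave-one-out cross-validated random-forest (or
   nearest-centroid) scoring, threshold-sweep ROC with trapezoid AUC
   (equal to the midrank Mann-Whitney pairwise formula), AUC significance
   via the normal approximation (exact permutation for small n), PCA
   projection, and covariate-stratified AUCs (age dichotomized at 50,
   stages III/IV merged).
6. **drugmap** — join of upregulated DMEG genes against a local
   drug-target TSV snapshot, with summary counts and per-gene exports.
7. **synthetic_data** — seeded generator of paired cohorts with planted,
   region-clustered methylation and expression effects plus a realized
   -effect truth table, so every stage is testable offline.

## Command line

```sh
# one-command end-to-end demo on a simulated cohort
methint run-all --demo --out demo_out --seed 1

# or stage by stage
methint simulate --out sim/ --seed 1
methint diff-meth --methylation sim/methylation_beta.tsv \
    --annotation sim/cpg_annotation.tsv --samples sim/samples.tsv \
    --level region --out dmr.tsv
methint diff-expr --expression sim/expression_log2.tsv \
    --samples sim/samples.tsv --out deg.tsv
methint integrate --region-table dmr.tsv --expr-table deg.tsv --out dmegs.tsv
methint drugmap --dmegs dmegs.tsv --out hits.tsv

# full pipeline from a YAML config
methint run-all --config pipeline.yaml
```

Example `pipeline.yaml`:

```yaml
inputs:
  methylation: sim/methylation_beta.tsv
  annotation: sim/cpg_annotation.tsv
  expression: sim/expression_log2.tsv
  samples: sim/samples.tsv
  # drug_targets: my_snapshot.tsv   # defaults to the shipped demo table
regions: [TSS1500, TSS200, Body]
thresholds: {meth_adj_p: 0.05, delta_beta: 0.2, expr_adj_p: 0.05, log2fc: 2}
classifier: {kind: random_forest, n_trees: 500}
stratify: [age, menopause]
seed: 1
output_dir: out/
```

`run-all` writes per-stage TSV/BED/JSON artifacts plus `manifest.json` with
thresholds, per-stage counts and output checksums; re-running with the same
inputs and seed reproduces identical checksums. Exit codes: 0 ok, 1 user
error, 2 internal error.

## File formats

- **Matrices**: TSV (CSV honoured by extension); first column = feature id,
  header row = sample ids.
- **CpG annotation**: TSV with `probe_id`, `chrom`, `pos`, `gene_symbols`
  (";"-joined), `region_labels` (";"-joined, positionally paired); empty
  gene field = intergenic; labels in
  {TSS1500, TSS200, 5UTR, 1stExon, Body, 3UTR} ("5'UTR"/"3'UTR" accepted).
- **Sample sheet**: TSV with `sample_id`, `group` (case/control) and
  optional covariates (age, menopause, race, stage).
- **Drug table**: TSV with `drug_id`, `drug_name`, `approval_status`
  (approved/experimental/other), `target_gene`.
- **Outputs**: differential tables and DMEG records as TSV; called sites
  additionally as 4-column BED (0-based half-open).
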