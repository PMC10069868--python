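# atacrna

Integration of paired two-condition ATAC-seq and RNA-seq data: from
called peaks and fragment files to differentially accessible regions,
distance-weighted cis-regulatory scores, per-gene regulatory-behavior
classes, and shuffled-background transcription-factor motif enrichment.

The package is aimed at regulatory genomicists comparing two cell
states or lineages (e.g. two chondrocyte lineages derived under
TGFB vs BMP signaling) with a small paired design (3 vs 3), who want
to ask not just *which* genes and regions change, but *how* each
gene's expression relates to the accessibility of its promoter and its
distal elements, and *which* transcription factors plausibly drive the
lineage-biased regions.

## The method

**Window refinement.** Each called peak is padded to 1000 bp around
its center and tiled with 250 bp windows every 50 bp (16 windows);
each promoter span (TSS ± 5 kb) is tiled with 2 kb windows every 50 bp
(161 windows). Per-sample window coverage (summed per-base fragment
depth) is smoothed — windows more than one standard deviation from the
region mean take the average of their neighbors' original values — and
the window with the greatest cross-sample 75th-percentile smoothed
coverage represents the region. Differential testing uses the selected
window's *raw* coverage; smoothing only steers the choice away from
transiently extreme windows.

**Differential testing.** A self-contained negative-binomial Wald test
(median-of-ratios size factors s_j, per-feature moment dispersion
α with Var = μ + αμ², per-condition mean MLE, Wald statistic
log FC / SE, Benjamini–Hochberg adjustment per table) applied
uniformly to RNA counts, peak windows and promoter windows;
significance at adjusted p < 0.05.

**Cis-regulatory score.** For gene *g* with TSS *t*, every optimized
peak window within 100 kb of *t* (excluding windows inside optimized
promoter regions) contributes its accessibility log2 fold change
weighted by distance *d*:

    score(g) = Σ_r log2FC_r · exp(−(0.5 + 4·d_r/100000))

a single signed, lineage-oriented scalar per gene.

**Regulatory behaviors.** Per gene, expression (variance-stabilized)
is regressed on promoter accessibility P and the distance-weighted
distal sum E with three OLS models — full (P + E + P:E), P only,
E only — and four variance metrics are formed: m_enh = R²_full −
R²_P, m_prom = R²_full − R²_E, m_combo = max(0, R²_full − R²_P −
R²_E), m_unexpl = 1 − R²_full. Ward clustering with k = 4 partitions
genes into enhancer-centric, promoter-centric, combo-centric and
unexplained behaviors, followed by direction-sharing chi-square tests
and cluster effect-size comparisons (ANOVA + Tukey HSD).

**Motif enrichment.** PWMs are scored as log-odds against a Markov
background estimated from the pooled peak set; the hit threshold is
the exact-p score at p = α/(2·250) = 2e-4 (α = 0.1), computed by
dynamic programming over the full null score distribution. Observed
hit counts in a target region set are standardized against n ≥ 30
shuffled sets (genome placement avoiding the true regions, or
resampling from the peak/promoter universe); significance from the
standard-normal CDF of z with BH correction per TF family.
Lineage-specificity requires enrichment in the matched-direction set
and none in the opposite one. Hypergeometric tests quantify overlap
with external ChIP-seq peaks.

**Synthetic data.** `atacrna.synthetic` generates a complete toy
study — genome, TSS models, peaks with planted roles and condition
biases, NB fragment counts, expression driven by promoter and/or
distal accessibility, planted motif instances — with exhaustive truth
tables, so every stage is validated by ground-truth recovery.

## Worked example

```bash
atacrna simulate --outdir sim --seed 3 --n-genes 40 --n-chroms 8 \
    --n-peaks 200 --fragments-per-sample 60000
# write a run config pointing at sim/ (see RunConfig), then:
atacrna validate --config run.yaml
atacrna run --config run.yaml
```

or in Python, on the default synthetic study (400 genes, 3 vs 3):

```python
from atacrna import pipeline, synthetic as syn

cfg = syn.SyntheticConfig(seed=1)
ds = syn.generate_dataset(cfg)
res = pipeline.run_pipeline(
    peaks=ds.peaks, tss=ds.tss_table, rna_counts=ds.rna_counts,
    fragments=ds.fragments, condition_labels=cfg.sample_conditions,
    chrom_sizes=ds.chrom_sizes)

truth = ds.genes.set_index("gene_id")["behavior_class"]
prof = res["profiles"]
print((truth.loc[prof.index] == prof["behavior_label"]).mean())
# 0.7725  -> fraction of genes assigned their generating behavior
print(res["differential"]["peaks"]["significant"].sum())
# 333     -> differentially accessible peak windows at BH p < 0.05
```

On this run, 95.4% of the 328 condition-biased peaks are recovered as
DARs with an observed false-discovery proportion of 0.060, and the
cis-regulatory score points toward the planted condition for 99% of
the biased enhancer-driven genes.

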