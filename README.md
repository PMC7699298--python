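# mirtrend

Quantitative workflow for studying how a microRNA regulates the
cancer-stem-cell (CSC) phenotype, built around the analysis of miR-486-5p in
colorectal cancer. The package covers four linked analyses:

1. **Pooled small-RNA-seq comparison** (`mirtrend.pool`) — TMM normalisation
   of miRNA × sample count tables, per-miRNA log2 fold changes, Student
   t / one-way ANOVA tests with Benjamini–Hochberg FDR, and the
   median-reads abundance filter used for sparse stool sequencing data.
2. **Relative qPCR quantification** (`mirtrend.qpcr`) — the 2^−ΔΔCt method
   with single- or multi-reference normalisation
   (ΔCt = Ct_target − mean Ct_references; ΔΔCt against a calibrator
   condition; FC = 2^−ΔΔCt), statistics on per-sample ΔCt.
3. **Random-effects meta-analysis** (`mirtrend.meta`) — Hedges' g
   standardized mean differences pooled with the DerSimonian–Laird
   estimator (τ² by moments, 95% CI from the normal quantile).
4. **The core trend screen** (`mirtrend.screen` + `mirtrend.jt`) — a
   genome-wide classification of genes as *promoted* or *inhibited* by the
   miRNA from an ordered treatment design (inhibitor < control < mimic,
   i.e. increasing miRNA activity) measured in two cell contexts
   (monolayer and CSC-enriched cultures). Each gene's monotone trend is
   tested with the Jonckheere–Terpstra statistic

   JT = Σ_{a<b} [ #{x∈a, y∈b : x<y} + ½·#{x=y} ]

   one-sided in the fitted direction, with empirical permutation p-values
   (add-one convention, exhaustive enumeration for small designs), per
   context and combined across the monolayer→CSC transition over six
   ordered groups. Genes whose direction agrees in both contexts and whose
   per-context trends are significant are *consistent with the working
   hypothesis*; hits are then tested for concentration in curated pathway
   gene sets with the weighted Kolmogorov–Smirnov (GSEA-style) enrichment
   score (`mirtrend.enrich`).

A seeded synthetic-data module (`mirtrend.simulate`) generates every input
type with planted ground truth, so the whole pipeline is testable without
any external download.

## Worked example

The built-in serum worked example is a published copy-number table from
pooled serum sequencing of a three-group colorectal-cancer cohort
(healthy / tumor / metastatic, two pooled replicates each):

```python
import numpy as np
import mirtrend as mt
from mirtrend.datasets import serum_pool_example

table = serum_pool_example()
mid = "hsa-miR-486-5p"
for a, b in [("tumor", "metastatic"), ("healthy", "metastatic"), ("healthy", "tumor")]:
    fc = mt.log2_group_fc(table, mid, a, b, use_normalized=False)
    print(f"log2 FC {b} vs {a}: {fc:.2f}")
print("ANOVA p:", round(float(mt.per_mirna_anova(table, use_normalized=False)[mid]), 4))
```

prints

```
log2 FC metastatic vs tumor: -0.22
log2 FC metastatic vs healthy: -0.86
log2 FC tumor vs healthy: -0.64
ANOVA p: 0.0083
```

— the progressive serum down-regulation of the miRNA with disease stage
(negative log2 fold changes versus the healthy pools) and its three-group
ANOVA significance. A full screen on simulated data:

```python
cfg = mt.TrendSimConfig(
    n_genes=500, noise_sd=0.5,
    planted_promoted=tuple((i, 1.0, True) for i in range(25)),
    planted_inhibited=tuple((25 + i, 1.0, True) for i in range(25)),
    seed=13,
)
study, truth = mt.simulate_expression(cfg)
res = mt.TrendScreen(study, alpha=0.05, n_perm=1000, correction="none").fit(seed=0)
print(res.summary())
```

```
Trend screen (Jonckheere-Terpstra, permutation p-values)
  genes: 500  tested: 500  degenerate: 0
  alpha: 0.05  n_perm: 1000  correction: none  seed: 0
  consistent with the working hypothesis: 50
```

— 48 of the 50 planted genes are recovered plus 2 false calls among the
450 nulls (the per-gene table in `res.table` carries directions, JT
statistics and the per-context/combined p-values; comparing it against
`truth` gives the recovery split).

The same stages are available from the shell:

```sh
mirtrend simulate --kind expression --seed 4 --out fixtures/
mirtrend screen --expression fixtures/expression.tsv --design fixtures/expr_design.tsv \
    --n-perm 10000 --seed 1 --out screen_out/
mirtrend enrich --ranking screen_out/ranking.tsv --gmt pathways.gmt --out enrichment.tsv
mirtrend run --config pipeline.yaml        # all configured stages + provenance
```

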