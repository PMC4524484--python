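# scdc — sex-biased genes, the X chromosome, and dosage compensation

`scdc` is an analysis toolkit for a classic question in *Drosophila*
genomics: **how are male- and female-biased genes distributed between the X
chromosome and the autosomes, and what does the dosage compensation
machinery have to do with it?**

In *D. melanogaster*, males hypertranscribe their single X roughly 2-fold
via the MSL/dosage-compensation complex (DCC). Two opposing forces then
shape where sex-biased genes live:

- **Overcompensation** — genes close to DCC binding sites can overshoot the
  2-fold target, acquiring *weak* male-biased expression without any
  sex-specific regulation. This predicts an *excess* of weakly male-biased
  genes on the X, close to DCC sites (the pattern seen in brain and head).
- **Interference / germline suppression** — genes that need strong
  male-specific upregulation are hindered near DCC sites and depleted from
  the X altogether. This predicts a *paucity* of strongly male-biased genes
  on the X, far from DCC sites (the pattern seen in gonads and whole flies).

The package implements the complete analysis chain that distinguishes these
signatures, plus a ground-truthed simulator that generates data under each
mechanism so every stage is testable without any external downloads.

## What it computes

| stage | statistic |
|---|---|
| bias classification | MBG / FBG / UBG calls under an FDR (Benjamini–Hochberg, α = 0.05) or nominal-p dialect; log₂(male/female) ratios; fold-change magnitude bins (≤2, 2–4, 4–6, >6 fold) |
| X:A enrichment | per-class autosome/X counts, X-linked percentages, expected X counts `E = n_class · n_X / n_total`, observed/expected ratios, Fisher exact tests |
| DCC proximity | minimum distance from each X-linked gene's transcriptional unit to the nearest MLE/MSL/MOF/HAS binding site (0 on overlap); Spearman ρ of log₂ ratio vs distance; Wilcoxon MBG-vs-UBG distance tests; magnitude-bin distance profiles |
| tissue specificity | τ = Σᵢ(1 − xᵢ/x_max)/(N−1) from a multi-tissue atlas, with probe collapsing, composite-tissue exclusion and condition averaging; housekeeping (τ < 0.4) and specific (τ > 0.7) flags |
| dosage & bookkeeping | RPKM, X:A median male-expression ratios under housekeeping filters, DCC-component expression (mean ± SEM), mean gene age (classes 0–6), hypergeometric set overlaps, remove-and-recompute sensitivity analyses |
| simulation | negative-binomial replicate counts with configurable sex effects, a distance-decaying overcompensation factor `1 + a·e^(−d/λ)` on the X, magnitude-scaled depletion of sex-regulated genes near sites, and a tissue atlas with a specificity dial — all with exposed ground truth |

## Worked example

Simulate a brain-like data set (overcompensation only, no sex-regulated
genes) and run the full analysis:

```python
from scdc import brain_like, simulate_dataset, TissueStudy, ThresholdConfig

ds = simulate_dataset(brain_like(seed=0))
study = TissueStudy.from_counts(ds.counts, ds.metadata, ds.classes,
                                genes=ds.genes, site_sets=[ds.sites],
                                name="brain-like simulation")
res = study.fit(ThresholdConfig(pseudocount=1))
print(res.summary())
```

```
Sex-bias analysis: brain-like simulation
  significance: FDR, alpha=0.05
  expressed genes: 2000 (320 X-linked, 16.0%)

  class  n_autosome  n_X  pct_X  O/E      Fisher p
  MBG            3   51    94    5.90  1.16e-38 ***
  FBG            0    0     0       -  1
  UBG         1677  269    14       -  -

  MLE proximity (n=320 expressed X genes): rho=-0.784 (p=9.19e-68***)
    median distance bp — MBG: 1067, FBG: nan, UBG: 12028; MBG vs UBG Wilcoxon p=1.95e-23
```

Reading this: 54 genes were called male-biased at 5% FDR, 51 of them
X-linked (94%, against a 16% X baseline — observed/expected 5.9,
Fisher p ≪ 0.001), the correlation between log₂(male/female) and distance
to the nearest DCC site is strongly negative, and the median MBG sits 1.1 kb
from a site versus 12 kb for unbiased genes. That is precisely the
overcompensation signature; the `gonad_like` regime produces the mirror
image (X paucity of MBG, positive ρ, strong bias far from sites).

The same objects work on real data: feed `TissueStudy` a per-gene DE table
(gene_id, expr_male, expr_female, p_raw) from any upstream tool, a GFF3
annotation via `read_gff`, and per-component BED site files via `read_bed`.

A CLI covers the same flow: `scdc simulate`, `scdc run --config
dataset.yaml`, `scdc compare runA runB`, `scdc classify`.

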