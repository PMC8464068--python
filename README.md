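# etg3d

Genome-wide pairing of enhancers with their target-gene promoters, for
regulatory genomicists who have peak calls, signal tracks and TAD calls and
want a ranked, FDR-controlled list of enhancer–target gene (ETG) pairs.

The method combines three signals:

1. **Hierarchical Contact (HC) score** — for enhancer *i* and promoter *j*,

       S_ij = Σ_{D} Σ_{w∈W} λ(w) · 1[i, j share a TAD in ensemble (D, w)],
       λ(w) = √(max(W)/w),

   summing TAD co-occurrence over Hi-C datasets *D* and hierarchy levels
   *w* (directionality-index windows, default W = [5, 10, 20, 50]). Finer
   levels weigh more; with 11 datasets, S ranges from 0 to ≈87.8 (≈7.98
   per dataset). Pairs with S ≤ 11 are discarded as poorly supported.

2. **Activity synchronization (CCA)** — per pair, the canonical
   correlations between enhancer features X (DNase, H3K27ac; k×2) and
   promoter features Y (DNase, H3K27ac, H3K4me3; k×3) across k cell types
   are tested for joint nullity via Wilks' Λ = Π(1−r_l²) with Rao's
   F-approximation, yielding one p-value per pair.

3. **Adaptive FDR control** — Bonferroni and Benjamini–Hochberg are
   provided, plus an adaptive p-value thresholding procedure that uses the
   HC score as side information: a masked two-groups model (logistic-Gamma
   GLMs on a natural cubic spline basis) learns where small p-values
   concentrate, and a mirror estimator of the false discovery proportion
   is driven below α by iterative peeling. FDR is controlled in finite
   samples; with informative side scores power is substantially higher
   than BH.

A synthetic-data module generates complete toy studies (nested TAD
hierarchies, planted correlated pairs, eQTL/capture-Hi-C-like truth sets),
and a benchmarking module computes precision/recall/F1/relative
improvement and PR curves against eQTL, capture Hi-C, CRISPR-screen and
curated references. See `docs/methods.md` for the full model description.

## Worked example

Simulate a toy study and run the full pipeline:

```sh
$ etg3d simulate --seed 3 --out fixture/
wrote 18 files to fixture/

$ etg3d run --fixture fixture/ --alpha 0.05 --out results/
497 enhancers, 60 promoters, 1065 candidates, 52 pairs rejected at alpha=0.05
```

Reading: from 497 catalogue enhancers and 60 promoters, 1,065 pairs
co-occur strongly enough in the TAD hierarchy (HC score > 11) to be
tested; at a target FDR of 5%, 52 pairs show significant activity
synchronization. The fixture planted 50 true pairs, 49 of which survive
the HC filter — and all 49 are among the 52 rejections, so on this run the
realized false-discovery proportion is 3/52 ≈ 0.06 at 100% recall of the
testable truth:

```sh
$ etg3d benchmark --predictions results/pairs.tsv \
      --truth fixture/true_pairs.tsv --out metrics.tsv
    Z   V   z   v  precision    recall       f1        ri
 1065  49  52  49   0.942308  1.000000  0.970297  20.480769
```

`results/pairs.tsv` lists every tested pair with its canonical
correlations, Wilks Λ, F statistic, p-value, HC score and rejection flag.
Library use mirrors the CLI: `etg3d.build_catalogue`,
`etg3d.compute_hc_table`, `etg3d.test_pairs`, `etg3d.adapt_per_chromosome`,
`etg3d.metrics`.

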