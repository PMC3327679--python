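# triomics

Three-layer microarray integration: differential expression of mRNA,
miRNA and protein array data between two conditions, anti-correlation
pairing of miRNAs with their predicted targets, and classification of
(miRNA, mRNA, protein) triplets into coherent/incoherent regulatory
loops.

## Who this is for

Groups comparing a drug-sensitive and a drug-resistant cell line (or
any two-condition design) across three platforms at once: two-color
gene-expression arrays, single-channel miRNA arrays, and a two-color
antibody (protein) panel, each with biological and dye-swapped
technical replicates. The package reproduces the whole analysis chain
on plain tab-separated tables and ships a synthetic-data generator
with planted ground truth, so every stage is testable without any
array downloads.

## The statistics at the core

**Moderated t.** Per feature, the two-sample statistics are the log2
fold change `logFC = mean(resistant) − mean(sensitive)` and the pooled
residual variance `s²` on `df = n₁ + n₂ − 2` degrees of freedom. An
empirical-Bayes prior `s² | σ² ~ σ² χ²_df / df`, `1/σ² ~ χ²_{d₀} /
(d₀ s₀²)` shrinks each variance to the posterior

    s̃² = (d₀ s₀² + df · s²) / (d₀ + df),
    t  = logFC / √(s̃² (1/n₁ + 1/n₂)),   t ~ t_{d₀ + df} under H₀,

with `(d₀, s₀²)` estimated by matching the empirical mean and variance
of `log s²` to their theoretical digamma/trigamma moments. P-values are
Benjamini–Hochberg adjusted; selection thresholds are layer-specific
(mRNA: FDR ≤ 0.01 and |logFC| ≥ 1; miRNA and protein: FDR ≤ 0.1).

**Loop taxonomy.** For a DE miRNA and a predicted target gene that is DE
at both the mRNA and the protein layer, the triplet of fold-change
signs (s_miRNA, s_mRNA, s_protein) is classified as

| type | pattern | coherence | reading |
|------|---------|-----------|---------|
| A | s_mRNA = −s_miRNA, s_protein = s_mRNA | coherent | target degradation propagates to protein |
| B | s_mRNA = s_miRNA, s_protein = −s_miRNA | incoherent | translational repression without mRNA decay |
| C | s_mRNA = s_miRNA, s_protein = s_miRNA | incoherent | expression does not support miRNA action |
| unclassified | s_mRNA = −s_miRNA, s_protein = s_miRNA | — | no mechanism in the taxonomy |

Negating all three signs never changes the type, so the classification
does not depend on which condition is called "up".

Around these sit the platform-specific preprocessing steps (normexp
background correction, lowess MA-normalization, rank-invariant
normalization for the antibody panel, an arsinh variance-stabilizing
transform for single-channel intensities, the 60% below-background
filter), hypergeometric gene-set enrichment, genomic miRNA clustering,
and SIF network export. See `docs/methods.md` for the details.

## Worked example

```python
from triomics import SimConfig, generate, PipelineConfig
from triomics.pipeline import run_bundle, recovery_report
from triomics.diffexpr import ModeratedTTest
from triomics.preprocess import collapse_replicates, vsn_like_normalize

# a synthetic study at the default conditions: 10k genes, 800 miRNAs,
# a 725-antibody panel, 3 biological x 4 technical replicates,
# 38/34/28 planted loops of types A/B/C at |logFC| = 1.5
bundle = generate(SimConfig(seed=1))

# one layer by hand, model-style
norm = vsn_like_normalize(bundle.mirna_fg)
res = ModeratedTTest(collapse_replicates(norm)).fit()
print(res.summary())

# the full pipeline
manifest = run_bundle(bundle, PipelineConfig("unused", "out", seed=1))
print("loop counts:", manifest["loop_counts"])
print("recovery:", recovery_report(bundle, "out/loops.tsv")["recovery_rate"])
```

prints

```
Moderated t-test summary — layer: miRNA
  features tested : 800 of 800
  prior           : d0 = 27.789, s0^2 = 0.033717
  thresholds      : FDR <= 0.1, |logFC| >= 0.0
  up / down / ns  : 25 / 25 / 750

loop counts: {'A': 38, 'B': 34, 'C': 28, 'unclassified': 0}
recovery: 1.0
```

All 47 planted DE miRNAs are recovered (25 up, 25 down includes three
false positives at FDR 0.1), and all 100 planted loops are recovered
with the correct type and no spurious triplets.

The same run is available from the shell:

```bash
triomics demo --seed 1 --out demo_dir     # simulate + analyse
triomics classify-loop 1 -- -1 -1          # -> A  coherent
```

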