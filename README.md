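# tscpath

Pathway-level transcriptional-similarity analysis of drug response in
clinical expression cohorts.

## The problem

In neoadjuvant trials of HER2+ breast cancer therapies (lapatinib,
trastuzumab, and their combination), tumors are profiled by bulk RNA-seq and
labeled responder / non-responder by pathological complete response (pCR).
Tumor expression profiles in such cohorts are extremely similar to one
another — the bulk of variation is shared — so single-gene biomarkers are
weak, and what distinguishes responders tends to live in the *co-expression
structure* of biological pathways rather than in individual gene levels.
`tscpath` targets exactly that: it scores each pathway's gene–gene
co-expression pattern, compares each patient against responders versus
non-responders, and turns the comparison into a classifier and a biomarker
ranking.

## The statistic

Let `P` be the genes × samples expression matrix of one pathway in one set
of samples ("population"). Its **off-diagonal Gram matrix** is

```
P0 = P Pᵀ − Diag(P Pᵀ)
```

— all pairwise gene–gene inner products with the self-products deleted,
which removes the dependence on how many samples each population contains.
The **transcriptional similarity coefficient (TSC)** of two populations
`P1`, `P2` on the same ordered gene list is the cosine of their
off-diagonal Grams:

```
TSC(P1, P2) = Σᵢ (P10 · P20)ᵢᵢ / sqrt(Σᵢⱼ (P10)ᵢⱼ² · Σᵢⱼ (P20)ᵢⱼ²)
```

It lies in [−1, 1], equals 1 for self-comparison, and is exactly invariant
to sample duplication and nonzero rescaling. On top of it the package
builds:

* **delta-TSC**: per sample and pathway, TSC against responders minus TSC
  against non-responders (leave-one-out), the pathway biomarker feature;
* a **responder classifier**: per held-out sample, 100 draws of 5
  responders and 5 non-responders; per draw, the medians over pathways of
  the two TSC vectors are compared and the majority vote decides;
* **biomarker evaluation** by concordance index (C-index; AUC for binary
  outcomes) with label-permutation significance and Benjamini–Hochberg
  adjustment, for pathways (delta-TSC) and single genes;
* **unsupervised clustering** (Spearman similarity, Ward linkage) with an
  adjusted-Rand readout against response;
* a **synthetic cohort generator** that emulates the trial structure —
  three arms at the printed pCR rates (24.7% / 29.5% / 51.3%), ER strata,
  >90% of sample pairs with Pearson r > 0.9 — and plants response-linked
  signal in pathway gene–gene covariance, so every stage is testable with
  known ground truth.

## Worked example

```python
import numpy as np
from tscpath import (CohortConfig, generate_cohort, delta_tsc_profile,
                     pathway_biomarkers, loocv_predict, emulation_report)

# default-condition cohort: calibration checklist
expr, labels, sets, truth = generate_cohort(CohortConfig(n_per_arm=34, seed=7))
rep = emulation_report(expr, labels, sets)
print("fraction of sample pairs with r > 0.9:", round(rep["fraction_pairs_r_gt_0.9"], 3))
print("responder fraction by arm:",
      {k: round(v, 3) for k, v in rep["responder_fraction_by_arm"].items()})

# high-signal cohort: biomarker discovery + classification
cfg = CohortConfig(n_per_arm=60, pcr_rate_by_arm={"combination": 0.5},
                   n_genes=800, n_pathways=20, n_signal_pathways=10,
                   effect_size=3.0, seed=7)
expr, labels, sets, truth = generate_cohort(cfg)
profile = delta_tsc_profile(expr, labels, sets)
for r in pathway_biomarkers(profile, labels, n_perm=200, seed=1)[:3]:
    print(f"{r.feature_name}  C-index={r.cindex:.3f}  perm_frac={r.perm_significance:.3f}")
preds = loocv_predict(expr, labels, sets, n_draws=100, draw_size=5, seed=1)
acc = np.mean([p.predicted == labels.label_of(p.sample_id) for p in preds])
print("LOOCV majority-vote accuracy:", round(float(acc), 3))
```

prints

```
fraction of sample pairs with r > 0.9: 1.0
responder fraction by arm: {'lapatinib': 0.265, 'trastuzumab': 0.206, 'combination': 0.471}
PW0002_SIGNAL  C-index=0.950  perm_frac=0.000
PW0006_SIGNAL  C-index=0.920  perm_frac=0.000
PW0010_SIGNAL  C-index=0.890  perm_frac=0.000
LOOCV majority-vote accuracy: 1.0
```

The first block verifies the generator reproduces the emulated cohort's
structure (near-universal r > 0.9 between samples; per-arm responder
fractions scattering around the configured pCR rates at n = 34/arm). The
second plants a strong covariance-only signal in 10 of 20 pathways: the
planted pathways top the biomarker ranking with C-indices above 0.89 and no
permutation beats them, and the majority-vote classifier recovers every
label.

The same stages are available from the shell:

```bash
tscpath simulate --out-prefix demo --seed 4
tscpath pathway-biomarkers --expression demo_expression.tsv \
    --clinical demo_clinical.tsv --gene-sets demo_sets.gmt --out pw.tsv
tscpath run --config config.yaml      # end-to-end, per arm x ER group
```

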