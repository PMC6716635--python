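# samgepc

**Sequential analysis of myocardial gene expression with phenotypic change:
cross-platform concordance as the error-control device.**

`samgepc` is a tested, reusable implementation of a longitudinal
differential-expression design used in heart-failure reverse-remodeling
studies: ventricular biopsies are profiled at baseline and after therapy on
up to three platforms (RT-qPCR, microarray, RNA-Seq), patients are
classified as reverse-remodeling **Responders (R)** or **Nonresponders
(NR)** from their LVEF change, and — instead of FDR-adjusted q-values — the
*directional agreement of independently measured DEG sets* is used to
separate biologically meaningful expression changes from platform noise.

It is aimed at analysts running paired before/after expression studies who
want the concordance arithmetic, the responder phenotyping, and a synthetic
cohort generator for power/design exploration in one place.

## The statistic

A gene is a DEG when its two-sided p < α (default 0.05, unadjusted; paired
Wilcoxon signed-rank within groups on the platform's untransformed readout,
Wilcoxon rank-sum for the R-vs-NR contrast) with a defined fold-change
direction. Two DEG sets are concordant in a gene when both call it
significant *with the same direction*. Total cross-platform concordance is

```
C_cpT = 100 · 2 · |same-direction intersection| / (|DEGs₁| + |DEGs₂|)
```

— the "percentage of overlapping genes" statistic when both platforms
measure the same gene universe. The same formula applied to one platform
across two cohorts gives cross-cohort concordance (C_ccT). For two
independent null tests at α = 0.05 the chance of same-direction dual
significance is α²/2 = 0.00125, which is what makes concordance a stringent
alternative to multiplicity correction.

Fold changes follow the platform conventions: qPCR `2^−ddCt` against a
GAPDH-normalized dCt, microarray/RNA-Seq `2^(log2 follow-up − log2
baseline)`, group folds as the *mean of per-patient ratios*, and R/NR folds
as the ratio of the two group folds.

## Worked example

The bundled `samgepc.datasets` module carries published two-platform
candidate-gene DEG lists from a 47-patient β-blocker reverse-remodeling
study. Feeding them through the concordance machinery:

```python
from samgepc import datasets
from samgepc.concordance import concordance_total

res = concordance_total(
    datasets.CANDIDATE_AS_QPCR_R, datasets.CANDIDATE_AS_ARRAY_R,
    label="A-S qPCR vs microarray, R analysis",
)
print(f"{res.label}: {res.n_side_a} vs {res.n_side_b} DEGs, "
      f"{res.n_concordant} concordant -> {res.c_total:.1f} ({res.c_total_printed})")
print("concordant up:", ", ".join(res.concordant_up))
```

prints

```
A-S qPCR vs microarray, R analysis: 23 vs 24 DEGs, 14 concordant -> 59.6 (60%)
concordant up: ADRB1, PLN, THRA1
```

i.e. of the 23 RT-qPCR and 24 microarray candidate-gene changes, 14 agree in
direction, so 28 of the 47 significance slots are concordant — a C_cpT of
60%, with the β₁-adrenergic receptor, phospholamban and thyroid-receptor
transcripts among the concordantly upregulated genes. Category up/down
asymmetry works the same way:

```python
from samgepc.category_stats import updown_asymmetry_p, bh_adjust
raw = [updown_asymmetry_p(u, d) for _, u, d in datasets.CATEGORY_UPDOWN_COUNTS]
adj = bh_adjust(raw)
# Growth/hypertrophy 8:21 -> p = 0.026, BH-adjusted = 0.078
```

showing the growth/hypertrophy category is disproportionately downregulated
during reverse remodeling.

## Pipeline and CLI

`samge run -c config.yaml` executes the full analysis (phenotyping → DEG
calling per platform/analysis → concordance → categories → per-tertile
correlation maps) from a YAML config, with either real input files or a
`simulate:` block; `samge simulate` emits a synthetic three-platform cohort
(TSV matrices, clinical CSV, truth table); `samge concordance` and `samge
categories` work on standalone DEG tables. Every run writes a manifest
(config hash, seed, version) and is bit-reproducible under a fixed seed.

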