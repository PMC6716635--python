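# Methods

## Design the package implements

Paired expression profiling in a reverse-remodeling cohort: each patient is
measured at baseline and again after 3 and/or 12 months of β-blocker
therapy, on up to three platforms. The analysis unit is the
baseline → follow-up change per gene per patient, with the 12-month sample
preferred and the 3-month sample carried forward when it is missing (LOCF).

Patients are phenotyped from LVEF change (absolute %):

| group | rule | default thresholds |
|---|---|---|
| Responder (R) | increase ≥ t₃ at 3 months *or* ≥ t₁₂ at 12 months (OR over observed timepoints) | t₃ = 5, t₁₂ = 8 |
| Nonresponder (NR) | analyzable but not R | — |
| Super-Responder (SR) | R with LOCF increase ≥ t_SR | t_SR = 10 |
| strict NR | every observed increase < 5 % | 5 |

The R rule is evaluated disjunctively per observed timepoint; a patient with
only a 12-month measurement and a 6 % increase is NR (the 12-month threshold
governs 12-month data). SR is a flag on top of R, never a separate branch.
Matching strict NRs by age/gender is not implemented — those covariates are
outside the data contract — so the strict-NR flag is purely the Δ < 5 % rule.

Tertiles of LVEF change are ⌈n/3⌉-balanced with the larger bins at the low
end (n = 47 → 16/16/15) and patient-ID lexicographic tie-breaks, which makes
the assignment a deterministic function of the (change, id) pairs.

## Statistical machinery

* **Within-group change** — Wilcoxon signed-rank on the platform's
  untransformed analysis readout (dCt, log2 intensity, FPKM). Zero
  differences are dropped; fewer than 4 informative pairs → the gene is
  flagged under-powered (missing p), not an error. Exact null distribution
  for n ≤ 25 with untied |differences| (computed from the rank-subset-count
  DP, so genome-wide stratified calling stays fast), otherwise normal
  approximation with tie and continuity corrections.
* **R vs NR** — Wilcoxon rank-sum on the subtracted (LOCF − baseline)
  values; exact when the smaller group ≤ 10 without ties, otherwise the
  corrected normal approximation. In genome-wide calling, combined n < 8 is
  treated as under-powered.
* **Direction** is always taken from the fold-change table, never from the
  test statistic, so the inverted Ct scale of qPCR cannot flip a call. A
  fold of exactly 1 leaves direction undefined and the gene out of every DEG
  set.
* **No multiplicity correction on DEG calling** — α = 0.05 unadjusted is the
  design; cross-platform concordance is the error-control device. The
  expected null concordance of two independent platforms is α²/2.
* **Category asymmetry** — continuity-corrected chi-square goodness of fit
  of (n_up, n_down) against 50:50: χ² = 2·max(|n_up − n/2| − ½, 0)²/(n/2) on
  1 df, clamped to zero inside the correction band. This specific form
  reproduces the published per-category p-values to their printed precision,
  which a plain chi-square or a 2×2 Fisher does not; an exact binomial sign
  test is available behind `method="binomial"`. BH adjustment
  (statsmodels `fdr_bh`) runs over the category family only; the totals row
  is a separate single test.
* **Concordance comparisons** — 2×2 chi-square on concordant slots
  (2·n_concordant) vs the remainder of each summed denominator, Fisher exact
  for small expected cells. Stratum homogeneity uses the 2×k chi-square
  with a seeded Monte-Carlo permutation chi-square (10⁴ draws) when any
  expected cell is below 5 — no closed-form exact r×k test is available in
  the stack, and the simulated p is reported with add-one smoothing.
* **Correlation maps** — Spearman rho (midranks) between candidate and
  genome-wide per-patient log2 fold changes, computed as Pearson on ranks in
  one matrix product. Display order comes from average-linkage clustering on
  a 1 − Pearson distance between rho vectors — the conventional default for
  expression heatmaps — computed on the largest-remodeling tertile and then
  reapplied to the other tertiles so maps are visually comparable. Missing
  rho values are imputed as 0 for ordering only and retained as missing in
  output; items are pre-sorted lexicographically so leaf order does not
  depend on input order.

## Numerical and formatting conventions

* RNA-Seq FPKM is floored at ε = 0.01 (configurable) before log2 — the fold
  formula is undefined at zero and flooring preserves patients rather than
  dropping them.
* All platforms share one delta sign convention (qPCR stores −ddCt), so
  positive delta ⇒ fold > 1 everywhere.
* Group fold change is the mean of per-patient ratios `mean(2^δ)`, not
  `2^mean(δ)`; deltas {2, 0} give (4+1)/2 = 2.5.
* Concordance percentages print as the nearest integer at ≥ 20 and one
  decimal below 20 (half-up); the raw value is always retained.
* Missing cells are explicit and propagate as per-gene-patient exclusions;
  nothing is imputed.
* Gene identifiers are opaque, case-sensitive strings; sample keys are
  `patientID_timepoint` with timepoint ∈ {baseline, m3, m12} and no
  underscores in patient IDs.

## The synthetic cohort generator

The generator is the test harness standing in for the study's biopsy data.
Defaults are the study conditions: 31 R / 16 NR; baseline LVEF ~ N(26, 8²)
truncated to the ≤ 40 % entry criterion; LVEF change N(21, 10²) in R vs
N(1, 4²) in NR (SEM→SD converted with the group sizes); 8/47 of patients
missing the 12-month measurement. Expression: 2 000 genes, 50 candidates,
10 % true DEGs (half up, half down, |log2FC| ~ N(1, 0.25), candidates
enriched 2×, NR effects null); per-platform noise Ct SD 0.35, array log2 SD
0.4, RNA-Seq negative-binomial dispersion 0.2 with fixed gene lengths and
log-normal library factors (SD 0.2).

Two generator features deserve explanation:

* **Effect–LVEF coupling** (default 0.5): each responder's planted effects
  are scaled by `max(0, 1 + 0.5·z)` where z is their standardized LVEF
  change. This is what produces the concordance-rises-with-remodeling
  tertile gradient.
* **Platform drift** (`platform_drift_sd`, default 0.25 log2 units): a
  per-(gene, platform) systematic baseline → follow-up shift applied to
  *all* patients. It models platform-specific temporal/batch artifacts.
  Such shifts are detected as spurious within-group "changes" on one
  platform but not the other (deflating R-only concordance), while the
  R-vs-NR contrast cancels them — which is precisely the argument for the
  R/NR design, and without some such term an R/NR concordance advantage
  cannot arise at all. Set it to 0 for a fully null,
  independent-measurement condition; the α²/2 null-concordance check is run
  in that condition because the analytic value assumes two independent
  tests, each at level α.

What the generator does *not* emulate: biopsy-sampling variability as a
distinct variance component (absorbed into platform noise), probe-level
microarray artifacts, RNA-Seq coverage bias, and any correlation structure
between genes beyond the shared responder effects. Passing tests therefore
show that the pipeline recovers what it is supposed to recover under an
idealized version of the design — not that any particular biological claim
transfers to real tissue.

## Problem sizes used in tests and the acceptance script

Stochastic properties are characterized at the default study conditions
with 200 independent seeds (DEG-calling sensitivity, R/NR-vs-R concordance
ordering, tertile gradient); the null-concordance Monte-Carlo uses one
10 000-gene null study; a few unit-level recovery examples use 20–30 seeds
or 200–300 genes, where the property being checked is insensitive to the
gene count. Cohort-only checks (label recovery) run all 200 seeds since no
expression needs simulating.

## Known limitations

* The concordance statistic is the thresholded directional form only; no
  continuous (fold-change-correlation) concordance is offered.
* Exact r×k homogeneity is Monte-Carlo, not Fisher–Freeman–Halton.
* The qPCR reference gene is assumed drift- and effect-free in simulation;
  real reference-gene instability would propagate into every dCt.
* One row per gene ID is assumed; collapsing multiple probe sets per gene
  is the caller's responsibility.
* Published summary lists bundled in `samgepc.datasets` carry directions
  and counts only, so reanalyses that need per-gene p-values or fold
  changes must start from the original matrices.
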