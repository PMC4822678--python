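# Methods notes

This note records the statistical conventions, modelling assumptions and
design choices behind the package, in the spirit of a model-description
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The score

The HNF1B score is a fixed-weight additive instrument over 17 phenotype
items. Weights: family history of renal disease/diabetes in a parent or child
+2; antenatal renal abnormality +2; per kidney — hyperechogenicity +4, renal
cysts +4, hypoplasia +2, multicystic/dysplastic kidney +2, urinary tract
malformation +1; solitary kidney +1; hypomagnesaemia (Mg²⁺ < 0.7 mmol/l) +2;
hypokalaemia (K⁺ < 3.5 mmol/l) +1; early-onset gout +2; glomerular cysts or
oligomeganephronia on biopsy +1; pancreas item (MODY/young-onset diabetes,
pancreatic hypoplasia, or exocrine insufficiency) +4 with a hard cap at 4;
genital tract malformation +4; unexplained liver test abnormality +2.

Decisions where the published description is ambiguous or internally
inconsistent:

- **Solitary kidney is scored once.** The published item table lists it under
  each kidney, but two absent kidneys are impossible, so the package models it
  record-level with a single +1. The arithmetic maximum of the published
  layout is 48; with record-level solitary an all-true record reaches 47. The
  bound `SCORE_MAX = 48` is kept as the documented ceiling.
- **Early-onset gout** is defined as diagnosis **before age 30**, following
  the study's methods text; the item table's "(>30 years of age)" annotation
  contradicts it and is treated as a typographical slip.
- **Young-onset diabetes (≤ 35 y) satisfies the MODY clause** of the pancreas
  item by default, because scoring was done from routine referral information
  in which MODY status is rarely confirmed. `strict_mody=True` restricts the
  item to pancreatic hypoplasia/exocrine failure.
- **Ties at the cutoff are positive** (score ≥ 8 tests positive).
- **Missing items score 0** and count as "absent" in contingency tables:
  referral-form data is incomplete by nature, and an unassessed feature cannot
  be acted on. Each record carries a `completeness` fraction so that analyses
  can report how much of the phenotype was actually assessed.
- **Laterality.** Feature tables treat a renal feature as present if either
  kidney is flagged. Input files may give per-kidney columns or patient-level
  columns; patient-level renal flags are expanded to both kidneys (the
  "bilateral" convention), which matches the typical bilateral presentation
  but is an assumption, not a statement of the source data.

## 2×2 association statistics

- **Odds ratio**: cross-product (a·d)/(b·c); 0 and +inf at the boundaries,
  undefined (NaN) when both products vanish. Infinite ORs serialise as the
  string `"inf"`.
- **CI policy**: Woolf logit interval `exp(log OR ± z·√(1/a+1/b+1/c+1/d))`
  when all cells are positive; conditional-exact limits otherwise, because a
  zero-cell row like "0 (0–65.1)" cannot come from Woolf.
- **Exact limits**: inversion of the noncentral hypergeometric tail at
  α/2 (Cornfield-style), computed via `scipy.stats.contingency.odds_ratio`.
  A `midp=True` variant counts only half the observed table's probability in
  each tail; this reproduces the zero-cell intervals printed in the study
  (e.g. upper limit 65.1 where the α/2 inversion gives 133.6), indicating the
  original analysis used mid-p exact limits for sparse rows. The default
  remains the plain conditional inversion, which is conservative.
- **Fisher's exact test**: two-sided by point-probability summation (the
  convention of scipy/R), i.e. the sum of probabilities of all tables with the
  same margins no more probable than the observed one.
- **Mann–Whitney U**: exact enumeration for n₁+n₂ ≤ 12 without ties,
  otherwise the tie-corrected normal approximation; medians and IQRs are
  reported alongside.
- **Reporting precision** follows the study's tables: one decimal below 100,
  whole numbers at ≥ 100.
- One published whole-cohort OR (pancreatic hypoplasia/exocrine failure,
  20.7) is not the cross-product of its own printed counts (which give 20.9);
  the estimator behind that sparse row is unstated. The package makes no
  attempt to guess it and documents the row as non-reproducible.

## Mantel–Haenszel pooling

`OR_MH = Σ(aᵢdᵢ/nᵢ) / Σ(bᵢcᵢ/nᵢ)` with the Robins–Breslow–Greenland
variance of log OR_MH:

```
V = Σ(PᵢRᵢ)/(2R²) + Σ(PᵢSᵢ + QᵢRᵢ)/(2RS) + Σ(QᵢSᵢ)/(2S²)
P = (a+d)/n,  Q = (b+c)/n,  R = ad/n,  S = bc/n;  R, S without subscripts are sums.
```

The point estimate is accumulated in exact rational arithmetic so a single
stratum reduces to its cross-product OR without floating-point drift. Zero
cells within a stratum get no continuity correction — the stratum simply
contributes its defined terms; strata with an empty margin carry no
information and are dropped with a warning. No heterogeneity statistics or
random-effects pooling are provided. Pooled ORs of the combined UK+French
referral data cannot be recomputed here because the French stratum counts are
not published; the pooling machinery is exercised on the UK age strata and on
simulated strata instead.

## ROC and predictive values

Scores are small integers with heavy ties, so the AUC is computed by the
tie-corrected rank formulation (probability a random carrier outscores a
random non-carrier, ties counted half), which is identical to trapezoidal
integration of the empirical ROC — the identity is enforced to 1e-12 in the
tests. The AUC interval uses DeLong's nonparametric variance estimator
(validated against R's pROC implementation); the choice is exposed rather
than hard-coded into results. Predictive values with zero denominators are
reported as nulls, never 0. The published "NPV of 8%" line is inconsistent
with the same study's abstract and discussion ("NPV of 85%") and with the
reconstruction 193/228 ≈ 84.6%; the 85% figure is treated as correct.

## Synthetic cohort generator

The generator emulates the UK referral study's sampling frame, not a general
population: n = 686; mutation prevalence 0.258; child fraction 0.606; each
feature Bernoulli with the published frequency conditional on (mutation
status, age group); renal findings bilateral with probability 0.8 when
present (configurable), all findings forced unilateral when a solitary kidney
was drawn; ages at diabetes diagnosis drawn from a log-normal matched to the
published medians/IQRs (16.5 [12–26.8] years in carriers, 32.5 [15.3–49.8] in
non-carriers), truncated at the young-onset limit of 35. Hypokalaemia is
scored but not tabulated in the source data; the defaults (5% in carriers,
2% in non-carriers) are a realistic referral-cohort choice documented here.

Features are generated **independently** given status and age group because
only marginal frequencies are published. This is the generator's main known
limitation: real phenotypes co-occur (cystic kidneys are often also
hyperechogenic), so the synthetic score distribution is narrower than a real
one and the synthetic AUC (~0.70 at the default configuration) should be read
as a diagnostic of the pipeline, not an estimate of the score's field
performance. Matching the published score medians (10 carriers vs 8
non-carriers) is likewise a reported diagnostic, not a calibration target —
the defaults are tuned only by the published marginal frequencies.

A single seeded `numpy` generator drives all draws; the seed is echoed into
the cohort label, and identical seeds give byte-identical CSV output. The
parameter-recovery harness regenerates cohorts at the configured frequencies
(200 replicates of n = 686 by default), estimates each feature's whole-cohort
OR per replicate (Haldane–Anscombe 0.5 correction only when a zero cell
occurs), and flags any feature whose generating marginal OR falls outside the
central 95% of the estimates.

## Problem sizes and numerical choices

Test and acceptance runs use the study's own sizes where they matter
(n = 686 cohorts; 200 recovery replicates), 1,000-repetition property sweeps
for the AUC and pooling identities, an exhaustive sweep of all 2×2 tables
with n ≤ 20 against the enumeration oracle for Fisher's test, and n = 10⁵ for
generator-frequency convergence. Root-finding for mid-p limits brackets
log ψ in [−50, 50]; CI levels default to 95% with z from the standard normal
quantile, not 1.96 rounded.
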