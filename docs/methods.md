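# Methods

This note documents the models, conventions and numerical choices behind
`methylmark`, and what the synthetic-data generators do and do not emulate.

## Reactivation screen

**Model.** Log2 expression for each probe is compared between drug
(demethylating agent) and vehicle arms within one cell line. The test is a
shrinkage-variance *t*: per-probe pooled variance s² (df = n₁+n₂−2) is
moderated toward the across-probe mean variance s₀² with prior degrees of
freedom d₀ (default 10), s̃² = (d₀s₀² + df·s²)/(d₀+df), and the statistic
Δ/√(s̃²(1/n₁+1/n₂)) is referred to a t distribution with df + d₀ degrees
of freedom. This is the standard remedy for unstable per-probe variances
in 2–3-replicate array designs; with many replicates it converges to the
ordinary *t* (a tested property). Welch's *t* is available
(`method="welch"`) for users who prefer no moderation. FDR is
Benjamini–Hochberg.

**Candidate rule.** A probe is a candidate when it passes **both** the
fold (|Δ| ≥ log2 1.5) and significance (p ≤ 0.05) criteria, in the same
direction, in every designated cancer line, and fails **at least one** of
the two criteria in the non-tumorigenic line. The lenient non-induction
rule (fail either criterion, rather than fail both) is deliberate: the
strictest reading would discard borderline probes that the screen design
intends to keep — a gene weakly and non-significantly induced in the
control line is still cancer-specific in any useful sense. Both thresholds
are configurable (`--fold-min`, `--p-max`).

**Cross-dataset validation** computes, per candidate, drug-minus-vehicle
differences per external cell line and a paired *t* across lines
(requires ≥ 3 pairs); the reported fraction counts candidates with p < 0.05
and a positive mean difference.

## CpG islands and coordinates

Island detection is the classic sliding-window scan: windows of 200 bp
(step 1) pass when GC ≥ 0.50 and ObsCpG/ExpCpG ≥ 0.6 with
Exp = nC·nG/window; the union of passing windows is merged and merged runs
≥ 200 bp are reported with whole-island statistics. All four thresholds
are configurable. CpGs straddling a window's right edge are counted in the
next window; the brute-force oracle in the test suite uses `str.count`,
which applies the same convention.

**TSS-relative convention (important).** Coordinates are plain integers
with **0 = the TSS base**; regions are inclusive at both ends, so
−290..+117 contains 290 + 1 + 117 = 408 bases. This is stated prominently
because promoter-region literature rarely defines its convention; every
on-disk interval (BED) is converted to 0-based half-open at the I/O
boundary only. Promoter-proximity annotation uses a window of
−1500..+500 around the TSS by default (a common promoter definition;
configurable).

## Bisulfite clone quantification

**Alignment.** Each cloned read is aligned globally against the
*unconverted* reference (Biopython `PairwiseAligner`; match +1, mismatch
−1, gap open −2, extend −0.5) with one asymmetric rule: reference C
aligned to clone T scores as a match, because that is the expected
bisulfite image of an unmethylated cytosine. The reverse pairing (ref T,
clone C) remains a mismatch. The aligner's optimal score is verified
against a brute-force Gotoh DP in the tests.

**Calling.** At each declared CpG cytosine the aligned clone base gives
the call: C methylated, T unmethylated, anything else (including a gap)
missing. Identity counts reference positions whose aligned base matches
(with C→T counted as matching); clones under a hard floor of 0.6 are
rejected as non-specific. Conversion rate is the converted fraction of
aligned non-CpG reference cytosines; QC defaults are conversion ≥ 95 %
and identity ≥ 90 %. QC never alters the calls of retained clones.

**Per-sample percent** pools all non-missing calls across clones
(methylated / called × 100). With no missing calls this equals the mean of
per-clone percentages; with missing calls the pooled form weights each
called site once, which is the robust choice.

**Tests.** Cancer-vs-control panels are compared with Mann–Whitney on
per-sample percents. Tumor/normal tissue *pairs* are compared with a
Wilcoxon signed-rank over the paired per-CpG fractions — within one pair
the CpG sites are the only replicated unit, so they carry the test.

## Exact nonparametric p-values

Mann–Whitney uses the exact distribution when both groups have n ≤ 20 and
the pooled sample is tie-free (scipy's exact method), else the
tie-corrected normal approximation. The Wilcoxon signed-rank exact p
(n ≤ 25 after dropping zero differences) is computed by a
generating-function convolution over the doubled (integer) average ranks,
which handles tied absolute differences exactly — a case the standard
exact algorithm refuses; an all-zero difference vector returns p = 1 with
a warning. Spearman's exact two-sided p (n ≤ 9) enumerates all n!
permutations of one rank vector; larger n uses the t approximation. All
three agree with full-enumeration oracles in the test suite.

## Cohort evaluation

**NAMS.** Per-sample scores are the arithmetic mean of the two array
probes (their Spearman correlation is reported as a concordance
diagnostic). Normalization maps each dataset's minimum to 0 and maximum to
100. The in-between mapping is under-determined by the verbal definition
("fit into a sigmoidal curve"), so both readings are implemented: a plain
affine min–max (default) and an endpoint-anchored logistic squash centered
at the midrange with steepness k per score-SD (default k = 1). Both are
rank-preserving; calls are deterministic given NAMS and margin. Multiple
datasets are normalized independently and pooled.

**Calls.** A tumor is hypermethylated when NAMS − mean(normal NAMS) > 30
(strictly greater, matching the ">30 higher" phrasing), hypomethylated
when < −30, neutral otherwise; frequencies are reported overall and per
grade.

**ROC.** Thresholds are midpoints between consecutive unique pooled
values (plus sentinels), sensitivity = fraction of tumors ≥ threshold,
specificity = fraction of normals < threshold, AUC by trapezoid (equal to
the tie-adjusted U/(n₁n₂), a tested invariant). The operating point
maximizes sensitivity subject to specificity = 1.0 — the right convention
when a screening test must not flag healthy individuals; Youden's J is
available as an alternative. The AUC CI is a seeded stratified bootstrap
(default 2000 replicates).

## Survival

Kaplan–Meier estimation is delegated to lifelines. The
Gehan–Breslow–Wilcoxon statistic is authored here: at each distinct event
time the observed-minus-expected events in one group (hypergeometric mean)
are weighted by the number at risk and normalized by the summed weighted
hypergeometric variances (Breslow convention for ties); p comes from χ²(1)
or, for small samples, from a seeded label-permutation null. The
implementation is cross-checked in the tests against lifelines'
Wilcoxon-weighted log-rank, which is never used as the implementation.

The cutoff scan truncates records at the follow-up horizon (events beyond
it become censored at the horizon; default 10 years), splits patients at
score ≥ c vs < c for each candidate cutoff (default {60, 65, 70, 75, 80,
85, 90}), and selects the minimum-p cutoff. Because that minimum is taken
without correction, every scan result carries an explicit multiplicity
caveat; the selected p should be read as descriptive, not confirmatory.

## qPCR and IHC quantification

Relative expression is the efficiency-corrected ΔCt model: abundance
∝ E^(−Ct) with E the per-primer amplification factor (validated to lie in
(1, 2.2]); the target quantity is divided by the geometric mean of the
reference-gene quantities (order-invariant; a single reference reduces to
the textbook 2^(−ΔCt) when E = 2). Replicate Cts are combined by
arithmetic mean; replicates more than 0.5 cycles apart are flagged (a QC
convention, not a rejection). Group summaries report linear-scale means
(ARE ± SEM) while tests run on log2 values — linear means are the field's
reporting convention, log2 values are closer to symmetric for testing.
The H-score is Σ(intensity 0–3 × percent cells), validated to a 100 ± 0.5
percent sum and bounded in [0, 300].

## Synthetic-data generators

All generators are deterministic under a fixed seed; every CLI and script
seed below 2³¹.

**Screen** (`ScreenSimSpec`): three cell lines (two cancer, one
non-tumorigenic), 3 replicates per arm, probe baselines N(7, 1.5²),
replicate noise SD 0.3 (typical post-normalization array noise), and a
+2.0 log2 induction of 50/1000 probes in cancer-line drug arms only. The
truth table enables recovery measurements.

**Bisulfite** (`BisulfiteSimSpec`): clones are the bisulfite image of the
reference with per-CpG retention probabilities, non-CpG C retention at the
conversion-failure rate, and uniform substitution errors. Five clones per
sample is the classic cloning depth. Not modeled: chromatogram noise,
strand-specific artifacts, PCR bias toward methylated or unmethylated
templates.

**Cohort** (`CohortSimSpec`): scores on a 0–100 raw scale; normals from a
truncated normal (40 ± 8), tumors from a high component (78 ± 9, with
probability 0.66) or an elevated low component (55 ± 12 — tumors that
escape hypermethylation still trend above healthy tissue, which matches
the observed near-absence of hypomethylated tumors). Probe pairs share
the latent score plus independent noise sized from the realized latent SD
so the pooled Spearman correlation hits ≈ 0.714 (the Spearman target is
converted to its bivariate-normal Pearson equivalent r = 2 sin(πρ/6)).
Hypermethylation truth is the margin rule applied to the generator's own
linear NAMS — planting anything else would make "recover the planted
frequency" unattainable after min–max rescaling moves the margin.
Survival is exponential with hazard 0.08/yr, multiplied by 3 for samples
with linear NAMS ≥ 80 (the planted step the cutoff scan should find),
with independent exponential censoring (0.05/yr) and administrative
censoring at 10 years.

**What passing tests do and do not show.** The generators reproduce the
*statistical structure* the methods assume — bimodality, probe
concordance, group separation, proportional-hazards survival — not the
measurement physics of arrays or sequencing (no batch effects, no probe
cross-hybridization, no beta-value compression, no spatial IHC effects).
Recovery results therefore validate the implementations, not the
biological claims one could make on real cohorts.

## Problem sizes

Defaults are chosen at the study scale the workflow targets: 1000-probe
screens with 3 replicates, 5-clone bisulfite samples over 8–22 CpGs,
cohorts of 338 tumors vs 33 normals, 50-seed recovery batteries. The full
test suite runs in well under a minute on one CPU; the acceptance script
in a few seconds.

## Known limitations

- The shrinkage *t* is a one-parameter moderation (fixed prior df), not
  an empirical-Bayes fit of the prior; for published analyses on real
  arrays a dedicated package (e.g. limma) is the right tool.
- The logistic NAMS mode is one defensible reading of an under-specified
  verbal rule; results that depend on the distinction between the two
  modes should be treated as fragile.
- The cutoff scan's best p is optimistic by construction (min over seven
  correlated tests); the emitted caveat is part of the result.
- Bisulfite alignment assumes clones come from the same strand as the
  reference; opposite-strand reads must be reverse-complemented upstream.
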