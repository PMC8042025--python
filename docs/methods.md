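# Methods

This note documents the statistical model behind each stage of the
pipeline, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Phenotype and genotype definitions

Phenotype classes derive from the absolute neutrophil count (ANC,
cells/mm³): ANC ≤ 500 is agranulocytosis, 500 < ANC ≤ 1500 neutropenia,
ANC > 1500 control. Both boundaries are inclusive, so the agranulocytosis
set is a subset of the neutropenia set by construction. Subjects without an
ANC are classifiable only when flagged as clinical-judgement cases (a
precipitous ANC drop observed under monitoring); the flag value (`1` or
`agran`) decides which case stratum they join, defaulting to
neutropenia-only, because the file format must carry the distinction and
nothing else records it. Missing-ANC subjects without the flag are reported
as unclassifiable, never silently dropped.

Hard calls are the argmax of the 3-simplex genotype posterior, kept when
the maximum posterior is **at least** 0.7 — the rule discards calls *below*
the threshold, so equality keeps the call — and exact ties are missing.
Variant QC applies three filters: missing-call fraction ≤ 0.1, minor-allele
frequency ≥ 0.01, and a Hardy–Weinberg exact test p ≥ 1e−5. The HWE test
conditions on allele counts and sums the probabilities of all heterozygote
configurations no more probable than the observed one (standard two-sided
exact test, no mid-p correction); it is evaluated in controls when a
control mask is supplied. Ancestry strata use the ≥ 80% rule on global
ancestry fractions (EUR, AFR, otherwise admixed).

## Local-ancestry summaries

Local ancestry is consumed as per-marker population dosages in [0, 2]
summing to 2 (within a configurable 1e−3 tolerance, since HMM estimates
are soft). Around the focal variant, dosages are averaged over a closed
±1 kb window (unweighted arithmetic mean over in-window markers). Two
populations are contrasted by the normed difference
(a − b)/(a + b) ∈ [−1, 1], which is scale-free and antisymmetric; it is
undefined (NaN, with a warning) when both dosages are zero.

Group comparisons report, per population, group means of dosages and, per
population pair, group means of **per-subject** normed differences. The
per-subject version is the default statistic because it admits a
permutation null; the normed difference of group means is also obtainable
from the reported means. Significance comes from a two-sided permutation
test: group labels are reshuffled without replacement (group sizes
preserved, draws with replacement from the relabeling space), and the
p-value uses the add-one estimator (k + 1)/(N + 1) with N = 10,000 by
default. When no permutation reaches the observed statistic the reported
string is `<1.00E-04`, the conventional below-resolution display. The
two-sided test (absolute difference of means) is the conservative default.

Kendall's tau-b (tie-corrected, normal-approximation p) supports the check
that local ancestry near the variant is not a proxy for global ancestry.

## Association model

The association is an additive logistic regression of case status on the
risk-allele count, fitted by Newton iteration (equivalently IRLS) to a
gradient norm below 1e−8 within 100 iterations, with Wald standard errors
from the observed information (statsmodels provides the optimizer). The
"global ancestry" model adjusts for PC1–PC7; the "global and local
ancestry" model adds the windowed AFR and EAS dosages as two linear
covariates, treating the local-ancestry effect as additive. Confidence
intervals are exp(β ± 1.96·se) and p-values are two-sided Wald. Subjects
missing the dose or any active covariate are excluded from that fit with a
logged count rather than imputed. Firth or other penalisation is **not**
applied; (quasi-)separated fits are flagged with an infinite-beta
indicator instead of reporting a silently divergent estimate. The
agranulocytosis analysis keeps only ANC ≤ 500 cases and drops the
remaining neutropenia cases entirely; controls are always ANC > 1500.

The ANC-threshold sweep refits the model for thresholds 500–1500 in steps
of 100 under explicit modes: `cumulative` (cases = ANC ≤ T),
`exclude_agranulocytosis` (ANC ≤ 500 subjects dropped, cases = 500 < ANC
≤ T; isolates the neutropenia-only signal), and
`exclude_neutropenia_band` (cases = ANC ≤ T, band subjects T < ANC ≤ 1500
dropped). Because controls are fixed at ANC > 1500, the first and third
modes coincide numerically; both names exist to make the exclusion
direction explicit, since prose descriptions of such sweeps are easy to
misread. Thresholds with no cases are skipped with a logged reason. The
trend of OR against threshold is a weighted least-squares line minimising
Σ wᵢ(ORᵢ − a − bTᵢ)² with wᵢ = 1/se(ORᵢ), the OR kept on its natural
scale (the trend is descriptive of the plotted quantity, not a model fit);
se(OR) uses the delta method, OR·se(β).

## Predictive utility

The genotype-only rule calls carriers (hard call ≥ 1) high risk. The
genotype-plus-LAE rule additionally calls non-carriers high risk when the
windowed AFR dosage strictly exceeds the EAS dosage; an exact tie is low
risk ("larger than" is strict). The widened rule's high-risk set is a
superset of the genotype-only set, so sensitivity can only rise and
specificity only fall — a property the tests assert on every synthetic
cohort.

Sample sensitivity and specificity (computed **unrounded** from the
confusion counts; rounding first visibly corrupts the fourth decimal of
the derived metrics) are recalibrated to an assumed population risk p via
Bayes' rule: PPV = s·p / (s·p + (1 − spec)(1 − p)) and
NPV = spec(1 − p) / (spec(1 − p) + (1 − s)p). The risk in the high-risk
group is the PPV, the risk in the low-risk group is 1 − NPV, and the
relative risk is p / PPV. Default assumed risks are 3.8% (neutropenia)
and 0.9% (agranulocytosis). When p equals the sample case fraction the
recalibration reduces exactly to the raw sample PPV/NPV.

`required_sensitivity(r, p)` inverts the residual risk among
test-negatives: under the perfect-specificity convention,
s = 1 − r(1 − p)/(p(1 − r)). The perfect-specificity form is the default
because for a rare high-specificity marker it is the natural bound and it
matches the published clinical-utility arithmetic; the general
specificity-aware inversion is exposed through the optional `spec`
argument (at these parameter values the two agree to three significant
figures, so the choice is not empirically distinguishable).

## Synthetic cohort generator

The generator's role is to produce cohorts in which every downstream
statistic has a known ground truth. Per subject it draws global ancestry
proportions from a Dirichlet (default α = (1.5, 1.5, 27), a
European-dominant cohort with minor AFR/EAS admixture, so that a majority
passes the ≥ 80% EUR stratum rule as in a predominantly European study
sample). Each of the two haplotypes is tiled by ancestry tracts whose
switch points follow a homogeneous Poisson process (default 2 switches/Mb
over the 25–35 Mb region, the order of magnitude implied by many-generation
admixture at ~1 cM/Mb) and whose labels are i.i.d. draws from the
subject's global proportions. This continuous Markov switch process was
chosen over a generation-explicit pedigree simulator because the analysis
consumes dosages, not pedigrees, and it keeps the generator O(switches).
Self-transitions are retained as distinct tracts, so inter-switch gaps are
exactly exponential (memoryless).

The risk allele is assigned per haplotype with probability depending on
the tract population at the focal position (default (0.01, 0.15, 0.01)
for AFR/EAS/EUR), which yields a ~2% allele frequency on European
backgrounds with strong EAS enrichment among carriers. Case status follows
logit p = β₀ + β_G·G + β_LA·nd·1[G = 0], where nd is the AFR-vs-EAS
normed contrast at the focal position (defined as 0 when no AFR or EAS
haplotypes are present, since there is then no local-ancestry signal).
Defaults: β₀ = −2 (a case-enriched cohort of roughly one case per seven
to eight subjects, matching a case–control design rather than population
incidence), β_G = log 6.2 (the effect size the association stage is meant
to recover), β_LA = 1.5 (a visible non-carrier local-ancestry effect).

ANC draws: controls come from a normal (mean 4200, sd 1100) reflected
above 1550 so every recorded control exceeds the neutropenia threshold;
no published control ANC distribution exists, so these are declared
defaults in a clinically ordinary range, not inferred values. Cases fall
in the agranulocytosis range (uniform 50–500) with probability 0.34
(approximately the observed agranulocytosis fraction among cases) and
otherwise uniformly in the neutropenia band. A `genotype_anc_gradient`
parameter replaces the mixture with genotype-tilted Beta draws (carrier
cases skewed toward low ANC), planting the monotone ANC–risk relationship
used to validate the threshold sweep. A configurable fraction of cases
(default 0.12, with 3/22 of them agranulocytosis-annotated) is recorded as
clinical-judgement cases with missing ANC, and controls lose their ANC
with probability 0.02, exercising the pipeline's missing-data paths.
Genotype posteriors are a point mass on the truth unless `gp_noise` blends
in a Dirichlet draw; emitted local-ancestry dosages are shrunk 5% toward
twice the global proportions to emulate soft HMM estimates while
preserving the sum-to-2 constraint exactly.

What the generator does **not** emulate: linkage disequilibrium between
multiple variants, coalescent tract-length correlations, HLA allele
structure, genotyping batch effects, or informative missingness. Passing
tests therefore demonstrate the pipeline's statistical correctness under
its own assumptions, not robustness to real-data artefacts.

All draws flow through one `numpy` Generator keyed by the seed with a
fixed draw order, so emitted cohorts are byte-reproducible; derived seeds
for permutation tests come from a `SeedSequence` spawn of the run seed.

## Numerical conventions and problem sizes

Coordinates are 1-based, fully closed intervals (VCF convention); analysis
windows are closed on both ends. Genotype-probability simplexes are
validated to 1e−4 and renormalised before the argmax; global ancestry
fractions to 1e−6; local-ancestry sums to 2 within 1e−3. Permutation
exceedance uses |stat| ≥ |observed| with a 1e−12 guard against float
noise. The PLINK-style distance-to-integer hard-call dialect is not
separately implemented: the 0.7 max-posterior rule is the one applied to
the analysis-critical calls, and both express the same confidence
filtering.

The test suite works at desk scale by design: parameter-recovery runs use
100 replicates of 5000 subjects, permutation calibration 2000 null
datasets of 20 values, sweep-trend checks 50 replicates of 2000 subjects,
and the end-to-end determinism check a 300-subject cohort. These sizes
give Monte-Carlo error comfortably inside the asserted bounds while the
whole suite stays fast.

## Known limitations

* Separated logistic fits are flagged, not rescued; a penalised
  (Firth-type) estimator is deliberately out of scope because the
  reference analysis reports plain ML estimates.
* Wald intervals are used throughout; profile-likelihood intervals would
  differ for very sparse tables.
* The permutation engine tests mean differences only; other statistics
  would need their own exceedance definition.
* The generator's ANC model is a convenience mixture; it reproduces class
  frequencies, not haematological dynamics.
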