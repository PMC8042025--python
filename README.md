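# clozanc

Case–control analysis of a candidate pharmacogenetic variant for
clozapine-induced neutropenia and agranulocytosis.

Clozapine is the only effective antipsychotic for treatment-resistant
schizophrenia, but it can trigger a dangerous collapse of the neutrophil
count. Cases are defined from the absolute neutrophil count (ANC):
agranulocytosis at ANC ≤ 500 cells/mm³ and neutropenia at ANC ≤ 1500
cells/mm³. A risk allele in the HLA region (carried preferentially on East
Asian-like local haplotype backgrounds, with a frequency around 2% in
European controls) has repeatedly been implicated, and local-ancestry
patterns around it carry additional signal: among non-carriers, cases show
elevated African-like and depressed East Asian-like local dosage.

`clozanc` re-implements that analysis as a tested, reusable pipeline for
statistical geneticists and pharmacogenetics researchers:

* **cohort_io** — read a single-site VCF (GT/GP), a phenotype/covariate
  table and an ELAI-style local-ancestry dosage table; derive best-guess
  genotypes (argmax posterior, calls below 0.7 set missing); apply the
  missingness ≤ 0.1 / MAF ≥ 0.01 / HWE exact-test ≥ 1e−5 variant filters;
  classify phenotypes from ANC and ancestry strata from ≥ 80% global
  ancestry fractions.
* **local_ancestry** — windowed dosage means (±1 kb around the focal
  variant), the normed difference (a − b)/(a + b) contrasting two
  populations, group comparisons with 10,000-permutation label-shuffling
  tests, and Kendall's tau-b for local-vs-global ancestry checks.
* **association** — additive logistic regression of case status on the
  risk-allele count, adjusted for principal components (PC1–PC7) and
  optionally for windowed AFR/EAS dosages; ANC-threshold sweeps
  (500–1500 in steps of 100) with explicit case-inclusion modes; a
  weighted least-squares trend of OR on threshold (weights = reciprocal
  SEs of the OR).
* **prediction** — genotype-only and genotype-plus-local-ancestry risk
  classifiers, confusion matrices, and predictive values recalibrated by
  Bayes' rule to assumed population risks (neutropenia 3.8%,
  agranulocytosis 0.9%), plus the minimum sensitivity required to push the
  residual risk in test-negatives below an acceptable level:
  `s = 1 − r(1 − p) / (p(1 − r))`.
* **synthetic_cohort** — a generator producing admixture tracts
  (memoryless switch process), an ancestry-linked risk allele, a liability
  model and ANC draws, so every stage is testable at desk scale.
* **cli** — `clozanc simulate | analyze | sweep | predict` with YAML
  config, deterministic outputs and a hash manifest per run.

## Worked example

Simulate a 1000-subject cohort and run the full pipeline:

```sh
clozanc simulate --seed 7 --out cohort --n-subjects 1000
cat > config.yaml <<EOF
vcf: cohort/cohort.vcf
phenotypes: cohort/phenotypes.tsv
local_ancestry: cohort/local_ancestry.tsv
seed: 7
EOF
clozanc analyze --config config.yaml --out results
```

`results/association.tsv` from that exact run:

```
phenotype        model         n_cases  n_controls  or_      ci_low   ci_high  p
neutropenia      global        135      780         5.25844  2.60029  10.6339  3.84211e-06
neutropenia      global_local  135      780         9.31247  4.06459  21.336   1.32523e-07
agranulocytosis  global        32       780         9.56737  3.47547  26.3373  1.23576e-05
agranulocytosis  global_local  32       780         12.6416  4.11973  38.7916  9.20884e-06
```

The generator plants a log-OR of log 6.2 per risk allele; the "global"
model recovers an OR near that value, and adding the windowed AFR/EAS
dosages ("global_local") strengthens the estimate because the
local-ancestry effect in non-carriers is then modelled — the same
qualitative behaviour the method is designed to expose. The prediction
table from the same run shows the classifier trade-off:

```
phenotype    rule               sensitivity  specificity  risk_high  risk_low
neutropenia  genotype_only      0.118519     0.975641     0.161209   0.034459
neutropenia  genotype_plus_lae  0.644444     0.487179     0.047292   0.028021
```

Adding the local-ancestry rule (non-carriers with AFR > EAS window dosage
are also called high risk) raises sensitivity sharply while specificity
falls — the trade the clinical-utility analysis quantifies. `risk_low` is
the residual neutropenia risk among test-negatives at an assumed 3.8%
population risk.

Library use mirrors the CLI:

```python
from clozanc import recalibrate, required_sensitivity

tc = recalibrate(sens=15 / 133, spec=838 / 868, p=0.038)
print(round(tc.risk_high, 4), round(tc.risk_low, 4), round(tc.rr, 4))
# 0.1142 0.035 0.3328
print(round(100 * required_sensitivity(0.0013, 0.009), 1))  # 85.7
```

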