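# pharmscan

Population-scale pharmacogenomics of adverse drug effects (ADEs) from
genotypes and electronic-health-record tables.

Biobanks that couple whole-genome sequencing with longitudinal prescription
and diagnosis records make it possible to ask, for every putatively
functional variant in a pharmacogene and every drug linked to that gene:
*are carriers who take the drug more likely to experience an adverse
effect?*  `pharmscan` implements that analysis end to end for statistical
geneticists and pharmacoepidemiologists:

- **Variant annotation** — rule-based classification of pharmacogene
  variants into loss-of-function (stop-gain, frameshift, essential splice
  site, with ancestral-allele and 3'-most-5%-of-transcript exclusions),
  missense, and promoter TFBS hits from an information-weighted
  position-weight-matrix scan of the 5-kb upstream window.
- **ADE phenotyping** — per-person case status from ICD10 diagnosis codes
  in a configurable list of drug-induced diagnoses (with
  physician-confirmation requirements for codes lacking an explicit drug
  link), plus self-reports; codes map into 12 diagnostic groups.
- **Cohorts and linkage** — drug-exposure cohorts at ATC level 4,
  multi-SNV allele carrier assignment, and gene → drug → ADE co-occurrence
  flows.
- **Association engine** — crude 2×2 odds ratios with Woolf CIs, and
  covariate-adjusted logistic models (additive dosage or carrier coding;
  BMI, sex, age, four genotype PCs, platform) for the candidate scan with
  its inclusion filters (≥500 interrogable participants, ≥1 carrier, ≥1
  ADE), the genome-wide scan (MAF ≥ 1%, suggestive p < 10⁻⁶), conditional
  adjustment for known variants, and drug-independent disease checks.
- **Replication** — diagnostic-group refinement of hits, Bonferroni gating,
  and unweighted sum-of-z (Stouffer) meta-analysis.
- **k-mer copy number** — a median-ratio estimator of gene copy number
  from region-diagnostic canonical k-mers, for segmental-duplication genes
  where read mapping fails.
- **Synthetic cohorts** — a generator with a realistic MAF spectrum,
  ATC-coded prescriptions, ICD10-coded diagnoses and *planted* logistic
  variant × drug → ADE effects, so the whole pipeline is testable without
  access-controlled biobank data.

## The model

For a drug cohort (persons with ≥1 prescription in one ATC-4 group), case
status is ADE occurrence, and the genotype effect is estimated by maximum
likelihood in

```
logit P(ADE_i = 1) = β₀ + β_g · g_i + γ' x_i
```

with `g_i` the dosage (0/1/2) or carrier indicator and `x_i` the covariates
above.  `exp(β_g)` is reported with its Wald 95% CI and two-sided p.  In a
2×2 collapse with counts `a,b,c,d` (ADE/no-ADE × carrier/non-carrier) the
covariate-free carrier fit reproduces the crude odds ratio `(a·d)/(b·c)`
exactly.  Replication evidence combines as `z = Σ zᵢ / √k` with
`zᵢ = Φ⁻¹(1 − pᵢ)` signed by effect direction.

## Worked example

A published validation table for the OCT1 transporter variant rs12208357
among tramadol users reports 52 carriers and 139 non-carriers with an ADE,
against 236 carriers and 961 non-carriers without:

```python
>>> from pharmscan import TwoByTwo, crude_or, sum_of_z
>>> res = crude_or(TwoByTwo(a=52, b=139, c=236, d=961))
>>> print(f"OR = {res.or_:.2f}  95% CI ({res.ci95[0]:.2f}, {res.ci95[1]:.2f})  p = {res.p:.4f}")
OR = 1.52  95% CI (1.07, 2.16)  p = 0.0181
```

Carriers have ~1.5-fold odds of a tramadol-related ADE, nominally
significant.  Combining a discovery p of 0.035 with a replication p of
0.004 (both two-sided, same effect direction) by sum-of-z:

```python
>>> meta = sum_of_z([0.035, 0.004], [1, 1], two_sided_inputs=True)
>>> print(f"z = {meta.z_combined:.3f}  one-sided p = {meta.p_one_sided:.2e}")
z = 3.526  one-sided p = 2.11e-04
```

The full pipeline (simulate → phenotype → link → candidate scan →
genome-wide scan → replicate) runs from the command line and writes a
provenance manifest:

```
pharmscan run --seed 1 --out demo_run/
pharmscan simulate --out cohort/ --seed 7
pharmscan phenotype --diagnoses cohort/diagnoses.tsv \
    --self-reports cohort/self_reports.tsv --out phenotypes.tsv
```

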