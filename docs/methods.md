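# Methods

## Scope and data model

`pharmscan` analyses three linked tables plus genotypes: prescriptions
(person, ATC code, date), diagnoses (person, ICD10 code, date,
physician-confirmation flag), self-reported adverse reactions, and a
covariate table (sex, age, BMI, four genotype principal components,
genotyping platform).  Genotypes are diploid dosages (0/1/2 ALT copies,
missing allowed) read from VCF 4.2.  All internal coordinates are 1-based
closed; BED input is converted at the boundary (0-based half-open).

## ADE phenotyping

A diagnosis is a possible adverse drug effect (ADE) when its ICD10 code
prefix-matches a configurable code list.  Matching is at the precision of
the configured code ("M60" matches "M60.9"), because EHR coding depth
varies.  Codes whose ICD10 title has no explicit drug link (e.g.,
unspecified myositis) additionally require the record's
`physician_confirmed` flag — the electronic stand-in for a manual chart
review.  Every self-report counts as an event.  Each configured code
belongs to exactly one of 12 diagnostic groups defined by leading
pathophysiological mechanism and affected organ system; groups drive
phenotype refinement during replication.  The bundled
`data/ade_codes.yaml` is a synthetic example list of 79 codes in 12 groups
(the curated list used in any given study is a data file, so the config is
editable, not hard-coded).

No temporal link between prescription and diagnosis is enforced; the
phenotype is lifetime ADE occurrence within the record window.

## Drug cohorts and linkage

Drugs are grouped at ATC level 4 (first five characters).  A cohort is the
set of distinct persons with any prescription in a group — refills do not
multiply-count — and enters the genome-wide stage when it holds at least
1000 persons (configurable).  Gene–drug linkage for the candidate scan is
at gene level: a variant is tested against every drug linked to *any*
variant of its gene in the PharmGKB-style map.  Multi-SNV alleles are
collapsed to carrier status: a person carries the allele iff any defining
variant has dosage ≥ 1; persons missing at every defining site are treated
as missing and dropped from that test only.

## Association model

The genotype effect is estimated by maximum-likelihood logistic regression
(Newton/IRLS via statsmodels, ≤100 iterations, tolerance 1e-10), additive
(dosage) or carrier coding, adjusting for BMI, sex, age, PC1–PC4 and
platform (0/1 indicators for sex and platform; no interactions).
Replication-stage fits use the reduced covariate set age, BMI and sex.
Wald beta/SE/p are reported for the genotype term.  Degenerate fits carry
explicit statuses instead of numbers: fewer than two cases or controls,
constant genotype, rank-deficient design (collinear), perfect separation
(statsmodels' separation signal, or |β| > 15), or non-convergence.

Crude 2×2 odds ratios use Woolf's log method,
`exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`, with a Wald p.  Zero cells yield a
`zero_cell` status unless the Haldane–Anscombe +0.5 correction is
explicitly requested.  The covariate-free carrier-coded logistic fit and
the closed-form 2×2 OR agree to machine precision (a test asserts 1e-6
over 200 random tables) — a useful internal consistency check because the
two routes share no code.

The candidate scan applies the study's inclusion filters per variant–drug
pair — ≥500 interrogable prescribed persons (configurable), ≥1 carrier
among the prescribed, ≥1 ADE among the prescribed — and tallies every skip
reason.  Significance inside the candidate scan is the nominal p < 0.05;
the genome-wide scan tests variants with MAF ≥ 1% and flags p < 10⁻⁶ as
suggestive.  No FDR machinery is layered on top, matching the two-stage
design (discovery filters, then independent replication with Bonferroni
gating).

Conditional analysis refits the index variant with known variants'
dosages appended as covariates; an |r| = 1 conditioning variant yields a
`collinear` status.  The drug-independent check tests a variant against
one diagnostic group with cases = persons with any ADE in that group
regardless of prescriptions and controls = persons with no ADE at all
(persons with ADEs only in other groups are excluded).

## Replication and meta-analysis

Each suggestive hit is refit within its cohort against each diagnostic
group (cases = cohort persons with an ADE in the group; controls = cohort
persons with no ADE); groups with fewer than two cases are skipped; the
minimizing group is kept, ties broken by larger case count then
lexicographic group id.  Replication p-values pass when below α/m
(α = 0.05; m = number of replication tests, so 0.01 for five).  Discovery
and replication combine by the unweighted sum-of-z method:
`zᵢ = Φ⁻¹(1 − pᵢ)` signed by effect direction, `z = Σzᵢ/√k`.  Two-sided
inputs are converted to directional one-sided p-values as p/2 with the
beta sign — the standard directional Stouffer construction; unweighted
combination matches the common default.  Both one- and two-sided combined
p-values are reported.

## Functional annotation

Loss of function covers stop-gain SNVs (codon becomes TAA/TAG/TGA),
frameshift indels (CDS indel with length mod 3 ≠ 0), and essential splice
variants (the two intronic bases at each intron end).  Two exclusions
apply to LoF candidates: ALT equal to the ancestral allele (taken from the
VCF `AA` INFO key when present), and position in the 3'-most 5% of the
*spliced transcript* — transcript rather than CDS length, the convention
of standard LoF curation; the basis is a documented choice.  Coding SNVs
that change the amino acid without stopping are missense; LoF takes
precedence.

Promoter scanning scores the 5-kb window upstream of the transcription
start (transcript strand, clipped at the contig edge) against nucleotide
frequency matrices with the information-weighted similarity

```
score = (Current − Min) / (Max − Min),   Current = Σᵢ I(i)·f(i, bᵢ),
I(i) = Σ_b f(i,b)·ln(4·f(i,b))           (0·ln 0 = 0)
```

computed over the full matrix (matrix similarity, default cut 0.95) and
over the core — the 5 consecutive positions of maximal summed information,
leftmost on ties — (core similarity, default cut 0.90).  Both strands are
scanned; windows containing N are skipped; a zero-information matrix
scores 1.0 by convention (Max = Min).  The default cut-offs are
configurable because profile-specific cut-off files from the commercial
matrix library are not redistributable.  An optional BED mask restricts
hits to intervals with ChIP-seq evidence.  TRANSFAC-format libraries are
parsed with Biopython.

Variant frequency statistics: AC counts minor alleles among non-missing
calls, MAF = AC/(2·n), bins are half-open and lower-inclusive
(<0.05%, 0.05–0.5%, 0.5–1%, 1–5%, ≥5%), and singletons/doubletons are
tagged AC=1/AC=2.  Novelty requires both the (chrom, pos, ref, alt) key
and the identifier to be absent from the user-supplied catalogue.

## k-mer copy number

For a gene inside a segmental duplication, copy number is estimated
without alignment: a panel of diagnostic k-mers (k = 25, canonical form,
occurring exactly once genome-wide and only in the target region) is
counted in the read set alongside a panel from a copy-number-2 control
region, and `CN = 2·median(diagnostic)/median(control)`.  Counts below 10%
of the control median are zeroed (sequencing-error tolerance), so a
deleted region reads CN 0 rather than noise.  Canonical k-mers make the
estimate invariant to read strand.  Median-ratio normalization and k = 25
are robust defaults from the k-mer CNV literature; all are flags.  Because
overlapping k-mers share reads, the median over a region fluctuates with
roughly (region length / read length) independent units — the validation
uses 5-kb regions at 30× so this quantization stays well below the 0.1
slope tolerance.

## Synthetic cohort generator

The generator emulates the joint structure of a sequenced biobank with
EHR linkage.  Per-variant MAFs are drawn from a five-bin spectrum whose
default weights (55.2 / 21.7 / 3.4 / 7.2 / 12.5% from rarest to most
common) reproduce the spectrum reported for pharmacogene variants in a
deeply sequenced north-European population; genotypes are Hardy–Weinberg
binomial draws.  Prescriptions are per-person-per-drug Bernoulli with 1–3
refills; dates are uniform over 2004-01 to 2015-08 (the EHR window).
Covariates: sex ~ Bernoulli(0.5), age ~ U(18, 90), BMI ~ N(26, 4²),
PCs ~ N(0, 1), platform WGS with probability 0.14 (the sequenced fraction
of a mostly chip-genotyped biobank).

Among persons prescribed a drug group, ADE status follows
`logit P = logit(base_ade_rate) + Σ planted β·g + γ'x` with small fixed
covariate coefficients on centred covariates (so the realized baseline
tracks `base_ade_rate`).  Event codes are uniform over the configured ADE
list, except that events attributable to a planted effect (events that
would not have occurred at the baseline linear predictor, identified by a
shared uniform draw) take codes from the effect's designated diagnostic
group when one is set — this is what lets group-refinement logic be tested
against truth.  A small drug-independent background diagnosis rate and
non-ADE chaff codes exercise the phenotyping filters.  Baseline per-drug
ADE rates in real data are not publicly tabulated; the defaults (5%
among the prescribed) are plausible placeholders and every rate is a
spec-file field.  Identical seeds give byte-identical files.

LD pairs are generated at the haplotype level: two loci with
`D = r·√(p_A q_A p_B q_B)` and random union of gametes, so genotype r²
matches the target in expectation; infeasible targets (beyond
`D_max = min(p_A, p_B) − p_A p_B`) raise with the attainable bound.

What the generator does *not* emulate: imputation error, relatedness and
population structure (PCs are noise, not ancestry), temporal ordering of
prescriptions and diagnoses, coding drift, drug dose or adherence.
Passing tests therefore demonstrate estimator correctness under the
generative model, not robustness to those real-data complications.

## Validation experiment sizes

The reproduction script (`scripts/acceptance.py`) and the acceptance tests
use these problem sizes, chosen to keep Monte-Carlo error small relative
to the tolerance being checked:

- **Planted-OR recovery**: 100 cohorts of n = 5000 (one drug group,
  prescription rate 0.5, base ADE rate 0.1, additive OR 2.5 at MAF 0.2,
  no background diagnoses so the generative and fitted models coincide);
  the Wald 95% CI should cover the truth in ≥90% of seeds.  With several
  drug groups the pooled any-ADE phenotype would dilute the per-drug
  planted effect by construction — a fixture property, not an estimator
  property — hence the single-group design.
- **Type-I error**: one null cohort of 20 000 persons, 60 drug cohorts at
  prescription rate 0.125 (≈2500 persons, ≈400 cases each, low pairwise
  overlap), 140 common variants → 8400 tests.  The size puts the Wald test
  in its asymptotic regime and makes the rate estimate's Monte-Carlo error
  (≈0.003) small against the [0.04, 0.06] acceptance band.
- **Conditional attenuation**: 100 LD pairs (r² = 0.8, MAF 0.3,
  n = 5000) with only the partner causal (OR 2).
- **PWM agreement**: 50 random matrices (length 6–12) × 400-bp sequences
  against an exhaustive per-window scorer.
- **k-mer linearity**: 40-kb toy genome, 5-kb target and control regions,
  copies 0–3, 30× error-free 100-bp reads.

## Known limitations

- The logistic Wald test is mildly liberal in small cohorts with few
  cases; score or likelihood-ratio tests (or the Firth option for
  separated fits) would behave better near the boundary.
- The annotator handles one transcript at a time and does not arbitrate
  across isoforms; splice-region (non-essential) and UTR effects are out
  of scope, as are protein-impact scores, star-allele haplotyping and HLA
  typing.
- The k-mer estimator assumes uniform coverage; GC bias and
  sequencing-error k-mers in real data would need the panel-filtering
  heuristics of dedicated CNV callers.
- Prefix matching of ICD10 codes can over-match if the configured list
  uses 3-character stems; the bundled example list uses full subcodes
  except where the stem is intended.
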