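# Methods

`tumoronly` implements a complete tumor-only somatic mutation analysis for
targeted-capture cancer cohorts that lack matched normal DNA — the typical
situation for decades-old archival FFPE material. The package covers four
stages: a multi-filter somatic calling cascade, hotspot discovery against a
multi-study reference catalog, mutation–covariate association testing, and
gated survival screening with permutation family-wise correction. A
synthetic cohort generator provides fully labeled data with the statistical
structure the analysis assumes, so every stage is testable end to end
without restricted patient data.

## The filtering cascade

Without a matched normal, a raw tumor variant list is dominated by germline
polymorphisms and recurrent pipeline artifacts. The cascade removes them
with population resources and unmatched-normal panels, applied in fixed
order:

1. **Target restriction.** Variants are kept only within the targeted
   regions (1-based inclusive; BED input is converted from 0-based
   half-open on read).
2. **Population frequency.** A variant with minor allele frequency strictly
   greater than 0.1% in *any* of three population resources is removed.
   Absence from the table is informative (frequency 0).
3. **Unmatched-normal calls.** A variant also called in 10 or more of the
   N₁ = 151 unmatched normal samples is removed — this catches common
   pipeline artifacts and polymorphisms missing from the population tables.
4. **Exome read-count panel.** A panel sample "has evidence" for a variant
   when it shows ≥ 3 supporting reads, ≥ 1% VAF and ≥ 20× coverage. If at
   least 1% of the N₂ = 912 exome panel samples have evidence, the variant
   is removed. The 1% is a fraction of the panel actually loaded, not a
   hard-coded count.
5. **Genome read-count panel.** Same evidence rule with an absolute
   threshold of 2 out of the N₃ = 87 genome-sequenced normals — this panel
   exists because some (especially indel-prone) regions are poorly covered
   in exome data.
6. **Binomial LLR classifier.** For x supporting reads out of n, the score
   is

   LLR = ln Binom(x; n, x/n) − ln Binom(x; n, p_err) = n · KL(x/n ‖ p_err)

   in natural-log units, with sequencing-error null p_err = 0.005. Variants
   with LLR below 10 (SNV/DNP) or below 6 (indels) are removed as not
   distinguishable from sequencing error. The exact form of the classifier
   is a design decision of this package: an evidence-vs-error LLR rather
   than a somatic-vs-germline-heterozygote contrast, because a p = 0.5
   alternative would eliminate the many VAF ≈ 0.5 variants (e.g. in
   cancer-predisposition genes) that the downstream germline-suspicion
   analysis is designed to examine. The printed thresholds are preserved.

**Boundary semantics** are encoded exactly as worded: "greater than 0.1%"
strict; "10 or more", "at least three/five", "20×", "1% VAF", "80%"
inclusive; "less than 10/six" strict removal (an exact tie on the LLR
threshold is kept). Coverage in the panel-evidence rule is read as ≥ 20×,
while sample QC uses strictly > 20×; both are configurable.

**Knowledge-base rescue.** Curated clinically relevant sites (e.g. kinase
hotspots) are re-called from read counts whenever ≥ 5 reads, ≥ 1% VAF and
≥ 20× support them, bypassing the cascade verdict; rescued calls are marked
in the trace. Rescue exists because automated callers miss low-frequency
variants of known importance.

**Auditability.** Every stage is evaluated for every on-target variant —
no short-circuiting — and the trace table records (stage, pass/fail,
metric) per variant. The final status cites the first failing stage. The
interactive manual-review step of a production pipeline is replaced by this
trace report.

**Sample QC** requires at least 80% of targeted bases covered above 20×;
failing samples are excluded from all downstream analyses. Mutation burden
is reported as c·m/(L/10⁶) mutations per MB over the tiled target length L,
with a correction factor c ≥ 1 for genes not assayed; zero-mutation samples
are flagged and excluded from cohort range summaries.

## Variant-class policies

Carrier status is defined under named policies: `non_silent` (missense,
nonsense, frameshift, in-frame indel, proximal splice site, plus RNA-gene
variants only for whitelisted genes — MALAT1 by default), `missense`,
`fs_ns` (truncating: frameshift or nonsense) and `fs_ns_splice`. Splice
*region* variants, UTRs, introns and silent changes never qualify. The
class sets nest (`fs_ns` ⊂ `fs_ns_splice` ⊂ `non_silent`), so carrier
matrices shrink monotonically as the policy narrows — a property test.

## Hotspots and panel selection

Study variants and a multi-study reference MAF (with per-study sample
totals summing to N_ref) are aggregated by amino-acid position; proximal
splice-site events are keyed by (gene, splice-junction id) so recurrent
splice disruption aggregates as one hotspot even when the underlying
genomic changes differ. Positions with at least three mutations in either
cohort enter a two-sided Fisher's exact test on
[[k_study, N_study−k_study], [k_ref, N_ref−k_ref]] (minimum-likelihood
two-sided convention, the default of mainstream statistical software), with
Benjamini–Hochberg correction across tested positions; a position is
flagged novel at q < 0.05 when the study proportion exceeds the reference.
N_study is the number of QC-passing samples, not samples with ≥ 1 variant.
Gene selection from the reference follows the panel-design rule: recurrence
≥ 2%, or ≥ 1% with druggability (strictly more than two druggable
categories or more than two anti-cancer drug interactions).

## Association testing

Test choice is codified: Fisher's exact for 2×2 tables; chi-squared for
larger tables unless any expected cell is below 5, in which case a seeded
Monte-Carlo conditional test (label permutation holding both margins,
ordered by the Pearson statistic) replaces the asymptotic approximation —
exhaustive enumeration of r×c tables at cohort sizes is not practical, and
the Monte-Carlo stream is seeded from the table itself so results are
deterministic and order-free. Continuous covariates use a
Kolmogorov–Smirnov check of each group against a fitted normal (α = 0.05):
Welch's two-sample t-test when both groups pass, Mann–Whitney U otherwise.
Group means are compared between disjoint patient groups, so the t-test is
unpaired by construction. Co-occurrence / mutual exclusivity is screened
over all pairs of the seven most-mutated genes (2×2 Fisher, direction from
the odds ratio, BH across the 21 pairs). BH families are one per
(policy × covariate) across the gene panel; the reportability threshold
q < 0.2 is a label in the output, never a filter.

The VAF-based germline-suspicion report counts, per flagged
cancer-predisposition gene (BRCA1/BRCA2/ATM by default), variants with VAF
strictly above 40% and above 60%, and compares mean VAF against all other
genes with the continuous-test rule: in impure tumors a clonal heterozygous
somatic variant sits well below VAF 0.5, so an excess of high-VAF variants
suggests unfiltered germline mutations.

## Survival screening

Per gene and endpoint (BCSS, RFS, OS as available): Kaplan–Meier curves,
the k-group log-rank (Mantel–Cox) test, a univariate Cox hazard ratio, and
a multivariate Cox model with node status (0 vs 1–3 vs 4+ as two dummies),
grade (3 vs 1/2), tumor size category (2/3/4 vs 1) and optional per-gene
copy-number flags. Tests run only when the carrier gate is met: ≥ 15
carriers for non-silent/missense status, ≥ 8 for truncating; gated-out
genes are reported with their gate status and no statistics.

KM and log-rank are computed with lifelines. The Cox partial likelihood is
maximized by a vectorized Newton–Raphson implemented in this package
(Efron tie handling by default, Breslow available; tie method recorded in
output metadata). The engine precomputes the risk-set structure —
sort orders, event-time groups, Efron tie fractions — once per dataset, so
refitting with new covariates costs a few array operations per Newton
step. This matters because the permutation adjustment refits every gated
gene for every permutation; a generic fitter would be orders of magnitude
slower. The implementation is cross-checked against lifelines (coefficients
and standard errors to ~1e−5, the difference attributable to lifelines'
looser gradient stopping rule) and against brute-force likelihood scans.

**Year-5 split.** To address non-proportional hazards and separate early
from late prognostic effects, each subject is expanded into
counting-process episodes [0, min(T, 5)) and, if T > 5, [5, T), with
period-specific copies of every covariate, yielding early/late coefficient
pairs. Episode splitting conserves total follow-up time and event counts.
Period copies that are constant (e.g. no late-period events among
carriers) are dropped from that fit rather than failing it.

**Min-p permutation adjustment.** For each of B permutations (default
1000), the survival outcome and clinical covariates are jointly permuted
against the fixed mutation matrix — implemented by permuting the carrier
columns with the corresponding reassignment, which produces the identical
fit while letting the risk-set structure and the clinical design block be
precomputed once. Every gated gene is refitted with the same model
specification and the minimum p across genes recorded as m_b; a gene's
adjusted p is (1/B)·Σ_b 1[m_b ≤ p_g] ("better" reads as ≤, so ties count
against the gene — conservative). Fits that fail in a permutation
contribute p = 1 for that permutation. For split fits the gene's headline p
is the smaller of its early/late Wald p-values, applied identically to
observed and permuted fits so the min-p procedure remains valid. The
finite-B estimate is clamped from below by the observed p, which the
population quantity P(min-p ≤ p_obs) can never undercut; an optional
(1 + count)/(1 + B) estimator is available behind a flag, default off.

**Two-gene interaction.** Patients are partitioned into
both/A-only/B-only/neither by non-silent carrier status of two genes
(MAP3K1 and PIK3CA by default); empty groups are dropped with a warning and
the log-rank df reduced.

## Synthetic cohort generator

The generator emulates a targeted-capture tumor-only breast-cancer cohort.
Per sample: tumor purity ~ Normal(0.65, 0.15) truncated to (0.05, 1];
PAM50-like subtype from configurable proportions (default 0.45/0.35/0.10/
0.05/0.05 for LumA/LumB/HER2E/Basal/Normal, an older ER+ cohort mix); age,
grade, node count, size category and receptor status from simple clinical
distributions. Per gene: a somatic mutation probability (optionally scaled
by subtype enrichment weights), a consequence-class mix, an optional
protein hotspot position with a concentration weight, and per-endpoint
log-hazard ratios.

Read counts: depth ~ NegBin(mean 140, dispersion 3), close to the ~136×
average of archival capture data; supporting reads ~ Binomial(depth,
vaf·(1−e) + (1−vaf)·e/3) with per-read miscall rate e = 0.005 (a miscall
lands on the variant base a third of the time). Somatic variants are clonal
heterozygous, so expected VAF = purity/2. Germline contaminants are drawn
from a pool of sites with log-uniform population MAFs in [3·10⁻⁴, 0.05] —
deliberately straddling the 0.1% filter threshold so some germline leakage
survives filtering, as in real tumor-only data — with per-sample carrier
probability proportional to heterozygote frequency (expectation 2 per
sample) and VAF ~ Beta(60, 60) around 0.5 (FFPE-like jitter without new
per-site parameters). Recurrent artifacts (Poisson mean 5 sites per
cohort) appear in 20% of tumors at VAF ~ Uniform(0.01, 0.10), are called in
the unmatched normals at rate 0.15 (so they exceed the 10/151 threshold in
expectation) and show qualifying read evidence in 5% of each read-count
panel. Survival: exponential baseline (scale 20 years) or Weibull, hazard
multiplied by exp(Σ log-HR) over carried genes, administrative censoring at
25 years plus random exponential censoring at 0.02/year.

Determinism: one root seed; each stage derives a child stream from a fixed
label (CRC-32 of the label into a seed sequence), so adding a generator
stage never perturbs the others, and identical configuration + seed yields
byte-identical outputs. Coordinates are 1-based with VCF-style ref/alt.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: subclonal architecture and copy-number variation
(all somatic variants are clonal het), mapping-quality and strand
artifacts beyond panel sharing, FFPE deamination spectra, germline-somatic
interaction, and informative censoring. The generator validates the
*machinery* (rule application, calibration, error control), not biological
effect sizes.

## Problem sizes and numerical choices

Bundled analyses and tests use scales chosen to exercise each property at
adequate power: the demonstration cohort is 400 samples × 20 genes with
B = 500 permutations; the family-wise error simulation uses 20 null genes,
n = 400, B = 200 over 100 replicates; hazard-ratio recovery uses n = 2000
at 15% carrier prevalence. Newton iterations stop when the step falls
below 1e−8 or the log-likelihood gain below 1e−12, with step-halving to
keep the likelihood monotone; non-convergence raises an error carrying
diagnostics (screens record such genes rather than aborting). Linear
predictors are clipped at ±30 before exponentiation. Fisher's two-sided
p-values follow scipy's minimum-likelihood convention, verified against
exhaustive hypergeometric enumeration on small tables.

## Known limitations

- The LLR classifier form is a documented reconstruction (the thresholds,
  not the formula, are fixed points); alternative error models would shift
  borderline low-support calls.
- Exact conditional tests for sparse r×c tables are Monte-Carlo, not
  network-algorithm exact.
- The permutation screen assumes exchangeability of (outcome, clinical)
  rows under the null; strong population structure would violate this.
- Early/late headline p for split fits takes the minimum of two Wald
  p-values, which is anti-conservative as a raw p; it is only used inside
  the min-p adjustment, where observed and permuted statistics match.
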