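# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `apoeqc`. Nothing here states an empirical number that the
test suite or `scripts/acceptance.py` does not itself compute.

## Genotype model

The ε alleles are defined by the joint haplotype of rs429358 (REF T, ALT C)
and rs7412 (REF C, ALT T): a chromosome is ε4 if it carries C at rs429358,
ε2 if it carries T at rs7412, and ε3 if it carries neither ALT arm.
A chromosome carrying both ALT arms would be ε1. The package assumes ε1 is
absent: it is vanishingly rare in European-ancestry cohorts and none of the
sources modelled here report it. Consequences:

* every unphased pair of site genotypes with ALT₄₂₉₃₅₈ + ALT₇₄₁₂ ≤ 2 maps to
  exactly one unordered ε pair (6 valid of the 9 combinations);
* the double heterozygote maps to ε2/ε4 and carries an `ambiguous` flag,
  since ε1/ε3 would fit the same unphased data;
* the three combinations with ALT counts summing to >2 are **hard errors**
  (`InconsistentHaplotypeError`), never silent drops, so corrupted input
  surfaces immediately. In the bulk pipeline, where a single corrupt WGS
  call must not abort a 10⁵-subject run, such calls are marked
  `wgs_inconsistent`, excluded from use, and counted — surfaced either way.

Imputed dosages are hard-called to the nearest integer ALT count; calls
farther than 0.4 from every integer are treated as missing, and a variant
with R² < 0.8 is unusable outright (the quality floor below which imputation
of these two SNPs is not trusted anywhere in the pipeline). The 0.4 window
is this package's choice; upstream imputation pipelines do not standardise
a hard-call rule, and the window only matters for the small mass of dosages
near 0.5/1.5 because the generator concentrates dosage noise near integers.

WES verification: current exome data call rs429358 but not rs7412, so a WES
call can count ε4 arms but never separate ε2 from ε3. It therefore verifies
only provided ε3/3, ε3/4 and ε4/4 genotypes; any provided genotype
containing ε2 is non-informative. A contradiction (ε4-arm count mismatch)
excludes the subject — the conservative reading of "verify". Subjects whose
*only* source is WES are excluded as `NO_APOE` rather than guessed: the
package does not invent an ε2/ε3 resolution.

## Adjudication

Approach 1 priority: WGS ≻ (WES-verified) provided ≻ nothing; imputation is
deliberately ignored at this stage, on the conventional reasoning that rare
local haplotypes might impute the component SNPs wrongly. Duplicate samples
are first closed transitively into groups; provided-only groups with
internally discordant provided genotypes are excluded
(`DUP_DISCORDANT_PROVIDED`), and groups whose sequencing calls contradict
each other (WGS vs WES ε4-arm count, or two conflicting WGS calls) are
excluded (`WGS_WES_DISCORDANT`). Within-group merging keeps a source value
only when it is unanimous among the samples that have it; discordant
non-excluding sources (e.g. two different imputed genotypes) collapse to
missing rather than to an arbitrary pick.

Approach 2 adds the stringent filter: a subject whose prioritized genotype
is provided-sourced but differs from a usable imputed genotype is excluded
(`APPROACH2_IMPUTED_DISCORDANT`). Sequencing-sourced genotypes are immune.
Discordance is any inequality of the unordered ε pair — no partial credit
for sharing one allele, and an ambiguous imputed double-heterozygote is
compared as ε2/ε4 with the flag propagated. A non-default
`discordant_policy="impute"` mode instead re-assigns the imputed genotype,
for users who consider exclusion overly conservative. An optional column of
later-released sequencing genotypes, when present, vetoes any prioritized
genotype it contradicts (`NEW_SEQ_DISCORDANT`).

Inclusion filters then restrict to CN/AD subjects aged ≥ 60 (inclusive).
Every exclusion carries exactly one reason, applied in pipeline order, and
the ledger reconciles to the input count by construction. Two structural
guarantees are tested as properties: the approach-2 retained set is a
subset of the approach-1 set on any input, and with zero planted error the
two approaches retain identical sets with no discordance flags.

## Misclassification model

For a phenotype group with true ε4/4 fraction `f_true`, type I rate `p1`
and type II rate `p2`:

    f_obs       = f_true·(1 − p2) + (1 − f_true)·p1
    concordance = f_true·(1 − p2) / f_obs

`concordance` is P(truly ε4/4 | observed ε4/4). It is 1 iff p1 = 0 (or
p2 = 1 degenerately) and is strictly increasing in `f_true` whenever
p1 > 0, which is the whole story of why controls (small `f_true`) are
hit harder than cases by the same assay error. Default anchors
`f_true` = 0.019 (control-like) and 0.129 (case-like) bracket what large
case-control collections observe; the default error grid spans 0–5% in 1%
steps. An independent Monte-Carlo estimator (Bernoulli truth, independent
flips, empirical conditional) cross-checks the closed form; agreement is
asserted within 3 binomial σ at n = 10⁶ per grid point.

## Haplotype frequencies and D′

LD between an ε allele and rs439401-T is estimated from unphased genotypes
by collapsing the ε alleles to a biallelic indicator (the queried allele vs
the other two pooled) and running a standard two-locus EM on the 3×3
genotype table. Allele frequencies are fixed by the table margins, so only
the double-heterozygote cell carries latent phase and the likelihood has a
single free parameter; EM starts at linkage equilibrium and stops when the
largest frequency change drops below 1e-8 (cap 1000 iterations). The
log-likelihood trajectory is recorded and tested to be non-decreasing, and
the estimator is tested against a profile-likelihood grid search on small
tables. D′ uses the textbook normalisation (D / D_max with the sign-specific
D_max); D = 0 returns D′ = 0, and a monomorphic locus raises rather than
returning a defined value.

Strata exploit phase certainty rather than statistical phasing:

* ε4/4 additive — both backgrounds are ε4, so any T is in phase with ε4;
* ε3/4 WT vs HOM — only rs439401 C/C and T/T subjects are kept; a T/C
  heterozygote's single T could sit on either background, so it is dropped;
* ε3/4 and ε3/3 additive — negative-control designs;
* full sample — additive T with ε2/ε4 allele dosages as covariates.

ε2/4 carriers enter none of the four genotype strata (sample paucity makes
them unanalysable) but are retained in the full-sample design, which
represents the whole analysis set.

## Association engine

Logistic regression (statsmodels) of AD status on the stratum's genotype
coding plus age, sex and five PCs; Wald OR, 95% CI and P; significance at
P < 0.05. Cohort fixed effects are off by default — the mega-analysis pools
cohorts, since per-cohort bins of a rare genotype become tiny — and are
available as a sensitivity switch. Mixed models with a genetic relationship
matrix are out of scope; the supported design is unrelated-subjects
logistic regression, which is also the natural replication design.
Degenerate fits are surfaced, not smoothed over: a constant genotype raises
`NoVariationError`, and separation (non-finite estimates or SE > 50 on the
log-OR) raises `SeparationError` advising inspection of the carrier counts.
The crude cross-product OR (Haldane–Anscombe 0.5 when a cell is empty) is
reported alongside as a covariate-free sanity check; without covariates the
two agree to numerical precision, which is tested.

## Synthetic cohort generator

The generator is the oracle for everything downstream, so its defaults are
the study conditions, chosen once:

| parameter | default | why |
|---|---|---|
| allele freqs (ε2, ε3, ε4) | 0.08, 0.77, 0.15 | conventional European-ancestry values |
| rs439401 T frequency | 0.36 | common regulatory-region variant |
| target D′ (ε3 vs T) | 0.95 | "high LD, D′ > 0.9" regime |
| ε4–T haplotype freq | 0.002 | rare in-phase haplotype |
| OR per ε4 / ε4,4 / per ε2 | 3 / 12 / 0.5 | canonical AD risk profile |
| case fraction | 0.5 | case-control design |
| age | N(74, 8) truncated at 40 | AD study age range |
| cohorts | 5 (30/25/20/15/10%), profiles array/array/array/wgs/wes | mixed source types |
| provided error | 5% in one array cohort ("COH_A"), 0.5% elsewhere | one bad cohort at the top of the plausible direct-assay error range |
| imputation / sequencing error | 0.2% / 0.05% per variant | imputation good but imperfect; sequencing near-truth |
| duplicate rate | 3% | matches the scale of duplicate overlap in pooled collections |
| provided / rs439401 missingness | 3% / 5% | missing sources exist but are minority |

Haplotypes are drawn i.i.d. from a six-class distribution (ε allele ×
rs439401 allele) constructed so the ε3–T frequency hits the target D′, the
ε4–T class gets the rare in-phase mass, and the remaining T mass goes to
ε2–T; infeasible combinations raise `InfeasibleLDError`. Disease follows
the logistic risk model with the intercept solved numerically so the
emitted case fraction matches the configured value. rs439401 has **no**
effect on disease — the null is built in, so any downstream association is
attributable to genotype error by construction. Genotype errors use a
symmetric kernel (a wrong genotype is uniform over the remaining five
labels; a wrong site call uniform over the remaining two ALT counts),
because the sources being emulated report error existence, not error
structure. Duplicates are re-emitted under independent error draws into a
random cohort and linked by an explicit pair file, which stands in for
identity-by-descent duplicate detection (out of scope).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: genome-wide background variation and
realistic PC structure (PCs are standard-normal noise), ancestry admixture,
assay-specific asymmetric error profiles (e.g. protein-isoform biases that
confuse ε2 with ε3 specifically), relatedness beyond exact duplicates,
imputation-quality dependence on local haplotype rarity, and cohort-level
confounding of phenotype with genotyping platform.

## Problem sizes and numerics

The standard simulated study is 20,000–50,000 subjects; the reversal
experiment runs 200 replicates of 20,000 subjects; the null calibration
runs 1,000 replicates of 600; EM-oracle equivalence uses tables of n ≤ 50
with a 20,001-point profile grid; Monte-Carlo cross-checks use 10⁶ draws
per grid point. D′ recovery is asserted within ±0.02 at n = 50,000,
matching the sampling noise of the EM estimate at that size. All
randomness flows from a single seed through `numpy.random.SeedSequence`
children. Report formatting is deterministic (percentages to two decimals,
OR/CI to two decimals, P in scientific notation), so identical inputs and
seed produce byte-identical outputs.

## Known limitations

* The ε1 haplotype and promoter-region *APOE* nomenclature are out of
  scope; inputs containing true ε1 carriers will surface as inconsistency
  errors rather than being genotyped.
* WES-only subjects are excluded rather than partially genotyped; studies
  with large WES-only arms lose those subjects under both approaches.
* The approach-2 filter is intentionally conservative: when provided and
  imputed genotypes disagree, the imputed one is sometimes the correct one,
  and the default policy discards the subject anyway (the `impute` policy
  trades this for reliance on imputation).
* Wald inference degrades in strata with a handful of carriers; the engine
  reports separation instead of estimates there, and the crude OR with the
  0.5 correction is the fallback for descriptive purposes.
* PLINK bed/bim/fam and BGEN ingestion are extension points, not features;
  inputs enter as VCF + TSV.
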