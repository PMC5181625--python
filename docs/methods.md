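# Methods

## Model and scope

`famvar` models the discovery of a dominant disease allele in multiplex
families by whole-exome filtering. The genetic model is a single causal
variant per family, heterozygous in carriers, transmitted Mendelian-ly from
a carrier founder, expressed with incomplete penetrance p (default 0.85,
the middle of the 80–90% range typical for familial otosclerosis) and an
optional phenocopy rate (default 0). The pipeline consumes called,
annotated variants; alignment, variant calling and predictor scores
(PolyPhen-2, SIFT, GERP) are upstream inputs, never computed here.

Coordinates are 1-based VCF convention. Variant keys are post-normalization
(multi-allelic records split per alternate allele, shared suffix/prefix
trimmed). Splitting conserves alternate-allele observations: the call for
each split entry counts copies of that allele, so het + 2·hom-alt summed
over the split entries equals the original allele count. Trimming is
reference-free; left-shifting an indel through a repeat tract requires the
reference genome, which the pipeline deliberately does not take as input —
callers that emit shifted representations of the same indel will produce
distinct keys.

## Filter cascade

All threshold comparisons are strict (Q > 30, AF > 0.02) so boundary values
are testable. Site quality is the VCF QUAL field, the variant-level
interpretation of "quality score"; per-genotype GQ filtering is out of
scope. A missing genotype in a sequenced affected member fails the
"present in all affected" test (conservative: no-call artifacts are not
promoted). Variants absent from a frequency panel are retained — novelty is
evidence of rarity, not of commonness. The consequence filter keeps
missense, nonsense, frameshift/in-frame indels and the configured splice
set (donor, acceptor, splice region by default) in protein-coding genes,
plus anything in a microRNA gene; synonymous, UTR and deep-intronic changes
and other non-coding genes are dropped. "Deleterious by either" means
PolyPhen-2 category ∈ {possibly, probably damaging} OR SIFT < 0.05 — the
tools' published default cutoffs, since the workflow being reproduced names
the tools but not thresholds. In-house database matching is by exact key,
not position. Per-family exceptions (which panels apply, whether the
homozygosity exclusion and the unaffected-carrier filter apply) are
config-driven; `study_filter_config()` reproduces the motivating study's
pattern.

The prioritization score is an explicit, documented stand-in for a manual
judgement that cannot be formalized (one published input, "known biological
role", has no computable definition). Default weights are (1, 1, 1, 1);
GERP is clamped to [0, 6]; consequence severity ranks truncating (5) >
canonical splice (4) > protein-altering (3) > splice region (2) > other
(1); ties break on (chrom, pos, ref, alt). This is a reproducibility gap by
construction and all weights are configurable.

## Segregation and screening

Exclusion rules: (i) any genotyped affected member without the alternate
allele; (ii) strictly more than one genotyped unaffected member older than
the family onset age carrying it. One unaffected carrier is tolerated
because penetrance is incomplete; members of unknown affection and
unaffected members at or below onset age never cause exclusion. The onset
age is a per-family input (real pedigrees must supply it; the simulator
draws it uniformly on 25–40 years).

Cohort allele frequencies assume heterozygous carriers (one alternate
allele each): 100·c/(2n), rounded half-up to one decimal. This reproduces
the motivating study's printed percentages exactly (2/88 → 1.1, 1/88 → 0.6,
1/57 → 0.9) and is recorded per variant with its own n, because different
variants are typically genotyped in different cohort subsets. Carrier
burden is 100·k/n over patients; the function takes the denominator
explicitly since published burden figures can be ambiguous about it. All
user-facing rounding is half-up (via `Decimal`), not banker's rounding,
matching how such tables are printed.

The frequency-threshold derivation is expected_freq = prevalence ×
familial_fraction (one dominant allele per familial case under
homogeneity), filter threshold = safety_factor × expected_freq; the default
safety factor 10 reflects known locus heterogeneity.

## Expression statistics

All tests are equal-variance two-tailed Student's t (Welch behind a flag).
The pooled-variance implementation is written out rather than delegated
because the pipeline needs defined conventions at zero pooled variance
(equal means → p = 1; unequal → p → 0, flagged) and a single-case form for
one-patient groups; it agrees with the scipy reference implementation to
1e-10 on random inputs (tested).

Exon-group comparison uses samples, not exons, as replication units (exons
within a sample are not independent); the per-sample statistic is the mean
count over the exon group and counts are compared raw, mirroring an
average-read-count presentation. Library-size scaling is out of scope for
the default path.

ΔΔCt: technical replicates are averaged within sample before any
between-sample statistic (avoids pseudo-replication). ΔCt = mean target Ct −
mean reference Ct per sample; ΔΔCt subtracts the calibrator-group mean ΔCt,
so the calibrator fold is exactly 1. The 95% CI is computed on the ΔΔCt
scale and exponentiated (asymmetric on the fold scale) with the pooled
two-sample standard error against the calibrator, SE² = s_p²(1/n_g +
1/n_cal), df = n_g + n_cal − 2. The naive within-group SE was rejected
because it ignores calibrator-mean uncertainty and undercovers (≈89% at
n = 10 vs 10 instead of 95%). For a single-sample group the same pooled
formula reduces to the single-case t (SE = s_cal·√(1 + 1/n_cal),
df = n_cal − 1). With noiseless constructed input there is no residual
spread and the CI is reported as absent rather than a degenerate interval.

Luciferase: per-well activity firefly/renilla, normalized within each
independent experiment to that experiment's wild-type mean (so wild type is
exactly 1 per experiment, to machine precision), then pooled across
experiments; each construct's pooled values are tested against wild type's.

## Synthetic cohorts

The generators define the study conditions; their defaults are not tuning
knobs. Background allele frequencies are Beta(0.2, 5) truncated to
(0, 0.5], a rare-heavy spectrum appropriate for exome filtering. Site
qualities are Normal(53, 15) clipped at 0, placing ≈93.7% of variants above
the Q > 30 threshold, matching the discovery data's reported retention.
15% of background variants are novel (absent from panels and dbSNP); 95% of
known variants carry a dbSNP id; 20% of known variants sit in the in-house
database. Consequence, predictor-score and biotype mixes are fixed
plausible exome proportions (30% synonymous, 32% missense of which 40%
damaging, 20% intronic, ~1% truncating, ~3% non-coding genes including
microRNAs). The candidate list holds 494 genes; each family's causal gene
is drawn from it so the causal variant flows through both branches. The
default background size is 5000 variants, which keeps the full test suite
around a minute while preserving every distributional feature the filters
see; the generators scale to ~90 000 to mimic discovery-exome magnitudes
(counts are data-dependent and not reproduced exactly at any scale).

Families are three generations: a founder couple (one carrier), children
with married-in non-carrier spouses, grandchildren. Affection is sampled as
carrier → affected with probability p, non-carrier → affected with the
phenocopy rate; draws are retried until the template's sequencing quota
(n affected, n unaffected) is satisfiable. Sequenced unaffected members are
drawn from unaffected non-carriers: in the emulated study the causal
variant survived the unaffected-individual filter, which entails the
sequenced unaffected individual did not carry it. The written VCF contains
only sequenced individuals (as in real WES of selected family members); the
PED lists the whole family with ages and sequenced flags, plus `#onset_age`
lines. Truth (the causal key per family) is a separate JSON sidecar.

Background genotypes are drawn per individual under Hardy–Weinberg from the
variant's allele frequency. This deliberately ignores identity-by-descent
among relatives for background variants (the causal variant alone is
transmitted through the pedigree), so the simulator understates
between-relative sharing of common variants; consequently the
"present in all affected" stage removes more background than it would on
real families, and absolute trace counts should not be compared with real
data. What passing tests show is that the *rules* are implemented correctly
(oracle equivalence, recovery, reporting arithmetic), not that the
simulator reproduces real exome counts. Other unmodelled features: linkage
disequilibrium, haplotype structure, sequencing and annotation errors,
population stratification between panels.

Expression generators: counts are negative binomial with mean m and
dispersion k (variance m + k·m², k = 0 giving Poisson), downstream exons
(5–8) at baseline mean 300 versus 100 upstream — the short transcript is
the major stapes isoform — with the case-group fold (default 0.5) applied
to the downstream block only. Ct replicates are Normal with sd 0.2 (a
typical qPCR technical spread); the target mean sits ΔCt-baseline above the
reference assay, shifted by −log2(true fold); group sizes default to the
expression study's 5 controls, 75 patients, 1 mutation carrier, with true
folds 1/1.9 and 1/2.4. Luciferase plates default to 3 wells × 4 independent
experiments per construct with multiplicative lognormal noise (σ = 0.1 on
the ratio) and true activities {1.0, 0.5, 0.6, 1.5}.

Determinism: every generator is a pure function of (config, seed); the same
inputs give byte-identical files (tested).

## Numerical choices and degenerate inputs

- Rounding: half-up at the reported precision everywhere a number is
  user-facing.
- "Not applied" cascade stages are represented as absent (dash in the
  trace), never zero, and excluded from stage averages.
- Unannotated variants are excluded with a counted warning rather than
  silently dropped or passed through.
- Missing genotype calls: fail the shared-affected test, drop the sample
  from screening denominators, and mark a member "not genotyped" for
  segregation of that variant.
- Empty candidate list → empty candidate branch (warning, not error); empty
  in-house database → identity filter.
- Prioritization tie-break is lexicographic on the variant key, making
  ranks a deterministic permutation.

## Known limitations

Dominant model only (no recessive/compound-het or X-linked handling); no
kinship inference, phasing or formal linkage; no qPCR efficiency
correction (Pfaffl); no multiple-testing correction across expression
assays (none is applied in the emulated workflow); reference-free indel
normalization as discussed above; the prioritization score is a documented
stand-in for expert judgement.
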