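"""Pedigree segregation filtering and unrelated-cohort carrier screening.

Segregation, under the dominant model: a prioritized variant is excluded if
any genotyped affected family member lacks the alternate allele, or if it is
carried by strictly more than one genotyped unaffected member older than the
family's age of onset (one unaffected carrier is tolerated — penetrance is
incomplete). Members of unknown affection, and unaffected members at or below
the onset age, never cause exclusion.

Screening: carrier counts in an unrelated patient cohort are converted to
allele-frequency percentages under the all-heterozygous assumption
(100*c/(2n)), which is how the study reports them; the cohort size n is
recorded per variant because different variants were genotyped in different
subsets.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

from .rounding import round_half_up
from .types import (
    Affection,
    ConfigurationError,
    FamvarError,
    Genotype,
    GenotypeMatrix,
    Pedigree,
    ScreenResult,
    SegregationReason,
    SegregationVerdict,
    VariantKey,
)


def segregation_filter(
    key: VariantKey, genotypes: GenotypeMatrix, pedigree: Pedigree
) -> SegregationVerdict:
    """Segregation verdict for one variant in its discovery family.

    Only members present in the genotype matrix with a non-missing call are
    considered genotyped for this variant.
    """
    genotyped = [
        ind
        for ind in pedigree.individuals
        if ind.id in genotypes and genotypes.call(ind.id, key) is not Genotype.MISSING
    ]
    if not genotyped:
        raise ConfigurationError(
            f"no genotyped member of family {pedigree.family_id} for {key}"
        )
    for ind in genotyped:
        if ind.affection is Affection.AFFECTED and not genotypes.call(
            ind.id, key
        ).carries_alt:
            return SegregationVerdict(
                key=key, retained=False, reason=SegregationReason.ABSENT_IN_AFFECTED
            )
    unaffected_above_onset_carriers = sum(
        1
        for ind in genotyped
        if ind.affection is Affection.UNAFFECTED
        and ind.age is not None
        and ind.age > pedigree.onset_age
        and genotypes.call(ind.id, key).carries_alt
    )
    if unaffected_above_onset_carriers > 1:
        return SegregationVerdict(
            key=key,
            retained=False,
            reason=SegregationReason.MULTIPLE_UNAFFECTED_ABOVE_ONSET,
        )
    return SegregationVerdict(key=key, retained=True, reason=SegregationReason.NONE)


def apply_segregation(
    prioritized: Iterable[tuple[VariantKey, str]],
    families: Mapping[str, tuple[GenotypeMatrix, Pedigree]],
) -> tuple[list[VariantKey], dict[VariantKey, SegregationVerdict]]:
    """Judge each (variant key, discovery family) pair in its family.

    Returns the retained keys (input order) and all verdicts.
    """
    retained: list[VariantKey] = []
    verdicts: dict[VariantKey, SegregationVerdict] = {}
    for key, family_id in prioritized:
        if family_id not in families:
            raise FamvarError(f"variant {key} has no discovery family {family_id!r}")
        genotypes, pedigree = families[family_id]
        verdict = segregation_filter(key, genotypes, pedigree)
        verdicts[key] = verdict
        if verdict.retained:
            retained.append(key)
    return retained, verdicts


def screen_carriers(
    key: VariantKey,
    cohort_genotypes: Mapping[str, Genotype],
    panel_freqs: Optional[Mapping[str, float]] = None,
) -> ScreenResult:
    """Count carriers of one variant in an unrelated cohort.

    Samples with missing calls are excluded from the denominator n; a carrier
    is any sample with at least one alternate allele.
    """
    if not cohort_genotypes:
        raise FamvarError("screening cohort is empty")
    genotyped = {
        s: g for s, g in cohort_genotypes.items() if g is not Genotype.MISSING
    }
    if not genotyped:
        raise FamvarError(f"no genotyped sample in the cohort for {key}")
    carriers = tuple(sorted(s for s, g in genotyped.items() if g.carries_alt))
    n = len(genotyped)
    return ScreenResult(
        key=key,
        carrier_samples=carriers,
        carrier_count=len(carriers),
        n=n,
        allele_freq_percent=allele_frequency_percent(len(carriers), n),
        panel_freqs=dict(panel_freqs or {}),
    )


def allele_frequency_percent(c: int, n: int) -> float:
    """Cohort allele frequency as a percentage, one decimal, assuming each of
    the ``c`` carriers is heterozygous: round_half_up(100*c/(2n), 1)."""
    if n < 1:
        raise FamvarError("cohort size n must be at least 1")
    if not 0 <= c <= n:
        raise FamvarError("carrier count must lie in [0, n]")
    return round_half_up(100.0 * c / (2 * n), 1)


def carrier_burden_percent(k_carriers: int, n_patients: int) -> float:
    """Fraction of patients carrying any qualifying variant, as a percentage
    with one decimal (half-up)."""
    if n_patients < 1:
        raise FamvarError("patient count must be at least 1")
    if not 0 <= k_carriers <= n_patients:
        raise FamvarError("carrier count must lie in [0, n]")
    return round_half_up(100.0 * k_carriers / n_patients, 1)


def causal_frequency_threshold(
    prevalence: float, familial_fraction: float, safety_factor: float = 10.0
) -> tuple[float, float]:
    """Expected causal-allele frequency under locus homogeneity and the panel
    filter threshold derived from it.

    expected_freq = prevalence * familial_fraction (each familial case
    attributed to one dominant allele); filter_threshold = safety_factor *
    expected_freq, set loose deliberately because the disease is
    heterogeneous.
    """
    for name, value in (("prevalence", prevalence), ("familial_fraction", familial_fraction)):
        if not 0 < value <= 1:
            raise FamvarError(f"{name} must lie in (0, 1]")
    if safety_factor < 1:
        raise FamvarError("safety factor must be >= 1")
    expected = prevalence * familial_fraction
    return expected, safety_factor * expected
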