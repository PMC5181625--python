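"""The two-pipeline exome filter cascade.

Shared initial filters (site quality, presence in all sequenced affected
family members, panel allele frequency, consequence class, and — where a
family has a sequenced unaffected member — exclusion of variants that member
carries) are followed by two parallel branches: a *naive* branch keeping
predicted-deleterious variants absent from dbSNP, and a *candidate-gene*
branch keeping variants in a curated gene list. Both branches then exclude
homozygous-in-affected variants (where the dominant model is assumed) and
variants seen in an in-house exome database, are combined by union, and the
union is ranked by an explicit prioritization score.

Every filter is a pure subset operation on its input, so per-family retained
counts along a branch are non-increasing and each filter is idempotent.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .types import (
    AnnotatedVariant,
    BranchResult,
    ConfigurationError,
    Consequence,
    FilterConfig,
    FilterTrace,
    GeneBiotype,
    Genotype,
    GenotypeMatrix,
    MAX_SEVERITY_RANK,
    Pedigree,
    PrioritizationWeights,
    PrioritizedVariant,
    ReferenceSets,
    VariantKey,
    severity_rank,
)

PROTEIN_ALTERING = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT_INDEL,
        Consequence.INFRAME_INDEL,
    }
)


def study_filter_config(
    family_b: str = "FamilyB", family_d: str = "FamilyD"
) -> FilterConfig:
    """The per-family exception pattern of the discovery study: the
    second-listed family is the only one with a sequenced unaffected member
    (so the unaffected-carrier filter applies there, and the 500-exomes panel
    does not, its ethnicity being inapplicable), and the homozygosity
    exclusion is disabled for the two families from small communities."""
    return FilterConfig(
        panels_applied={family_b: ["1000G"]},
        apply_unaffected_filter={family_b: True},
        exclude_homozygous={family_b: False, family_d: False},
    )


def filter_quality(
    variants: Iterable[AnnotatedVariant], threshold: float
) -> list[AnnotatedVariant]:
    """Retain variants whose site quality is strictly greater than ``threshold``."""
    if threshold < 0:
        raise ConfigurationError("quality threshold must be non-negative")
    return [v for v in variants if v.variant.qual > threshold]


def filter_shared_affected(
    variants: Iterable[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
) -> list[AnnotatedVariant]:
    """Retain variants carried (het or hom-alt) by every sequenced affected
    member of the family. A missing genotype in any sequenced affected
    excludes the variant (conservative: no-calls are not promoted)."""
    affected = pedigree.sequenced_affected()
    if not affected:
        raise ConfigurationError(
            f"family {pedigree.family_id} has no sequenced affected member"
        )
    kept = []
    for v in variants:
        if all(genotypes.call(ind.id, v.key).carries_alt for ind in affected):
            kept.append(v)
    return kept


def filter_panel_frequency(
    variants: Iterable[AnnotatedVariant],
    panels: Sequence[str],
    threshold: float,
    known: Optional[set[str]] = None,
) -> list[AnnotatedVariant]:
    """Exclude variants whose allele frequency in ANY of the given panels is
    strictly greater than ``threshold``; variants absent from all applied
    panels (novel variants) are retained."""
    if not 0 < threshold < 1:
        raise ConfigurationError("panel frequency threshold must lie in (0,1)")
    if known is not None:
        unknown = [p for p in panels if p not in known]
        if unknown:
            raise ConfigurationError(f"unknown panel name(s): {unknown}")
    kept = []
    for v in variants:
        freqs = v.annotation.panel_freqs
        if any(freqs.get(panel, 0.0) > threshold for panel in panels):
            continue
        kept.append(v)
    return kept


def filter_synonymous(variants: Iterable[AnnotatedVariant]) -> list[AnnotatedVariant]:
    return [v for v in variants if v.annotation.consequence is not Consequence.SYNONYMOUS]


def filter_noncoding(
    variants: Iterable[AnnotatedVariant],
    splice_consequences: frozenset[Consequence] = FilterConfig().splice_consequences,
) -> list[AnnotatedVariant]:
    """Keep protein-altering or splice-affecting variants in protein-coding
    genes, and any variant in a microRNA gene; drop everything else (UTR and
    intronic changes outside the splice set, other non-coding genes)."""
    kept = []
    for v in variants:
        ann = v.annotation
        if ann.gene_biotype is GeneBiotype.MIRNA:
            kept.append(v)
        elif ann.gene_biotype is GeneBiotype.PROTEIN_CODING and (
            ann.consequence in PROTEIN_ALTERING or ann.consequence in splice_consequences
        ):
            kept.append(v)
    return kept


def filter_consequence(
    variants: Iterable[AnnotatedVariant],
    splice_consequences: frozenset[Consequence] = FilterConfig().splice_consequences,
) -> list[AnnotatedVariant]:
    """Composition of the synonymous and non-coding exclusions: keep
    non-synonymous, splice-affecting and indel variants in coding genes plus
    microRNA-gene variants."""
    return filter_noncoding(filter_synonymous(variants), splice_consequences)


def filter_unaffected_carriers(
    variants: Iterable[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
) -> list[AnnotatedVariant]:
    """Exclude variants carried by any sequenced unaffected family member.
    With no sequenced unaffected member this is the identity."""
    unaffected = [i for i in pedigree.sequenced_unaffected() if i.id in genotypes]
    if not unaffected:
        return list(variants)
    kept = []
    for v in variants:
        if any(genotypes.call(ind.id, v.key).carries_alt for ind in unaffected):
            continue
        kept.append(v)
    return kept


def _exclude_homozygous(
    variants: Iterable[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
) -> list[AnnotatedVariant]:
    """Exclude variants homozygous-alternate in any sequenced affected member
    (under a dominant model the causal allele is expected heterozygous)."""
    affected = pedigree.sequenced_affected()
    kept = []
    for v in variants:
        if any(
            genotypes.call(ind.id, v.key) is Genotype.HOM_ALT for ind in affected
        ):
            continue
        kept.append(v)
    return kept


def _absent_from_dbsnp(
    variant: AnnotatedVariant, reference_sets: ReferenceSets
) -> bool:
    if reference_sets.dbsnp_ids is not None:
        rsid = variant.variant.rsid
        return rsid is None or rsid not in reference_sets.dbsnp_ids
    return not variant.annotation.in_dbsnp and variant.variant.rsid is None


def branch_naive(
    variants: Sequence[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    reference_sets: ReferenceSets,
    config: FilterConfig,
) -> BranchResult:
    """Naive branch: predicted deleterious (PolyPhen damaging OR SIFT below
    cutoff), absent from dbSNP, then the shared homozygosity and in-house
    exclusions."""
    stages: list[tuple[str, int]] = []
    rule = config.deleterious_rule
    current = [v for v in variants if rule.is_deleterious(v.annotation)]
    stages.append(("deleterious", len(current)))
    current = [v for v in current if _absent_from_dbsnp(v, reference_sets)]
    stages.append(("absent_dbsnp", len(current)))
    if config.homozygous_excluded(pedigree.family_id):
        current = _exclude_homozygous(current, genotypes, pedigree)
        stages.append(("exclude_homozygous", len(current)))
    current = [v for v in current if v.key not in reference_sets.inhouse_db]
    stages.append(("exclude_inhouse", len(current)))
    return BranchResult(branch="naive", retained=current, stages=stages)


def branch_candidate(
    variants: Sequence[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    reference_sets: ReferenceSets,
    config: FilterConfig,
) -> BranchResult:
    """Candidate-gene branch: variants in the curated gene list, then the
    shared homozygosity and in-house exclusions."""
    stages: list[tuple[str, int]] = []
    current = [
        v for v in variants if v.annotation.gene_symbol in reference_sets.candidate_genes
    ]
    stages.append(("candidate_gene_list", len(current)))
    if config.homozygous_excluded(pedigree.family_id):
        current = _exclude_homozygous(current, genotypes, pedigree)
        stages.append(("exclude_homozygous", len(current)))
    current = [v for v in current if v.key not in reference_sets.inhouse_db]
    stages.append(("exclude_inhouse", len(current)))
    return BranchResult(branch="candidate", retained=current, stages=stages)


def combine_branches(
    naive: BranchResult, candidate: BranchResult
) -> list[AnnotatedVariant]:
    """Union of the two branches, deduplicated by variant key and returned in
    genomic key order."""
    by_key: dict[VariantKey, AnnotatedVariant] = {}
    for v in list(naive.retained) + list(candidate.retained):
        by_key.setdefault(v.key, v)
    return [by_key[k] for k in sorted(by_key)]


def prioritize(
    combined: Sequence[AnnotatedVariant],
    weights: PrioritizationWeights,
    candidate_genes: set[str],
) -> list[PrioritizedVariant]:
    """Rank the combined set by an explicit stand-in for the study's manual
    prioritization:

    score = w_gerp * clamp(GERP, 0, 6)/6
          + w_severity * severity_rank/5
          + w_stapes * [expressed in stapes]
          + w_candidate * [gene in candidate list]

    Descending score; ties broken by (chrom, pos, ref, alt).
    """
    scored = []
    for v in combined:
        ann = v.annotation
        terms = {
            "gerp": weights.gerp * min(max(ann.gerp, 0.0), 6.0) / 6.0,
            "severity": weights.severity * severity_rank(ann.consequence) / MAX_SEVERITY_RANK,
            "stapes": weights.stapes * float(ann.stapes_expressed),
            "candidate": weights.candidate * float(ann.gene_symbol in candidate_genes),
        }
        scored.append((sum(terms.values()), v.key, terms))
    scored.sort(key=lambda item: (-item[0], item[1]))
    return [
        PrioritizedVariant(key=key, score=score, rank=rank, terms=terms)
        for rank, (score, key, terms) in enumerate(scored, start=1)
    ]


def _observed_in_family(
    variants: Sequence[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
) -> list[AnnotatedVariant]:
    """Variants carried by at least one sequenced member of the family — the
    family's 'all variants' starting set."""
    members = [i for i in pedigree.sequenced_members() if i.id in genotypes]
    return [
        v
        for v in variants
        if any(genotypes.call(ind.id, v.key).carries_alt for ind in members)
    ]


class CascadeResult:
    """Per-family outcome of the full cascade plus the combined trace."""

    def __init__(self) -> None:
        self.final: dict[str, list[AnnotatedVariant]] = {}
        self.prioritized: dict[str, list[PrioritizedVariant]] = {}
        self.branches: dict[str, dict[str, BranchResult]] = {}
        self.trace: FilterTrace = FilterTrace()


def run_cascade(
    variants: Sequence[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    pedigrees: Sequence[Pedigree],
    reference_sets: ReferenceSets,
    config: FilterConfig,
) -> CascadeResult:
    """Run the whole cascade for every family and assemble the trace.

    Stage order per family: all variants observed in the family -> quality ->
    shared affected -> panel frequency (one stage per applied panel) ->
    exclude synonymous -> exclude non-coding -> exclude unaffected carriers
    (where configured) -> both branches -> combined union -> prioritization.
    Trace cells for stages not applied to a family are absent (dash), never
    zero.
    """
    from .io import known_panels

    result = CascadeResult()
    panels_known = known_panels(variants)
    all_panels: list[str] = []
    for ped in pedigrees:
        for p in config.panels_for(ped.family_id):
            if p not in all_panels:
                all_panels.append(p)

    per_family: dict[str, dict] = {}
    for ped in pedigrees:
        fam = ped.family_id
        rows: dict[str, Optional[int]] = {}
        current = _observed_in_family(variants, genotypes, ped)
        rows["all_variants"] = len(current)
        current = filter_quality(current, config.qual_threshold)
        rows["quality"] = len(current)
        current = filter_shared_affected(current, genotypes, ped)
        rows["shared_affected"] = len(current)
        applied = config.panels_for(fam)
        for panel in all_panels:
            if panel in applied:
                current = filter_panel_frequency(
                    current, [panel], config.panel_af_threshold, known=panels_known
                )
                rows[f"panel_{panel}"] = len(current)
            else:
                rows[f"panel_{panel}"] = None
        current = filter_synonymous(current)
        rows["exclude_synonymous"] = len(current)
        current = filter_noncoding(current, config.splice_consequences)
        rows["exclude_noncoding"] = len(current)
        if config.unaffected_filter_applied(fam):
            current = filter_unaffected_carriers(current, genotypes, ped)
            rows["exclude_unaffected_carriers"] = len(current)
        else:
            rows["exclude_unaffected_carriers"] = None

        naive = branch_naive(current, genotypes, ped, reference_sets, config)
        candidate = branch_candidate(current, genotypes, ped, reference_sets, config)
        combined = combine_branches(naive, candidate)
        ranked = prioritize(
            combined, config.prioritization_weights, reference_sets.candidate_genes
        )
        result.final[fam] = combined
        result.prioritized[fam] = ranked
        result.branches[fam] = {"naive": naive, "candidate": candidate}
        per_family[fam] = {
            "rows": rows,
            "naive": dict(naive.stages),
            "candidate": dict(candidate.stages),
            "combined": len(combined),
        }

    families = [ped.family_id for ped in pedigrees]
    shared_order = (
        ["all_variants", "quality", "shared_affected"]
        + [f"panel_{p}" for p in all_panels]
        + ["exclude_synonymous", "exclude_noncoding", "exclude_unaffected_carriers"]
    )
    for stage in shared_order:
        counts = {fam: per_family[fam]["rows"].get(stage) for fam in families}
        if all(c is None for c in counts.values()):
            continue
        result.trace.add(stage, counts)
    for branch, stage_order in (
        ("candidate", ["candidate_gene_list", "exclude_homozygous", "exclude_inhouse"]),
        ("naive", ["deleterious", "absent_dbsnp", "exclude_homozygous", "exclude_inhouse"]),
    ):
        for stage in stage_order:
            counts = {fam: per_family[fam][branch].get(stage) for fam in families}
            if all(c is None for c in counts.values()):
                continue
            result.trace.add(stage, counts, branch=branch)
    result.trace.add(
        "combined", {fam: per_family[fam]["combined"] for fam in families}
    )
    return result
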