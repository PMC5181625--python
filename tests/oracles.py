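"""Independent brute-force oracles: plain per-variant predicate evaluation,
written without reusing the package's filter functions, for equivalence
checks on small instances."""

from __future__ import annotations

from famvar.types import (
    Affection,
    AnnotatedVariant,
    Consequence,
    FilterConfig,
    GeneBiotype,
    Genotype,
    GenotypeMatrix,
    Pedigree,
    ReferenceSets,
)

_KEEP_CODING = {
    "missense",
    "nonsense",
    "frameshift_indel",
    "inframe_indel",
}


def _carries(matrix: GenotypeMatrix, sample: str, key) -> bool:
    return int(matrix.call(sample, key)) in (1, 2)


def brute_force_cascade_final(
    annotated: list[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    reference: ReferenceSets,
    config: FilterConfig,
) -> set:
    """Final combined set for one family as a flat conjunction/disjunction of
    every predicate, evaluated per variant."""
    fam = pedigree.family_id
    sequenced = [i.id for i in pedigree.individuals if i.sequenced and i.id in genotypes]
    affected = [
        i.id
        for i in pedigree.individuals
        if i.sequenced and i.affection is Affection.AFFECTED
    ]
    unaffected = [
        i.id
        for i in pedigree.individuals
        if i.sequenced and i.affection is Affection.UNAFFECTED and i.id in genotypes
    ]
    splice = {c.value for c in config.splice_consequences}
    final = set()
    for av in annotated:
        key = av.key
        ann = av.annotation
        if not any(_carries(genotypes, s, key) for s in sequenced):
            continue
        if not av.variant.qual > config.qual_threshold:
            continue
        if not all(_carries(genotypes, s, key) for s in affected):
            continue
        too_common = False
        for panel in config.panels_for(fam):
            freq = ann.panel_freqs.get(panel)
            if freq is not None and freq > config.panel_af_threshold:
                too_common = True
        if too_common:
            continue
        conseq = ann.consequence.value
        if conseq == "synonymous":
            continue
        if ann.gene_biotype is GeneBiotype.MIRNA:
            pass
        elif ann.gene_biotype is GeneBiotype.PROTEIN_CODING and (
            conseq in _KEEP_CODING or conseq in splice
        ):
            pass
        else:
            continue
        if config.unaffected_filter_applied(fam) and any(
            _carries(genotypes, s, key) for s in unaffected
        ):
            continue
        hom_ok = (not config.homozygous_excluded(fam)) or not any(
            int(genotypes.call(s, key)) == 2 for s in affected
        )
        not_inhouse = key not in reference.inhouse_db
        deleterious = (
            ann.polyphen_category in config.deleterious_rule.damaging_categories
            or ann.sift_score < config.deleterious_rule.sift_cutoff
        )
        if reference.dbsnp_ids is not None:
            absent_dbsnp = (
                av.variant.rsid is None or av.variant.rsid not in reference.dbsnp_ids
            )
        else:
            absent_dbsnp = not ann.in_dbsnp and av.variant.rsid is None
        naive = deleterious and absent_dbsnp and hom_ok and not_inhouse
        candidate = (
            ann.gene_symbol in reference.candidate_genes and hom_ok and not_inhouse
        )
        if naive or candidate:
            final.add(key)
    return final


def brute_force_segregation(key, genotypes: GenotypeMatrix, pedigree: Pedigree) -> str:
    """Verdict reason by direct enumeration over the family members."""
    genotyped = [
        ind
        for ind in pedigree.individuals
        if ind.id in genotypes and int(genotypes.call(ind.id, key)) != -1
    ]
    for ind in genotyped:
        if ind.affection is Affection.AFFECTED and int(genotypes.call(ind.id, key)) == 0:
            return "absent_in_affected"
    adult_carriers = 0
    for ind in genotyped:
        if (
            ind.affection is Affection.UNAFFECTED
            and ind.age is not None
            and ind.age > pedigree.onset_age
            and int(genotypes.call(ind.id, key)) in (1, 2)
        ):
            adult_carriers += 1
    if adult_carriers > 1:
        return "carried_by_multiple_unaffected_above_onset"
    return "none"
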