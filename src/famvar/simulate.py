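"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generators emulate the discovery study's inputs end to end: dominant
families in which a founder carries a causal variant transmitted Mendelian-ly
and expressed with incomplete penetrance (default 0.85, the middle of the
80-90% range reported for the disease); a rare-heavy background of exome
variants with panel allele frequencies, annotation categories and predictor
scores; an unrelated screening cohort with specified carrier counts;
negative-binomial per-exon read counts with a group effect confined to the
downstream exon block; replicate Ct values with normal noise; and
firefly/renilla plate readings with lognormal noise.

Every generator is a pure function of (config, seed): identical inputs give
byte-identical outputs. Truth records (which variant is causal in which
family) are returned separately and written as a JSON sidecar, never into the
VCF, so the pipeline cannot cheat.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .types import (
    Affection,
    AnnotatedVariant,
    Consequence,
    FamvarError,
    GeneBiotype,
    Genotype,
    GenotypeMatrix,
    Individual,
    Pedigree,
    PolyPhenCategory,
    ReferenceSets,
    SegregationReason,
    Variant,
    VariantAnnotation,
    VariantKey,
)

_BASES = np.array(list("ACGT"))

#: Consequence mix for background variants in protein-coding genes.
CODING_CONSEQUENCE_MIX: dict[Consequence, float] = {
    Consequence.SYNONYMOUS: 0.30,
    Consequence.MISSENSE: 0.32,
    Consequence.INTRONIC: 0.20,
    Consequence.UTR5: 0.03,
    Consequence.UTR3: 0.05,
    Consequence.SPLICE_REGION: 0.02,
    Consequence.SPLICE_DONOR: 0.005,
    Consequence.SPLICE_ACCEPTOR: 0.005,
    Consequence.NONSENSE: 0.01,
    Consequence.FRAMESHIFT_INDEL: 0.01,
    Consequence.INFRAME_INDEL: 0.01,
    Consequence.INTERGENIC: 0.04,
}


@dataclass(frozen=True)
class FamilyTemplate:
    """Three-generation family: a founder couple (one carrier), their
    children with married-in spouses, and grandchildren."""

    family_id: str
    n_children: int = 3
    n_grandchildren_per_child: int = 2
    n_sequenced_affected: int = 2
    n_sequenced_unaffected: int = 0


@dataclass(frozen=True)
class CausalSpec:
    """Annotation profile of the spiked causal variant: a rare damaging
    missense change in a stapes-expressed candidate gene, absent from the
    frequency panels, dbSNP and the in-house database."""

    consequence: Consequence = Consequence.MISSENSE
    polyphen_category: PolyPhenCategory = PolyPhenCategory.PROBABLY_DAMAGING
    polyphen_score: float = 0.97
    sift_score: float = 0.01
    gerp: float = 5.2
    stapes_expressed: bool = True
    qual: float = 99.0


@dataclass(frozen=True)
class ExonCountConfig:
    """Per-exon RNA-seq counts: downstream exons (5-8) dominate in controls
    (the short transcript is the major stapes isoform) and carry the disease
    effect in cases."""

    n_exons: int = 8
    upstream_mean: float = 100.0
    downstream_mean: float = 300.0
    downstream_exons: frozenset[int] = frozenset({5, 6, 7, 8})
    dispersion: float = 0.1
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"control": 4, "case": 8, "single_patient": 1}
    )
    #: fold applied to the downstream exon block, per non-control group
    downstream_fold: Mapping[str, float] = field(
        default_factory=lambda: {"case": 0.5, "single_patient": 0.4}
    )
    upstream_fold: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CtConfig:
    """RT-qPCR replicate Ct values; group sizes mirror the expression study
    (5 control stapes, 75 patient stapes, 1 mutation carrier) and the default
    true folds mirror its reported reductions (1/1.9 and 1/2.4)."""

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"control": 5, "case": 75, "single_patient": 1}
    )
    group_folds: Mapping[str, float] = field(
        default_factory=lambda: {
            "control": 1.0,
            "case": 1.0 / 1.9,
            "single_patient": 1.0 / 2.4,
        }
    )
    replicates: int = 3
    sd: float = 0.2
    ref_ct_mean: float = 12.0
    dct_baseline: float = 10.0
    target_assay: str = "target_downstream"


@dataclass(frozen=True)
class LuciferaseConfig:
    """Dual-luciferase plates: 3 wells in each of 4 independent experiments
    (12 repeats) per construct, multiplicative lognormal noise."""

    activities: Mapping[str, float] = field(
        default_factory=lambda: {
            "wildtype": 1.0,
            "mut_3bp_del": 0.5,
            "mut_441": 0.6,
            "mut_601": 1.5,
        }
    )
    wells_per_experiment: int = 3
    n_experiments: int = 4
    noise_sigma: float = 0.1
    renilla_mean: float = 1000.0
    renilla_sigma: float = 0.3
    firefly_base: float = 5.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the whole synthetic cohort."""

    seed: int = 0
    families: tuple[FamilyTemplate, ...] = (
        FamilyTemplate("FamilyA", n_sequenced_affected=2),
        FamilyTemplate("FamilyB", n_sequenced_affected=2, n_sequenced_unaffected=1),
        FamilyTemplate("FamilyC", n_sequenced_affected=2),
        FamilyTemplate("FamilyD", n_sequenced_affected=3),
    )
    penetrance: float = 0.85
    phenocopy_rate: float = 0.0
    n_background_variants: int = 5000
    af_beta_a: float = 0.2
    af_beta_b: float = 5.0
    af_max: float = 0.5
    novel_fraction: float = 0.15
    dbsnp_prob_known: float = 0.95
    inhouse_fraction: float = 0.2
    damaging_missense_fraction: float = 0.4
    stapes_expressed_fraction: float = 0.3
    qual_mean: float = 53.0
    qual_sd: float = 15.0
    missing_rate: float = 0.0
    n_genes: int = 2000
    candidate_list_size: int = 494
    panels: tuple[str, ...] = ("1000G", "500Exomes")
    screen_cohort_size: int = 88
    causal: CausalSpec = field(default_factory=CausalSpec)
    exon_counts: ExonCountConfig = field(default_factory=ExonCountConfig)
    ct: CtConfig = field(default_factory=CtConfig)
    luciferase: LuciferaseConfig = field(default_factory=LuciferaseConfig)

    def __post_init__(self) -> None:
        for name in ("penetrance", "phenocopy_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {value}")
        if self.n_background_variants < 1 or self.screen_cohort_size < 1:
            raise ValueError("cohort sizes must be >= 1")
        for tpl in self.families:
            if tpl.n_sequenced_affected < 1:
                raise ValueError(
                    f"family {tpl.family_id} requests no sequenced affected member"
                )


@dataclass
class SimulatedCohort:
    """In-memory result of :func:`simulate_families`."""

    config: SimulationConfig
    variants: list[Variant]
    annotation_table: pd.DataFrame
    genotypes: GenotypeMatrix
    pedigrees: list[Pedigree]
    reference_sets: ReferenceSets
    truth: dict[str, VariantKey]  # family id -> causal variant key
    carriers: dict[str, dict[str, bool]]  # family id -> member id -> carrier

    def annotated_variants(self) -> list[AnnotatedVariant]:
        from .io import attach_annotations

        annotated, flagged = attach_annotations(self.variants, self.annotation_table)
        if flagged:
            raise FamvarError("simulated cohort produced unannotated variants")
        return annotated


def _draw_alleles(rng: np.random.Generator, consequence: Consequence) -> tuple[str, str]:
    b1, b2 = rng.choice(_BASES, size=2, replace=False)
    if consequence is Consequence.FRAMESHIFT_INDEL:
        extra = "".join(rng.choice(_BASES, size=1))
        return (b1 + extra, b1) if rng.random() < 0.5 else (b1, b1 + extra)
    if consequence is Consequence.INFRAME_INDEL:
        extra = "".join(rng.choice(_BASES, size=3))
        return (b1 + extra, b1) if rng.random() < 0.5 else (b1, b1 + extra)
    return b1, b2


def _sample_family(
    template: FamilyTemplate,
    penetrance: float,
    phenocopy: float,
    onset_age: float,
    rng: np.random.Generator,
) -> tuple[Pedigree, dict[str, bool]]:
    """One draw of family structure, transmission and affection. May not
    satisfy the sequencing quota; the caller retries."""
    fam = template.family_id
    members: list[dict] = []
    carrier: dict[str, bool] = {}

    def add(mid, father, mother, sex, age, is_carrier):
        members.append(
            {"id": mid, "father": father, "mother": mother, "sex": sex, "age": age}
        )
        carrier[mid] = is_carrier

    f0, m0 = f"{fam}_F0", f"{fam}_M0"
    add(f0, None, None, "1", float(rng.normal(78, 3)), True)
    add(m0, None, None, "2", float(rng.normal(78, 3)), False)
    for ci in range(template.n_children):
        child = f"{fam}_C{ci + 1}"
        spouse = f"{fam}_S{ci + 1}"
        child_sex = "1" if ci % 2 == 0 else "2"
        add(child, f0, m0, child_sex, float(rng.normal(52, 3)), bool(rng.random() < 0.5))
        add(spouse, None, None, "2" if child_sex == "1" else "1",
            float(rng.normal(52, 3)), False)
        for gi in range(template.n_grandchildren_per_child):
            gkid = f"{fam}_G{ci + 1}_{gi + 1}"
            inherits = carrier[child] and rng.random() < 0.5
            father = child if child_sex == "1" else spouse
            mother = spouse if child_sex == "1" else child
            add(gkid, father, mother, "1" if gi % 2 == 0 else "2",
                float(rng.normal(26, 3)), inherits)

    affection: dict[str, Affection] = {}
    for m in members:
        p_affected = penetrance if carrier[m["id"]] else phenocopy
        affection[m["id"]] = (
            Affection.AFFECTED if rng.random() < p_affected else Affection.UNAFFECTED
        )

    affected_ids = [m["id"] for m in members if affection[m["id"]] is Affection.AFFECTED]
    unaffected_noncarriers = [
        m["id"]
        for m in members
        if affection[m["id"]] is Affection.UNAFFECTED and not carrier[m["id"]]
    ]
    if len(affected_ids) < template.n_sequenced_affected:
        raise _QuotaMiss()
    if len(unaffected_noncarriers) < template.n_sequenced_unaffected:
        raise _QuotaMiss()
    seq_affected = list(
        rng.choice(affected_ids, size=template.n_sequenced_affected, replace=False)
    )
    seq_unaffected = list(
        rng.choice(
            unaffected_noncarriers, size=template.n_sequenced_unaffected, replace=False
        )
        if template.n_sequenced_unaffected
        else []
    )
    sequenced = set(seq_affected) | set(seq_unaffected)
    individuals = [
        Individual(
            id=m["id"],
            father=m["father"],
            mother=m["mother"],
            sex=m["sex"],
            affection=affection[m["id"]],
            age=round(max(m["age"], 1.0), 1),
            sequenced=m["id"] in sequenced,
        )
        for m in members
    ]
    return Pedigree(family_id=fam, individuals=individuals, onset_age=onset_age), carrier


class _QuotaMiss(Exception):
    """Family draw cannot supply the requested sequenced members; redraw."""


def simulate_families(
    config: SimulationConfig, seed: Optional[int] = None
) -> SimulatedCohort:
    """Simulate the discovery cohort: pedigrees, genotypes of the sequenced
    members, the annotation table, the reference sets and the causal truth.

    The sequenced unaffected member (where a template requests one) is drawn
    from unaffected non-carriers, matching a study in which the causal variant
    survived the unaffected-individual filter.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_background_variants

    # --- gene universe and reference sets -------------------------------
    genes = np.array(
        [f"GENE{i:04d}" for i in range(int(config.n_genes * 0.95))]
        + [f"MIR{i:03d}" for i in range(int(config.n_genes * 0.02))]
        + [f"LINC{i:04d}" for i in range(config.n_genes - int(config.n_genes * 0.95) - int(config.n_genes * 0.02))]
    )
    coding_genes = np.array([g for g in genes if g.startswith("GENE")])
    candidate_genes = set(
        rng.choice(coding_genes, size=min(config.candidate_list_size, coding_genes.size),
                   replace=False)
    )
    causal_genes = rng.choice(sorted(candidate_genes), size=len(config.families),
                              replace=False)

    # --- background variants --------------------------------------------
    af = rng.beta(config.af_beta_a, config.af_beta_b, size=n)
    for _ in range(100):
        bad = (af <= 0) | (af > config.af_max)
        if not bad.any():
            break
        af[bad] = rng.beta(config.af_beta_a, config.af_beta_b, size=int(bad.sum()))
    af = np.clip(af, 1e-6, config.af_max)
    chroms = rng.integers(1, 23, size=n).astype(str)
    positions = rng.choice(200_000_000, size=n + len(config.families), replace=False) + 1
    causal_positions = positions[n:]
    qual = np.clip(rng.normal(config.qual_mean, config.qual_sd, size=n), 0.0, None)
    novel = rng.random(n) < config.novel_fraction
    in_dbsnp = (~novel) & (rng.random(n) < config.dbsnp_prob_known)
    inhouse_mask = (~novel) & (rng.random(n) < config.inhouse_fraction)
    gene_of = rng.choice(genes, size=n)
    stapes = rng.random(n) < config.stapes_expressed_fraction
    gerp = rng.uniform(-3.0, 6.0, size=n)

    mix_conseq = list(CODING_CONSEQUENCE_MIX)
    mix_probs = np.array([CODING_CONSEQUENCE_MIX[c] for c in mix_conseq])
    mix_probs = mix_probs / mix_probs.sum()
    coding_draw = rng.choice(len(mix_conseq), size=n, p=mix_probs)

    variants: list[Variant] = []
    rows: list[dict] = []
    inhouse_keys: set[VariantKey] = set()
    rsid_counter = 1_000_000
    for i in range(n):
        gene = str(gene_of[i])
        if gene.startswith("GENE"):
            biotype = GeneBiotype.PROTEIN_CODING
            consequence = mix_conseq[coding_draw[i]]
        else:
            biotype = GeneBiotype.MIRNA if gene.startswith("MIR") else GeneBiotype.OTHER_NONCODING
            consequence = Consequence.NONCODING_EXON
        ref, alt = _draw_alleles(rng, consequence)
        if consequence is Consequence.MISSENSE and rng.random() < config.damaging_missense_fraction:
            if rng.random() < 0.5:
                category = PolyPhenCategory.PROBABLY_DAMAGING
                pp_score = float(rng.uniform(0.9, 1.0))
            else:
                category = PolyPhenCategory.POSSIBLY_DAMAGING
                pp_score = float(rng.uniform(0.45, 0.9))
            sift = float(rng.uniform(0.0, 0.15))
        else:
            category = PolyPhenCategory.BENIGN
            pp_score = float(rng.uniform(0.0, 0.4))
            sift = float(rng.uniform(0.05, 1.0))
        rsid = None
        if in_dbsnp[i]:
            rsid = f"rs{rsid_counter}"
            rsid_counter += 1
        variant = Variant(
            chrom=str(chroms[i]),
            pos=int(positions[i]),
            ref=str(ref),
            alt=str(alt),
            qual=float(qual[i]),
            rsid=rsid,
        )
        variants.append(variant)
        row = {
            "chrom": variant.chrom,
            "pos": variant.pos,
            "ref": variant.ref,
            "alt": variant.alt,
            "gene_symbol": gene,
            "gene_biotype": biotype.value,
            "consequence": consequence.value,
            "polyphen_category": category.value,
            "polyphen_score": round(pp_score, 4),
            "sift_score": round(sift, 4),
            "gerp": round(float(gerp[i]), 3),
            "in_dbsnp": bool(in_dbsnp[i]),
            "stapes_expressed": bool(stapes[i]),
            "transcript_effects": "",
        }
        for panel in config.panels:
            row[f"af_{panel}"] = None if novel[i] else round(float(af[i]), 6)
        rows.append(row)
        if inhouse_mask[i]:
            inhouse_keys.add(variant.key)

    # --- families, transmission, causal variants ------------------------
    pedigrees: list[Pedigree] = []
    carriers: dict[str, dict[str, bool]] = {}
    truth: dict[str, VariantKey] = {}
    causal_variants: list[Variant] = []
    for fi, template in enumerate(config.families):
        onset = round(float(rng.uniform(25, 40)), 1)
        pedigree = None
        for _ in range(1000):
            try:
                pedigree, carrier = _sample_family(
                    template, config.penetrance, config.phenocopy_rate, onset, rng
                )
                break
            except _QuotaMiss:
                continue
        if pedigree is None:
            raise FamvarError(
                f"could not draw family {template.family_id} satisfying its "
                "sequencing quota in 1000 attempts"
            )
        pedigrees.append(pedigree)
        carriers[template.family_id] = carrier
        spec = config.causal
        ref, alt = _draw_alleles(rng, spec.consequence)
        causal = Variant(
            chrom="17",
            pos=int(causal_positions[fi]),
            ref=str(ref),
            alt=str(alt),
            qual=spec.qual,
            rsid=None,
        )
        causal_variants.append(causal)
        truth[template.family_id] = causal.key
        row = {
            "chrom": causal.chrom,
            "pos": causal.pos,
            "ref": causal.ref,
            "alt": causal.alt,
            "gene_symbol": str(causal_genes[fi]),
            "gene_biotype": GeneBiotype.PROTEIN_CODING.value,
            "consequence": spec.consequence.value,
            "polyphen_category": spec.polyphen_category.value,
            "polyphen_score": spec.polyphen_score,
            "sift_score": spec.sift_score,
            "gerp": spec.gerp,
            "in_dbsnp": False,
            "stapes_expressed": spec.stapes_expressed,
            "transcript_effects": "",
        }
        for panel in config.panels:
            row[f"af_{panel}"] = None
        rows.append(row)

    all_variants = variants + causal_variants
    order = sorted(
        range(len(all_variants)),
        key=lambda i: (int(all_variants[i].chrom), all_variants[i].pos),
    )
    all_variants = [all_variants[i] for i in order]
    table = pd.DataFrame([rows[i] for i in order])

    # --- genotypes of the sequenced samples -----------------------------
    samples: list[str] = []
    for pedigree in pedigrees:
        samples.extend(ind.id for ind in pedigree.sequenced_members())
    keys = [v.key for v in all_variants]
    key_index = {k: j for j, k in enumerate(keys)}
    af_by_key = {variants[i].key: af[i] for i in range(n)}
    calls = np.zeros((len(samples), len(keys)), dtype=np.int8)
    af_vector = np.array([af_by_key.get(k, 0.0) for k in keys])
    for si in range(len(samples)):
        calls[si] = rng.binomial(2, af_vector).astype(np.int8)
    carrier_of = {
        ind_id: is_carrier
        for fam, cmap in carriers.items()
        for ind_id, is_carrier in cmap.items()
    }
    for fam, causal_key in truth.items():
        j = key_index[causal_key]
        calls[:, j] = Genotype.HOM_REF.value
        for si, sample in enumerate(samples):
            if carrier_of.get(sample, False) and sample.startswith(fam + "_"):
                calls[si, j] = Genotype.HET.value
    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls[miss] = Genotype.MISSING.value

    matrix = GenotypeMatrix(samples, keys, calls)
    reference = ReferenceSets(
        candidate_genes=candidate_genes, inhouse_db=inhouse_keys, dbsnp_ids=None
    )
    return SimulatedCohort(
        config=config,
        variants=all_variants,
        annotation_table=table,
        genotypes=matrix,
        pedigrees=pedigrees,
        reference_sets=reference,
        truth=truth,
        carriers=carriers,
    )


# ----------------------------------------------------------------------
# File output


def write_cohort(cohort: SimulatedCohort, out_dir) -> dict[str, Path]:
    """Write the cohort in the formats the pipeline consumes: multi-sample
    VCF, PED (+age/sequenced extension columns and #onset_age lines),
    annotation TSV, candidate gene list, in-house DB TSV, and the truth JSON
    sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "ped": out / "cohort.ped",
        "annotations": out / "annotations.tsv",
        "genes": out / "candidate_genes.txt",
        "inhouse": out / "inhouse_db.tsv",
        "truth": out / "truth.json",
    }

    header = pysam.VariantHeader()
    for contig in sorted({v.chrom for v in cohort.variants}, key=int):
        header.contigs.add(contig, length=250_000_000)
    header.formats.add("GT", 1, "String", "Genotype")
    for sample in cohort.genotypes.samples:
        header.add_sample(sample)
    gt_tuples = {
        Genotype.HOM_REF.value: (0, 0),
        Genotype.HET.value: (0, 1),
        Genotype.HOM_ALT.value: (1, 1),
        Genotype.MISSING.value: (None, None),
    }
    with pysam.VariantFile(str(paths["vcf"]), "w", header=header) as vcf:
        for variant in cohort.variants:
            rec = vcf.new_record(
                contig=variant.chrom,
                start=variant.pos - 1,
                alleles=(variant.ref, variant.alt),
                qual=round(variant.qual, 2),
                id=variant.rsid,
            )
            column = cohort.genotypes.variant_calls(variant.key)
            for sample, code in zip(cohort.genotypes.samples, column):
                rec.samples[sample]["GT"] = gt_tuples[int(code)]
            vcf.write(rec)

    ped_lines = []
    for pedigree in cohort.pedigrees:
        ped_lines.append(f"#onset_age {pedigree.family_id} {pedigree.onset_age}")
        for ind in pedigree.individuals:
            aff = {"affected": "2", "unaffected": "1", "unknown": "0"}[ind.affection.value]
            ped_lines.append(
                "\t".join(
                    [
                        pedigree.family_id,
                        ind.id,
                        ind.father or "0",
                        ind.mother or "0",
                        ind.sex or "0",
                        aff,
                        "." if ind.age is None else str(ind.age),
                        "1" if ind.sequenced else "0",
                    ]
                )
            )
    paths["ped"].write_text("\n".join(ped_lines) + "\n")

    table = cohort.annotation_table.copy()
    table.to_csv(paths["annotations"], sep="\t", index=False)
    paths["genes"].write_text(
        "\n".join(sorted(cohort.reference_sets.candidate_genes)) + "\n"
    )
    inhouse_lines = [
        "\t".join([k[0], str(k[1]), k[2], k[3]])
        for k in sorted(cohort.reference_sets.inhouse_db)
    ]
    paths["inhouse"].write_text("\n".join(inhouse_lines) + ("\n" if inhouse_lines else ""))
    truth = {
        fam: {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3]}
        for fam, k in cohort.truth.items()
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return paths


# ----------------------------------------------------------------------
# Screening cohort


def simulate_screen_cohort(
    variant_specs: Sequence[tuple[VariantKey, int]],
    n: int,
    seed: int = 0,
    sample_prefix: str = "OTSC",
) -> pd.DataFrame:
    """Place exactly the specified number of heterozygous carriers of each
    variant at random among ``n`` unrelated samples. Long-format output:
    (sample, chrom, pos, ref, alt, genotype)."""
    rng = np.random.default_rng(seed)
    samples = [f"{sample_prefix}{i + 1:03d}" for i in range(n)]
    rows = []
    for key, carriers in variant_specs:
        if not 0 <= carriers <= n:
            raise FamvarError(f"carrier count {carriers} exceeds cohort size {n}")
        carrier_idx = set(rng.choice(n, size=carriers, replace=False)) if carriers else set()
        for i, sample in enumerate(samples):
            rows.append(
                {
                    "sample": sample,
                    "chrom": key[0],
                    "pos": key[1],
                    "ref": key[2],
                    "alt": key[3],
                    "genotype": "het" if i in carrier_idx else "hom_ref",
                }
            )
    return pd.DataFrame(rows)


def screen_genotype_map(
    cohort: pd.DataFrame, key: VariantKey
) -> dict[str, Genotype]:
    """Extract one variant's sample->genotype mapping from a long-format
    screening table."""
    sub = cohort[
        (cohort["chrom"].astype(str) == key[0])
        & (cohort["pos"].astype(int) == key[1])
        & (cohort["ref"] == key[2])
        & (cohort["alt"] == key[3])
    ]
    codes = {"hom_ref": Genotype.HOM_REF, "het": Genotype.HET,
             "hom_alt": Genotype.HOM_ALT, "missing": Genotype.MISSING}
    return {str(r["sample"]): codes[str(r["genotype"])] for _, r in sub.iterrows()}


# ----------------------------------------------------------------------
# Expression generators


def _negative_binomial(
    rng: np.random.Generator, mean: float, dispersion: float, size
) -> np.ndarray:
    """NB draw parameterized by mean m and dispersion k (var = m + k*m^2);
    k = 0 is the Poisson limit."""
    if mean <= 0:
        raise FamvarError(f"negative-binomial mean must be positive, got {mean}")
    if dispersion < 0:
        raise FamvarError("dispersion must be non-negative")
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    shape = 1.0 / dispersion
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p, size=size)


def simulate_exon_counts(
    config: ExonCountConfig = ExonCountConfig(), seed: int = 0
) -> pd.DataFrame:
    """Per-exon read counts: rows are samples (index = sample id), columns
    exon_1..exon_E plus 'group'."""
    rng = np.random.default_rng(seed)
    for group, size in config.group_sizes.items():
        if size < 1:
            raise FamvarError(f"group {group!r} has size {size}")
    records = []
    index = []
    for group in config.group_sizes:
        folds_down = config.downstream_fold.get(group, 1.0)
        folds_up = config.upstream_fold.get(group, 1.0)
        for si in range(config.group_sizes[group]):
            index.append(f"{group}_{si + 1}")
            row = {"group": group}
            for exon in range(1, config.n_exons + 1):
                if exon in config.downstream_exons:
                    mean = config.downstream_mean * folds_down
                else:
                    mean = config.upstream_mean * folds_up
                row[f"exon_{exon}"] = int(
                    _negative_binomial(rng, mean, config.dispersion, None)
                )
            records.append(row)
    frame = pd.DataFrame(records, index=index)
    return frame[["group"] + [f"exon_{e}" for e in range(1, config.n_exons + 1)]]


def simulate_ct_table(config: CtConfig = CtConfig(), seed: int = 0) -> pd.DataFrame:
    """Replicate Ct values: the endogenous-control Ct is Normal(ref_ct_mean,
    sd); the target Ct mean sits dct_baseline above it, shifted by -log2 of
    the group's true fold. Long format (sample, group, assay, replicate, ct)."""
    if config.sd < 0:
        raise FamvarError("Ct noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for group, size in config.group_sizes.items():
        fold = config.group_folds.get(group, 1.0)
        if fold <= 0:
            raise FamvarError(f"true fold for group {group!r} must be positive")
        target_mean = config.ref_ct_mean + config.dct_baseline - math.log2(fold)
        for si in range(size):
            sample = f"{group}_{si + 1}"
            for rep in range(1, config.replicates + 1):
                rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "assay": "reference",
                        "replicate": rep,
                        "ct": float(rng.normal(config.ref_ct_mean, config.sd)),
                    }
                )
            for rep in range(1, config.replicates + 1):
                rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "assay": config.target_assay,
                        "replicate": rep,
                        "ct": float(rng.normal(target_mean, config.sd)),
                    }
                )
    return pd.DataFrame(rows)


def simulate_luciferase(
    config: LuciferaseConfig = LuciferaseConfig(), seed: int = 0
) -> pd.DataFrame:
    """Firefly/renilla plate readings: renilla is lognormal per well, firefly
    is renilla x base x true activity x lognormal noise. Long format
    (construct, experiment, firefly, renilla)."""
    rng = np.random.default_rng(seed)
    rows = []
    for experiment in range(1, config.n_experiments + 1):
        for construct, activity in config.activities.items():
            if activity <= 0:
                raise FamvarError(f"true activity for {construct!r} must be positive")
            for _ in range(config.wells_per_experiment):
                renilla = float(
                    rng.lognormal(math.log(config.renilla_mean), config.renilla_sigma)
                )
                noise = float(rng.lognormal(0.0, config.noise_sigma))
                rows.append(
                    {
                        "construct": construct,
                        "experiment": experiment,
                        "firefly": renilla * config.firefly_base * activity * noise,
                        "renilla": renilla,
                    }
                )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Segregation fixture


@dataclass
class SegregationFixture:
    """23 candidate variants across four fully genotyped families with a
    constructed truth: which are retained and which violate each segregation
    rule."""

    families: dict[str, tuple[GenotypeMatrix, Pedigree]]
    assignments: list[tuple[VariantKey, str]]
    truth: dict[VariantKey, SegregationReason]


def make_segregation_fixture(seed: int = 0, onset_age: float = 30.0) -> SegregationFixture:
    """Build the 23-variant segregation fixture.

    Nine variants segregate (all affected carry; at most one unaffected
    member above the onset age carries), eight are absent from one affected
    member, and six are carried by two unaffected members above onset. The
    seed permutes the pattern-to-variant assignment only; the truth labels
    are returned alongside.
    """
    rng = np.random.default_rng(seed)
    patterns = (
        [SegregationReason.NONE] * 9
        + [SegregationReason.ABSENT_IN_AFFECTED] * 8
        + [SegregationReason.MULTIPLE_UNAFFECTED_ABOVE_ONSET] * 6
    )
    rng.shuffle(patterns)

    family_ids = ["F1", "F2", "F3", "F4"]
    member_spec = [
        ("A1", Affection.AFFECTED, 55.0),
        ("A2", Affection.AFFECTED, 50.0),
        ("A3", Affection.AFFECTED, 45.0),
        ("U1", Affection.UNAFFECTED, 60.0),
        ("U2", Affection.UNAFFECTED, 58.0),
        ("U3", Affection.UNAFFECTED, 20.0),  # below onset: never causes exclusion
    ]
    per_family_keys: dict[str, list[VariantKey]] = {f: [] for f in family_ids}
    assignments: list[tuple[VariantKey, str]] = []
    truth: dict[VariantKey, SegregationReason] = {}
    per_family_patterns: dict[str, list[SegregationReason]] = {f: [] for f in family_ids}
    # The two adult unaffected members are 60 and 58; with an onset age at or
    # above 58 at most one of them counts as "above onset", so the
    # unaffected-carrier pattern no longer violates the rule.
    multiple_effective = onset_age < 58.0
    for i, reason in enumerate(patterns):
        fam = family_ids[i % len(family_ids)]
        key = ("1", 1_000_000 + i * 10, "A", "G")
        per_family_keys[fam].append(key)
        per_family_patterns[fam].append(reason)
        assignments.append((key, fam))
        if reason is SegregationReason.MULTIPLE_UNAFFECTED_ABOVE_ONSET and not multiple_effective:
            truth[key] = SegregationReason.NONE
        else:
            truth[key] = reason

    HET, REF = Genotype.HET.value, Genotype.HOM_REF.value
    families: dict[str, tuple[GenotypeMatrix, Pedigree]] = {}
    for fam in family_ids:
        samples = [f"{fam}_{mid}" for mid, _, _ in member_spec]
        keys = per_family_keys[fam]
        calls = np.zeros((len(samples), len(keys)), dtype=np.int8)
        for j, reason in enumerate(per_family_patterns[fam]):
            if reason is SegregationReason.NONE:
                column = [HET, HET, HET, HET, REF, HET]  # one adult unaffected carrier
            elif reason is SegregationReason.ABSENT_IN_AFFECTED:
                column = [REF, HET, HET, REF, REF, REF]
            else:
                column = [HET, HET, HET, HET, HET, REF]  # two adult unaffected carriers
            calls[:, j] = column
        individuals = [
            Individual(
                id=f"{fam}_{mid}", affection=aff, age=age, sequenced=True
            )
            for mid, aff, age in member_spec
        ]
        pedigree = Pedigree(family_id=fam, individuals=individuals, onset_age=onset_age)
        families[fam] = (GenotypeMatrix(samples, keys, calls), pedigree)
    return SegregationFixture(families=families, assignments=assignments, truth=truth)
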