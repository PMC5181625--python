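"""Readers/writers for cohorts, annotations, reference sets and the trace.

VCF access goes through :mod:`pysam`; multi-allelic records are split into
biallelic entries and alleles are normalized by shared suffix/prefix trimming
before keys are formed. The pedigree file is 6-column PED with two extension
columns (current age in years, sequenced flag) accepted after column 6.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .rounding import round_half_up, round_half_up_int
from .types import (
    Affection,
    AnnotatedVariant,
    ConsistencyError,
    Consequence,
    FamvarError,
    FilterTrace,
    GeneBiotype,
    Genotype,
    GenotypeMatrix,
    Individual,
    ParseError,
    Pedigree,
    PolyPhenCategory,
    ReferenceSets,
    StageRecord,
    TranscriptEffect,
    Variant,
    VariantAnnotation,
    VariantKey,
)

logger = logging.getLogger(__name__)

TRACE_DASH = "-"

REQUIRED_ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene_symbol",
    "gene_biotype",
    "consequence",
    "polyphen_category",
    "polyphen_score",
    "sift_score",
    "gerp",
    "in_dbsnp",
    "stapes_expressed",
]

PANEL_COLUMN_PREFIX = "af_"


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then prefix from an allele pair.

    This is reference-free normalization: it makes keys canonical for
    redundantly padded records but cannot left-shift an indel through a
    repeat tract (that needs the reference sequence, which this pipeline
    deliberately does not take as input).
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _affection_from_ped(code: str, path: str, lineno: int) -> Affection:
    mapping = {"1": Affection.UNAFFECTED, "2": Affection.AFFECTED}
    if code in mapping:
        return mapping[code]
    if code in {"0", "-9", "."}:
        return Affection.UNKNOWN
    raise ParseError(f"{path}:{lineno}: unknown affection code {code!r}")


def load_pedigrees(ped_path) -> list[Pedigree]:
    """Parse a PED file (6 core columns + age + sequenced) into pedigrees.

    The onset age is given per family on a header-style line
    ``#onset_age <family> <years>``; families without one default to 30.
    """
    path = str(ped_path)
    families: dict[str, list[Individual]] = {}
    onset: dict[str, float] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                fields = line[1:].split()
                if fields and fields[0] == "onset_age":
                    if len(fields) != 3:
                        raise ParseError(f"{path}:{lineno}: malformed onset_age line")
                    onset[fields[1]] = float(fields[2])
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected >=6 PED columns, got {len(fields)}"
                )
            fam, iid, father, mother, sex, aff = fields[:6]
            age = None
            sequenced = False
            if len(fields) >= 7 and fields[6] not in {".", ""}:
                try:
                    age = float(fields[6])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad age {fields[6]!r}") from exc
            if len(fields) >= 8:
                sequenced = fields[7] in {"1", "yes", "true", "True"}
            families.setdefault(fam, []).append(
                Individual(
                    id=iid,
                    father=None if father in {"0", "."} else father,
                    mother=None if mother in {"0", "."} else mother,
                    sex=None if sex in {"0", "."} else sex,
                    affection=_affection_from_ped(aff, path, lineno),
                    age=age,
                    sequenced=sequenced,
                )
            )
    pedigrees = []
    for fam, members in families.items():
        try:
            pedigrees.append(
                Pedigree(family_id=fam, individuals=members, onset_age=onset.get(fam, 30.0))
            )
        except ValueError as exc:
            raise ParseError(f"{path}: family {fam}: {exc}") from exc
    return pedigrees


def _genotype_code(gt: Optional[tuple], alt_index: int) -> int:
    if gt is None or any(a is None for a in gt):
        return Genotype.MISSING.value
    count = sum(1 for a in gt if a == alt_index)
    return min(count, 2)


def load_cohort(vcf_path, ped_path) -> tuple[list[Variant], GenotypeMatrix, list[Pedigree]]:
    """Load a multi-sample VCF and its pedigree file.

    Multi-allelic records are split into one entry per alternate allele; the
    per-sample call for each split entry counts copies of that allele, so the
    total number of alternate-allele observations is conserved by splitting.
    """
    pedigrees = load_pedigrees(ped_path)
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"{vcf_path}: {exc}") from exc
    with vcf:
        samples = list(vcf.header.samples)
        sample_set = set(samples)
        for ped in pedigrees:
            for ind in ped.sequenced_members():
                if ind.id not in sample_set:
                    raise ConsistencyError(
                        f"sequenced pedigree member {ind.id!r} (family "
                        f"{ped.family_id}) is absent from the VCF sample header"
                    )
        variants: list[Variant] = []
        columns: list[np.ndarray] = []
        seen: set[VariantKey] = set()
        for rec in vcf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                if alt is None or alt in {".", "*", "<NON_REF>"}:
                    continue
                pos, ref, alt_n = normalize_alleles(rec.pos, rec.ref, alt)
                try:
                    variant = Variant(
                        chrom=str(rec.chrom),
                        pos=pos,
                        ref=ref,
                        alt=alt_n,
                        qual=float(rec.qual) if rec.qual is not None else 0.0,
                        rsid=None if rec.id in (None, ".") else rec.id,
                    )
                except ValueError as exc:
                    raise ParseError(f"{vcf_path}: record {rec.chrom}:{rec.pos}: {exc}")
                if variant.key in seen:
                    raise ParseError(
                        f"{vcf_path}: duplicate variant key {variant.key} after "
                        "normalization"
                    )
                seen.add(variant.key)
                variants.append(variant)
                columns.append(
                    np.array(
                        [
                            _genotype_code(rec.samples[s].get("GT"), ai)
                            for s in samples
                        ],
                        dtype=np.int8,
                    )
                )
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    matrix = GenotypeMatrix(samples, [v.key for v in variants], calls)
    return variants, matrix, pedigrees


def read_annotation_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: annotation table lacks required columns {missing}")
    return table


def _parse_transcript_effects(cell) -> tuple[TranscriptEffect, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return ()
    effects = []
    for chunk in str(cell).split(";"):
        parts = chunk.split("|")
        if len(parts) < 2:
            raise ParseError(f"malformed transcript effect {chunk!r}")
        effects.append(
            TranscriptEffect(
                transcript_id=parts[0],
                consequence=Consequence(parts[1]),
                hgvs=parts[2] if len(parts) > 2 else "",
            )
        )
    return tuple(effects)


def _row_to_annotation(row: pd.Series, panel_columns: Sequence[str]) -> VariantAnnotation:
    panel_freqs = {}
    for col in panel_columns:
        value = row[col]
        if value is not None and not pd.isna(value):
            panel_freqs[col[len(PANEL_COLUMN_PREFIX):]] = float(value)
    return VariantAnnotation(
        gene_symbol=str(row["gene_symbol"]),
        gene_biotype=GeneBiotype(row["gene_biotype"]),
        consequence=Consequence(row["consequence"]),
        polyphen_category=PolyPhenCategory(row["polyphen_category"]),
        polyphen_score=float(row["polyphen_score"]),
        sift_score=float(row["sift_score"]),
        gerp=float(row["gerp"]),
        panel_freqs=panel_freqs,
        in_dbsnp=bool(row["in_dbsnp"]) if not isinstance(row["in_dbsnp"], str)
        else row["in_dbsnp"].lower() in {"1", "true", "yes"},
        transcript_effects=_parse_transcript_effects(row.get("transcript_effects")),
        stapes_expressed=bool(row["stapes_expressed"])
        if not isinstance(row["stapes_expressed"], str)
        else row["stapes_expressed"].lower() in {"1", "true", "yes"},
    )


def attach_annotations(
    variants: Iterable[Variant],
    annotation_table: pd.DataFrame,
    drop_unannotated: bool = True,
) -> tuple[list[AnnotatedVariant], list[Variant]]:
    """Join variants to their annotation rows by (chrom, pos, ref, alt).

    Returns (annotated variants, unannotated variants). Unannotated variants
    are excluded from the annotated list (with a logged count) unless
    ``drop_unannotated`` is false, in which case their presence still only
    shows up in the second return value.
    """
    keys = list(
        zip(
            annotation_table["chrom"].astype(str),
            annotation_table["pos"].astype(int),
            annotation_table["ref"].astype(str),
            annotation_table["alt"].astype(str),
        )
    )
    if len(set(keys)) != len(keys):
        dupes = pd.Series(keys)
        dupe = dupes[dupes.duplicated()].iloc[0]
        raise ParseError(f"annotation table has duplicate key {dupe}")
    panel_columns = [
        c for c in annotation_table.columns if c.startswith(PANEL_COLUMN_PREFIX)
    ]
    by_key = {
        key: _row_to_annotation(annotation_table.iloc[i], panel_columns)
        for i, key in enumerate(keys)
    }
    annotated: list[AnnotatedVariant] = []
    flagged: list[Variant] = []
    for variant in variants:
        annotation = by_key.get(variant.key)
        if annotation is None:
            flagged.append(variant)
        else:
            annotated.append(AnnotatedVariant(variant, annotation))
    if flagged:
        logger.warning(
            "%d variant(s) had no annotation row and were excluded", len(flagged)
        )
    return annotated, flagged


def known_panels(annotated: Iterable[AnnotatedVariant]) -> set[str]:
    """Panel names observed anywhere in the annotation set."""
    names: set[str] = set()
    for av in annotated:
        names.update(av.annotation.panel_freqs)
    return names


def load_reference_sets(
    gene_list_path=None, inhouse_path=None, dbsnp_path=None
) -> ReferenceSets:
    """Load the candidate gene list, the in-house exome variant database, and
    (optionally) a dbSNP id set that overrides annotation ``in_dbsnp`` flags."""
    genes: set[str] = set()
    if gene_list_path is not None:
        with open(gene_list_path) as handle:
            genes = {line.strip() for line in handle if line.strip()}
        if not genes:
            logger.warning("candidate gene list %s is empty", gene_list_path)
        else:
            logger.info("loaded %d candidate genes", len(genes))
    inhouse: set[VariantKey] = set()
    if inhouse_path is not None:
        with open(inhouse_path) as handle:
            for lineno, raw in enumerate(handle, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 4:
                    raise ParseError(
                        f"{inhouse_path}:{lineno}: expected chrom,pos,ref,alt"
                    )
                inhouse.add((fields[0], int(fields[1]), fields[2], fields[3]))
        logger.info("loaded %d in-house variant keys", len(inhouse))
    dbsnp: Optional[set[str]] = None
    if dbsnp_path is not None:
        with open(dbsnp_path) as handle:
            dbsnp = {line.strip() for line in handle if line.strip()}
    return ReferenceSets(candidate_genes=genes, inhouse_db=inhouse, dbsnp_ids=dbsnp)


def trace_average(per_family_counts: Iterable[Optional[int]]) -> int:
    """Arithmetic mean over families where the stage was applied, rounded
    half-up to the nearest integer. ``None`` marks a not-applied stage and is
    excluded from the mean."""
    counts = [c for c in per_family_counts if c is not None]
    if not counts:
        raise FamvarError("stage undefined: no family has a count")
    return round_half_up_int(sum(counts) / len(counts))


def trace_retention_percent(trace: FilterTrace, stage: str, base_stage: str) -> float:
    """100 x (summed counts at ``stage``) / (summed counts at ``base_stage``),
    half-up to one decimal."""
    num = sum(c for c in trace.record(stage).counts.values() if c is not None)
    den = sum(c for c in trace.record(base_stage).counts.values() if c is not None)
    if den == 0:
        raise FamvarError(f"base stage {base_stage!r} has zero total count")
    return round_half_up(100.0 * num / den, 1)


def write_trace(trace: FilterTrace, path) -> None:
    """Write the cascade trace as a TSV mirroring the study's summary table:
    one row per stage, one column per family plus the rounded average; dashes
    mark stages not applied to a family. Byte-stable for a fixed trace."""
    if not trace.records:
        raise FamvarError("cannot write an empty trace")
    families = trace.families()
    lines = ["\t".join(["stage", "branch"] + families + ["average"])]
    for rec in trace.records:
        cells = [rec.stage, rec.branch or TRACE_DASH]
        for fam in families:
            count = rec.counts.get(fam)
            cells.append(TRACE_DASH if count is None else str(count))
        cells.append(str(trace_average(rec.counts.get(f) for f in families)))
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace(path) -> FilterTrace:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty trace file")
    header = lines[0].split("\t")
    families = header[2:-1]
    trace = FilterTrace()
    for raw in lines[1:]:
        cells = raw.split("\t")
        counts = {
            fam: (None if cell == TRACE_DASH else int(cell))
            for fam, cell in zip(families, cells[2 : 2 + len(families)])
        }
        trace.add(cells[0], counts, branch=None if cells[1] == TRACE_DASH else cells[1])
    return trace
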