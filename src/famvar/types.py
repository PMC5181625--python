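"""Domain model for family-based rare-variant prioritization.

The types here mirror the artefacts of a dominant-disease exome study:
normalized variants with site quality, functional annotation with predictor
scores and panel allele frequencies, a sample-by-variant genotype matrix,
pedigrees with affection status and a family age of onset, curated reference
sets (candidate genes, in-house exomes, dbSNP), the filter configuration that
encodes per-family exceptions, and the cascade trace of retained-variant
counts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

VariantKey = tuple[str, int, str, str]

_ALLELE_CHARS = set("ACGT")


class FamvarError(Exception):
    """Base class for package errors."""


class ParseError(FamvarError):
    """Malformed input record; the message names the file and line."""


class ConsistencyError(FamvarError):
    """Inputs that individually parse but contradict each other."""


class ConfigurationError(FamvarError):
    """A filter or pedigree precondition is violated."""


class Genotype(enum.IntEnum):
    """Diallelic genotype call states used throughout the pipeline."""

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT)


class Affection(str, enum.Enum):
    UNAFFECTED = "unaffected"
    AFFECTED = "affected"
    UNKNOWN = "unknown"


class GeneBiotype(str, enum.Enum):
    PROTEIN_CODING = "protein_coding"
    MIRNA = "miRNA"
    OTHER_NONCODING = "other_noncoding"


class Consequence(str, enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SPLICE_DONOR = "splice_donor"
    SPLICE_ACCEPTOR = "splice_acceptor"
    SPLICE_REGION = "splice_region"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    UTR5 = "utr5"
    UTR3 = "utr3"
    INTRONIC = "intronic"
    NONCODING_EXON = "noncoding_exon"
    INTERGENIC = "intergenic"


#: Consequence severity used by prioritization: protein-truncating first,
#: then canonical splice sites, then protein-altering, then splice region.
SEVERITY_RANK: dict[Consequence, int] = {
    Consequence.NONSENSE: 5,
    Consequence.FRAMESHIFT_INDEL: 5,
    Consequence.SPLICE_DONOR: 4,
    Consequence.SPLICE_ACCEPTOR: 4,
    Consequence.MISSENSE: 3,
    Consequence.INFRAME_INDEL: 3,
    Consequence.SPLICE_REGION: 2,
}
MAX_SEVERITY_RANK = 5


def severity_rank(consequence: Consequence) -> int:
    return SEVERITY_RANK.get(consequence, 1)


class PolyPhenCategory(str, enum.Enum):
    BENIGN = "benign"
    POSSIBLY_DAMAGING = "possibly_damaging"
    PROBABLY_DAMAGING = "probably_damaging"


@dataclass(frozen=True)
class Variant:
    """A normalized biallelic variant with its site quality.

    Coordinates are 1-based (VCF convention); ``ref``/``alt`` are the
    post-normalization alleles (multi-allelic records split, shared
    prefix/suffix trimmed).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float = 0.0
    rsid: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _ALLELE_CHARS:
                raise ValueError(
                    f"allele {allele!r} at {self.chrom}:{self.pos} is not a "
                    "non-empty ACGT string"
                )
        if self.qual < 0:
            raise ValueError(f"site quality must be non-negative, got {self.qual}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class TranscriptEffect:
    transcript_id: str
    consequence: Consequence
    hgvs: str = ""


@dataclass(frozen=True)
class VariantAnnotation:
    """Functional annotation consumed (never computed) by the cascade."""

    gene_symbol: str
    gene_biotype: GeneBiotype
    consequence: Consequence
    polyphen_category: PolyPhenCategory
    polyphen_score: float
    sift_score: float
    gerp: float
    panel_freqs: Mapping[str, float] = field(default_factory=dict)
    in_dbsnp: bool = False
    transcript_effects: tuple[TranscriptEffect, ...] = ()
    stapes_expressed: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.polyphen_score <= 1.0:
            raise ValueError(f"polyphen score {self.polyphen_score} outside [0,1]")
        if not 0.0 <= self.sift_score <= 1.0:
            raise ValueError(f"SIFT score {self.sift_score} outside [0,1]")
        for panel, af in self.panel_freqs.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency {af} in panel {panel} outside [0,1]")


@dataclass(frozen=True)
class AnnotatedVariant:
    variant: Variant
    annotation: VariantAnnotation

    @property
    def key(self) -> VariantKey:
        return self.variant.key

    @property
    def gene(self) -> str:
        return self.annotation.gene_symbol


class GenotypeMatrix:
    """Sample-by-variant genotype calls stored as an int8 matrix.

    Rows follow ``samples``, columns follow ``variant_keys``; cell values are
    :class:`Genotype` codes.
    """

    def __init__(
        self,
        samples: Sequence[str],
        variant_keys: Sequence[VariantKey],
        calls: np.ndarray,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(variant_keys)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(samples)} samples x {len(variant_keys)} variants"
            )
        valid = np.isin(calls, [g.value for g in Genotype])
        if not valid.all():
            raise ValueError("genotype matrix contains values outside the call states")
        self.samples = list(samples)
        self.variant_keys = list(variant_keys)
        self.calls = calls
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._variant_index = {k: j for j, k in enumerate(self.variant_keys)}
        if len(self._variant_index) != len(self.variant_keys):
            raise ValueError("variant keys are not unique within the call set")
        if len(self._sample_index) != len(self.samples):
            raise ValueError("sample ids are not unique")

    def __contains__(self, sample: str) -> bool:
        return sample in self._sample_index

    def has_variant(self, key: VariantKey) -> bool:
        return key in self._variant_index

    def call(self, sample: str, key: VariantKey) -> Genotype:
        return Genotype(self.calls[self._sample_index[sample], self._variant_index[key]])

    def sample_calls(self, sample: str) -> np.ndarray:
        return self.calls[self._sample_index[sample]]

    def variant_calls(self, key: VariantKey) -> np.ndarray:
        return self.calls[:, self._variant_index[key]]

    def carriers(self, key: VariantKey) -> list[str]:
        col = self.variant_calls(key)
        return [s for s, g in zip(self.samples, col) if Genotype(g).carries_alt]


@dataclass(frozen=True)
class Individual:
    id: str
    father: Optional[str] = None
    mother: Optional[str] = None
    sex: Optional[str] = None
    affection: Affection = Affection.UNKNOWN
    age: Optional[float] = None
    sequenced: bool = False


@dataclass
class Pedigree:
    """One family: members with affection status, ages and sequenced flags,
    plus the family-specific age of onset used by segregation analysis."""

    family_id: str
    individuals: list[Individual]
    onset_age: float

    def __post_init__(self) -> None:
        if self.onset_age <= 0:
            raise ValueError(f"onset age must be positive, got {self.onset_age}")
        ids = {ind.id for ind in self.individuals}
        if len(ids) != len(self.individuals):
            raise ValueError(f"duplicate individual ids in family {self.family_id}")
        for ind in self.individuals:
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in ids:
                    raise ValueError(
                        f"{ind.id} in family {self.family_id} references parent "
                        f"{parent} absent from the family"
                    )
        if not any(ind.affection is Affection.AFFECTED for ind in self.individuals):
            raise ValueError(f"family {self.family_id} has no affected member")

    def member(self, individual_id: str) -> Individual:
        for ind in self.individuals:
            if ind.id == individual_id:
                return ind
        raise KeyError(individual_id)

    def affected(self) -> list[Individual]:
        return [i for i in self.individuals if i.affection is Affection.AFFECTED]

    def unaffected(self) -> list[Individual]:
        return [i for i in self.individuals if i.affection is Affection.UNAFFECTED]

    def sequenced_affected(self) -> list[Individual]:
        return [i for i in self.affected() if i.sequenced]

    def sequenced_unaffected(self) -> list[Individual]:
        return [i for i in self.unaffected() if i.sequenced]

    def sequenced_members(self) -> list[Individual]:
        return [i for i in self.individuals if i.sequenced]


@dataclass
class ReferenceSets:
    """Curated sets the cascade filters against."""

    candidate_genes: set[str] = field(default_factory=set)
    inhouse_db: set[VariantKey] = field(default_factory=set)
    dbsnp_ids: Optional[set[str]] = None


@dataclass(frozen=True)
class DeleteriousRule:
    """'Deleterious by either' predictor rule: PolyPhen category in the
    damaging set OR SIFT strictly below the cutoff (tool defaults)."""

    damaging_categories: frozenset[PolyPhenCategory] = frozenset(
        {PolyPhenCategory.POSSIBLY_DAMAGING, PolyPhenCategory.PROBABLY_DAMAGING}
    )
    sift_cutoff: float = 0.05

    def is_deleterious(self, annotation: VariantAnnotation) -> bool:
        return (
            annotation.polyphen_category in self.damaging_categories
            or annotation.sift_score < self.sift_cutoff
        )


@dataclass(frozen=True)
class PrioritizationWeights:
    gerp: float = 1.0
    severity: float = 1.0
    stapes: float = 1.0
    candidate: float = 1.0

    def __post_init__(self) -> None:
        if min(self.gerp, self.severity, self.stapes, self.candidate) < 0:
            raise ValueError("prioritization weights must be non-negative")


DEFAULT_SPLICE_CONSEQUENCES = frozenset(
    {Consequence.SPLICE_DONOR, Consequence.SPLICE_ACCEPTOR, Consequence.SPLICE_REGION}
)


@dataclass
class FilterConfig:
    """Cascade configuration, including the per-family exceptions.

    ``panels_applied`` maps family id to the ordered list of frequency panels
    applied to that family; families not listed get ``default_panels``.
    ``exclude_homozygous`` / ``apply_unaffected_filter`` likewise override the
    defaults per family (the study disabled the homozygosity exclusion in two
    families from small communities, and applied the unaffected-individual
    filter only in the one family with a sequenced unaffected member).
    """

    qual_threshold: float = 30.0
    panel_af_threshold: float = 0.02
    default_panels: list[str] = field(default_factory=lambda: ["1000G", "500Exomes"])
    panels_applied: dict[str, list[str]] = field(default_factory=dict)
    exclude_homozygous: dict[str, bool] = field(default_factory=dict)
    default_exclude_homozygous: bool = True
    apply_unaffected_filter: dict[str, bool] = field(default_factory=dict)
    default_apply_unaffected_filter: bool = False
    splice_consequences: frozenset[Consequence] = DEFAULT_SPLICE_CONSEQUENCES
    deleterious_rule: DeleteriousRule = field(default_factory=DeleteriousRule)
    prioritization_weights: PrioritizationWeights = field(
        default_factory=PrioritizationWeights
    )

    def __post_init__(self) -> None:
        if self.qual_threshold < 0:
            raise ValueError("quality threshold must be non-negative")
        if not 0 < self.panel_af_threshold < 1:
            raise ValueError("panel allele-frequency threshold must lie in (0,1)")

    def panels_for(self, family_id: str) -> list[str]:
        return list(self.panels_applied.get(family_id, self.default_panels))

    def homozygous_excluded(self, family_id: str) -> bool:
        return self.exclude_homozygous.get(family_id, self.default_exclude_homozygous)

    def unaffected_filter_applied(self, family_id: str) -> bool:
        return self.apply_unaffected_filter.get(
            family_id, self.default_apply_unaffected_filter
        )

    @classmethod
    def from_dict(cls, data: Mapping) -> "FilterConfig":
        kwargs: dict = {}
        simple = {
            "qual_threshold",
            "panel_af_threshold",
            "default_panels",
            "panels_applied",
            "exclude_homozygous",
            "default_exclude_homozygous",
            "apply_unaffected_filter",
            "default_apply_unaffected_filter",
        }
        for key in simple & set(data):
            kwargs[key] = data[key]
        if "splice_consequences" in data:
            kwargs["splice_consequences"] = frozenset(
                Consequence(c) for c in data["splice_consequences"]
            )
        if "deleterious_rule" in data:
            rule = data["deleterious_rule"]
            kwargs["deleterious_rule"] = DeleteriousRule(
                damaging_categories=frozenset(
                    PolyPhenCategory(c)
                    for c in rule.get(
                        "damaging_categories", ["possibly_damaging", "probably_damaging"]
                    )
                ),
                sift_cutoff=rule.get("sift_cutoff", 0.05),
            )
        if "prioritization_weights" in data:
            kwargs["prioritization_weights"] = PrioritizationWeights(
                **data["prioritization_weights"]
            )
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        import yaml

        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)


@dataclass
class StageRecord:
    """One trace row: retained counts per family after a filter stage.

    ``None`` marks a stage not applied to that family (printed as a dash),
    never as zero.
    """

    stage: str
    counts: dict[str, Optional[int]]
    branch: Optional[str] = None


@dataclass
class FilterTrace:
    """Ordered per-stage retained-variant counts per family."""

    records: list[StageRecord] = field(default_factory=list)

    def add(
        self,
        stage: str,
        counts: Mapping[str, Optional[int]],
        branch: Optional[str] = None,
    ) -> None:
        self.records.append(StageRecord(stage, dict(counts), branch))

    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for record in self.records:
            for fam in record.counts:
                seen.setdefault(fam)
        return list(seen)

    def record(self, stage: str, branch: Optional[str] = None) -> StageRecord:
        for rec in self.records:
            if rec.stage == stage and rec.branch == branch:
                return rec
        raise KeyError((stage, branch))


@dataclass
class BranchResult:
    """Outcome of one filtering branch for one family."""

    branch: str
    retained: list[AnnotatedVariant]
    stages: list[tuple[str, int]]

    @property
    def retained_keys(self) -> set[VariantKey]:
        return {v.key for v in self.retained}


@dataclass(frozen=True)
class PrioritizedVariant:
    key: VariantKey
    score: float
    rank: int
    terms: Mapping[str, float]


class SegregationReason(str, enum.Enum):
    NONE = "none"
    ABSENT_IN_AFFECTED = "absent_in_affected"
    MULTIPLE_UNAFFECTED_ABOVE_ONSET = "carried_by_multiple_unaffected_above_onset"


@dataclass(frozen=True)
class SegregationVerdict:
    key: VariantKey
    retained: bool
    reason: SegregationReason

    def __post_init__(self) -> None:
        if self.retained != (self.reason is SegregationReason.NONE):
            raise ValueError("reason must be 'none' exactly when retained")


@dataclass(frozen=True)
class ScreenResult:
    """Carrier count and allele frequency of one variant in a screening
    cohort; allele frequency assumes heterozygous carriers (one alternate
    allele each), i.e. 100*c/(2n)."""

    key: VariantKey
    carrier_samples: tuple[str, ...]
    carrier_count: int
    n: int
    allele_freq_percent: float
    panel_freqs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.carrier_count <= self.n:
            raise ValueError("carrier count must lie in [0, n]")
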