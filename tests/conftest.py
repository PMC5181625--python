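import numpy as np
import pytest

from famvar import study_filter_config
from famvar.simulate import SimulationConfig, simulate_families
from famvar.types import (
    Affection,
    AnnotatedVariant,
    Consequence,
    GeneBiotype,
    Genotype,
    GenotypeMatrix,
    Individual,
    Pedigree,
    PolyPhenCategory,
    Variant,
    VariantAnnotation,
)


def make_annotated(
    chrom="1",
    pos=100,
    ref="A",
    alt="G",
    qual=60.0,
    rsid=None,
    gene="GENE0001",
    biotype=GeneBiotype.PROTEIN_CODING,
    consequence=Consequence.MISSENSE,
    polyphen=PolyPhenCategory.BENIGN,
    polyphen_score=0.1,
    sift=0.5,
    gerp=2.0,
    panel_freqs=None,
    in_dbsnp=False,
    stapes=False,
) -> AnnotatedVariant:
    return AnnotatedVariant(
        Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual, rsid=rsid),
        VariantAnnotation(
            gene_symbol=gene,
            gene_biotype=biotype,
            consequence=consequence,
            polyphen_category=polyphen,
            polyphen_score=polyphen_score,
            sift_score=sift,
            gerp=gerp,
            panel_freqs=panel_freqs or {},
            in_dbsnp=in_dbsnp,
            stapes_expressed=stapes,
        ),
    )


def make_trio_pedigree(family_id="FamilyX", onset=30.0) -> Pedigree:
    """Two sequenced affected sibs, one sequenced unaffected parent."""
    return Pedigree(
        family_id=family_id,
        individuals=[
            Individual(id="dad", affection=Affection.AFFECTED, age=62.0, sequenced=True),
            Individual(id="mum", affection=Affection.UNAFFECTED, age=60.0, sequenced=True),
            Individual(
                id="kid",
                father="dad",
                mother="mum",
                affection=Affection.AFFECTED,
                age=35.0,
                sequenced=True,
            ),
        ],
        onset_age=onset,
    )


def matrix_for(keys, calls_by_sample) -> GenotypeMatrix:
    samples = list(calls_by_sample)
    calls = np.array([calls_by_sample[s] for s in samples], dtype=np.int8)
    return GenotypeMatrix(samples, keys, calls)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_families(SimulationConfig(seed=7, n_background_variants=400))


@pytest.fixture(scope="session")
def study_config():
    return study_filter_config()
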