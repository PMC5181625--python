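import numpy as np
import pytest

from famvar import (
    FilterConfig,
    PrioritizationWeights,
    branch_candidate,
    branch_naive,
    combine_branches,
    filter_consequence,
    filter_panel_frequency,
    filter_quality,
    filter_shared_affected,
    filter_unaffected_carriers,
    prioritize,
    run_cascade,
    study_filter_config,
)
from famvar.simulate import SimulationConfig, simulate_families
from famvar.types import (
    Affection,
    ConfigurationError,
    Consequence,
    GeneBiotype,
    Individual,
    Pedigree,
    PolyPhenCategory,
    ReferenceSets,
    severity_rank,
)
from conftest import make_annotated, make_trio_pedigree, matrix_for
from oracles import brute_force_cascade_final


class TestQualityFilter:
    def test_threshold_is_strict(self):
        kept = filter_quality(
            [make_annotated(pos=1, qual=31), make_annotated(pos=2, qual=30)], 30
        )
        assert [v.variant.pos for v in kept] == [1]

    def test_empty_input(self):
        assert filter_quality([], 30) == []

    def test_matches_linear_scan_on_random_qualities(self):
        rng = np.random.default_rng(0)
        variants = [
            make_annotated(pos=i + 1, qual=float(q))
            for i, q in enumerate(rng.uniform(0, 100, size=1000))
        ]
        kept = filter_quality(variants, 30)
        expected = [v for v in variants if v.variant.qual > 30]  # independent scan
        assert kept == expected


class TestSharedAffected:
    def keys(self):
        return [("1", 100, "A", "G")]

    def test_all_affected_het_retained(self):
        ped = make_trio_pedigree()
        matrix = matrix_for(self.keys(), {"dad": [1], "mum": [0], "kid": [1]})
        kept = filter_shared_affected([make_annotated()], matrix, ped)
        assert len(kept) == 1

    def test_one_affected_hom_ref_excluded(self):
        ped = make_trio_pedigree()
        matrix = matrix_for(self.keys(), {"dad": [0], "mum": [1], "kid": [1]})
        assert filter_shared_affected([make_annotated()], matrix, ped) == []

    def test_missing_call_in_affected_excludes(self):
        ped = make_trio_pedigree()
        matrix = matrix_for(self.keys(), {"dad": [-1], "mum": [0], "kid": [1]})
        assert filter_shared_affected([make_annotated()], matrix, ped) == []

    def test_no_sequenced_affected_is_an_error(self):
        ped = Pedigree(
            family_id="F",
            individuals=[
                Individual(id="a", affection=Affection.AFFECTED, sequenced=False),
                Individual(id="b", affection=Affection.UNAFFECTED, sequenced=True),
            ],
            onset_age=30,
        )
        matrix = matrix_for(self.keys(), {"b": [1]})
        with pytest.raises(ConfigurationError):
            filter_shared_affected([make_annotated()], matrix, ped)

    def test_matches_enumeration_on_random_family(self):
        rng = np.random.default_rng(1)
        ped = Pedigree(
            family_id="F",
            individuals=[
                Individual(id=f"m{i}",
                           affection=Affection.AFFECTED if i < 2 else Affection.UNAFFECTED,
                           age=50.0, sequenced=True)
                for i in range(4)
            ],
            onset_age=30,
        )
        keys = [("1", 10 + i, "A", "G") for i in range(50)]
        calls = rng.integers(-1, 3, size=(4, 50))
        matrix = matrix_for(keys, {f"m{i}": calls[i] for i in range(4)})
        variants = [make_annotated(pos=10 + i) for i in range(50)]
        kept = {v.key for v in filter_shared_affected(variants, matrix, ped)}
        expected = {
            k for k in keys
            if all(int(matrix.call(f"m{i}", k)) in (1, 2) for i in range(2))
        }
        assert kept == expected


class TestPanelFrequency:
    def test_threshold_is_strict(self):
        v_hi = make_annotated(pos=1, panel_freqs={"1000G": 0.021})
        v_at = make_annotated(pos=2, panel_freqs={"1000G": 0.020})
        kept = filter_panel_frequency([v_hi, v_at], ["1000G"], 0.02)
        assert [v.variant.pos for v in kept] == [2]

    def test_novel_variant_is_retained(self):
        kept = filter_panel_frequency([make_annotated(panel_freqs={})], ["1000G"], 0.02)
        assert len(kept) == 1

    def test_disabled_panel_is_ignored(self):
        # a variant common in the disabled panel but absent from the applied one
        v = make_annotated(panel_freqs={"500Exomes": 0.5})
        assert filter_panel_frequency([v], ["1000G"], 0.02) == [v]
        assert filter_panel_frequency([v], ["1000G", "500Exomes"], 0.02) == []

    def test_unknown_panel_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            filter_panel_frequency(
                [make_annotated(panel_freqs={"1000G": 0.1})],
                ["NoSuchPanel"],
                0.02,
                known={"1000G"},
            )


class TestConsequenceFilter:
    @pytest.mark.parametrize(
        "consequence,biotype,kept",
        [
            (Consequence.SYNONYMOUS, GeneBiotype.PROTEIN_CODING, False),
            (Consequence.MISSENSE, GeneBiotype.PROTEIN_CODING, True),
            (Consequence.FRAMESHIFT_INDEL, GeneBiotype.PROTEIN_CODING, True),
            (Consequence.SPLICE_DONOR, GeneBiotype.PROTEIN_CODING, True),
            (Consequence.SPLICE_REGION, GeneBiotype.PROTEIN_CODING, True),
            (Consequence.INTRONIC, GeneBiotype.PROTEIN_CODING, False),
            (Consequence.UTR5, GeneBiotype.PROTEIN_CODING, False),
            (Consequence.NONCODING_EXON, GeneBiotype.MIRNA, True),
            (Consequence.NONCODING_EXON, GeneBiotype.OTHER_NONCODING, False),
        ],
    )
    def test_rules(self, consequence, biotype, kept):
        v = make_annotated(consequence=consequence, biotype=biotype)
        assert (filter_consequence([v]) == [v]) is kept


class TestUnaffectedCarriers:
    def test_carrier_excluded_and_noncarrier_retained(self):
        ped = make_trio_pedigree()
        keys = [("1", 100, "A", "G"), ("1", 200, "C", "T")]
        matrix = matrix_for(keys, {"dad": [1, 1], "mum": [1, 0], "kid": [1, 1]})
        variants = [make_annotated(pos=100), make_annotated(pos=200, ref="C", alt="T")]
        kept = filter_unaffected_carriers(variants, matrix, ped)
        assert [v.variant.pos for v in kept] == [200]

    def test_no_sequenced_unaffected_is_identity(self):
        ped = Pedigree(
            family_id="F",
            individuals=[
                Individual(id="a", affection=Affection.AFFECTED, sequenced=True),
                Individual(id="u", affection=Affection.UNAFFECTED, sequenced=False),
            ],
            onset_age=30,
        )
        matrix = matrix_for([("1", 100, "A", "G")], {"a": [1]})
        variants = [make_annotated()]
        assert filter_unaffected_carriers(variants, matrix, ped) == variants


class TestBranches:
    def setup_method(self):
        self.ped = make_trio_pedigree()
        self.reference = ReferenceSets(
            candidate_genes={"CAND1"}, inhouse_db={("1", 300, "A", "G")}
        )

    def run_naive(self, variants, config=None):
        keys = [v.key for v in variants]
        matrix = matrix_for(
            keys,
            {
                "dad": [1] * len(keys),
                "mum": [0] * len(keys),
                "kid": [1] * len(keys),
            },
        )
        return branch_naive(
            variants, matrix, self.ped, self.reference, config or FilterConfig()
        )

    def test_deleterious_by_either_predictor(self):
        # damaging PolyPhen but tolerated SIFT: still deleterious
        v = make_annotated(
            polyphen=PolyPhenCategory.PROBABLY_DAMAGING, polyphen_score=0.99, sift=0.8
        )
        assert self.run_naive([v]).retained == [v]
        # benign PolyPhen but SIFT below cutoff: deleterious too
        v2 = make_annotated(sift=0.01)
        assert self.run_naive([v2]).retained == [v2]
        # benign by both: dropped
        v3 = make_annotated(sift=0.5)
        assert self.run_naive([v3]).retained == []

    def test_dbsnp_presence_excludes(self):
        v = make_annotated(
            polyphen=PolyPhenCategory.PROBABLY_DAMAGING, polyphen_score=0.99, rsid="rs1"
        )
        assert self.run_naive([v]).retained == []

    def test_homozygosity_exclusion_is_configurable(self):
        v = make_annotated(polyphen=PolyPhenCategory.PROBABLY_DAMAGING, polyphen_score=0.99)
        matrix = matrix_for([v.key], {"dad": [2], "mum": [0], "kid": [1]})
        on = branch_naive([v], matrix, self.ped, self.reference, FilterConfig())
        assert on.retained == []
        off = branch_naive(
            [v], matrix, self.ped, self.reference,
            FilterConfig(exclude_homozygous={"FamilyX": False}),
        )
        assert off.retained == [v]

    def test_inhouse_db_exact_key_match(self):
        v = make_annotated(pos=300, sift=0.01)
        assert self.run_naive([v]).retained == []
        v_nearby = make_annotated(pos=301, sift=0.01)
        assert self.run_naive([v_nearby]).retained == [v_nearby]

    def test_candidate_branch(self):
        keys_calls = lambda vs: matrix_for(
            [v.key for v in vs], {"dad": [1] * len(vs), "mum": [0] * len(vs), "kid": [1] * len(vs)}
        )
        listed = make_annotated(pos=1, gene="CAND1")
        unlisted = make_annotated(pos=2, gene="OTHER")
        inhouse = make_annotated(pos=300, gene="CAND1")
        vs = [listed, unlisted, inhouse]
        result = branch_candidate(vs, keys_calls(vs), self.ped, self.reference, FilterConfig())
        assert result.retained == [listed]
        empty_ref = ReferenceSets()
        result = branch_candidate(vs, keys_calls(vs), self.ped, empty_ref, FilterConfig())
        assert result.retained == []


class TestCombineAndPrioritize:
    def test_union_semantics(self):
        from famvar.types import BranchResult

        a, b, c = (make_annotated(pos=p) for p in (1, 2, 3))
        naive = BranchResult("naive", [a, b], [])
        candidate = BranchResult("candidate", [b, c], [])
        assert {v.key for v in combine_branches(naive, candidate)} == {a.key, b.key, c.key}
        disjoint = combine_branches(BranchResult("naive", [a], []), BranchResult("candidate", [c], []))
        assert len(disjoint) == 2
        subset = combine_branches(BranchResult("naive", [a, b], []), BranchResult("candidate", [b], []))
        assert {v.key for v in subset} == {a.key, b.key}

    def test_single_variant_gets_rank_one(self):
        ranked = prioritize([make_annotated()], PrioritizationWeights(), set())
        assert ranked[0].rank == 1

    def test_higher_gerp_ranks_first(self):
        low = make_annotated(pos=1, gerp=1.0)
        high = make_annotated(pos=2, gerp=5.0)
        ranked = prioritize([low, high], PrioritizationWeights(), set())
        assert ranked[0].key == high.key

    def test_matches_independent_score_computation(self):
        rng = np.random.default_rng(3)
        variants = []
        consequences = list(Consequence)
        for i in range(20):
            variants.append(
                make_annotated(
                    pos=i + 1,
                    gene=f"G{i % 5}",
                    consequence=consequences[rng.integers(len(consequences))],
                    gerp=float(rng.uniform(-4, 8)),
                    stapes=bool(rng.random() < 0.5),
                )
            )
        candidates = {"G0", "G3"}
        weights = PrioritizationWeights(gerp=2.0, severity=1.5, stapes=0.5, candidate=1.0)
        ranked = prioritize(variants, weights, candidates)
        # independent re-computation of the score formula
        def score(v):
            ann = v.annotation
            return (
                2.0 * min(max(ann.gerp, 0.0), 6.0) / 6.0
                + 1.5 * severity_rank(ann.consequence) / 5.0
                + 0.5 * (1.0 if ann.stapes_expressed else 0.0)
                + 1.0 * (1.0 if ann.gene_symbol in candidates else 0.0)
            )
        expected = sorted(variants, key=lambda v: (-score(v), v.key))
        assert [pv.key for pv in ranked] == [v.key for v in expected]
        assert [pv.rank for pv in ranked] == list(range(1, 21))
        for pv, v in zip(ranked, expected):
            assert pv.score == pytest.approx(score(v))


class TestRunCascade:
    def test_causal_variant_survives_and_counts_decrease(self, small_cohort, study_config):
        result = run_cascade(
            small_cohort.annotated_variants(),
            small_cohort.genotypes,
            small_cohort.pedigrees,
            small_cohort.reference_sets,
            study_config,
        )
        for fam, causal_key in small_cohort.truth.items():
            final_keys = {v.key for v in result.final[fam]}
            assert causal_key in final_keys
            # causal gene is in the candidate list, so it sits in both branches
            assert causal_key in result.branches[fam]["naive"].retained_keys
            assert causal_key in result.branches[fam]["candidate"].retained_keys
        # shared stages are a subset chain: per-family counts non-increasing
        fams = [p.family_id for p in small_cohort.pedigrees]
        shared = [r for r in result.trace.records if r.branch is None and r.stage != "combined"]
        for fam in fams:
            counts = [r.counts[fam] for r in shared if r.counts[fam] is not None]
            assert counts == sorted(counts, reverse=True)

    def test_filters_are_idempotent_pure_subsets(self, small_cohort):
        variants = small_cohort.annotated_variants()
        once = filter_quality(variants, 30)
        assert filter_quality(once, 30) == once
        assert set(v.key for v in once) <= set(v.key for v in variants)
        ped = small_cohort.pedigrees[0]
        shared = filter_shared_affected(variants, small_cohort.genotypes, ped)
        assert filter_shared_affected(shared, small_cohort.genotypes, ped) == shared

    def test_branch_order_does_not_change_union(self, small_cohort, study_config):
        variants = small_cohort.annotated_variants()
        ped = small_cohort.pedigrees[0]
        gm, ref = small_cohort.genotypes, small_cohort.reference_sets
        naive = branch_naive(variants, gm, ped, ref, study_config)
        cand = branch_candidate(variants, gm, ped, ref, study_config)
        ab = {v.key for v in combine_branches(naive, cand)}
        ba = {v.key for v in combine_branches(cand, naive)}  # type: ignore[arg-type]
        assert ab == ba

    def test_trace_average_column_is_recomputable(self, small_cohort, study_config):
        from famvar import trace_average, write_trace

        result = run_cascade(
            small_cohort.annotated_variants(),
            small_cohort.genotypes,
            small_cohort.pedigrees,
            small_cohort.reference_sets,
            study_config,
        )
        for record in result.trace.records:
            if any(c is not None for c in record.counts.values()):
                trace_average(record.counts.values())  # must not raise

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_on_small_cohorts(self, seed, study_config):
        cohort = simulate_families(
            SimulationConfig(seed=seed, n_background_variants=90)
        )
        annotated = cohort.annotated_variants()
        result = run_cascade(
            annotated, cohort.genotypes, cohort.pedigrees,
            cohort.reference_sets, study_config,
        )
        for ped in cohort.pedigrees:
            expected = brute_force_cascade_final(
                annotated, cohort.genotypes, ped, cohort.reference_sets, study_config
            )
            assert {v.key for v in result.final[ped.family_id]} == expected
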