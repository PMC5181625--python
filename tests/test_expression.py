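import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famvar import (
    ddct_relative_expression,
    exon_group_compare,
    luciferase_relative_activity,
    student_t_two_tailed,
)
from famvar.expression import TranscriptExonMap
from famvar.simulate import (
    CtConfig,
    ExonCountConfig,
    LuciferaseConfig,
    simulate_ct_table,
    simulate_exon_counts,
    simulate_luciferase,
)
from famvar.types import FamvarError


class TestStudentT:
    def test_identical_groups(self):
        result = student_t_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.t == 0.0 and result.p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # means 2 and 5, pooled sd 1, se = sqrt(2/3): t = -3/0.8165 = -3.674
        result = student_t_two_tailed([1, 2, 3], [4, 5, 6])
        assert result.t == pytest.approx(-3.674, abs=5e-4)
        assert result.df == 4

    def test_zero_variance_conventions(self):
        equal = student_t_two_tailed([2.0, 2.0], [2.0, 2.0])
        assert equal.p == 1.0 and equal.zero_variance
        unequal = student_t_two_tailed([2.0, 2.0], [3.0, 3.0])
        assert unequal.p == 0.0 and math.isinf(unequal.t) and unequal.zero_variance

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a = rng.normal(size=rng.integers(2, 12))
            b = rng.normal(size=rng.integers(2, 12))
            ours = student_t_two_tailed(a, b)
            t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
            assert ours.t == pytest.approx(float(t_ref), abs=1e-10)
            assert ours.p == pytest.approx(float(p_ref), abs=1e-10)

    def test_single_observation_group_uses_single_case_form(self):
        rng = np.random.default_rng(5)
        cal = rng.normal(size=10)
        single = np.array([1.3])
        result = student_t_two_tailed(single, cal)
        s = cal.std(ddof=1)
        expected_t = (1.3 - cal.mean()) / (s * math.sqrt(1 + 1 / 10))
        assert result.df == 9
        assert result.t == pytest.approx(expected_t, abs=1e-12)


def counts_frame(control_rows, case_rows):
    rows = []
    index = []
    for i, values in enumerate(control_rows):
        rows.append({"group": "control", **{f"exon_{j + 1}": v for j, v in enumerate(values)}})
        index.append(f"control_{i}")
    for i, values in enumerate(case_rows):
        rows.append({"group": "case", **{f"exon_{j + 1}": v for j, v in enumerate(values)}})
        index.append(f"case_{i}")
    return pd.DataFrame(rows, index=index)


class TestExonGroupCompare:
    exon_map = TranscriptExonMap(
        groups={"upstream": frozenset({1, 2}), "downstream": frozenset({3, 4})}
    )

    def test_identical_groups_give_unit_fold(self):
        frame = counts_frame([[10, 12, 20, 22]] * 3, [[10, 12, 20, 22]] * 3)
        results = exon_group_compare(frame, self.exon_map)
        for r in results.values():
            assert r.fold == pytest.approx(1.0)
            assert r.p == pytest.approx(1.0)

    def test_matches_hand_computed_pooled_t(self):
        # per-sample upstream means: control {10, 12}, case {20, 22}
        frame = counts_frame([[10, 10, 5, 5], [12, 12, 5, 5]], [[20, 20, 5, 5], [22, 22, 5, 5]])
        r = exon_group_compare(frame, self.exon_map)["upstream"]
        # hand: means 11 vs 21, ss=4, df=2, sp=sqrt(2), se=sqrt(2)*1 -> t=10/sqrt(2)
        assert r.t == pytest.approx(10 / math.sqrt(2), abs=1e-12)
        assert r.df == 2
        assert r.p == pytest.approx(2 * stats.t.sf(10 / math.sqrt(2), 2), abs=1e-12)
        assert r.fold == pytest.approx(21 / 11)

    def test_requires_two_samples_per_group(self):
        frame = counts_frame([[10, 10, 5, 5]], [[20, 20, 5, 5], [22, 22, 5, 5]])
        with pytest.raises(FamvarError):
            exon_group_compare(frame, self.exon_map)

    def test_detects_downstream_only_effect(self):
        counts = simulate_exon_counts(ExonCountConfig(), seed=123)
        counts = counts[counts["group"] != "single_patient"]
        results = exon_group_compare(counts)
        assert results["downstream"].p < 0.05
        assert results["downstream"].fold < 0.75
        assert 0.5 < results["upstream"].fold < 2.0


class TestDdct:
    def build_table(self, case_shift, n_control=3, n_case=3):
        rows = []
        for group, n, shift in [("control", n_control, 0.0), ("case", n_case, case_shift)]:
            for i in range(n):
                sample = f"{group}_{i}"
                for rep in range(2):
                    rows.append({"sample": sample, "group": group, "assay": "reference",
                                 "replicate": rep, "ct": 10.0})
                    rows.append({"sample": sample, "group": group, "assay": "target",
                                 "replicate": rep, "ct": 15.0 + shift})
        return pd.DataFrame(rows)

    def test_calibrator_fold_is_exactly_one(self):
        results = ddct_relative_expression(self.build_table(1.0), "target", "control")
        assert results["control"].fold == 1.0
        assert results["control"].p == 1.0

    def test_unit_ddct_halves_expression(self):
        results = ddct_relative_expression(self.build_table(1.0), "target", "control")
        assert results["case"].fold == pytest.approx(0.5)
        results = ddct_relative_expression(self.build_table(-1.0), "target", "control")
        assert results["case"].fold == pytest.approx(2.0)

    def test_missing_reference_assay_names_sample(self):
        table = self.build_table(1.0)
        table = table[~((table["sample"] == "case_1") & (table["assay"] == "reference"))]
        with pytest.raises(FamvarError, match="case_1"):
            ddct_relative_expression(table, "target", "control")

    def test_invariant_to_global_ct_shift(self):
        table = self.build_table(1.0)
        noisy = table.copy()
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 0.3, size=len(table))
        table = table.assign(ct=table["ct"] + noise)
        shifted = table.assign(ct=table["ct"] + 3.7)  # same shift on both assays
        a = ddct_relative_expression(table, "target", "control")
        b = ddct_relative_expression(shifted, "target", "control")
        for group in a:
            assert a[group].fold == pytest.approx(b[group].fold, rel=1e-12)
            assert a[group].p == pytest.approx(b[group].p, rel=1e-9)

    def test_noiseless_simulation_recovers_true_folds(self):
        config = CtConfig(sd=0.0)
        table = simulate_ct_table(config, seed=1)
        results = ddct_relative_expression(table, config.target_assay, "control")
        assert results["case"].fold == pytest.approx(1 / 1.9, rel=1e-9)
        assert results["single_patient"].fold == pytest.approx(1 / 2.4, rel=1e-9)

    def test_fold_effects_multiply(self):
        # 2x upstream and 4x downstream true effects: downstream/upstream ~ 2
        base = CtConfig(
            group_sizes={"control": 12, "case": 12},
            replicates=3,
            sd=0.1,
        )
        up = CtConfig(**{**base.__dict__, "group_folds": {"control": 1.0, "case": 2.0},
                         "target_assay": "target_upstream"})
        down = CtConfig(**{**base.__dict__, "group_folds": {"control": 1.0, "case": 4.0},
                           "target_assay": "target_downstream"})
        f_up = ddct_relative_expression(
            simulate_ct_table(up, seed=21), "target_upstream", "control"
        )["case"].fold
        f_down = ddct_relative_expression(
            simulate_ct_table(down, seed=22), "target_downstream", "control"
        )["case"].fold
        assert f_down / f_up == pytest.approx(2.0, rel=0.15)

    def test_single_patient_group_is_reported_with_p_value(self):
        table = simulate_ct_table(CtConfig(sd=0.2), seed=3)
        results = ddct_relative_expression(table, "target_downstream", "control")
        single = results["single_patient"]
        assert single.n == 1
        assert 0.0 <= single.p <= 1.0
        assert single.ci95[0] < single.fold < single.ci95[1]


class TestLuciferase:
    def plate(self, activities, reps=3, experiments=2):
        rows = []
        for e in range(1, experiments + 1):
            for construct, act in activities.items():
                for _ in range(reps):
                    rows.append({"construct": construct, "experiment": e,
                                 "firefly": 100.0 * act, "renilla": 50.0})
        return pd.DataFrame(rows)

    def test_wildtype_normalizes_to_exactly_one(self):
        results = luciferase_relative_activity(self.plate({"wildtype": 1.0}))
        assert results["wildtype"].activity == pytest.approx(1.0, abs=1e-15)

    def test_mutant_identical_to_wildtype(self):
        results = luciferase_relative_activity(self.plate({"wildtype": 1.0, "mut": 1.0}))
        assert results["mut"].activity == pytest.approx(1.0)
        assert results["mut"].p == pytest.approx(1.0)

    def test_noiseless_simulation_recovers_configured_activities(self):
        config = LuciferaseConfig(noise_sigma=0.0, renilla_sigma=0.0)
        plate = simulate_luciferase(config, seed=0)
        results = luciferase_relative_activity(plate)
        for construct, activity in config.activities.items():
            assert results[construct].activity == pytest.approx(activity, rel=1e-12)

    def test_per_experiment_wildtype_mean_is_one(self):
        plate = simulate_luciferase(seed=9)
        plate = plate.assign(ratio=plate["firefly"] / plate["renilla"])
        for _, sub in plate.groupby("experiment"):
            wt_mean = sub.loc[sub["construct"] == "wildtype", "ratio"].mean()
            normalized = sub.loc[sub["construct"] == "wildtype", "ratio"] / wt_mean
            assert normalized.mean() == pytest.approx(1.0, abs=1e-12)

    def test_experiment_without_wildtype_is_an_error(self):
        plate = self.plate({"wildtype": 1.0, "mut": 0.5})
        broken = plate[~((plate["experiment"] == 2) & (plate["construct"] == "wildtype"))]
        with pytest.raises(FamvarError):
            luciferase_relative_activity(broken)
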