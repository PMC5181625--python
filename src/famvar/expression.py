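"""Downstream expression statistics on stapes tissue.

Three analyses mirror the study's functional follow-up of the candidate gene:

* exon-group read-count comparison — the alternative transcript comprises the
  downstream exons (5-8) only, so per-sample mean read counts over an exon
  group are compared between otosclerotic and control stapes with a Student's
  two-tailed t-test;
* ddCt relative quantification of RT-qPCR data against an endogenous control
  and a calibrator group, fold change = 2^(-mean ddCt) with a t-based 95% CI;
* dual-luciferase reporter normalization — per-well firefly/renilla activity,
  normalized within each independent experiment to that experiment's
  wild-type mean, pooled, and compared against wild type.

All tests are equal-variance Student's t (the study's stated test); Welch is
available behind a flag on the t-test itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import FamvarError

CT_COLUMNS = ["sample", "group", "assay", "replicate", "ct"]
LUCIFERASE_COLUMNS = ["construct", "experiment", "firefly", "renilla"]
REFERENCE_ASSAY = "reference"


@dataclass(frozen=True)
class TranscriptExonMap:
    """Named exon groups (defaults match a gene whose short transcript holds
    exons 5-8 and whose full-length transcript starts at exon 1)."""

    groups: Mapping[str, frozenset[int]] = field(
        default_factory=lambda: {
            "upstream": frozenset({1, 2, 3, 4}),
            "downstream": frozenset({5, 6, 7, 8}),
        }
    )
    transcripts: Mapping[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.groups)
        for name in names:
            if not self.groups[name]:
                raise ValueError(f"exon group {name!r} is empty")
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if self.groups[a] & self.groups[b]:
                    raise ValueError(f"exon groups {a!r} and {b!r} overlap")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    zero_variance: bool = False


def student_t_two_tailed(
    values_a: Sequence[float],
    values_b: Sequence[float],
    welch: bool = False,
) -> TTestResult:
    """Two-sample Student's t-test (pooled variance), two-tailed.

    Degenerate cases follow explicit conventions: zero pooled variance with
    equal means gives t=0, p=1; zero pooled variance with unequal means gives
    the p=0 limit, flagged. One group may hold a single observation (the
    single-case comparison used for the one mutation-carrier stapes sample);
    the pooled formula then reduces to the single-case t with df = n-1 of the
    other group.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 1 or b.size < 1 or a.size + b.size < 3:
        raise FamvarError("t-test needs at least 3 observations across the groups")
    if welch:
        if a.size < 2 or b.size < 2:
            raise FamvarError("Welch's t-test needs >=2 observations per group")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        df = (va / a.size + vb / b.size) ** 2 / (
            (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
        )
        return TTestResult(t=float(t), df=int(df), p=float(p))
    df = a.size + b.size - 2
    ss = float(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
    diff = float(a.mean() - b.mean())
    if ss == 0.0:
        if diff == 0.0:
            return TTestResult(t=0.0, df=df, p=1.0, zero_variance=True)
        return TTestResult(
            t=math.copysign(math.inf, diff), df=df, p=0.0, zero_variance=True
        )
    sp = math.sqrt(ss / df)
    se = sp * math.sqrt(1.0 / a.size + 1.0 / b.size)
    t = diff / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p=p)


@dataclass(frozen=True)
class ExonGroupComparison:
    exon_group: str
    group_means: Mapping[str, float]
    fold: float
    t: float
    df: int
    p: float
    per_sample: Mapping[str, Mapping[str, float]]


def exon_group_compare(
    counts: pd.DataFrame,
    exon_map: TranscriptExonMap = TranscriptExonMap(),
    group_a: str = "control",
    group_b: str = "case",
) -> dict[str, ExonGroupComparison]:
    """Compare per-sample mean read counts over each named exon group between
    two sample groups.

    ``counts`` has one row per sample, columns ``exon_1..exon_E`` plus a
    ``group`` column; counts are compared raw (no library-size scaling),
    matching an average-read-count presentation. The per-sample statistic is
    the mean count over the exon group; groups are compared with an
    equal-variance two-tailed t-test and fold = mean(group_b)/mean(group_a).
    """
    if "group" not in counts.columns:
        raise FamvarError("count table needs a 'group' column")
    exon_cols = {
        int(c.split("_", 1)[1]): c for c in counts.columns if c.startswith("exon_")
    }
    if (counts[list(exon_cols.values())] < 0).any().any():
        raise FamvarError("read counts must be non-negative")
    results: dict[str, ExonGroupComparison] = {}
    for name, exons in exon_map.groups.items():
        missing = [e for e in exons if e not in exon_cols]
        if missing:
            raise FamvarError(f"exon group {name!r} references absent exon(s) {missing}")
        cols = [exon_cols[e] for e in sorted(exons)]
        per_sample = counts[cols].mean(axis=1)
        a = per_sample[counts["group"] == group_a]
        b = per_sample[counts["group"] == group_b]
        if len(a) < 2 or len(b) < 2:
            raise FamvarError(
                f"need >=2 samples per group for {name!r}; got "
                f"{len(a)} ({group_a}) and {len(b)} ({group_b})"
            )
        test = student_t_two_tailed(b.to_numpy(), a.to_numpy())
        results[name] = ExonGroupComparison(
            exon_group=name,
            group_means={group_a: float(a.mean()), group_b: float(b.mean())},
            fold=float(b.mean() / a.mean()) if a.mean() != 0 else math.inf,
            t=test.t,
            df=test.df,
            p=test.p,
            per_sample={
                grp: dict(
                    zip(
                        counts.loc[counts["group"] == grp].index.astype(str),
                        per_sample[counts["group"] == grp],
                    )
                )
                for grp in counts["group"].unique()
            },
        )
    return results


@dataclass(frozen=True)
class RelativeExpressionResult:
    group: str
    n: int
    delta_ct: Mapping[str, float]
    ddct: Mapping[str, float]
    mean_ddct: float
    fold: float
    ci95: Optional[tuple[float, float]]  # None when there is no residual spread
    t: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold change must be positive")
        if self.ci95 is not None:
            lo, hi = self.ci95
            if not (lo < self.fold < hi):
                raise ValueError("95% CI must strictly bracket the fold estimate")


def _sample_delta_ct(
    table: pd.DataFrame, target_assay: str, reference_assay: str
) -> dict[str, float]:
    delta: dict[str, float] = {}
    for sample, sub in table.groupby("sample", sort=True):
        target = sub.loc[sub["assay"] == target_assay, "ct"]
        reference = sub.loc[sub["assay"] == reference_assay, "ct"]
        if target.empty:
            continue  # sample not measured with this assay
        if reference.empty:
            raise FamvarError(
                f"sample {sample!r} has no {reference_assay!r} assay replicates"
            )
        delta[str(sample)] = float(target.mean() - reference.mean())
    return delta


def ddct_relative_expression(
    ct_table: pd.DataFrame,
    target_assay: str,
    calibrator_group: str = "control",
    reference_assay: str = REFERENCE_ASSAY,
) -> dict[str, RelativeExpressionResult]:
    """ddCt relative quantification per sample group against a calibrator.

    Per sample, dCt = mean Ct(target replicates) - mean Ct(endogenous-control
    replicates); ddCt = dCt - mean dCt over the calibrator group; the group
    fold change is 2^(-mean ddCt) (exactly 1 for the calibrator). Technical
    replicates are averaged within sample before any between-sample statistic.
    The 95% CI is computed on the ddCt scale with the pooled two-sample
    t-machinery against the calibrator and exponentiated (asymmetric on the
    fold scale); for a single-sample group the pooled formula reduces to the
    single-case t with the calibrator's spread.
    """
    missing = [c for c in CT_COLUMNS if c not in ct_table.columns]
    if missing:
        raise FamvarError(f"Ct table lacks column(s) {missing}")
    if (ct_table["ct"] <= 0).any():
        raise FamvarError("Ct values must be positive")
    delta_ct = _sample_delta_ct(ct_table, target_assay, reference_assay)
    groups = {
        str(g): [str(s) for s in sub["sample"].unique() if str(s) in delta_ct]
        for g, sub in ct_table.groupby("group", sort=True)
    }
    calibrator_samples = groups.get(calibrator_group, [])
    if not calibrator_samples:
        raise FamvarError(f"calibrator group {calibrator_group!r} is empty")
    calibrator_mean = float(np.mean([delta_ct[s] for s in calibrator_samples]))
    ddct = {s: d - calibrator_mean for s, d in delta_ct.items()}
    cal_values = np.array([ddct[s] for s in calibrator_samples])
    results: dict[str, RelativeExpressionResult] = {}
    for group, samples in groups.items():
        if not samples:
            continue
        values = np.array([ddct[s] for s in samples])
        test = student_t_two_tailed(values, cal_values)
        mean_ddct = float(values.mean())
        fold = 1.0 if group == calibrator_group else 2.0 ** (-mean_ddct)
        df = test.df
        ss = float(
            ((values - values.mean()) ** 2).sum()
            + ((cal_values - cal_values.mean()) ** 2).sum()
        )
        ci = None  # noiseless input leaves no residual spread: estimate is exact
        if ss > 0.0 and df >= 1:
            se = math.sqrt(ss / df) * math.sqrt(1.0 / len(values) + 1.0 / len(cal_values))
            tq = float(stats.t.ppf(0.975, df))
            ci = (2.0 ** (-(mean_ddct + tq * se)), 2.0 ** (-(mean_ddct - tq * se)))
            if not ci[0] < fold < ci[1]:  # numerically degenerate interval
                ci = None
        results[group] = RelativeExpressionResult(
            group=group,
            n=len(samples),
            delta_ct={s: delta_ct[s] for s in samples},
            ddct={s: ddct[s] for s in samples},
            mean_ddct=mean_ddct,
            fold=fold,
            ci95=ci,
            t=test.t,
            df=df,
            p=1.0 if group == calibrator_group else test.p,
        )
    return results


@dataclass(frozen=True)
class LuciferaseResult:
    construct: str
    activity: float
    sem: float
    n: int
    t: float
    df: int
    p: float
    values: tuple[float, ...]


def luciferase_relative_activity(
    plate: pd.DataFrame, wildtype_label: str = "wildtype"
) -> dict[str, LuciferaseResult]:
    """Normalize dual-luciferase readings and compare constructs to wild type.

    Per-well activity is firefly/renilla; within each independent experiment
    all wells are divided by that experiment's wild-type mean (so the
    wild-type mean is exactly 1 per experiment), then wells are pooled across
    experiments and each mutant's pooled values are compared with the
    wild-type pooled values by a two-tailed Student's t-test.
    """
    missing = [c for c in LUCIFERASE_COLUMNS if c not in plate.columns]
    if missing:
        raise FamvarError(f"luciferase table lacks column(s) {missing}")
    if (plate["firefly"] <= 0).any() or (plate["renilla"] <= 0).any():
        raise FamvarError("luminometer readings must be positive")
    plate = plate.copy()
    plate["ratio"] = plate["firefly"] / plate["renilla"]
    normalized: dict[str, list[float]] = {}
    for experiment, sub in plate.groupby("experiment", sort=True):
        wt = sub.loc[sub["construct"] == wildtype_label, "ratio"]
        if wt.empty:
            raise FamvarError(
                f"experiment {experiment!r} has no {wildtype_label!r} wells"
            )
        wt_mean = float(wt.mean())
        for construct, csub in sub.groupby("construct", sort=True):
            normalized.setdefault(str(construct), []).extend(
                (csub["ratio"] / wt_mean).tolist()
            )
    wt_values = np.array(normalized[wildtype_label])
    results: dict[str, LuciferaseResult] = {}
    for construct, values_list in sorted(normalized.items()):
        values = np.array(values_list)
        test = student_t_two_tailed(values, wt_values)
        results[construct] = LuciferaseResult(
            construct=construct,
            activity=float(values.mean()),
            sem=float(values.std(ddof=1) / math.sqrt(len(values)))
            if len(values) > 1
            else 0.0,
            n=len(values),
            t=test.t,
            df=test.df,
            p=1.0 if construct == wildtype_label else test.p,
            values=tuple(float(v) for v in values),
        )
    return results
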