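"""Cohort descriptive statistics and two-sample significance tests.

Group-level tables follow the layout N / mean / SD / min / max, and the
headline between-group comparison is a two-sided Student t-test at
alpha = 0.05 with a 95% confidence interval on the mean difference.  The
discriminating intensity statistic is the "mean minimums": per recording,
the minimum cry-active (voiced-frame) meter value; then the group mean of
those minima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .features import MeterTrace, SpectrumSeries, summarize_trace
from .linguistics import CryStructure, voiced_frame_mask


@dataclass
class CohortSummary:
    variable: str
    n: int
    mean: float
    sd: float
    min: float
    max: float


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    ci_low: float
    ci_high: float
    alpha: float
    welch: bool

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


@dataclass
class IntensityRow:
    """One meter's intensity statistics for one group."""

    group: str
    meter: str
    mean: float  # mean over recordings of per-recording voiced means, U
    min: float  # global minimum voiced value, U
    max: float  # global maximum voiced value, U
    mean_minimum: float  # group mean of per-recording minima, U
    n: int


@dataclass
class IntensityTable:
    rows: list[IntensityRow]
    tests: dict[str, TTestResult]  # meter -> t-test on per-recording minima

    def row(self, group: str, meter: str) -> IntensityRow:
        for r in self.rows:
            if r.group == group and r.meter == meter:
                return r
        raise KeyError((group, meter))


def summarize_variable(values: Sequence[float], name: str = "") -> CohortSummary:
    """N, sample mean, sample SD (n-1 denominator), min and max."""
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty variable")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return CohortSummary(
        variable=name,
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        min=float(arr.min()),
        max=float(arr.max()),
    )


def t_test(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    welch: bool = False,
) -> TTestResult:
    """Two-sided two-sample t-test (Student pooled by default).

    Degenerate inputs: if both groups are constant with equal means the
    test is vacuous and p = 1 by convention; constant groups with unequal
    means are an error (the t statistic is undefined).
    """
    x = np.asarray(list(a), dtype=np.float64)
    y = np.asarray(list(b), dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            df = x.size + y.size - 2
            return TTestResult(t=0.0, df=df, p=1.0, ci_low=0.0, ci_high=0.0,
                               alpha=alpha, welch=welch)
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return TTestResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        alpha=alpha,
        welch=welch,
    )


def t_test_auto(a: Sequence[float], b: Sequence[float], alpha: float = 0.05,
                variance_ratio_limit: float = 4.0) -> TTestResult:
    """Student pooled t-test, switching to Welch when variances differ.

    When the sample-variance ratio exceeds ``variance_ratio_limit`` the
    Welch variant is used instead (and noted via a warning).
    """
    x = np.asarray(list(a), dtype=np.float64)
    y = np.asarray(list(b), dtype=np.float64)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    welch = False
    if min(v1, v2) > 0 and max(v1, v2) / min(v1, v2) > variance_ratio_limit:
        welch = True
        warnings.warn(
            f"variance ratio {max(v1, v2) / min(v1, v2):.1f} exceeds "
            f"{variance_ratio_limit}; using Welch t-test", stacklevel=2)
    return t_test(a, b, alpha=alpha, welch=welch)


def _voiced_values(trace: MeterTrace | SpectrumSeries, structure: CryStructure) -> np.ndarray:
    if isinstance(trace, SpectrumSeries):
        values = trace.frame_peaks()
    else:
        values = trace.values
    mask = voiced_frame_mask(structure, values.size, trace.frame_ms)
    return values[mask]


def intensity_table(
    cohorts: dict[str, list[dict[str, MeterTrace | SpectrumSeries]]],
    structures: dict[str, list[CryStructure]],
    meters: Iterable[str] = ("VU", "PPM", "Spectrum"),
    alpha: float = 0.05,
) -> IntensityTable:
    """Group intensity statistics over voiced (cry-active) frames.

    ``cohorts`` maps a group label to a list of per-recording trace dicts
    keyed by meter name; ``structures`` supplies the matching
    segmentations that define which frames are voiced.  For each group
    and meter the table holds the mean of per-recording voiced means, the
    global voiced min-max range, and the group mean of per-recording
    minima; Student t-tests on the per-recording VU and PPM minima are
    attached.
    """
    meters = list(meters)
    rows: list[IntensityRow] = []
    minima: dict[tuple[str, str], list[float]] = {}
    for group, recs in cohorts.items():
        structs = structures[group]
        if len(structs) != len(recs):
            raise ValueError(f"group {group}: traces and structures differ in length")
        for meter in meters:
            rec_means, rec_mins, rec_maxs = [], [], []
            for trace_dict, structure in zip(recs, structs):
                vals = _voiced_values(trace_dict[meter], structure)
                if vals.size == 0:
                    continue
                rec_means.append(float(vals.mean()))
                rec_mins.append(float(vals.min()))
                rec_maxs.append(float(vals.max()))
            if not rec_means:
                raise ValueError(f"group {group}, meter {meter}: no voiced frames")
            rows.append(IntensityRow(
                group=group,
                meter=meter,
                mean=float(np.mean(rec_means)),
                min=float(np.min(rec_mins)),
                max=float(np.max(rec_maxs)),
                mean_minimum=float(np.mean(rec_mins)),
                n=len(rec_means),
            ))
            minima[(group, meter)] = rec_mins
    tests: dict[str, TTestResult] = {}
    groups = list(cohorts)
    if len(groups) == 2:
        g1, g2 = groups
        for meter in meters:
            if meter in ("VU", "PPM"):
                a, b = minima[(g1, meter)], minima[(g2, meter)]
                if len(a) >= 2 and len(b) >= 2:
                    tests[meter] = t_test(a, b, alpha=alpha)
    return IntensityTable(rows=rows, tests=tests)
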