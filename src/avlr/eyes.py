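"""Left/right eye comparison of AVLR feature records.

Retinal vascular change from systemic disease is often bilateral;
pronounced inter-eye asymmetry of the arteriovenous length ratios is
itself a finding.  This module quantifies per-metric asymmetry for one
subject and tests it across a cohort with a paired Wilcoxon signed-rank
test (nonparametric, robust to the right-skew typical of ratio features;
zero differences are dropped per the classic Wilcoxon treatment).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

from .features import RATIO_NAMES, ImageFeatureRecord


@dataclasses.dataclass
class MetricComparison:
    left: float
    right: float
    difference: float       # right - left
    log_ratio: float        # log(right / left)
    asymmetry_index: float  # |right - left| / mean(right, left), in [0, 2]
    missing: bool


@dataclasses.dataclass
class EyePairReport:
    subject_id: str
    roi_name: str
    metrics: dict[str, MetricComparison]

    def complete_metrics(self) -> list[str]:
        return [m for m, c in self.metrics.items() if not c.missing]


def compare_eyes(left: ImageFeatureRecord, right: ImageFeatureRecord,
                 subject_id: str = "") -> EyePairReport:
    """Per-metric asymmetry between one subject's two eyes.

    Both records must come from the same ring ROI; comparing a 2-3 ROD
    ring against a 2-5 ROD ring would not be like-for-like.
    """
    if left.roi_name != right.roi_name:
        raise ValueError(
            f"ROI mismatch: left={left.roi_name!r} right={right.roi_name!r}")
    out: dict[str, MetricComparison] = {}
    for name in RATIO_NAMES:
        lv = left.ratios.get(name, math.nan)
        rv = right.ratios.get(name, math.nan)
        missing = not (np.isfinite(lv) and np.isfinite(rv))
        if missing:
            out[name] = MetricComparison(lv, rv, math.nan, math.nan, math.nan, True)
            continue
        diff = rv - lv
        log_ratio = math.log(rv / lv) if lv > 0 and rv > 0 else math.nan
        denom = 0.5 * (rv + lv)
        asym = abs(diff) / denom if denom > 0 else math.nan
        out[name] = MetricComparison(lv, rv, diff, log_ratio, asym, False)
    return EyePairReport(subject_id=subject_id, roi_name=left.roi_name, metrics=out)


@dataclasses.dataclass
class AsymmetryTestResult:
    metric: str
    n_pairs: int
    statistic: float
    p_value: float
    median_difference: float
    all_zero: bool = False


class InsufficientPairsError(ValueError):
    pass


def cohort_asymmetry_test(pairs: list[EyePairReport], metric: str) -> AsymmetryTestResult:
    """Paired Wilcoxon signed-rank test of left vs right across a cohort.

    Pairs where the metric is missing on either side are dropped.  If every
    remaining difference is exactly zero the test statistic is undefined;
    the result carries ``all_zero=True`` with p = 1.
    """
    lefts, rights = [], []
    for p in pairs:
        cmp = p.metrics.get(metric)
        if cmp is None or cmp.missing:
            continue
        lefts.append(cmp.left)
        rights.append(cmp.right)
    if len(lefts) < 2:
        raise InsufficientPairsError(
            f"need >= 2 complete pairs for {metric}, have {len(lefts)}")
    lefts = np.asarray(lefts)
    rights = np.asarray(rights)
    diffs = rights - lefts
    median_diff = float(np.median(diffs))
    if np.all(diffs == 0):
        return AsymmetryTestResult(metric, len(diffs), 0.0, 1.0, 0.0, all_zero=True)
    res = stats.wilcoxon(rights, lefts, zero_method="wilcox",
                         alternative="two-sided")
    return AsymmetryTestResult(metric, len(diffs), float(res.statistic),
                               float(res.pvalue), median_diff)
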