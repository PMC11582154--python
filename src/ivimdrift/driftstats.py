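"""Drift quantification, test–retest repeatability, and exact rank tests.

Drift is summarized per ROI either as the signal difference between a
scan's first and last b = 0 acquisition normalized to 5 minutes, or as the
slope of a linear fit to the ROI-median signal over acquisition time (with
one intercept per encoding direction when b > 0, absorbing the directional
dependence of the diffusion-weighted signal).

Group comparisons across correction methods or acquisition orders use the
Friedman test with the test statistic's permutation null enumerated
exactly, gated at p < 0.05 before pairwise exact Wilcoxon signed-rank
tests — the standard nonparametric repeated-measures scheme for small
cohorts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import IVIMMaps, ImageSeries

__all__ = [
    "DriftSummary",
    "RepeatabilityRecord",
    "TestResult",
    "drift_first_last",
    "drift_slope",
    "repeatability",
    "friedman_exact",
    "signed_rank_exact",
    "select_representative",
]

logger = logging.getLogger(__name__)


@dataclass
class DriftSummary:
    """ROI-level drift in % per 5 min."""

    roi: str
    value: float
    metric: str            # "first_last" or "slope"
    scan_id: str
    b: float


@dataclass
class RepeatabilityRecord:
    """Test–retest summary for one parameter in one ROI."""

    parameter: str
    roi: str
    average: float         # mean of the two repetitions' ROI medians
    abs_difference: float  # |difference| of the two ROI medians
    group: str = ""        # correction method / acquisition order label


@dataclass
class TestResult:
    statistic: float
    p_exact: float
    n_blocks: int
    k_treatments: int
    method: str


def drift_first_last(series: ImageSeries, roi: np.ndarray,
                     roi_name: str = "") -> DriftSummary:
    """Signed drift between the first and last b = 0 acquisition, % / 5 min."""
    idx = series.scheme.b0_indices
    if idx.size < 2:
        raise ValueError("need >= 2 b = 0 acquisitions")
    roi = np.asarray(roi, dtype=bool)
    first = float(np.median(series.data[roi][:, idx[0]]))
    last = float(np.median(series.data[roi][:, idx[-1]]))
    if first == 0:
        raise ValueError("zero ROI-median signal at the first b = 0 volume")
    t = series.scheme.t
    elapsed = t[idx[-1]] - t[idx[0]]
    value = 100.0 * (last / first - 1.0) * 300.0 / elapsed
    scan = series.scheme.acquisitions[int(idx[0])].scan_id
    return DriftSummary(roi_name, value, "first_last", scan, 0.0)


def drift_slope(series: ImageSeries, roi: np.ndarray, b: float,
                roi_name: str = "") -> DriftSummary:
    """Slope of a linear fit to the ROI-median signal over time, % / 5 min.

    For b > 0 the model has one intercept per encoding direction and a
    common slope (fixed per-direction intercepts standing in for a random
    intercept); the slope is expressed as percent of the mean intercept.
    """
    sch = series.scheme
    sel = np.flatnonzero(sch.b == b)
    if sel.size < 2:
        raise ValueError(f"need >= 2 acquisitions at b = {b}")
    roi = np.asarray(roi, dtype=bool)
    y = np.array([np.median(series.data[roi][:, i]) for i in sel])
    t = sch.t[sel]

    if b == 0:
        groups = np.zeros(sel.size, dtype=int)
    else:
        dirs = [sch.acquisitions[int(i)].direction for i in sel]
        uniq = sorted(set(dirs))
        groups = np.array([uniq.index(d) for d in dirs])
        counts = np.bincount(groups)
        if np.any(counts < 2):
            raise ValueError("every direction group needs >= 2 time points")
    n_groups = groups.max() + 1
    A = np.zeros((sel.size, n_groups + 1))
    A[np.arange(sel.size), groups] = 1.0
    A[:, -1] = t
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    intercepts, slope = coef[:-1], coef[-1]
    value = 100.0 * slope * 300.0 / float(np.mean(intercepts))
    scan = sch.acquisitions[int(sel[0])].scan_id
    return DriftSummary(roi_name, value, "slope", scan, float(b))


def repeatability(maps_rep1: IVIMMaps, maps_rep2: IVIMMaps,
                  rois: dict[str, np.ndarray],
                  group: str = "") -> list[RepeatabilityRecord]:
    """Average and absolute difference of ROI medians across two scans."""
    records = []
    p1, p2 = maps_rep1.present(), maps_rep2.present()
    for param in p1:
        if param not in p2 or param in ("S0", "A"):
            continue
        for roi_name, roi in rois.items():
            v1 = p1[param][roi]
            v2 = p2[param][roi]
            v1, v2 = v1[~np.isnan(v1)], v2[~np.isnan(v2)]
            if v1.size == 0 or v2.size == 0:
                raise ValueError(f"ROI {roi_name!r} empty after validity "
                                 f"masking for {param!r}")
            m1, m2 = np.median(v1), np.median(v2)
            records.append(RepeatabilityRecord(
                param, roi_name, (m1 + m2) / 2.0, abs(m1 - m2), group))
    return records


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Friedman chi-square from within-block ranks (average ranks on ties)."""
    n, k = ranks.shape
    R = ranks.sum(axis=0)
    return float(12.0 / (n * k * (k + 1)) * np.sum(R ** 2) - 3.0 * n * (k + 1))


def friedman_exact(values: np.ndarray, cap: int = 10_000_000,
                   fallback: bool = True) -> TestResult:
    """Friedman test with the permutation null enumerated exactly.

    The p-value is the fraction of all (k!)^n within-block rank
    permutations whose statistic is >= the observed one.  Above ``cap``
    enumerated assignments the chi-square approximation is used instead
    (logged), unless ``fallback`` is False.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be an (n_blocks, k_treatments) table")
    n, k = values.shape
    if n < 2 or k < 2:
        raise ValueError("need n_blocks >= 2 and k_treatments >= 2")
    ranks = np.vstack([sps.rankdata(row) for row in values])
    observed = _friedman_statistic(ranks)

    total = math.factorial(k) ** n
    if total > cap:
        if not fallback:
            raise ValueError(f"(k!)^n = {total} exceeds enumeration cap {cap}")
        logger.info("friedman_exact: %d assignments exceed cap %d; using "
                    "chi-square approximation", total, cap)
        p = float(sps.chi2.sf(observed, k - 1))
        return TestResult(observed, p, n, k, "friedman-chi2-approx")

    # Convolve per-block rank-sum distributions; rank sums are half-integer
    # at worst, so keep 2x-scaled integer keys.
    perms = list(permutations(range(k)))
    states: dict[tuple, int] = {tuple([0] * k): 1}
    for row in ranks:
        row2 = np.rint(2.0 * row).astype(int)
        block = [tuple(row2[list(p)]) for p in perms]
        new: dict[tuple, int] = {}
        for state, cnt in states.items():
            for arr in block:
                key = tuple(s + a for s, a in zip(state, arr))
                new[key] = new.get(key, 0) + cnt
        states = new

    count = 0
    scale = 12.0 / (n * k * (k + 1))
    shift = 3.0 * n * (k + 1)
    for key, cnt in states.items():
        stat = scale * sum((r / 2.0) ** 2 for r in key) - shift
        if stat >= observed - 1e-9:
            count += cnt
    return TestResult(observed, count / total, n, k, "friedman-exact")


def signed_rank_exact(x, y, max_exact_n: int = 25) -> TestResult:
    """Two-sided Wilcoxon signed-rank test with exact sign enumeration.

    Zero differences are dropped; |differences| are ranked with average
    ranks on ties; the exact two-sided p-value sums, over all 2^n sign
    assignments, those with |W - T/2| >= |observed W - T/2| (the null
    distribution is symmetric about half the total rank sum T).  For
    n > ``max_exact_n`` the normal approximation is used.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    W = float(ranks[d > 0].sum())
    T = float(ranks.sum())
    n = d.size

    if n > max_exact_n:
        res = sps.wilcoxon(d, alternative="two-sided", method="approx",
                           correction=False)
        return TestResult(W, float(res.pvalue), n, 2, "signed-rank-approx")

    # Distribution of 2W over sign flips by integer convolution.
    dist: dict[int, int] = {0: 1}
    for r in np.rint(2.0 * ranks).astype(int):
        new: dict[int, int] = {}
        for s, cnt in dist.items():
            for add in (0, r):
                new[s + add] = new.get(s + add, 0) + cnt
        dist = new
    center = T  # = 2T/2 on the doubled scale
    obs_dev = abs(2.0 * W - center)
    count = sum(cnt for s, cnt in dist.items()
                if abs(s - center) >= obs_dev - 1e-9)
    return TestResult(W, count / 2 ** n, n, 2, "signed-rank-exact")


def select_representative(drift_table: pd.DataFrame) -> tuple:
    """Pick the (subject, repetition) closest to typical drift behavior.

    ``drift_table`` has columns subject, repetition, roi, scan, value.  For
    each (roi, scan) column the absolute distance to the column median is
    ranked (average ranks on ties); the (subject, repetition) with the
    lowest rank sum wins, ties broken by lowest subject then repetition.
    """
    required = {"subject", "repetition", "roi", "scan", "value"}
    if drift_table.empty or not required.issubset(drift_table.columns):
        raise ValueError(f"drift_table needs columns {sorted(required)} and "
                         "at least one row")
    pivot = drift_table.pivot_table(index=["subject", "repetition"],
                                    columns=["roi", "scan"], values="value")
    dist = (pivot - pivot.median(axis=0)).abs()
    ranksum = dist.rank(axis=0, method="average").sum(axis=1)
    best = ranksum[ranksum == ranksum.min()]
    return tuple(sorted(best.index)[0])
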