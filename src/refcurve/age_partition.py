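"""Overlapping age groups with high temporal resolution.

Step 1 of the pipeline: every day of life gets (conceptually) its own age
group; to bound the total number of groups, the base group width grows
linearly with age (1% of the age in days by default), and consecutive groups
tile the age axis edge-to-edge.  Each group is then expanded symmetrically
(left first) until it holds at least ``n_min`` samples, where samples are
counted after per-subject deduplication: within a group a subject keeps only
the measurement whose age is most central.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core_io import MeasurementSet, PipelineConfig

logger = logging.getLogger(__name__)


@dataclass
class AgeGroup:
    """One overlapping age group.

    ``base_lower/base_upper`` come from the width rule alone; ``lower/upper``
    after expansion to ``n_min``.  ``member_idx`` are positional indices into
    the originating MeasurementSet, at most one per subject.
    """

    center_day: int
    base_lower: int
    base_upper: int
    lower: int
    upper: int
    member_idx: np.ndarray

    @property
    def n_members(self) -> int:
        return len(self.member_idx)


def base_halfwidth(center_day: float, width_growth: float) -> float:
    """Half-width of the base group: at least half a day, growing as
    ``width_growth * age / 2`` (so total width is ``width_growth * age``)."""
    return max(0.5, width_growth * center_day / 2.0)


def _base_range(center: int, width_growth: float) -> tuple[int, int]:
    h = base_halfwidth(center, width_growth)
    return math.ceil(center - h), math.floor(center + h)


def candidate_centers(max_age_days: int, width_growth: float) -> list[int]:
    """Center days of the tiled groups over [1, max_age_days].

    While the half-width is at the half-day floor (center <= 1/width_growth)
    centers advance daily; beyond that the next center is the smallest
    integer whose base range starts after the previous base range ends, so
    consecutive base ranges tile the axis without gaps.
    """
    if max_age_days < 1:
        raise ValueError("max_age_days must be >= 1")
    if not 0 < width_growth < 1:
        raise ValueError("width_growth must lie in (0, 1)")
    centers = [1]
    _, prev_upper = _base_range(1, width_growth)
    c = 1
    while True:
        nxt = c + 1
        while math.ceil(nxt - base_halfwidth(nxt, width_growth)) <= prev_upper:
            nxt += 1
        if nxt > max_age_days:
            break
        centers.append(nxt)
        _, prev_upper = _base_range(nxt, width_growth)
        c = nxt
    return centers


def daily_center_count(max_age_days: int) -> int:
    """Number of daily candidate groups before width-based thinning: one per
    day of life from day 1 through max_age_days."""
    return int(max_age_days)


def select_central_sample_per_subject(
    center: int,
    member_indices: np.ndarray,
    ages: np.ndarray,
    subject_codes: np.ndarray,
) -> np.ndarray:
    """Keep, per subject, the one sample with age closest to ``center``.

    Ties in |age - center| keep the younger sample; remaining ties keep the
    first occurrence.  ``ages`` and ``subject_codes`` are aligned with the
    full dataset; ``member_indices`` select the group's rows.
    """
    idx = np.asarray(member_indices)
    if idx.size == 0:
        return idx
    a = ages[idx]
    s = subject_codes[idx]
    dist = np.abs(a - center)
    order = np.lexsort((idx, a, dist, s))  # by subject, then dist, age, index
    s_sorted = s[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = s_sorted[1:] != s_sorted[:-1]
    kept = idx[order[first]]
    kept.sort()
    return kept


class _AgeIndex:
    """Age-sorted view of a dataset for fast windowed member queries."""

    def __init__(self, ages: np.ndarray, subject_ids: np.ndarray) -> None:
        self.order = np.argsort(ages, kind="stable")
        self.ages_sorted = ages[self.order]
        _, codes = np.unique(subject_ids, return_inverse=True)
        self.codes = codes
        self.codes_sorted = codes[self.order]
        self.ages = ages
        self.age_min = int(self.ages_sorted[0])
        self.age_max = int(self.ages_sorted[-1])

    def window(self, lower: int, upper: int) -> np.ndarray:
        i0 = np.searchsorted(self.ages_sorted, lower, side="left")
        i1 = np.searchsorted(self.ages_sorted, upper, side="right")
        return self.order[i0:i1]

    def distinct_subjects(self, lower: int, upper: int) -> int:
        i0 = np.searchsorted(self.ages_sorted, lower, side="left")
        i1 = np.searchsorted(self.ages_sorted, upper, side="right")
        if i1 <= i0:
            return 0
        return len(np.unique(self.codes_sorted[i0:i1]))


def _range_after_steps(
    base_lower: int, base_upper: int, steps: int, dmin: int, dmax: int
) -> tuple[int, int]:
    """Day range after ``steps`` one-day extensions, alternating lower first;
    a side stopped at the data's age bound spills its steps to the other."""
    cap_left = max(0, base_lower - dmin)
    cap_right = max(0, dmax - base_upper)
    left = math.ceil(steps / 2)
    right = steps // 2
    if left > cap_left and right > cap_right:
        left, right = cap_left, cap_right
    elif left > cap_left:
        left = cap_left
        right = min(cap_right, steps - cap_left)
    elif right > cap_right:
        right = cap_right
        left = min(cap_left, steps - cap_right)
    return base_lower - left, base_upper + right


def expand_group_to_min_n(
    center: int,
    base_lower: int,
    base_upper: int,
    index: _AgeIndex,
    n_min: int,
) -> tuple[int, int, np.ndarray]:
    """Minimal symmetric expansion of a base range to >= n_min deduplicated
    members; returns (lower, upper, member_idx).

    The expansion schedule alternates one-day extensions starting with the
    lower bound; the deduplicated member count is monotone in the number of
    steps, so the minimal step count is found by bisection.
    """
    dmin, dmax = index.age_min, index.age_max
    base_lower_c = max(base_lower, 0)

    def count(steps: int) -> int:
        lo, hi = _range_after_steps(base_lower_c, base_upper, steps, dmin, dmax)
        return index.distinct_subjects(lo, hi)

    s_max = max(0, base_lower_c - dmin) + max(0, dmax - base_upper)
    if count(0) >= n_min:
        steps = 0
    else:
        # exponential search keeps probe windows near the target size,
        # then bisection pins the minimal step count (count is monotone)
        last_fail = 0
        hi_s = 1
        while hi_s < s_max and count(hi_s) < n_min:
            last_fail = hi_s
            hi_s = min(2 * hi_s, s_max)
        if count(hi_s) < n_min:
            logger.warning(
                "group at day %d: dataset holds only %d distinct-subject samples "
                "(< n_min = %d); group spans all data", center, count(hi_s), n_min,
            )
            steps = s_max
        else:
            lo_s = last_fail
            while hi_s - lo_s > 1:  # count(lo_s) < n_min <= count(hi_s)
                mid = (lo_s + hi_s) // 2
                if count(mid) >= n_min:
                    hi_s = mid
                else:
                    lo_s = mid
            steps = hi_s
    lower, upper = _range_after_steps(base_lower_c, base_upper, steps, dmin, dmax)
    members = index.window(lower, upper)
    kept = select_central_sample_per_subject(center, members, index.ages, index.codes)
    return lower, upper, kept


def build_age_groups(ms: MeasurementSet, config: PipelineConfig) -> list[AgeGroup]:
    """Construct all age groups for a dataset (step 1 of the pipeline)."""
    index = _AgeIndex(ms.age_days, ms.subject_id)
    centers = candidate_centers(config.max_age_days, config.width_growth)
    groups: list[AgeGroup] = []
    for i, c in enumerate(centers):
        b_lo, b_hi = _base_range(c, config.width_growth)
        if i == 0:
            b_lo = 0  # newborn day-0 samples belong to the first group
        lo, hi, kept = expand_group_to_min_n(c, b_lo, b_hi, index, config.n_min)
        groups.append(AgeGroup(c, b_lo, b_hi, lo, hi, kept))
    logger.info("built %d age groups over days [0, %d]", len(groups), config.max_age_days)
    return groups


def groups_to_frame(groups: list[AgeGroup]):
    """Diagnostic table (center, lower, upper, n) for export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "center_day": [g.center_day for g in groups],
            "lower": [g.lower for g in groups],
            "upper": [g.upper for g in groups],
            "n": [g.n_members for g in groups],
        }
    )
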