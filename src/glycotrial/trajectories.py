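"""Classification of longitudinal HbA1c series into progression patterns.

A three-year analysis frame is anchored at each person's first in-frame
measurement (the baseline).  Follow-up values are labelled with one of four
trajectory patterns, applied in order with first match winning:

1. sustained decrease  - at least one value strictly below baseline and all
   values at or below baseline;
2. sustained increase  - at least one value strictly above baseline and all
   values at or above baseline;
3. oscillatory, predominantly decreasing - a majority (but not all) of the
   values at or below baseline;
4. oscillatory, predominantly increasing - half or more (but not all) of the
   values strictly above baseline.

A series whose follow-ups all equal baseline fits none of the strict
conditions and is reported as unclassifiable rather than forced into a
category.  Eligibility requires a baseline at or above a floor (default 52
mmol/mol), at least three measurements inside the frame and, by default, no
glucose-lowering medication change inside the frame.  Sustained-improvement
rates between two groups are compared with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DomainError

__all__ = [
    "PATTERN_LABELS",
    "EligibilityRule",
    "is_eligible",
    "classify_pattern",
    "classify_series",
    "pattern_table",
    "compare_sustained_rates",
]

PATTERN_LABELS = (
    "sustained_decrease",
    "sustained_increase",
    "oscillatory_decreasing",
    "oscillatory_increasing",
    "unclassifiable",
)


@dataclass(frozen=True)
class EligibilityRule:
    """Inclusion filters for the trajectory analysis."""
    min_measurements: int = 3
    frame_days: int = 1095
    baseline_floor: float = 52.0
    require_no_med_change: bool = True

    def __post_init__(self):
        if self.min_measurements < 2:
            raise DomainError("min_measurements must be at least 2")
        if self.frame_days <= 0:
            raise DomainError("frame_days must be positive")


def _frame_mask(days: np.ndarray, rule: EligibilityRule) -> np.ndarray:
    return days <= days[0] + rule.frame_days


def is_eligible(days: Sequence[float], hba1c: Sequence[float],
                med_change: Sequence[bool], rule: EligibilityRule) -> bool:
    """True iff the series passes baseline floor, count and medication filters.

    ``days`` must be sorted ascending; the analysis frame starts at the first
    measurement.
    """
    d = np.asarray(days, float)
    if d.size == 0:
        raise DataError("empty series")
    if np.any(np.diff(d) < 0):
        raise DataError("series days must be sorted ascending")
    v = np.asarray(hba1c, float)
    m = np.asarray(med_change, bool)
    in_frame = _frame_mask(d, rule)
    if v[0] < rule.baseline_floor:
        return False
    if int(in_frame.sum()) < rule.min_measurements:
        return False
    if rule.require_no_med_change and m[in_frame].any():
        return False
    return True


def classify_pattern(baseline: float, followups: Sequence[float]) -> str:
    """Assign one of the four trajectory patterns (or unclassifiable).

    Rules are checked in order 1-4 with first match winning; see module
    docstring for definitions.
    """
    f = np.asarray(followups, float)
    if f.size == 0:
        raise DomainError("at least one follow-up value is required")
    n = f.size
    n_below = int((f < baseline).sum())
    n_le = int((f <= baseline).sum())
    n_above = int((f > baseline).sum())
    n_ge = int((f >= baseline).sum())
    if n_below >= 1 and n_le == n:
        return "sustained_decrease"
    if n_above >= 1 and n_ge == n:
        return "sustained_increase"
    if n_le > n / 2 and n_le < n:
        return "oscillatory_decreasing"
    if n_above >= n / 2 and n_above < n:
        return "oscillatory_increasing"
    return "unclassifiable"


def classify_series(visits: pd.DataFrame, rule: EligibilityRule | None = None,
                    value_col: str = "hba1c") -> pd.DataFrame:
    """Classify every person in a long visits table.

    Expects columns ``id, day, med_change`` plus ``value_col``; rows with a
    missing value are dropped before framing.  Returns one row per eligible
    person: ``id, label, n_measurements, frame_span_days``.
    """
    rule = rule or EligibilityRule()
    rows = []
    for pid, g in visits.dropna(subset=[value_col]).groupby("id", sort=True):
        g = g.sort_values("day")
        d = g["day"].to_numpy(float)
        if np.unique(d).size != d.size:
            raise DataError(f"duplicate visit days for id {pid}")
        if not is_eligible(d, g[value_col].to_numpy(), g["med_change"].to_numpy(), rule):
            continue
        in_frame = _frame_mask(d, rule)
        vals = g[value_col].to_numpy(float)[in_frame]
        label = classify_pattern(vals[0], vals[1:])
        rows.append({
            "id": pid, "label": label, "n_measurements": int(in_frame.sum()),
            "frame_span_days": int(d[in_frame][-1] - d[0]),
        })
    return pd.DataFrame(rows, columns=["id", "label", "n_measurements", "frame_span_days"])


def pattern_table(labels: Sequence[str]) -> pd.DataFrame:
    """Counts and proportions per pattern label; proportions sum to one."""
    labels = list(labels)
    if not labels:
        raise DomainError("pattern_table requires at least one classified series")
    counts = pd.Series(labels).value_counts()
    out = pd.DataFrame({
        "label": PATTERN_LABELS,
        "count": [int(counts.get(l, 0)) for l in PATTERN_LABELS],
    })
    out["proportion"] = out["count"] / len(labels)
    return out


def compare_sustained_rates(n_users: int, k_users_sustained: int,
                            n_controls: int, k_controls_sustained: int) -> float:
    """Two-sided Fisher exact p for sustained improvement, users vs controls."""
    for n, k in ((n_users, k_users_sustained), (n_controls, k_controls_sustained)):
        if not 0 <= k <= n:
            raise DomainError(f"need 0 <= k <= n, got k={k}, n={n}")
    table = [[k_users_sustained, n_users - k_users_sustained],
             [k_controls_sustained, n_controls - k_controls_sustained]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
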