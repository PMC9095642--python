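"""Quarterly exposure-response binning and BCT weighted responder scoring.

During year one, participants attend quarterly visits.  Each adjacent pair
of year-one visits with HbA1c on both ends defines a quarterly period; the
themes completed in the half-open interval (previous visit day, current
visit day] are its exposure and the HbA1c difference (end minus start) its
response.  Periods are pooled across participants into exposure bins
{0, 1-4, >=5 themes}.

For the behavior-change-technique analysis, a participant completing a theme
in a period counts as a responder if HbA1c fell over that period and as a
non-responder otherwise (a zero change is "similar", hence non-responder).
Per theme and quarter the responder and non-responder counts are multiplied
by each of the theme's 2-4 BCT dominance weights, and the products are summed
over quarters and themes into one responder and one non-responder score per
BCT.  The resulting 2xK score table is compared with a Pearson chi-square
test; when the scores are non-integer this treats weighted scores as counts,
so the statistic scales linearly with any rescaling of the weights (a caveat
the function warns about).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd

from .cohort import ThemeCatalog
from .errors import DataError, DomainError

__all__ = [
    "QuarterPeriod",
    "YEAR1_WINDOW_DAYS",
    "quarterly_periods",
    "exposure_response_bins",
    "bct_scores",
    "bct_chi_square",
]

#: Visits starting up to this day count as year-one (quarterly) visits;
#: allows for scheduling jitter around the nominal day-365 visit.
YEAR1_WINDOW_DAYS = 410

EXPOSURE_BINS = ("0", "1-4", ">=5")


@dataclass(frozen=True)
class QuarterPeriod:
    id: str
    quarter_index: int
    themes_completed: int
    delta_hba1c: float


def quarterly_periods(visits: pd.DataFrame, completions: pd.DataFrame,
                      max_quarters: int = 4) -> pd.DataFrame:
    """One row per year-one quarterly period with HbA1c at both ends.

    ``visits`` is the long table (id, day, hba1c, ...); ``completions`` holds
    theme events (id, day, theme_id).  Theme events are counted in the
    half-open interval (previous visit day, current visit day].  Periods with
    a missing HbA1c at either bounding visit are omitted, not imputed.
    """
    rows = []
    comp_by_id = dict(tuple(completions.groupby("id"))) if len(completions) else {}
    for pid, g in visits.groupby("id", sort=True):
        g = g.sort_values("day")
        days = g["day"].to_numpy()
        if np.unique(days).size != days.size:
            raise DataError(f"duplicate visit days for id {pid}")
        year1 = g[g["day"] <= YEAR1_WINDOW_DAYS]
        d = year1["day"].to_numpy()
        v = year1["hba1c"].to_numpy(float)
        comp_days = (comp_by_id[pid]["day"].to_numpy()
                     if pid in comp_by_id else np.empty(0, int))
        for q in range(min(len(d) - 1, max_quarters)):
            start, end = d[q], d[q + 1]
            if np.isnan(v[q]) or np.isnan(v[q + 1]):
                continue
            count = int(((comp_days > start) & (comp_days <= end)).sum())
            rows.append({
                "id": pid, "quarter_index": q + 1, "themes_completed": count,
                "delta_hba1c": float(v[q + 1] - v[q]),
                "start_day": int(start), "end_day": int(end),
            })
    return pd.DataFrame(
        rows, columns=["id", "quarter_index", "themes_completed", "delta_hba1c",
                       "start_day", "end_day"])


def exposure_response_bins(periods: pd.DataFrame) -> pd.DataFrame:
    """Per-bin (n, mean delta, SEM) for theme-count bins {0, 1-4, >=5}.

    Bin sizes always sum to the number of periods; an empty bin is reported
    with n = 0 and undefined (NaN) mean and SEM.
    """
    if len(periods) == 0:
        raise DomainError("exposure_response_bins requires at least one period")
    counts = periods["themes_completed"].to_numpy()
    delta = periods["delta_hba1c"].to_numpy(float)
    masks = {"0": counts == 0, "1-4": (counts >= 1) & (counts <= 4), ">=5": counts >= 5}
    rows = []
    for label in EXPOSURE_BINS:
        sel = delta[masks[label]]
        n = int(sel.size)
        mean = float(sel.mean()) if n else float("nan")
        sem = float(sel.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append({"bin": label, "n": n, "mean_delta": mean, "sem": sem})
    return pd.DataFrame(rows, columns=["bin", "n", "mean_delta", "sem"])


def bct_scores(visits: pd.DataFrame, completions: pd.DataFrame,
               catalog: ThemeCatalog, count_repeats: bool = True) -> pd.DataFrame:
    """Responder / non-responder weighted scores per behavior change technique.

    For every quarterly period and theme, the number of responder completions
    (period HbA1c change < 0) and non-responder completions (change >= 0) is
    multiplied by each of the theme's BCT dominance weights and accumulated
    over the four quarters and all themes.  With ``count_repeats`` (default)
    every completion event counts; otherwise a participant contributes at most
    once per theme per quarter.
    """
    weight_map: Dict[str, Dict[str, float]] = {t.theme_id: t.bct_weights
                                               for t in catalog.themes}
    unknown = set(completions["theme_id"]) - set(weight_map)
    if unknown:
        raise DataError(f"completions reference unknown themes: {sorted(unknown)[:5]}")
    periods = quarterly_periods(visits, completions)
    bct_ids = sorted({b for w in weight_map.values() for b in w})
    resp = {b: 0.0 for b in bct_ids}
    nonresp = {b: 0.0 for b in bct_ids}
    comp_by_id = dict(tuple(completions.groupby("id"))) if len(completions) else {}
    for row in periods.itertuples():
        if row.id not in comp_by_id:
            continue
        c = comp_by_id[row.id]
        in_period = c[(c["day"] > row.start_day) & (c["day"] <= row.end_day)]
        themes = (in_period["theme_id"] if count_repeats
                  else in_period["theme_id"].drop_duplicates())
        target = resp if row.delta_hba1c < 0 else nonresp
        for theme_id, k in themes.value_counts().items():
            for b, w in weight_map[theme_id].items():
                target[b] += float(k) * w
    return pd.DataFrame({
        "bct_id": bct_ids,
        "responder_score": [resp[b] for b in bct_ids],
        "nonresponder_score": [nonresp[b] for b in bct_ids],
    })


def bct_chi_square(table: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square on the 2xK responder/non-responder score table.

    Columns (BCTs) with a zero total are excluded with a warning; df = K - 1.
    Scores are treated as counts, so non-integer (weighted) scores make the
    statistic scale with the overall weight normalization - also warned about.
    """
    r = table["responder_score"].to_numpy(float)
    s = table["nonresponder_score"].to_numpy(float)
    keep = (r + s) > 0
    if (~keep).any():
        warnings.warn(
            f"excluding {int((~keep).sum())} BCT column(s) with zero total score",
            stacklevel=2)
    r, s = r[keep], s[keep]
    if r.size < 2:
        raise DomainError("chi-square needs at least 2 BCTs with positive totals")
    obs = np.vstack([r, s])
    if not np.allclose(obs, np.round(obs)):
        warnings.warn(
            "scores are non-integer; chi-square treats them as counts and the "
            "statistic scales with the weight normalization", stacklevel=2)
    row_tot = obs.sum(axis=1, keepdims=True)
    col_tot = obs.sum(axis=0, keepdims=True)
    expected = row_tot @ col_tot / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = obs.shape[1] - 1
    from scipy import stats as sps
    p = float(sps.chi2.sf(stat, df))
    return stat, df, p
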