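"""Readers and writers for the pipeline's delimited-text interchange files.

All files are comma-separated UTF-8 with a header row; dates are integer day
offsets from each person's first visit, so no locale or date-format parsing
is involved.  Round-trips through these functions are lossless at float
precision (pandas round-trip representation).

Files
-----
participants.csv : one row per participant (baseline covariates, arm, flags)
visits.csv       : long format, one row per visit with raw and biomarker columns
registry.csv     : long format, one row per registry HbA1c registration
completions.csv  : theme-completion events (id, day, theme_id)
themes.json      : theme catalog with per-theme BCT dominance weights
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Tuple

import pandas as pd

from .cohort import (
    ParticipantRecord,
    RegistryRecord,
    Theme,
    ThemeCatalog,
    Visit,
    VisitSeries,
    SECONDARY_BASELINES,
)

PARTICIPANT_COLUMNS = [
    "id", "sex", "age", "height_cm", "bmi", "weight_kg", "baseline_hba1c",
    "arm", "mod", "usage_class", "dropped_out", "education", "socioeconomic",
    "medication",
]
VISIT_COLUMNS = [
    "id", "day", "hba1c", "weight", "resistance", "reactance", "med_change",
] + list(SECONDARY_BASELINES)
REGISTRY_COLUMNS = ["id", "sex", "age", "bmi", "diagnosis_day", "day", "hba1c", "med_change"]
COMPLETION_COLUMNS = ["id", "day", "theme_id"]


def participants_frame(participants: Sequence[ParticipantRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in participants], columns=PARTICIPANT_COLUMNS)


def visits_frame(series: Sequence[VisitSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for v in s.visits:
            row = {
                "id": s.id, "day": v.day, "hba1c": v.hba1c, "weight": v.weight,
                "resistance": v.resistance, "reactance": v.reactance,
                "med_change": v.med_change,
            }
            row.update(v.extras)
            rows.append(row)
    return pd.DataFrame(rows, columns=VISIT_COLUMNS)


def registry_frame(records: Sequence[RegistryRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        med = set(r.med_change_days)
        prev = -1
        for day, value in zip(r.days, r.hba1c):
            flag = any(prev < m <= day for m in med)
            rows.append({
                "id": r.id, "sex": r.sex, "age": r.age, "bmi": r.bmi,
                "diagnosis_day": r.diagnosis_day, "day": day, "hba1c": value,
                "med_change": flag,
            })
            prev = day
    return pd.DataFrame(rows, columns=REGISTRY_COLUMNS)


def completions_frame(events: Sequence[Tuple[str, int, str]]) -> pd.DataFrame:
    return pd.DataFrame(list(events), columns=COMPLETION_COLUMNS)


# ---------------------------------------------------------------------------
# round-trip readers


def write_participants(df_or_records, path: Path) -> None:
    df = df_or_records if isinstance(df_or_records, pd.DataFrame) else participants_frame(df_or_records)
    df.to_csv(path, index=False)


def read_participants(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("mod", "dropped_out"):
        df[col] = df[col].astype(bool)
    return df[PARTICIPANT_COLUMNS]


def write_visits(df_or_series, path: Path) -> None:
    df = df_or_series if isinstance(df_or_series, pd.DataFrame) else visits_frame(df_or_series)
    df.to_csv(path, index=False)


def read_visits(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["med_change"] = df["med_change"].astype(bool)
    return df[VISIT_COLUMNS]


def write_registry(df_or_records, path: Path) -> None:
    df = df_or_records if isinstance(df_or_records, pd.DataFrame) else registry_frame(df_or_records)
    df.to_csv(path, index=False)


def read_registry(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["med_change"] = df["med_change"].astype(bool)
    return df[REGISTRY_COLUMNS]


def write_completions(df_or_events, path: Path) -> None:
    df = df_or_events if isinstance(df_or_events, pd.DataFrame) else completions_frame(df_or_events)
    df.to_csv(path, index=False)


def read_completions(path: Path) -> pd.DataFrame:
    return pd.read_csv(path)[COMPLETION_COLUMNS]


def write_theme_catalog(catalog: ThemeCatalog, path: Path) -> None:
    payload = {
        "themes": [
            {"theme_id": t.theme_id, "bct_weights": t.bct_weights}
            for t in catalog.themes
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_theme_catalog(path: Path) -> ThemeCatalog:
    payload = json.loads(Path(path).read_text())
    return ThemeCatalog(
        themes=[Theme(theme_id=t["theme_id"], bct_weights=dict(t["bct_weights"]))
                for t in payload["themes"]]
    )
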