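"""Deterministic derived measurements.

Bioimpedance body composition from single-frequency resistance/reactance
readings (sex-specific fat-free-mass and total-body-water prediction
equations with height in centimetres and impedance in ohms), physical
activity dose from IPAQ questionnaire minutes, and per-user tool cost
aggregation.  All functions are pure and accept numpy arrays elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .errors import DomainError, ImplausibleMeasurementError

__all__ = [
    "BodyComposition",
    "IpaqSummary",
    "fat_free_mass",
    "total_body_water",
    "body_composition",
    "ipaq_met_minutes",
    "ipaq_to_kcal",
    "tool_cost_per_user",
    "add_body_composition",
    "MUSCLE_MASS_FACTOR",
]

ArrayLike = Union[float, np.ndarray]

#: Muscle mass as a share of fat-free mass: FFM minus extracellular water
#: (29%) and bone mineral (7%).
MUSCLE_MASS_FACTOR = 1.0 - 0.29 - 0.07  # = 0.64

#: MET values of the standard IPAQ scoring protocol.
MET_VIGOROUS, MET_MODERATE, MET_WALKING = 8.0, 4.0, 3.3


@dataclass(frozen=True)
class BodyComposition:
    """Body compartments in kg and as percentages of body weight."""
    ffm: float
    tbw: float
    fm: float
    mm: float
    fat_pct: float
    muscle_pct: float


@dataclass(frozen=True)
class IpaqSummary:
    met_minutes: float
    kcal: float


def _is_male(sex) -> np.ndarray:
    s = np.asarray(sex)
    if s.dtype.kind in "USO":
        return np.char.lower(s.astype(str)) == "male"
    return s.astype(bool)


def _check_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if np.any(np.asarray(value) <= 0):
            raise DomainError(f"{name} must be strictly positive")


def fat_free_mass(sex, height: ArrayLike, weight: ArrayLike,
                  resistance: ArrayLike, reactance: ArrayLike) -> ArrayLike:
    """Fat-free mass (kg) from a single-frequency bioimpedance reading.

    FFM = -4.104 + 0.518 h^2/R + 0.231 w + 0.130 Xc, plus 4.229 for males
    (the sex indicator is the only term distinguishing the two equations).
    Height in cm, impedance in ohm, weight in kg.
    """
    _check_positive(height=height, weight=weight, resistance=resistance)
    if np.any(np.asarray(reactance) < 0):
        raise DomainError("reactance must be non-negative")
    h, w = np.asarray(height, float), np.asarray(weight, float)
    r, xc = np.asarray(resistance, float), np.asarray(reactance, float)
    ffm = -4.104 + 0.518 * h * h / r + 0.231 * w + 0.130 * xc + 4.229 * _is_male(sex)
    return float(ffm) if np.isscalar(height) else ffm


def total_body_water(sex, height: ArrayLike, weight: ArrayLike,
                     resistance: ArrayLike) -> ArrayLike:
    """Total body water (kg) from the sex-specific multi-component model.

    Males:   TBW = 1.20 + 0.45 h^2/R + 0.18 w
    Females: TBW = 3.75 + 0.45 h^2/R + 0.11 w
    """
    _check_positive(height=height, weight=weight, resistance=resistance)
    h, w = np.asarray(height, float), np.asarray(weight, float)
    r = np.asarray(resistance, float)
    male = _is_male(sex)
    hr = 0.45 * h * h / r
    tbw = np.where(male, 1.20 + hr + 0.18 * w, 3.75 + hr + 0.11 * w)
    return float(tbw) if np.isscalar(height) else tbw


def body_composition(sex, height: float, weight: float,
                     resistance: float, reactance: float) -> BodyComposition:
    """Full body-composition breakdown for one measurement.

    Fat mass is body weight minus fat-free mass (conservation holds exactly);
    muscle mass is 0.64 x FFM.  An FFM at or above body weight is raised as an
    implausible measurement rather than clipped.
    """
    ffm = fat_free_mass(sex, height, weight, resistance, reactance)
    if ffm >= weight:
        raise ImplausibleMeasurementError(
            f"fat-free mass {ffm:.2f} kg >= body weight {weight:.2f} kg"
        )
    tbw = total_body_water(sex, height, weight, resistance)
    fm = weight - ffm
    mm = MUSCLE_MASS_FACTOR * ffm
    return BodyComposition(
        ffm=ffm, tbw=tbw, fm=fm, mm=mm,
        fat_pct=100.0 * fm / weight, muscle_pct=100.0 * mm / weight,
    )


def ipaq_met_minutes(vigorous_min_wk: ArrayLike, moderate_min_wk: ArrayLike,
                     walking_min_wk: ArrayLike) -> ArrayLike:
    """Weekly MET-minutes from IPAQ activity minutes (8.0/4.0/3.3 MET)."""
    for name, v in (("vigorous_min_wk", vigorous_min_wk),
                    ("moderate_min_wk", moderate_min_wk),
                    ("walking_min_wk", walking_min_wk)):
        if np.any(np.asarray(v) < 0):
            raise DomainError(f"{name} must be non-negative")
    out = (MET_VIGOROUS * np.asarray(vigorous_min_wk, float)
           + MET_MODERATE * np.asarray(moderate_min_wk, float)
           + MET_WALKING * np.asarray(walking_min_wk, float))
    return float(out) if np.isscalar(vigorous_min_wk) else out


def ipaq_to_kcal(met_minutes: ArrayLike, weight: ArrayLike) -> ArrayLike:
    """Kilocalories per week: MET-minutes x (weight in kg / 60 kg).

    MET-minute scores equal kilocalories for a 60-kg person.
    """
    if np.any(np.asarray(met_minutes) < 0):
        raise DomainError("met_minutes must be non-negative")
    _check_positive(weight=weight)
    out = np.asarray(met_minutes, float) * np.asarray(weight, float) / 60.0
    return float(out) if np.isscalar(met_minutes) else out


def tool_cost_per_user(components: Iterable[float]) -> tuple[float, float]:
    """Sum yearly per-user cost components in dollars.

    Returns ``(total, total rounded to one decimal)``; an empty component
    list costs nothing.
    """
    comps = [float(c) for c in components]
    if any(c < 0 for c in comps):
        raise DomainError("cost components must be non-negative")
    total = float(sum(comps))
    return total, round(total, 1)


def add_body_composition(visits: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Vectorized entry point over the long visits table.

    Joins sex and height from the participants table and appends the derived
    columns ``ffm_kg, fm_kg, mm_kg, fat_pct, muscle_pct``.  Rows with
    implausible compositions (FFM >= weight) raise, listing the offending ids.
    """
    merged = visits.merge(participants[["id", "sex", "height_cm"]], on="id", how="left")
    if merged["sex"].isna().any():
        missing = merged.loc[merged["sex"].isna(), "id"].unique()
        raise DomainError(f"visits reference unknown participants: {list(missing)[:5]}")
    ffm = fat_free_mass(merged["sex"].to_numpy(), merged["height_cm"].to_numpy(),
                        merged["weight"].to_numpy(), merged["resistance"].to_numpy(),
                        merged["reactance"].to_numpy())
    bad = ffm >= merged["weight"].to_numpy()
    if bad.any():
        ids = merged.loc[bad, "id"].unique()
        raise ImplausibleMeasurementError(
            f"fat-free mass >= body weight for ids {list(ids)[:10]}"
        )
    out = visits.copy()
    out["ffm_kg"] = ffm
    out["fm_kg"] = merged["weight"].to_numpy() - ffm
    out["mm_kg"] = MUSCLE_MASS_FACTOR * ffm
    out["fat_pct"] = 100.0 * out["fm_kg"] / merged["weight"].to_numpy()
    out["muscle_pct"] = 100.0 * out["mm_kg"] / merged["weight"].to_numpy()
    return out
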