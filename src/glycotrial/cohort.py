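"""Synthetic trial cohort, registry control pool and theme catalog.

The generator emulates a randomized wait-list trial of a self-managed digital
lifestyle tool in type 2 diabetes: participants enter with HbA1c at or above a
treatment-target floor, are randomized 1:1 to immediate access or a 12-week
wait, attend quarterly visits in year one and semiannual visits thereafter,
and settle into one of four usage classes (biweekly / monthly / bimonthly /
non-user).  HbA1c follows a slow secular upward drift plus a usage-dependent
improvement; a pathophysiological subgroup (MOD: obese, insulin-resistant,
preserved secretion) responds more strongly.  A registry pool of usual-care
patients with diagnosis dates, routine HbA1c series and sporadic
glucose-lowering medication changes supplies matched controls.

All randomness flows through a single ``numpy.random.Generator`` derived from
the config seed, so identical configs produce bitwise-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "CohortConfig",
    "ParticipantRecord",
    "Visit",
    "VisitSeries",
    "RegistryRecord",
    "Theme",
    "ThemeCatalog",
    "ngsp_rate_to_ifcc",
    "generate_cohort",
    "generate_registry",
    "generate_theme_catalog",
    "generate_completions",
    "USAGE_CLASSES",
    "SECONDARY_BASELINES",
    "SECONDARY_EFFECTS_BIWEEKLY",
    "SECONDARY_NOISE_SD",
]

USAGE_CLASSES = ("biweekly", "monthly", "bimonthly", "nonuser")

#: Baseline (mean, sd) of the secondary biomarkers carried on every visit row.
#: Values are typical for a type 2 diabetes population of this age and BMI.
SECONDARY_BASELINES: Dict[str, Tuple[float, float]] = {
    "homa2_ir": (2.5, 1.2),   # insulin resistance index
    "homa2_b": (70.0, 25.0),  # beta-cell function, %
    "fpg": (8.5, 2.0),        # fasting plasma glucose, mmol/l
    "tc": (4.5, 1.0),         # total cholesterol, mmol/l
    "ldl": (2.5, 0.9),        # mmol/l
    "hdl": (1.2, 0.3),        # mmol/l
    "tg": (1.8, 0.9),         # triglycerides, mmol/l
    "sbp": (135.0, 15.0),     # systolic BP, mm Hg
    "dbp": (80.0, 10.0),      # diastolic BP, mm Hg
}

#: Treatment effect on each secondary biomarker for a biweekly user at full
#: ramp; other classes are scaled by (class HbA1c effect / biweekly effect).
SECONDARY_EFFECTS_BIWEEKLY: Dict[str, float] = {
    "homa2_ir": -0.5,
    "homa2_b": 20.4,
    "fpg": -1.0,
    "tc": -0.1,
    "ldl": -0.1,
    "hdl": 0.1,
    "tg": -0.01,
    "sbp": -11.0,
    "dbp": -1.0,
}

SECONDARY_NOISE_SD: Dict[str, float] = {
    "homa2_ir": 0.5,
    "homa2_b": 8.0,
    "fpg": 0.8,
    "tc": 0.4,
    "ldl": 0.35,
    "hdl": 0.1,
    "tg": 0.4,
    "sbp": 8.0,
    "dbp": 5.0,
}

_EDUCATION_LEVELS = ("basic", "medium", "college")
_EDUCATION_PROBS = (0.162, 0.315, 0.523)
_SES_LEVELS = ("employed", "unemployed", "retired", "sick_leave", "household")
_SES_PROBS = (0.448, 0.021, 0.479, 0.043, 0.009)
_MEDICATION_LEVELS = ("none", "oral", "oral_insulin", "insulin")
_MEDICATION_PROBS = (0.039, 0.661, 0.219, 0.081)


def ngsp_rate_to_ifcc(ngsp_per_year: float) -> float:
    """Convert an HbA1c drift rate from NGSP %/year to IFCC mmol/mol/year.

    The master equation IFCC = 10.929 x (NGSP - 2.15) is affine, so a rate
    (increment per year) converts by the slope alone: 0.15 %/year becomes
    10.929 x 0.15 = 1.639 mmol/mol/year.
    """
    return 10.929 * ngsp_per_year


@dataclass(frozen=True)
class CohortConfig:
    """Ground-truth parameters of the synthetic trial and registry.

    Defaults encode the study conditions: 370 participants, 61.9% male, age
    63.3 (9.7) years, BMI 31.1 (5.2), HbA1c 63.2 (10.2) mmol/mol with an
    inclusion floor of 52, a 30% MOD subgroup, dropout of 14% (tool arm) vs
    4% (wait arm), class effects -6.5/-4.2/-3.6/0 mmol/mol over follow-up
    with an extra -2.8 for MOD, and a usual-care drift of 0.15 NGSP %/year.
    """

    n_participants: int = 370
    n_registry: int = 10_000
    frac_male: float = 0.619
    age_mean_sd: Tuple[float, float] = (63.3, 9.7)
    bmi_mean_sd: Tuple[float, float] = (31.1, 5.2)
    hba1c_mean_sd: Tuple[float, float] = (63.2, 10.2)
    hba1c_floor: float = 52.0
    frac_mod: float = 0.30
    dropout_tool: float = 0.14
    dropout_wait: float = 0.04
    # biweekly / monthly / bimonthly / non-user shares of the merged cohort
    usage_class_probs: Tuple[float, float, float, float] = (0.215, 0.314, 0.215, 0.256)
    effect_biweekly: float = -6.5
    effect_monthly: float = -4.2
    effect_bimonthly: float = -3.6
    effect_mod_extra: float = -2.8
    control_drift_ngsp: float = 0.15
    visit_noise_sd: float = 4.0
    followup_days: int = 730
    effect_ramp_days: int = 365
    med_change_rate: float = 0.2          # events per patient-year
    adherence_confounding: float = 0.3    # logit shift of usage class per SD of age/BMI
    themes_per_quarter: Tuple[float, float, float, float] = (6.5, 3.0, 1.5, 0.0)
    seed: int = 0

    def validate(self) -> None:
        props = {
            "frac_male": self.frac_male,
            "frac_mod": self.frac_mod,
            "dropout_tool": self.dropout_tool,
            "dropout_wait": self.dropout_wait,
        }
        for name, value in props.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if len(self.usage_class_probs) != 4:
            raise ConfigurationError("usage_class_probs must have 4 entries")
        if any(p < 0 or p > 1 for p in self.usage_class_probs):
            raise ConfigurationError("usage_class_probs entries must be in [0, 1]")
        if abs(sum(self.usage_class_probs) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"usage_class_probs must sum to 1, got {sum(self.usage_class_probs)}"
            )
        if self.hba1c_floor > self.hba1c_mean_sd[0]:
            raise ConfigurationError(
                "hba1c_floor must not exceed the hba1c mean "
                f"({self.hba1c_floor} > {self.hba1c_mean_sd[0]})"
            )
        if self.n_participants <= 0:
            raise ConfigurationError("n_participants must be positive")
        if self.n_registry < 2 * self.n_participants:
            raise ConfigurationError(
                "n_registry must be at least twice n_participants for 1:2 matching "
                f"({self.n_registry} < {2 * self.n_participants})"
            )
        for name in ("visit_noise_sd", "med_change_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("age_mean_sd", "bmi_mean_sd", "hba1c_mean_sd"):
            if getattr(self, name)[1] < 0:
                raise ConfigurationError(f"{name} sd must be non-negative")

    @property
    def drift_ifcc_per_year(self) -> float:
        return ngsp_rate_to_ifcc(self.control_drift_ngsp)

    @property
    def class_effects(self) -> Dict[str, float]:
        return {
            "biweekly": self.effect_biweekly,
            "monthly": self.effect_monthly,
            "bimonthly": self.effect_bimonthly,
            "nonuser": 0.0,
        }

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


@dataclass
class ParticipantRecord:
    id: str
    sex: str                 # "male" / "female"
    age: float               # years
    height_cm: float
    bmi: float
    weight_kg: float
    baseline_hba1c: float    # mmol/mol
    arm: str                 # "tool" / "wait"
    mod: bool
    usage_class: str
    dropped_out: bool
    education: str
    socioeconomic: str
    medication: str


@dataclass
class Visit:
    day: int
    hba1c: float
    weight: float
    resistance: float
    reactance: float
    med_change: bool
    extras: Dict[str, float] = field(default_factory=dict)


@dataclass
class VisitSeries:
    id: str
    visits: List[Visit]


@dataclass
class RegistryRecord:
    id: str
    sex: str
    age: float               # age at first registered measurement
    bmi: float
    diagnosis_day: float     # day offset of diagnosis relative to first measurement
    days: List[int]
    hba1c: List[float]
    med_change_days: List[int]


@dataclass
class Theme:
    theme_id: str
    bct_weights: Dict[str, float]


@dataclass
class ThemeCatalog:
    themes: List[Theme]

    @property
    def bct_ids(self) -> List[str]:
        ids = set()
        for t in self.themes:
            ids.update(t.bct_weights)
        return sorted(ids)

    def weights_of(self, theme_id: str) -> Dict[str, float]:
        for t in self.themes:
            if t.theme_id == theme_id:
                return t.bct_weights
        raise KeyError(theme_id)


# ---------------------------------------------------------------------------
# sampling helpers


def _truncated_location(target_mean: float, sd: float, floor: float) -> float:
    """Location mu such that N(mu, sd) truncated at `floor` has `target_mean`.

    The configured HbA1c mean describes the enrolled (already-truncated)
    population, so the pre-truncation location must sit slightly lower.
    """
    from scipy import optimize, stats as sps

    if sd == 0:
        return target_mean

    def gap(mu):
        alpha = (floor - mu) / sd
        tail = sps.norm.sf(alpha)
        return mu + sd * sps.norm.pdf(alpha) / tail - target_mean

    return float(optimize.brentq(gap, target_mean - 6 * sd, target_mean + sd))


def _truncated_normal(rng: np.random.Generator, target_mean: float, sd: float,
                      floor: float, size: int) -> np.ndarray:
    """Sample a >= floor truncated normal whose mean equals `target_mean`."""
    if sd == 0:
        if target_mean < floor:
            raise ConfigurationError("hba1c_floor exceeds a zero-variance mean")
        return np.full(size, target_mean)
    mean = _truncated_location(target_mean, sd, floor)
    out = rng.normal(mean, sd, size)
    bad = out < floor
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < floor
    return out


def visit_schedule(followup_days: int) -> np.ndarray:
    """Nominal visit days: quarterly (91 d) in year one, semiannual after."""
    days = [0, 91, 182, 273, 365]
    d = 365
    while d + 182 <= followup_days:
        d += 182
        days.append(d)
    return np.array([x for x in days if x <= followup_days], dtype=int)


def _jittered_schedule(rng: np.random.Generator, followup_days: int,
                       jitter: int = 7) -> np.ndarray:
    base = visit_schedule(followup_days)
    days = base.copy()
    if len(days) > 1 and jitter > 0:
        days[1:] = days[1:] + rng.integers(-jitter, jitter + 1, len(days) - 1)
    return days


def _ramp(days: np.ndarray, start: float, ramp_days: float) -> np.ndarray:
    """Linear ramp from 0 at `start` to 1 at `start + ramp_days`, then flat."""
    if ramp_days <= 0:
        return (days >= start).astype(float)
    return np.clip((days - start) / ramp_days, 0.0, 1.0)


# ---------------------------------------------------------------------------
# generators


def generate_cohort(config: CohortConfig) -> Tuple[List[ParticipantRecord], List[VisitSeries]]:
    """Generate participants and their longitudinal visit series.

    HbA1c model for participant *i* at visit day *t*::

        hba1c_i(t) = baseline_i + drift * t/365.25 + effect_i * ramp_i(t) + eps

    where ``effect_i = class_effect + mod_extra * (mod_i - frac_mod)`` for
    active usage classes (the MOD deviation is mean-centered so the marginal
    class effect equals the configured value exactly), ``ramp_i`` rises
    linearly over ``effect_ramp_days`` starting at day 0 for the tool arm and
    at the second visit for the wait arm, and ``eps ~ N(0, visit_noise_sd)``
    (zero at the baseline visit, which defines baseline).  Participants who
    drop out contribute only their baseline visit.  Bioimpedance raw values
    are generated by inverting the sex-specific single-frequency fat-free-mass
    equation from a target FFM fraction, so derived body composition is
    physiologic by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    sex = np.where(rng.random(n) < config.frac_male, "male", "female")
    male = sex == "male"
    age = rng.normal(*config.age_mean_sd, n).clip(35, 95)
    bmi = rng.normal(*config.bmi_mean_sd, n).clip(16, 60)
    height = np.where(male, rng.normal(175, 7, n), rng.normal(162, 6, n)).clip(140, 210)
    weight0 = bmi * (height / 100.0) ** 2
    hba1c0 = _truncated_normal(rng, *config.hba1c_mean_sd, config.hba1c_floor, n)

    # MOD = obese insulin-resistant cluster: ranked on BMI plus noise so the
    # flag correlates with BMI while hitting the configured fraction exactly.
    mod_score = bmi + rng.normal(0, 3.0, n)
    n_mod = int(round(config.frac_mod * n))
    mod = np.zeros(n, dtype=bool)
    mod[np.argsort(-mod_score)[:n_mod]] = True

    # 1:1 randomization by permutation
    arm = np.array(["wait"] * n, dtype=object)
    arm[rng.permutation(n)[: n // 2]] = "tool"

    dropout_p = np.where(arm == "tool", config.dropout_tool, config.dropout_wait)
    dropped = rng.random(n) < dropout_p

    # usage class: multinomial logit around the configured shares with a mild
    # adherence gradient (older, leaner participants adhere more), providing
    # the confounding structure that the propensity weighting corrects.
    age_z = (age - config.age_mean_sd[0]) / config.age_mean_sd[1]
    bmi_z = (bmi - config.bmi_mean_sd[0]) / config.bmi_mean_sd[1]
    eta = config.adherence_confounding * age_z - 0.2 * config.adherence_confounding * bmi_z
    class_gradient = np.array([1.0, 0.33, -0.33, -1.0])
    logits = np.log(np.asarray(config.usage_class_probs)) + np.outer(eta, class_gradient)
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    cum = probs.cumsum(axis=1)
    class_idx = (u[:, None] > cum).sum(axis=1)
    usage_class = np.array(USAGE_CLASSES, dtype=object)[class_idx]

    education = rng.choice(_EDUCATION_LEVELS, n, p=_EDUCATION_PROBS)
    ses = rng.choice(_SES_LEVELS, n, p=_SES_PROBS)
    medication = rng.choice(_MEDICATION_LEVELS, n, p=_MEDICATION_PROBS)

    class_effect = np.array([config.class_effects[c] for c in usage_class])
    active = usage_class != "nonuser"
    effect = class_effect + np.where(
        active, config.effect_mod_extra * (mod.astype(float) - config.frac_mod), 0.0
    )
    weight_effect = np.where(active, -2.9, 0.0) * (class_effect / config.effect_biweekly
                                                   if config.effect_biweekly != 0 else 0.0)

    # fat-free mass fraction at baseline, used to invert bioimpedance
    ffm_frac = np.where(
        male, rng.normal(0.65, 0.06, n), rng.normal(0.55, 0.06, n)
    ).clip(0.40, 0.80)
    ffm0 = ffm_frac * weight0

    drift = config.drift_ifcc_per_year
    participants: List[ParticipantRecord] = []
    series: List[VisitSeries] = []
    sec_base = {
        k: rng.normal(m, s, n).clip(0.05 if k in ("homa2_ir", "hdl") else None, None)
        for k, (m, s) in SECONDARY_BASELINES.items()
    }
    for i in range(n):
        pid = f"P{i + 1:04d}"
        participants.append(
            ParticipantRecord(
                id=pid, sex=str(sex[i]), age=float(age[i]), height_cm=float(height[i]),
                bmi=float(bmi[i]), weight_kg=float(weight0[i]),
                baseline_hba1c=float(hba1c0[i]), arm=str(arm[i]), mod=bool(mod[i]),
                usage_class=str(usage_class[i]), dropped_out=bool(dropped[i]),
                education=str(education[i]), socioeconomic=str(ses[i]),
                medication=str(medication[i]),
            )
        )
        days = _jittered_schedule(rng, config.followup_days)
        if dropped[i]:
            days = days[:1]
        m_visits = len(days)
        start = 0.0 if arm[i] == "tool" else 91.0
        ramp = _ramp(days.astype(float), start, float(config.effect_ramp_days))
        noise = rng.normal(0, config.visit_noise_sd, m_visits)
        noise[0] = 0.0
        hba1c = hba1c0[i] + drift * days / 365.25 + effect[i] * ramp + noise

        wnoise = rng.normal(0, 0.8, m_visits)
        wnoise[0] = 0.0
        weight = weight0[i] + weight_effect[i] * ramp + wnoise
        ffm = np.full(m_visits, ffm0[i])
        reactance = rng.normal(50, 8, m_visits).clip(5, None)
        # invert the single-frequency BIA equation so that fat_free_mass()
        # applied to (resistance, reactance) returns ffm exactly
        const = -4.104 + (4.229 if male[i] else 0.0)
        denom = ffm - const - 0.231 * weight - 0.130 * reactance
        denom = np.clip(denom, 5.0, None)
        resistance = 0.518 * height[i] ** 2 / denom

        # medication-change events: Poisson process over follow-up, flagged on
        # the first visit at or after each event
        span_years = max(days[-1], 1) / 365.25
        n_events = rng.poisson(config.med_change_rate * span_years)
        event_days = np.sort(rng.integers(1, max(int(days[-1]), 2), n_events)) if n_events else []
        med_flags = np.zeros(m_visits, dtype=bool)
        for ev in event_days:
            idx = int(np.searchsorted(days, ev))
            if idx < m_visits:
                med_flags[idx] = True

        scale = (class_effect[i] / config.effect_biweekly) if config.effect_biweekly != 0 else 0.0
        visits = []
        for j in range(m_visits):
            extras = {}
            for k in SECONDARY_BASELINES:
                enoise = 0.0 if j == 0 else rng.normal(0, SECONDARY_NOISE_SD[k])
                val = sec_base[k][i] + SECONDARY_EFFECTS_BIWEEKLY[k] * scale * ramp[j] + enoise
                if k in ("homa2_ir", "homa2_b", "fpg", "tc", "ldl", "hdl", "tg"):
                    val = max(val, 0.05)
                extras[k] = float(val)
            visits.append(
                Visit(day=int(days[j]), hba1c=float(hba1c[j]), weight=float(weight[j]),
                      resistance=float(resistance[j]), reactance=float(reactance[j]),
                      med_change=bool(med_flags[j]), extras=extras)
            )
        series.append(VisitSeries(id=pid, visits=visits))
    return participants, series


def generate_registry(config: CohortConfig) -> List[RegistryRecord]:
    """Generate the usual-care registry pool.

    Each record carries a diagnosis date, a roughly semiannual HbA1c series
    under the configured secular drift, and sporadic medication-change events
    (a Poisson process at ``med_change_rate`` per year).  Covariates are drawn
    from the same distributions as the participants so matching is feasible.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n = config.n_registry
    if n <= 0:
        raise ConfigurationError("n_registry must be positive")

    sex = np.where(rng.random(n) < config.frac_male, "male", "female")
    age = rng.normal(*config.age_mean_sd, n).clip(35, 95)
    bmi = rng.normal(*config.bmi_mean_sd, n).clip(16, 60)
    hba1c0 = rng.normal(*config.hba1c_mean_sd, n)
    diagnosis = -rng.uniform(365, 3650, n)  # diagnosis 1-10 years before first record

    drift = config.drift_ifcc_per_year
    span = 6 * 365
    records: List[RegistryRecord] = []
    for i in range(n):
        base_days = np.arange(0, span + 1, 182)
        jit = rng.integers(-14, 15, len(base_days))
        jit[0] = 0
        days = np.maximum.accumulate(base_days + jit)
        noise = rng.normal(0, config.visit_noise_sd, len(days))
        noise[0] = 0.0
        values = hba1c0[i] + drift * days / 365.25 + noise
        n_events = rng.poisson(config.med_change_rate * span / 365.25)
        med_days = sorted(int(d) for d in rng.integers(1, span, n_events)) if n_events else []
        records.append(
            RegistryRecord(
                id=f"R{i + 1:05d}", sex=str(sex[i]), age=float(age[i]), bmi=float(bmi[i]),
                diagnosis_day=float(diagnosis[i]),
                days=[int(d) for d in days], hba1c=[float(v) for v in values],
                med_change_days=med_days,
            )
        )
    return records


def generate_theme_catalog(seed: int = 0) -> ThemeCatalog:
    """Build the 80-theme catalog over a pool of 24 behavior change techniques.

    Each theme carries 2-4 BCTs with positive dominance weights normalized to
    sum to one; every BCT in the pool appears in at least one theme.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    bct_pool = [f"BCT{k + 1:02d}" for k in range(24)]
    themes: List[Theme] = []
    for t in range(80):
        size = int(rng.integers(2, 5))
        ids = set()
        if t < 24:
            ids.add(bct_pool[t])  # guarantees full coverage of the pool
        while len(ids) < size:
            ids.add(bct_pool[int(rng.integers(0, 24))])
        ids = sorted(ids)
        w = np.sort(rng.dirichlet(np.ones(len(ids))))[::-1]
        w = w / w.sum()
        themes.append(Theme(theme_id=f"T{t + 1:02d}",
                            bct_weights={b: float(x) for b, x in zip(ids, w)}))
    return ThemeCatalog(themes=themes)


def generate_completions(
    participants: Sequence[ParticipantRecord],
    series: Sequence[VisitSeries],
    catalog: ThemeCatalog,
    config: CohortConfig,
) -> List[Tuple[str, int, str]]:
    """Theme-completion event stream (participant id, day, theme id).

    Per inter-visit period the number of completions is negative binomial
    (dispersion 8) with mean set by the usage class per quarter (biweekly
    ~6.5, monthly 3, bimonthly 1.5, non-user 0), scaled to the period length.
    Wait-arm participants complete nothing before the 12-week merge.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    means = dict(zip(USAGE_CLASSES, config.themes_per_quarter))
    theme_ids = [t.theme_id for t in catalog.themes]
    k_disp = 8.0
    events: List[Tuple[str, int, str]] = []
    by_id = {s.id: s for s in series}
    for p in participants:
        if p.dropped_out:
            continue
        mu_q = means[p.usage_class]
        if mu_q <= 0:
            continue
        s = by_id[p.id]
        days = [v.day for v in s.visits]
        access_start = 0 if p.arm == "tool" else 91
        for prev, cur in zip(days[:-1], days[1:]):
            lo = max(prev, access_start)
            if cur <= lo:
                continue
            mu = mu_q * (cur - lo) / 91.0
            p_nb = k_disp / (k_disp + mu)
            count = int(rng.negative_binomial(k_disp, p_nb)) if mu > 0 else 0
            if count == 0:
                continue
            ev_days = rng.integers(lo + 1, cur + 1, count)
            themes = rng.choice(theme_ids, count)
            for d, th in zip(ev_days, themes):
                events.append((p.id, int(d), str(th)))
    events.sort()
    return events
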