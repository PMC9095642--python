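"""Pipeline orchestration: generate -> measure -> classify -> score -> infer.

Each stage reads and writes the delimited-text interchange files in one
output directory, so stages can be re-run in isolation.  A single global
seed is split deterministically into per-stage substreams; a manifest with
the config hash, seed and per-file checksums makes identical runs
byte-verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .cohort import (
    CohortConfig,
    generate_cohort,
    generate_completions,
    generate_registry,
    generate_theme_catalog,
)
from .errors import DataError, GlycotrialError
from .exposure import bct_chi_square, bct_scores, exposure_response_bins, quarterly_periods
from .inference import (
    PowerSpec,
    empirical_power,
    endpoint_contrast,
    estimate_propensity,
    interaction_test,
    ipw_weights,
    match_controls,
    mediation,
    sample_size_two_groups,
    weighted_group_difference,
)
from .measures import add_body_composition
from .trajectories import EligibilityRule, classify_series, compare_sustained_rates, pattern_table

log = logging.getLogger("glycotrial")

#: Endpoint -> column of the derived visits table; the 13 key secondary
#: endpoints (changes from baseline to end of follow-up).
ENDPOINT_COLUMNS = {
    "hba1c_mmol_mol": "hba1c",
    "homa2_ir": "homa2_ir",
    "homa2_b_pct": "homa2_b",
    "body_weight_kg": "weight",
    "fat_mass_pct": "fat_pct",
    "muscle_mass_pct": "muscle_pct",
    "fasting_glucose_mmol_l": "fpg",
    "total_cholesterol_mmol_l": "tc",
    "ldl_cholesterol_mmol_l": "ldl",
    "hdl_cholesterol_mmol_l": "hdl",
    "triglycerides_mmol_l": "tg",
    "systolic_bp_mmhg": "sbp",
    "diastolic_bp_mmhg": "dbp",
}

USAGE_SETS = {
    "at_least_biweekly": ("biweekly",),
    "at_least_monthly": ("biweekly", "monthly"),
    "at_least_bimonthly": ("biweekly", "monthly", "bimonthly"),
}


class PipelineError(GlycotrialError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    eligibility: EligibilityRule = field(default_factory=EligibilityRule)
    run_mediation: bool = True
    run_bct: bool = True
    match_ratio: int = 2
    n_boot: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream below 2**31."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2 ** 31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in raw.pop("cohort", {}).items()})
        elig = EligibilityRule(**raw.pop("eligibility", {}))
        return cls(cohort=cohort, eligibility=elig, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    cc = config.cohort.with_(seed=config.stage_seed("simulate"))
    participants, series = generate_cohort(cc)
    registry = generate_registry(cc)
    catalog = generate_theme_catalog(cc.seed)
    completions = generate_completions(participants, series, catalog, cc)
    gio.write_participants(participants, outdir / "participants.csv")
    gio.write_visits(series, outdir / "visits.csv")
    gio.write_registry(registry, outdir / "registry.csv")
    gio.write_completions(completions, outdir / "completions.csv")
    gio.write_theme_catalog(catalog, outdir / "themes.json")
    log.info("simulate: %d participants, %d registry patients, %d completions",
             len(participants), len(registry), len(completions))


def stage_measure(outdir: Path) -> None:
    participants = gio.read_participants(outdir / "participants.csv")
    visits = gio.read_visits(outdir / "visits.csv")
    derived = add_body_composition(visits, participants)
    derived.to_csv(outdir / "visits_derived.csv", index=False)
    log.info("measure: %d visit rows with body-composition columns", len(derived))


def _truncate_at_med_change(visits: pd.DataFrame) -> pd.DataFrame:
    """Keep each person's visits up to (not including) the first med change."""
    out = []
    for pid, g in visits.groupby("id", sort=True):
        g = g.sort_values("day")
        flags = g["med_change"].to_numpy(bool)
        stop = int(np.argmax(flags)) if flags.any() else len(g)
        out.append(g.iloc[:stop])
    return pd.concat(out, ignore_index=True) if out else visits.iloc[:0]


def participant_deltas(outdir: Path) -> pd.DataFrame:
    """Change from baseline to last analyzable visit, per endpoint column.

    Visits after a glucose-lowering medication change are discarded (the last
    visit with unchanged medication defines end of follow-up); participants
    with only a baseline visit left are dropped.
    """
    participants = gio.read_participants(outdir / "participants.csv")
    visits = pd.read_csv(outdir / "visits_derived.csv")
    visits["med_change"] = visits["med_change"].astype(bool)
    visits = _truncate_at_med_change(visits)
    rows = []
    for pid, g in visits.groupby("id", sort=True):
        g = g.sort_values("day")
        if len(g) < 2:
            continue
        first, last = g.iloc[0], g.iloc[-1]
        row = {"id": pid, "followup_days": int(last["day"] - first["day"])}
        for endpoint, col in ENDPOINT_COLUMNS.items():
            row[endpoint] = float(last[col] - first[col])
        rows.append(row)
    deltas = pd.DataFrame(rows)
    return deltas.merge(
        participants[["id", "sex", "age", "bmi", "baseline_hba1c", "arm", "mod",
                      "usage_class", "dropped_out"]], on="id")


def stage_patterns(config: PipelineConfig, outdir: Path) -> dict:
    visits = gio.read_visits(outdir / "visits.csv")
    registry = gio.read_registry(outdir / "registry.csv")
    participants = gio.read_participants(outdir / "participants.csv")
    users = participants.loc[~participants["dropped_out"]
                             & (participants["usage_class"] != "nonuser"), "id"]
    pat_users = classify_series(visits[visits["id"].isin(users)], config.eligibility)
    pat_reg = classify_series(registry, config.eligibility)
    pat_users.assign(group="users").to_csv(outdir / "patterns.csv", index=False)
    pat_reg.assign(group="registry").to_csv(outdir / "patterns_registry.csv", index=False)

    summary = {}
    if len(pat_users) and len(pat_reg):
        ku = int((pat_users["label"] == "sustained_decrease").sum())
        kr = int((pat_reg["label"] == "sustained_decrease").sum())
        summary = {
            "n_users": len(pat_users), "k_users_sustained": ku,
            "n_registry": len(pat_reg), "k_registry_sustained": kr,
            "fisher_p": compare_sustained_rates(len(pat_users), ku, len(pat_reg), kr),
        }
    table = pd.concat([
        pattern_table(pat_users["label"]).assign(group="users") if len(pat_users) else pd.DataFrame(),
        pattern_table(pat_reg["label"]).assign(group="registry") if len(pat_reg) else pd.DataFrame(),
    ], ignore_index=True)
    table.to_csv(outdir / "pattern_summary.csv", index=False)
    _write_json(summary, outdir / "patterns.json")
    log.info("patterns: %d user and %d registry series classified",
             len(pat_users), len(pat_reg))
    return summary


def stage_exposure(outdir: Path) -> pd.DataFrame:
    visits = gio.read_visits(outdir / "visits.csv")
    completions = gio.read_completions(outdir / "completions.csv")
    periods = quarterly_periods(visits, completions)
    bins = exposure_response_bins(periods)
    periods.to_csv(outdir / "quarterly_periods.csv", index=False)
    bins.to_csv(outdir / "exposure_bins.csv", index=False)
    log.info("exposure: %d quarterly periods into bins %s",
             len(periods), bins["n"].tolist())
    return bins


def stage_bct(outdir: Path) -> dict:
    visits = gio.read_visits(outdir / "visits.csv")
    completions = gio.read_completions(outdir / "completions.csv")
    catalog = gio.read_theme_catalog(outdir / "themes.json")
    scores = bct_scores(visits, completions, catalog)
    scores.to_csv(outdir / "bct_scores.csv", index=False)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        stat, df, p = bct_chi_square(scores)
    result = {"chi_square": stat, "df": df, "p": p}
    _write_json(result, outdir / "bct_chi_square.json")
    log.info("bct: %d techniques scored, chi-square %.2f (df=%d)", len(scores), stat, df)
    return result


def stage_match(config: PipelineConfig, outdir: Path):
    participants = gio.read_participants(outdir / "participants.csv")
    registry = gio.read_registry(outdir / "registry.csv")
    active = participants[~participants["dropped_out"]]
    result = match_controls(active, registry, ratio=config.match_ratio,
                            seed=config.stage_seed("match"),
                            followup_days=config.cohort.followup_days)
    result.balance.to_csv(outdir / "balance.csv", index=False)
    pairs = pd.DataFrame(
        [(pid, cid) for pid, cids in result.pairs.items() for cid in cids],
        columns=["participant_id", "control_id"])
    pairs["index_day"] = pairs["control_id"].map(result.index_dates)
    pairs.to_csv(outdir / "matched_pairs.csv", index=False)
    result.candidates.to_csv(outdir / "control_candidates.csv", index=False)
    log.info("match: %d participants matched to %d controls (1:%d)",
             len(result.pairs), len(pairs), config.match_ratio)
    return result


def stage_contrasts(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Endpoint contrasts for the three cumulative usage patterns.

    HbA1c is contrasted against the matched registry controls' change over
    the corresponding window; the other endpoints (unavailable for registry
    patients) are contrasted against non-user participants.
    """
    deltas = participant_deltas(outdir)
    pairs = pd.read_csv(outdir / "matched_pairs.csv")
    candidates = pd.read_csv(outdir / "control_candidates.csv")
    control_delta = candidates.set_index("id")["delta_hba1c"]

    rows = []
    nonusers = deltas[deltas["usage_class"] == "nonuser"]
    for usage_name, classes in USAGE_SETS.items():
        users = deltas[deltas["usage_class"].isin(classes)]
        if len(users) < 2:
            continue
        ctl_ids = pairs.loc[pairs["participant_id"].isin(users["id"]), "control_id"]
        ctl = control_delta.loc[[c for c in ctl_ids if c in control_delta.index]]
        for endpoint in ENDPOINT_COLUMNS:
            if endpoint == "hba1c_mmol_mol":
                comparison = ctl.to_numpy()
            else:
                comparison = nonusers[endpoint].to_numpy()
            if len(comparison) < 2:
                continue
            c = endpoint_contrast(users[endpoint].to_numpy(), comparison,
                                  alpha=config.alpha)
            rows.append({
                "endpoint": endpoint, "usage": usage_name, "n_users": len(users),
                "n_controls": len(comparison), "estimate": c.estimate,
                "ci_low": c.ci[0], "ci_high": c.ci[1], "p": c.p,
            })
    contrasts = pd.DataFrame(rows)
    contrasts.to_csv(outdir / "contrasts.csv", index=False)
    log.info("contrast: %d endpoint rows", len(contrasts))
    return contrasts


def stage_weights(config: PipelineConfig, outdir: Path,
                  scheme: str = "user_vs_nonuser") -> dict:
    """Propensity-weighted HbA1c contrast (biweekly users vs non-users)."""
    deltas = participant_deltas(outdir)
    sub = deltas[deltas["usage_class"].isin(("biweekly", "nonuser"))].copy()
    labels = (sub["usage_class"] == "biweekly").to_numpy()
    features = sub[["age", "bmi", "baseline_hba1c"]].to_numpy()
    fit = estimate_propensity(features, labels, max_trees=500, n_grid=10,
                              cv_folds=3, seed=config.stage_seed("weights"))
    w = ipw_weights(scheme, fit.probabilities, labels)
    res = weighted_group_difference(sub["hba1c_mmol_mol"].to_numpy(), labels, w)
    unweighted = weighted_group_difference(
        sub["hba1c_mmol_mol"].to_numpy(), labels, np.ones(len(sub)))
    out = {
        "scheme": scheme, "n_trees": fit.n_trees,
        "weighted": {"estimate": res.estimate, "se": res.se,
                     "ci": list(res.ci), "p": res.p},
        "unweighted": {"estimate": unweighted.estimate, "se": unweighted.se,
                       "ci": list(unweighted.ci), "p": unweighted.p},
    }
    pd.DataFrame({"id": sub["id"], "probability": fit.probabilities,
                  "weight": w}).to_csv(outdir / "weights.csv", index=False)
    _write_json(out, outdir / "weighted_contrast.json")
    log.info("weights: %s with %d trees, weighted estimate %.2f",
             scheme, fit.n_trees, res.estimate)
    return out


def stage_interaction(config: PipelineConfig, outdir: Path) -> dict:
    """MOD x usage interaction on the long-term HbA1c change."""
    deltas = participant_deltas(outdir)
    sub = deltas[deltas["usage_class"].isin(
        ("biweekly", "monthly", "bimonthly", "nonuser"))]
    group = (sub["usage_class"] != "nonuser").to_numpy()
    coef, p = interaction_test(sub["hba1c_mmol_mol"].to_numpy(), group,
                               sub["mod"].to_numpy())
    out = {"interaction_coef": coef, "p": p}
    _write_json(out, outdir / "interaction.json")
    log.info("interaction: MOD x usage coefficient %.2f (p=%.4f)", coef, p)
    return out


def stage_mediate(config: PipelineConfig, outdir: Path) -> dict:
    deltas = participant_deltas(outdir)
    completions = gio.read_completions(outdir / "completions.csv")
    themes_total = completions.groupby("id").size()
    deltas["themes"] = deltas["id"].map(themes_total).fillna(0.0)
    moderators = pd.DataFrame({
        "bmi": deltas["bmi"],
        "male": (deltas["sex"] == "male").astype(float),
    })
    res = mediation(deltas["themes"], deltas["body_weight_kg"],
                    deltas["hba1c_mmol_mol"], moderators,
                    n_boot=config.n_boot, seed=config.stage_seed("mediate"))
    out = {
        "exposure": "themes_completed", "mediator": "body_weight_change",
        "outcome": "hba1c_change",
        "total_effect": res.total_effect, "direct_effect": res.direct_effect,
        "indirect_effect": res.indirect_effect, "prop_mediated": res.prop_mediated,
        "boot_ci": {k: list(v) for k, v in res.boot_ci.items()},
    }
    _write_json(out, outdir / "mediation.json")
    log.info("mediate: indirect %.4f of total %.4f", res.indirect_effect,
             res.total_effect)
    return out


def stage_power(config: PipelineConfig, outdir: Path, reps: int = 10_000) -> dict:
    rand_spec = PowerSpec(delta=2, sd=6, alpha=0.05, power=0.80, allocation_ratio=1)
    match_spec = PowerSpec(delta=5, sd=7, alpha=0.05, power=0.80, allocation_ratio=2)
    n1 = sample_size_two_groups(rand_spec)
    n2 = sample_size_two_groups(match_spec)
    emp = empirical_power(n1[0], n1[1], rand_spec.delta, rand_spec.sd,
                          rand_spec.alpha, reps=reps,
                          seed=config.stage_seed("power"))
    out = {
        "randomization_phase": {"n_cases": n1[0], "n_controls": n1[1]},
        "matched_comparison": {"n_cases": n2[0], "n_controls": n2[1]},
        "empirical_power_at_randomization_n": emp,
    }
    _write_json(out, outdir / "design.json")
    log.info("power: n=%d per group, empirical power %.3f", n1[0], emp)
    return out


# ---------------------------------------------------------------------------
# orchestration and rendering


STAGE_ORDER = ["simulate", "measure", "patterns", "exposure", "bct", "match",
               "contrast", "weights", "interaction", "mediate", "power", "render"]


def run_pipeline(config: PipelineConfig, outdir: Path) -> dict:
    """Run every stage and write a manifest; identical config+seed gives a
    byte-identical bundle."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.cohort.n_participants <= 0:
        raise PipelineError("simulate: empty cohort requested")

    def _run(stage, fn, *args):
        try:
            return fn(*args)
        except GlycotrialError as exc:
            raise PipelineError(f"{stage}: {exc}") from exc

    _run("simulate", stage_simulate, config, outdir)
    _run("measure", stage_measure, outdir)
    _run("patterns", stage_patterns, config, outdir)
    _run("exposure", stage_exposure, outdir)
    if config.run_bct:
        _run("bct", stage_bct, outdir)
    _run("match", stage_match, config, outdir)
    _run("contrast", stage_contrasts, config, outdir)
    _run("weights", stage_weights, config, outdir)
    _run("interaction", stage_interaction, config, outdir)
    if config.run_mediation:
        _run("mediate", stage_mediate, config, outdir)
    _run("power", stage_power, config, outdir)
    _run("render", render_tables, outdir)

    files = sorted(p.name for p in outdir.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "checksums": {name: _sha256(outdir / name) for name in files},
    }
    _write_json(manifest, outdir / "manifest.json")
    return manifest


def render_tables(outdir: Path) -> Dict[str, pd.DataFrame]:
    """Render baseline, endpoint and exposure-bin summary tables as CSV text.

    Endpoint cells are formatted ``estimate (low to high)`` with the 95% CI.
    """
    outdir = Path(outdir)
    for req in ("participants.csv", "contrasts.csv", "exposure_bins.csv"):
        if not (outdir / req).exists():
            raise DataError(f"render_tables requires {req}; run earlier stages first")
    participants = gio.read_participants(outdir / "participants.csv")
    if len(participants) == 0:
        raise DataError("render_tables: empty participants table")

    def _mean_sd(g, col):
        return f"{g[col].mean():.1f} ({g[col].std(ddof=1):.1f})"

    rows = []
    groups = {"tool": participants[participants["arm"] == "tool"],
              "wait": participants[participants["arm"] == "wait"],
              "all": participants}
    for label, fn in [
        ("male_pct", lambda g: f"{100 * (g['sex'] == 'male').mean():.1f}"),
        ("age_years", lambda g: _mean_sd(g, "age")),
        ("bmi", lambda g: _mean_sd(g, "bmi")),
        ("hba1c_mmol_mol", lambda g: _mean_sd(g, "baseline_hba1c")),
        ("mod_pct", lambda g: f"{100 * g['mod'].mean():.1f}"),
    ]:
        rows.append({"characteristic": label,
                     **{k: fn(g) for k, g in groups.items()}})
    table1 = pd.DataFrame(rows, columns=["characteristic", "tool", "wait", "all"])
    table1.to_csv(outdir / "table1_baseline.csv", index=False)

    contrasts = pd.read_csv(outdir / "contrasts.csv")
    cells = contrasts.assign(
        cell=[f"{r.estimate:.2f} ({r.ci_low:.2f} to {r.ci_high:.2f})"
              for r in contrasts.itertuples()])
    table2 = cells.pivot(index="endpoint", columns="usage", values="cell")
    table2 = table2.reindex(index=list(ENDPOINT_COLUMNS),
                            columns=list(USAGE_SETS)).reset_index()
    table2.to_csv(outdir / "table2_endpoints.csv", index=False)

    bins = pd.read_csv(outdir / "exposure_bins.csv")
    bins.to_csv(outdir / "table_fig1c_exposure.csv", index=False)
    return {"table1": table1, "table2": table2, "exposure": bins}
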