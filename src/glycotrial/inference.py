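"""Matching, inverse-probability weighting, endpoint contrasts, mediation
and design calculations.

The comparison machinery mirrors a two-stage trial design: a randomized
wait-list phase analyzed by Welch t-tests (optionally reweighted for
differential dropout or adherence), and an open-label phase where users are
compared with registry controls matched exactly on sex and by Mahalanobis
nearest-neighbour distance on age, BMI and HbA1c at a randomly selected
index date.  Propensity scores come from gradient boosting (shrinkage 0.001,
interaction depth 3) with the tree count chosen by cross-validation to
minimize the average absolute standardized mean difference of the features
under the implied weights.  Weighted contrasts use least squares with an HC1
sandwich standard error.  Mediation follows the linear no-interaction
decomposition (indirect = a x b, total = direct + indirect) with percentile
bootstrap intervals resampling whole subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .errors import (
    DataError,
    DegenerateInputError,
    DomainError,
    InsufficientControlsError,
)

__all__ = [
    "smd",
    "MatchResult",
    "select_index_dates",
    "match_controls",
    "PropensityFit",
    "estimate_propensity",
    "ipw_weights",
    "WEIGHT_SCHEMES",
    "ContrastResult",
    "weighted_group_difference",
    "endpoint_contrast",
    "interaction_test",
    "MediationResult",
    "mediation",
    "PowerSpec",
    "sample_size_two_groups",
    "empirical_power",
]

WEIGHT_SCHEMES = ("dropout_adjust", "adherence_adjust", "user_vs_nonuser")


def smd(values_a: Sequence[float], values_b: Sequence[float],
        weights_a: Optional[Sequence[float]] = None,
        weights_b: Optional[Sequence[float]] = None) -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled SD.

    Pooled SD is sqrt((s_a^2 + s_b^2) / 2).  With weights, weighted means and
    variances are used.  A zero pooled SD is undefined and raises.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both groups must be non-empty")

    def _moments(x, w):
        if w is None:
            return x.mean(), x.var(ddof=1) if x.size > 1 else 0.0
        w = np.asarray(w, float)
        m = np.average(x, weights=w)
        v = np.average((x - m) ** 2, weights=w)
        return m, v

    ma, va = _moments(a, weights_a)
    mb, vb = _moments(b, weights_b)
    pooled = math.sqrt((va + vb) / 2.0)
    if pooled == 0.0:
        raise DomainError("pooled standard deviation is zero; SMD undefined")
    return (ma - mb) / pooled


# ---------------------------------------------------------------------------
# matching


@dataclass
class MatchResult:
    pairs: Dict[str, List[str]]
    index_dates: Dict[str, int]
    balance: pd.DataFrame            # covariate, smd_pre, smd_post
    candidates: pd.DataFrame = field(repr=False, default=None)


def select_index_dates(registry: pd.DataFrame, rng: np.random.Generator,
                       min_post_diagnosis_days: int = 730,
                       followup_days: int = 730,
                       min_followup_days: int = 365) -> pd.DataFrame:
    """Pick one admissible index date per registry patient, uniformly at random.

    A registration is admissible when it falls at least two years after the
    diagnosis date, at least ``min_followup_days`` of subsequent measurements
    exist, and no medication change occurs within the follow-up window after
    it.  Patients with no admissible registration are dropped.  Returns one
    candidate row per patient with covariates evaluated at the index date
    (age at index, BMI, HbA1c) and the observed HbA1c change over follow-up.
    """
    rows = []
    for pid, g in registry.groupby("id", sort=True):
        g = g.sort_values("day")
        days = g["day"].to_numpy()
        vals = g["hba1c"].to_numpy(float)
        med = g["med_change"].to_numpy(bool)
        diag = float(g["diagnosis_day"].iloc[0])
        last = days[-1]
        admissible = []
        for j, d in enumerate(days):
            if d - diag < min_post_diagnosis_days:
                continue
            if last - d < min_followup_days:
                continue
            in_window = (days > d) & (days <= d + followup_days)
            if med[in_window].any():
                continue
            admissible.append(j)
        if not admissible:
            continue
        j = int(rng.choice(admissible))
        d = days[j]
        in_window = (days > d) & (days <= d + followup_days)
        end_j = int(np.nonzero(in_window)[0][-1]) if in_window.any() else j
        rows.append({
            "id": pid, "sex": g["sex"].iloc[0],
            "age": float(g["age"].iloc[0]) + d / 365.25,
            "bmi": float(g["bmi"].iloc[0]),
            "hba1c": float(vals[j]),
            "index_day": int(d),
            "delta_hba1c": float(vals[end_j] - vals[j]),
            "followup_span": int(days[end_j] - d),
        })
    return pd.DataFrame(rows)


def match_controls(participants: pd.DataFrame, registry: pd.DataFrame,
                   ratio: int = 2,
                   covariates: Tuple[str, ...] = ("age", "bmi", "hba1c"),
                   seed: int = 0,
                   followup_days: int = 730) -> MatchResult:
    """Greedy 1:ratio nearest-Mahalanobis matching within exact sex strata.

    ``participants`` needs columns id, sex and the covariates (``hba1c``
    resolves to ``baseline_hba1c`` if present); ``registry`` is the long
    registry table.  Index dates are drawn first (see
    :func:`select_index_dates`); the Mahalanobis metric uses the covariance
    of the full candidate pool; participants are processed in random order
    and controls are used without replacement.  Pre- and post-match SMDs are
    reported per covariate.
    """
    rng = np.random.default_rng(seed)
    cands = select_index_dates(registry, rng, followup_days=followup_days)
    part = participants.copy()
    if "hba1c" in covariates and "hba1c" not in part.columns:
        part = part.rename(columns={"baseline_hba1c": "hba1c"})

    if len(cands) == 0:
        raise InsufficientControlsError("no admissible registry controls at all")
    cov_mat = np.cov(cands[list(covariates)].to_numpy(float), rowvar=False)
    vi = np.linalg.pinv(np.atleast_2d(cov_mat))

    pairs: Dict[str, List[str]] = {}
    index_dates: Dict[str, int] = {}
    shortfall = {}
    for sex_value in sorted(part["sex"].unique()):
        p_sex = part[part["sex"] == sex_value]
        c_sex = cands[cands["sex"] == sex_value].reset_index(drop=True)
        need = ratio * len(p_sex)
        if len(c_sex) < need:
            shortfall[sex_value] = (len(c_sex), need)
            continue
        px = p_sex[list(covariates)].to_numpy(float)
        cx = c_sex[list(covariates)].to_numpy(float)
        dist = cdist(px, cx, metric="mahalanobis", VI=vi)
        used = np.zeros(len(c_sex), dtype=bool)
        order = rng.permutation(len(p_sex))
        for i in order:
            d = np.where(used, np.inf, dist[i])
            chosen = np.argsort(d)[:ratio]
            used[chosen] = True
            pid = p_sex["id"].iloc[i]
            pairs[pid] = [c_sex["id"].iloc[int(j)] for j in chosen]
            for j in chosen:
                index_dates[c_sex["id"].iloc[int(j)]] = int(c_sex["index_day"].iloc[int(j)])
    if shortfall:
        detail = ", ".join(f"{s}: {have} available < {need} needed"
                           for s, (have, need) in shortfall.items())
        raise InsufficientControlsError(f"eligible control shortfall ({detail})")

    matched_ids = [cid for ids in pairs.values() for cid in ids]
    matched = cands.set_index("id").loc[matched_ids]
    rows = []
    for c in covariates:
        rows.append({
            "covariate": c,
            "smd_pre": smd(part[c], cands[c]),
            "smd_post": smd(part[c], matched[c]),
        })
    return MatchResult(pairs=pairs, index_dates=index_dates,
                       balance=pd.DataFrame(rows), candidates=cands)


# ---------------------------------------------------------------------------
# propensity weighting


@dataclass
class PropensityFit:
    probabilities: np.ndarray
    n_trees: int
    cv_balance: pd.DataFrame     # n_trees, mean_abs_smd over the CV grid


def _mean_abs_smd(features: np.ndarray, labels: np.ndarray,
                  weights: np.ndarray) -> float:
    vals = []
    for j in range(features.shape[1]):
        x = features[:, j]
        ok = ~np.isnan(x)
        xa, wa = x[ok & (labels == 1)], weights[ok & (labels == 1)]
        xb, wb = x[ok & (labels == 0)], weights[ok & (labels == 0)]
        if xa.size < 2 or xb.size < 2:
            continue
        try:
            vals.append(abs(smd(xa, xb, wa, wb)))
        except DomainError:
            continue
    return float(np.mean(vals)) if vals else 0.0


def estimate_propensity(features, labels, shrinkage: float = 0.001,
                        depth: int = 3, max_trees: int = 2000,
                        cv_folds: int = 5, n_grid: int = 20,
                        seed: int = 0) -> PropensityFit:
    """Gradient-boosted propensity scores with balance-driven tree selection.

    Fits a gradient boosting classifier (learning rate = ``shrinkage``, tree
    depth = ``depth``) and selects the number of trees on a grid up to
    ``max_trees`` by K-fold cross-validation: for each candidate count the
    out-of-fold probabilities imply inverse-probability weights, and the
    candidate minimizing the mean absolute SMD of the features between the
    two groups is chosen.  Missing feature values are handled natively by
    the tree splits (splits use observed values only).  Deterministic given
    ``seed``.
    """
    from sklearn.ensemble import HistGradientBoostingClassifier
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(features, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("labels contain a single class")

    def _new_clf():
        return HistGradientBoostingClassifier(
            learning_rate=shrinkage, max_depth=depth, max_iter=1,
            warm_start=True, early_stopping=False, random_state=seed)

    grid = np.unique(np.linspace(max(1, max_trees // n_grid), max_trees,
                                 n_grid).astype(int))
    oof = np.full((len(grid), len(y)), np.nan)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for train, test in skf.split(X, y):
        clf = _new_clf()
        for gi, m in enumerate(grid):
            clf.set_params(max_iter=int(m))
            clf.fit(X[train], y[train])
            oof[gi, test] = clf.predict_proba(X[test])[:, 1]

    balances = []
    for gi, m in enumerate(grid):
        p = np.clip(oof[gi], 1e-6, 1 - 1e-6)
        w = np.where(y == 1, 1.0 / p, 1.0 / (1.0 - p))
        balances.append(_mean_abs_smd(X, y, w))
    best = int(np.argmin(balances))
    n_trees = int(grid[best])

    final = HistGradientBoostingClassifier(
        learning_rate=shrinkage, max_depth=depth, max_iter=n_trees,
        early_stopping=False, random_state=seed)
    final.fit(X, y)
    probs = np.clip(final.predict_proba(X)[:, 1], 1e-6, 1 - 1e-6)
    return PropensityFit(
        probabilities=probs, n_trees=n_trees,
        cv_balance=pd.DataFrame({"n_trees": grid, "mean_abs_smd": balances}))


def ipw_weights(scheme: str, probabilities: Sequence[float],
                group_labels: Sequence[bool]) -> np.ndarray:
    """Per-subject analysis weights for one of the three weight definitions.

    dropout_adjust    : 1/p for the treatment group (p = probability of being
                        a non-dropout), exactly 1 for the wait group.
    adherence_adjust  : 1/p for the access group (p = probability of using
                        the tool as recommended), exactly 1 for the wait group.
    user_vs_nonuser   : 1/p for users, 1/(1-p) for non-users (p = probability
                        of being a user).

    Weights are attached to subjects and never normalized silently.
    """
    if scheme not in WEIGHT_SCHEMES:
        raise DomainError(f"unknown scheme {scheme!r}; expected one of {WEIGHT_SCHEMES}")
    p = np.asarray(probabilities, float)
    g = np.asarray(group_labels).astype(bool)
    if np.any((p <= 0) | (p >= 1)):
        raise DomainError("probabilities must lie strictly inside (0, 1)")
    if scheme == "user_vs_nonuser":
        return np.where(g, 1.0 / p, 1.0 / (1.0 - p))
    return np.where(g, 1.0 / p, 1.0)


# ---------------------------------------------------------------------------
# contrasts


@dataclass(frozen=True)
class ContrastResult:
    estimate: float
    se: float
    ci: Tuple[float, float]
    p: float


def weighted_group_difference(outcome_delta, group, weights) -> ContrastResult:
    """Weighted least-squares group difference with HC1 sandwich SE."""
    import statsmodels.api as sm

    y = np.asarray(outcome_delta, float)
    g = np.asarray(group).astype(float)
    w = np.asarray(weights, float)
    if np.any(w < 0) or w.sum() == 0:
        raise DomainError("weights must be non-negative and not all zero")
    if len(np.unique(g)) < 2:
        raise DegenerateInputError("only one group present")
    for grp in (0.0, 1.0):
        if w[g == grp].sum() == 0:
            raise DomainError("weights sum to zero within one group")
    X = sm.add_constant(g)
    fit = sm.WLS(y, X, weights=w).fit(cov_type="HC1")
    est = float(fit.params[1])
    se = float(fit.bse[1])
    lo, hi = fit.conf_int()[1]
    return ContrastResult(estimate=est, se=se, ci=(float(lo), float(hi)),
                          p=float(fit.pvalues[1]))


def endpoint_contrast(group_a_deltas, group_b_deltas,
                      alpha: float = 0.05) -> ContrastResult:
    """Welch two-sided t-test contrast, reported as mean(a) - mean(b)."""
    a = np.asarray(group_a_deltas, float)
    b = np.asarray(group_b_deltas, float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("need at least 2 observations per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    diff = float(a.mean() - b.mean())
    se = math.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    return ContrastResult(estimate=diff, se=se, ci=(float(ci.low), float(ci.high)),
                          p=float(res.pvalue))


def interaction_test(outcome_delta, group, subgroup,
                     covariates: Optional[pd.DataFrame] = None) -> Tuple[float, float]:
    """Group x subgroup interaction coefficient and two-sided p from OLS.

    Fits outcome ~ group + subgroup + group:subgroup (+ optional covariates,
    e.g. age and baseline HbA1c).  All four cells must be non-empty.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome_delta, float)
    g = np.asarray(group).astype(float)
    s = np.asarray(subgroup).astype(float)
    for gv in (0, 1):
        for sv in (0, 1):
            if not np.any((g == gv) & (s == sv)):
                raise DegenerateInputError(f"empty design cell group={gv}, subgroup={sv}")
    cols = [g, s, g * s]
    names = ["group", "subgroup", "group_x_subgroup"]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(np.asarray(covariates[c], float))
            names.append(c)
    X = sm.add_constant(np.column_stack(cols))
    fit = sm.OLS(y, X).fit()
    idx = 1 + names.index("group_x_subgroup")
    return float(fit.params[idx]), float(fit.pvalues[idx])


# ---------------------------------------------------------------------------
# mediation


@dataclass
class MediationResult:
    total_effect: float
    direct_effect: float
    indirect_effect: float
    prop_mediated: float
    boot_ci: Dict[str, Tuple[float, float]]
    a_path: float
    b_path: float


def _lstsq_coef(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise DegenerateInputError("singular design (collinear moderators?)")
    return coef


def mediation(exposure, mediator, outcome,
              moderators: Optional[pd.DataFrame] = None,
              n_boot: int = 5000, seed: int = 0,
              ci_level: float = 0.95) -> MediationResult:
    """Linear mediation decomposition with percentile bootstrap intervals.

    a-path: mediator ~ exposure (+ mean-centered moderators);
    outcome model: outcome ~ exposure + mediator (+ moderators).
    indirect = a x b, direct = the exposure coefficient of the outcome model,
    total = direct + indirect (which equals the exposure coefficient of
    outcome ~ exposure (+ moderators) exactly, a linear-model identity).
    The bootstrap resamples whole subjects.
    """
    x = np.asarray(exposure, float)
    m = np.asarray(mediator, float)
    y = np.asarray(outcome, float)
    mask = ~(np.isnan(x) | np.isnan(m) | np.isnan(y))
    Z = None
    if moderators is not None:
        Z = np.asarray(moderators, float)
        if Z.ndim == 1:
            Z = Z[:, None]
        mask &= ~np.isnan(Z).any(axis=1)
    x, m, y = x[mask], m[mask], y[mask]
    if Z is not None:
        Z = Z[mask]
        Z = Z - Z.mean(axis=0)
    n = x.size
    if n < 10:
        raise DegenerateInputError(f"need at least 10 complete cases, got {n}")
    if n_boot < 1000:
        raise DomainError("n_boot must be at least 1000")

    def _fit(idx):
        xi, mi, yi = x[idx], m[idx], y[idx]
        Zi = Z[idx] if Z is not None else None
        ones = np.ones_like(xi)
        Xa = np.column_stack([ones, xi] + ([Zi] if Zi is not None else []))
        a = _lstsq_coef(Xa, mi)[1]
        Xb = np.column_stack([ones, xi, mi] + ([Zi] if Zi is not None else []))
        cb = _lstsq_coef(Xb, yi)
        direct, b = cb[1], cb[2]
        return a, b, direct

    idx_all = np.arange(n)
    a, b, direct = _fit(idx_all)
    indirect = a * b
    total = direct + indirect
    prop = indirect / total if total != 0 else float("nan")

    rng = np.random.default_rng(seed)
    draws = {"total": [], "direct": [], "indirect": []}
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            ab, bb, db = _fit(idx)
        except DegenerateInputError:
            continue
        draws["indirect"].append(ab * bb)
        draws["direct"].append(db)
        draws["total"].append(db + ab * bb)
    lo_q, hi_q = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
    boot_ci = {k: (float(np.percentile(v, lo_q)), float(np.percentile(v, hi_q)))
               for k, v in draws.items()}
    return MediationResult(
        total_effect=float(total), direct_effect=float(direct),
        indirect_effect=float(indirect), prop_mediated=float(prop),
        boot_ci=boot_ci, a_path=float(a), b_path=float(b))


# ---------------------------------------------------------------------------
# design calculations


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the two-group normal-approximation sample-size formula."""
    delta: float          # detectable difference, mmol/mol
    sd: float             # SD of the outcome change, mmol/mol
    alpha: float = 0.05   # two-sided level
    power: float = 0.80
    allocation_ratio: float = 1.0   # controls per case

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise DomainError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise DomainError("power must be in (0, 1)")
        if self.sd <= 0:
            raise DomainError("sd must be positive")
        if self.allocation_ratio < 1:
            raise DomainError("allocation_ratio must be at least 1")


def sample_size_two_groups(spec: PowerSpec) -> Tuple[int, int]:
    """Per-group sample sizes for a two-sided two-sample comparison of means.

    n_cases = ceil((1 + 1/k) (z_{1-alpha/2} + z_{power})^2 sd^2 / delta^2),
    n_controls = k x n_cases.  With delta 2, sd 6 and 1:1 allocation this
    gives 142 per group; with delta 5, sd 7 and 1:2 allocation, 24 and 48.
    """
    if spec.delta == 0:
        raise DomainError("delta must be non-zero")
    k = spec.allocation_ratio
    z = stats.norm.ppf(1 - spec.alpha / 2) + stats.norm.ppf(spec.power)
    n_cases = math.ceil((1 + 1 / k) * z ** 2 * spec.sd ** 2 / spec.delta ** 2)
    return n_cases, math.ceil(k * n_cases)


def empirical_power(n_cases: int, n_controls: int, delta: float, sd: float,
                    alpha: float = 0.05, reps: int = 10_000,
                    seed: int = 0) -> float:
    """Monte-Carlo rejection rate of the two-sided t-test under the alternative."""
    if reps < 1000:
        raise DomainError("reps must be at least 1000")
    rng = np.random.default_rng(seed)
    a = rng.normal(delta, sd, (reps, n_cases))
    b = rng.normal(0.0, sd, (reps, n_controls))
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    return float((res.pvalue < alpha).mean())
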