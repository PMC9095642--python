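"""Matching, weighting, contrasts, mediation and design calculations."""

import math

import numpy as np
import pandas as pd
import pytest

from glycotrial.errors import (
    DegenerateInputError,
    DomainError,
    InsufficientControlsError,
)
from glycotrial.inference import (
    PowerSpec,
    empirical_power,
    endpoint_contrast,
    estimate_propensity,
    interaction_test,
    ipw_weights,
    match_controls,
    mediation,
    sample_size_two_groups,
    smd,
    weighted_group_difference,
)


class TestSmd:
    def test_identical_groups_zero(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert smd(x, x) == pytest.approx(0.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(1, 1, 50), rng.normal(0, 2, 40)
        assert smd(a, b) == pytest.approx(-smd(b, a))

    def test_unit_shift_estimand(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(1, 1, 100_000), rng.normal(0, 1, 100_000)
        assert smd(a, b) == pytest.approx(1.0, abs=0.02)

    def test_weighted_moments(self):
        # weights of 2 equal duplicating the observation
        a, wa = [1.0, 3.0], [2.0, 1.0]
        b = [0.0, 1.0, 2.0]
        got = smd(a, b, weights_a=wa)
        # check against explicit weighted-moment computation
        ma = np.average(a, weights=wa)
        va = np.average((np.asarray(a) - ma) ** 2, weights=wa)
        mb, vb = np.mean(b), np.var(b, ddof=1)
        assert got == pytest.approx((ma - mb) / math.sqrt((va + vb) / 2))

    def test_zero_pooled_sd_raises(self):
        with pytest.raises(DomainError):
            smd([1.0, 1.0], [1.0, 1.0])


def _registry_from_participants(participants, copies=2, extra=0, seed=0):
    """Registry pool containing `copies` exact covariate duplicates of each
    participant, each with a single admissible index date at day 0."""
    rows = []
    k = 0
    for _, p in participants.iterrows():
        for _ in range(copies):
            k += 1
            rid = f"R{k:04d}"
            for day, val in [(0, p["hba1c"]), (370, p["hba1c"] + 1.0)]:
                rows.append({"id": rid, "sex": p["sex"], "age": p["age"],
                             "bmi": p["bmi"], "diagnosis_day": -730.0,
                             "day": day, "hba1c": val, "med_change": False})
    rng = np.random.default_rng(seed)
    for _ in range(extra):
        k += 1
        rid = f"R{k:04d}"
        for day, val in [(0, rng.normal(70, 5)), (370, rng.normal(70, 5))]:
            rows.append({"id": rid, "sex": rng.choice(["male", "female"]),
                         "age": rng.normal(55, 5), "bmi": rng.normal(27, 3),
                         "diagnosis_day": -730.0, "day": day, "hba1c": val,
                         "med_change": False})
    return pd.DataFrame(rows)


def _participants(n=12, seed=4):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "id": [f"P{i:03d}" for i in range(n)],
        "sex": rng.choice(["male", "female"], n),
        "age": rng.normal(63, 9, n),
        "bmi": rng.normal(31, 5, n),
        "hba1c": rng.normal(63, 10, n),
    })


class TestMatchControls:
    def test_exact_duplicates_selected_smd_zero(self):
        part = _participants()
        registry = _registry_from_participants(part, copies=2, extra=30)
        res = match_controls(part, registry, ratio=2, seed=1)
        assert all(len(v) == 2 for v in res.pairs.values())
        assert res.balance["smd_post"].abs().max() == pytest.approx(0.0, abs=1e-9)
        # sex matches exactly, controls never reused
        used = [c for v in res.pairs.values() for c in v]
        assert len(used) == len(set(used))

    def test_index_dates_recorded(self):
        part = _participants()
        registry = _registry_from_participants(part)
        res = match_controls(part, registry, ratio=1, seed=1)
        assert all(d == 0 for d in res.index_dates.values())

    def test_shortfall_error_lists_strata(self):
        part = _participants(n=20)
        registry = _registry_from_participants(part.iloc[:3], copies=1)
        with pytest.raises(InsufficientControlsError, match="shortfall"):
            match_controls(part, registry, ratio=2, seed=0)

    def test_covariate_shift_reduced_by_matching(self):
        """With shifted registry covariates, matching shrinks the worst SMD."""
        rng = np.random.default_rng(11)
        n = 60
        part = pd.DataFrame({
            "id": [f"P{i:03d}" for i in range(n)],
            "sex": rng.choice(["male", "female"], n),
            "age": rng.normal(63, 9, n),
            "bmi": rng.normal(31, 5, n),
            "hba1c": rng.normal(63, 10, n)})
        rows = []
        for i in range(1200):
            rid = f"R{i:04d}"
            for day, val in [(0, rng.normal(58, 10)), (370, rng.normal(58, 10))]:
                rows.append({"id": rid, "sex": rng.choice(["male", "female"]),
                             "age": rng.normal(59, 9), "bmi": rng.normal(28, 5),
                             "diagnosis_day": -730.0, "day": day,
                             "hba1c": val, "med_change": False})
        res = match_controls(part, pd.DataFrame(rows), ratio=2, seed=2)
        assert (res.balance["smd_post"].abs().max()
                < res.balance["smd_pre"].abs().max())


class TestPropensity:
    def test_monotone_on_separable_feature(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-2, 0.5, 60), rng.normal(2, 0.5, 60)])
        y = np.array([0] * 60 + [1] * 60)
        fit = estimate_propensity(x, y, max_trees=300, n_grid=6, cv_folds=3, seed=0)
        assert fit.probabilities[y == 1].mean() > fit.probabilities[y == 0].mean()
        assert fit.n_trees <= 300

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 3))
        y = (rng.random(80) < 0.5).astype(int)
        a = estimate_propensity(X, y, max_trees=100, n_grid=5, cv_folds=3, seed=9)
        b = estimate_propensity(X, y, max_trees=100, n_grid=5, cv_folds=3, seed=9)
        assert np.array_equal(a.probabilities, b.probabilities)
        assert a.n_trees == b.n_trees

    def test_handles_missing_values(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 2))
        X[rng.random(X.shape) < 0.2] = np.nan
        y = (rng.random(100) < 0.5).astype(int)
        fit = estimate_propensity(X, y, max_trees=50, n_grid=3, cv_folds=2, seed=0)
        assert np.all((fit.probabilities > 0) & (fit.probabilities < 1))

    def test_single_class_raises(self):
        with pytest.raises(DegenerateInputError):
            estimate_propensity(np.zeros((10, 1)), np.ones(10))


class TestIpwWeights:
    def test_user_vs_nonuser(self):
        w = ipw_weights("user_vs_nonuser", [0.5, 0.2], [True, False])
        assert w[0] == pytest.approx(2.0)
        assert w[1] == pytest.approx(1.25)

    @pytest.mark.parametrize("scheme", ["dropout_adjust", "adherence_adjust"])
    def test_comparison_group_weight_is_one(self, scheme):
        w = ipw_weights(scheme, [0.7, 0.3, 0.9], [True, False, False])
        assert w[0] == pytest.approx(1 / 0.7)
        assert w[1] == 1.0 and w[2] == 1.0

    def test_probability_outside_unit_interval_raises(self):
        with pytest.raises(DomainError):
            ipw_weights("user_vs_nonuser", [0.0, 0.5], [True, False])
        with pytest.raises(DomainError):
            ipw_weights("bogus", [0.5], [True])


class TestWeightedGroupDifference:
    def test_unit_weights_equal_mean_difference(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=60)
        g = np.repeat([0, 1], 30)
        res = weighted_group_difference(y, g, np.ones(60))
        assert res.estimate == pytest.approx(y[g == 1].mean() - y[g == 0].mean(), abs=1e-10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=50)
        g = (rng.random(50) < 0.5).astype(int)
        w = rng.uniform(0.5, 2.0, 50)
        a = weighted_group_difference(y, g, w)
        b = weighted_group_difference(y, g, 2 * w)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-10)
        assert a.se == pytest.approx(b.se, rel=1e-8)

    def test_closed_form_weighted_means_oracle(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=40)
        g = (rng.random(40) < 0.5).astype(int)
        w = rng.uniform(0.1, 3.0, 40)
        res = weighted_group_difference(y, g, w)
        want = (np.sum(w[g == 1] * y[g == 1]) / np.sum(w[g == 1])
                - np.sum(w[g == 0] * y[g == 0]) / np.sum(w[g == 0]))
        assert res.estimate == pytest.approx(want, abs=1e-10)

    def test_single_group_raises(self):
        with pytest.raises(DegenerateInputError):
            weighted_group_difference([1.0, 2.0], [1, 1], [1.0, 1.0])


class TestEndpointContrast:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = endpoint_contrast(x, x)
        assert res.estimate == 0.0 and res.p == pytest.approx(1.0)

    def test_pure_shift(self):
        rng = np.random.default_rng(0)
        b = rng.normal(size=30)
        res = endpoint_contrast(b + 5, b)
        assert res.estimate == pytest.approx(5.0, abs=1e-12)

    def test_insufficient_data(self):
        with pytest.raises(DegenerateInputError):
            endpoint_contrast([1.0], [1.0, 2.0])


class TestInteraction:
    def test_saturated_model_identity(self):
        rng = np.random.default_rng(0)
        cells = {(0, 0): 0.0, (0, 1): 0.0, (1, 0): 0.0, (1, 1): -4.0}
        rows = []
        for (g, s), m in cells.items():
            for _ in range(25):
                rows.append((m + rng.normal(0, 1), g, s))
        y, g, s = map(np.array, zip(*rows))
        coef, p = interaction_test(y, g, s)
        means = {k: y[(g == k[0]) & (s == k[1])].mean() for k in cells}
        want = (means[(1, 1)] - means[(1, 0)]) - (means[(0, 1)] - means[(0, 0)])
        assert coef == pytest.approx(want, abs=1e-9)

    def test_empty_cell_raises(self):
        with pytest.raises(DegenerateInputError):
            interaction_test([1.0, 2.0, 3.0], [0, 1, 1], [0, 0, 0])

    def test_null_interaction_type_I_rate(self):
        """Additive truth: the interaction p is ~uniform, rejection ~5%."""
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 400
        for _ in range(reps):
            g = np.repeat([0, 1], 20)
            s = np.tile([0, 1], 20)
            y = 1.0 * g + 0.5 * s + rng.normal(0, 1, 40)
            _, p = interaction_test(y, g, s)
            rejections += p < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / reps)


class TestMediation:
    def test_decomposition_identity(self):
        rng = np.random.default_rng(0)
        n = 120
        x = rng.normal(size=n)
        m = 0.7 * x + rng.normal(0, 1, n)
        y = -0.4 * x - 0.8 * m + rng.normal(0, 1, n)
        Z = pd.DataFrame({"z": rng.normal(size=n)})
        res = mediation(x, m, y, Z, n_boot=1000, seed=1)
        assert res.total_effect == pytest.approx(
            res.direct_effect + res.indirect_effect, abs=1e-12)
        # total equals the coefficient of y ~ x (+ moderators)
        ones = np.ones(n)
        X = np.column_stack([ones, x, Z["z"] - Z["z"].mean()])
        beta = np.linalg.lstsq(X, y, rcond=None)[0][1]
        assert res.total_effect == pytest.approx(beta, abs=1e-9)

    def test_fully_mediated_truth(self):
        rng = np.random.default_rng(3)
        n = 300
        x = rng.normal(size=n)
        m = x + rng.normal(0, 0.3, n)
        y = -0.5 * m + rng.normal(0, 0.3, n)
        res = mediation(x, m, y, n_boot=1000, seed=2)
        assert res.prop_mediated == pytest.approx(1.0, abs=0.15)
        assert res.indirect_effect == pytest.approx(-0.5, abs=0.1)

    def test_null_indirect_ci_covers_zero(self):
        rng = np.random.default_rng(4)
        n = 200
        x = rng.normal(size=n)
        m = rng.normal(size=n)            # mediator independent of exposure
        y = 0.5 * x + rng.normal(size=n)
        res = mediation(x, m, y, n_boot=1000, seed=5)
        lo, hi = res.boot_ci["indirect"]
        assert lo < 0 < hi

    def test_collinear_moderators_raise(self):
        rng = np.random.default_rng(5)
        n = 50
        x = rng.normal(size=n)
        Z = pd.DataFrame({"a": x, "b": 2 * x})   # collinear with exposure
        with pytest.raises(DegenerateInputError):
            mediation(x, rng.normal(size=n), rng.normal(size=n), Z,
                      n_boot=1000, seed=0)

    def test_too_few_cases_raise(self):
        with pytest.raises(DegenerateInputError):
            mediation([1.0] * 5, [1.0] * 5, [1.0] * 5, n_boot=1000)


class TestDesign:
    def test_randomization_phase_sample_size(self):
        spec = PowerSpec(delta=2, sd=6, alpha=0.05, power=0.80, allocation_ratio=1)
        assert sample_size_two_groups(spec) == (142, 142)

    def test_matched_comparison_sample_size(self):
        spec = PowerSpec(delta=5, sd=7, alpha=0.05, power=0.80, allocation_ratio=2)
        assert sample_size_two_groups(spec) == (24, 48)

    def test_variance_proportionality(self):
        n1, _ = sample_size_two_groups(PowerSpec(delta=2, sd=6))
        n2, _ = sample_size_two_groups(PowerSpec(delta=2, sd=12))
        z = 2.8015879  # z_{0.975} + z_{0.80}
        raw1 = 2 * z ** 2 * 36 / 4
        assert n2 == math.ceil(4 * raw1)

    def test_zero_delta_raises(self):
        with pytest.raises(DomainError):
            sample_size_two_groups(PowerSpec(delta=0, sd=6))

    def test_invalid_spec_raises(self):
        with pytest.raises(DomainError):
            PowerSpec(delta=2, sd=-1)
        with pytest.raises(DomainError):
            PowerSpec(delta=2, sd=6, alpha=1.5)

    def test_null_rejection_rate_is_alpha(self):
        rate = empirical_power(50, 50, delta=0.0, sd=6, alpha=0.05,
                               reps=4000, seed=3)
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / 4000)

    def test_power_monotone_in_delta(self):
        powers = [empirical_power(40, 40, d, 6, reps=2000, seed=4)
                  for d in (0.5, 2.0, 4.0)]
        assert powers[0] < powers[1] < powers[2]
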