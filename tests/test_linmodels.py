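import numpy as np
import pandas as pd
import pytest

from morphuniq.linmodels import (
    dispersion_vs_influence,
    effect_code,
    influence_index,
    manova,
    manova_nested,
    trajectory_angle,
)


def _toy_two_group(rng, n=30, m=2, shift=1.0):
    y = rng.normal(size=(n, m))
    g = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    y[g == "b"] += shift
    return y, g


def brute_force_one_way_wilks(y, groups):
    """Independent oracle: E and H from explicit group-mean SSCP algebra."""
    levels = sorted(set(groups))
    grand = y.mean(0)
    e = np.zeros((y.shape[1], y.shape[1]))
    h = np.zeros_like(e)
    for lev in levels:
        sub = y[groups == lev]
        gm = sub.mean(0)
        d = sub - gm
        e += d.T @ d
        h += sub.shape[0] * np.outer(gm - grand, gm - grand)
    return np.linalg.det(e) / np.linalg.det(e + h), e, h


class TestManova:
    def test_two_group_matches_brute_force_sscp(self, rng):
        y, g = _toy_two_group(rng)
        res = manova(y, {"g": g})[0]
        lam_oracle, e, h = brute_force_one_way_wilks(y, g)
        assert res.wilks_lambda == pytest.approx(lam_oracle, abs=1e-10)
        # Rao F for q=1: F = (1-Λ)/Λ · (df_e - m + 1)/m
        n, m = y.shape
        df_e = n - 2
        f_oracle = (1 - lam_oracle) / lam_oracle * (df_e - m + 1) / m
        assert res.f == pytest.approx(f_oracle, abs=1e-10)
        from scipy.stats import f as fdist

        assert res.p == pytest.approx(fdist.sf(f_oracle, m, df_e - m + 1), abs=1e-12)

    def test_single_df_eta_squared_identity(self, rng):
        y, g = _toy_two_group(rng, shift=2.0)
        res = manova(y, {"g": g})[0]
        assert res.partial_eta_sq == pytest.approx(1 - res.wilks_lambda, abs=1e-14)

    def test_identical_group_means_lambda_one(self, rng):
        y = rng.normal(size=(40, 3))
        y -= y.mean(0)
        g = np.array(["a", "b"] * 20)
        # force exactly equal group means
        for lev in ("a", "b"):
            y[g == lev] -= y[g == lev].mean(0)
        res = manova(y, {"g": g})[0]
        assert res.wilks_lambda == pytest.approx(1.0, abs=1e-10)
        assert res.partial_eta_sq == pytest.approx(0.0, abs=1e-10)
        assert res.p > 0.99

    def test_matches_statsmodels_wilks(self, rng):
        """Independent package oracle for a two-factor type-III design."""
        statsmodels = pytest.importorskip("statsmodels.multivariate.manova")
        n = 60
        y = rng.normal(size=(n, 3))
        a = rng.choice(["x", "y"], n)
        b = rng.choice(["p", "q", "r"], n)
        y[a == "x"] += 0.8
        res = {r.effect: r for r in manova(y, {"a": a, "b": b})}
        df = pd.DataFrame(y, columns=["v1", "v2", "v3"])
        df["a"], df["b"] = a, b
        mv = statsmodels.MANOVA.from_formula(
            "v1 + v2 + v3 ~ C(a, Sum) + C(b, Sum)", data=df
        )
        tests = mv.mv_test()
        for name, key in (("a", "C(a, Sum)"), ("b", "C(b, Sum)")):
            stat = tests.results[key]["stat"]
            assert res[name].wilks_lambda == pytest.approx(
                float(stat.loc["Wilks' lambda", "Value"]), abs=1e-8
            )
            assert res[name].p == pytest.approx(
                float(stat.loc["Wilks' lambda", "Pr > F"]), abs=1e-8
            )

    def test_balanced_design_type_iii_equals_sequential(self, rng):
        """In a balanced two-way design the type-III Λ equals the Λ from a
        sequential (add-one-term) comparison."""
        reps = 10
        a = np.repeat(["x", "y"], 2 * reps)
        b = np.tile(np.repeat(["p", "q"], reps), 2)
        y = rng.normal(size=(4 * reps, 3))
        y[a == "y"] += 0.5
        y[b == "q", 1] += 0.7
        res = {r.effect: r for r in manova(y, {"a": a, "b": b})}
        # sequential: effect of a comparing [1] vs [1, a]
        from morphuniq.linmodels import wilks_model_comparison

        ca, _ = effect_code(a)
        cb, _ = effect_code(b)
        ones = np.ones((y.shape[0], 1))
        seq_a = wilks_model_comparison(y, np.hstack([ones, cb, ca]), np.hstack([ones, cb]))
        assert res["a"].wilks_lambda == pytest.approx(seq_a.wilks_lambda, abs=1e-10)

    def test_aliased_effects_named(self, rng):
        y = rng.normal(size=(20, 2))
        g = np.array(["a", "b"] * 10)
        with pytest.raises(ValueError, match="dup"):
            manova(y, {"g": g, "dup": g})

    def test_observed_power_in_range(self, rng):
        y, g = _toy_two_group(rng, shift=1.0)
        res = manova(y, {"g": g})[0]
        assert 0.05 <= res.observed_power <= 1.0


class TestNested:
    def _nested_data(self, rng, host_shift=1.0, pop_shift=0.0):
        pops = {"h1": ["p1", "p2", "p3"], "h2": ["p4", "p5"]}
        rows_h, rows_p = [], []
        for h, ps in pops.items():
            for p in ps:
                rows_h += [h] * 12
                rows_p += [p] * 12
        host = np.array(rows_h)
        pop = np.array(rows_p)
        y = rng.normal(size=(host.size, 3))
        y[host == "h2"] += host_shift
        for i, p in enumerate(sorted(set(pop))):
            y[pop == p, 1] += pop_shift * i
        return y, host, pop

    def test_df_bookkeeping(self, rng):
        y, host, pop = self._nested_data(rng)
        res = {r.effect: r for r in manova_nested(y, host, pop)}
        # df_h(pop within host) = (3-1) + (2-1) = 3; multivariate df1 = 3 * m
        assert res["population(host)"].df_h == 3
        assert res["population(host)"].df1 == 9
        assert res["host"].df_h == 1

    def test_host_effect_only_detected(self, rng):
        y, host, pop = self._nested_data(rng, host_shift=1.5, pop_shift=0.0)
        res = {r.effect: r for r in manova_nested(y, host, pop)}
        assert res["host"].p < 0.001
        assert res["population(host)"].p > 0.01

    def test_nested_effect_detected(self, rng):
        y, host, pop = self._nested_data(rng, host_shift=0.0, pop_shift=1.5)
        res = {r.effect: r for r in manova_nested(y, host, pop)}
        assert res["population(host)"].p < 0.001

    def test_inner_spanning_outer_rejected(self, rng):
        y = rng.normal(size=(20, 2))
        host = np.array(["h1"] * 10 + ["h2"] * 10)
        pop = np.array(["p1"] * 15 + ["p2"] * 5)  # p1 spans both hosts
        with pytest.raises(ValueError, match="span"):
            manova_nested(y, host, pop)

    def test_degenerate_nesting_flagged(self, rng):
        y = rng.normal(size=(20, 2))
        host = np.array(["h1"] * 10 + ["h2"] * 10)
        pop = np.array(["p1"] * 10 + ["p2"] * 10)  # one pop per host
        res = manova_nested(y, host, pop)
        nested = [r for r in res if "(" in r.effect][0]
        assert not nested.defined


class TestTrajectoryAngle:
    def test_same_data_zero_angle(self, rng):
        x = rng.normal(size=(40, 5))
        res = trajectory_angle(x, x, n_boot=99, seed=0)
        assert res.angle_deg == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_axes_ninety_degrees(self, rng):
        n = 200
        a = np.zeros((n, 4))
        a[:, 0] = rng.normal(0, 5, n)
        a[:, 1:] = rng.normal(0, 0.1, (n, 3))
        b = np.zeros((n, 4))
        b[:, 1] = rng.normal(0, 5, n)
        b[:, [0, 2, 3]] = rng.normal(0, 0.1, (n, 3))
        res = trajectory_angle(a, b, n_boot=99, seed=0)
        assert res.angle_deg > 85

    def test_shared_trajectory_not_rejected_under_null(self):
        """Two samples from one population share a trajectory: the test stays
        non-significant in the vast majority of replicates."""
        rng = np.random.default_rng(17)
        cov_scale = np.array([4.0, 1.0, 0.5, 0.25])
        nonsig = 0
        reps = 40
        for _ in range(reps):
            a = rng.normal(size=(60, 4)) * cov_scale
            b = rng.normal(size=(60, 4)) * cov_scale
            res = trajectory_angle(a, b, n_boot=199, seed=int(rng.integers(2**31)))
            nonsig += res.p_value > 0.05
        assert nonsig / reps >= 0.9


class TestGeneFlow:
    def test_influence_arithmetic(self):
        rec = influence_index([("P", 0.5, 0.3, 2.0)])[0]
        assert rec.influence == pytest.approx(0.4)

    def test_zero_proportions_zero_influence(self):
        assert influence_index([("P", 0.0, 0.0, 3.0)])[0].influence == 0.0

    def test_bad_distance_rejected(self):
        with pytest.raises(ValueError):
            influence_index([("P", 0.1, 0.1, 0.0)])

    def test_published_influence_values_feed_regression(self, rng):
        """The study's influence column is consumed as-is for the dispersion
        regression over six populations."""
        influences = {"HVA": 15.97, "LA": 0.21, "LRN": 0.39,
                      "OUTA": 119.89, "PRC": 2.62, "VPC": 19.46}
        pops = np.repeat(list(influences), 10)
        scores = rng.normal(size=(60, 3))
        reg = dispersion_vs_influence(scores, pops, influences)
        assert set(reg.sem_table.index) == set(influences)
        assert 0 <= reg.mean_sem_fit["p"] <= 1

    def test_constructed_dispersion_gradient_detected(self):
        rng = np.random.default_rng(5)
        influences = {f"P{i}": float(i) for i in range(6)}
        pops = np.repeat(list(influences), 30)
        scores = np.concatenate(
            [rng.normal(0, 0.2 + 1.0 * i, size=(30, 3)) for i in range(6)]
        )
        reg = dispersion_vs_influence(scores, pops, influences)
        assert reg.mean_sem_fit["slope"] > 0
        assert reg.mean_sem_fit["p"] < 0.05

    def test_null_slope_near_zero(self):
        slopes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            influences = {f"P{i}": float(i) for i in range(6)}
            pops = np.repeat(list(influences), 15)
            scores = rng.normal(size=(90, 3))
            reg = dispersion_vs_influence(scores, pops, influences)
            slopes.append(reg.mean_sem_fit["slope"])
        assert abs(np.mean(slopes)) < 0.02

    def test_constant_population_flagged(self, rng):
        influences = {"A": 1.0, "B": 2.0, "C": 3.0}
        pops = np.repeat(list(influences), 5)
        scores = rng.normal(size=(15, 3))
        scores[pops == "B"] = 0.0
        reg = dispersion_vs_influence(scores, pops, influences)
        assert "B" in reg.flagged

    def test_too_few_populations_rejected(self, rng):
        with pytest.raises(ValueError):
            dispersion_vs_influence(
                rng.normal(size=(10, 3)), np.repeat(["A", "B"], 5), {"A": 1.0, "B": 2.0}
            )
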