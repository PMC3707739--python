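import numpy as np
import pytest
from scipy.stats import norm

from morphuniq.uniqueness import (
    DominanceTable,
    ZeroVarianceGroupError,
    dominance_table,
    mu_significance,
    overall_mu,
    pairwise_mu,
    rw_overlap,
    rw_uniqueness,
)
from morphuniq.warps import relative_warps


class TestOverlap:
    def test_identical_samples_overlap_one(self, rng):
        x = rng.normal(size=200)
        assert rw_overlap(x, x) == pytest.approx(1.0, abs=1e-3)

    def test_normal_shift_matches_closed_form(self):
        """Overlap of N(0,1) vs N(2,1) tends to 2Φ(−1) ≈ 0.3173."""
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 2000)
        b = rng.normal(2, 1, 2000)
        assert rw_overlap(a, b) == pytest.approx(2 * norm.cdf(-1), abs=0.03)

    def test_matches_scipy_kde_oracle(self):
        """Our grid KDE overlap agrees with an independent scipy KDE route."""
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 400)
        b = rng.normal(1.2, 1.4, 300)
        from scipy.stats import gaussian_kde

        grid = np.linspace(-6, 8, 4000)
        fa = gaussian_kde(a, bw_method="silverman")(grid)
        fb = gaussian_kde(b, bw_method="silverman")(grid)
        fa /= np.trapezoid(fa, grid)
        fb /= np.trapezoid(fb, grid)
        oracle = np.trapezoid(np.minimum(fa, fb), grid)
        # scipy's silverman factor ignores the IQR guard, so allow KDE-level slack
        assert rw_overlap(a, b) == pytest.approx(oracle, abs=0.02)

    def test_disjoint_supports_near_zero(self, rng):
        a = rng.normal(0, 0.05, 50)
        b = rng.normal(50, 0.05, 50)
        assert rw_overlap(a, b) < 0.01

    def test_bounds_always_hold(self, rng):
        for _ in range(30):
            a = rng.normal(rng.uniform(-3, 3), rng.uniform(0.1, 4), rng.integers(3, 60))
            b = rng.normal(rng.uniform(-3, 3), rng.uniform(0.1, 4), rng.integers(3, 60))
            for rule in ("union_extended", "largest_group"):
                ov = rw_overlap(a, b, range_rule=rule)
                assert 0.0 <= ov <= 1.0

    def test_uniqueness_complements_overlap(self, rng):
        a, b = rng.normal(size=50), rng.normal(2, 1, 60)
        assert rw_uniqueness(a, b) == pytest.approx(1 - rw_overlap(a, b), abs=1e-12)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ZeroVarianceGroupError):
            rw_overlap(np.ones(10), np.arange(10.0))

    def test_uniqueness_monotone_in_separation(self):
        """Mean estimated uniqueness is non-decreasing along a shift grid."""
        deltas = [0.0, 0.5, 1.0, 2.0, 4.0]
        means = []
        rng = np.random.default_rng(11)
        for d in deltas:
            vals = [
                rw_uniqueness(rng.normal(0, 1, 60), rng.normal(d, 1, 60))
                for _ in range(60)
            ]
            means.append(np.mean(vals))
        assert all(b >= a - 0.02 for a, b in zip(means, means[1:]))


def _rw_from(scores, rng=None):
    return relative_warps(np.asarray(scores))


class TestOverallMU:
    def test_weights_sum_to_one_and_bounds(self, rng):
        x = rng.normal(size=(60, 5))
        rw = _rw_from(x)
        labels = np.array(["A"] * 30 + ["B"] * 30)
        res = overall_mu(rw, labels)
        assert res.weights.sum() == pytest.approx(1.0)
        assert 0.0 <= res.overall_mu <= 1.0

    def test_homogeneous_split_gives_small_mu(self):
        vals = []
        for seed in range(10):
            x = np.random.default_rng(seed).normal(size=(100, 4))
            rw = _rw_from(x)
            labels = np.array(["A"] * 50 + ["B"] * 50)
            vals.append(overall_mu(rw, labels).overall_mu)
        assert np.mean(vals) < 0.15

    def test_separation_on_rw1_gives_weight1(self, rng):
        """Shifting group B 10 SD along the leading axis makes MU ≈ w₁."""
        x = rng.normal(size=(120, 4)) * np.array([3.0, 1.0, 0.5, 0.25])
        x[60:, 0] += 30.0
        rw = _rw_from(x)
        labels = np.array(["A"] * 60 + ["B"] * 60)
        res = overall_mu(rw, labels)
        w1 = res.weights[0]
        assert res.overall_mu == pytest.approx(w1, abs=0.05)


class TestSignificance:
    def test_strong_separation_attains_minimum_p(self, rng):
        x = rng.normal(size=(40, 3))
        x[:20, 0] += 10
        rw = _rw_from(x)
        labels = np.array(["A"] * 20 + ["B"] * 20)
        res = mu_significance(rw, labels, n_resamples=1000, seed=5)
        assert res.p_value == pytest.approx(1 / 1001, abs=1e-12)

    def test_seed_reproducibility(self, rng):
        x = rng.normal(size=(40, 3))
        rw = _rw_from(x)
        labels = np.array(["A"] * 20 + ["B"] * 20)
        r1 = mu_significance(rw, labels, n_resamples=200, seed=9)
        r2 = mu_significance(rw, labels, n_resamples=200, seed=9)
        assert r1.p_value == r2.p_value
        assert r1.null_mean == r2.null_mean

    @pytest.mark.parametrize("mode", ["bootstrap_labels", "permute_labels"])
    def test_null_rejection_rate_close_to_alpha(self, mode):
        """Coarse calibration check (50 replicates); the full 500-replicate
        version backs the acceptance suite."""
        rng = np.random.default_rng(99)
        rej = 0
        n_rep = 50
        for _ in range(n_rep):
            x = rng.normal(size=(60, 2))
            rw = _rw_from(x)
            labels = np.array(["A"] * 30 + ["B"] * 30)
            res = mu_significance(rw, labels, n_resamples=199, seed=rng, mode=mode)
            rej += res.p_value <= 0.05
        assert rej / n_rep <= 0.14  # generous 3-sigma band around 0.05


class TestPairwise:
    def test_two_levels_mean_equals_single_mu(self, rng):
        x = rng.normal(size=(60, 3))
        rw = _rw_from(x)
        labels = np.array(["A"] * 30 + ["B"] * 30)
        mat, mean = pairwise_mu(rw, labels)
        assert mean == pytest.approx(mat.loc["A", "B"])
        assert mat.loc["A", "A"] == 0.0

    def test_matrix_symmetric(self, rng):
        x = rng.normal(size=(90, 3))
        rw = _rw_from(x)
        labels = np.array(["A"] * 30 + ["B"] * 30 + ["C"] * 30)
        mat, _ = pairwise_mu(rw, labels)
        np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T, atol=1e-12)

    def test_small_level_dropped(self, rng):
        x = rng.normal(size=(63, 3))
        rw = _rw_from(x)
        labels = np.array(["A"] * 30 + ["B"] * 31 + ["C"] * 2)
        mat, _ = pairwise_mu(rw, labels)
        assert list(mat.index) == ["A", "B"]


class TestDominance:
    def test_counts_sum_to_number_of_rws(self, rng):
        x = rng.normal(size=(80, 4))
        rw = _rw_from(x)
        factors = {
            "sex": np.array(["M", "F"] * 40),
            "host": np.array(["A"] * 40 + ["C"] * 40),
        }
        dom = dominance_table(rw, factors)
        assert dom.rw_dom.sum() == 4
        assert (dom.table["dominant"] == dom.table[["sex", "host"]].idxmax(axis=1)).all()

    def test_injected_sex_effect_dominates(self, study_chain):
        """With a dominant injected sex effect, sex tops the overall MU
        ranking computed from the emulated study data."""
        ds, truth, gpa, basis, sv, rw = study_chain
        factors = {
            "sex": ds.factor("sex"),
            "host": ds.factor("host"),
            "population": ds.factor("population"),
            "rearing": ds.factor("rearing"),
        }
        dom = dominance_table(rw, factors)
        assert dom.ranking[0] == "sex"
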