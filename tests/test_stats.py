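"""Population statistics: correlations, permutation tests, REML, DAPC."""

import numpy as np
import pytest

import chromamesh as cm
from chromamesh.errors import ParameterError, StatError, StructuralError
from chromamesh.stats import DAPC


def _pop(X, label="p", year=2016):
    return cm.PopulationSample(label=label, X=np.asarray(X, dtype=float), year=year)


class TestVectorCorrelation:
    def test_self_and_negation(self, rng):
        v = rng.normal(size=50)
        assert cm.vector_correlation(v, v) == pytest.approx(1.0)
        assert cm.vector_correlation(v, -v) == pytest.approx(-1.0)

    def test_location_invariance(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cm.vector_correlation(v, v + 17.3) == pytest.approx(1.0)

    def test_textbook_formula_oracle(self, rng):
        u = rng.normal(size=200)
        v = rng.normal(size=200)
        n = len(u)
        expected = (n * (u * v).sum() - u.sum() * v.sum()) / np.sqrt(
            (n * (u**2).sum() - u.sum() ** 2) * (n * (v**2).sum() - v.sum() ** 2)
        )
        assert cm.vector_correlation(u, v) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_undefined(self):
        with pytest.raises(StatError):
            cm.vector_correlation(np.ones(5), np.arange(5.0))


class TestBootstrapDirections:
    def test_constant_populations_give_zero(self):
        X = np.full((4, 10), 0.3)
        d = cm.bootstrap_directions(_pop(X), _pop(X), B=20, seed=0)
        np.testing.assert_allclose(d, 0.0)

    def test_consistency_with_true_difference(self, rng):
        p = 40
        delta = rng.normal(0, 1, p)
        hp = _pop(rng.normal(0, 1, (60, p)))
        lp = _pop(delta + rng.normal(0, 1, (60, p)))
        d = cm.bootstrap_directions(hp, lp, B=1000, seed=1)
        se = d.std(axis=0)
        observed = lp.X.mean(axis=0) - hp.X.mean(axis=0)
        assert np.all(np.abs(d.mean(axis=0) - observed) < 3 * se / np.sqrt(1000) * 30)
        # bootstrap mean direction within 3 SE of the true difference
        assert np.all(np.abs(d.mean(axis=0) - delta) < 3 * np.maximum(se, 1e-3))

    def test_seed_determinism(self, rng):
        hp = _pop(rng.normal(size=(10, 5)))
        lp = _pop(rng.normal(size=(12, 5)))
        d1 = cm.bootstrap_directions(hp, lp, B=50, seed=42)
        d2 = cm.bootstrap_directions(hp, lp, B=50, seed=42)
        np.testing.assert_array_equal(d1, d2)

    def test_whole_rows_resampled(self):
        # rows are constant vectors; any whole-row mean keeps each replicate
        # direction constant across variables, so within-fish structure is
        # preserved by construction
        vals = np.arange(6.0)
        X = np.tile(vals[:, None], (1, 30))
        d = cm.bootstrap_directions(_pop(X), _pop(X + 1.0), B=100, seed=3)
        assert np.allclose(d.std(axis=1), 0.0)

    def test_empty_population_raises(self):
        with pytest.raises(StructuralError):
            cm.bootstrap_directions(_pop(np.empty((0, 3))), _pop(np.ones((2, 3))), B=5)


class TestPairwiseDirectionCorrelation:
    def _river(self, rng, delta, n=40, noise=1.0):
        p = len(delta)
        hp = _pop(rng.normal(0, noise, (n, p)))
        lp = _pop(delta + rng.normal(0, noise, (n, p)))
        return hp, lp

    def test_duplicate_river_gives_r_one(self, rng):
        river = self._river(rng, rng.normal(0, 1, 60))
        dist = cm.pairwise_direction_correlation(river, river, B=100, seed=0)
        assert dist.observed == pytest.approx(1.0)

    def test_orthogonal_directions_ci_straddles_zero(self, rng):
        p = 80
        dA = rng.normal(size=p)
        dA -= dA.mean()
        dB = rng.normal(size=p)
        dB -= dB.mean()
        dB -= (dB @ dA) / (dA @ dA) * dA  # exactly uncorrelated directions
        dA *= 2.0 / dA.std()
        dB *= 2.0 / dB.std()
        riverA = self._river(rng, dA, n=80, noise=0.5)
        riverB = self._river(rng, dB, n=80, noise=0.5)
        dist = cm.pairwise_direction_correlation(riverA, riverB, B=400, seed=1)
        assert dist.ci[0] < 0.0 < dist.ci[1]

    def test_shared_direction_ci_excludes_zero(self, rng):
        delta = rng.normal(0, 1, 60) * 2.0
        riverA = self._river(rng, delta, n=60, noise=0.3)
        riverB = self._river(rng, delta, n=60, noise=0.3)
        dist = cm.pairwise_direction_correlation(riverA, riverB, B=400, seed=2)
        assert dist.ci[0] > 0.5
        assert dist.observed > 0.8

    def test_draws_in_unit_interval(self, rng):
        river = self._river(rng, rng.normal(0, 1, 30), n=10)
        dist = cm.pairwise_direction_correlation(river, river, B=200, seed=3)
        assert np.all(dist.draws >= -1.0) and np.all(dist.draws <= 1.0)


class TestRandomVectorNull:
    def test_mean_and_sd(self):
        mean_r, r = cm.random_vector_null(B=800, p=500, seed=7)
        assert np.all((r >= -1) & (r <= 1))
        assert abs(mean_r) < 0.005
        # asymptotic null SD of Pearson r is 1/sqrt(p-1)
        assert r.std() == pytest.approx(1 / np.sqrt(499), rel=0.10)

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            cm.random_vector_null(B=0, p=10)


class TestTraceOfCovariance:
    def test_identical_rows_zero(self):
        assert cm.trace_of_covariance(_pop(np.tile([1.0, 2.0], (5, 1)))) == 0.0

    def test_hand_computation(self):
        # two specimens, one variable, values {0, 1}: var = 0.5 with n-1
        assert cm.trace_of_covariance(_pop([[0.0], [1.0]])) == pytest.approx(0.5)

    def test_full_matrix_oracle(self, rng):
        X = rng.normal(size=(20, 30))
        expected = np.trace(np.cov(X, rowvar=False))
        assert cm.trace_of_covariance(_pop(X)) == pytest.approx(expected, abs=1e-10)

    def test_needs_two_rows(self):
        with pytest.raises(StatError):
            cm.trace_of_covariance(_pop(np.ones((1, 3))))


class TestPermutationVarianceTest:
    def test_identical_groups(self, rng):
        X = rng.normal(size=(15, 20))
        obs, null, p = cm.permutation_variance_test(_pop(X), _pop(X.copy()), n_perm=199, seed=0)
        assert obs == pytest.approx(0.0)
        assert p > 0.9

    def test_power_against_4x_variance(self, rng):
        # lp variance 4x hp: detected at alpha = 0.05 in nearly all repeats
        hits = 0
        reps = 40
        for rep in range(reps):
            hp = _pop(rng.normal(0, 1, (30, 300)))
            lp = _pop(rng.normal(0, 2, (30, 300)))
            _, _, p = cm.permutation_variance_test(hp, lp, n_perm=199, seed=rep)
            hits += p < 0.05
        assert hits >= int(0.95 * reps)

    def test_rows_never_altered(self, rng):
        hp_X = rng.normal(size=(8, 12))
        lp_X = rng.normal(size=(9, 12))
        hp, lp = _pop(hp_X.copy()), _pop(lp_X.copy())
        cm.permutation_variance_test(hp, lp, n_perm=50, seed=1)
        np.testing.assert_array_equal(hp.X, hp_X)
        np.testing.assert_array_equal(lp.X, lp_X)

    def test_sign_convention(self, rng):
        hp = _pop(rng.normal(0, 1, (20, 10)))
        lp = _pop(rng.normal(0, 3, (20, 10)))
        obs_lp_hp, _, _ = cm.permutation_variance_test(hp, lp, n_perm=19, seed=0)
        obs_hp_lp, _, _ = cm.permutation_variance_test(
            hp, lp, n_perm=19, seed=0, sign="hp_minus_lp"
        )
        assert obs_lp_hp == pytest.approx(-obs_hp_lp)
        assert obs_lp_hp > 0  # lp is the more variable group


class TestVarianceComponents:
    def test_no_population_effect(self, rng):
        # all populations share one mean: nearly all variance is within
        labels = np.repeat(np.arange(11), 50)
        props = []
        for _ in range(20):
            y = rng.normal(0, 1, 11 * 50)
            props.append(cm.variance_components(y, labels).prop_within)
        assert np.mean(props) == pytest.approx(1.0, abs=0.05)

    def test_equal_components_recovered(self, rng):
        # sigma2_pop = sigma2_resid = 1: prop_within ~ 0.5 averaged over points
        k, m = 11, 20
        labels = np.repeat(np.arange(k), m)
        props = []
        for _ in range(200):
            effects = rng.normal(0, 1, k)
            y = effects[labels] + rng.normal(0, 1, k * m)
            props.append(cm.variance_components(y, labels).prop_within)
        assert np.mean(props) == pytest.approx(0.5, abs=0.05)

    def test_balanced_matches_anova_closed_form(self, rng):
        k, m = 6, 8
        labels = np.repeat(np.arange(k), m)
        effects = rng.normal(0, 0.8, k)
        y = effects[labels] + rng.normal(0, 1, k * m)
        vc = cm.variance_components(y, labels)
        gm = y.reshape(k, m).mean(axis=1)
        msb = m * ((gm - gm.mean()) ** 2).sum() / (k - 1)
        msw = ((y.reshape(k, m) - gm[:, None]) ** 2).sum() / (k * (m - 1))
        sigma2_pop_anova = max((msb - msw) / m, 0.0)
        assert vc.sigma2_resid == pytest.approx(msw, abs=1e-6)
        assert vc.sigma2_pop == pytest.approx(sigma2_pop_anova, abs=1e-6)

    def test_matches_statsmodels_mixedlm(self, rng):
        # independent oracle: REML fit of the same random-intercept model
        import statsmodels.formula.api as smf
        import pandas as pd

        k, m = 5, 12
        labels = np.repeat(np.arange(k), m)
        years = np.tile([2016, 2017], k * m // 2)
        effects = rng.normal(0, 1.0, k)
        y = 0.3 * (years == 2017) + effects[labels] + rng.normal(0, 0.7, k * m)
        vc = cm.variance_components(y, labels, years)
        df = pd.DataFrame({"y": y, "pop": labels, "year": years.astype(str)})
        fit = smf.mixedlm("y ~ year", df, groups="pop").fit(reml=True)
        assert vc.sigma2_resid == pytest.approx(fit.scale, rel=1e-3)
        assert vc.sigma2_pop == pytest.approx(float(fit.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-4)

    def test_year_confounded_with_population(self, rng):
        # year constant within population still yields a valid decomposition
        labels = np.repeat(np.arange(4), 20)
        years = np.repeat([2016, 2016, 2017, 2017], 20)
        effects = np.array([0.0, 1.0, 0.0, 1.0])
        y = effects[labels] + rng.normal(0, 0.5, 80)
        vc = cm.variance_components(y, labels, years)
        assert 0.0 <= vc.prop_within <= 1.0

    def test_requires_two_groups(self):
        with pytest.raises(StructuralError):
            cm.variance_components(np.ones(10), np.zeros(10))


class TestDAPC:
    def test_point_mass_groups(self):
        X = np.vstack([np.tile([0.0, 0.0, 0.0], (5, 1)), np.tile([1.0, 1.0, 1.0], (5, 1))])
        y = np.repeat(["a", "b"], 5)
        model = DAPC(n_pcs=1).fit(X, y)
        assert model.n_axes_ == 1
        np.testing.assert_allclose(model.explained_variance_ratio_, [1.0])
        assert (model.predict(X) == y).all()

    def test_separable_gaussians_perfect_assignment(self, rng):
        centers = rng.normal(0, 30, (3, 20))
        X = np.vstack([c + rng.normal(0, 1, (15, 20)) for c in centers])
        y = np.repeat(list("abc"), 15)
        model = DAPC(n_pcs=5).fit(X, y)
        assert (model.predict(X) == y).all()
        assert model.n_axes_ == 2  # groups - 1

    def test_axis_count_rank_constraint(self, rng):
        X = rng.normal(size=(40, 25))
        y = np.repeat(list("abcd"), 10)
        model = DAPC(n_pcs=8).fit(X, y)
        assert model.n_axes_ == 3

    def test_too_many_pcs_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        y = np.repeat(["a", "b"], 5)
        with pytest.raises(ParameterError, match="fewer"):
            DAPC(n_pcs=12).fit(X, y)

    def test_variance_ratios_sum_to_one(self, rng):
        centers = rng.normal(0, 10, (4, 30))
        X = np.vstack([c + rng.normal(0, 1, (12, 30)) for c in centers])
        y = np.repeat(list("abcd"), 12)
        model = DAPC(n_pcs=10).fit(X, y)
        assert model.explained_variance_ratio_.sum() == pytest.approx(1.0)
        assert np.all(np.diff(model.explained_variance_ratio_) <= 1e-12)


class TestDapcXval:
    def test_separable_groups_perfect(self, rng):
        centers = rng.normal(0, 30, (3, 15))
        X = np.vstack([c + rng.normal(0, 0.5, (20, 15)) for c in centers])
        y = np.repeat(list("abc"), 20)
        table = cm.dapc_xval(X, y, pc_grid=[2, 5], n_rep=20, seed=0)
        assert (table["mean_success"] == 1.0).all()
        assert (table["rmse"] == 0.0).all()

    def test_chance_level_on_permuted_labels(self, rng):
        # validation success on label-permuted data sits at 1/k; single
        # datasets swing by ~0.05, so pool several independent datasets
        k = 4
        vals = []
        for s in range(6):
            X = rng.normal(size=(120, 30))
            y = rng.permutation(np.repeat(list("abcd"), 30))
            table = cm.dapc_xval(X, y, pc_grid=[10], n_rep=25, seed=s)
            vals.append(table["mean_success"].iloc[0])
        assert abs(np.mean(vals) - 1.0 / k) < 0.05

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(40, 12))
        y = np.repeat(["a", "b"], 20)
        t1 = cm.dapc_xval(X, y, pc_grid=[3, 6], n_rep=10, seed=9)
        t2 = cm.dapc_xval(X, y, pc_grid=[3, 6], n_rep=10, seed=9)
        assert t1.equals(t2)

    def test_infeasible_grid_values_skipped(self, rng):
        X = rng.normal(size=(20, 10))
        y = np.repeat(["a", "b"], 10)
        with pytest.warns(UserWarning, match="skipping"):
            table = cm.dapc_xval(X, y, pc_grid=[2, 500], n_rep=5, seed=0)
        assert list(table["n_pc"]) == [2]
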