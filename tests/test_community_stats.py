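import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from nbssbench import community_stats as cs


def make_matrix(x: np.ndarray, labels=None, kind="euclidean_distance"):
    d = squareform(pdist(np.atleast_2d(x.T).T if x.ndim == 1 else x))
    labels = labels or [f"s{i}" for i in range(d.shape[0])]
    return cs.ResemblanceMatrix(list(labels), d, kind)


class TestBrayCurtis:
    def test_identical_rows_fully_similar(self):
        t = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        m = cs.bray_curtis(t)
        assert m.similarity_percent()[0, 1] == pytest.approx(100.0)

    def test_disjoint_supports_zero_similarity(self):
        t = pd.DataFrame([[1, 2, 0, 0], [0, 0, 3, 4]], index=["a", "b"])
        m = cs.bray_curtis(t)
        assert m.similarity_percent()[0, 1] == pytest.approx(0.0)

    def test_integer_fixture_matches_direct_formula(self):
        t = pd.DataFrame(
            [[4, 0, 1, 9], [1, 1, 0, 4], [0, 16, 4, 0]], index=["a", "b", "c"]
        )
        m = cs.bray_curtis(t, transform="sqrt")
        x = np.sqrt(t.to_numpy(float))
        for i, j in itertools.combinations(range(3), 2):
            expect = np.abs(x[i] - x[j]).sum() / (x[i] + x[j]).sum()
            assert m.values[i, j] == pytest.approx(expect, rel=1e-12)

    def test_zero_taxon_column_is_ignored(self, rng):
        t = pd.DataFrame(rng.integers(0, 20, (5, 6)).astype(float))
        t2 = t.copy()
        t2["ghost"] = 0.0
        assert np.allclose(cs.bray_curtis(t).values, cs.bray_curtis(t2).values)

    def test_all_zero_row_rejected(self):
        t = pd.DataFrame([[1, 2], [0, 0]], index=["a", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            cs.bray_curtis(t)


def oracle_permanova_f(d: np.ndarray, groups: list) -> float:
    """Independent pseudo-F: explicit among/within partition of d^2."""
    n = d.shape[0]
    names = sorted(set(groups))
    ss_t = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in names:
        idx = [i for i, gi in enumerate(groups) if gi == g]
        ss_w += sum(
            d[i, j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    ss_a = ss_t - ss_w
    k = len(names)
    return (ss_a / (k - 1)) / (ss_w / (n - k))


class TestPermanova:
    def test_statistic_matches_oracle(self, rng):
        x = rng.normal(size=(9, 3))
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        m = make_matrix(x)
        res = cs.permanova_oneway(m, groups, n_perm=99, seed=1)
        assert res.statistic == pytest.approx(oracle_permanova_f(m.values, groups), rel=1e-12)

    def test_statistic_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        x = rng.normal(size=(10, 4))
        groups = ["a"] * 5 + ["b"] * 5
        m = make_matrix(x)
        res = cs.permanova_oneway(m, groups, n_perm=99, seed=1)
        dm = skbio.DistanceMatrix(m.values, ids=m.labels)
        sk = sk_permanova(dm, grouping=groups, permutations=9)
        assert res.statistic == pytest.approx(float(sk["test statistic"]), rel=1e-9)

    def test_exhaustive_enumeration_on_six_samples(self, rng):
        """n=6, two groups of 3: p must equal the full 20-arrangement scan."""
        x = rng.normal(size=6) + np.array([0, 0, 0, 2, 2, 2.0])
        groups = ["a", "a", "a", "b", "b", "b"]
        m = make_matrix(x[:, None])
        res = cs.permanova_oneway(m, groups, n_perm=9999, seed=7)
        assert res.exhaustive
        f_obs = oracle_permanova_f(m.values, groups)
        f_all = [
            oracle_permanova_f(m.values, list(p))
            for p in set(itertools.permutations(groups))
        ]
        # distinct label arrangements: C(6,3) = 20
        assert len(f_all) == 20
        p_oracle = np.mean([f >= f_obs - 1e-12 for f in f_all])
        assert res.p_perm == pytest.approx(p_oracle)

    def test_separated_clusters_hit_permutation_floor(self):
        x = np.array([0.0, 0.1, 0.2, 10.0, 10.1, 10.2])[:, None]
        res = cs.permanova_oneway(make_matrix(x), ["a"] * 3 + ["b"] * 3, seed=1)
        # exhaustive p floor: 2/20 (observed split and its mirror)
        assert res.p_perm == pytest.approx(0.1)

    def test_label_order_invariance(self, rng):
        x = rng.normal(size=(8, 2))
        groups = ["a", "b"] * 4
        m = make_matrix(x)
        order = rng.permutation(8)
        m2 = cs.ResemblanceMatrix(
            [m.labels[i] for i in order], m.values[np.ix_(order, order)], m.kind
        )
        r1 = cs.permanova_oneway(m, groups, n_perm=99, seed=3)
        r2 = cs.permanova_oneway(m2, [groups[i] for i in order], n_perm=99, seed=3)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_seed_determinism(self, rng):
        x = rng.normal(size=(12, 3))
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        m = make_matrix(x)
        p1 = cs.permanova_oneway(m, groups, n_perm=499, seed=11).p_perm
        p2 = cs.permanova_oneway(m, groups, n_perm=499, seed=11).p_perm
        assert p1 == p2

    def test_singleton_group_rejected(self, rng):
        m = make_matrix(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match=">= 2"):
            cs.permanova_oneway(m, ["a", "a", "a", "a", "b"], seed=1)


class TestRelate:
    def test_self_correlation_is_one(self, rng):
        m = make_matrix(rng.normal(size=(7, 3)))
        res = cs.relate_mantel(m, m, n_perm=99, seed=1)
        assert res.statistic == pytest.approx(1.0)

    def test_rank_reversed_copy_is_minus_one(self, rng):
        m = make_matrix(rng.normal(size=(6, 3)))
        flipped = m.values.max() + m.values.min() - m.values
        np.fill_diagonal(flipped, 0.0)
        m2 = cs.ResemblanceMatrix(m.labels, flipped, m.kind)
        res = cs.relate_mantel(m, m2, n_perm=99, seed=1)
        assert res.statistic == pytest.approx(-1.0)

    def test_statistic_matches_skbio_mantel(self, rng):
        pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.stats.distance import mantel

        a = make_matrix(rng.normal(size=(8, 3)))
        b = make_matrix(rng.normal(size=(8, 3)) + 0.5 * a.values[:, :3])
        res = cs.relate_mantel(a, b, n_perm=99, seed=1)
        corr = mantel(
            DistanceMatrix(a.values, ids=a.labels),
            DistanceMatrix(b.values, ids=b.labels),
            method="spearman",
            permutations=0,
        )
        sk_rho = float(corr[0]) if isinstance(corr, tuple) else float(corr.statistic)
        assert res.statistic == pytest.approx(sk_rho, rel=1e-9)

    def test_label_mismatch_rejected(self, rng):
        a = make_matrix(rng.normal(size=(5, 2)))
        b = make_matrix(rng.normal(size=(5, 2)), labels=list("vwxyz"))
        with pytest.raises(ValueError, match="labels"):
            cs.relate_mantel(a, b)

    def test_shared_gradient_strength_separates_regimes(self, rng):
        """Matrices sharing a strong latent gradient give higher rho than
        matrices sharing a weak one (the moderate-vs-poor matching regimes)."""
        def rho_for(mix: float) -> float:
            g = rng.normal(size=12)
            a = make_matrix((g + rng.normal(0, 0.3, 12))[:, None])
            b = make_matrix((mix * g + rng.normal(0, 1.0, 12))[:, None])
            return cs.relate_mantel(a, b, n_perm=49, seed=5).statistic

        strong = np.mean([rho_for(2.0) for _ in range(40)])
        weak = np.mean([rho_for(0.3) for _ in range(40)])
        assert strong > 0.45
        assert weak < strong - 0.2


class TestDistLM:
    def _env(self, rng, n=18, p=4):
        return pd.DataFrame(
            rng.normal(size=(n, p)), columns=[f"v{i}" for i in range(p)],
            index=[f"s{i}" for i in range(n)],
        )

    def test_single_generating_predictor_explains_everything(self, rng):
        env = self._env(rng)
        dist = make_matrix(env[["v0"]].to_numpy())
        res = cs.distlm(dist, env, n_perm=99, seed=2)
        marg = res.marginal.set_index("predictor")
        assert marg.loc["v0", "pct_var"] > 99.9
        assert res.selected[0] == "v0"
        assert marg.loc["v0", "p"] <= 0.01

    def test_single_predictor_mode_reproduces_marginal(self, rng):
        env = self._env(rng, p=1)
        dist = make_matrix(rng.normal(size=(18, 3)))
        res = cs.distlm(dist, env, n_perm=199, seed=3)
        forward = cs.distlm(dist, env, mode="marginal", n_perm=199, seed=3)
        assert res.marginal.loc[0, "pseudo_F"] == pytest.approx(
            forward.marginal.loc[0, "pseudo_F"], rel=1e-12
        )

    def test_pseudo_f_equals_anova_f_for_euclidean_univariate(self, rng):
        """On 1-D Euclidean distances the pseudo-F equals the classical
        regression F statistic."""
        y = rng.normal(size=15)
        env = self._env(rng, n=15, p=1)
        dist = make_matrix(y[:, None])
        res = cs.distlm(dist, env, n_perm=49, seed=1)
        x = (env["v0"] - env["v0"].mean()) / env["v0"].std(ddof=1)
        ols = stats.linregress(x, y)
        f_classic = ols.rvalue**2 / (1 - ols.rvalue**2) * (15 - 2)
        assert res.marginal.loc[0, "pseudo_F"] == pytest.approx(f_classic, rel=1e-9)

    def test_collinear_predictor_dropped_with_warning(self, rng):
        env = self._env(rng, p=2)
        env["v2"] = 2.0 * env["v0"] + 1.0
        dist = make_matrix(rng.normal(size=(18, 2)))
        with pytest.warns(UserWarning, match="collinear"):
            res = cs.distlm(dist, env, n_perm=49, seed=4)
        assert "v2" not in res.marginal["predictor"].tolist()

    def test_forward_selection_recovers_two_generating_predictors(self, rng):
        env = self._env(rng, n=24)
        signal = env["v0"].to_numpy() + env["v1"].to_numpy()
        dist = make_matrix((signal + rng.normal(0, 0.4, 24))[:, None])
        res = cs.distlm(dist, env, n_perm=99, seed=5)
        assert set(res.selected[:2]) == {"v0", "v1"}
        assert res.r2_selected > 0.7

    def test_seed_determinism(self, rng):
        env = self._env(rng)
        dist = make_matrix(rng.normal(size=(18, 2)))
        p1 = cs.distlm(dist, env, n_perm=199, seed=9).marginal["p"].tolist()
        p2 = cs.distlm(dist, env, n_perm=199, seed=9).marginal["p"].tolist()
        assert p1 == p2


class TestGammaGLM:
    def test_constant_mass_has_no_direction(self, rng):
        temp = np.repeat([0.0, 4.0, 8.0], 20)
        dm = np.full(60, 5.0) * rng.uniform(0.999, 1.001, 60)
        res = cs.taxon_temp_glm(dm, temp)
        assert res.direction == "none"
        assert abs(res.coefficient) < 0.01

    def test_recovers_negative_temperature_coefficient(self, rng):
        temp = rng.uniform(-2.0, 8.0, 500)
        dm = np.exp(3.0 - 0.1 * temp) * rng.gamma(shape=5.0, scale=0.2, size=500)
        res = cs.taxon_temp_glm(dm, temp)
        assert res.direction == "negative"
        assert abs(res.coefficient - (-0.1)) < 2 * res.se

    def test_two_level_design_matches_log_mean_ratio(self, rng):
        t0, t1 = 0.0, 5.0
        dm0 = rng.gamma(4.0, 2.0, 200)
        dm1 = rng.gamma(4.0, 1.0, 200)
        res = cs.taxon_temp_glm(
            np.concatenate([dm0, dm1]), np.concatenate([np.full(200, t0), np.full(200, t1)])
        )
        expect = (np.log(dm1.mean()) - np.log(dm0.mean())) / (t1 - t0)
        assert res.coefficient == pytest.approx(expect, rel=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="positive"):
            cs.taxon_temp_glm([1.0, -1.0] + [1.0] * 10, [0.0, 1.0] * 6)
        with pytest.raises(ValueError, match="10"):
            cs.taxon_temp_glm([1.0] * 5, [0.0, 1.0, 0.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="temperature"):
            cs.taxon_temp_glm([1.0] * 12, [3.0] * 12)
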