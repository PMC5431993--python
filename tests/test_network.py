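"""Coexpression network: adjacency, scale-free fit, TOM, modules,
eigengenes, GS/kME, hubs, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sysgen.network import (
    CoexpressionNetwork,
    adjacency,
    cluster_modules,
    enrichment_test,
    gene_significance,
    identify_hub_genes,
    module_eigengenes,
    module_membership,
    module_trait_association,
    pick_soft_threshold,
    scale_free_fit_index,
    tom,
)


def _frame(mat, prefix="g"):
    mat = np.asarray(mat, dtype=float)
    return pd.DataFrame(
        mat,
        index=[f"{prefix}{i}" for i in range(mat.shape[0])],
        columns=[f"s{j}" for j in range(mat.shape[1])],
    )


def _cor_oracle(x):
    """Two-pass Pearson correlation, elementwise."""
    n_genes = x.shape[0]
    out = np.empty((n_genes, n_genes))
    for i in range(n_genes):
        for j in range(n_genes):
            a, b = x[i] - x[i].mean(), x[j] - x[j].mean()
            out[i, j] = (a * b).sum() / np.sqrt((a**2).sum() * (b**2).sum())
    return out


class TestAdjacency:
    def test_negative_half_correlation_sixth_power(self):
        t = np.linspace(0, 1, 50)
        # construct two genes with cor exactly -0.5
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        e = rng.standard_normal(200)
        e -= np.polyval(np.polyfit(x, e, 1), x)  # orthogonalize
        y = -0.5 * (x - x.mean()) / x.std() + np.sqrt(0.75) * (
            e / e.std()
        )
        expr = _frame(np.vstack([x, y]))
        a = adjacency(expr, beta=6)
        assert a.iloc[0, 1] == pytest.approx(0.5**6, rel=1e-9)

    def test_perfect_correlation_is_one_for_any_power(self):
        x = np.random.default_rng(1).standard_normal(30)
        expr = _frame(np.vstack([x, 2 * x + 1]))
        for beta in (1, 6, 12):
            assert adjacency(expr, beta).iloc[0, 1] == pytest.approx(1.0)

    def test_matches_two_pass_oracle(self, rng):
        x = rng.standard_normal((5, 20))
        a = adjacency(_frame(x), beta=6).to_numpy()
        expected = np.abs(_cor_oracle(x)) ** 6
        np.fill_diagonal(expected, 1.0)
        assert np.max(np.abs(a - expected)) < 1e-12

    def test_constant_gene_named_in_error(self):
        mat = np.ones((2, 10))
        mat[1] = np.random.default_rng(2).normal(size=10)
        with pytest.raises(ValueError, match="g0"):
            adjacency(_frame(mat), 6)


class TestScaleFreeFit:
    def test_power_law_scores_high(self, rng):
        # p(k) ~ k^-1.5 via inverse-CDF sampling
        u = rng.uniform(size=10_000)
        k = (1 - u) ** (-1 / 0.5)  # Pareto alpha=0.5 => density ~ k^-1.5
        assert scale_free_fit_index(k) >= 0.8

    def test_gaussian_connectivities_score_low(self, rng):
        k = rng.normal(50, 1, size=10_000)
        assert scale_free_fit_index(k) < 0.5

    def test_exact_loglog_line_scores_one(self):
        # frequencies engineered so every bin lies on a log-log line
        k = np.concatenate([
            np.full(1000 // (i + 1), 10.0 * (i + 1)) for i in range(10)
        ])
        r2 = scale_free_fit_index(k + np.random.default_rng(3).uniform(
            0, 1e-6, size=k.size
        ))
        assert r2 > 0.99

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            scale_free_fit_index(np.ones(100))


class TestPickSoftThreshold:
    def test_zero_target_returns_smallest_beta(self, default_bundle):
        beta, _ = pick_soft_threshold(
            default_bundle.expression, betas=(2, 4, 6), r2_target=0.0
        )
        assert beta == 2

    def test_unreachable_target_warns_and_returns_best(self, rng):
        expr = _frame(rng.standard_normal((30, 50)))
        with pytest.warns(UserWarning, match="no candidate power"):
            beta, profile = pick_soft_threshold(
                expr, betas=(1, 2), r2_target=0.999
            )
        best = profile.loc[profile["signed_r2"].idxmax(), "beta"]
        assert beta == best

    def test_selected_beta_crosses_target(self, default_bundle):
        beta, profile = pick_soft_threshold(default_bundle.expression)
        row = profile[profile["beta"] == beta]
        assert row["signed_r2"].iloc[0] >= 0.8
        below = profile[profile["beta"] < beta]
        assert (below["signed_r2"] < 0.8).all()


def _tom_oracle(a):
    """Triple-loop evaluation of the topological overlap formula."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=0)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = sum(a[i, u] * a[u, j] for u in range(n) if u != i)
            out[i, j] = num_plus = (num + a[i, j]) / (
                min(k[i], k[j]) + 1 - a[i, j]
            )
    return out


class TestTom:
    def test_perfect_triangle(self):
        a = pd.DataFrame(np.ones((3, 3)))
        t = tom(a)
        assert np.allclose(t.to_numpy(), 1.0)

    def test_path_graph_hand_value(self):
        a = pd.DataFrame(
            [[1, 1, 0], [1, 1, 1], [0, 1, 1]], dtype=float
        )
        t = tom(a)
        assert t.iloc[0, 2] == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            c = rng.uniform(0, 1, size=(6, 6))
            a = (c + c.T) / 2
            np.fill_diagonal(a, 1.0)
            t = tom(pd.DataFrame(a)).to_numpy()
            assert np.max(np.abs(t - _tom_oracle(a))) < 1e-12

    def test_bounded_in_unit_interval(self, rng):
        c = rng.uniform(0, 1, size=(15, 15))
        a = (c + c.T) / 2
        np.fill_diagonal(a, 1.0)
        t = tom(pd.DataFrame(a)).to_numpy()
        assert t.min() >= 0.0 and t.max() <= 1.0 + 1e-12


class TestClusterModules:
    def test_two_separable_blocks_recovered_exactly(self, rng):
        v1, v2 = rng.standard_normal(60), rng.standard_normal(60)
        rows = [v1 + 0.01 * rng.standard_normal(60) for _ in range(40)]
        rows += [v2 + 0.01 * rng.standard_normal(60) for _ in range(40)]
        expr = _frame(np.vstack(rows))
        labels = cluster_modules(1 - tom(adjacency(expr, 6)), expr=expr)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score([0] * 40 + [1] * 40, labels) == 1.0
        assert len(set(labels) - {"grey"}) == 2

    def test_pure_noise_stays_grey(self, rng):
        expr = _frame(rng.standard_normal((100, 200)))
        labels = cluster_modules(1 - tom(adjacency(expr, 6)), expr=expr)
        assert (labels == "grey").all()

    def test_min_module_size_validated(self, rng):
        expr = _frame(rng.standard_normal((10, 30)))
        with pytest.raises(ValueError, match="min_module_size"):
            cluster_modules(1 - tom(adjacency(expr, 6)), min_module_size=2)


class TestEigengenes:
    def test_identical_genes_reproduce_profile(self, rng):
        v = rng.standard_normal(40)
        expr = _frame(np.vstack([v, v, v]))
        labels = pd.Series(["m", "m", "m"], index=expr.index)
        me = module_eigengenes(expr, labels)["MEm"]
        vz = (v - v.mean()) / v.std(ddof=1)
        assert np.allclose(me, vz, atol=1e-9)
        kme, _ = module_membership(expr, me.to_frame("MEm"))
        assert np.allclose(kme["m"], 1.0)

    def test_sign_convention_realigns_negated_module(self, rng):
        mat = rng.standard_normal((5, 40)) + rng.standard_normal(40)
        expr = _frame(mat)
        labels = pd.Series("m", index=expr.index)
        me_pos = module_eigengenes(expr, labels)["MEm"]
        me_neg = module_eigengenes(-expr, labels)["MEm"]
        # correlation structure invariant: both align positively with
        # their members
        assert np.corrcoef(me_pos, -me_neg)[0, 1] == pytest.approx(1.0)

    def test_eigengene_tracks_planted_factor(self, default_bundle):
        b = default_bundle
        labels = b.truth["labels"].map(
            lambda v: f"m{v}" if v > 0 else "grey"
        )
        mes = module_eigengenes(b.expression, labels)
        for m in range(1, 6):
            r = np.corrcoef(
                mes[f"MEm{m}"], b.truth["factors"].iloc[m - 1]
            )[0, 1]
            assert abs(r) >= 0.9

    def test_first_pc_explains_most_module_variance(self, default_bundle):
        b = default_bundle
        genes = b.truth["labels"].index[b.truth["labels"] == 1]
        sub = b.expression.loc[genes].to_numpy()
        z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, keepdims=True)
        svals = np.linalg.svd(z, compute_uv=False)
        share = svals[0] ** 2 / (svals**2).sum()
        assert share > 1 / len(genes) * 5  # far above the flat spectrum


class TestModuleTrait:
    def test_trait_equal_to_me_gives_unit_correlation(self, rng):
        me = rng.standard_normal(100)
        age = rng.uniform(30, 70, 100)
        res = module_trait_association(me, me, age)
        assert res["r"] == pytest.approx(1.0)
        assert res["r2"] == pytest.approx(1.0)

    def test_trait_equal_to_age_partials_out(self, rng):
        # trait carried entirely by the covariate: only residual noise
        # remains after adjustment, so the partial r sits at null level
        me = rng.standard_normal(200)
        age = rng.uniform(30, 70, 200)
        trait = age + 1e-6 * rng.standard_normal(200)
        res = module_trait_association(me, trait, age)
        assert abs(res["r"]) < 0.2

    def test_known_partial_correlation_recovered(self, rng):
        # construct trait with partial correlation 0.5 given age
        n = 200
        me = rng.standard_normal(n)
        age = rng.standard_normal(n)
        eps = rng.standard_normal(n)
        trait = 0.5 * me + np.sqrt(0.75) * eps + 0.8 * age
        rs = []
        for _ in range(10):
            me = rng.standard_normal(n)
            eps = rng.standard_normal(n)
            age = rng.standard_normal(n)
            trait = 0.5 * me + np.sqrt(0.75) * eps + 0.8 * age
            rs.append(module_trait_association(me, trait, age)["r"])
        assert abs(np.mean(rs) - 0.5) < 0.12

    def test_constant_trait_rejected(self, rng):
        with pytest.raises(ValueError, match="zero variance"):
            module_trait_association(
                rng.standard_normal(50), np.ones(50), rng.uniform(size=50)
            )


class TestGeneSignificance:
    def test_t_transform_small_sample(self, rng):
        # r = 0.5, n = 10 -> t = 1.633, p ~ 0.141 (df = 8)
        x = rng.standard_normal(10)
        e = rng.standard_normal(10)
        e -= np.polyval(np.polyfit(x, e, 1), x)
        y = 0.5 * (x - x.mean()) / x.std() + np.sqrt(0.75) * e / e.std()
        gs, p = gene_significance(x, y)
        assert gs == pytest.approx(0.5, abs=1e-9)
        t = 0.5 * np.sqrt(8 / 0.75)
        assert t == pytest.approx(1.633, abs=1e-3)
        assert p == pytest.approx(2 * stats.t.sf(t, 8), rel=1e-9)
        assert p == pytest.approx(0.141, abs=2e-3)

    def test_zero_correlation_unit_p(self, rng):
        x = rng.standard_normal(50)
        e = rng.standard_normal(50)
        e -= np.polyval(np.polyfit(x, e, 1), x)
        gs, p = gene_significance(x, e)
        assert gs < 1e-12 and p == pytest.approx(1.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gene_significance(np.ones(20), np.arange(20.0))


class TestModuleMembership:
    def test_null_kme_small(self, rng):
        expr = _frame(rng.standard_normal((200, 200)))
        me = pd.DataFrame(
            {"MEx": rng.standard_normal(200)}, index=expr.columns
        )
        kme, p = module_membership(expr, me)
        assert np.quantile(kme["x"], 0.95) < 0.15

    def test_non_member_gene_reported(self, rng):
        v = rng.standard_normal(50)
        expr = _frame(np.vstack([v, v, rng.standard_normal(50)]))
        labels = pd.Series(["m", "m", "grey"], index=expr.index)
        mes = module_eigengenes(expr, labels)
        kme, _ = module_membership(expr, mes)
        # the grey gene gets a kME to module m even though not a member
        assert "g2" in kme.index and not np.isnan(kme.loc["g2", "m"])


class TestHubs:
    def _setup(self):
        gs = pd.Series({"a": 0.23, "b": 0.5, "c": 0.05})
        kme = pd.DataFrame(
            {"m": [0.90, 0.80, 0.95]}, index=["a", "b", "c"]
        )
        labels = pd.Series({"a": "m", "b": "m", "c": "m"})
        return gs, kme, labels

    def test_criteria_mode_strict_thresholds(self):
        gs, kme, labels = self._setup()
        hubs = identify_hub_genes(gs, kme, labels)
        # a: kME .90 > .8 and GS .23 > .2 -> hub
        # b: kME exactly .80 -> excluded (strict >)
        # c: GS .05 -> excluded
        assert hubs == {"m": ["a"]}

    def test_degenerate_thresholds_return_all_members(self):
        gs, kme, labels = self._setup()
        hubs = identify_hub_genes(gs, kme, labels, mm_cut=0.0, gs_cut=0.0)
        assert hubs == {"m": ["a", "b", "c"]}

    def test_max_connectivity_mode_hand_example(self):
        gs, kme, labels = self._setup()
        adj = pd.DataFrame(
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.8], [0.1, 0.8, 1.0]],
            index=["a", "b", "c"],
            columns=["a", "b", "c"],
        )
        # intramodular connectivity: a=1.0, b=1.7, c=0.9
        hubs = identify_hub_genes(
            gs, kme, labels, mode="max_connectivity", adj=adj
        )
        assert hubs == {"m": ["b"]}


class TestEnrichment:
    def test_module_equal_to_universe_is_null(self):
        universe = [f"g{i}" for i in range(20)]
        cats = {"c1": universe[:5], "c2": universe[5:]}
        out = enrichment_test(universe, cats, universe)
        assert (out["fold"] == 1.0).all()
        assert np.allclose(out["p"], 1.0)

    def test_hypergeometric_against_enumeration(self):
        universe = [f"g{i}" for i in range(100)]
        cat = universe[:10]
        module = universe[:5] + universe[50:55]
        out = enrichment_test(module, {"c": cat}, universe)
        assert out.loc[0, "fold"] == pytest.approx(5.0)
        # exact upper tail: sum over k=5..10 of hypergeometric masses
        from math import comb

        p_exact = sum(
            comb(10, k) * comb(90, 10 - k) for k in range(5, 11)
        ) / comb(100, 10)
        assert out.loc[0, "p"] == pytest.approx(p_exact, rel=1e-12)

    def test_empty_overlap(self):
        universe = [f"g{i}" for i in range(50)]
        out = enrichment_test(
            universe[:10], {"c": universe[40:]}, universe
        )
        assert out.loc[0, "fold"] == 0.0
        assert out.loc[0, "p"] == 1.0

    def test_unknown_category_skipped_with_warning(self):
        universe = ["a", "b"]
        with pytest.warns(UserWarning, match="skipped"):
            out = enrichment_test(["a"], {"c": ["zz"]}, universe)
        assert out.empty


class TestEstimator:
    def test_fit_exposes_network_attributes(self, default_bundle):
        net = CoexpressionNetwork(beta=6).fit(default_bundle.expression)
        assert net.beta_ == 6
        assert net.tom_.shape == net.adjacency_.shape
        assert set(net.labels_.index) == set(default_bundle.expression.index)
        assert net.eigengenes_.shape[0] == default_bundle.expression.shape[1]

    def test_kme_of_members_exceeds_nonmembers(self, default_bundle):
        net = CoexpressionNetwork(beta=6).fit(default_bundle.expression)
        module = next(m for m in net.kme_.columns)
        members = net.labels_.index[net.labels_ == module]
        others = net.labels_.index[net.labels_ == "grey"]
        assert (
            net.kme_.loc[members, module].mean()
            > net.kme_.loc[others, module].mean() + 0.3
        )

    def test_get_params(self):
        net = CoexpressionNetwork(beta=8, min_module_size=20)
        params = net.get_params()
        assert params["beta"] == 8 and params["min_module_size"] == 20
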