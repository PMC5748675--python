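"""Signed network construction, TOM, modules, eigengenes, traits, ordination."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracles
from triadexpr import coexpnet as cx


def _expr(mat, prefix="s"):
    mat = np.asarray(mat, dtype=float)
    return pd.DataFrame(
        mat,
        index=[f"g{i}" for i in range(mat.shape[0])],
        columns=[f"{prefix}{j}" for j in range(mat.shape[1])],
    )


class TestVst:
    def test_closed_forms_and_monotonicity(self):
        counts = _expr([[0, 7, 14]])
        sf = pd.Series(1.0, index=counts.columns)
        out = cx.vst(counts, sf)
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[0, 1] == pytest.approx(3.0)  # log2(8)
        assert out.iloc[0, 2] > out.iloc[0, 1]

    def test_nonpositive_size_factor_rejected(self):
        counts = _expr([[1, 2]])
        with pytest.raises(ValueError):
            cx.vst(counts, pd.Series([1.0, 0.0], index=counts.columns))


class TestAdjacency:
    def test_correlation_closed_forms(self):
        x = np.arange(5.0)
        expr = _expr([x, x, -x, np.array([1.0, -1, 2, -2, 0.5])])
        a = cx.signed_adjacency(expr, beta=5)
        assert a.iloc[0, 1] == pytest.approx(1.0)       # cor +1
        assert a.iloc[0, 2] == pytest.approx(0.0, abs=1e-12)  # cor -1
        r03 = np.corrcoef(x, expr.iloc[3])[0, 1]
        assert a.iloc[0, 3] == pytest.approx(((1 + r03) / 2) ** 5)

    def test_zero_correlation_closed_form(self):
        expr = _expr([[1.0, -1, 1, -1], [1.0, 1, -1, -1]])
        a = cx.signed_adjacency(expr, beta=5)
        assert a.iloc[0, 1] == pytest.approx(0.5**5)

    def test_raising_beta_shrinks_off_diagonal(self):
        expr, _ = oracles.simulate_block_expression(10, [5, 5], 5, 0.6, 1)
        a2 = cx.signed_adjacency(expr, 2).to_numpy()
        a4 = cx.signed_adjacency(expr, 4).to_numpy()
        off = ~np.eye(len(a2), dtype=bool)
        sub_unity = a2 < 1.0
        assert (a4[off & sub_unity] < a2[off & sub_unity]).all()

    def test_zero_variance_gene_rejected(self):
        expr = _expr([[1.0, 1, 1, 1], [1.0, 2, 3, 4]])
        with pytest.raises(ValueError):
            cx.signed_adjacency(expr, 5)


class TestSoftThreshold:
    def test_heterogeneous_structure_reaches_target(self):
        expr, _ = oracles.simulate_block_expression(
            9, [400, 300, 250, 200, 150, 120, 100, 80, 60, 50, 40, 30], 1500, 0.7, 0
        )
        beta, fit = cx.pick_soft_threshold(expr)
        assert fit.attrs["target_reached"]
        assert fit.loc[fit["beta"] == beta, "fit"].iloc[0] >= 0.8

    def test_five_block_structure_returns_finite_beta(self):
        expr, _ = oracles.simulate_block_expression(50, [60] * 5, 0, 0.7, 0)
        beta, fit = cx.pick_soft_threshold(expr)
        assert 1 <= beta <= 20
        # connectivity decays with beta; fit improves over beta = 1
        assert fit["fit"].iloc[-1] > fit["fit"].iloc[0]
        assert fit["mean_k"].is_monotonic_decreasing

    def test_independent_genes_flagged_argmax(self):
        expr, _ = oracles.simulate_block_expression(20, [], 150, 0.0, 3)
        beta, fit = cx.pick_soft_threshold(expr, candidate_betas=(1, 2, 3, 4, 5, 6))
        assert not fit.attrs["target_reached"]
        valid = fit.dropna(subset=["fit"])
        assert beta == int(valid.loc[valid["fit"].idxmax(), "beta"])


class TestTOM:
    def test_two_gene_saturated_edge(self):
        a = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=["a", "b"], columns=["a", "b"])
        assert cx.tom_similarity(a).iloc[0, 1] == pytest.approx(1.0)

    def test_empty_network_stays_empty(self):
        a = pd.DataFrame(np.eye(4))
        tom = cx.tom_similarity(a).to_numpy()
        assert np.allclose(tom[~np.eye(4, dtype=bool)], 0.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            m = rng.random((20, 20))
            a = (m + m.T) / 2
            np.fill_diagonal(a, 1.0)
            tom = cx.tom_similarity(pd.DataFrame(a)).to_numpy()
            assert np.abs(tom - oracles.tom_tripleloop(a)).max() < 1e-12

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(8)
        m = rng.random((30, 30))
        a = (m + m.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = cx.tom_similarity(pd.DataFrame(a)).to_numpy()
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0


class TestModules:
    def test_two_perfect_blocks(self):
        rng = np.random.default_rng(9)
        z1, z2 = rng.normal(size=8), rng.normal(size=8)
        expr = _expr([z1 * s for s in (1, 2, 3, 0.5)] + [z2 * s for s in (1, 2, 3, 0.5)])
        adj = cx.signed_adjacency(expr, 5)
        labels = cx.detect_modules(1 - cx.tom_similarity(adj), min_module_size=2)
        assert labels.nunique() == 2 and (labels != cx.GREY).all()
        assert labels.iloc[:4].nunique() == 1 and labels.iloc[4:].nunique() == 1

    def test_planted_blocks_recovered(self):
        expr, truth = oracles.simulate_block_expression(50, [60] * 5, 0, 0.7, 10)
        from sklearn.metrics import adjusted_rand_score

        beta, _ = cx.pick_soft_threshold(expr)
        adj = cx.signed_adjacency(expr, beta)
        labels = cx.detect_modules(1 - cx.tom_similarity(adj), min_module_size=30)
        assert adjusted_rand_score(truth, labels.to_numpy()) >= 0.8

    def test_oversized_min_module_greys_everything(self):
        expr, _ = oracles.simulate_block_expression(10, [10], 0, 0.5, 11)
        adj = cx.signed_adjacency(expr, 3)
        with pytest.warns(UserWarning):
            labels = cx.detect_modules(1 - cx.tom_similarity(adj), min_module_size=100)
        assert (labels == cx.GREY).all()


class TestEigengene:
    def test_identical_genes_reproduce_profile(self):
        z = np.array([1.0, -2.0, 0.5, 1.5, -1.0])
        expr = _expr([z, z, z])
        e, ve = cx.module_eigengene(expr, expr.index)
        zs = (z - z.mean()) / z.std(ddof=1)
        expected = zs / np.linalg.norm(zs)
        assert np.allclose(e.to_numpy(), expected, atol=1e-10)
        assert ve == pytest.approx(1.0)

    def test_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(12)
        expr = _expr(rng.normal(size=(15, 9)))
        e, ve = cx.module_eigengene(expr, expr.index)
        x = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=1), axis=0)
        _, s, vt = np.linalg.svd(x.to_numpy(), full_matrices=False)
        assert min(
            np.abs(e.to_numpy() - vt[0]).max(), np.abs(e.to_numpy() + vt[0]).max()
        ) < 1e-10
        assert ve == pytest.approx(s[0] ** 2 / (s**2).sum(), abs=1e-12)

    def test_variance_explained_is_optimal(self):
        rng = np.random.default_rng(13)
        expr = _expr(rng.normal(size=(10, 7)))
        _, ve = cx.module_eigengene(expr, expr.index)
        x = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=1), axis=0).to_numpy()
        total = (x**2).sum()
        for _ in range(50):  # no random unit direction explains more
            v = rng.normal(size=7)
            v /= np.linalg.norm(v)
            assert ((x @ v) ** 2).sum() / total <= ve + 1e-12
        for g in range(10):  # nor any single member gene's profile
            v = x[g] / np.linalg.norm(x[g])
            assert ((x @ v) ** 2).sum() / total <= ve + 1e-12

    def test_small_module_rejected(self):
        expr = _expr(np.random.default_rng(0).normal(size=(3, 5)))
        with pytest.raises(ValueError):
            cx.module_eigengene(expr, ["g0"])


class TestModuleTrait:
    def test_perfect_correlation(self):
        e = pd.DataFrame([[1.0, 2, 3, 4, 5, 6, 7, 8, 9]], index=["blue"])
        traits = pd.DataFrame({"had_ratio": np.arange(1.0, 10)}, index=e.columns)
        out = cx.module_trait_cor(e, traits)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_p_matches_t_oracle(self):
        rng = np.random.default_rng(14)
        e = pd.DataFrame([rng.normal(size=9)], index=["m"])
        traits = pd.DataFrame({"t": rng.normal(size=9)}, index=e.columns)
        out = cx.module_trait_cor(e, traits)
        r = out["r"].iloc[0]
        t = r * np.sqrt(7) / np.sqrt(1 - r**2)
        assert out["p"].iloc[0] == pytest.approx(2 * stats.t.sf(abs(t), 7), rel=1e-12)

    def test_r_09_n9_reference_point(self):
        # r = 0.9 at n = 9: t ~= 5.46, p ~= 9.4e-4
        t = 0.9 * np.sqrt(7) / np.sqrt(1 - 0.81)
        assert t == pytest.approx(5.4627, abs=1e-3)
        assert 2 * stats.t.sf(t, 7) == pytest.approx(9.4e-4, rel=0.02)

    def test_null_flag_rate_about_one_percent(self):
        rng = np.random.default_rng(15)
        flags = 0
        n_perm = 500
        e = pd.DataFrame([rng.normal(size=9)], index=["m"])
        for _ in range(n_perm):
            traits = pd.DataFrame({"t": rng.normal(size=9)}, index=e.columns)
            out = cx.module_trait_cor(e, traits, p_threshold=0.01)
            flags += int(out["significant"].iloc[0])
        se = np.sqrt(0.01 * 0.99 / n_perm)
        assert flags / n_perm <= 0.01 + 4 * se

    def test_zero_variance_trait_flagged(self):
        e = pd.DataFrame([np.arange(5.0)], index=["m"])
        traits = pd.DataFrame({"t": np.ones(5)}, index=e.columns)
        out = cx.module_trait_cor(e, traits)
        assert np.isnan(out["r"].iloc[0]) and not out["significant"].iloc[0]


class TestGSMMHubs:
    def test_trivial_identities(self):
        rng = np.random.default_rng(16)
        profile = rng.normal(size=9)
        expr = _expr([profile, rng.normal(size=9)])
        eig = pd.DataFrame([profile], index=["blue"], columns=expr.columns)
        trait = pd.Series(profile, index=expr.columns)
        gs, mm = cx.gene_significance_and_mm(expr, eig, trait)
        assert gs["g0"] == pytest.approx(1.0)
        assert mm.loc["g0", "blue"] == pytest.approx(1.0)

    def test_hub_thresholds_strict(self):
        gs = pd.Series({"a": 0.71, "b": 0.70, "c": 0.9})
        mm = pd.DataFrame({"blue": {"a": 0.72, "b": 0.9, "c": 0.79}})
        labels = pd.Series({"a": "blue", "b": "blue", "c": "blue"})
        hubs = cx.select_hub_genes(gs, mm, labels, 0.7, 0.7)
        assert set(hubs["gene"]) == {"a", "c"}  # b fails GS = 0.7 exactly
        strict = cx.select_hub_genes(gs, mm, labels, 0.8, 0.8)
        assert set(strict["gene"]) == set()  # a fails at (0.8, 0.8); c fails MM

    def test_grey_genes_never_hubs(self):
        gs = pd.Series({"a": 0.99})
        mm = pd.DataFrame({"blue": {"a": 0.99}})
        labels = pd.Series({"a": cx.GREY})
        assert cx.select_hub_genes(gs, mm, labels).empty

    def test_gs_mm_concordance_for_trait_module(self):
        expr, truth = oracles.simulate_block_expression(30, [60, 60, 60], 60, 0.7, 17)
        labels = pd.Series(
            [f"m{b}" if b >= 0 else cx.GREY for b in truth], index=expr.index
        )
        ms = cx.compute_eigengenes(expr, labels)
        rng = np.random.default_rng(18)
        trait = ms.eigengenes.loc["m0"] + rng.normal(0, 0.3, size=expr.shape[1])
        trait.index = expr.columns
        gs, mm = cx.gene_significance_and_mm(expr, ms.eigengenes, trait)
        members = labels.index[labels == "m0"]
        r = np.corrcoef(gs[members].abs(), mm.loc[members, "m0"].abs())[0, 1]
        assert r >= 0.5


class TestAnova:
    def test_hand_computed_example(self):
        # (1,2,3), (2,3,4), (3,4,5): SSB = 6, SSW = 6 -> F = 3.0, p = sf(3; 2, 6)
        e = pd.Series([1.0, 2, 3, 2, 3, 4, 3, 4, 5], index=[f"s{i}" for i in range(9)])
        g = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=e.index)
        res = cx.eigengene_anova(e, g)
        assert res["F"] == pytest.approx(3.0, rel=1e-12)
        assert res["df"] == (2, 6)
        assert res["p"] == pytest.approx(float(stats.f.sf(3.0, 2, 6)), rel=1e-12)
        f_sp, p_sp = stats.f_oneway(e[:3], e[3:6], e[6:])
        assert res["F"] == pytest.approx(f_sp) and res["p"] == pytest.approx(p_sp)

    def test_constant_values_degenerate(self):
        e = pd.Series(np.ones(9), index=[f"s{i}" for i in range(9)])
        g = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=e.index)
        res = cx.eigengene_anova(e, g)
        assert res["degenerate"]

    def test_null_f_averages_one(self):
        rng = np.random.default_rng(19)
        fs = []
        for _ in range(300):
            e = pd.Series(rng.normal(size=9), index=[f"s{i}" for i in range(9)])
            g = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=e.index)
            fs.append(cx.eigengene_anova(e, g)["F"])
        # E[F] = df2/(df2-2) = 6/4 = 1.5 for F(2,6)
        assert np.mean(fs) == pytest.approx(1.5, rel=0.25)


class TestOrdination:
    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(20)
        base = rng.normal(size=(30, 4))
        expr = _expr(np.hstack([base, base[:, :1]]))  # s4 duplicates s0
        scores, _ = cx.sample_ordination(expr, top_n=20)
        assert np.allclose(scores.loc["s0"], scores.loc["s4"], atol=1e-10)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(21)
        expr = _expr(rng.normal(size=(50, 8)))
        _, frac = cx.sample_ordination(expr, top_n=30)
        assert frac.sum() == pytest.approx(1.0, abs=1e-10)

    def test_species_clusters_separate(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(22)
        groups = []
        for _ in range(3):
            centre = rng.normal(0, 3, size=40)
            groups.append(np.column_stack([centre + rng.normal(0, 0.5, 40) for _ in range(3)]))
        expr = _expr(np.hstack(groups))
        scores, _ = cx.sample_ordination(expr, top_n=40)
        lab = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        assert silhouette_score(scores[["PC1", "PC2"]], lab) > 0.5

    def test_top_n_validated(self):
        expr = _expr(np.random.default_rng(0).normal(size=(5, 4)))
        with pytest.raises(ValueError):
            cx.sample_ordination(expr, top_n=10)
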