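"""AMOVA decomposition, pairwise Fst and DAPC against independent oracles."""

import numpy as np
import pytest
from scipy.linalg import eigh as scipy_eigh

import hybridzone as hz
from hybridzone.genotypes import GenotypeMatrix
from hybridzone.structure import (amova, amova_from_distance, dapc,
                                  genotype_distance_matrix, pairwise_fst,
                                  fst_matrix, weir_cockerham_theta)
from conftest import stack_classes


def centroid_decomposition(X, groups, pops):
    """Brute-force nested sums of squares from explicit centroids."""
    grand = X.mean(axis=0)
    ss_tot = ((X - grand) ** 2).sum()
    ss_wp = sum(((X[pops == p] - X[pops == p].mean(axis=0)) ** 2).sum()
                for p in np.unique(pops))
    ss_wg = sum(((X[groups == g] - X[groups == g].mean(axis=0)) ** 2).sum()
                for g in np.unique(groups))
    return ss_tot - ss_wg, ss_wg - ss_wp, ss_wp


class TestAmova:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_sums_of_squares_match_centroid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(3, 7, size=5)
        pops = np.repeat(np.arange(5), sizes)
        groups = np.array([0, 0, 1, 1, 2])[pops]
        X = rng.normal(size=(pops.size, 6))
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
        res = amova_from_distance(d2, [groups, pops])
        ss_ag, ss_ap, ss_wp = centroid_decomposition(X, groups, pops)
        assert res.ss[0] == pytest.approx(ss_ag, abs=1e-12 * max(1, ss_ag))
        assert res.ss[1] == pytest.approx(ss_ap, abs=1e-12 * max(1, ss_ap))
        assert res.ss[2] == pytest.approx(ss_wp, abs=1e-12 * max(1, ss_wp))
        assert sum(res.percent) == pytest.approx(100.0, abs=1e-6)
        assert sum(res.df) == pops.size - 1

    @pytest.mark.parametrize("seed", range(8))
    def test_nested_phi_identity(self, seed):
        rng = np.random.default_rng(100 + seed)
        pops = np.repeat(np.arange(6), 4)
        groups = rng.integers(0, 2, size=6)[pops]
        if np.unique(groups).size < 2:
            groups[pops >= 3] = 1 - groups[pops >= 3]
        X = rng.normal(size=(24, 5)) + groups[:, None]
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
        phi = amova_from_distance(d2, [groups, pops]).phi
        assert (1 - phi["PhiCT"]) * (1 - phi["PhiSC"]) == pytest.approx(
            1 - phi["PhiST"], abs=1e-9)

    def test_three_population_toy_variance_components(self):
        # direct evaluation of the two-level moment equations
        X = np.array([[0.0], [0.0], [1.0], [2.0], [2.0], [3.0], [5.0], [5.0]])
        pops = np.array([0, 0, 0, 1, 1, 1, 2, 2])
        d2 = (X - X.T) ** 2
        res = amova_from_distance(d2, [pops])
        ss_wp = sum(((X[pops == p] - X[pops == p].mean()) ** 2).sum()
                    for p in range(3))
        ss_ap = ((X - X.mean()) ** 2).sum() - ss_wp
        sigma_w = ss_wp / (8 - 3)
        n_prime = (8 - (9 + 9 + 4) / 8) / 2
        sigma_a = (ss_ap / 2 - sigma_w) / n_prime
        assert res.sigma2[0] == pytest.approx(sigma_a, abs=1e-12)
        assert res.sigma2[1] == pytest.approx(sigma_w, abs=1e-12)

    def test_identical_genotypes_are_degenerate(self):
        g = GenotypeMatrix([f"i{k}" for k in range(8)],
                           ["P1"] * 4 + ["P2"] * 4, ["L1", "L2"],
                           np.full((8, 2), 2, dtype=np.int8))
        res = amova(g, {"P1": "g1", "P2": "g1"})
        assert all(s == 0 for s in res.ss)
        assert all(np.isnan(v) for v in res.phi.values())

    def test_private_group_haplotypes_maximise_phi_ct(self):
        # each group fixed for a private profile; populations within
        # groups identical
        rng = np.random.default_rng(2)
        X = np.repeat(np.array([[0.0, 0.0], [50.0, 50.0]]), 20, axis=0)
        X += rng.normal(scale=1.0, size=X.shape)  # within-population noise
        pops = np.repeat(np.arange(8), 5)
        groups = np.array([0] * 20 + [1] * 20)
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
        res = amova_from_distance(d2, [groups, pops])
        assert res.phi["PhiSC"] == pytest.approx(0.0, abs=0.15)
        assert res.phi["PhiCT"] > 0.99

    def test_four_level_design_df_and_percent(self, six_class_panel):
        g = six_class_panel
        grouping = {p: ("A" if p in ("pureA", "BxA") else "B")
                    for p in g.populations}
        res = amova(g, grouping)
        assert sum(res.df) == 2 * g.n_individuals - 1
        assert np.nansum(res.percent) == pytest.approx(100.0, abs=1e-6)

    def test_permutation_p_values_valid_under_null(self):
        rng = np.random.default_rng(31)
        hits = 0
        reps = 100
        for t in range(reps):
            X = rng.normal(size=(16, 3))
            pops = np.repeat(np.arange(4), 4)
            d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
            res = amova_from_distance(d2, [pops], n_perm=49, seed=t)
            hits += res.p_values["PhiST"] <= 0.05
        assert hits / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps) + 0.01


class TestPairwiseFst:
    def test_complete_differentiation_boundary(self, diagnostic_freqs):
        fa, fb = diagnostic_freqs
        g = stack_classes(fa, fb, [("P1", "pureA", 8), ("P2", "pureB", 8)],
                          seed=1)
        res = pairwise_fst(g, "P1", "P2", n_perm=999, seed=0)
        assert res.fst == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 1000)
        assert res.wc_theta == pytest.approx(1.0)

    def test_toy_two_population_hand_computation(self):
        # 2 pops x 2 individuals x 2 loci; distances counted by hand
        geno = np.array([[2, 2], [2, 1], [0, 0], [0, 1]], dtype=np.int8)
        g = GenotypeMatrix(["a", "b", "c", "d"], ["P1", "P1", "P2", "P2"],
                           ["L1", "L2"], geno)
        d2 = genotype_distance_matrix(g)
        expected = np.array([[0, 1, 4, 3],
                             [1, 0, 3, 2],
                             [4, 3, 0, 1],
                             [3, 2, 1, 0]], dtype=float)
        assert (d2 == expected).all()
        res = pairwise_fst(g, "P1", "P2", n_perm=9, seed=0)
        # two-level moment equations evaluated directly
        ss_wp = (0.5 + 0.5)
        ss_ap = d2.sum() / 8 - ss_wp
        sigma_w = ss_wp / 2
        sigma_a = (ss_ap - sigma_w) / 2
        assert res.fst == pytest.approx(sigma_a / (sigma_a + sigma_w),
                                        abs=1e-12)

    def test_panmictic_split_is_null(self):
        rng = np.random.default_rng(32)
        pvals = []
        fsts = []
        for t in range(60):
            dose = rng.binomial(2, 0.5, size=(16, 20)).astype(np.int8)
            g = GenotypeMatrix([f"i{k}" for k in range(16)],
                               ["P1"] * 8 + ["P2"] * 8,
                               [f"L{j}" for j in range(20)], dose)
            res = pairwise_fst(g, "P1", "P2", n_perm=99, seed=t)
            pvals.append(res.p)
            fsts.append(res.fst)
        assert abs(np.mean(fsts)) < 0.05
        assert np.mean(np.array(pvals) <= 0.05) < 0.20

    def test_matrix_shape_and_mask(self, six_class_panel):
        sub = six_class_panel.subset(
            np.isin(six_class_panel.pops, ["pureA", "pureB", "F1"]))
        f, p, sig = fst_matrix(sub, n_perm=49, seed=0)
        assert f.shape == (3, 3)
        assert np.isnan(f.to_numpy()[np.triu_indices(3, 1)]).all()
        assert sig.loc["pureB", "pureA"]

    def test_small_population_rejected(self, six_class_panel):
        g = six_class_panel.subset(
            np.arange(six_class_panel.n_individuals) < 21)
        with pytest.raises(ValueError):
            pairwise_fst(g, "pureA", "pureB")


class TestDapc:
    def test_variance_target_retains_minimal_pcs(self, six_class_panel):
        res = dapc(six_class_panel, variance_target=0.8)
        x = six_class_panel.genotypes.astype(float)
        x -= x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1
        x /= sd
        ev = np.linalg.svd(x, compute_uv=False) ** 2
        cum = np.cumsum(ev / ev.sum())
        k_min = int(np.searchsorted(cum, 0.8) + 1)
        assert res.n_pcs == k_min

    def test_fixed_differences_separate_groups_on_axis_one(self,
                                                           diagnostic_freqs):
        fa, fb = diagnostic_freqs
        g = stack_classes(fa, fb, [("P1", "pureA", 10), ("P2", "pureB", 10)],
                          seed=2)
        res = dapc(g, n_pcs=5)
        s1 = res.scores[:, 0]
        assert max(s1[:10].max(), s1[10:].max()) > \
            min(s1[:10].min(), s1[10:].min())
        assert s1[:10].max() < s1[10:].min() or s1[10:].max() < s1[:10].min()

    def test_matches_independent_two_step_eigendecomposition(self):
        rng = np.random.default_rng(33)
        dose = rng.binomial(2, 0.4, size=(30, 12)).astype(np.int8)
        labels = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        dose[10:20] += rng.binomial(1, 0.4, size=(10, 12)).astype(np.int8)
        dose = np.clip(dose, 0, 2)
        g = GenotypeMatrix([f"i{k}" for k in range(30)], labels,
                           [f"L{j}" for j in range(12)], dose)
        k = 6
        res = dapc(g, n_pcs=k)
        # oracle: explicit covariance eigendecomposition, then the
        # generalised discriminant eigenproblem in the retained space
        x = dose.astype(float)
        x -= x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1
        x /= sd
        cov = x.T @ x / x.shape[0]
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1][:k]
        y = x @ vecs[:, order]
        lab = np.asarray(labels)
        grand = y.mean(axis=0)
        sw = np.zeros((k, k))
        sb = np.zeros((k, k))
        for grp in ("A", "B", "C"):
            yg = y[lab == grp]
            mg = yg.mean(axis=0)
            sw += (yg - mg).T @ (yg - mg)
            sb += yg.shape[0] * np.outer(mg - grand, mg - grand)
        ref = np.sort(scipy_eigh(sb, sw, eigvals_only=True))[::-1][:2]
        assert np.allclose(np.sort(res.eigenvalues)[::-1], ref, atol=1e-8)

    def test_weir_cockerham_multi_population(self, six_class_panel):
        sub = six_class_panel.subset(
            np.isin(six_class_panel.pops, ["pureA", "pureB"]))
        assert weir_cockerham_theta(sub) == pytest.approx(1.0)
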