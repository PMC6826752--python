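"""He/Ho/F_IS, exact Hardy-Weinberg tests, genotypic LD, Bonferroni."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

import hybridzone as hz
from hybridzone.diversity import (LDResult, bonferroni, fisher_combine,
                                  hwe_exact_test, ld_genotypic_test,
                                  locus_diversity, population_summary)
from hybridzone.genotypes import MISSING, GenotypeMatrix


def matrix_from_counts(n_aa, n_ab, n_bb, pop="P"):
    dosage = [2] * n_aa + [1] * n_ab + [0] * n_bb
    n = len(dosage)
    return GenotypeMatrix([f"i{k}" for k in range(n)], [pop] * n, ["L1"],
                          np.array(dosage, dtype=np.int8)[:, None])


def levene_pvalue_bruteforce(n_aa, n_ab, n_bb):
    """Independent enumeration of Levene's conditional distribution with
    exact rational arithmetic."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab

    def prob(h):
        aa = (n_a - h) // 2
        bb = n - aa - h
        return (Fraction(math.factorial(n), math.factorial(aa)
                         * math.factorial(h) * math.factorial(bb))
                * Fraction(2 ** h)
                * Fraction(math.factorial(n_a) * math.factorial(2 * n - n_a),
                           math.factorial(2 * n)))

    support = range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    probs = {h: prob(h) for h in support}
    obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= obs))


class TestLocusDiversity:
    def test_hand_computed_unbiased_he(self):
        g = matrix_from_counts(3, 4, 3)
        row = locus_diversity(g, "P").iloc[0]
        assert row["p"] == pytest.approx(0.5)
        assert row["Ho"] == pytest.approx(0.4)
        assert row["He"] == pytest.approx((20 / 19) * 0.5)

    def test_all_heterozygous_gives_ho_one_and_negative_fis(self):
        g = matrix_from_counts(0, 12, 0)
        row = locus_diversity(g, "P").iloc[0]
        assert row["Ho"] == 1.0
        assert row["F_IS"] < 0

    def test_monomorphic_locus_undefined_fis(self):
        g = matrix_from_counts(9, 0, 0)
        row = locus_diversity(g, "P").iloc[0]
        assert row["He"] == 0.0 and row["Ho"] == 0.0
        assert np.isnan(row["F_IS"])
        assert row["hwe_p"] == 1.0

    def test_fis_sign_convention(self):
        deficit = locus_diversity(matrix_from_counts(6, 1, 5), "P").iloc[0]
        excess = locus_diversity(matrix_from_counts(2, 9, 1), "P").iloc[0]
        assert deficit["F_IS"] > 0 > excess["F_IS"]

    def test_he_estimator_is_unbiased(self):
        rng = np.random.default_rng(21)
        for n, p in [(5, 0.1), (5, 0.5), (20, 0.1), (20, 0.5)]:
            target = 2 * p * (1 - p)
            vals = []
            for _ in range(3000):
                dose = rng.binomial(2, p, size=n)
                ph = dose.mean() / 2
                vals.append((2 * n / (2 * n - 1))
                            * (1 - ph ** 2 - (1 - ph) ** 2))
            assert np.mean(vals) == pytest.approx(target, abs=0.01)

    def test_population_summary_shape(self, small_bundle):
        outdir, _, _ = small_bundle
        from hybridzone.genotypes import read_genepop
        g = read_genepop(str(outdir / "genotypes.genepop"))
        table = population_summary(g)
        assert list(table["population"]) == g.populations
        assert table["N"].sum() == g.n_individuals
        # parental ponds are monomorphic at diagnostic loci (no He defined);
        # admixed ponds must report He in (0, 1]
        he = table.set_index("population")["He_mean"]
        assert he.dropna().between(0, 1).all()
        assert he["CH60"] > 0 and he["CHN6"] > 0


class TestHweExact:
    def test_monomorphic_p_is_one(self):
        assert hwe_exact_test(5, 0, 0) == 1.0

    @pytest.mark.parametrize("counts", [
        (1, 8, 1), (5, 2, 5), (0, 10, 0), (3, 3, 3), (7, 1, 2), (2, 5, 13),
    ])
    def test_enumeration_matches_bruteforce_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            levene_pvalue_bruteforce(*counts), abs=1e-12)

    def test_markov_chain_converges_to_enumeration(self):
        rng = np.random.default_rng(22)
        failures = 0
        trials = 60
        for t in range(trials):
            n = int(rng.integers(4, 26))
            n_aa = int(rng.integers(0, n + 1))
            n_ab = int(rng.integers(0, n - n_aa + 1))
            n_bb = n - n_aa - n_ab
            p_enum = hwe_exact_test(n_aa, n_ab, n_bb)
            p_mc, se = hwe_exact_test(n_aa, n_ab, n_bb, method="markov_chain",
                                      iterations=50_000, seed=t,
                                      return_se=True)
            if abs(p_mc - p_enum) > max(3 * se, 1e-9):
                failures += 1
        assert failures <= math.ceil(0.01 * trials)

    def test_validity_under_hardy_weinberg_sampling(self):
        # P(p <= alpha) <= alpha + granularity for exact conditional tests
        rng = np.random.default_rng(23)
        for alpha in (0.01, 0.05, 0.2):
            hits = 0
            reps = 2000
            for _ in range(reps):
                dose = rng.binomial(2, 0.4, size=15)
                p = hwe_exact_test(int((dose == 2).sum()),
                                   int((dose == 1).sum()),
                                   int((dose == 0).sum()))
                hits += p <= alpha
            assert hits / reps <= alpha + 3 * np.sqrt(alpha / reps) + 0.02

    def test_fisher_combination(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)
        assert fisher_combine([0.001, 0.002]) < 0.001
        assert np.isnan(fisher_combine([]))


class TestLdGenotypic:
    def _two_locus(self, a, b, pop="P"):
        n = len(a)
        geno = np.stack([a, b], axis=1).astype(np.int8)
        return GenotypeMatrix([f"i{k}" for k in range(n)], [pop] * n,
                              ["L1", "L2"], geno)

    def test_perfect_association_saturates_permutation_floor(self):
        rng = np.random.default_rng(24)
        a = rng.binomial(2, 0.5, size=30)
        while np.unique(a).size < 2:
            a = rng.binomial(2, 0.5, size=30)
        g = self._two_locus(a, a.copy())
        res = ld_genotypic_test(g, "P", "L1", "L2", n_perm=999, seed=0)
        assert res.p == pytest.approx(1 / 1000)

    def test_monomorphic_locus_flagged_not_one(self):
        g = self._two_locus(np.array([1, 2, 0, 1, 1]),
                            np.zeros(5, dtype=int))
        res = ld_genotypic_test(g, "P", "L1", "L2", n_perm=99)
        assert isinstance(res, LDResult) and not res.defined
        assert np.isnan(res.p)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(25)
        reps, hits = 300, 0
        for t in range(reps):
            a = rng.binomial(2, 0.5, size=25)
            b = rng.binomial(2, 0.5, size=25)
            if np.unique(a).size < 2 or np.unique(b).size < 2:
                continue
            res = ld_genotypic_test(self._two_locus(a, b), "P", "L1", "L2",
                                    n_perm=99, seed=t)
            hits += res.p <= 0.05
        rate = hits / reps
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps) + 0.01

    def test_tiny_table_matches_exhaustive_pairing(self):
        a = np.array([0, 1, 2, 1, 0])
        b = np.array([2, 1, 0, 0, 1])
        g = self._two_locus(a, b)
        res = ld_genotypic_test(g, "P", "L1", "L2", n_perm=20000, seed=1)
        from hybridzone.diversity import _g_statistic
        obs = _g_statistic(a, b)
        exact = np.mean([_g_statistic(a, np.array(perm)) >= obs - 1e-12
                         for perm in itertools.permutations(b)])
        assert res.p == pytest.approx(exact, abs=0.02)


class TestBonferroni:
    def test_single_test_threshold_is_alpha(self):
        mask, thr = bonferroni([0.03], alpha=0.05)
        assert thr == 0.05 and mask.tolist() == [True]

    def test_fifty_tests_threshold(self):
        mask, thr = bonferroni([0.5] * 50, alpha=0.05)
        assert thr == pytest.approx(0.001)
        assert not mask.any()

    def test_empty_input(self):
        mask, thr = bonferroni([], alpha=0.05)
        assert mask.size == 0 and np.isnan(thr)

    def test_all_ones_never_significant(self):
        mask, _ = bonferroni(np.ones(10), alpha=0.05)
        assert not mask.any()
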