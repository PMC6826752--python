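"""Per-locus, per-population diversity and equilibrium statistics.

Implements unbiased expected heterozygosity, Weir & Cockerham's
within-population inbreeding coefficient f (F_IS), Levene/Haldane exact
Hardy-Weinberg tests (full enumeration and the Guo-Thompson switch chain),
a genotypic linkage-disequilibrium permutation test, and the Bonferroni
correction used for the multiple-testing summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .genotypes import MISSING, GenotypeMatrix

# ---------------------------------------------------------------------------
# He / Ho / F_IS
# ---------------------------------------------------------------------------


def _locus_counts(dosage: np.ndarray) -> tuple[int, int, int]:
    """(n_AA, n_AB, n_BB) over non-missing genotypes (A = allele 1)."""
    valid = dosage[dosage != MISSING]
    return int((valid == 2).sum()), int((valid == 1).sum()), int((valid == 0).sum())


def _wc_components(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """Weir & Cockerham (1984) single-population variance components (b, c).

    b is the between-individual, c the within-individual component; the
    per-locus inbreeding coefficient is f = b / (b + c), negative under
    heterozygote excess and positive under deficit.
    """
    n = n_aa + n_ab + n_bb
    if n < 2:
        return np.nan, np.nan
    p = (2 * n_aa + n_ab) / (2 * n)
    ho = n_ab / n
    b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * ho)
    c = ho / 2
    return b, c


def locus_diversity(g: GenotypeMatrix, pop: str) -> pd.DataFrame:
    """Per-locus diversity table for one population.

    Columns: locus, n, p (allele-1 frequency), Ho, He (unbiased,
    (2n/(2n-1))(1 - sum p_i^2)), F_IS (Weir-Cockerham f; NaN when the locus
    is monomorphic), F_IS_naive (1 - Ho/He) and the exact HWE p-value.
    """
    mask = g.pop_mask(pop)
    sub = g.genotypes[mask]
    if sub.shape[0] == 0:
        raise ValueError(f"population {pop!r} is empty")
    rows = []
    for j, locus in enumerate(g.loci):
        n_aa, n_ab, n_bb = _locus_counts(sub[:, j])
        n = n_aa + n_ab + n_bb
        if n == 0:
            rows.append({"locus": locus, "n": 0, "p": np.nan, "Ho": np.nan,
                         "He": np.nan, "F_IS": np.nan, "F_IS_naive": np.nan,
                         "hwe_p": np.nan})
            continue
        p = (2 * n_aa + n_ab) / (2 * n)
        ho = n_ab / n
        he = (2 * n / (2 * n - 1)) * (1 - p ** 2 - (1 - p) ** 2)
        b, c = _wc_components(n_aa, n_ab, n_bb)
        denom = b + c
        fis = b / denom if np.isfinite(b) and denom != 0 else np.nan
        fis_naive = 1 - ho / he if he > 0 else np.nan
        rows.append({"locus": locus, "n": n, "p": p, "Ho": ho, "He": he,
                     "F_IS": fis if he > 0 else np.nan,
                     "F_IS_naive": fis_naive,
                     "hwe_p": hwe_exact_test(n_aa, n_ab, n_bb)})
    return pd.DataFrame(rows)


def population_summary(g: GenotypeMatrix,
                       pops: list[str] | None = None) -> pd.DataFrame:
    """Per-population summary in the shape of the study's diversity table.

    Mean and s.d. of He across polymorphic loci, the multi-locus HWE
    p-value (Fisher combination of per-locus exact tests), and the
    multilocus Weir-Cockerham F_IS (summed components) with the across-locus
    s.d. of per-locus f.
    """
    pops = pops or g.populations
    out = []
    for pop in pops:
        table = locus_diversity(g, pop)
        poly = table[(table["He"] > 0) & table["He"].notna()]
        mask = g.pop_mask(pop)
        sub = g.genotypes[mask]
        b_sum = c_sum = 0.0
        for j in range(g.n_loci):
            n_aa, n_ab, n_bb = _locus_counts(sub[:, j])
            b, c = _wc_components(n_aa, n_ab, n_bb)
            if np.isfinite(b) and (b != 0 or c != 0):
                b_sum += b
                c_sum += c
        multilocus_fis = b_sum / (b_sum + c_sum) if (b_sum + c_sum) != 0 else np.nan
        out.append({
            "population": pop,
            "N": int(mask.sum()),
            "He_mean": poly["He"].mean(),
            "He_sd": poly["He"].std(ddof=1),
            "hwe_multilocus_p": fisher_combine(poly["hwe_p"].dropna()),
            "F_IS_multilocus": multilocus_fis,
            "F_IS_sd": poly["F_IS"].std(ddof=1),
        })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Exact HWE tests
# ---------------------------------------------------------------------------


def _levene_log_prob(n_ab: int, n_a: int, n: int) -> float:
    """log P(n_AB heterozygotes | allele count n_A, sample size n) (Levene)."""
    n_aa = (n_a - n_ab) // 2
    n_bb = n - n_aa - n_ab
    return (gammaln(n + 1) - gammaln(n_aa + 1) - gammaln(n_ab + 1)
            - gammaln(n_bb + 1) + n_ab * np.log(2)
            + gammaln(n_a + 1) + gammaln(2 * n - n_a + 1) - gammaln(2 * n + 1))


def _het_support(n_a: int, n: int) -> np.ndarray:
    """Feasible heterozygote counts given n_A allele-1 copies in n diploids."""
    n_b = 2 * n - n_a
    hi = min(n_a, n_b)
    lo = n_a % 2
    return np.arange(lo, hi + 1, 2)


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int,
                   method: str = "enumeration",
                   iterations: int = 100_000,
                   dememorization: int = 1000,
                   seed: int = 0,
                   return_se: bool = False):
    """Exact Hardy-Weinberg test for a biallelic locus.

    The p-value is the probability, under Levene's distribution of genotype
    counts conditional on allele counts, of outcomes no more probable than
    the observed heterozygote count.  ``enumeration`` sums the full support;
    ``markov_chain`` estimates the same quantity with the Guo-Thompson
    switch chain (returns (p, se) when ``return_se``; the standard error
    comes from batch means over 50 batches).

    A monomorphic locus has a single attainable table, so p = 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    if n == 0 or n_a == 0 or n_a == 2 * n:
        return (1.0, 0.0) if return_se else 1.0
    support = _het_support(n_a, n)
    logp = np.array([_levene_log_prob(h, n_a, n) for h in support])
    obs_logp = _levene_log_prob(n_ab, n_a, n)
    if method == "enumeration":
        probs = np.exp(logp - logp.max())
        probs /= probs.sum()
        p = probs[logp <= obs_logp + 1e-9].sum()
        return (float(p), 0.0) if return_se else float(p)
    if method != "markov_chain":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    h = int(support[rng.integers(support.size)])
    lookup = {int(hh): lp for hh, lp in zip(support, logp)}

    def step(h: int) -> int:
        if rng.random() < 0.5:
            h2 = h + 2  # merge an AA with a BB into two heterozygotes
        else:
            h2 = h - 2  # split two heterozygotes
        if h2 < support[0] or h2 > support[-1]:
            return h
        ratio = np.exp(lookup[h2] - lookup[h])
        return h2 if rng.random() < min(1.0, ratio) else h

    for _ in range(dememorization):
        h = step(h)
    hits = np.empty(iterations, dtype=np.float64)
    thresh = obs_logp + 1e-9
    for t in range(iterations):
        h = step(h)
        hits[t] = lookup[h] <= thresh
    p = float(hits.mean())
    n_batches = 50
    batches = hits[: iterations // n_batches * n_batches].reshape(n_batches, -1)
    se = float(batches.mean(axis=1).std(ddof=1) / np.sqrt(n_batches))
    # batch means degenerate to zero when the indicator never (or always)
    # flips; floor the error with the add-one binomial estimate at a
    # conservative effective sample size (switch-chain autocorrelation)
    p_add = (hits.sum() + 1) / (iterations + 1)
    se_floor = float(np.sqrt(p_add * (1 - p_add) / max(iterations / 10, 1)))
    se = max(se, se_floor)
    return (p, se) if return_se else p


def hwe_exact_test_locus(g: GenotypeMatrix, pop: str, locus: str,
                         **kwargs):
    """Convenience wrapper: exact HWE test on one locus-population cell."""
    j = g.loci.index(locus)
    sub = g.genotypes[g.pop_mask(pop)][:, j]
    n_aa, n_ab, n_bb = _locus_counts(sub)
    return hwe_exact_test(n_aa, n_ab, n_bb, **kwargs)


def fisher_combine(pvalues) -> float:
    """Fisher's method across independent tests (per-population HWE)."""
    p = np.asarray(list(pvalues), dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        return np.nan
    p = np.clip(p, 1e-300, 1.0)
    stat = -2 * np.log(p).sum()
    return float(chi2.sf(stat, 2 * p.size))


# ---------------------------------------------------------------------------
# Genotypic linkage disequilibrium
# ---------------------------------------------------------------------------


@dataclass
class LDResult:
    defined: bool
    g_stat: float = np.nan
    p: float = np.nan
    n: int = 0
    reason: str = ""


def _g_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Log-likelihood-ratio G on the 3x3 genotype contingency table."""
    table = np.zeros((3, 3))
    np.add.at(table, (a, b), 1.0)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return float(2 * terms.sum())


def ld_genotypic_test(g: GenotypeMatrix, pop: str, locus_a: str, locus_b: str,
                      n_perm: int = 1000, seed: int = 0) -> LDResult:
    """Permutation test of genotypic association between two loci.

    The observed G statistic on the 3x3 genotype table is compared with its
    distribution under random re-pairing of single-locus genotypes;
    p uses the add-one estimator (never exactly zero).  Undefined (flagged)
    when either locus is monomorphic in the population.
    """
    sub = g.genotypes[g.pop_mask(pop)]
    ja, jb = g.loci.index(locus_a), g.loci.index(locus_b)
    ok = (sub[:, ja] != MISSING) & (sub[:, jb] != MISSING)
    a, b = sub[ok, ja].astype(int), sub[ok, jb].astype(int)
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        return LDResult(defined=False, n=int(ok.sum()),
                        reason="monomorphic locus")
    obs = _g_statistic(a, b)
    rng = np.random.default_rng(seed)
    hits = 0
    bp = b.copy()
    for _ in range(n_perm):
        rng.shuffle(bp)
        if _g_statistic(a, bp) >= obs - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return LDResult(defined=True, g_stat=obs, p=p, n=a.size)


def bonferroni(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Bonferroni mask and per-test threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.nan
    threshold = alpha / p.size
    return p < threshold, threshold
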