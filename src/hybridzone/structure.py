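"""Between-population structure: AMOVA, pairwise Fst, DAPC and admixture.

The AMOVA is a fully general nested decomposition of squared inter-unit
distances (Excoffier-style): units may be individuals (allele-difference
distances), mtDNA sequences (pairwise differences) or allele copies (the
four-level genotypic design).  Variance components come from the
method-of-moments equations for nested random effects with unequal cluster
sizes; negative components are reported as computed, never truncated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .genotypes import MISSING, GenotypeMatrix

# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


def genotype_distance_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise number of allele differences between multilocus genotypes.

    For dosages a, b in {0,1,2} the per-locus contribution is |a - b|;
    loci missing in either member of a pair are skipped for that pair.
    """
    x = g.genotypes.astype(float)
    x[g.genotypes == MISSING] = np.nan
    diff = np.abs(x[:, None, :] - x[None, :, :])
    return np.nansum(diff, axis=2)


def allele_copy_matrix(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(copies, individual index) for the 4-level genotypic AMOVA.

    Copies is a (2N, L) 0/1 allele matrix (phase arbitrary — every AMOVA
    sum of squares is phase-invariant); loci with missing genotypes are
    dropped so the nested design stays balanced within individuals.
    """
    keep = ~(g.genotypes == MISSING).any(axis=0)
    dose = g.genotypes[:, keep]
    first = (dose >= 1).astype(np.int8)
    second = (dose == 2).astype(np.int8)
    copies = np.empty((2 * dose.shape[0], dose.shape[1]), dtype=np.int8)
    copies[0::2] = first
    copies[1::2] = second
    owner = np.repeat(np.arange(dose.shape[0]), 2)
    return copies, owner


def copy_distance_matrix(copies: np.ndarray) -> np.ndarray:
    """Hamming distance between allele copies (squared Euclidean on 0/1)."""
    x = copies.astype(float)
    return np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)


# ---------------------------------------------------------------------------
# Nested AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    """Nested AMOVA table plus Phi statistics and permutation p-values."""

    levels: list[str]
    df: list[int]
    ss: list[float]
    sigma2: list[float]
    percent: list[float]
    phi: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    n_perm: int = 0

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"source": self.levels, "df": self.df,
                             "SS": self.ss, "variance": self.sigma2,
                             "percent": self.percent})


def _codes(labels) -> np.ndarray:
    _, codes = np.unique(np.asarray(labels), return_inverse=True)
    return codes


def _ssd_within(d2: np.ndarray, codes: np.ndarray) -> float:
    """Sum over clusters of (1 / 2 n_c) * full double sum of d2 inside."""
    total = 0.0
    for c in np.unique(codes):
        idx = np.flatnonzero(codes == c)
        total += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    return total


def _moment_matrix(partitions: list[np.ndarray]) -> np.ndarray:
    """Coefficient matrix C with E[SS_r] = sum_k C[r, k] * sigma2_k.

    ``partitions`` runs from the top grouping down to the units themselves
    (each an integer-coded label array over units); component k is the
    among-partition-k effect, the last component the within-bottom error.
    """
    n_units = partitions[0].size
    m = len(partitions)  # the last partition is the unit singletons (error)
    sizes = [np.bincount(p) for p in partitions]
    # T_r coefficients: coef_T[r][k] for r in 0..m (0 = grand cluster)
    coef_t = np.zeros((m + 1, m))
    for r in range(m + 1):
        part_r = np.zeros(n_units, dtype=int) if r == 0 else partitions[r - 1]
        for k in range(1, m + 1):
            if k <= r:
                coef_t[r, k - 1] = n_units
            else:
                # sum over clusters d of partition k of n_d^2 / n_anc_r(d),
                # computed per unit as n_{cluster_k(u)} / n_{anc_r(u)}
                anc_sizes = (np.full(n_units, n_units) if r == 0
                             else sizes[r - 1][part_r])
                coef_t[r, k - 1] = (sizes[k - 1][partitions[k - 1]]
                                    / anc_sizes).sum()
    return coef_t[1:] - coef_t[:-1]


def _amova_components(d2: np.ndarray,
                      levels: list[np.ndarray]) -> tuple[list, list, list]:
    """(df, SS, sigma2) for the nested design given squared distances."""
    n = d2.shape[0]
    parts = [_codes(lv) for lv in levels] + [np.arange(n)]
    ssd = [d2.sum() / (2 * n)] + [_ssd_within(d2, p) for p in parts]
    ss = [ssd[r] - ssd[r + 1] for r in range(len(parts))]
    ks = [len(np.unique(p)) for p in parts]
    df = [ks[0] - 1] + [ks[r] - ks[r - 1] for r in range(1, len(parts))]
    # a zero-df level adds no information: drop it from the moment system
    # and report its component (and dependent Phi) as undefined
    keep = [r for r, d in enumerate(df) if d > 0]
    if len(keep) < len(parts):
        reduced = [parts[r] for r in keep]
        c = _moment_matrix(reduced)
        sol = np.linalg.solve(c, np.array([ss[r] for r in keep]))
        sigma2 = np.full(len(parts), np.nan)
        for val, r in zip(sol, keep):
            sigma2[r] = val
    else:
        sigma2 = np.linalg.solve(_moment_matrix(parts), np.array(ss))
    return df, ss, list(sigma2)


def _phi_from_sigma(sigma2: list[float], n_levels: int) -> dict[str, float]:
    s = np.array(sigma2, dtype=float)
    tot = np.nansum(s)
    phi: dict[str, float] = {}
    if n_levels == 1:
        phi["PhiST"] = s[0] / tot if tot != 0 else np.nan
    elif n_levels == 2:
        phi["PhiCT"] = s[0] / tot if tot != 0 else np.nan
        denom = s[1] + s[2]
        phi["PhiSC"] = s[1] / denom if denom != 0 else np.nan
        phi["PhiST"] = (s[0] + s[1]) / tot if tot != 0 else np.nan
    elif n_levels == 3:
        phi["PhiCT"] = s[0] / tot if tot != 0 else np.nan
        denom_sc = s[1] + s[2] + s[3]
        phi["PhiSC"] = s[1] / denom_sc if denom_sc != 0 else np.nan
        denom_is = s[2] + s[3]
        phi["PhiIS"] = s[2] / denom_is if denom_is != 0 else np.nan
        phi["PhiST"] = (s[0] + s[1]) / tot if tot != 0 else np.nan
        phi["PhiIT"] = (s[0] + s[1] + s[2]) / tot if tot != 0 else np.nan
    return phi


_LEVEL_NAMES = {
    1: ["Among populations", "Within populations"],
    2: ["Among groups", "Among populations within groups",
        "Within populations"],
    3: ["Among groups", "Among populations within groups",
        "Among individuals within populations", "Within individuals"],
}


def amova_from_distance(d2: np.ndarray, levels: list[np.ndarray],
                        n_perm: int = 0, seed: int = 0) -> AmovaResult:
    """Nested AMOVA on a squared-distance matrix.

    ``levels`` lists label arrays from the top of the hierarchy down
    (e.g. [groups, populations] for the 3-level haplotypic design, or
    [groups, populations, individuals] over allele copies for the 4-level
    genotypic design).  Permutation p-values use level-appropriate schemes:
    whole populations among groups for Phi_CT, bottom blocks among
    populations within groups for Phi_SC, units among populations for
    Phi_ST, and copies among individuals within populations for Phi_IS.
    """
    d2 = np.asarray(d2, dtype=float)
    if d2.shape[0] != d2.shape[1]:
        raise ValueError("distance matrix must be square")
    m = len(levels)
    if m not in (1, 2, 3):
        raise ValueError("supported designs have 1-3 nested levels")
    df, ss, sigma2 = _amova_components(d2, levels)
    total = np.nansum(sigma2)
    percent = [100 * s / total if total != 0 else np.nan for s in sigma2]
    phi = _phi_from_sigma(sigma2, m)
    res = AmovaResult(levels=_LEVEL_NAMES[m], df=df, ss=ss, sigma2=sigma2,
                      percent=percent, phi=phi, n_perm=n_perm)
    if n_perm > 0:
        res.p_values = _amova_permutations(d2, levels, phi, n_perm, seed)
    return res


def _perm_phi(d2: np.ndarray, levels: list[np.ndarray]) -> dict[str, float]:
    _, _, sigma2 = _amova_components(d2, levels)
    return _phi_from_sigma(sigma2, len(levels))


def _amova_permutations(d2, levels, phi_obs, n_perm, seed) -> dict[str, float]:
    rng = np.random.default_rng(seed)
    m = len(levels)
    parts = [np.asarray(lv) for lv in levels]
    n = d2.shape[0]
    hits = {k: 0 for k, v in phi_obs.items() if np.isfinite(v)}

    pop_level = parts[-1] if m <= 2 else parts[-2]
    group_level = parts[0] if m >= 2 else None

    for _ in range(n_perm):
        if "PhiST" in hits:
            # permute bottom blocks (units / individuals) among populations
            perm = _block_permutation(n, parts[-1] if m == 3 else None, rng,
                                      scope=np.zeros(n, dtype=int))
            lv = [p[perm] for p in parts[:-1]] + [parts[-1]] if m == 3 \
                else [p[perm] for p in parts]
            val = _perm_phi(d2, lv).get("PhiST", np.nan)
            if np.isfinite(val) and val >= phi_obs["PhiST"] - 1e-12:
                hits["PhiST"] += 1
        if m >= 2 and "PhiSC" in hits:
            # permute units/individuals among populations within groups
            perm = _block_permutation(n, parts[-1] if m == 3 else None, rng,
                                      scope=_codes(group_level))
            if m == 3:
                lv = [parts[0], parts[1][perm], parts[2]]
            else:
                lv = [parts[0], parts[1][perm]]
            val = _perm_phi(d2, lv).get("PhiSC", np.nan)
            if np.isfinite(val) and val >= phi_obs["PhiSC"] - 1e-12:
                hits["PhiSC"] += 1
        if m >= 2 and "PhiCT" in hits:
            # permute whole populations among groups
            pops = _codes(pop_level)
            pop_ids = np.unique(pops)
            pop_group = np.array([_codes(group_level)[pops == p][0]
                                  for p in pop_ids])
            shuffled = rng.permutation(pop_group)
            new_groups = shuffled[pops]
            lv = [new_groups] + [p for p in parts[1:]]
            val = _perm_phi(d2, lv).get("PhiCT", np.nan)
            if np.isfinite(val) and val >= phi_obs["PhiCT"] - 1e-12:
                hits["PhiCT"] += 1
        if m == 3 and "PhiIS" in hits:
            # permute allele copies among individuals within populations
            perm = np.arange(n)
            pops = _codes(parts[1])
            for p in np.unique(pops):
                idx = np.flatnonzero(pops == p)
                perm[idx] = rng.permutation(idx)
            lv = [parts[0], parts[1], parts[2][perm]]
            val = _perm_phi(d2, lv).get("PhiIS", np.nan)
            if np.isfinite(val) and val >= phi_obs["PhiIS"] - 1e-12:
                hits["PhiIS"] += 1
    return {k: (1 + h) / (n_perm + 1) for k, h in hits.items()}


def _block_permutation(n: int, blocks: np.ndarray | None,
                       rng: np.random.Generator,
                       scope: np.ndarray) -> np.ndarray:
    """Permute unit indices, keeping ``blocks`` together, within ``scope``."""
    perm = np.arange(n)
    if blocks is None:
        for s in np.unique(scope):
            idx = np.flatnonzero(scope == s)
            perm[idx] = rng.permutation(idx)
        return perm
    codes = _codes(blocks)
    for s in np.unique(scope):
        in_scope = np.flatnonzero(scope == s)
        blk = np.unique(codes[in_scope])
        order = rng.permutation(blk)
        starts = {b: np.flatnonzero(codes == b) for b in blk}
        new_idx = np.concatenate([starts[b] for b in order])
        perm[np.concatenate([starts[b] for b in blk])] = new_idx
    return perm


def amova(g: GenotypeMatrix, grouping: dict[str, str] | None = None,
          n_perm: int = 0, seed: int = 0) -> AmovaResult:
    """Four-level genotypic AMOVA (groups / populations / individuals /
    allele copies) from a genotype matrix.

    ``grouping`` maps population label -> group id; with one group the
    among-groups level collapses and a 3-level design over copies is used.
    """
    grouping = grouping or {p: "all" for p in g.populations}
    missing_pops = [p for p in g.populations if p not in grouping]
    if missing_pops:
        raise ValueError(f"populations without a group: {missing_pops}")
    copies, owner = allele_copy_matrix(g)
    d2 = copy_distance_matrix(copies)
    pops = np.array(g.pops)[owner]
    groups = np.array([grouping[p] for p in pops])
    inds = owner
    if len(set(grouping.values())) > 1:
        return amova_from_distance(d2, [groups, pops, inds], n_perm, seed)
    # no among-group level: populations / individuals / copies
    return _amova_three_over_copies(d2, pops, inds, n_perm, seed)


def _amova_three_over_copies(d2, pops, inds, n_perm, seed) -> AmovaResult:
    """Populations / individuals / copies design (no group level)."""
    df, ss, sigma2 = _amova_components(d2, [_codes(pops), _codes(inds)])
    total = sum(sigma2)
    percent = [100 * s / total if total != 0 else np.nan for s in sigma2]
    s = sigma2
    phi = {
        "PhiST": s[0] / total if total != 0 else np.nan,
        "PhiIS": s[1] / (s[1] + s[2]) if (s[1] + s[2]) != 0 else np.nan,
        "PhiIT": (s[0] + s[1]) / total if total != 0 else np.nan,
    }
    res = AmovaResult(
        levels=["Among populations", "Among individuals within populations",
                "Within individuals"],
        df=df, ss=ss, sigma2=sigma2, percent=percent, phi=phi, n_perm=n_perm)
    if n_perm:
        rng = np.random.default_rng(seed)
        hits = {k: 0 for k, v in phi.items() if np.isfinite(v)}
        n = d2.shape[0]
        for _ in range(n_perm):
            if "PhiST" in hits:
                perm = _block_permutation(n, inds, rng,
                                          scope=np.zeros(n, dtype=int))
                _, _, s2 = _amova_components(
                    d2, [_codes(pops)[perm], _codes(inds)])
                val = s2[0] / sum(s2) if sum(s2) != 0 else np.nan
                if np.isfinite(val) and val >= phi["PhiST"] - 1e-12:
                    hits["PhiST"] += 1
            if "PhiIS" in hits:
                perm = np.arange(n)
                pcodes = _codes(pops)
                for p in np.unique(pcodes):
                    idx = np.flatnonzero(pcodes == p)
                    perm[idx] = rng.permutation(idx)
                _, _, s2 = _amova_components(
                    d2, [_codes(pops), _codes(inds)[perm]])
                denom = s2[1] + s2[2]
                val = s2[1] / denom if denom != 0 else np.nan
                if np.isfinite(val) and val >= phi["PhiIS"] - 1e-12:
                    hits["PhiIS"] += 1
        res.p_values = {k: (1 + h) / (n_perm + 1) for k, h in hits.items()}
    return res


# ---------------------------------------------------------------------------
# Pairwise Fst
# ---------------------------------------------------------------------------


@dataclass
class FstResult:
    fst: float
    p: float
    wc_theta: float
    n_perm: int


def weir_cockerham_theta(g: GenotypeMatrix, pops: list[str] | None = None) -> float:
    """Multi-locus Weir & Cockerham (1984) theta across the given populations."""
    pops = pops or g.populations
    subs = [g.genotypes[g.pop_mask(p)] for p in pops]
    r = len(subs)
    if r < 2:
        raise ValueError("theta needs at least two populations")
    num = den = 0.0
    for j in range(g.n_loci):
        n_i, p_i, h_i = [], [], []
        for sub in subs:
            d = sub[:, j]
            d = d[d != MISSING]
            if d.size == 0:
                continue
            n_i.append(d.size)
            p_i.append((d == 2).sum() * 2 + (d == 1).sum())
            h_i.append((d == 1).sum())
        if len(n_i) < 2:
            continue
        n_i = np.array(n_i, dtype=float)
        p_i = np.array(p_i, dtype=float) / (2 * n_i)
        h_i = np.array(h_i, dtype=float) / n_i
        ri = n_i.size
        nbar = n_i.mean()
        if nbar <= 1:
            continue
        nc = (ri * nbar - (n_i ** 2).sum() / (ri * nbar)) / (ri - 1)
        pbar = (n_i * p_i).sum() / (ri * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((ri - 1) * nbar)
        hbar = (n_i * h_i).sum() / (ri * nbar)
        if nc == 0:
            continue
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (ri - 1) / ri
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (ri - 1) / ri
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den if den != 0 else np.nan


def pairwise_fst(g: GenotypeMatrix, pop_a: str, pop_b: str,
                 n_perm: int = 1000, seed: int = 0,
                 d2: np.ndarray | None = None) -> FstResult:
    """Fst between two populations as the two-level AMOVA Phi_ST.

    Distances are numbers of allele differences between individual
    multilocus genotypes; the permutation p-value shuffles individuals
    between the two populations (add-one estimator).  Weir-Cockerham theta
    is reported alongside for comparison.
    """
    mask = g.pop_mask(pop_a) | g.pop_mask(pop_b)
    if g.pop_mask(pop_a).sum() < 2 or g.pop_mask(pop_b).sum() < 2:
        raise ValueError("pairwise Fst needs >= 2 individuals per population")
    sub = g.subset(mask)
    d2 = genotype_distance_matrix(sub) if d2 is None else d2
    labels = np.array(sub.pops)
    res = amova_from_distance(d2, [labels], n_perm=0)
    fst = res.phi["PhiST"]
    theta = weir_cockerham_theta(sub, [pop_a, pop_b])
    if not np.isfinite(fst):  # zero total variance: Fst undefined
        return FstResult(fst=np.nan, p=np.nan, wc_theta=theta, n_perm=n_perm)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels.size)
        val = _perm_phi(d2, [labels[perm]])["PhiST"]
        if np.isfinite(val) and val >= fst - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return FstResult(fst=fst, p=p, wc_theta=theta, n_perm=n_perm)


def fst_matrix(g: GenotypeMatrix, n_perm: int = 1000, seed: int = 0,
               alpha: float = 0.05
               ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Lower-triangular Fst matrix with permutation p-values and a
    significance mask at the given alpha."""
    pops = g.populations
    k = len(pops)
    fst = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(k):
        fst[i, i] = 0.0
        for j in range(i):
            res = pairwise_fst(g, pops[j], pops[i], n_perm=n_perm,
                               seed=int(rng.integers(2 ** 31)))
            fst[i, j] = res.fst
            pval[i, j] = res.p
    f = pd.DataFrame(fst, index=pops, columns=pops)
    p = pd.DataFrame(pval, index=pops, columns=pops)
    return f, p, p < alpha


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------


@dataclass
class DapcResult:
    scores: np.ndarray            # individuals x discriminant axes
    eigenvalues: np.ndarray       # discriminant eigenvalues
    n_pcs: int
    pc_variance: np.ndarray       # explained-variance ratio of retained PCs
    loadings: np.ndarray          # loci x axes (in scaled-dosage space)
    groups: list[str]


def dapc(g: GenotypeMatrix, labels: list[str] | None = None,
         n_pcs: int | None = None,
         variance_target: float | None = None) -> DapcResult:
    """Discriminant analysis of principal components on allele dosages.

    Dosages (0/1/2, missing imputed to the locus mean) are centred and
    scaled; PCA retains ``n_pcs`` components or the smallest number whose
    cumulative explained variance reaches ``variance_target``; linear
    discriminant axes then maximise between/within group variance in the
    retained space (ridge-regularised when the within-group scatter is
    singular).
    """
    labels = list(labels) if labels is not None else list(g.pops)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("DAPC needs at least two groups")
    x = g.genotypes.astype(float)
    x[g.genotypes == MISSING] = np.nan
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    x -= x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    x /= sd
    n = x.shape[0]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    ev_ratio = s ** 2 / (s ** 2).sum()
    max_pcs = int((s > 1e-10).sum())
    if n_pcs is None:
        if variance_target is None:
            raise ValueError("give n_pcs or variance_target")
        k = int(np.searchsorted(np.cumsum(ev_ratio), variance_target) + 1)
    else:
        k = n_pcs
    if k >= n:
        raise ValueError("n_pcs must be smaller than the number of individuals")
    k = min(k, max_pcs)
    y = u[:, :k] * s[:k]
    lab = np.asarray(labels)
    grand = y.mean(axis=0)
    sw = np.zeros((k, k))
    sb = np.zeros((k, k))
    for grp in groups:
        yg = y[lab == grp]
        mg = yg.mean(axis=0)
        dev = yg - mg
        sw += dev.T @ dev
        sb += yg.shape[0] * np.outer(mg - grand, mg - grand)
    ridge = 1e-8 * np.trace(sw) / k if np.trace(sw) > 0 else 1e-8
    vals, vecs = eigh(sb, sw + ridge * np.eye(k))
    order = np.argsort(vals)[::-1][: len(groups) - 1]
    w = vecs[:, order]
    scores = y @ w
    loadings = vt[:k].T @ w
    return DapcResult(scores=scores, eigenvalues=vals[order], n_pcs=k,
                      pc_variance=ev_ratio[:k], loadings=loadings,
                      groups=groups)


# ---------------------------------------------------------------------------
# Admixture Gibbs sampler
# ---------------------------------------------------------------------------


@dataclass
class AdmixtureRun:
    K: int
    Q: np.ndarray                 # individuals x K posterior-mean membership
    freqs: np.ndarray             # K x loci posterior-mean allele-1 frequency
    log_likelihood: np.ndarray    # per-sweep trace (post-burn-in)
    mean_lnP: float
    seed: int
    burnin: int
    sweeps: int


def admixture_gibbs(g: GenotypeMatrix, K: int, burnin: int = 2000,
                    sweeps: int = 5000, seed: int = 0,
                    alpha_prior: float = 1.0) -> AdmixtureRun:
    """STRUCTURE-style admixture model fitted by Gibbs sampling.

    Latent cluster origins are sampled per allele copy; individual
    membership vectors get a symmetric Dirichlet(alpha) prior and cluster
    allele frequencies a uniform Beta prior.  The per-sweep log-likelihood
    ln P(X | Q, P) trace is recorded and its post-burn-in mean serves as
    the model-choice score for the Evanno procedure.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > g.n_individuals:
        raise ValueError("K exceeds the number of individuals")
    rng = np.random.default_rng(seed)
    dose = g.genotypes
    n, L = dose.shape
    observed = dose != MISSING
    # allele carried by each copy (phase arbitrary)
    allele = np.stack([(dose >= 1), (dose == 2)], axis=2).astype(np.int8)
    obs3 = np.repeat(observed[:, :, None], 2, axis=2)

    q = rng.dirichlet(np.full(K, alpha_prior), size=n)
    p = rng.uniform(0.2, 0.8, size=(K, L))
    q_acc = np.zeros((n, K))
    p_acc = np.zeros((K, L))
    trace = []
    for sweep in range(burnin + sweeps):
        # P(z = k | copy) ~ q_ik * p or (1 - p)
        af = allele[:, :, :, None]  # n,L,2,1
        pk = p.T[None, :, None, :]  # 1,L,1,K
        lik = np.where(af == 1, pk, 1.0 - pk)
        prob = lik * q[:, None, None, :]
        tot = prob.sum(axis=3, keepdims=True)
        prob = prob / np.maximum(tot, 1e-300)
        u = rng.random((n, L, 2, 1))
        z = (prob.cumsum(axis=3) < u).sum(axis=3)  # n,L,2 in 0..K-1
        counts_q = np.zeros((n, K))
        for k in range(K):
            counts_q[:, k] = ((z == k) & obs3).sum(axis=(1, 2))
        q = rng.gamma(alpha_prior + counts_q)
        q /= q.sum(axis=1, keepdims=True)
        for k in range(K):
            sel = (z == k) & obs3
            n1 = (sel & (allele == 1)).sum(axis=(0, 2))
            n0 = (sel & (allele == 0)).sum(axis=(0, 2))
            p[k] = rng.beta(1.0 + n1, 1.0 + n0)
        if sweep >= burnin:
            q_acc += q
            p_acc += p
            mix = q[:, None, None, :] * np.where(allele[:, :, :, None] == 1,
                                                 p.T[None, :, None, :],
                                                 1 - p.T[None, :, None, :])
            ll = np.log(np.maximum(mix.sum(axis=3), 1e-300))
            trace.append(float(ll[obs3].sum()))
    trace = np.array(trace)
    return AdmixtureRun(K=K, Q=q_acc / sweeps, freqs=p_acc / sweeps,
                        log_likelihood=trace, mean_lnP=float(trace.mean()),
                        seed=seed, burnin=burnin, sweeps=sweeps)


def evanno_delta_k(runs: list[AdmixtureRun]) -> pd.DataFrame:
    """Evanno table: mean lnP(X|K), its s.d. across replicates and Delta K.

    Delta K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K));
    undefined (NaN) at the endpoints and where the replicate s.d. is zero.
    """
    by_k: dict[int, list[float]] = {}
    for run in runs:
        by_k.setdefault(run.K, []).append(run.mean_lnP)
    ks = sorted(by_k)
    if len(ks) < 3 or any(ks[i + 1] - ks[i] != 1 for i in range(len(ks) - 1)):
        raise ValueError("Evanno needs >= 3 consecutive K values")
    if any(len(v) < 2 for v in by_k.values()):
        raise ValueError("Evanno needs >= 2 replicates per K")
    mean = {k: float(np.mean(by_k[k])) for k in ks}
    sd = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        if k == ks[0] or k == ks[-1]:
            dk = np.nan
        else:
            second = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
            dk = second / sd[k] if sd[k] > 0 else np.nan
        rows.append({"K": k, "n_reps": len(by_k[k]), "mean_lnP": mean[k],
                     "sd_lnP": sd[k], "deltaK": dk})
    return pd.DataFrame(rows)


def align_cluster_labels(runs: list[AdmixtureRun],
                         method: str = "exhaustive"
                         ) -> tuple[list[AdmixtureRun], np.ndarray]:
    """Align cluster labels across replicate runs and build a consensus Q.

    Each run's clusters are permuted to maximise the summed element-wise
    agreement of its Q matrix with the first run's; ``exhaustive`` searches
    all K! permutations (K <= 6), ``greedy`` picks columns sequentially by
    best match.  Returns the aligned runs and the element-wise mean Q.
    """
    if not runs:
        raise ValueError("no runs to align")
    K = runs[0].K
    ref = runs[0].Q
    aligned = [runs[0]]
    for run in runs[1:]:
        if run.K != K or run.Q.shape != ref.shape:
            raise ValueError("runs must share K and individuals")
        if method == "exhaustive":
            if K > 6:
                raise ValueError("exhaustive alignment supports K <= 6")
            best, best_score = None, -np.inf
            for perm in itertools.permutations(range(K)):
                score = float((ref * run.Q[:, perm]).sum())
                if score > best_score:
                    best, best_score = perm, score
            perm = list(best)
        elif method == "greedy":
            # optimal column assignment (Hungarian); because the objective
            # is a sum of per-column agreements this always attains the
            # exhaustive-search score at any K
            from scipy.optimize import linear_sum_assignment

            sim = ref.T @ run.Q
            rows, cols = linear_sum_assignment(-sim)
            perm = [int(cols[np.flatnonzero(rows == i)[0]]) for i in range(K)]
        else:
            raise ValueError(f"unknown method {method!r}")
        aligned.append(AdmixtureRun(
            K=K, Q=run.Q[:, perm], freqs=run.freqs[perm],
            log_likelihood=run.log_likelihood, mean_lnP=run.mean_lnP,
            seed=run.seed, burnin=run.burnin, sweeps=run.sweeps))
    consensus = np.mean([r.Q for r in aligned], axis=0)
    return aligned, consensus
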