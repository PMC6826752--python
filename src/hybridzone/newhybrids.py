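"""Bayesian assignment of individuals to six genealogical classes.

The model follows the classic two-species hybrid-category framework: each
individual belongs to one of pure A, pure B, F1, F2, backcross-to-A or
backcross-to-B, and each class fixes the expected proportions of per-locus
ancestry pairs (both alleles from A, one from each, both from B).  A Gibbs
sampler alternates between per-locus ancestry pairs, per-individual classes
and the two species' allele frequencies (Dirichlet posterior under a
Uniform or Jeffreys prior).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .synthetic import CLASS_TABLE, CLASSES

PRIORS = {"uniform": 1.0, "jeffreys": 0.5}


@dataclass
class GenealogyModel:
    """Six-class genealogy model with prior choices.

    ``class_table`` rows give, per class, the expected proportion of loci
    whose ancestry pair is (A,A), (A,B), (B,B); ``freq_prior`` selects the
    Dirichlet prior on species allele frequencies (uniform = Dir(1,1),
    jeffreys = Dir(1/2,1/2)); ``class_prior`` is the prior over the six
    classes (uniform by default).
    """

    freq_prior: str = "uniform"
    class_prior: np.ndarray = field(
        default_factory=lambda: np.full(len(CLASSES), 1.0 / len(CLASSES)))

    def __post_init__(self) -> None:
        if self.freq_prior not in PRIORS:
            raise ValueError("freq_prior must be 'uniform' or 'jeffreys'")
        self.class_prior = np.asarray(self.class_prior, dtype=float)
        if self.class_prior.shape != (len(CLASSES),) or \
                not np.isclose(self.class_prior.sum(), 1.0):
            raise ValueError("class_prior must be a simplex over six classes")

    @property
    def table(self) -> np.ndarray:
        return np.array([CLASS_TABLE[c] for c in CLASSES])


@dataclass
class HybridPosterior:
    """Per-individual posterior over the six genealogical classes."""

    ids: list[str]
    pops: list[str]
    classes: list[str]
    posterior: np.ndarray        # individuals x 6, rows sum to 1
    freq_a: np.ndarray           # posterior-mean allele-1 frequency, species A
    freq_b: np.ndarray
    sweeps: int
    burnin: int
    seed: int

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.posterior, columns=self.classes)
        df.insert(0, "population", self.pops)
        df.insert(0, "id", self.ids)
        return df


def _genotype_lik(freq_a: np.ndarray, freq_b: np.ndarray) -> np.ndarray:
    """lik[w, l, g]: genotype probability given ancestry pair and freqs."""
    pa, qa = freq_a, 1 - freq_a
    pb, qb = freq_b, 1 - freq_b
    L = freq_a.size
    lik = np.empty((3, L, 3))
    lik[0] = np.stack([qa ** 2, 2 * pa * qa, pa ** 2], axis=1)        # (A,A)
    lik[1] = np.stack([qa * qb, pa * qb + qa * pb, pa * pb], axis=1)  # (A,B)
    lik[2] = np.stack([qb ** 2, 2 * pb * qb, pb ** 2], axis=1)        # (B,B)
    return lik


def newhybrids_gibbs(g: GenotypeMatrix,
                     model: GenealogyModel | None = None,
                     burnin: int = 2000, sweeps: int = 8000, seed: int = 0,
                     known_parentals: dict[str, list[int]] | None = None
                     ) -> HybridPosterior:
    """Gibbs sampler over classes, per-locus ancestry pairs and frequencies.

    ``known_parentals`` optionally maps "A"/"B" to individual indices whose
    class is clamped to the corresponding pure class; this anchors the
    species labels.  Without it, labels are fixed after sampling by the
    convention that the first population's majority class is pure A.
    Missing genotypes contribute no likelihood at that locus.
    """
    model = model or GenealogyModel()
    if burnin <= 0 or sweeps <= 0:
        raise ValueError("chain settings must be positive")
    if g.n_individuals < 1:
        raise ValueError("need at least one individual")
    rng = np.random.default_rng(seed)
    dose = g.genotypes
    n, L = dose.shape
    observed = dose != MISSING
    gsafe = np.where(observed, dose, 0).astype(int)
    table = model.table                      # 6 x 3
    log_class_prior = np.log(model.class_prior)
    prior = PRIORS[model.freq_prior]

    clamped = np.full(n, -1, dtype=int)
    if known_parentals:
        for label, cls in (("A", CLASSES.index("pureA")),
                           ("B", CLASSES.index("pureB"))):
            for idx in known_parentals.get(label, []):
                if not 0 <= idx < n:
                    raise IndexError(f"known_parentals index {idx} out of range")
                clamped[idx] = cls

    # initial state
    freq = dose[dose != MISSING].mean() / 2 if observed.any() else 0.5
    fa = np.clip(rng.normal(min(freq + 0.2, 0.9), 0.05, L), 0.05, 0.95)
    fb = np.clip(rng.normal(max(freq - 0.2, 0.1), 0.05, L), 0.05, 0.95)
    z = np.where(clamped >= 0, clamped, rng.integers(0, 6, size=n))

    post_counts = np.zeros((n, 6))
    fa_acc = np.zeros(L)
    fb_acc = np.zeros(L)
    # log of zero entries is a large negative finite value so that the
    # class log-probability matmul stays NaN-free (0 * -inf traps)
    log_table = np.log(np.maximum(table, 1e-300))

    for sweep in range(burnin + sweeps):
        lik = _genotype_lik(fa, fb)                       # 3 x L x 3
        lik_obs = lik[:, np.arange(L)[None, :], gsafe]     # 3 x n x L
        lik_obs = np.transpose(lik_obs, (1, 2, 0))         # n x L x 3

        # (a) classes with the per-locus ancestry pair marginalised out:
        # P(z | g, f) ~ prior(z) * prod_l sum_w T[z, w] P(g_l | w, f);
        # sampling z from the marginal and then w | z is a blocked Gibbs
        # move — updating z given a sampled w would freeze the chain in
        # the deterministic classes (pure, F1) whose ancestry is forced
        per_locus = np.einsum("nlw,cw->nlc", lik_obs, table)   # n x L x 6
        loglik = np.where(observed[:, :, None],
                          np.log(np.maximum(per_locus, 1e-300)), 0.0).sum(axis=1)
        logp = log_class_prior[None, :] + loglik
        logp -= logp.max(axis=1, keepdims=True)
        pz = np.exp(logp)
        pz /= pz.sum(axis=1, keepdims=True)
        uz = rng.random((n, 1))
        z = (pz.cumsum(axis=1) < uz).sum(axis=1)
        z = np.where(clamped >= 0, clamped, z)

        # (b) ancestry pairs given class, genotype, freqs
        w_prior = table[z][:, None, :]                     # n x 1 x 3
        prob = np.where(observed[:, :, None], lik_obs, 1.0) * w_prior
        tot = prob.sum(axis=2, keepdims=True)
        prob = prob / np.maximum(tot, 1e-300)
        u = rng.random((n, L, 1))
        w = (prob.cumsum(axis=2) < u).sum(axis=2)          # n x L in {0,1,2}

        # (c) species frequencies from allele copies attributed per species
        # w=0: both copies -> A; w=2: both -> B; w=1: one each, with the
        # heterozygous orientation sampled from its conditional
        is_aa = (w == 0) & observed
        is_bb = (w == 2) & observed
        is_ab = (w == 1) & observed
        a1_a = (gsafe * is_aa).sum(axis=0).astype(float)
        a2_a = ((2 - gsafe) * is_aa).sum(axis=0).astype(float)
        a1_b = (gsafe * is_bb).sum(axis=0).astype(float)
        a2_b = ((2 - gsafe) * is_bb).sum(axis=0).astype(float)
        hom2 = is_ab & (gsafe == 2)     # allele 1 to both species
        hom0 = is_ab & (gsafe == 0)     # allele 2 to both species
        a1_a += hom2.sum(axis=0)
        a1_b += hom2.sum(axis=0)
        a2_a += hom0.sum(axis=0)
        a2_b += hom0.sum(axis=0)
        het = is_ab & (gsafe == 1)
        if het.any():
            p_orient = fa * (1 - fb)
            denom = p_orient + (1 - fa) * fb
            p_orient = np.where(denom > 0, p_orient / denom, 0.5)
            orient = rng.random((n, L)) < p_orient[None, :]
            to_a1 = (het & orient).sum(axis=0)      # allele1 from A
            to_b1 = (het & ~orient).sum(axis=0)     # allele1 from B
            a1_a += to_a1
            a2_b += to_a1
            a1_b += to_b1
            a2_a += to_b1
        fa = rng.beta(prior + a1_a, prior + a2_a)
        fb = rng.beta(prior + a1_b, prior + a2_b)

        if sweep >= burnin:
            post_counts[np.arange(n), z] += 1
            fa_acc += fa
            fb_acc += fb

    posterior = post_counts / sweeps
    fa_mean = fa_acc / sweeps
    fb_mean = fb_acc / sweeps

    if not known_parentals:
        posterior, fa_mean, fb_mean = _anchor_labels(
            g, posterior, fa_mean, fb_mean)
    return HybridPosterior(ids=list(g.ids), pops=list(g.pops),
                           classes=list(CLASSES), posterior=posterior,
                           freq_a=fa_mean, freq_b=fb_mean,
                           sweeps=sweeps, burnin=burnin, seed=seed)


def _anchor_labels(g, posterior, fa, fb):
    """Resolve A/B label switching: population 1's majority is pure A."""
    first = g.populations[0]
    mask = g.pop_mask(first)
    mean_post = posterior[mask].mean(axis=0)
    if mean_post[CLASSES.index("pureB")] > mean_post[CLASSES.index("pureA")]:
        swap = [CLASSES.index(c) for c in
                ("pureB", "pureA", "F1", "F2", "BxB", "BxA")]
        posterior = posterior[:, swap]
        fa, fb = fb, fa
    return posterior, fa, fb


def assign_classes(post: HybridPosterior, threshold: float = 0.5
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign individuals whose maximum posterior strictly exceeds the
    threshold; others are "unassigned".

    Returns (assignments, composition): per-individual assignments and the
    per-population percentage of individuals in each class.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    rows = np.asarray(post.posterior)
    if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("posterior rows must sum to 1")
    best = rows.argmax(axis=1)
    assigned = np.where(rows[np.arange(len(rows)), best] > threshold,
                        np.array(post.classes)[best], "unassigned")
    table = pd.DataFrame({"id": post.ids, "population": post.pops,
                          "assigned_class": assigned,
                          "max_posterior": rows.max(axis=1)})
    comp = (table.groupby(["population", "assigned_class"]).size()
            .unstack(fill_value=0))
    comp = comp.div(comp.sum(axis=1), axis=0) * 100
    return table, comp
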