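"""Synthetic two-species hybrid-zone data with machine-readable ground truth.

Emulates the study system: two parental gene pools of annual killifish that
share a fraction of fixed allelic differences, hybrid ponds containing F1,
F2 and first-generation backcross individuals, pooled transcriptome
sequencing of each species plus the hybrid zone (binomial read counts with a
symmetric per-base error), and a two-clade mitochondrial alignment separated
by a configurable number of step mutations.

Every generator takes an explicit seed and the full determinism contract
holds: identical (config, seed) produce byte-identical on-disk bundles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, write_csv, write_genepop, write_structure

BASES = np.array(["A", "C", "G", "T"])

#: six genealogical classes -> expected proportions of per-locus ancestry
#: pairs (A,A), (A,B), (B,B)
CLASS_TABLE: dict[str, tuple[float, float, float]] = {
    "pureA": (1.0, 0.0, 0.0),
    "pureB": (0.0, 0.0, 1.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "BxA": (0.5, 0.5, 0.0),
    "BxB": (0.0, 0.5, 0.5),
}
CLASSES = list(CLASS_TABLE)


@dataclass
class SpeciesPairModel:
    """Data-generating assumptions for the species pair.

    Parameters
    ----------
    n_loci : int
        Number of SNP sites simulated.
    prop_fixed_diff : float
        Expected fraction of loci fixed for alternative alleles between the
        species (diagnostic loci).
    nondiagnostic_freq_range : (float, float)
        Per-species allele-1 frequency at non-diagnostic loci is drawn
        independently and uniformly from this interval.
    seq_error_rate : float
        Per-base probability that a pooled read reports the wrong allele.
    pool_depth_mean, pool_depth_dispersion : float
        Per-site read depth is negative-binomial with this mean and
        dispersion (variance = mean + mean^2/dispersion), clipped to
        [pool_depth_min, pool_depth_max].
    mt_length : int
        Alignment length of the mitochondrial marker (bp).
    mt_interclade_steps : int
        Substitutions separating the two clade centroid sequences.
    mt_intraclade_mutations : float
        Expected Poisson number of private substitutions per sequence.
    seed : int
        Base seed for all draws.
    """

    n_loci: int = 1000
    prop_fixed_diff: float = 0.1
    nondiagnostic_freq_range: tuple[float, float] = (0.05, 0.95)
    seq_error_rate: float = 0.0
    pool_depth_mean: float = 80.0
    pool_depth_dispersion: float = 10.0
    pool_depth_min: int = 20
    pool_depth_max: int = 200
    mt_length: int = 795
    mt_interclade_steps: int = 51
    mt_intraclade_mutations: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop_fixed_diff <= 1.0:
            raise ValueError("prop_fixed_diff must lie in [0, 1]")
        if not 0.0 <= self.seq_error_rate <= 1.0:
            raise ValueError("seq_error_rate must lie in [0, 1]")
        lo, hi = self.nondiagnostic_freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("nondiagnostic_freq_range must be within [0, 1]")
        for name in ("n_loci", "mt_length", "mt_interclade_steps",
                     "pool_depth_min", "pool_depth_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mt_interclade_steps >= self.mt_length:
            raise ValueError("mt_interclade_steps must be < mt_length")


def draw_parental_freqs(model: SpeciesPairModel,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-locus parental allele frequencies and diagnostic truth flags.

    A locus is diagnostic when one species carries allele 1 at frequency 1.0
    and the other at 0.0 (direction randomised); the rest get independent
    uniform frequencies, which exercises "nearly fixed" edge cases.
    """
    rng = np.random.default_rng(model.seed) if rng is None else rng
    n = model.n_loci
    diagnostic = rng.random(n) < model.prop_fixed_diff
    lo, hi = model.nondiagnostic_freq_range
    freq_a = rng.uniform(lo, hi, size=n)
    freq_b = rng.uniform(lo, hi, size=n)
    direction = rng.random(n) < 0.5
    freq_a[diagnostic] = np.where(direction[diagnostic], 1.0, 0.0)
    freq_b[diagnostic] = np.where(direction[diagnostic], 0.0, 1.0)
    # allele identities: pick two distinct bases per locus
    base1 = rng.integers(0, 4, size=n)
    base2 = (base1 + rng.integers(1, 4, size=n)) % 4
    return pd.DataFrame({
        "locus": [f"SNP_{i + 1:04d}" for i in range(n)],
        "freqA": freq_a,
        "freqB": freq_b,
        "allele1": BASES[base1],
        "allele2": BASES[base2],
        "diagnostic": diagnostic,
    })


def simulate_class_genotypes(freqs_a: np.ndarray, freqs_b: np.ndarray,
                             genealogical_class: str, n_ind: int,
                             seed: int | np.random.Generator = 0,
                             loci: list[str] | None = None,
                             pop: str = "pop1",
                             id_prefix: str | None = None) -> GenotypeMatrix:
    """Simulate diploid genotypes for one genealogical class.

    Each individual draws, per locus, an ancestry pair from the class's
    expected mixture and then one allele from each ancestral species'
    frequency (Mendelian expectations; loci independent).
    """
    if genealogical_class not in CLASS_TABLE:
        raise ValueError(f"unknown genealogical class {genealogical_class!r}")
    freqs_a = np.asarray(freqs_a, dtype=float)
    freqs_b = np.asarray(freqs_b, dtype=float)
    if freqs_a.shape != freqs_b.shape:
        raise ValueError("parental frequency tables must share loci")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n_loci = freqs_a.size
    probs = np.array(CLASS_TABLE[genealogical_class])
    ancestry = rng.choice(3, size=(n_ind, n_loci), p=probs)  # 0=AA,1=AB,2=BB
    # copy 1 is the "maternal" copy: species A for ancestry AA/AB, B for BB
    f1 = np.where(ancestry <= 1, freqs_a, freqs_b)
    f2 = np.where(ancestry == 0, freqs_a, freqs_b)
    dosage = (rng.random((n_ind, n_loci)) < f1).astype(np.int8)
    dosage += (rng.random((n_ind, n_loci)) < f2).astype(np.int8)
    prefix = id_prefix if id_prefix is not None else pop
    ids = [f"{prefix}_{i + 1:03d}" for i in range(n_ind)]
    loci = loci if loci is not None else [f"SNP_{j + 1:04d}" for j in range(n_loci)]
    return GenotypeMatrix(ids, [pop] * n_ind, list(loci), dosage)


def _draw_depths(model: SpeciesPairModel, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    r = model.pool_depth_dispersion
    p = r / (r + model.pool_depth_mean)
    depth = rng.negative_binomial(r, p, size=n)
    return np.clip(depth, model.pool_depth_min, model.pool_depth_max)


def simulate_pool_counts(pool_freqs: pd.DataFrame, model: SpeciesPairModel,
                         rng: np.random.Generator | None = None,
                         contig_length: int = 2000) -> pd.DataFrame:
    """Simulate a per-site base-count table for the three pooled samples.

    ``pool_freqs`` needs columns locus/allele1/allele2 plus one allele-1
    frequency column per pool (speciesA, speciesB, hybrid).  Depth is drawn
    per site and pool; the allele-1 read count is binomial(depth, f') with
    f' = f(1-e) + (1-f)e for symmetric error e.  Sites are placed on
    synthetic contigs (one site per contig by default) so flank filtering is
    exercised downstream; no depth filtering happens here.
    """
    rng = np.random.default_rng(model.seed + 1) if rng is None else rng
    pools = ["speciesA", "speciesB", "hybrid"]
    n = len(pool_freqs)
    e = model.seq_error_rate
    pos = rng.integers(1, contig_length + 1, size=n)
    out = {
        "contig": [f"contig_{i + 1:05d}" for i in range(n)],
        "pos": pos,
        "contig_length": np.full(n, contig_length),
        "ref": pool_freqs["allele1"].to_numpy(),
        "locus": pool_freqs["locus"].to_numpy(),
    }
    b1 = pool_freqs["allele1"].to_numpy()
    b2 = pool_freqs["allele2"].to_numpy()
    for pool in pools:
        f = pool_freqs[pool].to_numpy(dtype=float)
        f_err = f * (1 - e) + (1 - f) * e
        depth = _draw_depths(model, n, rng)
        c1 = rng.binomial(depth, f_err)
        counts = {b: np.zeros(n, dtype=int) for b in "ACGT"}
        for i in range(n):
            counts[b1[i]][i] += c1[i]
            counts[b2[i]][i] += depth[i] - c1[i]
        for b in "ACGT":
            out[f"{pool}_{b}"] = counts[b]
    return pd.DataFrame(out)


def simulate_mtdna_alignment(model: SpeciesPairModel,
                             pop_sizes: dict[str, int],
                             clade_assignment: dict[str, str],
                             seed: int | None = None
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a gap-free two-clade mitochondrial alignment.

    Two clade centroids differ at exactly ``mt_interclade_steps`` positions;
    each sequence adds Poisson(``mt_intraclade_mutations``) private
    substitutions at columns outside the centroid-difference set.

    Returns (alignment, truth): alignment has columns id/population/sequence,
    truth has id/clade.
    """
    rng = np.random.default_rng(model.seed + 2 if seed is None else seed)
    L = model.mt_length
    centroid_a = rng.integers(0, 4, size=L)
    diff_cols = rng.choice(L, size=model.mt_interclade_steps, replace=False)
    centroid_b = centroid_a.copy()
    centroid_b[diff_cols] = (centroid_b[diff_cols]
                             + rng.integers(1, 4, size=diff_cols.size)) % 4
    free_cols = np.setdiff1d(np.arange(L), diff_cols)
    rows = []
    truth = []
    for pop, n in pop_sizes.items():
        clade = clade_assignment[pop]
        if clade not in ("A", "B"):
            raise ValueError("clade_assignment values must be 'A' or 'B'")
        centroid = centroid_a if clade == "A" else centroid_b
        for k in range(n):
            seq = centroid.copy()
            n_mut = rng.poisson(model.mt_intraclade_mutations)
            n_mut = min(n_mut, free_cols.size)
            if n_mut:
                cols = rng.choice(free_cols, size=n_mut, replace=False)
                seq[cols] = (seq[cols] + rng.integers(1, 4, size=n_mut)) % 4
            sid = f"{pop}_mt{k + 1:03d}"
            rows.append({"id": sid, "population": pop,
                         "sequence": "".join(BASES[seq])})
            truth.append({"id": sid, "clade": clade})
    return pd.DataFrame(rows), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

#: study design: 2 parental ponds + 6 hybrid-zone ponds with class mixtures
DEFAULT_POP_DESIGN: dict[str, dict] = {
    "CH66": {"n": 10, "classes": {"pureA": 1.0}, "clade": "A"},
    "CH43": {"n": 14, "classes": {"pureB": 1.0}, "clade": "B"},
    "CH60": {"n": 21, "classes": {"F2": 0.6, "BxA": 0.2, "pureA": 0.2},
             "clade": "A"},
    "CH54-61": {"n": 12, "classes": {"pureA": 0.8, "BxA": 0.2}, "clade": "A"},
    "CHN3": {"n": 8, "classes": {"pureA": 0.8, "F2": 0.2}, "clade": "A"},
    "CHN4": {"n": 7, "classes": {"pureA": 1.0}, "clade": "A"},
    "CHN6": {"n": 12, "classes": {"F2": 0.5, "BxB": 0.3, "pureB": 0.2},
             "clade": "B"},
    "CH64": {"n": 10, "classes": {"pureA": 0.8, "BxA": 0.2}, "clade": "A"},
}


@dataclass
class FixtureConfig:
    """Configuration of a full on-disk fixture bundle."""

    model: SpeciesPairModel = field(default_factory=SpeciesPairModel)
    n_panel_loci: int = 106
    pop_design: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_POP_DESIGN.items()})
    panel_missing_rate: float = 0.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["model"]["nondiagnostic_freq_range"] = list(
            d["model"]["nondiagnostic_freq_range"])
        return d


def _panel_truth_classes(config: FixtureConfig,
                         rng: np.random.Generator) -> list[tuple[str, str]]:
    """(population, class) per individual; deterministic rounded mixtures."""
    out = []
    for pop, d in config.pop_design.items():
        n = d["n"]
        classes = list(d["classes"])
        weights = np.array([d["classes"][c] for c in classes], dtype=float)
        weights = weights / weights.sum()
        counts = np.floor(weights * n).astype(int)
        while counts.sum() < n:
            counts[int(np.argmax(weights * n - counts))] += 1
        for cls, k in zip(classes, counts):
            out.extend((pop, cls) for _ in range(k))
    return out


def generate_fixture_bundle(config: FixtureConfig, outdir: str | Path) -> dict:
    """Write the full self-describing fixture bundle and return its truth.

    Files: pool_counts.tsv, genotypes.{genepop,str,csv}, mtdna.fasta,
    mtdna_pops.tsv and truth.json (config echo + per-locus, per-individual
    and per-sequence truth).
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {outdir}: {exc}") from exc
    model = config.model
    rng = np.random.default_rng(model.seed)

    # 1. discovery substrate: parental freqs + pooled counts over all sites
    freqs = draw_parental_freqs(model, rng)
    pool_freqs = freqs.copy()
    pool_freqs["speciesA"] = freqs["freqA"]
    pool_freqs["speciesB"] = freqs["freqB"]
    pool_freqs["hybrid"] = 0.5 * (freqs["freqA"] + freqs["freqB"])
    pool_table = simulate_pool_counts(pool_freqs, model, rng)
    pool_table.to_csv(outdir / "pool_counts.tsv", sep="\t", index=False)

    # 2. SNP panel genotypes: diagnostic loci from the discovery draw,
    # topped up with panel-only diagnostic loci when the draw is short
    # (the validated assay panel is all-diagnostic by construction)
    diag = freqs[freqs["diagnostic"]].head(config.n_panel_loci)
    fa = diag["freqA"].to_numpy()
    fb = diag["freqB"].to_numpy()
    source = list(diag["locus"])
    short = config.n_panel_loci - len(diag)
    if short > 0:
        direction = rng.random(short) < 0.5
        fa = np.concatenate([fa, direction.astype(float)])
        fb = np.concatenate([fb, 1.0 - direction.astype(float)])
        source += [f"panel_only_{k + 1:03d}" for k in range(short)]
    panel_loci = [f"SNP_{j + 1:03d}" for j in range(config.n_panel_loci)]
    assignments = _panel_truth_classes(config, rng)
    parts = []
    ind_truth = []
    counter: dict[str, int] = {}
    for pop, cls in assignments:
        counter[pop] = counter.get(pop, 0) + 1
        gm = simulate_class_genotypes(fa, fb, cls, 1, rng, loci=panel_loci,
                                      pop=pop)
        iid = f"{pop}_{counter[pop]:03d}"
        gm.ids = [iid]
        parts.append(gm)
        ind_truth.append({"id": iid, "population": pop, "class": cls})
    genotypes = np.vstack([p.genotypes for p in parts])
    if config.panel_missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.panel_missing_rate
        genotypes[mask] = MISSING
    gm = GenotypeMatrix(ids=[p.ids[0] for p in parts],
                        pops=[p.pops[0] for p in parts],
                        loci=panel_loci, genotypes=genotypes)
    write_genepop(gm, str(outdir / "genotypes.genepop"))
    write_structure(gm, str(outdir / "genotypes.str"))
    write_csv(gm, str(outdir / "genotypes.csv"))

    # 3. mtDNA alignment
    pop_sizes = {p: d["n"] for p, d in config.pop_design.items()}
    clades = {p: d["clade"] for p, d in config.pop_design.items()}
    aln, mt_truth = simulate_mtdna_alignment(model, pop_sizes, clades)
    with open(outdir / "mtdna.fasta", "w", encoding="utf-8") as fh:
        for _, row in aln.iterrows():
            fh.write(f">{row['id']}\n{row['sequence']}\n")
    aln[["id", "population"]].to_csv(outdir / "mtdna_pops.tsv", sep="\t",
                                     index=False)

    truth = {
        "config": config.to_dict(),
        "loci": freqs.assign(diagnostic=freqs["diagnostic"].astype(bool))
                     .to_dict(orient="records"),
        "panel_loci": [
            {"panel_locus": pl, "source_locus": sl}
            for pl, sl in zip(panel_loci, source)],
        "individuals": ind_truth,
        "mt_clades": mt_truth.to_dict(orient="records"),
    }
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, default=float)
    return truth
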