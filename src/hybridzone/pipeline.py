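"""End-to-end pipeline: simulate -> discover -> diversity -> structure ->
classify -> mtdna, with a reproducible manifest.

Every stage seeds its randomness from the global seed through a documented
derivation (``stage_seed = SeedSequence(global_seed).spawn``-style integer
hashing), so stages can be rerun individually and the whole bundle is
byte-reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discovery import DiscoveryParams, call_diagnostic_snps, export_panel, filter_flanks
from .diversity import bonferroni, ld_genotypic_test, population_summary
from .genotypes import read_genepop
from .mtdna import (collapse_haplotypes, diversity_table, median_joining_network,
                    read_alignment, write_network)
from .newhybrids import GenealogyModel, assign_classes, newhybrids_gibbs
from .structure import (admixture_gibbs, amova, amova_from_distance,
                        align_cluster_labels, dapc, evanno_delta_k, fst_matrix)
from .synthetic import FixtureConfig, generate_fixture_bundle

STAGES = ("simulate", "discover", "diversity", "structure", "classify", "mtdna")


@dataclass
class PipelineConfig:
    """All pipeline parameters with study-anchored defaults.

    Defaults mirror the published protocol: coverage 10-8000, hybrid
    minor-allele frequency 0.10, 100-bp flanks, 1000 permutations,
    posterior-assignment threshold 0.5 and alpha 0.05; chain lengths
    default to a scaled-down preset suitable for desk-scale runs.
    """

    outdir: str = "results/pipeline"
    seed: int = 1
    stages: tuple[str, ...] = STAGES
    fixture: FixtureConfig = field(default_factory=FixtureConfig)
    discovery: DiscoveryParams = field(default_factory=DiscoveryParams)
    n_perm: int = 1000
    alpha: float = 0.05
    admixture_ks: tuple[int, ...] = (1, 2, 3, 4, 5)
    admixture_reps: int = 3
    admixture_burnin: int = 300
    admixture_sweeps: int = 700
    classify_burnin: int = 2000
    classify_sweeps: int = 8000
    assignment_threshold: float = 0.5
    grouping: dict[str, str] | None = None

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        child = np.random.SeedSequence(
            entropy=self.seed, spawn_key=(STAGES.index(stage),))
        return int(child.generate_state(1)[0] % (2 ** 31))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["admixture_ks"] = list(self.admixture_ks)
        d["fixture"] = self.fixture.to_dict()
        return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages and write the report bundle.

    Returns the manifest (also written as manifest.json).  Stage failures
    abort the run; the manifest records the stages completed so far.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": config.to_dict(), "completed": [],
                      "timings_s": {}}
    state: dict = {}
    try:
        for stage in config.stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            t0 = time.perf_counter()
            _STAGE_FUNCS[stage](config, out, state)
            manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
            manifest["completed"].append(stage)
    finally:
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _stage_simulate(config: PipelineConfig, out: Path, state: dict) -> None:
    fixture = dataclasses.replace(
        config.fixture,
        model=dataclasses.replace(config.fixture.model,
                                  seed=config.stage_seed("simulate")))
    state["truth"] = generate_fixture_bundle(fixture, out / "fixture")
    state["fixture_dir"] = out / "fixture"


def _stage_discover(config: PipelineConfig, out: Path, state: dict) -> None:
    fdir = state.get("fixture_dir", out / "fixture")
    table = pd.read_csv(fdir / "pool_counts.tsv", sep="\t")
    calls = call_diagnostic_snps(table, config.discovery)
    lengths = dict(zip(table["contig"], table["contig_length"]))
    calls = filter_flanks(calls, lengths, params=config.discovery)
    export_panel(calls, str(out / "panel.vcf"), str(out / "panel_sheet.tsv"),
                 contig_lengths=lengths)
    state["calls"] = calls


def _load_genotypes(state: dict, out: Path):
    if "genotypes" not in state:
        fdir = state.get("fixture_dir", out / "fixture")
        state["genotypes"] = read_genepop(str(fdir / "genotypes.genepop"))
    return state["genotypes"]


def _stage_diversity(config: PipelineConfig, out: Path, state: dict) -> None:
    g = _load_genotypes(state, out)
    summary = population_summary(g)
    summary.to_csv(out / "table1_diversity.tsv", sep="\t", index=False,
                   na_rep="NA")
    # genotypic LD across the first locus pairs per population (screen)
    rows = []
    seed = config.stage_seed("diversity")
    for pop in g.populations:
        for j in range(min(5, g.n_loci - 1)):
            res = ld_genotypic_test(g, pop, g.loci[j], g.loci[j + 1],
                                    n_perm=200, seed=seed)
            rows.append({"population": pop, "locusA": g.loci[j],
                         "locusB": g.loci[j + 1],
                         "p": res.p if res.defined else np.nan})
    ld = pd.DataFrame(rows)
    mask, threshold = bonferroni(ld["p"].fillna(1.0), config.alpha)
    ld["significant_bonferroni"] = mask
    ld.to_csv(out / "ld_tests.tsv", sep="\t", index=False, na_rep="NA")
    state["ld_threshold"] = threshold


def _stage_structure(config: PipelineConfig, out: Path, state: dict) -> None:
    g = _load_genotypes(state, out)
    seed = config.stage_seed("structure")
    fst, pvals, sig = fst_matrix(g, n_perm=config.n_perm, seed=seed,
                                 alpha=config.alpha)
    fst.to_csv(out / "table3_fst.tsv", sep="\t", na_rep="NA")
    pvals.to_csv(out / "fst_pvalues.tsv", sep="\t", na_rep="NA")
    grouping = config.grouping or {
        p: ("parentalA" if i == 0 else "parentalB" if i == 1 else "hybrid")
        for i, p in enumerate(g.populations)}
    res = amova(g, grouping, n_perm=min(config.n_perm, 200), seed=seed)
    table = res.table()
    table["phi"] = ""
    table.to_csv(out / "table2_amova.tsv", sep="\t", index=False, na_rep="NA")
    with open(out / "amova_phi.json", "w", encoding="utf-8") as fh:
        json.dump({"phi": res.phi, "p": res.p_values}, fh, indent=1)
    d = dapc(g, n_pcs=min(20, g.n_individuals - 2))
    pd.DataFrame({"id": g.ids, "population": g.pops,
                  "LD1": d.scores[:, 0],
                  "LD2": d.scores[:, 1] if d.scores.shape[1] > 1 else np.nan}
                 ).to_csv(out / "dapc_scores.tsv", sep="\t", index=False)
    runs = []
    for K in config.admixture_ks:
        for rep in range(config.admixture_reps):
            runs.append(admixture_gibbs(
                g, K, burnin=config.admixture_burnin,
                sweeps=config.admixture_sweeps,
                seed=seed + 1000 * K + rep))
    ev = evanno_delta_k(runs)
    ev.to_csv(out / "evanno.tsv", sep="\t", index=False, na_rep="NA")
    best_k = int(ev.loc[ev["deltaK"].idxmax(), "K"]) \
        if ev["deltaK"].notna().any() else 2
    aligned, consensus = align_cluster_labels(
        [r for r in runs if r.K == best_k])
    qdf = pd.DataFrame(consensus,
                       columns=[f"Q{k + 1}" for k in range(best_k)])
    qdf.insert(0, "population", g.pops)
    qdf.insert(0, "id", g.ids)
    qdf.to_csv(out / "qmatrix_consensus.tsv", sep="\t", index=False)
    state["best_k"] = best_k


def _stage_classify(config: PipelineConfig, out: Path, state: dict) -> None:
    g = _load_genotypes(state, out)
    seed = config.stage_seed("classify")
    for prior in ("uniform", "jeffreys"):
        post = newhybrids_gibbs(g, GenealogyModel(freq_prior=prior),
                                burnin=config.classify_burnin,
                                sweeps=config.classify_sweeps, seed=seed)
        post.frame().to_csv(out / f"hybrid_posterior_{prior}.tsv", sep="\t",
                            index=False)
        assignments, composition = assign_classes(
            post, config.assignment_threshold)
        assignments.to_csv(out / f"hybrid_assignments_{prior}.tsv", sep="\t",
                           index=False)
        composition.to_csv(out / f"class_composition_{prior}.tsv", sep="\t",
                           na_rep="NA")


def _stage_mtdna(config: PipelineConfig, out: Path, state: dict) -> None:
    fdir = state.get("fixture_dir", out / "fixture")
    aln = read_alignment(str(fdir / "mtdna.fasta"), str(fdir / "mtdna_pops.tsv"))
    diversity_table(aln).to_csv(out / "table4_mtdna.tsv", sep="\t",
                                index=False, na_rep="NA")
    haps = collapse_haplotypes(aln)
    haps.counts.to_csv(out / "haplotypes.tsv", sep="\t")
    net = median_joining_network(haps)
    write_network(net, str(out / "network_edges.tsv"), str(out / "network.gml"))
    # haplotype-level pairwise-difference AMOVA across populations
    from .mtdna import analyzed_columns
    cols = analyzed_columns(aln)
    m = aln.matrix()[:, cols]
    d2 = (m[:, None, :] != m[None, :, :]).sum(axis=2).astype(float)
    labels = np.array(aln.pops)
    res = amova_from_distance(d2, [labels], n_perm=min(config.n_perm, 200),
                              seed=config.stage_seed("mtdna"))
    with open(out / "mtdna_amova.json", "w", encoding="utf-8") as fh:
        json.dump({"phi": res.phi, "p": res.p_values,
                   "percent": res.percent}, fh, indent=1)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "discover": _stage_discover,
    "diversity": _stage_diversity,
    "structure": _stage_structure,
    "classify": _stage_classify,
    "mtdna": _stage_mtdna,
}
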