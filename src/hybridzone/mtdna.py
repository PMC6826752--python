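"""Mitochondrial haplotype statistics and median-joining networks.

Operates on a gap-free view of an aligned Cytb-style matrix: columns with
gaps or ambiguous bases are excluded (complete deletion, the DnaSP
convention) before haplotype collapsing, diversity statistics and network
construction; the Kimura two-parameter distance also offers pairwise
deletion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

VALID = set("ACGT")
PURINES = {"A", "G"}


@dataclass
class SequenceAlignment:
    """Equal-length nucleotide sequences with population labels."""

    ids: list[str]
    pops: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len({len(s) for s in self.seqs}) > 1:
            raise ValueError("alignment sequences must share one length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def matrix(self) -> np.ndarray:
        return np.array([list(s) for s in self.seqs])

    def subset(self, pop: str) -> "SequenceAlignment":
        idx = [i for i, p in enumerate(self.pops) if p == pop]
        if not idx:
            raise KeyError(f"unknown population {pop!r}")
        return SequenceAlignment([self.ids[i] for i in idx],
                                 [self.pops[i] for i in idx],
                                 [self.seqs[i] for i in idx])


def read_alignment(fasta_path: str, pops_path: str | None = None
                   ) -> SequenceAlignment:
    """Read a FASTA alignment; population labels come from a sidecar TSV
    (columns id, population) or, failing that, from an ``id|pop`` suffix."""
    from Bio import SeqIO

    records = list(SeqIO.parse(fasta_path, "fasta"))
    ids = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    if pops_path is not None:
        table = pd.read_csv(pops_path, sep="\t", dtype=str)
        mapping = dict(zip(table["id"], table["population"]))
        pops = [mapping.get(i, "unknown") for i in ids]
    else:
        pops = [i.rsplit("|", 1)[1] if "|" in i else "unknown" for i in ids]
    return SequenceAlignment(ids, pops, seqs)


def analyzed_columns(aln: SequenceAlignment) -> np.ndarray:
    """Indices of columns free of gaps/ambiguities (complete deletion)."""
    m = aln.matrix()
    ok = np.all(np.isin(m, list(VALID)), axis=0)
    return np.flatnonzero(ok)


# ---------------------------------------------------------------------------
# Haplotypes
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeTable:
    sequences: list[str]                 # representative analyzed-site strings
    ids: list[str]                       # H1..Hk
    counts: pd.DataFrame                 # haplotypes x populations
    members: dict[str, list[str]]        # haplotype id -> sequence ids

    @property
    def n_haplotypes(self) -> int:
        return len(self.ids)

    def frequencies(self) -> np.ndarray:
        tot = self.counts.to_numpy().sum()
        return self.counts.sum(axis=1).to_numpy() / tot


def collapse_haplotypes(aln: SequenceAlignment,
                        missing_policy: str = "complete") -> HaplotypeTable:
    """Collapse identical sequences over analyzed columns into haplotypes.

    Under the default complete-deletion policy every column containing a
    gap or N anywhere in the alignment is excluded first, so a sequence
    with a single N collapses with its resolved twin.
    """
    if missing_policy != "complete":
        raise ValueError("only the complete-deletion policy is implemented")
    cols = analyzed_columns(aln)
    if cols.size == 0:
        raise ValueError("no analyzable columns after complete deletion")
    m = aln.matrix()[:, cols]
    strings = ["".join(row) for row in m]
    order: dict[str, int] = {}
    for s in strings:
        order.setdefault(s, len(order))
    hap_ids = [f"H{order[s] + 1}" for s in strings]
    uniq = sorted(order, key=order.get)
    pops = sorted(set(aln.pops))
    counts = pd.DataFrame(0, index=[f"H{i + 1}" for i in range(len(uniq))],
                          columns=pops)
    members: dict[str, list[str]] = {h: [] for h in counts.index}
    for sid, pop, h in zip(aln.ids, aln.pops, hap_ids):
        counts.loc[h, pop] += 1
        members[h].append(sid)
    return HaplotypeTable(sequences=uniq, ids=list(counts.index),
                          counts=counts, members=members)


# ---------------------------------------------------------------------------
# Kimura two-parameter distance
# ---------------------------------------------------------------------------


class K2PSaturationError(ValueError):
    """The K2P logarithms are undefined (sequences too diverged)."""


def k2p_pair(s1: str, s2: str) -> float:
    """K2P distance between two sequences over shared unambiguous sites."""
    pairs = [(a, b) for a, b in zip(s1.upper(), s2.upper())
             if a in VALID and b in VALID]
    n = len(pairs)
    if n == 0:
        raise ValueError("no comparable sites")
    ts = sum(1 for a, b in pairs
             if a != b and (a in PURINES) == (b in PURINES))
    tv = sum(1 for a, b in pairs
             if a != b and (a in PURINES) != (b in PURINES))
    p, q = ts / n, tv / n
    w1 = 1 - 2 * p - q
    w2 = 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        raise K2PSaturationError(
            f"K2P undefined: 1-2P-Q={w1:.4g}, 1-2Q={w2:.4g}")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def k2p_matrix(aln: SequenceAlignment,
               deletion: str = "pairwise") -> pd.DataFrame:
    """Pairwise K2P distances; saturated pairs are reported as NaN."""
    seqs = aln.seqs
    if deletion == "complete":
        cols = analyzed_columns(aln)
        m = aln.matrix()[:, cols]
        seqs = ["".join(r) for r in m]
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'complete' or 'pairwise'")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            try:
                d[i, j] = d[j, i] = k2p_pair(seqs[i], seqs[j])
            except K2PSaturationError:
                d[i, j] = d[j, i] = np.nan
    return pd.DataFrame(d, index=aln.ids, columns=aln.ids)


def k2p_population_means(aln: SequenceAlignment,
                         deletion: str = "pairwise"
                         ) -> tuple[pd.Series, pd.DataFrame]:
    """Mean within-population K2P and the between-population mean matrix."""
    d = k2p_matrix(aln, deletion).to_numpy()
    pops = np.array(aln.pops)
    names = sorted(set(aln.pops))
    within = {}
    between = pd.DataFrame(np.nan, index=names, columns=names)
    for a in names:
        ia = np.flatnonzero(pops == a)
        if ia.size >= 2:
            pairs = [d[i, j] for i, j in itertools.combinations(ia, 2)]
            within[a] = float(np.nanmean(pairs))
        else:
            within[a] = np.nan
        for b in names:
            ib = np.flatnonzero(pops == b)
            if a != b:
                between.loc[a, b] = float(np.nanmean(d[np.ix_(ia, ib)]))
    return pd.Series(within, name="K2P_within"), between


# ---------------------------------------------------------------------------
# Diversity and Tajima's D
# ---------------------------------------------------------------------------


@dataclass
class MtDiversity:
    population: str
    n: int
    n_haplotypes: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float
    S: int
    tajima_d: float
    tajima_p: float
    significance: str


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(n: int, S: int, mean_pairwise: float) -> tuple[float, float]:
    """Tajima's D and its two-sided p from the beta approximation.

    ``mean_pairwise`` is the mean number of pairwise differences (not per
    site).  Returns (NaN, NaN) when S = 0.
    """
    if n < 2:
        raise ValueError("Tajima's D needs n >= 2")
    if S == 0:
        return np.nan, np.nan
    c = _tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:  # n = 2: numerator and variance both vanish
        return np.nan, np.nan
    d = (mean_pairwise - S / c["a1"]) / np.sqrt(var)
    # beta approximation: D ranges over [Dmin, Dmax] with mean 0, var 1
    dmin = (2 / n - 1 / c["a1"]) / np.sqrt(c["e2"])
    dmax = ((n + 1) / (2 * n) - 1 / c["a1"]) / np.sqrt(c["e2"])
    rng_ = dmax - dmin
    m = (0 - dmin) / rng_
    v = 1 / rng_ ** 2
    common = m * (1 - m) / v - 1
    if common <= 0:
        return d, np.nan
    a, b = m * common, (1 - m) * common
    x = np.clip((d - dmin) / rng_, 0.0, 1.0)
    cdf = beta_dist.cdf(x, a, b)
    p = 2 * min(cdf, 1 - cdf)
    return float(d), float(min(p, 1.0))


def diversity_stats(aln: SequenceAlignment, pop: str | None = None
                    ) -> MtDiversity:
    """Haplotype diversity h, nucleotide diversity pi, S and Tajima's D.

    h uses the unbiased estimator n(1 - sum x_i^2)/(n - 1) with Nei's
    sampling variance; pi is the mean pairwise difference per analyzed
    site with Nei's (1987) variance; significance flags mirror the usual
    "NS / p > 0.10 / p < 0.05" reporting.
    """
    sub = aln if pop is None else aln.subset(pop)
    n = len(sub.seqs)
    if n < 2:
        raise ValueError("diversity needs at least two sequences")
    cols = analyzed_columns(sub)
    m = sub.matrix()[:, cols]
    L = cols.size
    # haplotype diversity
    _, counts = np.unique(["".join(r) for r in m], return_counts=True)
    x = counts / n
    h = n * (1 - (x ** 2).sum()) / (n - 1)
    sum2, sum3 = (x ** 2).sum(), (x ** 3).sum()
    h_var = 2 / (n * (n - 1)) * (2 * (n - 2) * (sum3 - sum2 ** 2)
                                 + sum2 - sum2 ** 2)
    # pairwise differences
    diffs = [np.sum(m[i] != m[j]) for i, j in itertools.combinations(range(n), 2)]
    mean_pw = float(np.mean(diffs))
    pi = mean_pw / L
    pi_var = (n + 1) / (3 * (n - 1)) * pi / L \
        + 2 * (n ** 2 + n + 3) / (9 * n * (n - 1)) * pi ** 2
    S = int((~np.all(m == m[0], axis=0)).sum())
    d, p = tajimas_d(n, S, mean_pw)
    if not np.isfinite(d):
        sig = "undefined (S=0)"
    elif not np.isfinite(p):
        sig = "NS"
    elif p < 0.05:
        sig = "p < 0.05"
    elif p < 0.10:
        sig = "0.05 < p < 0.10"
    else:
        sig = "p > 0.10 (NS)"
    return MtDiversity(population=pop or "all", n=n,
                       n_haplotypes=len(counts), h=float(h),
                       h_sd=float(np.sqrt(max(h_var, 0.0))), pi=float(pi),
                       pi_sd=float(np.sqrt(max(pi_var, 0.0))), S=S,
                       tajima_d=float(d) if np.isfinite(d) else np.nan,
                       tajima_p=float(p) if np.isfinite(p) else np.nan,
                       significance=sig)


def diversity_table(aln: SequenceAlignment) -> pd.DataFrame:
    """Per-population diversity rows (N, HpN, h, pi, within-K2P, D)."""
    within, _ = k2p_population_means(aln)
    rows = []
    for pop in sorted(set(aln.pops)):
        try:
            st = diversity_stats(aln, pop)
        except ValueError:
            continue
        rows.append({"population": pop, "N": st.n, "HpN": st.n_haplotypes,
                     "h": st.h, "h_sd": st.h_sd, "pi": st.pi,
                     "pi_sd": st.pi_sd, "K2P_within": within[pop],
                     "S": st.S, "tajima_D": st.tajima_d,
                     "significance": st.significance})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Median-joining network
# ---------------------------------------------------------------------------


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _spanning_tree(names: list[str], seqs: dict[str, str]) -> nx.Graph:
    """Deterministic minimum spanning tree over Hamming distances.

    Kruskal with ties broken by lexicographic haplotype id, so repeated
    runs give byte-identical networks.
    """
    pairs = sorted(
        (_hamming(seqs[a], seqs[b]), a, b)
        for i, a in enumerate(names) for b in names[i + 1:])
    tree = nx.Graph()
    tree.add_nodes_from(names)
    parent = {v: v for v in names}

    def find(v: str) -> str:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for d, a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            tree.add_edge(a, b, weight=d)
    return tree


def _path_max_weight(tree: nx.Graph) -> dict[tuple[str, str], int]:
    """Largest edge weight on the unique tree path between every pair."""
    out: dict[tuple[str, str], int] = {}
    for src in tree.nodes:
        best = {src: 0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, data in tree[u].items():
                if v not in best:
                    best[v] = max(best[u], data["weight"])
                    stack.append(v)
        for v, w in best.items():
            out[(src, v)] = w
    return out


def _quasi_median(a: str, b: str, c: str) -> str:
    """Per-column majority state of three sequences (a's state on ties)."""
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(x)
    return "".join(out)


@dataclass
class HaploNetwork:
    graph: nx.Graph
    observed: list[str]
    medians: list[str] = field(default_factory=list)

    def total_length(self) -> int:
        return sum(d for _, _, d in self.graph.edges.data("weight"))

    def edge_list(self) -> pd.DataFrame:
        rows = [{"from": u, "to": v, "steps": d}
                for u, v, d in self.graph.edges.data("weight")]
        return pd.DataFrame(rows)


def median_joining_network(table: HaplotypeTable,
                           epsilon: int = 0,
                           max_rounds: int = 20) -> HaploNetwork:
    """Median-joining network over the collapsed haplotypes.

    Iterates: build the deterministic spanning network (lexicographic
    tie-break); for every triplet whose members are pairwise feasible —
    adjacent, or with a direct link no longer than epsilon plus the
    largest step on their connecting path (tied alternative connections
    count as feasible at epsilon = 0) — compute the quasi-median
    (per-column majority) and add it when novel and when it shortens the
    network; repeat until stable.  Median vectors left dangling (degree
    < 2, i.e. off every shortest observed-to-observed connection of the
    final network) are removed.  Total length therefore never exceeds the
    minimum-spanning-tree length of the observed haplotypes.
    """
    if table.n_haplotypes == 0:
        raise ValueError("empty haplotype table")
    observed = list(table.ids)
    seqs = {h: s for h, s in zip(table.ids, table.sequences)}
    freqs = table.counts.sum(axis=1)
    if table.n_haplotypes == 1:
        g = nx.Graph()
        g.add_node(observed[0], observed=True,
                   frequency=int(freqs.iloc[0]), sequence=table.sequences[0])
        return HaploNetwork(graph=g, observed=observed)

    median_count = 0
    tree = _spanning_tree(list(seqs), seqs)
    for _ in range(max_rounds):
        names = sorted(seqs)
        length = sum(d for _, _, d in tree.edges.data("weight"))
        pmax = _path_max_weight(tree)
        candidates: list[str] = []
        seen = set(seqs.values())
        for a, b, c in itertools.combinations(names, 3):
            feasible = all(
                tree.has_edge(u, v)
                or _hamming(seqs[u], seqs[v]) <= pmax[(u, v)] + epsilon
                for u, v in ((a, b), (a, c), (b, c)))
            if not feasible:
                continue
            med = _quasi_median(seqs[a], seqs[b], seqs[c])
            if med not in seen:
                seen.add(med)
                candidates.append(med)
        added = False
        for med in candidates:
            name = f"mv{median_count + 1}"
            trial = dict(seqs)
            trial[name] = med
            trial_tree = _spanning_tree(sorted(trial), trial)
            trial_len = sum(d for _, _, d in trial_tree.edges.data("weight"))
            if trial_len < length:
                seqs[name] = med
                median_count += 1
                tree = trial_tree
                length = trial_len
                added = True
        if not added:
            break

    # drop dangling median vectors (leaves of the tree are off every
    # shortest connection between observed haplotypes)
    while True:
        dangling = [v for v in tree.nodes
                    if v not in observed and tree.degree(v) < 2]
        if not dangling:
            break
        tree.remove_nodes_from(dangling)
        for v in dangling:
            del seqs[v]

    for h in tree.nodes:
        tree.nodes[h]["observed"] = h in table.ids
        tree.nodes[h]["frequency"] = int(freqs[h]) if h in table.ids else 0
        tree.nodes[h]["sequence"] = seqs[h]
    medians = [v for v in tree.nodes if v not in observed]
    return HaploNetwork(graph=tree, observed=observed, medians=medians)


def mst_total_length(seqs: list[str]) -> int:
    """Minimum-spanning-tree length over Hamming distances (oracle helper)."""
    g = nx.Graph()
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            g.add_edge(i, j, weight=_hamming(seqs[i], seqs[j]))
    t = nx.minimum_spanning_tree(g)
    return sum(d for _, _, d in t.edges.data("weight"))


def write_network(net: HaploNetwork, edge_path: str, gml_path: str) -> None:
    net.edge_list().to_csv(edge_path, sep="\t", index=False)
    g = net.graph.copy()
    for _, data in g.nodes(data=True):
        data["observed"] = int(data.get("observed", False))
    nx.write_gml(g, gml_path)
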