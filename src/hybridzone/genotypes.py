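"""Diploid genotype matrix container and GENEPOP / STRUCTURE / CSV dialects.

The in-memory representation is a dense integer matrix of allele-1 dosages:
``genotypes[i, l]`` counts copies of the locus's first allele carried by
individual ``i`` (0, 1 or 2), with -1 for a missing genotype.  All loci are
biallelic by construction — the SNP panel produced by the discovery stage
only ever contains two alleles per site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci with population labels.

    Parameters
    ----------
    ids : list of str
        Unique individual identifiers.
    pops : list of str
        Population label per individual (same order as ``ids``).
    loci : list of str
        Locus names.
    genotypes : ndarray of int8, shape (n_individuals, n_loci)
        Allele-1 dosage, ``MISSING`` (-1) when not genotyped.
    alleles : list of (str, str), optional
        Per-locus allele labels (e.g. bases); defaults to ("1", "2").
    """

    ids: list[str]
    pops: list[str]
    loci: list[str]
    genotypes: np.ndarray
    alleles: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, m = self.genotypes.shape
        if len(self.ids) != n or len(self.pops) != n or len(self.loci) != m:
            raise ValueError("inconsistent GenotypeMatrix dimensions")
        if len(set(self.ids)) != n:
            raise ValueError("individual ids must be unique")
        bad = ~np.isin(self.genotypes, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype dosages must be in {-1, 0, 1, 2}")
        if not self.alleles:
            self.alleles = [("1", "2")] * m

    # -- basic views -------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.pops:
            seen.setdefault(p)
        return list(seen)

    def pop_mask(self, pop: str) -> np.ndarray:
        mask = np.array([p == pop for p in self.pops])
        if not mask.any():
            raise KeyError(f"unknown population: {pop!r}")
        return mask

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        idx = np.flatnonzero(np.asarray(mask))
        return GenotypeMatrix(
            ids=[self.ids[i] for i in idx],
            pops=[self.pops[i] for i in idx],
            loci=list(self.loci),
            genotypes=self.genotypes[idx].copy(),
            alleles=list(self.alleles),
        )

    def missingness(self) -> pd.Series:
        """Per-locus fraction of missing genotypes."""
        frac = (self.genotypes == MISSING).mean(axis=0)
        return pd.Series(frac, index=self.loci, name="missing_fraction")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.pops == other.pops
            and self.loci == other.loci
            and np.array_equal(self.genotypes, other.genotypes)
        )


class GenotypeParseError(ValueError):
    """Malformed genotype file; carries the offending line number."""

    def __init__(self, path: str, line: int, message: str):
        super().__init__(f"{path}:{line}: {message}")
        self.line = line


# ---------------------------------------------------------------------------
# GENEPOP
# ---------------------------------------------------------------------------


def write_genepop(g: GenotypeMatrix, path: str, digits: int = 2,
                  title: str = "hybridzone genotype export") -> None:
    """Write GENEPOP with 2- or 3-digit allele coding (alleles 1/2, 0=missing)."""
    if digits not in (2, 3):
        raise ValueError("GENEPOP coding uses 2 or 3 digits per allele")
    fmt = f"0{digits}d"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(title + "\n")
        for locus in g.loci:
            fh.write(locus + "\n")
        current = None
        for i, (ind, pop) in enumerate(zip(g.ids, g.pops)):
            if pop != current:
                fh.write("POP\n")
                current = pop
            codes = []
            for d in g.genotypes[i]:
                if d == MISSING:
                    a = b = 0
                else:
                    a = 1 if d >= 1 else 2
                    b = 1 if d == 2 else 2
                codes.append(f"{a:{fmt}}{b:{fmt}}")
            fh.write(f"{ind} ,  " + " ".join(codes) + "\n")


def read_genepop(path: str) -> GenotypeMatrix:
    """Read a biallelic GENEPOP file (2- or 3-digit codings auto-detected).

    Population labels are taken from the last individual id of each POP
    block when it looks like a shared prefix, otherwise ``pop1..popN``;
    since our writer stores the true label as each id's prefix before the
    last ``_``, round trips are lossless for generated data.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise GenotypeParseError(path, len(lines), "truncated GENEPOP file")
    # locus names: lines 2..first POP; support comma-separated single line
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        loci.extend(x.strip() for x in lines[i].split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise GenotypeParseError(path, len(lines), "no POP delimiter found")
    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[int]] = []
    pop_idx = 0
    for ln in range(i, len(lines)):
        line = lines[ln].strip()
        if not line:
            continue
        if line.upper() == "POP":
            pop_idx += 1
            continue
        if "," not in line:
            raise GenotypeParseError(path, ln + 1, "expected 'id , genotypes'")
        ind, geno = line.split(",", 1)
        ind = ind.strip()
        codes = geno.split()
        if len(codes) != len(loci):
            raise GenotypeParseError(
                path, ln + 1,
                f"expected {len(loci)} genotypes, found {len(codes)}")
        row = []
        for c in codes:
            if len(c) not in (4, 6) or not c.isdigit():
                raise GenotypeParseError(path, ln + 1, f"bad allele code {c!r}")
            half = len(c) // 2
            a, b = int(c[:half]), int(c[half:])
            if a == 0 or b == 0:
                row.append(MISSING)
            else:
                if not {a, b} <= {1, 2}:
                    raise GenotypeParseError(
                        path, ln + 1, f"non-biallelic code {c!r}")
                row.append((a == 1) + (b == 1))
        ids.append(ind)
        pops.append(f"pop{pop_idx}")
        rows.append(row)
    if not rows:
        raise GenotypeParseError(path, len(lines), "no individuals found")
    # recover original population labels from id prefixes where present
    pops = _labels_from_ids(ids, pops)
    return GenotypeMatrix(ids, pops, loci, np.array(rows, dtype=np.int8))


def _labels_from_ids(ids: list[str], fallback: list[str]) -> list[str]:
    labels = []
    for ind, fb in zip(ids, fallback):
        m = re.match(r"^(.*)_[^_]+$", ind)
        labels.append(m.group(1) if m else fb)
    # only trust prefixes if they are consistent with the POP blocks
    blocks: dict[str, set[str]] = {}
    for lab, fb in zip(labels, fallback):
        blocks.setdefault(fb, set()).add(lab)
    if all(len(v) == 1 for v in blocks.values()) and \
            len({next(iter(v)) for v in blocks.values()}) == len(blocks):
        return labels
    return fallback


# ---------------------------------------------------------------------------
# STRUCTURE
# ---------------------------------------------------------------------------


def write_structure(g: GenotypeMatrix, path: str, two_rows: bool = True,
                    missing_code: int = -9) -> None:
    """Write STRUCTURE input; two-rows-per-individual or one-row layout."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(g.loci) + "\n")
        popnum = {p: k + 1 for k, p in enumerate(g.populations)}
        for i, (ind, pop) in enumerate(zip(g.ids, g.pops)):
            a1, a2 = [], []
            for d in g.genotypes[i]:
                if d == MISSING:
                    a1.append(missing_code)
                    a2.append(missing_code)
                else:
                    a1.append(1 if d >= 1 else 2)
                    a2.append(1 if d == 2 else 2)
            if two_rows:
                fh.write("\t".join([ind, str(popnum[pop])] + list(map(str, a1))) + "\n")
                fh.write("\t".join([ind, str(popnum[pop])] + list(map(str, a2))) + "\n")
            else:
                inter = [str(v) for pair in zip(a1, a2) for v in pair]
                fh.write("\t".join([ind, str(popnum[pop])] + inter) + "\n")


def read_structure(path: str, two_rows: bool = True,
                   missing_code: int = -9,
                   pop_names: list[str] | None = None) -> GenotypeMatrix:
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise GenotypeParseError(path, len(lines), "truncated STRUCTURE file")
    loci = lines[0].split()
    body = [ln.split() for ln in lines[1:]]
    ids: list[str] = []
    popnums: list[int] = []
    rows: list[list[int]] = []

    def decode(a: int, b: int, ln: int) -> int:
        if a == missing_code or b == missing_code:
            return MISSING
        if not {a, b} <= {1, 2}:
            raise GenotypeParseError(path, ln, f"non-biallelic allele {a}/{b}")
        return (a == 1) + (b == 1)

    if two_rows:
        if len(body) % 2:
            raise GenotypeParseError(path, len(lines),
                                     "odd row count in two-row layout")
        for j in range(0, len(body), 2):
            r1, r2 = body[j], body[j + 1]
            ln = j + 2
            if len(r1) != len(loci) + 2 or len(r2) != len(loci) + 2:
                raise GenotypeParseError(path, ln, "wrong column count")
            if r1[0] != r2[0]:
                raise GenotypeParseError(path, ln + 1,
                                         "paired rows disagree on id")
            ids.append(r1[0])
            popnums.append(int(r1[1]))
            rows.append([decode(int(a), int(b), ln)
                         for a, b in zip(r1[2:], r2[2:])])
    else:
        for j, r in enumerate(body):
            ln = j + 2
            if len(r) != 2 * len(loci) + 2:
                raise GenotypeParseError(path, ln, "wrong column count")
            ids.append(r[0])
            popnums.append(int(r[1]))
            vals = list(map(int, r[2:]))
            rows.append([decode(vals[2 * k], vals[2 * k + 1], ln)
                         for k in range(len(loci))])
    if pop_names is None:
        order: dict[int, None] = {}
        for p in popnums:
            order.setdefault(p)
        pop_names = [f"pop{p}" for p in order]
        nummap = {p: name for p, name in zip(order, pop_names)}
    else:
        order = {}
        for p in popnums:
            order.setdefault(p)
        nummap = {p: name for p, name in zip(order, pop_names)}
    pops = _labels_from_ids(ids, [nummap[p] for p in popnums])
    return GenotypeMatrix(ids, pops, loci, np.array(rows, dtype=np.int8))


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------


def write_csv(g: GenotypeMatrix, path: str) -> None:
    """CSV with id, population, then one "a/b" genotype column per locus."""
    data = {"id": g.ids, "population": g.pops}
    strings = {MISSING: "./.", 0: "2/2", 1: "1/2", 2: "1/1"}
    for j, locus in enumerate(g.loci):
        data[locus] = [strings[int(d)] for d in g.genotypes[:, j]]
    pd.DataFrame(data).to_csv(path, index=False)


def read_csv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "id" or df.columns[1] != "population":
        raise GenotypeParseError(path, 1, "expected 'id,population,...' header")
    loci = list(df.columns[2:])
    decode = {"./.": MISSING, "2/2": 0, "1/2": 1, "2/1": 1, "1/1": 2}
    rows = np.empty((len(df), len(loci)), dtype=np.int8)
    for j, locus in enumerate(loci):
        for i, val in enumerate(df[locus]):
            try:
                rows[i, j] = decode[val]
            except KeyError:
                raise GenotypeParseError(path, i + 2,
                                         f"bad genotype {val!r}") from None
    return GenotypeMatrix(list(df["id"]), list(df["population"]), loci, rows)


DIALECTS = {"genepop": (read_genepop, write_genepop),
            "structure": (read_structure, write_structure),
            "csv": (read_csv, write_csv)}


def read_genotypes(path: str, dialect: str, **kw) -> GenotypeMatrix:
    try:
        reader, _ = DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}") from None
    return reader(path, **kw)


def write_genotypes(g: GenotypeMatrix, path: str, dialect: str, **kw) -> None:
    try:
        _, writer = DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}") from None
    writer(g, path, **kw)
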