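"""Fixed-allele diagnostic SNP discovery from three pooled samples.

Inputs are per-site base counts for a species-A pool, a species-B pool and
a hybrid-zone pool.  A site passes when depth bounds are met in every pool,
each parental pool is fixed (to within a tolerance) for a different base,
and both parental bases segregate in the hybrid pool at a minor-allele
frequency above threshold.  Every input site is returned with a status and
machine-readable fail reasons so the panel is fully auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

POOLS = ("speciesA", "speciesB", "hybrid")
BASES = ("A", "C", "G", "T")


@dataclass
class DiscoveryParams:
    """Thresholds of the diagnostic-SNP filter.

    min_coverage/max_coverage bound per-pool read depth; hybrid_min_maf is
    the minimum minor-allele frequency among hybrid reads carrying either
    parental allele; fixation_tolerance relaxes the strict 100 % parental
    fixation requirement (a pool is "fixed" when its major base frequency is
    at least 1 - fixation_tolerance); min_flank_bp is the assay-design flank
    each side of the site.
    """

    min_coverage: int = 10
    max_coverage: int = 8000
    hybrid_min_maf: float = 0.10
    fixation_tolerance: float = 0.0
    min_flank_bp: int = 100

    def __post_init__(self) -> None:
        if self.min_coverage < 0 or self.max_coverage < self.min_coverage:
            raise ValueError("need 0 <= min_coverage <= max_coverage")
        if not 0.0 <= self.hybrid_min_maf <= 0.5:
            raise ValueError("hybrid_min_maf must lie in [0, 0.5]")
        if not 0.0 <= self.fixation_tolerance < 0.5:
            raise ValueError("fixation_tolerance must lie in [0, 0.5)")
        if self.min_flank_bp < 0:
            raise ValueError("min_flank_bp must be non-negative")


def _pool_counts(table: pd.DataFrame, pool: str) -> np.ndarray:
    cols = [f"{pool}_{b}" for b in BASES]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"pool count columns missing: {missing}")
    counts = table[cols].to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError(f"negative base counts in pool {pool!r}")
    return counts


def validate_pool_table(table: pd.DataFrame) -> None:
    """Check the PoolSiteTable contract (columns, sorted unique positions)."""
    for col in ("contig", "pos"):
        if col not in table.columns:
            raise ValueError(f"pool table lacks column {col!r}")
    for pool in POOLS:
        _pool_counts(table, pool)
    dup = table.duplicated(subset=["contig", "pos"])
    if dup.any():
        raise ValueError("duplicate contig/position rows in pool table")
    for _, sub in table.groupby("contig", sort=False):
        if not sub["pos"].is_monotonic_increasing:
            raise ValueError("positions must be sorted within contigs")


def call_diagnostic_snps(table: pd.DataFrame,
                         params: DiscoveryParams | None = None) -> pd.DataFrame:
    """Screen every site for the fixed-allele diagnostic pattern.

    Returns one row per input site with columns contig, pos, alleleA,
    alleleB, hybrid_maf, per-pool depths, status ("pass"/"fail") and a
    semicolon-joined ``fail_reasons`` audit column.
    """
    params = params or DiscoveryParams()
    validate_pool_table(table)
    n = len(table)
    counts = {pool: _pool_counts(table, pool) for pool in POOLS}
    depths = {pool: counts[pool].sum(axis=1) for pool in POOLS}

    reasons: list[list[str]] = [[] for _ in range(n)]
    for pool in POOLS:
        low = depths[pool] < params.min_coverage
        high = depths[pool] > params.max_coverage
        for i in np.flatnonzero(low):
            reasons[i].append(f"min_coverage:{pool}")
        for i in np.flatnonzero(high):
            reasons[i].append(f"max_coverage:{pool}")

    def fixed_base(pool: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        c = counts[pool]
        d = np.maximum(depths[pool], 1)
        major = c.argmax(axis=1)
        major_freq = c.max(axis=1) / d
        fixed = (major_freq >= 1.0 - params.fixation_tolerance) & (depths[pool] > 0)
        # a genuine third allele above tolerance in a parental pool
        order = np.sort(c, axis=1)
        multi = ((c > 0).sum(axis=1) >= 3) & \
            (order[:, -3] / d > params.fixation_tolerance)
        return major, fixed, multi

    maj_a, fixed_a, multi_a = fixed_base("speciesA")
    maj_b, fixed_b, multi_b = fixed_base("speciesB")
    for i in np.flatnonzero(multi_a):
        reasons[i].append("multi_allelic:speciesA")
    for i in np.flatnonzero(multi_b):
        reasons[i].append("multi_allelic:speciesB")
    for i in np.flatnonzero(~fixed_a):
        reasons[i].append("not_fixed:speciesA")
    for i in np.flatnonzero(~fixed_b):
        reasons[i].append("not_fixed:speciesB")
    same = fixed_a & fixed_b & (maj_a == maj_b)
    for i in np.flatnonzero(same):
        reasons[i].append("same_allele")

    # hybrid MAF over reads carrying either parental allele
    hyb = counts["hybrid"]
    idx = np.arange(n)
    c_a = hyb[idx, maj_a]
    c_b = hyb[idx, maj_b]
    either = c_a + c_b
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(either > 0, np.minimum(c_a, c_b) / np.maximum(either, 1),
                       0.0)
    parental_ok = fixed_a & fixed_b & (maj_a != maj_b)
    hybrid_fail = parental_ok & ((c_a == 0) | (c_b == 0)
                                 | (maf < params.hybrid_min_maf))
    for i in np.flatnonzero(hybrid_fail):
        reasons[i].append("hybrid_maf")

    status = np.array(["fail" if r else "pass" for r in reasons])
    out = pd.DataFrame({
        "contig": table["contig"].to_numpy(),
        "pos": table["pos"].to_numpy(),
        "alleleA": np.array(BASES)[maj_a],
        "alleleB": np.array(BASES)[maj_b],
        "hybrid_maf": maf,
        "depthA": depths["speciesA"].astype(int),
        "depthB": depths["speciesB"].astype(int),
        "depthHybrid": depths["hybrid"].astype(int),
        "status": status,
        "fail_reasons": [";".join(r) for r in reasons],
    })
    # allele calls are meaningless where a parental pool is not fixed
    bad = ~parental_ok
    out.loc[bad, ["alleleA", "alleleB"]] = "."
    if "locus" in table.columns:
        out.insert(2, "locus", table["locus"].to_numpy())
    return out


def filter_flanks(calls: pd.DataFrame, contig_lengths: dict[str, int],
                  all_variant_positions: pd.DataFrame | None = None,
                  params: DiscoveryParams | None = None,
                  clean_flank: bool = False) -> pd.DataFrame:
    """Annotate assay eligibility by the flanking-region rule.

    A site is eligible when at least ``min_flank_bp`` bases exist on both
    sides: ``pos - 1 >= min_flank_bp`` and ``length - pos >= min_flank_bp``
    (1-based inclusive coordinates).  In ``clean_flank`` mode a site is also
    flagged when any other variant in ``all_variant_positions`` lies within
    the flank.
    """
    params = params or DiscoveryParams()
    out = calls.copy()
    lengths = np.empty(len(out), dtype=int)
    for i, contig in enumerate(out["contig"]):
        try:
            lengths[i] = contig_lengths[contig]
        except KeyError:
            raise KeyError(f"unknown contig {contig!r}") from None
    pos = out["pos"].to_numpy(dtype=int)
    left_ok = (pos - 1) >= params.min_flank_bp
    right_ok = (lengths - pos) >= params.min_flank_bp
    eligible = left_ok & right_ok
    reason = np.where(eligible, "",
                      np.where(~left_ok & ~right_ok, "both_flanks",
                               np.where(~left_ok, "left_flank", "right_flank")))
    if clean_flank:
        if all_variant_positions is None:
            raise ValueError("clean_flank mode needs all_variant_positions")
        by_contig: dict[str, np.ndarray] = {
            c: np.sort(sub["pos"].to_numpy())
            for c, sub in all_variant_positions.groupby("contig")}
        conflicted = np.zeros(len(out), dtype=bool)
        for i, (contig, p) in enumerate(zip(out["contig"], pos)):
            others = by_contig.get(contig, np.empty(0, dtype=int))
            near = others[(np.abs(others - p) <= params.min_flank_bp)
                          & (others != p)]
            conflicted[i] = near.size > 0
        eligible = eligible & ~conflicted
        reason = np.where(conflicted,
                          np.where(reason == "", "flank_conflict",
                                   reason + ";flank_conflict"),
                          reason)
    out["flank_eligible"] = eligible
    out["flank_reason"] = reason
    return out


# ---------------------------------------------------------------------------
# Panel export
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=hybridzone-pool-snp-discovery
##INFO=<ID=DPA,Number=1,Type=Integer,Description="Species A pool depth">
##INFO=<ID=DPB,Number=1,Type=Integer,Description="Species B pool depth">
##INFO=<ID=DPH,Number=1,Type=Integer,Description="Hybrid pool depth">
##INFO=<ID=HMAF,Number=1,Type=Float,Description="Hybrid pool minor allele frequency over parental alleles">
"""


def export_panel(calls: pd.DataFrame, vcf_path: str, sheet_path: str,
                 contig_lengths: dict[str, int] | None = None) -> int:
    """Write pass+eligible calls as VCF 4.2 plus a TSV audit sheet.

    The species-A allele is written as REF and the species-B allele as ALT
    (a reference-surrogate convention for a transcriptome without a
    published genome).  Returns the number of VCF records written.
    """
    import pysam

    keep = calls[(calls["status"] == "pass")
                 & calls.get("flank_eligible", True)]
    header_text = _VCF_HEADER
    contigs = list(dict.fromkeys(calls["contig"]))
    for c in contigs:
        if contig_lengths and c in contig_lengths:
            header_text += f"##contig=<ID={c},length={contig_lengths[c]}>\n"
        else:
            header_text += f"##contig=<ID={c}>\n"
    header = pysam.VariantHeader()
    for line in header_text.rstrip("\n").split("\n")[1:]:
        header.add_line(line)
    with pysam.VariantFile(vcf_path, "w", header=header) as vcf:
        for _, row in keep.iterrows():
            rec = vcf.new_record(
                contig=row["contig"], start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(row["alleleA"], row["alleleB"]))
            rec.id = row["locus"] if "locus" in keep.columns else None
            rec.info["DPA"] = int(row["depthA"])
            rec.info["DPB"] = int(row["depthB"])
            rec.info["DPH"] = int(row["depthHybrid"])
            rec.info["HMAF"] = float(row["hybrid_maf"])
            vcf.write(rec)
    calls.to_csv(sheet_path, sep="\t", index=False)
    return len(keep)


def read_panel_vcf(vcf_path: str) -> pd.DataFrame:
    """Re-import an exported panel VCF (lossless for pass records)."""
    import pysam

    rows = []
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            rows.append({
                "contig": rec.contig, "pos": rec.pos,
                "alleleA": rec.ref, "alleleB": rec.alts[0],
                "hybrid_maf": float(rec.info["HMAF"]),
                "depthA": int(rec.info["DPA"]),
                "depthB": int(rec.info["DPB"]),
                "depthHybrid": int(rec.info["DPH"]),
                "locus": rec.id,
            })
    return pd.DataFrame(rows)
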