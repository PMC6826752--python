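"""Diagnostic-SNP filter: fixed-allele rule, depth bounds, flanks, export."""

import numpy as np
import pandas as pd
import pytest

import hybridzone as hz
from hybridzone.discovery import (DiscoveryParams, call_diagnostic_snps,
                                  export_panel, filter_flanks, read_panel_vcf)


def make_site(a_counts, b_counts, h_counts, contig="c1", pos=500):
    """One-row pool table; counts are dicts base -> count."""
    row = {"contig": contig, "pos": pos, "ref": "C"}
    for pool, counts in (("speciesA", a_counts), ("speciesB", b_counts),
                         ("hybrid", h_counts)):
        for b in "ACGT":
            row[f"{pool}_{b}"] = counts.get(b, 0)
    return pd.DataFrame([row])


class TestDiagnosticCalls:
    def test_textbook_heterozygous_hybrid_site_passes(self):
        # homozygous C in one species, T in the other, C/T in the hybrid pool
        table = make_site({"C": 50}, {"T": 48}, {"C": 20, "T": 15})
        calls = call_diagnostic_snps(table)
        assert calls.loc[0, "status"] == "pass"
        assert calls.loc[0, "alleleA"] == "C" and calls.loc[0, "alleleB"] == "T"
        assert calls.loc[0, "hybrid_maf"] == pytest.approx(15 / 35)

    def test_hybrid_missing_one_allele_fails_maf(self):
        table = make_site({"C": 50}, {"T": 48}, {"C": 40})
        calls = call_diagnostic_snps(table)
        assert calls.loc[0, "status"] == "fail"
        assert "hybrid_maf" in calls.loc[0, "fail_reasons"]

    @pytest.mark.parametrize("depth,reason", [(9, "min_coverage"),
                                              (8001, "max_coverage")])
    def test_depth_bounds(self, depth, reason):
        table = make_site({"C": depth}, {"T": 48}, {"C": 20, "T": 15})
        calls = call_diagnostic_snps(table)
        assert calls.loc[0, "status"] == "fail"
        assert f"{reason}:speciesA" in calls.loc[0, "fail_reasons"]

    def test_same_fixed_allele_fails(self):
        table = make_site({"C": 50}, {"C": 48}, {"C": 20, "T": 15})
        calls = call_diagnostic_snps(table)
        assert "same_allele" in calls.loc[0, "fail_reasons"]

    def test_non_fixed_parental_pool_fails(self):
        table = make_site({"C": 40, "T": 10}, {"T": 48}, {"C": 20, "T": 15})
        calls = call_diagnostic_snps(table)
        assert "not_fixed:speciesA" in calls.loc[0, "fail_reasons"]

    def test_third_allele_in_parental_pool_flagged_multiallelic(self):
        table = make_site({"C": 40, "T": 5, "G": 5}, {"T": 48},
                          {"C": 20, "T": 15})
        calls = call_diagnostic_snps(table)
        assert "multi_allelic:speciesA" in calls.loc[0, "fail_reasons"]

    def test_error_free_fixture_recovered_exactly(self):
        model = hz.SpeciesPairModel(n_loci=1000, prop_fixed_diff=0.1,
                                    seq_error_rate=0.0, seed=13)
        freqs = hz.draw_parental_freqs(model)
        freqs["speciesA"] = freqs["freqA"]
        freqs["speciesB"] = freqs["freqB"]
        freqs["hybrid"] = 0.5 * (freqs["freqA"] + freqs["freqB"])
        table = hz.simulate_pool_counts(freqs, model)
        calls = call_diagnostic_snps(table)
        truth = freqs["diagnostic"].to_numpy()
        passed = (calls["status"] == "pass").to_numpy()
        assert (passed == truth).all()

    def test_monotonicity_in_thresholds(self):
        model = hz.SpeciesPairModel(n_loci=500, prop_fixed_diff=0.3,
                                    seq_error_rate=0.002, seed=14)
        freqs = hz.draw_parental_freqs(model)
        freqs["speciesA"] = freqs["freqA"]
        freqs["speciesB"] = freqs["freqB"]
        freqs["hybrid"] = 0.25 * freqs["freqA"] + 0.75 * freqs["freqB"]
        table = hz.simulate_pool_counts(freqs, model)
        base = set(np.flatnonzero(
            call_diagnostic_snps(table)["status"] == "pass"))
        for params in (DiscoveryParams(hybrid_min_maf=0.3),
                       DiscoveryParams(min_coverage=60)):
            tighter = set(np.flatnonzero(
                call_diagnostic_snps(table, params)["status"] == "pass"))
            assert tighter <= base

    def test_audit_covers_every_site_once(self):
        model = hz.SpeciesPairModel(n_loci=200, prop_fixed_diff=0.2, seed=15)
        freqs = hz.draw_parental_freqs(model)
        freqs["speciesA"] = freqs["freqA"]
        freqs["speciesB"] = freqs["freqB"]
        freqs["hybrid"] = 0.5 * (freqs["freqA"] + freqs["freqB"])
        table = hz.simulate_pool_counts(freqs, model)
        calls = call_diagnostic_snps(table)
        assert len(calls) == len(table)
        assert set(calls["status"]) <= {"pass", "fail"}
        failing = calls[calls["status"] == "fail"]
        assert (failing["fail_reasons"].str.len() > 0).all()


class TestFlankFilter:
    def test_boundary_arithmetic_of_the_100bp_rule(self):
        calls = pd.DataFrame({"contig": ["c1", "c1"], "pos": [100, 101],
                              "status": ["pass", "pass"]})
        out = filter_flanks(calls, {"c1": 500})
        assert not out.loc[0, "flank_eligible"]   # only 99 bp on the left
        assert out.loc[1, "flank_eligible"]

    def test_right_flank_boundary(self):
        calls = pd.DataFrame({"contig": ["c1", "c1"], "pos": [400, 401],
                              "status": ["pass", "pass"]})
        out = filter_flanks(calls, {"c1": 500})
        assert out.loc[0, "flank_eligible"]       # 100 bp right of pos 400
        assert not out.loc[1, "flank_eligible"]

    def test_clean_flank_mode_flags_mutual_conflicts(self):
        calls = pd.DataFrame({"contig": ["c1", "c1"], "pos": [200, 250],
                              "status": ["pass", "pass"]})
        variants = calls[["contig", "pos"]]
        out = filter_flanks(calls, {"c1": 1000},
                            all_variant_positions=variants, clean_flank=True)
        assert not out["flank_eligible"].any()
        assert (out["flank_reason"].str.contains("flank_conflict")).all()

    def test_matches_brute_force_recheck_on_random_positions(self):
        rng = np.random.default_rng(16)
        n = 10_000
        lengths = {f"c{i}": int(rng.integers(150, 3000)) for i in range(200)}
        contigs = rng.choice(list(lengths), size=n)
        pos = np.array([rng.integers(1, lengths[c] + 1) for c in contigs])
        calls = pd.DataFrame({"contig": contigs, "pos": pos,
                              "status": "pass"})
        out = filter_flanks(calls, lengths)
        brute = np.array([(p - 1) >= 100 and (lengths[c] - p) >= 100
                          for c, p in zip(contigs, pos)])
        assert (out["flank_eligible"].to_numpy() == brute).all()

    def test_unknown_contig_raises(self):
        calls = pd.DataFrame({"contig": ["nope"], "pos": [5],
                              "status": ["pass"]})
        with pytest.raises(KeyError):
            filter_flanks(calls, {"c1": 100})


class TestPanelExport:
    def _calls(self, tmp_path, n=30):
        model = hz.SpeciesPairModel(n_loci=300, prop_fixed_diff=0.2, seed=17)
        freqs = hz.draw_parental_freqs(model)
        freqs["speciesA"] = freqs["freqA"]
        freqs["speciesB"] = freqs["freqB"]
        freqs["hybrid"] = 0.5 * (freqs["freqA"] + freqs["freqB"])
        table = hz.simulate_pool_counts(freqs, model, contig_length=2000)
        calls = call_diagnostic_snps(table)
        lengths = dict(zip(table["contig"], table["contig_length"]))
        return filter_flanks(calls, lengths, params=DiscoveryParams()), lengths

    def test_roundtrip_is_lossless(self, tmp_path):
        calls, lengths = self._calls(tmp_path)
        vcf = tmp_path / "panel.vcf"
        n = export_panel(calls, str(vcf), str(tmp_path / "sheet.tsv"),
                         contig_lengths=lengths)
        back = read_panel_vcf(str(vcf))
        assert len(back) == n
        kept = calls[(calls["status"] == "pass")
                     & calls["flank_eligible"]].reset_index(drop=True)
        assert (back["contig"] == kept["contig"]).all()
        assert (back["pos"].to_numpy() == kept["pos"].to_numpy()).all()
        assert (back["alleleA"] == kept["alleleA"]).all()
        assert np.allclose(back["hybrid_maf"], kept["hybrid_maf"], atol=1e-6)

    def test_empty_pass_set_yields_valid_headers_only_vcf(self, tmp_path):
        calls = pd.DataFrame({"contig": ["c1"], "pos": [50],
                              "alleleA": ["C"], "alleleB": ["T"],
                              "hybrid_maf": [0.0], "depthA": [20],
                              "depthB": [20], "depthHybrid": [20],
                              "status": ["fail"], "fail_reasons": ["hybrid_maf"]})
        vcf = tmp_path / "empty.vcf"
        n = export_panel(calls, str(vcf), str(tmp_path / "sheet.tsv"))
        assert n == 0
        assert len(read_panel_vcf(str(vcf))) == 0
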