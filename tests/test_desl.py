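"""DESL analysis: feature tiling, counting, NB test, calling, enrichment."""

import numpy as np
import pandas as pd
import pytest

from ectosrna.core import GenomicFeature, MappedRead, MiRNALocus
from ectosrna.desl import (
    build_features,
    call_desl,
    count_features,
    desl_deg_overlap,
    mirna_enrichment_test,
    nb_test,
    size_factors,
)
from ectosrna.stats import bh_adjust
from ectosrna.synthdata import SimConfig, sample_groups, simulate_counts


def _gene(contig, start, end, strand, gid):
    return GenomicFeature(contig, start, end, strand, gid, "gene")


class TestBuildFeatures:
    def test_twelve_kb_gap_tiles_into_three_bins(self):
        ann = [_gene("c1", 1000, 5000, "+", "geneA"),
               _gene("c1", 17000, 20000, "+", "geneB")]
        feats = build_features(ann, [], {"c1": 20000}, bin_size=5000)
        plus_bins = [f for f in feats if f.category == "intergenic_bin"
                     and f.strand == "+" and f.feature_id.startswith("geneA")]
        assert [(f.start, f.end) for f in plus_bins] == [
            (5000, 10000), (10000, 15000), (15000, 17000)
        ]
        assert [f.feature_id for f in plus_bins] == [
            "geneA_1+", "geneA_2+", "geneA_3+"
        ]

    def test_leading_gap_uses_start_sentinel(self):
        ann = [_gene("c1", 1000, 5000, "+", "geneA")]
        feats = build_features(ann, [], {"c1": 5000})
        lead = [f for f in feats if f.strand == "+" and f.start == 0]
        assert lead[0].feature_id == "c1_START_1+"

    def test_zero_gap_produces_no_bin(self):
        ann = [_gene("c1", 0, 5000, "+", "geneA"),
               _gene("c1", 5000, 10000, "+", "geneB")]
        feats = build_features(ann, [], {"c1": 10000})
        assert not any(
            f.category == "intergenic_bin" and f.strand == "+" for f in feats
        )

    def test_mirna_loci_excluded_from_bins(self):
        locus = MiRNALocus("mir1", "c1", "+", (2000, 2021), (2036, 2057), "5p",
                           "T" + "A" * 20, "T" * 21)
        feats = build_features([], [locus], {"c1": 4057})
        assert any(f.feature_id == "mir1" for f in feats)
        for f in feats:
            if f.category == "intergenic_bin" and f.strand == "+":
                assert f.end <= 2000 or f.start >= 2057

    @pytest.mark.parametrize("seed", range(3))
    def test_per_strand_coverage_is_exact_partition(self, seed):
        rng = np.random.default_rng(seed)
        length = 30_000
        ann = []
        pos = 0
        i = 0
        while pos + 3000 < length:
            start = pos + int(rng.integers(200, 2000))
            end = start + int(rng.integers(500, 4000))
            if end >= length:
                break
            ann.append(_gene("c1", start, end,
                             "+-"[int(rng.integers(0, 2))], f"g{i}"))
            pos = end
            i += 1
        feats = build_features(ann, [], {"c1": length}, bin_size=5000)
        for strand in "+-":
            ivs = sorted((f.start, f.end) for f in feats if f.strand == strand)
            assert ivs[0][0] == 0 and ivs[-1][1] == length
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 == s2  # disjoint and gapless

    def test_unknown_contig_rejected(self):
        with pytest.raises(ValueError, match="contig"):
            build_features([_gene("cX", 0, 10, "+", "g")], [], {"c1": 100})


def _read(contig, start, length, strand, n_loci=1):
    return MappedRead(contig, start, start + length, strand,
                      "A" * length, n_loci)


class TestCountFeatures:
    def _features(self):
        return [
            _gene("c1", 0, 1000, "+", "gA"),
            _gene("c1", 1000, 2000, "+", "gB"),
            GenomicFeature("c1", 0, 2000, "-", "binR", "intergenic_bin"),
        ]

    def test_sense_only_counting(self):
        feats = self._features()
        m = count_features(feats, {"s": [_read("c1", 100, 21, "+")]})
        assert m.loc["gA", "s"] == 1 and m.loc["binR", "s"] == 0

    def test_antisense_read_goes_to_reverse_bin(self):
        feats = self._features()
        m = count_features(feats, {"s": [_read("c1", 100, 21, "-")]})
        assert m.loc["binR", "s"] == 1 and m.loc["gA", "s"] == 0

    def test_min_read_length_excludes_short(self):
        feats = self._features()
        reads = [_read("c1", 100, 14, "+"), _read("c1", 100, 15, "+")]
        m = count_features(feats, {"s": reads}, min_read_len=15)
        assert m.loc["gA", "s"] == 1

    def test_boundary_read_assigned_to_larger_overlap(self):
        feats = self._features()
        # 21-nt read spanning gA|gB boundary: 6 bases in gA, 15 in gB
        m = count_features(feats, {"s": [_read("c1", 994, 21, "+")]})
        assert m.loc["gB", "s"] == 1 and m.loc["gA", "s"] == 0

    def test_tie_goes_leftmost(self):
        feats = [_gene("c1", 0, 1000, "+", "gA"), _gene("c1", 1000, 2000, "+", "gB")]
        # 20-nt read split 10/10
        m = count_features(feats, {"s": [_read("c1", 990, 20, "+")]})
        assert m.loc["gA", "s"] == 1

    def test_multimapper_counts_each_placement(self):
        feats = self._features()
        placements = [_read("c1", 100, 21, "+", n_loci=2),
                      _read("c1", 1500, 21, "+", n_loci=2)]
        m = count_features(feats, {"s": placements})
        assert m.loc["gA", "s"] == 1 and m.loc["gB", "s"] == 1

    def test_matches_bruteforce_on_simulated_reads(self, small_study):
        truth = small_study["truth"]
        feats = build_features(
            small_study["features"], truth.loci, truth.contig_lengths
        )
        reads = small_study["total"][:500]
        m = count_features(feats, {"s": reads})
        brute = {f.feature_id: 0 for f in feats}
        for r in reads:
            if len(r) < 15:
                continue
            best, best_ov = None, 0
            for f in feats:  # features sorted as produced; leftmost-first
                if f.contig != r.contig or f.strand != r.strand:
                    continue
                ov = min(f.end, r.end) - max(f.start, r.start)
                if ov > best_ov or (
                    ov == best_ov and best is not None and ov > 0
                    and f.start < best.start
                ):
                    best, best_ov = f, ov
            if best is not None:
                brute[best.feature_id] += 1
        assert {k: int(v) for k, v in m["s"].items()} == brute

    def test_counting_conservation(self, small_study):
        truth = small_study["truth"]
        feats = build_features(
            small_study["features"], truth.loci, truth.contig_lengths
        )
        reads = small_study["total"]
        m = count_features(feats, {"s": reads})
        n_pass = sum(1 for r in reads if len(r) >= 15)
        assert int(m["s"].sum()) == n_pass


class TestSizeFactors:
    def test_all_equal_samples_give_unit_factors(self):
        m = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]},
                         index=["f1", "f2", "f3"])
        assert size_factors(m).to_numpy() == pytest.approx([1.0, 1.0])

    def test_doubling_a_sample_doubles_its_factor(self):
        m = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]},
                         index=["f1", "f2", "f3"])
        f = size_factors(m)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_recovers_simulated_depth_ratios(self):
        cfg = SimConfig(seed=8, frac_de=0.0, nb_mean=200.0)
        m, _ = simulate_counts([f"f{i}" for i in range(2000)], cfg, 2)
        scale = np.array([1.0, 2.0, 0.5, 1.0])
        scaled = (m.to_numpy(float) * scale).round().astype(int)
        m2 = pd.DataFrame(scaled, index=m.index, columns=m.columns)
        f = size_factors(m2).to_numpy()
        rel = f / np.exp(np.mean(np.log(f)))
        expect = scale / np.exp(np.mean(np.log(scale)))
        assert rel == pytest.approx(expect, rel=0.05)


class TestNbTest:
    def test_null_type_i_calibration(self):
        cfg = SimConfig(seed=1, frac_de=0.0)
        m, _ = simulate_counts([f"f{i}" for i in range(5000)], cfg, 3)
        diff = nb_test(m, sample_groups(m))
        rate = float((diff["pvalue"] < 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_power_on_planted_effects(self):
        cfg = SimConfig(seed=2, frac_de=0.1, lfc_de=2.0, nb_mean=100.0,
                        nb_dispersion=0.1)
        ids = [f"f{i}" for i in range(5000)]
        m, truth = simulate_counts(ids, cfg, 3)
        diff = nb_test(m, sample_groups(m))
        called = call_desl(diff, 0.05)
        de = set(truth.de_lfc)
        assert len(called & de) / len(de) >= 0.9

    def test_fdr_controlled_on_mixture(self):
        cfg = SimConfig(seed=4, frac_de=0.1, lfc_de=2.0)
        ids = [f"f{i}" for i in range(5000)]
        m, truth = simulate_counts(ids, cfg, 3)
        called = call_desl(nb_test(m, sample_groups(m)), 0.05)
        de = set(truth.de_lfc)
        fdr = len(called - de) / max(len(called), 1)
        assert fdr <= 0.05 + 0.025  # Monte-Carlo slack

    def test_identical_counts_give_null_result(self):
        m = pd.DataFrame({"s1": [5], "s2": [5], "s3": [5], "s4": [5]},
                         index=["f"])
        d = nb_test(m, ["g1", "g1", "g2", "g2"])
        assert d.loc["f", "log2FC"] == 0.0
        assert d.loc["f", "pvalue"] == pytest.approx(1.0)

    def test_single_replicate_group_rejected(self):
        m = pd.DataFrame({"s1": [5], "s2": [6], "s3": [7]}, index=["f"])
        with pytest.raises(ValueError, match="replicates"):
            nb_test(m, ["g1", "g1", "g2"])

    def test_all_zero_features_excluded_from_bh(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(50, (20, 4))
        counts[5] = 0
        counts[11] = 0
        m = pd.DataFrame(counts, index=[f"f{i}" for i in range(20)],
                         columns=["a", "b", "c", "d"])
        d = nb_test(m, ["g1", "g1", "g2", "g2"])
        assert np.isnan(d.loc["f5", "pvalue"]) and np.isnan(d.loc["f5", "padj"])
        tested = d["pvalue"].notna()
        assert d.loc[tested, "padj"].to_numpy() == pytest.approx(
            bh_adjust(d.loc[tested, "pvalue"].to_numpy())
        )

    def test_padj_never_below_pvalue(self):
        cfg = SimConfig(seed=6, frac_de=0.05)
        m, _ = simulate_counts([f"f{i}" for i in range(500)], cfg, 3)
        d = nb_test(m, sample_groups(m)).dropna()
        assert (d["padj"] >= d["pvalue"] - 1e-12).all()


class TestCallAndOverlap:
    def test_deg_thresholds_stricter_than_desl(self):
        from ectosrna.desl import call_degs

        cfg = SimConfig(seed=9, frac_de=0.1, lfc_de=2.0)
        m, truth = simulate_counts([f"f{i}" for i in range(2000)], cfg, 3)
        diff = nb_test(m, sample_groups(m))
        degs = call_degs(diff)
        desls = call_desl(diff, 0.05, 0.0)
        assert degs <= desls
        assert degs  # |lfc|=2 effects clear the 0.001 / >=1 thresholds

    def test_thresholds(self):
        d = pd.DataFrame(
            {"log2FC": [2.0, 0.5, -3.0], "padj": [0.001, 0.2, 0.04]},
            index=["a", "b", "c"],
        )
        assert call_desl(d, 0.05, 1.0) == {"a", "c"}
        assert call_desl(d, 0.05, 0.0) == {"a", "c"}
        assert call_desl(d, 1.01, 0.0) == {"a", "b", "c"}
        assert call_desl(pd.DataFrame(), 0.05) == set()

    def test_overlap_properties(self):
        rng = np.random.default_rng(5)
        a = {f"x{i}" for i in rng.integers(0, 100, 40)}
        b = {f"x{i}" for i in rng.integers(0, 100, 40)}
        n, ids = desl_deg_overlap(a, b)
        assert n == len(a & b) <= min(len(a), len(b))
        assert desl_deg_overlap(b, a)[0] == n
        assert ids == sorted(a & b)


class TestEnrichment:
    def test_reported_counts_underflow(self):
        for n_mirna, n_desl_mirna in ((59, 36), (295, 101)):
            chi2, p = mirna_enrichment_test(n_desl_mirna, n_mirna, 911, 78512)
            assert p < 2.2e-16
            assert chi2 > 0

    def test_equal_rates_give_zero(self):
        chi2, p = mirna_enrichment_test(10, 100, 100, 1000)
        assert chi2 == pytest.approx(0.0, abs=1e-9)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            mirna_enrichment_test(50, 40, 100, 1000)
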