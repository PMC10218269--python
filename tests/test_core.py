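import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuromethyl import core
from neuromethyl.io import CytosineRecord, GenomicFeature

from _oracles import brute_metagene_bins, brute_weighted_level


def sample_from(rows, name="s"):
    recs = [CytosineRecord(*r) for r in rows]
    return core.MethylomeSample.from_records(name, recs)


class TestNonconversion:
    def test_all_unmethylated_gives_zero_rates(self):
        rows = [("chrL", i, "+", ctx, 0, 10)
                for i, ctx in enumerate(["CG", "CA", "CC", "CT"])]
        nc = core.estimate_nonconversion(sample_from(rows))
        assert all(v == 0.0 for v in nc.rates.values())

    def test_rate_is_pooled_count_ratio(self):
        rows = ([("chrL", i, "+", "CA", 1, 200) for i in range(5)]
                + [("chrL", 50 + i, "+", ctx, 0, 10)
                   for i, ctx in enumerate(["CG", "CC", "CT"])])
        nc = core.estimate_nonconversion(sample_from(rows))
        assert nc.rate("CA") == pytest.approx(5 / 1000)

    def test_ch_rate_pools_subcontexts(self):
        rows = [("chrL", 0, "+", "CA", 4, 100), ("chrL", 1, "+", "CC", 0, 100),
                ("chrL", 2, "+", "CT", 2, 100), ("chrL", 3, "+", "CG", 0, 10)]
        nc = core.estimate_nonconversion(sample_from(rows))
        assert nc.rate("CH") == pytest.approx(6 / 300)

    def test_zero_calls_in_context_names_it(self):
        rows = [("chrL", i, "+", ctx, 0, 10)
                for i, ctx in enumerate(["CG", "CA", "CC"])]
        rows.append(("chrL", 9, "+", "CT", 0, 0))
        with pytest.raises(ValueError, match="CT"):
            core.estimate_nonconversion(sample_from(rows))


class TestWeightedLevel:
    def test_pooled_counts_not_mean_of_levels(self):
        # two CA sites 3/4 and 1/6: pooled 4/10, not mean(0.75, 0.167)
        s = sample_from([("chr1", 10, "+", "CA", 3, 4), ("chr1", 20, "-", "CA", 1, 6)])
        wl = core.weighted_level(s, "CA")
        assert wl.raw_level == pytest.approx(0.4)

    def test_correction_clips_at_zero(self):
        s = sample_from([("chr1", 10, "+", "CG", 7, 1000)])
        nc = core.NonconversionRates({"CG": 10, "CA": 0, "CC": 0, "CT": 0},
                                     {"CG": 1000, "CA": 1, "CC": 1, "CT": 1})
        wl = core.weighted_level(s, "CG", nc)
        assert wl.raw_level == pytest.approx(0.007)
        assert wl.corrected_level == 0.0

    def test_zero_call_scope_is_missing_not_zero(self):
        s = sample_from([("chr1", 10, "+", "CG", 0, 0)])
        wl = core.weighted_level(s, "CG")
        assert wl.missing and np.isnan(wl.corrected_level) and wl.reason

    def test_region_restriction_half_open(self):
        s = sample_from([("chr1", 9, "+", "CA", 1, 1), ("chr1", 10, "+", "CA", 0, 1),
                         ("chr1", 19, "+", "CA", 0, 1), ("chr1", 20, "+", "CA", 1, 1)])
        region = GenomicFeature("chr1", 10, 20, "r")
        wl = core.weighted_level(s, "CA", region=region)
        assert (wl.m_calls, wl.total_calls) == (0, 2)

    def test_ch_pools_against_brute_force(self, neuron_pair):
        a, _, ncs = neuron_pair
        recs = a.records()
        for context in ("CH", "CA", "CG"):
            nc = ncs["invitro"].rate(context)
            raw, corr = brute_weighted_level(recs, context, nc)
            wl = core.weighted_level(a, context, ncs["invitro"])
            assert wl.raw_level == pytest.approx(raw, abs=1e-12)
            assert wl.corrected_level == pytest.approx(corr, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 500), st.sampled_from(["CG", "CA", "CC", "CT"]),
                              st.integers(0, 20), st.integers(0, 20)),
                    min_size=1, max_size=40, unique_by=lambda t: t[0]))
    def test_matches_oracle_on_random_instances(self, raw_rows):
        rows = [("chr1", pos, "+", ctx, min(m, t), t) for pos, ctx, m, t in raw_rows]
        s = sample_from(rows)
        region = GenomicFeature("chr1", 100, 400, "r")
        for context in ("CG", "CH", "CT"):
            expected = brute_weighted_level(s.records(), context, region=region)
            wl = core.weighted_level(s, context, region=region)
            if expected is None:
                assert wl.missing
            else:
                assert wl.raw_level == pytest.approx(expected[0], abs=1e-12)


class TestAggregateByFeature:
    def test_feature_with_no_cytosines_is_missing(self):
        s = sample_from([("chr1", 10, "+", "CG", 1, 2)])
        f = GenomicFeature("chr1", 500, 600, "empty")
        df = core.aggregate_by_feature(s, [f], "CG", min_calls=1)
        assert bool(df.loc[0, "missing"]) and np.isnan(df.loc[0, "corrected_level"])

    def test_whole_chromosome_feature_equals_global(self, neuron_pair):
        a, _, ncs = neuron_pair
        f = GenomicFeature("chr1", 0, 10**9, "all")
        df = core.aggregate_by_feature(a, [f], "CH", ncs["invitro"], min_calls=1)
        wl = core.weighted_level(a, "CH", ncs["invitro"])
        assert df.loc[0, "corrected_level"] == pytest.approx(wl.corrected_level, abs=1e-15)

    def test_overlapping_features_both_counted(self):
        s = sample_from([("chr1", 10, "+", "CG", 2, 4)])
        feats = [GenomicFeature("chr1", 0, 20, "f1"), GenomicFeature("chr1", 5, 15, "f2")]
        df = core.aggregate_by_feature(s, feats, "CG", min_calls=1)
        assert (df["m_calls"] == 2).all()

    def test_random_features_match_brute_force(self, neuron_pair):
        a, _, _ = neuron_pair
        rng = np.random.default_rng(7)
        feats = []
        for i in range(100):
            start = int(rng.integers(0, 149_000))
            feats.append(GenomicFeature("chr1", start, start + int(rng.integers(200, 3000)),
                                        f"f{i}"))
        df = core.aggregate_by_feature(a, feats, "CA", min_calls=1)
        recs = a.records()
        for i, f in enumerate(feats):
            expected = brute_weighted_level(recs, "CA", region=f)
            if expected is None:
                assert bool(df.loc[i, "missing"])
            else:
                assert df.loc[i, "raw_level"] == pytest.approx(expected[0], abs=1e-12)

    def test_below_min_calls_flagged_missing(self):
        s = sample_from([("chr1", 10, "+", "CG", 2, 4)])
        df = core.aggregate_by_feature(s, [GenomicFeature("chr1", 0, 20, "f")],
                                       "CG", min_calls=5)
        assert bool(df.loc[0, "missing"])


class TestMetageneProfile:
    def test_uniform_methylation_gives_flat_profile(self):
        rows = [("chr1", p, "+", "CG", 3, 10) for p in range(0, 30_000, 25)]
        s = sample_from(rows)
        genes = [GenomicFeature("chr1", 10_000, 14_000, "g1", "gene", "+"),
                 GenomicFeature("chr1", 20_000, 26_000, "g2", "gene", "-")]
        prof = core.metagene_profile(s, genes, "CG", flank_bp=2_000,
                                     n_body_bins=10, n_flank_bins=4)
        assert np.allclose(prof["raw_level"], 0.3)

    def test_minus_strand_gene_mirrors_plus_strand(self):
        rng = np.random.default_rng(3)
        flank, gene_len = 500, 2_000
        pos_a = np.arange(1_000 - flank, 1_000 + gene_len + flank, 13)
        counts = rng.integers(0, 8, size=(len(pos_a), 2))
        rows = [("chr1", int(p), "+", "CA", int(min(m, t)), int(t))
                for p, (m, t) in zip(pos_a, counts)]
        # mirrored gene on the minus strand at [9000, 11000)
        mirror = lambda p: 9_000 + (gene_len - 1) - (p - 1_000)
        rows += [("chr1", int(mirror(p)), "-", "CA", int(min(m, t)), int(t))
                 for p, (m, t) in zip(pos_a, counts)]
        s = sample_from(rows)
        gene_plus = GenomicFeature("chr1", 1_000, 1_000 + gene_len, "gp", "gene", "+")
        gene_minus = GenomicFeature("chr1", 9_000, 9_000 + gene_len, "gm", "gene", "-")
        p1 = core.metagene_profile(s, [gene_plus], "CA", flank_bp=flank,
                                   n_body_bins=8, n_flank_bins=4)
        p2 = core.metagene_profile(s, [gene_minus], "CA", flank_bp=flank,
                                   n_body_bins=8, n_flank_bins=4)
        assert np.array_equal(p1["m_calls"], p2["m_calls"])
        assert np.array_equal(p1["total_calls"], p2["total_calls"])

    def test_bin_assignment_matches_case_analysis_oracle(self, neuron_pair, ann_small):
        a, _, _ = neuron_pair
        genes = ann_small.genes[:10]
        prof = core.metagene_profile(a, genes, "CG", flank_bp=1_000,
                                     n_body_bins=12, n_flank_bins=5)
        ca = a.data[a.data["context"] == "CG"]
        sites = list(zip(ca["chrom"], ca["pos"], ca["count_m"], ca["count_total"]))
        m = np.zeros(22, dtype=int)
        t = np.zeros(22, dtype=int)
        for gene in genes:
            for b, cm, ct in brute_metagene_bins(sites, gene, 1_000, 12, 5):
                m[b] += cm
                t[b] += ct
        assert np.array_equal(prof["m_calls"].to_numpy(), m)
        assert np.array_equal(prof["total_calls"].to_numpy(), t)

    def test_strandless_gene_rejected(self):
        s = sample_from([("chr1", 10, "+", "CG", 1, 2)])
        with pytest.raises(ValueError, match="strand"):
            core.metagene_profile(s, [GenomicFeature("chr1", 0, 100, "g")], "CG")


class TestFeatureClassSummary:
    def test_missing_class_listed(self, neuron_pair, ann_small):
        a, _, _ = neuron_pair
        classes = ann_small.feature_classes()
        del classes["CGI"]
        with pytest.raises(ValueError, match="CGI"):
            core.feature_class_summary(a, classes, "CG")

    def test_exons_covering_everything_equal_genome(self):
        rows = [("chr1", p, "+", "CG", 2, 5) for p in range(0, 1_000, 10)]
        s = sample_from(rows)
        whole = [GenomicFeature("chr1", 0, 1_000, "x", "exon")]
        classes = {"intergenic": whole, "introns": whole, "exons": whole,
                   "CGI": whole, "TSS_window": [GenomicFeature("chr1", 0, 1000, "t")]}
        df = core.feature_class_summary(s, classes, "CG").set_index("feature_class")
        assert df.loc["exons", "raw_level"] == df.loc["whole_genome", "raw_level"]

    def test_recovers_cgi_vs_genebody_setpoints(self, cfg_small, ann_small, neuron_pair):
        a, _, ncs = neuron_pair
        profile = cfg_small.group_profiles["invitro_neuron"]
        df = core.feature_class_summary(a, ann_small.feature_classes(), "CG",
                                        ncs["invitro"]).set_index("feature_class")
        cgi = df.loc["CGI"]
        se = np.sqrt(profile.mcg_cgi * (1 - profile.mcg_cgi) / cgi["total_calls"])
        assert abs(cgi["corrected_level"] - profile.mcg_cgi) < 3 * se + 0.01

    def test_tss_windows_are_1kb(self, ann_small):
        assert all(f.length == 1000 for f in ann_small.tss_windows)


def test_pooling_property_union_of_disjoint_regions(neuron_pair):
    """Weighted level of a union equals count pooling of parts, not level means."""
    a, _, _ = neuron_pair
    r1 = GenomicFeature("chr1", 0, 50_000, "r1")
    r2 = GenomicFeature("chr1", 50_000, 150_000, "r2")
    whole = GenomicFeature("chr1", 0, 150_000, "w")
    w1 = core.weighted_level(a, "CA", region=r1)
    w2 = core.weighted_level(a, "CA", region=r2)
    ww = core.weighted_level(a, "CA", region=whole)
    pooled = (w1.m_calls + w2.m_calls) / (w1.total_calls + w2.total_calls)
    assert ww.raw_level == pytest.approx(pooled, abs=1e-15)
    assert ww.raw_level != pytest.approx((w1.raw_level + w2.raw_level) / 2, abs=1e-6)


def test_correction_monotone_in_nonconversion():
    s = sample_from([("chr1", 10, "+", "CG", 50, 100)])
    levels = []
    for nc_m in (0, 5, 10, 20):
        nc = core.NonconversionRates({"CG": nc_m, "CA": 0, "CC": 0, "CT": 0},
                                     {"CG": 1000, "CA": 1, "CC": 1, "CT": 1})
        levels.append(core.weighted_level(s, "CG", nc).corrected_level)
    assert levels[0] == 0.5  # nc = 0 leaves raw untouched
    assert all(x >= y for x, y in zip(levels, levels[1:]))
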