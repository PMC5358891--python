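"""Distance-binned GWAS enrichment and the resampling burden test."""

import numpy as np
import pandas as pd
import pytest

from lpscourse import (
    SimConfig,
    burden_pvalue,
    enrichment_profile,
    gen_genome_and_variants,
    tss_burden_scores,
)
from lpscourse.enrichment import assign_bins
from lpscourse.errors import SchemaError


def tss_frame(positions, strands=None, prefix="g", chrom="chr1"):
    strands = strands or ["+"] * len(positions)
    return pd.DataFrame(
        {
            "feature_id": [f"{prefix}{i}" for i in range(len(positions))],
            "chrom": chrom,
            "tss_pos": positions,
            "strand": strands,
        }
    )


def variant_frame(rows):
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "pvalue"])


class TestAssignBins:
    def test_bin_width_and_formula(self):
        tss = tss_frame([1_000_000])
        variants = variant_frame([("rs1", "chr1", 1_001_000, 0.5)])
        out = assign_bins(variants, tss, n_bins=1000, span=1_000_000)
        # 1000 bins over 2 Mb -> 2 kb bins; offset +999 -> bin 500
        assert out.loc[0, "offset"] == 999
        assert out.loc[0, "bin_index"] == 500

    def test_strand_orientation_flips_offset(self):
        tss = tss_frame([1_000_000], strands=["-"])
        variants = variant_frame([("rs1", "chr1", 1_001_000, 0.5)])
        out = assign_bins(variants, tss, n_bins=1000, span=1_000_000)
        assert out.loc[0, "offset"] == -999  # downstream of a '-' TSS

    def test_equidistant_variant_goes_to_lower_coordinate_tss(self):
        tss = tss_frame([1_000_000, 1_002_000])
        variants = variant_frame([("rs1", "chr1", 1_001_001, 0.5)])
        out = assign_bins(variants, tss, n_bins=10, span=10_000)
        assert out.loc[0, "tss_id"] == "g0"

    def test_outside_span_unassigned_and_edge_clamped(self):
        tss = tss_frame([5_000_000])
        variants = variant_frame(
            [
                ("far", "chr1", 9_000_000, 0.5),
                ("edge", "chr1", 5_000_000 + 1_000_000 + 1, 0.5),  # offset = +span
            ]
        )
        out = assign_bins(variants, tss, n_bins=1000, span=1_000_000)
        assert pd.isna(out.loc[0, "bin_index"])
        assert out.loc[1, "bin_index"] == 999

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(4)
        tss_pos = np.sort(rng.integers(1_500_000, 20_000_000, 12))
        strands = rng.choice(["+", "-"], 12).tolist()
        tss = tss_frame(tss_pos, strands=strands)
        variants = variant_frame(
            [
                (f"rs{i}", "chr1", int(p), 0.5)
                for i, p in enumerate(rng.integers(1, 22_000_000, 800))
            ]
        )
        out = assign_bins(variants, tss, n_bins=100, span=500_000)
        for row, (_, v) in zip(out.itertuples(index=False), variants.iterrows()):
            pos0 = v["pos"] - 1
            dists = np.abs(pos0 - tss_pos)
            j = int(np.argmin(dists))  # argmin ties -> first (lower coordinate)
            sign = -1 if strands[j] == "-" else 1
            offset = (pos0 - tss_pos[j]) * sign
            if abs(offset) > 500_000:
                assert pd.isna(row.bin_index)
            else:
                expect = min(int((offset + 500_000) // 10_000), 99)
                assert row.bin_index == expect
                assert row.tss_id == f"g{j}"

    def test_no_variant_counted_twice(self):
        rng = np.random.default_rng(5)
        tss = tss_frame(np.sort(rng.integers(1_000_000, 5_000_000, 5)))
        variants = variant_frame(
            [(f"rs{i}", "chr1", int(p), 0.5)
             for i, p in enumerate(rng.integers(1, 6_000_000, 300))]
        )
        out = assign_bins(variants, tss, n_bins=50, span=400_000)
        assert len(out) == len(variants)  # one row per variant, single assignment


class TestEnrichmentProfile:
    def test_all_significant_in_tss_bin_closed_form(self):
        """Panel built so every significant variant sits in the central bin:
        that bin's ratio is (total/all_b)/(total_sig/total... ) by the global
        scaling, all other bins 0."""
        tss = tss_frame([5_000_000])
        rows = []
        # 10 significant variants right at the TSS (central bin)
        for i in range(10):
            rows.append((f"s{i}", "chr1", 5_000_001 + i, 1e-8))
        # 90 null variants spread elsewhere within the window
        for i in range(90):
            rows.append((f"n{i}", "chr1", 5_000_001 + 10_000 + 900 * i, 0.9))
        profile = enrichment_profile(variant_frame(rows), tss, alpha=1e-6,
                                     n_bins=100, span=100_000)
        t = profile.table
        central = t.loc[t["observed"] > 0]
        assert len(central) == 1
        all_b = central["all"].iloc[0]
        expected = all_b * (10 / 100)
        assert central["ratio"].iloc[0] == pytest.approx(10 / expected)
        assert t["observed"].sum() == 10  # conservation

    def test_conservation_of_significant_count(self):
        rng = np.random.default_rng(6)
        cfg = SimConfig(n_variants=3000, seed=6)
        tss = tss_frame(np.sort(rng.integers(2_000_000, 48_000_000, 20)))
        variants, _ = gen_genome_and_variants(cfg, tss)
        profile = enrichment_profile(variants, tss, alpha=cfg.sig_p_threshold)
        assigned = assign_bins(variants, tss)
        n_sig_assigned = int(
            ((assigned["pvalue"] < cfg.sig_p_threshold)
             & assigned["bin_index"].notna()).sum()
        )
        assert profile.table["observed"].sum() == n_sig_assigned

    def test_null_panel_mean_ratio_near_one(self):
        means = []
        for seed in range(5):
            cfg = SimConfig(n_variants=20_000, enrichment_fold=1.0, seed=seed)
            rng = np.random.default_rng(seed)
            tss = tss_frame(np.sort(rng.integers(2_000_000, 48_000_000, 40)))
            variants, _ = gen_genome_and_variants(cfg, tss)
            profile = enrichment_profile(variants, tss, alpha=cfg.sig_p_threshold,
                                         n_bins=200)
            means.append(profile.mean_ratio())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 1.0) <= 3 * max(se, 0.02)

    def test_zero_significant_variants_all_ratios_zero(self):
        tss = tss_frame([1_000_000])
        variants = variant_frame(
            [(f"rs{i}", "chr1", 1_000_000 + 100 * i, 0.9) for i in range(20)]
        )
        profile = enrichment_profile(variants, tss, alpha=1e-6, n_bins=10,
                                     span=10_000)
        nz = profile.table.loc[profile.table["all"] > 0, "ratio"]
        assert (nz == 0).all()


class TestBurden:
    def _panel(self, seed, fold, n_uni=100, n_set=20):
        cfg = SimConfig(seed=seed, enrichment_fold=fold, frac_enriched_tss=1.0)
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.integers(1_200_000, cfg.genome_length - 1_200_000, n_uni))
        uni = tss_frame(pos)
        sel = uni.iloc[np.sort(rng.choice(n_uni, n_set, replace=False))]
        variants, _ = gen_genome_and_variants(cfg, sel)
        return variants, sel, uni, cfg

    def test_pvalue_floor(self):
        variants, sel, uni, cfg = self._panel(1, 10.0)
        res = burden_pvalue(variants, sel, uni, alpha=cfg.sig_p_threshold,
                            n_draws=999, seed=0)
        assert res.empirical_p >= 1 / 1000
        if res.empirical_p == 1 / 1000:
            # observed beat every draw: (1 + 0) / (1 + 999)
            assert res.statistic > 0

    def test_set_equal_universe_gives_p_one(self):
        variants, sel, uni, cfg = self._panel(2, 1.0)
        res = burden_pvalue(variants, uni, uni, alpha=cfg.sig_p_threshold,
                            n_draws=199, seed=0)
        assert res.empirical_p == 1.0

    def test_planted_enrichment_detected(self):
        hits = 0
        for seed in range(5):
            variants, sel, uni, cfg = self._panel(seed, 10.0)
            res = burden_pvalue(variants, sel, uni, alpha=cfg.sig_p_threshold,
                                n_draws=199, seed=seed)
            hits += res.empirical_p <= 0.01
        assert hits >= 4

    def test_universe_must_contain_set(self):
        variants, sel, uni, _ = self._panel(3, 1.0)
        outsider = tss_frame([123_456], prefix="x")
        with pytest.raises(SchemaError):
            burden_pvalue(variants, outsider, uni, n_draws=99)

    def test_scores_zero_when_no_variants_in_window(self):
        variants = variant_frame([("rs1", "chr1", 10_000_000, 0.5)])
        tss = tss_frame([1_000_000])
        scores = tss_burden_scores(variants, tss, window=100_000)
        assert (scores == 0).all()

    def test_max_score_equals_best_variant(self):
        variants = variant_frame(
            [
                ("rs1", "chr1", 1_010_001, 1e-4),
                ("rs2", "chr1", 1_060_001, 1e-2),
                ("rs3", "chr1", 1_090_001, 1e-6),
            ]
        )
        tss = tss_frame([1_000_000])
        scores = tss_burden_scores(variants, tss, window=100_000)
        assert scores.iloc[0] == pytest.approx(6.0)
        sums = tss_burden_scores(variants, tss, window=100_000, aggregate="sum")
        # rs1 and rs2 share no 50 kb block with rs3; blocks keep their best
        assert sums.iloc[0] == pytest.approx(4.0 + 6.0)


class TestAlternativeReadings:
    def test_count_all_windows_counts_shared_variants_twice(self):
        tss = tss_frame([1_000_000, 1_050_000])
        variants = variant_frame([("rs1", "chr1", 1_025_001, 1e-8)])
        nearest = assign_bins(variants, tss, n_bins=10, span=100_000)
        assert len(nearest) == 1
        both = assign_bins(variants, tss, n_bins=10, span=100_000,
                           multiplicity="all")
        assert len(both) == 2
        assert set(both["tss_id"]) == {"g0", "g1"}

    def test_profile_plot_is_byte_deterministic(self, tmp_path):
        rng = np.random.default_rng(1)
        cfg = SimConfig(n_variants=2000, seed=1)
        tss = tss_frame(np.sort(rng.integers(2_000_000, 48_000_000, 10)))
        variants, _ = gen_genome_and_variants(cfg, tss)
        profile = enrichment_profile(variants, tss, alpha=cfg.sig_p_threshold,
                                     n_bins=100)
        from lpscourse.enrichment import profile_plot

        a, b = tmp_path / "a.png", tmp_path / "b.png"
        profile_plot(profile, a)
        profile_plot(profile, b)
        assert a.read_bytes() == b.read_bytes()
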