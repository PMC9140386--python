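"""SNP index, filters, windows, the simulated null band, and interval calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsamap import (
    BulkDesign,
    CausalLocus,
    ChromSpec,
    FilterConfig,
    GenomeSpec,
    MutationModel,
    WindowConfig,
    apply_filters,
    call_candidates,
    compute_snp_index,
    delta_snp_index,
    map_dataset,
    simulate_experiment,
    simulate_null_thresholds,
    sliding_windows,
    snp_index,
    write_dataset,
)
from bsamap.mapping import null_replicate_deltas, tile_windows

from conftest import make_sites


class TestSnpIndex:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [(0, 8, 1.0), (5, 5, 0.5), (12, 4, 0.25), (0, 0, np.nan)],
    )
    def test_scalar_examples(self, ref, alt, expected):
        got = snp_index(ref, alt)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            snp_index(-1, 5)
        with pytest.raises(ValueError):
            compute_snp_index(make_sites([("chr1", 1, -1, 5, 5, 5)]))

    @pytest.mark.parametrize(
        "im,iw,expected", [(0.5, 0.5, 0.0), (1.0, 1 / 3, 2 / 3), (0.0, 1.0, -1.0)]
    )
    def test_delta_examples(self, im, iw, expected):
        assert delta_snp_index(im, iw) == pytest.approx(expected)

    def test_delta_missing_propagates(self):
        assert np.isnan(delta_snp_index(np.nan, 0.5))
        assert np.isnan(delta_snp_index(0.5, np.nan))

    @given(
        st.lists(
            st.tuples(*[st.integers(min_value=0, max_value=60)] * 4),
            min_size=1,
            max_size=30,
        )
    )
    @settings(deadline=None, max_examples=60)
    def test_table_matches_scalar_and_stays_in_bounds(self, counts):
        sites = make_sites(
            [("chr1", 10 * (i + 1), *c) for i, c in enumerate(counts)]
        )
        rec = compute_snp_index(sites)
        for i, (mr, ma, wr, wa) in enumerate(counts):
            for col, (r, a) in (("index_mut", (mr, ma)), ("index_wt", (wr, wa))):
                expect = snp_index(r, a)
                got = rec[col].iloc[i]
                assert (np.isnan(got) and np.isnan(expect)) or got == expect
        ok = rec["delta"].dropna()
        assert ((ok >= -1) & (ok <= 1)).all()
        in_bounds = rec[["index_mut", "index_wt"]].stack().dropna()
        assert ((in_bounds >= 0) & (in_bounds <= 1)).all()


class TestFilters:
    def records(self, rows):
        return compute_snp_index(make_sites(rows))

    def test_low_index_in_both_bulks_removed(self):
        rec = self.records([("chr1", 1, 18, 2, 16, 4)])  # indices 0.1, 0.2
        kept, rep = apply_filters(rec)
        assert len(kept) == 0 and rep.n_low_index == 1

    def test_one_good_bulk_retains_site(self):
        rec = self.records([("chr1", 1, 3, 27, 18, 2)])  # 0.9 / 0.1, support 27 / 2
        kept, rep = apply_filters(rec)
        assert len(kept) == 1 and rep.n_removed == 0

    def test_missing_one_bulk_removed(self):
        rec = self.records([("chr1", 1, 10, 10, 0, 0)])
        kept, rep = apply_filters(rec)
        assert len(kept) == 0 and rep.n_missing_bulk == 1

    def test_low_support_in_both_bulks_removed(self):
        rec = self.records([("chr1", 1, 10, 5, 10, 6)])  # indices 1/3, 3/8 >= 0.3
        kept, rep = apply_filters(rec)
        assert len(kept) == 0 and rep.n_low_support == 1

    @given(
        st.lists(
            st.tuples(*[st.integers(min_value=0, max_value=40)] * 4),
            max_size=40,
        )
    )
    @settings(deadline=None, max_examples=40)
    def test_filters_never_increase_count(self, counts):
        rec = self.records([("chr1", 5 * (i + 1), *c) for i, c in enumerate(counts)])
        kept, rep = apply_filters(rec)
        assert len(kept) <= len(rec)
        assert rep.n_kept == len(kept)
        assert rep.n_input == len(rec)


class TestWindows:
    def test_mean_of_three_snps(self):
        genome = GenomeSpec((ChromSpec("chr1", 1000, 1.0),))
        rec = pd.DataFrame(
            {"chrom": "chr1", "pos": [100, 200, 300], "delta": [0.2, 0.4, 0.6]}
        )
        win = sliding_windows(rec, genome, WindowConfig(1000, 1000, 3))
        assert len(win) == 1
        assert win["mean_delta"].iloc[0] == pytest.approx(0.4)

    def test_empty_window_missing(self):
        genome = GenomeSpec((ChromSpec("chr1", 1000, 1.0),))
        rec = pd.DataFrame({"chrom": [], "pos": [], "delta": []})
        win = sliding_windows(rec, genome, WindowConfig(1000, 1000, 1))
        assert win["n_snps"].iloc[0] == 0 and np.isnan(win["mean_delta"].iloc[0])

    def test_snp_shared_by_overlapping_windows(self):
        genome = GenomeSpec((ChromSpec("chr1", 300, 1.0),))
        rec = pd.DataFrame(
            {"chrom": "chr1", "pos": [50, 150, 250], "delta": [0.1, 0.5, 0.9]}
        )
        win = sliding_windows(rec, genome, WindowConfig(200, 100, 1))
        # windows [1,200], [101,300] (start 101 appended to cover the end)
        assert list(win["n_snps"]) == [2, 2]
        assert win["mean_delta"].tolist() == pytest.approx([0.3, 0.7])

    def test_window_means_match_naive_oracle(self):
        """Prefix-sum windowing equals a per-window loop on a 50-SNP toy."""
        rng = np.random.default_rng(12)
        genome = GenomeSpec(
            (ChromSpec("chrA", 100_000, 1.0), ChromSpec("chrB", 60_000, 1.0))
        )
        pos = np.sort(rng.choice(np.arange(1, 100_001), size=30, replace=False))
        posB = np.sort(rng.choice(np.arange(1, 60_001), size=20, replace=False))
        rec = pd.DataFrame(
            {
                "chrom": ["chrA"] * 30 + ["chrB"] * 20,
                "pos": np.concatenate([pos, posB]),
                "delta": rng.uniform(-1, 1, 50),
            }
        )
        cfg = WindowConfig(20_000, 7_000, 2)
        win = sliding_windows(rec, genome, cfg)
        for _, w in win.iterrows():
            sel = rec[
                (rec["chrom"] == w["chrom"])
                & (rec["pos"] >= w["start"])
                & (rec["pos"] <= w["end"])
            ]
            assert w["n_snps"] == len(sel)
            if len(sel) < cfg.min_snps_per_window:
                assert np.isnan(w["mean_delta"])
            else:
                # equal up to float summation order (prefix sums vs direct)
                assert w["mean_delta"] == pytest.approx(
                    sel["delta"].mean(), abs=1e-12
                )

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            WindowConfig(window_bp=100, step_bp=200)

    def test_window_larger_than_chromosome_single_window(self):
        genome = GenomeSpec((ChromSpec("chr1", 500, 1.0),))
        win = tile_windows(genome, WindowConfig(1000, 1000, 1))
        assert len(win) == 1
        assert (win["start"].iloc[0], win["end"].iloc[0]) == (1, 500)


class TestNullThresholds:
    def toy_records(self, n_sites=40, depth=30, seed=5):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(np.arange(1, 200_001), n_sites, replace=False))
        alt_m = rng.binomial(depth, 0.5, n_sites)
        alt_w = rng.binomial(depth, 0.5, n_sites)
        sites = make_sites(
            [
                ("chr1", int(p), depth - am, am, depth - aw, aw)
                for p, am, aw in zip(pos, alt_m, alt_w)
            ]
        )
        return compute_snp_index(sites)

    def test_same_seed_identical(self):
        genome = GenomeSpec((ChromSpec("chr1", 200_000, 1.0),))
        rec = self.toy_records()
        kw = dict(cfg=WindowConfig(50_000, 10_000, 2), genome=genome,
                  n_rep=100, seed=9)
        t1 = simulate_null_thresholds(rec, BulkDesign(), **kw)
        t2 = simulate_null_thresholds(rec, BulkDesign(), **kw)
        np.testing.assert_array_equal(t1.upper, t2.upper)
        np.testing.assert_array_equal(t1.lower, t2.lower)

    def test_band_shrinks_to_zero_with_depth_and_bulk_size(self):
        depth = 200_000
        rec = self.toy_records(depth=depth, seed=2)
        genome = GenomeSpec((ChromSpec("chr1", 200_000, 1.0),))
        t = simulate_null_thresholds(
            rec, BulkDesign(50_000, 50_000),
            cfg=WindowConfig(200_000, 200_000, 1), genome=genome,
            n_rep=200, seed=1,
        )
        assert abs(t.upper[0]) < 0.01 and abs(t.lower[0]) < 0.01
        assert t.lower[0] <= 0 <= t.upper[0]

    def test_invalid_n_rep_rejected(self):
        rec = self.toy_records()
        genome = GenomeSpec((ChromSpec("chr1", 200_000, 1.0),))
        with pytest.raises(ValueError):
            simulate_null_thresholds(rec, BulkDesign(), WindowConfig(),
                                     genome, n_rep=0)

    def test_quantiles_match_naive_oracle(self):
        """Vectorised window means + quantiles equal a pure-Python
        recomputation from the same replicate delta matrix (<= 50 sites)."""
        rec = self.toy_records(n_sites=50)
        genome = GenomeSpec((ChromSpec("chr1", 200_000, 1.0),))
        cfg = WindowConfig(50_000, 10_000, 2)
        n_rep, seed = 60, 3
        thr = simulate_null_thresholds(
            rec, BulkDesign(), cfg, genome, n_rep=n_rep, confidence=0.95,
            seed=seed,
        )
        # same replicate deltas (shared generation), independent windowing
        deltas = null_replicate_deltas(
            rec, BulkDesign(), n_rep, np.random.default_rng(seed)
        )
        windows = tile_windows(genome, cfg)
        for j, w in windows.iterrows():
            sel = [
                i
                for i, r in rec.iterrows()
                if r["chrom"] == w["chrom"] and w["start"] <= r["pos"] <= w["end"]
            ]
            if len(sel) < cfg.min_snps_per_window:
                assert np.isnan(thr.upper[j]) and np.isnan(thr.lower[j])
                continue
            means = [float(np.mean([deltas[k, i] for i in sel]))
                     for k in range(n_rep)]
            # equal up to float summation order (prefix sums vs direct)
            assert thr.lower[j] == pytest.approx(np.quantile(means, 0.025),
                                                 abs=1e-12)
            assert thr.upper[j] == pytest.approx(np.quantile(means, 0.975),
                                                 abs=1e-12)


class TestCandidateCalling:
    def _win_and_thr(self, mean_deltas, upper):
        genome = GenomeSpec((ChromSpec("chr1", len(mean_deltas) * 100, 1.0),))
        cfg = WindowConfig(100, 100, 0)
        windows = tile_windows(genome, cfg)
        windows["n_snps"] = 1
        windows["mean_delta"] = mean_deltas
        from bsamap.mapping import ThresholdCurve

        thr = ThresholdCurve(
            windows=windows[["chrom", "start", "end", "n_snps"]].copy(),
            lower=-np.asarray(upper, dtype=float),
            upper=np.asarray(upper, dtype=float),
            n_replicates=1, confidence=0.95, seed=0,
        )
        return windows, thr

    def test_all_below_threshold_empty(self):
        windows, thr = self._win_and_thr([0.1, 0.0, -0.2], [0.3, 0.3, 0.3])
        assert call_candidates(windows, thr) == []

    def test_single_exceeding_window(self):
        windows, thr = self._win_and_thr([0.1, 0.5, 0.1], [0.3, 0.3, 0.3])
        (c,) = call_candidates(windows, thr)
        assert (c.start, c.end, c.n_windows) == (101, 200, 1)
        assert c.peak_delta == 0.5

    def test_run_of_windows_merged_with_peak(self):
        windows, thr = self._win_and_thr(
            [0.4, 0.6, 0.5, 0.1, 0.4], [0.3] * 5
        )
        c1, c2 = call_candidates(windows, thr)
        assert (c1.start, c1.end, c1.n_windows) == (1, 300, 3)
        assert c1.peak_delta == 0.6 and c1.peak_pos == 150
        assert (c2.start, c2.end) == (401, 500)

    def test_missing_windows_never_called(self):
        windows, thr = self._win_and_thr([np.nan, np.nan], [0.0, 0.0])
        assert call_candidates(windows, thr) == []

    def test_misaligned_inputs_rejected(self):
        windows, thr = self._win_and_thr([0.1, 0.2], [0.3, 0.3])
        assert call_candidates(windows, thr) == []
        with pytest.raises(ValueError, match="aligned"):
            call_candidates(windows.iloc[:1], thr)


class TestMapDataset:
    def test_fixture_run_one_interval_on_causal_chromosome(
        self, tmp_path, default_genome
    ):
        causal = CausalLocus("chr2", 15_000_000, "G", "A")
        ds = simulate_experiment(genome=default_genome, causal=causal, seed=1)
        paths = write_dataset(ds, tmp_path)
        report = map_dataset(paths["vcf"], default_genome, n_rep=300, seed=7)
        assert len(report.candidates) == 1
        top = report.candidates[0]
        assert top.chrom == "chr2"
        assert top.start <= causal.pos <= top.end

    def test_rerun_identical(self, tmp_path, small_genome, small_causal):
        ds = simulate_experiment(genome=small_genome, causal=small_causal, seed=3)
        paths = write_dataset(ds, tmp_path)
        r1 = map_dataset(paths["vcf"], small_genome, n_rep=100, seed=5)
        r2 = map_dataset(paths["vcf"], small_genome, n_rep=100, seed=5)
        pd.testing.assert_frame_equal(r1.window_table, r2.window_table)
        pd.testing.assert_frame_equal(r1.snp_table, r2.snp_table)
        assert [vars(c) for c in r1.candidates] == [vars(c) for c in r2.candidates]

    def test_empty_post_filter_warns_zero_candidates(self, tmp_path, small_genome):
        from bsamap import vcfio

        sites = make_sites([("chr1", 100 + i, 10, 10, 0, 0) for i in range(5)])
        path = vcfio.write_vcf(sites, tmp_path / "allbad.vcf", genome=small_genome)
        report = map_dataset(path, small_genome, n_rep=10, seed=0)
        assert report.candidates == []
        assert any("no sites survived" in w for w in report.warnings)

    def test_malformed_vcf_cites_line(self, tmp_path):
        from bsamap.vcfio import VcfFormatError

        bad = tmp_path / "bad.vcf"
        bad.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tbulk_mut\tbulk_wt\n"
            "chr1\tnotanumber\t.\tG\tA\t.\t.\t.\tAD\t1,2\t3,4\n"
        )
        with pytest.raises(VcfFormatError, match=":3:"):
            map_dataset(bad, GenomeSpec((ChromSpec("chr1", 1000, 1.0),)))


class TestSignalDecay:
    def test_delta_decreases_with_genetic_distance(self, small_genome):
        """Binned mean delta falls off with cM distance from the causal locus
        (negative Spearman rank correlation over pooled replicates)."""
        from scipy.stats import spearmanr

        causal = CausalLocus("chr1", 2_500_000, "G", "A")
        dist, delta = [], []
        for seed in range(8):
            ds = simulate_experiment(
                genome=small_genome, causal=causal,
                mutation=MutationModel(snp_rate_per_Mb=40.0),
                n_f2=200, seed=seed,
            )
            rec = compute_snp_index(ds.sites).dropna(subset=["delta"])
            cM = small_genome.genetic_pos("chr1", rec["pos"].to_numpy())
            causal_cM = small_genome.genetic_pos("chr1", causal.pos)
            dist.extend(np.abs(cM - causal_cM).tolist())
            delta.extend(rec["delta"].tolist())
        dist, delta = np.asarray(dist), np.asarray(delta)
        bins = np.linspace(0, dist.max() + 1e-9, 11)
        centers, means = [], []
        for lo, hi in zip(bins[:-1], bins[1:]):
            m = (dist >= lo) & (dist < hi)
            if m.any():
                centers.append((lo + hi) / 2)
                means.append(delta[m].mean())
        rho, p = spearmanr(centers, means)
        assert rho < 0 and p < 0.01
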