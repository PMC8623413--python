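"""Depth binning, normalization, duplication calling and male-specific SNPs."""

import numpy as np
import pandas as pd
import pytest

from ytraffic import covdup
from ytraffic.reference import depth_naive
from ytraffic.simdata import GenomeSpec, ReadSimConfig, simulate_genome, simulate_reads


def _track(norm_male, norm_female=None, scaffold="s", bin_bp=1000):
    n = len(norm_male)
    if norm_female is None:
        norm_female = [1.0] * n
    return pd.DataFrame(
        {
            "scaffold_id": [scaffold] * n,
            "start": np.arange(n) * bin_bp,
            "end": (np.arange(n) + 1) * bin_bp,
            "norm_male": norm_male,
            "norm_female": norm_female,
        }
    )


class TestBinDepth:
    def test_constant_depth_constant_bins(self):
        d = {"s": np.full(10_000, 8.0)}
        bins = covdup.bin_depth(d, d, bin_bp=1000)
        assert len(bins) == 10
        assert (bins["mean_depth_male"] == 8.0).all()
        assert (bins["mean_depth_female"] == 8.0).all()

    def test_short_trailing_bin(self):
        d = {"s": np.ones(1_500)}
        bins = covdup.bin_depth(d, d, bin_bp=1000)
        assert list(bins["end"] - bins["start"]) == [1000, 500]
        assert (bins["mean_depth_male"] == 1.0).all()

    def test_negative_depth_rejected(self):
        d = {"s": np.array([-1.0] * 200)}
        with pytest.raises(ValueError):
            covdup.bin_depth(d, d, bin_bp=100)

    def test_simulated_depth_within_poisson_noise(self):
        scaffolds, truth = simulate_genome(GenomeSpec(1, 0, 50_000, seed=41))
        name = next(iter(scaffolds))
        reads, prov = simulate_reads(
            scaffolds, truth, ReadSimConfig(sex="male", depth=20, seed=42)
        )
        depth = covdup.depth_from_placements(prov, {name: 50_000}, 100)
        bins = covdup.bin_depth(depth, depth, bin_bp=1000)
        # bin mean noise is driven by Poisson read starts: sd = depth/sqrt(starts)
        sd = 20 / np.sqrt(20 * 1000 / 100)
        inner = bins.iloc[1:-1]  # edge bins lose reads off the scaffold ends
        assert (np.abs(inner["mean_depth_male"] - 20) <= 3.5 * sd).all()

    def test_depth_from_placements_matches_interval_painting(self):
        scaffolds, truth = simulate_genome(GenomeSpec(1, 0, 5_000, seed=43))
        name = next(iter(scaffolds))
        _, prov = simulate_reads(
            scaffolds, truth, ReadSimConfig(sex="male", depth=5, seed=44)
        )
        fast = covdup.depth_from_placements(prov, {name: 5_000}, 100)[name]
        assert np.array_equal(fast, depth_naive(prov, 5_000, 100))


class TestNormalize:
    def test_baseline_depth_normalizes_to_one(self):
        d = {"s": np.full(5_000, 12.0)}
        bins = covdup.bin_depth(d, d)
        track = covdup.normalize(bins, 12.0, 12.0)
        assert (track["norm_male"] == 1.0).all()
        assert not track["female_zero"].any()

    def test_female_zero_flag(self):
        bins = covdup.bin_depth({"s": np.full(2_000, 6.0)}, {"s": np.zeros(2_000)})
        track = covdup.normalize(bins, 6.0, 6.0)
        assert track["female_zero"].all()

    def test_implanted_male_excess_visible_in_ratio(self):
        male = np.full(20_000, 10.0)
        male[5_000:10_000] = 60.0  # 6x the female-normalized level
        bins = covdup.bin_depth({"s": male}, {"s": np.full(20_000, 10.0)})
        track = covdup.normalize(bins, 10.0, 10.0)
        window = track[(track["start"] >= 5_000) & (track["end"] <= 10_000)]
        assert np.allclose(window["norm_male"], 6.0 * window["norm_female"])

    def test_zero_baseline_rejected(self):
        bins = covdup.bin_depth({"s": np.ones(1_000)}, {"s": np.ones(1_000)})
        with pytest.raises(ValueError):
            covdup.normalize(bins, 0.0, 1.0)


class TestCallSegdups:
    def test_flat_track_no_calls(self):
        track = _track([1.0] * 50)
        assert covdup.call_segdups(track).empty

    def test_short_elevation_filtered_by_min_len(self):
        norm = [1.0] * 50
        norm[10:13] = [6.0] * 3  # 3 kb < 10 kb floor
        assert covdup.call_segdups(_track(norm), min_len_bp=10_000).empty

    def test_boundaries_recovered_within_one_bin(self):
        norm = [1.0] * 100
        norm[30:60] = [6.0] * 30
        calls = covdup.call_segdups(_track(norm))
        assert len(calls) == 1
        assert abs(calls.iloc[0]["start"] - 30_000) <= 1000
        assert abs(calls.iloc[0]["end"] - 60_000) <= 1000

    def test_gap_bridging_merges_runs(self):
        norm = [1.0] * 100
        norm[10:30] = [6.0] * 20
        norm[33:50] = [6.0] * 17  # 3-bin dip bridged at max_gap_bins=5
        calls = covdup.call_segdups(_track(norm))
        assert len(calls) == 1
        calls = covdup.call_segdups(_track(norm), max_gap_bins=0, min_len_bp=5_000)
        assert len(calls) == 2

    def test_raising_threshold_never_extends_calls(self):
        rng = np.random.default_rng(45)
        norm = 1.0 + rng.random(200) * 6.0
        prev_span = np.inf
        prev_n = np.inf
        for thr in (1.4, 2.0, 3.0, 5.0):
            calls = covdup.call_segdups(
                _track(norm), min_male_norm=thr, min_len_bp=1000, max_gap_bins=0
            )
            span = (calls["end"] - calls["start"]).sum() if len(calls) else 0
            assert span <= prev_span
            prev_span = span

    def test_calls_never_overlap(self):
        rng = np.random.default_rng(46)
        norm = np.where(rng.random(300) < 0.3, 6.0, 1.0)
        calls = covdup.call_segdups(_track(norm), min_len_bp=1000)
        calls = calls.sort_values("start")
        assert (calls["start"].to_numpy()[1:] >= calls["end"].to_numpy()[:-1]).all()


class TestCopyNumber:
    def test_single_copy_algebra(self):
        assert covdup.estimate_copy_number_from_means(1.5, 1.0) == (1, False)

    def test_ten_copy_algebra(self):
        assert covdup.estimate_copy_number_from_means(6.0, 1.0) == (10, False)

    def test_nonpositive_estimate_flagged(self):
        est, low_conf = covdup.estimate_copy_number_from_means(0.9, 1.0)
        assert est == 1 and low_conf


class TestMaleSpecificSnps:
    def _sites(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "scaffold", "position",
                "male_A", "male_C", "male_G", "male_T",
                "female_A", "female_C", "female_G", "female_T",
            ],
        )

    def test_identical_pileups_count_zero(self):
        sites = self._sites([("s", 5, 10, 0, 10, 0, 12, 0, 9, 0)])
        assert covdup.count_male_specific_snps(sites) == 0

    def test_male_only_allele_counted(self):
        sites = self._sites([("s", 5, 10, 0, 10, 0, 12, 0, 0, 0)])
        assert covdup.count_male_specific_snps(sites) == 1

    def test_thresholds_respected(self):
        # 2 male alt reads < min_male_alt
        sites = self._sites([("s", 5, 10, 0, 2, 0, 12, 0, 0, 0)])
        assert covdup.count_male_specific_snps(sites) == 0
        # female depth below the floor
        sites = self._sites([("s", 5, 10, 0, 10, 0, 3, 0, 0, 0)])
        assert covdup.count_male_specific_snps(sites) == 0

    def test_diverged_y_copy_snp_count_matches_binomial(self):
        # one hemizygous Y copy at 1% divergence over 100 kb
        from ytraffic.simdata import implant_segdup

        scaffolds, truth = simulate_genome(GenomeSpec(1, 0, 110_000, seed=47))
        name = next(iter(scaffolds))
        genome, truth = implant_segdup(
            scaffolds, (name, 0, 100_000), n_copies=1,
            per_copy_divergence=0.01, seed=48, truth=truth,
        )
        male, prov_m = simulate_reads(
            genome, truth, ReadSimConfig(sex="male", depth=20, seed=49)
        )
        female, prov_f = simulate_reads(
            genome, truth, ReadSimConfig(sex="female", depth=20, seed=50)
        )
        copy_name = truth.segdups[0].copy_scaffolds[0]
        # project Y-copy reads onto the source coordinates (no indels here)
        prov_m = prov_m.replace({"scaffold": {copy_name: name}})
        lengths = {name: len(scaffolds[name])}
        mc = covdup.allele_counts(male, prov_m, lengths)
        fc = covdup.allele_counts(female, prov_f, lengths)
        sites = covdup.pileup_sites(mc, fc)
        n = covdup.count_male_specific_snps(sites, region=(name, 0, 100_000))
        n_true = sum(1 for e in truth.segdups[0].events[0] if e[0] == "substitution")
        sd = np.sqrt(100_000 * 0.01 * 0.99)
        assert abs(n - n_true) <= 3 * sd
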