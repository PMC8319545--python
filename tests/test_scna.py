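import numpy as np
import pandas as pd
import pytest

from ffpesoma.scna import (
    Log2Profile,
    bin_genome,
    bin_offtarget_reads,
    call_gain_loss,
    compute_log2_ratio,
    estimate_purity_naive,
    mode_normalize,
    penetrance_track,
    purity_adjusted_cutoffs,
    segment_profile,
    select_replicate_by_purity,
    weighted_mode_offset,
)
from ffpesoma.synthetic import simulate_log2_profiles

LENGTHS = {"chr1": 100_000}


class TestBinning:
    def test_bins_tile_without_overlap(self):
        bins = bin_genome({"chr1": 10_500}, 1000)
        assert bins["start"].tolist() == list(range(0, 10_500, 1000))
        assert bins["end"].iloc[-1] == 10_500
        with pytest.raises(ValueError):
            bin_genome(LENGTHS, 500)

    def test_all_reads_on_target_gives_zero(self):
        targets = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                "end": [100_000]})
        _, counts = bin_offtarget_reads(
            {"chr1": np.arange(0, 90_000, 100)}, targets, LENGTHS, 1000)
        assert counts.sum() == 0

    def test_uniform_reads_no_targets_poisson_bound(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 99_000, 50_000)
        bins, counts = bin_offtarget_reads(
            {"chr1": starts}, pd.DataFrame(columns=["chrom", "start", "end"]),
            LENGTHS, 1000)
        mean = counts[:-1].mean()
        assert np.all(np.abs(counts[:-1] - mean) < 3.5 * np.sqrt(mean) + 5)

    def test_overlap_exclusion_matches_interval_oracle(self):
        rng = np.random.default_rng(1)
        starts = rng.integers(0, 98_000, 1000)
        targets = pd.DataFrame({
            "chrom": ["chr1"] * 5,
            "start": [5_000, 20_000, 40_000, 60_000, 80_000],
            "end": [6_000, 25_000, 41_000, 61_500, 82_000]})
        margin, read_length = 200, 101
        bins, counts = bin_offtarget_reads(
            {"chr1": starts}, targets, LENGTHS, 1000,
            read_length=read_length, margin=margin)
        expected = np.zeros(len(bins), dtype=int)
        for s in starts:
            on = any(s < e + margin and s + read_length > t - margin
                     for t, e in zip(targets["start"], targets["end"]))
            if not on:
                expected[s // 1000] += 1
        assert np.array_equal(counts, expected)


class TestLog2Ratio:
    def test_equal_counts_give_zero(self):
        bins = bin_genome(LENGTHS, 1000)
        counts = np.full(len(bins), 40)
        profile = compute_log2_ratio(counts, counts, bins)
        assert np.allclose(profile.log2, 0.0)

    def test_doubled_chromosome_near_plus_one(self):
        lengths = {"chr1": 50_000, "chr2": 50_000}
        bins = bin_genome(lengths, 1000)
        normal = np.full(len(bins), 100)
        tumor = normal.copy()
        chr1 = (bins["chrom"] == "chr1").to_numpy()
        tumor[chr1] *= 2
        profile = compute_log2_ratio(tumor, normal, bins)
        # library-size normalization shifts everything by log2(2/1.5)
        diff = profile.log2[chr1].mean() - profile.log2[~chr1].mean()
        assert diff == pytest.approx(1.0, abs=1e-9)

    def test_zero_coverage_bins_masked_and_dropped(self):
        bins = bin_genome({"chr1": 20_000}, 1000)
        tumor = np.full(len(bins), 50)
        normal = np.full(len(bins), 50)
        tumor[3] = 0
        normal[7] = 0
        profile = compute_log2_ratio(tumor, normal, bins)
        assert np.isnan(profile.log2[3]) and np.isnan(profile.log2[7])
        segmented = segment_profile(profile, seed=0)
        member = np.concatenate([s.bin_indices for s in segmented.segments])
        assert 3 not in member and 7 not in member

    def test_mismatched_binning_error(self):
        bins = bin_genome({"chr1": 20_000}, 1000)
        with pytest.raises(ValueError):
            compute_log2_ratio(np.ones(5), np.ones(len(bins)), bins)


class TestSegmentation:
    def test_flat_profile_rarely_splits(self):
        splits = 0
        for seed in range(20):
            [profile] = simulate_log2_profiles(
                1, {"chr1": 100_000}, 1000, events=[], noise_sd=0.05,
                seed=seed)
            segmented = segment_profile(profile, seed=seed)
            splits += len(segmented.segments) > 1
        assert splits <= 1  # >= 95% single-segment

    def test_step_breakpoint_localized(self):
        hits = 0
        for seed in range(10):
            [profile] = simulate_log2_profiles(
                1, {"chr1": 100_000}, 1000,
                events=[([0], "chr1", 50, 100, 1.0)], noise_sd=0.05,
                seed=100 + seed)
            segmented = segment_profile(profile, seed=seed)
            boundaries = {s.bin_indices[0] for s in segmented.segments}
            hits += any(abs(b - 50) <= 2 for b in boundaries)
        assert hits >= 9

    def test_deterministic_given_seed(self):
        [profile] = simulate_log2_profiles(
            1, {"chr1": 80_000}, 1000, events=[([0], "chr1", 20, 50, 0.8)],
            noise_sd=0.05, seed=7)
        a = segment_profile(profile, seed=3)
        b = segment_profile(profile, seed=3)
        assert [(s.start, s.end, s.mean) for s in a.segments] == \
            [(s.start, s.end, s.mean) for s in b.segments]


class TestModeNormalization:
    def test_shift_arithmetic(self):
        [profile] = simulate_log2_profiles(
            1, {"chr1": 100_000}, 1000,
            events=[([0], "chr1", 0, 100, 0.3), ([0], "chr1", 80, 100, 1.0)],
            noise_sd=0.01, seed=2)
        segmented = segment_profile(profile, seed=2)
        normalized = mode_normalize(segmented)
        assert normalized.mode_offset == pytest.approx(0.3, abs=1e-9)
        means = sorted(s.mean for s in normalized.segments)
        assert means[0] == pytest.approx(0.0, abs=0.02)
        assert means[-1] == pytest.approx(1.0, abs=0.02)

    def test_centered_profile_small_offset(self):
        [profile] = simulate_log2_profiles(
            1, {"chr1": 100_000}, 1000, events=[], noise_sd=0.03, seed=5)
        segmented = segment_profile(profile, seed=5)
        normalized = mode_normalize(segmented)
        assert abs(normalized.mode_offset) < 0.025 + 1e-12

    def test_tie_breaks_toward_zero(self):
        offset = weighted_mode_offset([0.5, -0.25], [10, 10])
        assert offset == pytest.approx(-0.25)

    def test_shift_equivariance_of_calls(self):
        [profile] = simulate_log2_profiles(
            1, {"chr1": 100_000}, 1000,
            events=[([0], "chr1", 60, 100, 0.9)], noise_sd=0.03, seed=9)
        cutoffs = purity_adjusted_cutoffs(0.8)
        base = call_gain_loss(mode_normalize(
            segment_profile(profile, seed=1)), cutoffs)
        shifted_profile = Log2Profile(profile.sample_id, profile.bins,
                                      profile.log2 + 0.45)
        shifted = call_gain_loss(mode_normalize(
            segment_profile(shifted_profile, seed=1)), cutoffs)
        assert [s.call for s in base.segments] == \
            [s.call for s in shifted.segments]


class TestCutoffsAndCalls:
    def test_admixture_formula(self):
        gain, loss = purity_adjusted_cutoffs(1.0, calling_factor=1.0)
        assert gain == pytest.approx(np.log2(1.5))
        assert loss == pytest.approx(-1.0)
        gain_half, _ = purity_adjusted_cutoffs(0.5, calling_factor=1.0)
        assert gain_half == pytest.approx(np.log2(1.25))

    def test_cutoffs_monotone_in_purity(self):
        purities = np.linspace(0.1, 1.0, 10)
        gains, losses = zip(*(purity_adjusted_cutoffs(p) for p in purities))
        assert np.all(np.diff(gains) > 0)
        assert np.all(np.diff(losses) < 0)

    def test_invalid_purity(self):
        with pytest.raises(ValueError):
            purity_adjusted_cutoffs(0.0)

    def test_single_sample_penetrance(self):
        profiles = simulate_log2_profiles(
            1, {"chr1": 50_000, "chr2": 50_000}, 1000,
            events=[([0], "chr1", 0, 50, 1.0)], noise_sd=0.02, seed=3)
        called = [call_gain_loss(mode_normalize(
            segment_profile(p, seed=3)), purity_adjusted_cutoffs(0.9))
            for p in profiles]
        track = penetrance_track(called)
        chr1 = (track.bins["chrom"] == "chr1").to_numpy()
        assert track.gain_fraction[chr1].mean() == pytest.approx(1.0)
        assert track.gain_fraction[~chr1].max() == 0.0

    def test_disjoint_gains_give_half_penetrance(self):
        profiles = simulate_log2_profiles(
            2, {"chr1": 50_000, "chr2": 50_000}, 1000,
            events=[([0], "chr1", 0, 50, 1.0), ([1], "chr2", 0, 50, 1.0)],
            noise_sd=0.02, seed=4)
        called = [call_gain_loss(mode_normalize(
            segment_profile(p, seed=4)), purity_adjusted_cutoffs(0.9))
            for p in profiles]
        track = penetrance_track(called)
        assert np.allclose(track.gain_fraction, 0.5)


class TestReplicateSelection:
    def test_argmax_single_and_tie(self, caplog):
        assert select_replicate_by_purity({"r1": 0.4, "r2": 0.7}) == "r2"
        assert select_replicate_by_purity({"only": 0.5}) == "only"
        with caplog.at_level("INFO"):
            assert select_replicate_by_purity({"b": 0.5, "a": 0.5}) == "a"
        with pytest.raises(ValueError):
            select_replicate_by_purity({})


class TestNaivePurity:
    def test_arithmetic_and_clipping(self):
        assert estimate_purity_naive([0.25] * 6) == pytest.approx(0.5)
        assert estimate_purity_naive([0.6] * 6) == 1.0
        with pytest.raises(ValueError):
            estimate_purity_naive([0.3] * 4)

    def test_recovers_planted_purity(self, cascade, default_cohort):
        """Clonal-VAF model: planted VAF ~ Beta with mean 0.25 emulates
        purity ~0.5; the estimator lands within +-0.1."""
        sid = default_cohort.cohort.samples[0].sample_id
        truth = default_cohort.truth_by_sample()[sid]
        vafs = [c.vaf for k, c in cascade.final[sid].items()
                if k in truth and truth[k].truth_class == "true_somatic"
                and k.is_snv]
        estimate = estimate_purity_naive(vafs)
        assert estimate == pytest.approx(0.5, abs=0.1)
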