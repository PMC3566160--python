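"""Windowed Poisson enrichment calling, smoothing, and peak splitting."""

import numpy as np
import pytest

import acetyldiff as ad
from acetyldiff.calling import (CallerParams, call_enriched_regions,
                                empirical_fdr, smooth_profile, split_region)
from acetyldiff.coverage import CoverageProfile
from acetyldiff.synthetic import PlantedRegion, SimConfig, simulate_tags
from acetyldiff.tags import TagSet


def null_pair(seed, rate=0.01, length=1_000_000):
    cfg = SimConfig(genome_length=length, n_chromosomes=1, n_genes=1,
                    background_rate=rate, seed=seed)
    return (simulate_tags(cfg, "control", "chip"),
            simulate_tags(cfg, "control", "input"), cfg.chrom_sizes())


class TestCallEnrichedRegions:
    def test_no_signal_no_regions(self):
        chip = TagSet.from_arrays(["chr1"] * 3, [10, 500, 900], ["+"] * 3)
        inp = TagSet.from_arrays(["chr1"] * 3, [20, 400, 800], ["-"] * 3)
        regions = call_enriched_regions(chip, inp, CallerParams(),
                                        {"chr1": 1_000})
        assert regions == []

    def test_empty_input_library_guidance(self):
        chip = TagSet.from_arrays(["chr1"], [10], ["+"])
        with pytest.raises(ad.DivisionError, match="pseudocount"):
            call_enriched_regions(chip, TagSet(), CallerParams(), {"chr1": 100})

    def test_planted_region_recovered_with_score_near_truth(self):
        # FE=10 plant, rate 0.01/bp, width 1 kb: exactly the plant found,
        # fold-change score in [6, 14]
        found, scores = 0, []
        for seed in range(20):
            cfg = SimConfig(genome_length=1_000_000, n_chromosomes=1,
                            n_genes=1, background_rate=0.01, seed=seed,
                            planted_regions=[
                                PlantedRegion("chr1", 500_000, 501_000, 10.0)])
            regions = call_enriched_regions(
                simulate_tags(cfg, "control", "chip"),
                simulate_tags(cfg, "control", "input"),
                CallerParams(), cfg.chrom_sizes())
            overlapping = [r for r in regions
                           if r.start < 501_000 and r.end > 500_000]
            if overlapping:
                found += 1
                scores.append(max(r.score for r in overlapping))
            assert len(regions) <= len(overlapping) + 1  # at most 1 stray
        assert found >= 19
        assert 6 <= np.median(scores) <= 14

    def test_output_sorted_by_score_then_position(self, small_regions):
        keys = [(-r.score, r.chrom, r.start) for r in small_regions]
        assert keys == sorted(keys)
        assert [r.name for r in small_regions] == \
            [f"region_{i+1:05d}" for i in range(len(small_regions))]

    def test_thresholds_monotone(self, small_study):
        config, _, tags = small_study
        chip, inp = tags[("control", "chip")], tags[("control", "input")]
        sizes = config.chrom_sizes()
        base = len(call_enriched_regions(chip, inp, CallerParams(), sizes))
        stricter_fold = len(call_enriched_regions(
            chip, inp, CallerParams(min_fold=8), sizes))
        stricter_fdr = len(call_enriched_regions(
            chip, inp, CallerParams(fdr=1e-6), sizes))
        assert stricter_fold <= base
        assert stricter_fdr <= base

    def test_null_calibration_small(self):
        # a quick null check; the full 100-seed calibration runs in the
        # acceptance suite
        total = 0
        for seed in range(10):
            chip, inp, sizes = null_pair(seed)
            total += len(call_enriched_regions(chip, inp, CallerParams(),
                                               sizes))
        assert total == 0

    def test_empirical_fdr_shuffle_crosscheck(self, small_study):
        config, _, tags = small_study
        result = empirical_fdr(tags[("control", "chip")],
                               tags[("control", "input")],
                               CallerParams(), config.chrom_sizes(),
                               n_shuffles=3, seed=1)
        assert result["observed"] > 0
        assert result["fdr_estimate"] <= 0.02


class TestSmoothProfile:
    def test_constant_profile_unchanged(self):
        prof = CoverageProfile(values={"chr1": np.full(100, 7.0)}, units="raw")
        np.testing.assert_allclose(smooth_profile(prof, 10).values["chr1"], 7.0)

    def test_spike_becomes_unit_plateau(self):
        w = 11
        v = np.zeros(100)
        v[50] = w
        prof = CoverageProfile(values={"chr1": v}, units="raw")
        sm = smooth_profile(prof, w).values["chr1"]
        plateau = np.flatnonzero(np.isclose(sm, 1.0))
        assert len(plateau) == w
        assert np.isclose(sm.sum(), w)  # mass conserved away from edges

    def test_never_increases_maximum(self):
        rng = np.random.default_rng(4)
        v = rng.poisson(5, 500).astype(float)
        prof = CoverageProfile(values={"chr1": v}, units="raw")
        for w in (2, 5, 50):
            assert smooth_profile(prof, w).values["chr1"].max() <= v.max()


def region_over(values, start=0, **kw):
    """Wrap a depth vector in a profile + matching region."""
    v = np.asarray(values, dtype=float)
    prof = CoverageProfile(values={"chr1": v}, units="raw")
    region = ad.EnrichedRegion(chrom="chr1", start=start, end=len(v),
                               chip_tags=10, input_expected=1.0, score=5.0,
                               p_value=1e-9, q_value=1e-6,
                               summit=len(v) // 2, name="r1")
    return region, prof


class TestSplitRegion:
    def test_unimodal_profile_not_split(self):
        region, prof = region_over([1, 2, 5, 9, 5, 2, 1])
        out = split_region(region, prof)
        assert len(out) == 1
        assert out[0].start == region.start and out[0].end == region.end
        assert out[0].summit == 3

    def test_deep_valley_splits_at_minimum(self):
        # maxima 10/10, valley 2 < 0.5 * 10: split fires at the valley
        region, prof = region_over([1, 5, 10, 5, 2, 5, 10, 5, 1])
        out = split_region(region, prof, valley_fraction=0.5)
        assert len(out) == 2
        assert out[0].end == out[1].start == 4  # argmin position
        assert {r.summit for r in out} == {2, 6}

    def test_shallow_valley_kept_whole(self):
        region, prof = region_over([1, 5, 10, 9, 8, 9, 10, 5, 1])
        assert len(split_region(region, prof, valley_fraction=0.5)) == 1

    def test_subregions_partition_parent(self):
        rng = np.random.default_rng(2)
        v = np.abs(np.convolve(rng.poisson(4, 400), np.ones(21) / 21, "same"))
        region, prof = region_over(v)
        out = split_region(region, prof, valley_fraction=0.9)
        bounds = [(r.start, r.end) for r in out]
        assert bounds[0][0] == region.start and bounds[-1][1] == region.end
        for (_, e1), (s2, _) in zip(bounds[:-1], bounds[1:]):
            assert e1 == s2

    def test_rescoring_with_tags(self, small_study, small_regions):
        config, _, tags = small_study
        chip, inp = tags[("control", "chip")], tags[("control", "input")]
        prof = ad.build_profile(chip, 200, config.chrom_sizes())
        sm = smooth_profile(prof, 500)
        peaks = ad.split_regions(small_regions, sm, chip=chip, input_tags=inp)
        assert len(peaks) >= len(small_regions)
        assert all(p.score > 0 for p in peaks)
        # splitting preserves total covered span
        assert (sum(p.end - p.start for p in peaks)
                == sum(r.end - r.start for r in small_regions))
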