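"""Window CN formula, segmentation, gain/loss/LOH/doubling calls."""

import numpy as np
import pytest

from preclone import copy_number as cn


class TestWindowCn:
    def test_diploid_baseline(self):
        # 500 Kb of coverage from 3 Gb of data is exactly diploid
        assert cn.window_cn(np.array([500.0]), 3.0)[0] == pytest.approx(2.0)

    def test_linear_in_coverage(self):
        out = cn.window_cn(np.array([250.0, 500.0, 1000.0]), 3.0)
        assert out == pytest.approx([1.0, 2.0, 4.0])

    def test_inverse_in_data_volume(self):
        assert cn.window_cn(np.array([500.0]), 6.0)[0] == pytest.approx(1.0)

    def test_zero_coverage(self):
        assert cn.window_cn(np.array([0.0]), 3.0)[0] == 0.0

    def test_zero_data_rejected(self):
        with pytest.raises(ValueError):
            cn.window_cn(np.array([500.0]), 0.0)

    def test_gc_normalization_flattens_bias(self):
        rng = np.random.default_rng(0)
        gc = rng.uniform(0.3, 0.6, 200)
        bias = 1.0 + 2.0 * (gc - 0.45)          # strong linear GC effect
        cov = 500.0 * bias
        raw = cn.window_cn(cov, 3.0)
        out = cn.window_cn(cov, 3.0, gc=gc)
        # normalization flattens the GC trend (scale anchors to the genome median)
        assert np.std(out) < 0.2 * np.std(raw)
        assert np.median(out) == pytest.approx(2.0, abs=0.1)


class TestSegmentation:
    def test_constant_single_segment(self):
        assert cn.segment_values(np.full(20, 2.0)) == [(0, 20, 2.0)]

    def test_noise_free_step(self):
        segs = cn.segment_values(np.array([2, 2, 2, 4, 4, 4.0]), min_width=1)
        assert segs == [(0, 3, 2.0), (3, 6, 4.0)]

    def test_noisy_step_breakpoint_within_one_window(self):
        rng = np.random.default_rng(3)
        x = np.r_[rng.normal(2, 0.15, 30), rng.normal(4, 0.15, 30)]
        segs = cn.segment_values(x, alpha=0.01, min_width=1, n_perm=500, seed=1)
        breaks = [s for s, _, _ in segs[1:]]
        assert any(abs(b - 30) <= 1 for b in breaks)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        x = np.r_[rng.normal(2, 0.4, 25), rng.normal(3, 0.4, 25)]
        a = cn.segment_values(x, seed=7, n_perm=300)
        b = cn.segment_values(x, seed=7, n_perm=300)
        assert a == b

    def test_segment_cn_respects_chromosomes(self):
        windows = [cn.CoverageWindow("chr1", i * 10, (i + 1) * 10, 500.0)
                   for i in range(4)]
        windows += [cn.CoverageWindow("chr2", i * 10, (i + 1) * 10, 1000.0)
                    for i in range(4)]
        vals = np.array([2.0] * 4 + [4.0] * 4)
        segs = cn.segment_cn(windows, vals, n_perm=100)
        assert len(segs) == 2
        assert {s.chrom for s in segs} == {"chr1", "chr2"}


class TestGainLoss:
    @pytest.mark.parametrize(
        "c,expected",
        [(2.0, "neutral"), (3.0, "gain"), (1.0, "loss"),
         (2.5, "gain"), (2.49, "neutral"), (1.5, "loss"), (1.51, "neutral")],
    )
    def test_thresholds_inclusive(self, c, expected):
        assert cn.call_gain_loss(c, 2.0) == expected

    def test_sweep_flips_exactly_at_cutoffs(self):
        sweep = np.round(np.arange(0.5, 4.0001, 0.01), 2)
        gains = [c for c in sweep if cn.call_gain_loss(float(c), 2.0) == "gain"]
        losses = [c for c in sweep if cn.call_gain_loss(float(c), 2.0) == "loss"]
        assert min(gains) == pytest.approx(2.5)
        assert max(losses) == pytest.approx(1.5)

    def test_ploidy_scaling(self):
        # CN 4 is neutral for a tetraploid sample
        assert cn.call_gain_loss(4.0, 4.0) == "neutral"

    def test_bad_ploidy(self):
        with pytest.raises(ValueError):
            cn.call_gain_loss(2.0, 0.0)


class TestFga:
    def segs(self, statuses, lengths):
        return [cn.Segment("chr1", s, e, 1, 2.0, status)
                for (s, e), status in zip(lengths, statuses)]

    def test_all_neutral(self):
        assert cn.fraction_genome_altered(
            self.segs(["neutral"] * 3, [(0, 10), (10, 20), (20, 30)])) == 0.0

    def test_half_gained(self):
        assert cn.fraction_genome_altered(
            self.segs(["gain", "neutral"], [(0, 50), (50, 100)])) == 0.5

    def test_matches_manual_summation(self):
        segs = self.segs(["gain", "loss", "neutral", "gain"],
                         [(0, 10), (10, 35), (35, 80), (80, 90)])
        manual = (10 + 25 + 10) / 90
        assert cn.fraction_genome_altered(segs) == pytest.approx(manual)

    def test_invariant_under_subdivision(self):
        whole = self.segs(["gain", "neutral"], [(0, 40), (40, 100)])
        split = self.segs(["gain", "gain", "neutral", "neutral"],
                          [(0, 20), (20, 40), (40, 70), (70, 100)])
        assert cn.fraction_genome_altered(whole) == \
            cn.fraction_genome_altered(split)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            cn.fraction_genome_altered([])


class TestLoh:
    def test_balanced_not_loh(self):
        assert cn.call_loh(np.full(10, 0.5)) is False

    def test_mirrored_deviation_is_loh(self):
        assert cn.call_loh(np.array([0.9, 0.88, 0.93, 0.1, 0.07])) is True

    def test_below_snp_minimum_indeterminate(self):
        assert cn.call_loh(np.array([0.9, 0.1, 0.9])) is None

    def test_empty_indeterminate(self):
        assert cn.call_loh(np.array([])) is None

    def test_purity_aware_threshold(self):
        # full LOH at CN 1 deviates by p / (2 (2 - p)); threshold is half that
        p = 0.6
        dev_full = p / (2 * (2 - p))
        assert cn.loh_threshold_purity_aware(p, 1) == pytest.approx(dev_full / 2)

    def test_purity_aware_call_at_low_purity(self):
        # at purity 0.3 a monoallelic deletion is invisible to the fixed
        # 0.15 default but caught by the purity-aware threshold
        p = 0.3
        baf_loh = np.full(20, (1 - p) / (2 - p))
        assert cn.call_loh(baf_loh) is False
        assert cn.call_loh(baf_loh, purity=p, cn=1) is True


class TestGenomeDoubling:
    def seg(self, length, major, minor):
        return cn.Segment("chr1", 0, length, 1, float(major + minor),
                          major=major, minor=minor)

    def test_uniform_2_2_doubled(self):
        assert cn.call_genome_doubling([self.seg(100, 2, 2)]) is True

    def test_uniform_1_1_not_doubled(self):
        assert cn.call_genome_doubling([self.seg(100, 1, 1)]) is False

    def test_sixty_percent_major_two(self):
        segs = [cn.Segment("chr1", 0, 60, 1, 4.0, major=2, minor=2),
                cn.Segment("chr1", 60, 100, 1, 2.0, major=1, minor=1)]
        assert cn.call_genome_doubling(segs) is True

    def test_insufficient_support_indeterminate(self):
        segs = [cn.Segment("chr1", 0, 30, 1, 4.0, major=2, minor=2),
                cn.Segment("chr1", 30, 100, 1, 2.0)]
        assert cn.call_genome_doubling(segs) is None


class TestPurityPloidy:
    def model(self, p, pl, cns, minors):
        dr = np.array([(c * p + 2 * (1 - p)) / (pl * p + 2 * (1 - p)) for c in cns])
        baf = np.array([(m * p + (1 - p)) / (c * p + 2 * (1 - p))
                        for c, m in zip(cns, minors)])
        return dr, baf

    def test_parameter_recovery(self):
        dr, baf = self.model(0.7, 2.0, [1, 2, 2, 3, 2, 4], [0, 1, 1, 1, 0, 2])
        p, pl, warn = cn.estimate_purity_ploidy(dr, baf, np.ones(6))
        assert not warn
        assert p == pytest.approx(0.7, abs=0.05)
        assert pl == pytest.approx(2.0, abs=0.1)

    def test_pure_diploid_degenerate(self):
        p, pl, warn = cn.estimate_purity_ploidy(
            np.ones(5), np.full(5, 0.5), np.ones(5))
        assert (p, pl, warn) == (1.0, 2.0, True)

    def test_deterministic(self):
        dr, baf = self.model(0.5, 2.5, [1, 2, 3, 4], [0, 1, 1, 2])
        a = cn.estimate_purity_ploidy(dr, baf, np.ones(4))
        b = cn.estimate_purity_ploidy(dr, baf, np.ones(4))
        assert a == b


class TestUbiquity:
    def test_ubiquitous(self):
        label, _ = cn.classify_cna_ubiquity(
            {f"s{i}": "gain" for i in range(4)})
        assert label == "ubiquitous"

    def test_partial(self):
        label, _ = cn.classify_cna_ubiquity(
            {"s1": "gain", "s2": "gain", "s3": "neutral", "s4": "neutral"})
        assert label == "partial"

    def test_breakpoint_concordance_within_one_window(self):
        label, conc = cn.classify_cna_ubiquity(
            {"s1": "gain", "s2": "gain"},
            breakpoints={"s1": (1_000_000, 3_000_000),
                         "s2": (1_400_000, 3_200_000)},
            tolerance_bp=500_000)
        assert label == "ubiquitous" and conc is True

    def test_breakpoint_discordance(self):
        _, conc = cn.classify_cna_ubiquity(
            {"s1": "gain", "s2": "gain"},
            breakpoints={"s1": (0, 3_000_000), "s2": (2_000_000, 6_000_000)},
            tolerance_bp=500_000)
        assert conc is False
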