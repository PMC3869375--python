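import math

import numpy as np
import pytest
from scipy import stats

from enact.genome_core import GenomicInterval, TagLibrary, read_bed, write_bed
from enact.island_caller import (Island, IslandParams, bh_adjust,
                                 bh_adjust_log10, candidate_islands,
                                 load_tag_library, log_poisson_sf,
                                 preprocess_tags, score_islands_vs_control,
                                 specificity_filter)
from reference_impls import brute_candidate_islands

LN10 = math.log(10)


def read(chrom, start, strand="+", length=50):
    return GenomicInterval(chrom, start, start + length, strand=strand)


class TestPreprocess:
    def test_redundancy_removal(self):
        lib = preprocess_tags([read("chr1", 1000)] * 3, IslandParams())
        assert lib.total_count == 1

    def test_plus_strand_shift(self):
        lib = preprocess_tags([read("chr1", 1000)], IslandParams(fragment_size=150))
        assert list(lib.positions["chr1"]) == [1075]

    def test_mixed_strand_oracle(self):
        # hand-computed: + reads shift +75 from start, - reads -75 from end
        reads = [read("chr1", 1000, "+"), read("chr1", 2000, "-"),
                 read("chr1", 3000, "+"), read("chr2", 100, "-")]
        lib = preprocess_tags(reads, IslandParams(fragment_size=150))
        assert list(lib.positions["chr1"]) == [1075, 1975, 3075]
        assert list(lib.positions["chr2"]) == [75]

    def test_load_tag_library_equivalent(self, tmp_path):
        rng = np.random.default_rng(3)
        reads = [read("chr1", int(s), "+" if b else "-")
                 for s, b in zip(rng.integers(100, 50_000, 500),
                                 rng.random(500) < 0.5)]
        path = tmp_path / "reads.bed"
        write_bed(reads, path)
        slow = preprocess_tags(read_bed(path), IslandParams())
        fast = load_tag_library(path, IslandParams())
        assert slow.total_count == fast.total_count
        for chrom in slow.chroms():
            assert np.array_equal(slow.positions[chrom], fast.positions[chrom])


class TestCandidateIslands:
    CHROMS = {"chr1": 1_000_000}

    def test_empty_library(self):
        assert candidate_islands(TagLibrary({}), self.CHROMS) == []

    def test_single_hot_window(self):
        # 60 tags in one 200-bp window on 1 Mb: background ~ 0
        lib = TagLibrary({"chr1": list(range(10_000, 10_060))})
        islands = candidate_islands(lib, self.CHROMS,
                                    IslandParams(window_size=200))
        assert len(islands) == 1
        isl = islands[0]
        assert (isl.interval.start, isl.interval.end) == (10_000, 10_200)
        assert isl.chip_count == 60

    @pytest.mark.parametrize("gap_windows,n_expected", [(1, 2), (2, 1)])
    def test_gap_merging(self, gap_windows, n_expected):
        """Two eligible windows separated by 2 ineligible windows merge
        only when the allowed gap is >= 2."""
        w = 200
        lib = TagLibrary({"chr1": [10_000 + i for i in range(30)]
                          + [10_600 + i for i in range(30)]})
        params = IslandParams(window_size=w, gap_windows=gap_windows)
        islands = candidate_islands(lib, self.CHROMS, params)
        assert len(islands) == n_expected

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_reference(self, seed):
        """On toy chromosomes the caller equals a window-by-window
        enumeration of the island definition."""
        rng = np.random.default_rng(seed)
        length = 50_000
        # clustered + uniform tags for interesting structure
        pos = np.concatenate([
            rng.integers(0, length, size=300),
            rng.integers(20_000, 21_000, size=100),
            rng.integers(35_000, 35_400, size=100),
        ])
        lib = TagLibrary({"chr1": pos})
        params = IslandParams(window_size=200, gap_windows=1)
        lam = lib.total_count * params.window_size / (
            length * params.effective_genome_fraction)
        expected = brute_candidate_islands(
            sorted(pos.tolist()), length, params.window_size,
            params.gap_windows, params.eligibility_p, lam)
        got = candidate_islands(lib, {"chr1": length}, params)
        assert [(i.interval.start, i.interval.end, i.chip_count)
                for i in got] == [e[:3] for e in expected]
        for isl, exp in zip(got, expected):
            assert isl.score == pytest.approx(exp[3], rel=1e-9)

    def test_islands_disjoint_and_separated(self):
        rng = np.random.default_rng(11)
        lib = TagLibrary({"chr1": rng.integers(0, 50_000, size=500)})
        params = IslandParams(window_size=200, gap_windows=1)
        islands = candidate_islands(lib, {"chr1": 50_000}, params)
        gap_bp = params.gap_windows * params.window_size
        for a, b in zip(islands, islands[1:]):
            assert b.interval.start - a.interval.end > gap_bp
        for isl in islands:
            assert isl.interval.length % params.window_size == 0


class TestScoring:
    def make_pair(self, chip_pos, ctrl_pos, length=1_000_000):
        return (TagLibrary({"chr1": chip_pos}), TagLibrary({"chr1": ctrl_pos}))

    def test_no_enrichment_not_retained(self):
        rng = np.random.default_rng(5)
        bg = rng.integers(0, 1_000_000, size=20_000)
        chip, ctrl = self.make_pair(bg, rng.integers(0, 1_000_000, size=20_000))
        params = IslandParams(window_size=200, fdr_threshold=1e-3)
        cand = candidate_islands(chip, {"chr1": 1_000_000}, params)
        retained = score_islands_vs_control(cand, chip, ctrl, params,
                                            chrom_lengths={"chr1": 1_000_000})
        assert len(retained) <= 1

    def test_strong_island_retained_at_tiny_fdr(self):
        """chip 100 tags vs control 0 at equal depth: log Poisson tail is
        ~ -158 decades, retained even at FDR 1e-15."""
        rng = np.random.default_rng(6)
        bg = rng.integers(0, 1_000_000, size=5_000)
        chip_pos = np.concatenate([bg, np.full(100, 500_050)])
        ctrl_pos = rng.integers(0, 1_000_000, size=5_100)
        ctrl_pos = ctrl_pos[(ctrl_pos < 499_000) | (ctrl_pos > 501_000)]
        chip, ctrl = self.make_pair(chip_pos, ctrl_pos)
        params = IslandParams(window_size=200, fdr_threshold=1e-15,
                              redundancy_threshold=1000)
        cand = candidate_islands(chip, {"chr1": 1_000_000}, params)
        retained = score_islands_vs_control(cand, chip, ctrl, params,
                                            chrom_lengths={"chr1": 1_000_000})
        assert any(i.interval.start <= 500_050 < i.interval.end
                   for i in retained)

    def test_fdr_threshold_monotone(self):
        rng = np.random.default_rng(8)
        bg = rng.integers(0, 200_000, size=4_000)
        peaks = np.concatenate([np.full(40, c) for c in
                                (10_050, 50_050, 90_050, 130_050)])
        chip = TagLibrary({"chr1": np.concatenate([bg, peaks])})
        ctrl = TagLibrary({"chr1": rng.integers(0, 200_000, size=4_000)})
        params_loose = IslandParams(window_size=200, fdr_threshold=1e-3)
        cand = candidate_islands(chip, {"chr1": 200_000}, params_loose)
        loose = score_islands_vs_control(cand, chip, ctrl, params_loose,
                                         chrom_lengths={"chr1": 200_000})
        strict = score_islands_vs_control(
            cand, chip, ctrl,
            IslandParams(window_size=200, fdr_threshold=1e-10),
            chrom_lengths={"chr1": 200_000})
        loose_keys = {(i.interval.start, i.interval.end) for i in loose}
        assert {(i.interval.start, i.interval.end)
                for i in strict} <= loose_keys

    def test_empty_control_rejected(self):
        chip = TagLibrary({"chr1": [1, 2, 3]})
        with pytest.raises(ValueError):
            score_islands_vs_control(
                [Island(GenomicInterval("chr1", 0, 200), 3, 1.0)],
                chip, TagLibrary({}))


class TestSpecificityFilter:
    def island_at(self, start, end=None):
        return Island(GenomicInterval("chr1", start, end or start + 200), 0, 0.0)

    def test_equal_signal_not_retained(self):
        lib = TagLibrary({"chr1": np.arange(10_000, 10_200)})
        assert specificity_filter([self.island_at(10_000)], lib, lib) == []

    def test_ablated_site_retained(self):
        ctrl = TagLibrary({"chr1": np.arange(10_000, 10_200)})   # 200 tags
        ko = TagLibrary({"chr1": np.arange(50_000, 50_200)})      # depth equal
        retained = specificity_filter([self.island_at(10_000)], ctrl, ko,
                                      fdr=1e-15)
        assert len(retained) == 1

    def test_recovers_true_sites_from_simulation(self, sim_config,
                                                 sim_annotation):
        """With artifact peaks present in both genotypes, the filter keeps
        exactly the planted MLL4-dependent sites."""
        from enact.synthetic_data import simulate_chip_tags
        params = IslandParams(window_size=50, fdr_threshold=1e-15)
        chip = preprocess_tags(
            simulate_chip_tags(sim_config, sim_annotation, "mll4", "control"),
            params)
        ko = preprocess_tags(
            simulate_chip_tags(sim_config, sim_annotation, "mll4", "ko"),
            params)
        inp = preprocess_tags(
            simulate_chip_tags(sim_config, sim_annotation, "input", "input"),
            params)
        cand = candidate_islands(chip, sim_config.chrom_lengths, params)
        called = score_islands_vs_control(cand, chip, inp, params,
                                          chrom_lengths=sim_config.chrom_lengths)
        retained = specificity_filter(called, chip, ko, fdr=1e-15)
        true_centers = [e.center for e in sim_annotation.mll4_sites]
        artifact_centers = [e.center for e in sim_annotation.elements
                            if e.kind == "artifact"]

        def covers(center):
            return any(i.interval.start - 300 <= center <= i.interval.end + 300
                       for i in retained)

        recall = np.mean([covers(c) for c in true_centers])
        artifact_hits = sum(covers(c) for c in artifact_centers)
        assert recall >= 0.9
        assert artifact_hits == 0


class TestBH:
    def test_single_p(self):
        assert bh_adjust([0.01]) == pytest.approx([0.01])

    def test_step_up_by_hand(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_permutation_paired_with_input(self):
        p = [0.4, 0.001, 0.2, 0.9, 0.05]
        adj = bh_adjust(p)
        perm = [3, 0, 4, 1, 2]
        adj_perm = bh_adjust([p[i] for i in perm])
        assert adj_perm == pytest.approx([adj[i] for i in perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_log10_variant_matches_linear(self):
        rng = np.random.default_rng(9)
        p = 10 ** (-6 * rng.random(40))
        assert 10 ** bh_adjust_log10(np.log10(p)) == pytest.approx(
            bh_adjust(p), rel=1e-9)

    def test_log10_deep_tail_representable(self):
        """BH on p-values far below the double underflow limit stays
        finite in log space."""
        adj = bh_adjust_log10([-4000.0, -2.0, -0.1])
        assert np.isfinite(adj).all()
        assert adj[0] < -3999

    def test_bh_by_hand_example_at_threshold(self):
        # {1e-20, 0.5, 0.9} at threshold 1e-3: adjusted {3e-20, 0.75, 0.9}
        adj = bh_adjust([1e-20, 0.5, 0.9])
        assert (adj < 1e-3).sum() == 1


class TestLogPoissonTail:
    def test_no_underflow_to_minus_inf(self):
        # |log10 p| up to ~5000
        val = log_poisson_sf(2000, 0.5) / LN10
        assert np.isfinite(val) and val < -5000

    def test_matches_scipy_in_representable_range(self):
        for k, mu in [(3, 5.0), (10, 2.0), (50, 30.0), (0, 1.0)]:
            assert log_poisson_sf(k, mu) == pytest.approx(
                float(stats.poisson.logsf(k - 1, mu)), abs=1e-10)

    def test_monotone_in_k(self):
        vals = [log_poisson_sf(k, 3.0) for k in range(0, 40)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
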