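"""Per-base labeling, corrections, merging and summary statistics."""

import numpy as np
import pytest

from asmflag.coverage import CoverageTrack, track_to_histogram
from asmflag.errors import ParseError
from asmflag.flagging import (
    HSAT_MULTIPLIERS,
    LABEL_CODES,
    LABEL_NAMES,
    FlagBlock,
    FlagConfig,
    apply_hsat_correction,
    apply_mapq_correction,
    flag_track,
    merge_and_finalize,
    n50,
    run_pipeline,
    run_windowed_flagging,
    summarize,
)
from asmflag.mixture import AssignmentTable
from asmflag.simulate import HsatPlant, RegionPlant, SimSpec, simulate_coverage

from conftest import make_track

ERR, DUP, HAP, COL, UNK = (LABEL_CODES[n] for n in LABEL_NAMES)


def table_from_map(mapping, max_depth):
    labels = np.full(max_depth + 1, HAP, dtype=np.int8)
    for depth, lab in mapping.items():
        labels[depth] = lab
    return AssignmentTable(labels=labels)


def labels_dict(blocks, lengths):
    out = {c: np.full(n, -1, dtype=np.int8) for c, n in lengths.items()}
    for b in blocks:
        out[b.contig][b.start : b.end] = LABEL_CODES[b.label]
    return out


class TestFlagTrack:
    def test_example_blocks(self):
        track = make_track({"c1": [0] * 5 + [40] * 95})
        table = table_from_map({0: ERR, 40: HAP}, 40)
        blocks = flag_track(track, table)
        assert [(b.start, b.end, b.label) for b in blocks] == [
            (0, 5, "Err"), (5, 100, "Hap")]

    def test_uniform_contig_single_block(self):
        track = make_track({"c1": [40] * 200})
        blocks = flag_track(track, table_from_map({}, 40))
        assert len(blocks) == 1 and blocks[0].label == "Hap"

    def test_depth_beyond_table_rejected(self):
        track = make_track({"c1": [99] * 10})
        with pytest.raises(ParseError):
            flag_track(track, table_from_map({}, 40))

    def test_matches_per_base_oracle(self, rng):
        depths = rng.integers(0, 50, 3_000)
        track = make_track({"c1": depths})
        labels = rng.integers(0, 4, 51).astype(np.int8)
        table = AssignmentTable(labels=labels)
        blocks = flag_track(track, table)
        per_base = np.empty(3_000, dtype=np.int8)
        for b in blocks:
            per_base[b.start : b.end] = LABEL_CODES[b.label]
        assert np.array_equal(per_base, labels[depths])
        # blocks tile the contig
        assert sum(b.length for b in blocks) == 3_000


class TestWindowedFlagging:
    def _spec_track(self, lengths, seed=0):
        spec = SimSpec(contig_lengths=lengths, hap_mean=40.0,
                       block_size=1_000, seed=seed)
        return simulate_coverage(spec)[0]

    def test_short_contig_uses_whole_genome_model(self):
        track = self._spec_track({"long": 6_000_000, "short": 300_000})
        config = FlagConfig(window_size=2_000_000, min_contig=2_000_000)
        labels, models, fallbacks = run_windowed_flagging(track, config)
        assert set(labels) == {"long", "short"}
        sources = {w.source for w in models}
        assert "whole_genome" in sources
        windowed = [w for w in models if w.source == "window"]
        assert all(w.contig == "long" for w in windowed)

    def test_long_contig_gets_one_model_per_window(self):
        track = self._spec_track({"c": 6_000_000})
        config = FlagConfig(window_size=2_000_000, min_contig=2_000_000)
        _, models, fallbacks = run_windowed_flagging(track, config)
        windowed = [w for w in models if w.source == "window"]
        assert len(windowed) == 3
        assert not fallbacks

    def test_zero_coverage_window_falls_back(self):
        # a window of pure zero depth has a single-valued histogram
        track = CoverageTrack({"c": 4_000_000})
        rng = np.random.default_rng(0)
        depths = np.repeat(rng.poisson(40.0, 4_000), 1_000)
        depths[1_000_000:2_000_000] = 0
        track.set_per_base("c", depths)
        config = FlagConfig(window_size=1_000_000, min_contig=2_000_000)
        labels, models, fallbacks = run_windowed_flagging(track, config)
        assert any(w.start == 1_000_000 for w in fallbacks)
        # the zero window is still labeled (as Err, via the genome model)
        assert np.all(labels["c"][1_000_000:2_000_000] == ERR)


class TestHsatCorrection:
    def test_biased_satellite_reflagged_hap(self):
        # HSat2 with a true 1.6x coverage rise: the base model calls it
        # collapsed; refitting with the 1.25x start point recovers haploid
        spec = SimSpec(
            contig_lengths={"c": 6_000_000},
            hap_mean=40.0,
            hsat_plants=[HsatPlant("c", 2_000_000, 2_500_000, "HSat2", 1.6)],
            block_size=1_000,
            seed=5,
        )
        track, _ = simulate_coverage(spec)
        config = FlagConfig()
        labels, _, _ = run_windowed_flagging(track, config)
        region = slice(2_000_000, 2_500_000)
        assert (labels["c"][region] == COL).mean() > 0.5
        hsat = [("c", 2_000_000, 2_500_000, "HSat2")]
        mean = track_to_histogram(track).mean()
        fixed = apply_hsat_correction(labels, hsat, track, mean, config)
        assert (fixed["c"][region] == HAP).mean() > 0.95
        # outside the satellite nothing changes
        assert np.array_equal(fixed["c"][: 2_000_000], labels["c"][: 2_000_000])

    def test_empty_region_list_is_identity(self):
        labels = {"c": np.full(1000, HAP, dtype=np.int8)}
        track = make_track({"c": [40] * 1000})
        out = apply_hsat_correction(labels, [], track, 40.0, FlagConfig())
        assert np.array_equal(out["c"], labels["c"])

    def test_unknown_class_rejected(self):
        labels = {"c": np.full(1000, HAP, dtype=np.int8)}
        track = make_track({"c": [40] * 1000})
        with pytest.raises(ParseError, match="HSat"):
            apply_hsat_correction(
                labels, [("c", 0, 10, "HSat9")], track, 40.0, FlagConfig())

    def test_class_start_point_multipliers(self):
        assert HSAT_MULTIPLIERS == {"HSat1": 0.75, "HSat2": 1.25, "HSat3": 1.25}


class TestMapqCorrection:
    def _labels(self):
        arr = np.full(10_000, HAP, dtype=np.int8)
        arr[2_000:3_000] = DUP
        arr[5_000:6_000] = COL
        arr[8_000:8_500] = ERR
        return {"c": arr}

    def test_supported_dup_becomes_hap(self):
        hq = make_track({"c": [6] * 10_000})
        out = apply_mapq_correction(self._labels(), hq, min_support=5)
        assert np.all(out["c"][2_000:3_000] == HAP)

    def test_exactly_min_support_keeps_dup(self):
        hq = make_track({"c": [5] * 10_000})
        out = apply_mapq_correction(self._labels(), hq, min_support=5)
        assert np.all(out["c"][2_000:3_000] == DUP)

    def test_minimum_depth_over_block_decides(self):
        depths = np.full(10_000, 30)
        depths[2_500] = 5  # one weakly supported base in the Dup block
        hq = make_track({"c": depths})
        out = apply_mapq_correction(self._labels(), hq, min_support=5)
        assert np.all(out["c"][2_000:3_000] == DUP)

    def test_other_labels_untouched(self):
        hq = make_track({"c": [50] * 10_000})
        out = apply_mapq_correction(self._labels(), hq, min_support=5)
        assert np.all(out["c"][5_000:6_000] == COL)
        assert np.all(out["c"][8_000:8_500] == ERR)

    def test_idempotent(self):
        hq = make_track({"c": [6] * 10_000})
        once = apply_mapq_correction(self._labels(), hq, min_support=5)
        twice = apply_mapq_correction(once, hq, min_support=5)
        assert np.array_equal(once["c"], twice["c"])


class TestMergeAndFinalize:
    def _labels(self, runs, n):
        arr = np.full(n, HAP, dtype=np.int8)
        for s, e, lab in runs:
            arr[s:e] = lab
        return {"c": arr}

    def test_gap_below_threshold_merges(self):
        # Hap - 999-base Err gap - Hap: Hap merges across, Err contested
        labels = self._labels([(5_000, 5_999, ERR)], 10_000)
        blocks = merge_and_finalize(labels, 1_000)
        spans = [(b.start, b.end, b.label) for b in blocks]
        assert spans == [(0, 5_000, "Hap"), (5_000, 5_999, "Unk"), (5_999, 10_000, "Hap")]

    def test_gap_at_threshold_stays_separate(self):
        labels = self._labels([(5_000, 6_000, ERR)], 10_000)
        blocks = merge_and_finalize(labels, 1_000)
        spans = [(b.start, b.end, b.label) for b in blocks]
        assert spans == [(0, 5_000, "Hap"), (5_000, 6_000, "Err"), (6_000, 10_000, "Hap")]

    def test_contested_span_becomes_unk(self):
        # two Dup blocks 500 apart inside a Hap gap of the same size: both
        # the Dup pair and the surrounding Hap merge over the same span
        labels = self._labels([(4_000, 4_200, DUP), (4_700, 4_900, DUP)], 10_000)
        blocks = merge_and_finalize(labels, 1_000)
        spans = {(b.start, b.end, b.label) for b in blocks}
        assert (4_000, 4_900, "Unk") in spans

    def test_result_tiles_contig(self, rng):
        arr = rng.integers(0, 4, 20_000).astype(np.int8)
        blocks = merge_and_finalize({"c": arr}, 1_000)
        covered = np.zeros(20_000, dtype=int)
        for b in blocks:
            covered[b.start : b.end] += 1
        assert np.all(covered == 1)

    def test_idempotent(self, rng):
        arr = np.full(50_000, HAP, dtype=np.int8)
        for _ in range(30):
            s = int(rng.integers(0, 49_000))
            arr[s : s + int(rng.integers(100, 900))] = int(rng.integers(0, 4))
        once = merge_and_finalize({"c": arr}, 1_000)
        again = merge_and_finalize(labels_dict(once, {"c": 50_000}), 1_000)
        assert [(b.start, b.end, b.label) for b in once] == \
               [(b.start, b.end, b.label) for b in again]


class TestSummarize:
    def test_all_hap_is_fully_reliable(self):
        blocks = [FlagBlock("c", 0, 1_000_000, "Hap")]
        s = summarize(blocks)
        assert s.unreliable_fraction == 0.0
        assert s.unreliable_n50 == 0

    def test_single_error_block_statistics(self):
        blocks = [
            FlagBlock("c", 0, 500_000, "Hap"),
            FlagBlock("c", 500_000, 510_000, "Err"),
            FlagBlock("c", 510_000, 1_000_000, "Hap"),
        ]
        s = summarize(blocks)
        assert s.unreliable_fraction == pytest.approx(0.01)
        assert s.unreliable_n50 == 10_000
        assert s.unreliable_bases == 10_000

    def test_n50_matches_bruteforce(self, rng):
        for _ in range(20):
            lens = rng.integers(1, 10_000, int(rng.integers(1, 50)))
            total = lens.sum()
            # brute force: sort descending, accumulate to half the total
            acc = 0
            expect = None
            for L in sorted(lens, reverse=True):
                acc += L
                if acc >= total / 2:
                    expect = L
                    break
            assert n50(lens) == expect


def test_pipeline_blocks_tile_every_contig():
    spec = SimSpec(
        contig_lengths={"a": 6_000_000, "b": 400_000},
        hap_mean=40.0,
        plants=[RegionPlant("a", 1_000_000, 1_050_000, "Col", 2.0)],
        block_size=1_000,
        seed=3,
    )
    track, _ = simulate_coverage(spec)
    result = run_pipeline(track)
    for contig, n in spec.contig_lengths.items():
        covered = np.zeros(n, dtype=int)
        for b in result.blocks:
            if b.contig == contig:
                covered[b.start : b.end] += 1
        assert np.all(covered == 1)
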