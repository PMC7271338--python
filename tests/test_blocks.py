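"""Window tiling and block typing."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tetramosaic.blocks import (
    BlockType,
    infer_track,
    merge_runs,
    summarize_track,
    tile_windows,
    type_window,
)
from tetramosaic.markers import MarkerCall, Origin


def brute_force_type(n_m, n_p, n_np, support, min_markers, min_np):
    """Independent restatement of the window rule, by enumeration of
    every condition in turn."""
    total = n_m + n_p + n_np
    if total == 0 or total < min_markers:
        return "no-data"
    counts = {"maternal": n_m, "paternal": n_p, "non-parental": n_np}
    best = max(counts.values())
    leaders = [k for k, v in counts.items() if v == best]
    if len(leaders) != 1:
        return "ambiguous"
    if best / total < support:
        return "ambiguous"
    if leaders[0] == "non-parental" and n_np < min_np:
        return "ambiguous"
    return leaders[0]


def _call(pos, origin, chrom="chr01", sister="s"):
    return MarkerCall((chrom, pos, "A", "T"), sister, origin)


class TestTileWindows:
    def test_truncated_last_window(self):
        track = tile_windows({"chr01": 25_000}, 10_000)
        wins = track.windows["chr01"]
        assert [(w.start, w.end) for w in wins] == [
            (0, 10_000), (10_000, 20_000), (20_000, 25_000)]

    def test_exact_multiple_gives_single_window(self):
        track = tile_windows({"chr01": 10_000}, 10_000)
        assert len(track.windows["chr01"]) == 1

    def test_140_windows_span_1_4_mb(self):
        track = tile_windows({"chr01": 1_400_000}, 10_000)
        wins = track.windows["chr01"]
        assert len(wins) == 140
        assert sum(w.length for w in wins) == 1_400_000

    def test_zero_length_chromosome_raises(self):
        with pytest.raises(ValueError):
            tile_windows({"chr01": 0})
        with pytest.raises(ValueError):
            tile_windows({"chr01": 100}, window_size=0)


class TestTypeWindow:
    @pytest.mark.parametrize("thresholds", [
        (0.75, 1, 5),      # default rule
        (0.60, 2, 3),      # perturbed
        (0.90, 1, 7),      # perturbed
    ])
    def test_matches_brute_force_on_all_small_triples(self, thresholds):
        support, min_markers, min_np = thresholds
        for n_m, n_p, n_np in itertools.product(range(21), repeat=3):
            if n_m + n_p + n_np > 20:
                continue
            got, _ = type_window(n_m, n_p, n_np, support, min_markers, min_np)
            assert got.value == brute_force_type(
                n_m, n_p, n_np, support, min_markers, min_np
            ), (n_m, n_p, n_np, thresholds)

    def test_rule_instantiations(self):
        assert type_window(8, 2, 0) == (BlockType.MATERNAL, 0.8)
        assert type_window(0, 0, 0) == (BlockType.NO_DATA, None)
        btype, support = type_window(2, 0, 5)
        assert btype is BlockType.AMBIGUOUS and support == pytest.approx(5 / 7)
        assert type_window(0, 0, 4)[0] is BlockType.AMBIGUOUS
        assert type_window(0, 0, 5)[0] is BlockType.NON_PARENTAL

    def test_75_percent_is_inclusive(self):
        assert type_window(3, 1, 0)[0] is BlockType.MATERNAL  # exactly 0.75

    def test_ties_are_ambiguous(self):
        assert type_window(4, 4, 0)[0] is BlockType.AMBIGUOUS

    @given(
        st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
        st.floats(0.5, 1.0),
    )
    def test_raising_support_never_types_an_ambiguous_window(self, m, p, np_, s):
        low, _ = type_window(m, p, np_, support_threshold=s)
        high, _ = type_window(m, p, np_, support_threshold=min(1.0, s + 0.1))
        if low is BlockType.AMBIGUOUS:
            assert high in (BlockType.AMBIGUOUS, BlockType.NO_DATA)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            type_window(-1, 0, 0)


class TestInferTrack:
    def test_markers_binned_by_position(self):
        scaffold = tile_windows({"chr01": 30_000}, 10_000)
        markers = [
            _call(1, Origin.MATERNAL), _call(10_000, Origin.MATERNAL),
            _call(10_001, Origin.PATERNAL), _call(29_999, Origin.NON_PARENTAL),
        ]
        track = infer_track(markers, scaffold)
        w = track.windows["chr01"]
        # pos 10 000 is the last bp of window 0 (1-based -> floor((pos-1)/ws))
        assert (w[0].n_maternal, w[1].n_paternal, w[2].n_np) == (2, 1, 1)

    def test_all_maternal_markers_type_every_nonempty_window(self):
        scaffold = tile_windows({"chr01": 50_000}, 10_000)
        markers = [_call(p, Origin.MATERNAL) for p in range(1, 50_001, 777)]
        track = infer_track(markers, scaffold)
        for w in track:
            assert w.block_type in (BlockType.MATERNAL, BlockType.NO_DATA)

    def test_hotspot_window_typed_non_parental(self):
        scaffold = tile_windows({"chr01": 20_000}, 10_000)
        markers = [_call(10_001 + i, Origin.NON_PARENTAL) for i in range(5)]
        track = infer_track(markers, scaffold)
        assert track.windows["chr01"][1].block_type is BlockType.NON_PARENTAL

    def test_marker_beyond_chromosome_end_raises(self):
        scaffold = tile_windows({"chr01": 10_000}, 10_000)
        with pytest.raises(ValueError, match="beyond"):
            infer_track([_call(10_001, Origin.MATERNAL)], scaffold)

    def test_truth_recovery_on_noise_free_pedigree(self, small_pedigree):
        """With window-aligned breakpoints every typed maternal/paternal
        window matches the planted origin."""
        from tetramosaic.markers import classify_all

        cfg, ped = small_pedigree
        streams = classify_all(ped.callset, cfg.mother, cfg.father, cfg.sisters)
        scaffold = tile_windows(cfg.chrom_lengths, cfg.window_size)
        for sister in cfg.sisters:
            track = infer_track(streams[sister], scaffold, sister=sister)
            for w in track:
                if w.block_type in (BlockType.MATERNAL, BlockType.PATERNAL):
                    truth = ped.truth.block_origin[(sister, w.chrom, w.window_index)]
                    assert w.block_type.value == truth


class TestSummarizeAndMerge:
    def test_all_no_data_track_covers_chromosome(self):
        track = tile_windows({"chr01": 123_456}, 10_000)
        cov = summarize_track(track)
        assert cov[BlockType.NO_DATA]["coverage_bp"] == 123_456

    def test_coverage_conservation(self, small_pedigree):
        from tetramosaic.markers import classify_all

        cfg, ped = small_pedigree
        streams = classify_all(ped.callset, cfg.mother, cfg.father, cfg.sisters)
        scaffold = tile_windows(cfg.chrom_lengths, cfg.window_size)
        genome = sum(cfg.chrom_lengths.values())
        for sister in cfg.sisters:
            track = infer_track(streams[sister], scaffold, sister=sister)
            total = sum(d["coverage_bp"] for d in summarize_track(track).values())
            assert total == genome

    def test_merge_runs_partitions_chromosome(self):
        scaffold = tile_windows({"chr01": 50_000}, 10_000)
        markers = (
            [_call(p, Origin.MATERNAL) for p in (1, 5_000, 10_001, 15_000)]
            + [_call(p, Origin.PATERNAL) for p in (20_001, 25_000)]
        )
        track = infer_track(markers, scaffold)
        segs = merge_runs(track)
        assert segs[0] == ("chr01", 0, 20_000, BlockType.MATERNAL)
        assert segs[1] == ("chr01", 20_000, 30_000, BlockType.PATERNAL)
        assert sum(e - s for _, s, e, _ in segs) == 50_000
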