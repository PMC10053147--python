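import numpy as np
import pandas as pd
import pytest

from riskscreen import (
    GenomeTrackConfig, define_candidate_enhancers, intersect_peaks,
    simulate_genome_tracks, tile_sgrnas,
)


def _bed(intervals, prefix="p"):
    return pd.DataFrame(
        {"contig": [c for c, *_ in intervals],
         "start": [s for _, s, _ in intervals],
         "end": [e for *_, e in intervals],
         "peak_id": [f"{prefix}{i}" for i in range(len(intervals))]}
    )


def _points(positions, contig="chr1"):
    return pd.DataFrame(
        {"contig": contig, "start": positions, "end": [p + 1 for p in positions],
         "ccv_id": [f"rs{i}" for i in range(len(positions))]}
    )


class TestIntersect:
    def test_one_bp_overlap_kept_half_open_touch_dropped(self):
        atac = _bed([("chr1", 100, 200), ("chr1", 300, 400)])
        kept = intersect_peaks(atac, _bed([("chr1", 199, 300)], "k"))
        assert list(kept["start"]) == [100]  # 1 bp overlap kept
        kept = intersect_peaks(atac, _bed([("chr1", 200, 300)], "k"))
        assert len(kept) == 0  # bookended intervals do not overlap

    def test_full_original_extent_returned(self):
        atac = _bed([("chr1", 100, 900)])
        kept = intersect_peaks(atac, _bed([("chr1", 400, 410)], "k"))
        assert (kept.loc[0, "start"], kept.loc[0, "end"]) == (100, 900)

    def test_contig_mismatch_error_lists_unshared(self):
        with pytest.raises(ValueError, match="chr2"):
            intersect_peaks(_bed([("chr1", 0, 10)]), _bed([("chr2", 0, 10)], "k"))

    def test_matches_quadratic_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n_a, n_k = rng.integers(5, 60, size=2)
            contigs = ["chr1", "chr2"]
            atac = pd.DataFrame({
                "contig": rng.choice(contigs, n_a),
                "start": (s := rng.integers(0, 5000, n_a)),
                "end": s + rng.integers(1, 400, n_a),
                "peak_id": [f"a{i}" for i in range(n_a)]})
            k27 = pd.DataFrame({
                "contig": rng.choice(contigs, n_k),
                "start": (s := rng.integers(0, 5000, n_k)),
                "end": s + rng.integers(1, 400, n_k),
                "peak_id": [f"k{i}" for i in range(n_k)]})
            kept = intersect_peaks(atac, k27)
            brute = {
                row.peak_id
                for row in atac.itertuples()
                if any(row.contig == o.contig and row.start < o.end and o.start < row.end
                       for o in k27.itertuples())
            }
            assert set(kept["peak_id"]) == brute, trial

    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError, match="start >= end"):
            intersect_peaks(_bed([("chr1", 10, 10)]), _bed([("chr1", 0, 5)], "k"))


class TestCandidateEnhancers:
    def test_two_overlapping_windows_merge_with_union_of_ccvs(self):
        """Peak centers 10,000 and 10,600 with CCVs at 10,100 and 10,650:
        both 1-kb windows retained and merged into [9500, 11100)."""
        peaks = _bed([("chr1", 9_900, 10_100), ("chr1", 10_500, 10_700)])
        enh = define_candidate_enhancers(peaks, _points([10_100, 10_650]))
        assert len(enh) == 1
        row = enh.iloc[0]
        assert (row["start"], row["end"]) == (9_500, 11_100)
        assert row["n_ccvs"] == 2
        assert row["n_windows"] == 2

    def test_window_without_ccv_dropped(self):
        peaks = _bed([("chr1", 9_900, 10_100), ("chr1", 50_000, 50_200)])
        enh = define_candidate_enhancers(peaks, _points([10_100]))
        assert list(enh["start"]) == [9_500]

    def test_no_ccvs_gives_empty_output(self):
        enh = define_candidate_enhancers(_bed([("chr1", 0, 1000)]), _points([]))
        assert enh.empty

    def test_chained_windows_build_multi_kb_enhancer(self):
        """Closely spaced CCV-bearing peaks chain into one enhancer much
        longer than a single 1-kb window."""
        centers = [10_000, 10_800, 11_600, 12_400]
        peaks = _bed([("chr1", c - 100, c + 100) for c in centers])
        enh = define_candidate_enhancers(peaks, _points([c for c in centers]))
        assert len(enh) == 1
        assert enh.iloc[0]["end"] - enh.iloc[0]["start"] == 3_400  # > 2 windows
        assert enh.iloc[0]["n_windows"] == 4

    def test_matches_brute_force_merge_oracle_on_random_tracks(self):
        """Independent oracle: paint retained windows onto a coordinate
        array and read out maximal runs."""
        rng = np.random.default_rng(1)
        for trial in range(15):
            n_p = int(rng.integers(3, 40))
            n_c = int(rng.integers(1, 40))
            length = 30_000
            starts = rng.integers(500, length - 500, n_p)
            peaks = _bed([("chr1", int(s), int(s + rng.integers(50, 600))) for s in starts])
            ccvs = _points(sorted(int(x) for x in rng.integers(0, length, n_c)))
            enh = define_candidate_enhancers(peaks, ccvs)

            paint = np.zeros(length + 2_000, dtype=bool)
            for row in peaks.itertuples():
                center = (row.start + row.end) // 2
                lo, hi = max(center - 500, 0), center + 500
                if any(lo <= p < hi for p in ccvs["start"]):
                    paint[lo:hi] = True
            edges = np.flatnonzero(np.diff(paint.astype(int)))
            runs = [(int(edges[i] + 1), int(edges[i + 1] + 1)) for i in range(0, len(edges), 2)]
            got = [(int(r.start), int(r.end)) for r in enh.itertuples()]
            assert got == runs, trial
            # disjoint and sorted
            for (s1, e1), (s2, e2) in zip(got, got[1:]):
                assert e1 <= s2
            # CCV conservation: every CCV inside a retained window appears
            # in exactly one enhancer
            claimed = [c for row in enh.itertuples() for c in row.ccv_ids.split(",") if c]
            assert len(claimed) == len(set(claimed))
            inside = {c.ccv_id for c in ccvs.itertuples() if paint[c.start]}
            assert set(claimed) == inside

    def test_merge_idempotent_on_own_output(self):
        peaks = _bed([("chr1", 9_900, 10_100), ("chr1", 10_500, 10_700),
                      ("chr1", 40_000, 40_200)])
        ccvs = _points([10_100, 10_650, 40_050])
        enh = define_candidate_enhancers(peaks, ccvs)
        halfwidth = int((enh.iloc[0]["end"] - enh.iloc[0]["start"]) // 2)
        again = define_candidate_enhancers(
            enh.rename(columns={"enhancer_id": "peak_id"}), ccvs, window_halfwidth=halfwidth)
        # the first (merged, even-length) enhancer reproduces itself
        assert (again.iloc[0]["start"], again.iloc[0]["end"]) == (
            enh.iloc[0]["start"], enh.iloc[0]["end"])

    def test_merge_then_intersect_flag(self):
        # two overlapping windows, only one contains the CCV: under
        # intersect-then-merge the empty window is dropped before merging
        peaks = _bed([("chr1", 9_900, 10_100), ("chr1", 10_500, 10_700)])
        ccvs = _points([10_050])
        default = define_candidate_enhancers(peaks, ccvs)
        assert (default.iloc[0]["start"], default.iloc[0]["end"]) == (9_500, 10_500)
        merged_first = define_candidate_enhancers(peaks, ccvs, merge_before_intersect=True)
        assert (merged_first.iloc[0]["start"], merged_first.iloc[0]["end"]) == (9_500, 11_100)


class TestTiling:
    def test_one_kb_enhancer_gets_ten_positions(self):
        enh = pd.DataFrame([{"contig": "chr1", "start": 9_500, "end": 10_500,
                             "enhancer_id": "E1"}])
        tiles = tile_sgrnas(enh, spacing=100)
        assert len(tiles) == 10
        assert list(tiles["position"])[:2] == [9_550, 9_650]

    def test_short_interval_positions(self):
        enh = pd.DataFrame([
            {"contig": "chr1", "start": 0, "end": 250, "enhancer_id": "E1"},
            {"contig": "chr1", "start": 1_000, "end": 1_040, "enhancer_id": "E2"},
        ])
        tiles = tile_sgrnas(enh, spacing=100)
        assert list(tiles.loc[tiles["enhancer_id"] == "E1", "position"]) == [50, 150]
        # shorter than the spacing: one central position
        assert list(tiles.loc[tiles["enhancer_id"] == "E2", "position"]) == [1_020]

    def test_count_formula_on_random_intervals(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            start = int(rng.integers(0, 10_000))
            length = int(rng.integers(100, 5_000))
            enh = pd.DataFrame([{"contig": "chr1", "start": start,
                                 "end": start + length, "enhancer_id": "E"}])
            tiles = tile_sgrnas(enh, spacing=100)
            assert len(tiles) == len(range(start + 50, start + length, 100))
            if length % 100 == 0:
                assert len(tiles) == length // 100

    def test_bad_spacing_rejected(self):
        with pytest.raises(ValueError):
            tile_sgrnas(pd.DataFrame(columns=["contig", "start", "end", "enhancer_id"]), 0)


class TestTracks:
    def test_same_seed_identical_tracks(self):
        cfg = GenomeTrackConfig(seed=5)
        a, b = simulate_genome_tracks(cfg), simulate_genome_tracks(cfg)
        pd.testing.assert_frame_equal(a.atac, b.atac)
        pd.testing.assert_frame_equal(a.ccvs, b.ccvs)

    def test_planted_positives_recovered_by_enhancer_mapping(self):
        tracks = simulate_genome_tracks(GenomeTrackConfig(seed=3))
        marked = intersect_peaks(tracks.atac, tracks.h3k27ac)
        enh = define_candidate_enhancers(marked, tracks.ccvs)
        for row in tracks.planted.itertuples():
            center = (row.start + row.end) // 2
            assert ((enh["start"] <= center) & (center < enh["end"])).any()

    def test_zero_ccvs_empty_downstream(self):
        tracks = simulate_genome_tracks(GenomeTrackConfig(n_ccvs=0, fraction_planted=0, seed=1))
        marked = intersect_peaks(tracks.atac, tracks.h3k27ac)
        assert define_candidate_enhancers(marked, tracks.ccvs).empty

    def test_intervals_in_bounds(self):
        cfg = GenomeTrackConfig(seed=9)
        tracks = simulate_genome_tracks(cfg)
        for df in (tracks.atac, tracks.h3k27ac, tracks.ccvs):
            assert (df["start"] >= 0).all()
            assert (df["end"] <= cfg.length).all()
            assert (df["start"] < df["end"]).all()
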