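"""Unit and property tests for depth windowing, ratios and block detection."""

import numpy as np
import pytest

from bchromkit.coverage import (
    CandidateBlock,
    CoverageRatioTrack,
    DepthProfile,
    block_size,
    detect_blocks,
    jaccard,
    normalize,
    rank_blocks,
    ratio_track,
    window_depth,
)
from bchromkit.mapping import build_seed_index, map_reads_exact
from bchromkit.simulate import FastqRead, TruthSpec, make_reference, simulate_cohort


def make_profile(counts, w=100, sample_id="s", length=None):
    arr = np.asarray(counts, dtype=np.int64)
    length = length if length is not None else len(arr) * w
    return DepthProfile(
        sample_id=sample_id,
        window_size=w,
        counts={"scaffold_1": arr},
        ref_lengths={"scaffold_1": length},
        library_size=int(arr.sum()),
    )


class TestMapper:
    def test_error_free_reads_return_to_origin(self, spec1, cohort1):
        reads = cohort1.read_sets["0B"][:200]
        result = map_reads_exact(reads, cohort1.reference)
        placed = {p.read_name: (p.scaffold, p.start) for p in result.placements}
        for read in reads:
            _, template, start = read.name.split("|")
            if read.name in placed:
                assert placed[read.name] == (template, int(start))

    def test_agrees_with_exhaustive_hamming_scan(self):
        """Seeded placement equals a brute-force full scan (the oracle)."""
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        ref = {"scaffold_1": "".join(rng.choice(bases, 10_000))}
        reads = []
        for i in range(50):
            start = int(rng.integers(0, 10_000 - 100))
            reads.append(FastqRead(f"r{i}", ref["scaffold_1"][start : start + 100], "I" * 100))

        def brute(read_seq, max_mm=2):
            hits = []
            seq = ref["scaffold_1"]
            for pos in range(len(seq) - len(read_seq) + 1):
                dist = sum(a != b for a, b in zip(read_seq, seq[pos : pos + len(read_seq)]))
                if dist <= max_mm:
                    hits.append((dist, pos))
            if not hits:
                return None
            hits.sort()
            if len(hits) > 1 and hits[1][0] == hits[0][0]:
                return "ambiguous"
            return hits[0][1]

        result = map_reads_exact(reads, ref)
        placed = {p.read_name: p.start for p in result.placements}
        for read in reads:
            expected = brute(read.sequence)
            if expected in (None, "ambiguous"):
                assert read.name not in placed
            else:
                assert placed[read.name] == expected

    def test_mapper_inflates_source_locus_of_duplicated_block(self, cohort1):
        """Reads from B copies map back to the A-complement source."""
        blk = cohort1.truth_blocks[0]
        b_reads = [r for r in cohort1.read_sets["1B"] if "|B|" in r.name][:100]
        result = map_reads_exact(b_reads, cohort1.reference)
        assert result.n_mapped > 0
        for p in result.placements:
            assert p.scaffold == blk.scaffold
            assert blk.start - 100 <= p.start < blk.end


class TestWindowDepth:
    def test_read_counts_in_window_of_leftmost_base(self):
        profile = window_depth([("scaffold_1", 10)], {"scaffold_1": 500}, 100)
        assert profile.counts["scaffold_1"].tolist() == [1, 0, 0, 0, 0]

    def test_boundary_read_counts_once_by_start_position(self):
        # a read starting at 99 spans windows 0 and 1 but counts only in 0
        profile = window_depth([("scaffold_1", 99)], {"scaffold_1": 500}, 100)
        assert profile.counts["scaffold_1"].tolist() == [1, 0, 0, 0, 0]

    def test_empty_input_gives_zero_profile(self):
        profile = window_depth([], {"scaffold_1": 500}, 100)
        assert profile.library_size == 0
        assert profile.counts["scaffold_1"].sum() == 0

    def test_depth_conservation(self, cohort1):
        result = map_reads_exact(cohort1.read_sets["1B"], cohort1.reference)
        lengths = {k: len(v) for k, v in cohort1.reference.items()}
        profile = window_depth(result.placements, lengths, 1000)
        assert sum(c.sum() for c in profile.counts.values()) == profile.library_size
        profile.check()

    def test_unknown_reference_named_in_error(self):
        with pytest.raises(ValueError, match="chrUn"):
            window_depth([("chrUn", 5)], {"scaffold_1": 500}, 100)

    def test_small_window_rejected(self):
        with pytest.raises(ValueError):
            window_depth([], {"scaffold_1": 500}, 10)


class TestNormalize:
    def test_reads_per_million(self):
        profile = make_profile([50])
        profile.library_size = 1_000_000
        assert normalize(profile)["scaffold_1"][0] == pytest.approx(50.0)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            normalize(make_profile([0, 0]))

    def test_proportional_profiles_normalize_identically(self):
        a = make_profile([10, 30, 60])
        b = make_profile([20, 60, 120])
        assert np.allclose(normalize(a)["scaffold_1"], normalize(b)["scaffold_1"])


class TestRatioTrack:
    def test_example_ratio(self):
        # nd0=4, nd1=9 (library 1e6 makes counts equal RPM), alpha=1 -> r1=2
        p0, p1, p2 = make_profile([4]), make_profile([9]), make_profile([4])
        for p in (p0, p1, p2):
            p.library_size = 1_000_000
        track = ratio_track(p0, p1, p2, alpha=1.0)
        assert track.r1["scaffold_1"][0] == pytest.approx(2.0)

    def test_empty_windows_ratio_one(self):
        p = make_profile([5, 0, 5])
        track = ratio_track(p, p, p, alpha=0.5)
        assert np.allclose(track.r1["scaffold_1"], 1.0)
        assert np.allclose(track.r2["scaffold_1"], 1.0)

    def test_self_ratio_is_identically_one(self, cohort1):
        result = map_reads_exact(cohort1.read_sets["1B"], cohort1.reference)
        lengths = {k: len(v) for k, v in cohort1.reference.items()}
        p = window_depth(result.placements, lengths, 1000)
        track = ratio_track(p, p, p)
        for scaffold in track.r1:
            assert np.allclose(track.r1[scaffold], 1.0)
            assert np.allclose(track.r2[scaffold], 1.0)

    def test_mismatched_windowing_rejected(self):
        with pytest.raises(ValueError):
            ratio_track(make_profile([1, 2]), make_profile([1, 2], w=200), make_profile([1, 2]))


def make_track(r, w=100):
    arr = np.asarray(r, dtype=float)
    ones = {"scaffold_1": np.ones_like(arr)}
    return CoverageRatioTrack(
        window_size=w,
        pseudocount=0.5,
        ref_lengths={"scaffold_1": len(arr) * w},
        nd0=ones,
        nd1=ones,
        nd2=ones,
        r1={"scaffold_1": arr},
        r2={"scaffold_1": arr.copy()},
    )


def brute_force_blocks(r, theta, min_windows, max_gap):
    """Oracle: enumerate all window runs and keep the maximal merged ones."""
    qual = [i for i, v in enumerate(r) if v >= theta]
    groups = []
    for i in qual:
        if groups and i - groups[-1][-1] - 1 <= max_gap:
            groups[-1].append(i)
        else:
            groups.append([i])
    return [(g[0], g[-1] + 1) for g in groups if len(g) >= min_windows]


class TestDetectBlocks:
    def test_single_run_example(self):
        track = make_track([1, 1, 3, 3.1, 3, 1])
        blocks = detect_blocks(track, theta=1.5, min_windows=2, max_gap=1)
        assert [(b.start, b.end) for b in blocks] == [(200, 500)]
        assert blocks[0].n_windows == 3

    def test_flat_track_yields_nothing(self):
        assert detect_blocks(make_track([1.0] * 20)) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_run_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.choice([0.8, 1.0, 1.6, 2.5], size=60)
        track = make_track(r)
        got = [(b.start // 100, b.end // 100) for b in detect_blocks(track, 1.5, 3, 1)]
        assert got == brute_force_blocks(r, 1.5, 3, 1)

    def test_invariant_to_background_scaffolds(self):
        track = make_track([1, 1, 3, 3.1, 3, 1])
        flat = np.ones(30)
        for part in (track.nd0, track.nd1, track.nd2, track.r1, track.r2):
            part["scaffold_2"] = flat.copy()
        track.ref_lengths["scaffold_2"] = 3000
        blocks = detect_blocks(track, theta=1.5, min_windows=2, max_gap=1)
        assert [(b.scaffold, b.start, b.end) for b in blocks] == [("scaffold_1", 200, 500)]

    @pytest.mark.parametrize("seed", range(3))
    def test_planted_block_recovered(self, seed):
        """Planted high-copy block recovered with Jaccard >= 0.8."""
        spec = TruthSpec(seed=100 + seed)
        cohort = simulate_cohort(spec, n_contigs=1)
        result = {
            g: map_reads_exact(cohort.read_sets[g], cohort.reference) for g in ("0B", "1B", "2B")
        }
        lengths = {k: len(v) for k, v in cohort.reference.items()}
        profiles = [window_depth(result[g].placements, lengths, 1000) for g in ("0B", "1B", "2B")]
        blocks = detect_blocks(ratio_track(*profiles))
        blk = cohort.truth_blocks[0]
        best = max(
            (jaccard((b.start, b.end), (blk.start, blk.end)) for b in blocks if b.scaffold == blk.scaffold),
            default=0.0,
        )
        assert best >= 0.8


def make_block(d, cv, r2=3.0, start=0):
    return CandidateBlock(
        scaffold="scaffold_1",
        start=start,
        end=start + 1000,
        n_windows=3,
        mean_r1=1.0 + (r2 - 1.0) / 2,
        mean_r2=r2,
        cv_r2=cv,
        dose_consistency=d,
    )


class TestRankBlocks:
    def test_lower_dose_consistency_first(self):
        a, b = make_block(0.4, 0.1), make_block(0.05, 0.1, start=5000)
        assert rank_blocks([a, b])[0] is b

    def test_cv_breaks_dose_ties(self):
        a, b = make_block(0.1, 0.5), make_block(0.1, 0.1, start=5000)
        assert rank_blocks([a, b])[0] is b

    def test_single_block_is_itself(self):
        a = make_block(0.2, 0.2)
        assert rank_blocks([a]) == [a]


class TestBlockSize:
    @pytest.mark.parametrize(
        "start,end,size",
        [(9112721, 9126380, 13_659), (5682225, 5684956, 2_731), (7, 8, 1)],
    )
    def test_size_is_end_minus_start(self, start, end, size):
        assert block_size((start, end)) == size

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            block_size((10, 10))
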