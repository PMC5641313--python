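import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbskit.profiles import make_block_profile
from sbskit.synthetic import synth_track
from sbskit.tracks import Track, bin_track, correlate_profile_tracks, read_bedgraph


def make_track(intervals, name="t"):
    chrom, starts, ends, values = zip(*intervals)
    return Track.from_arrays(list(chrom), list(starts), list(ends), list(values), name=name)


BIN = 50_000


class TestBinTrack:
    def test_uniform_coverage_gives_constant_bins(self):
        tr = make_track([("chrS", 0, 10 * BIN, 5.0)])
        binned = bin_track(tr, "chrS", 0, BIN, 10)
        assert np.allclose(binned, 5.0)

    def test_half_covered_bin_weighted_mean_hand_example(self):
        # one interval of value 10 covering exactly half of bin 0; weighted
        # mean over covered bases is 10, the rest of the bins are missing
        tr = make_track([("chrS", 0, BIN // 2, 10.0)])
        binned = bin_track(tr, "chrS", 0, BIN, 4)
        assert binned[0] == pytest.approx(10.0)
        assert np.isnan(binned[1:]).all()

    def test_two_intervals_in_one_bin_are_base_weighted(self):
        # 3/4 of the bin at value 4, 1/4 at value 8 -> mean 5
        tr = make_track([("chrS", 0, 3 * BIN // 4, 4.0), ("chrS", 3 * BIN // 4, BIN, 8.0)])
        binned = bin_track(tr, "chrS", 0, BIN, 1)
        assert binned[0] == pytest.approx(5.0)

    def test_empty_track_is_all_missing(self):
        tr = Track.from_arrays([], [], [], [], name="empty")
        binned = bin_track(tr, "chrS", 0, BIN, 5)
        assert np.isnan(binned).all()

    def test_chromosome_mismatch_rejected(self):
        tr = make_track([("chr9", 0, BIN, 1.0)])
        with pytest.raises(ValueError, match="chr"):
            bin_track(tr, "chrS", 0, BIN, 4)


class TestCorrelations:
    def test_planted_track_perfectly_correlates_with_its_type(self, toy_block_profile):
        tr = synth_track(toy_block_profile, 0, noise_sd=0.0, seed=0)
        res = correlate_profile_tracks(toy_block_profile, [tr])
        assert res.matrix[0, 0] == pytest.approx(1.0)
        # the complementary type is perfectly anti-correlated in the 2-type toy
        assert res.matrix[1, 0] == pytest.approx(-1.0)

    def test_negated_track_gives_minus_one(self, toy_block_profile):
        row = toy_block_profile.abundance[0].astype(float)
        starts = toy_block_profile.bin_starts()
        tr = Track.from_arrays(
            toy_block_profile.chrom, starts, starts + toy_block_profile.bin_size_bp, row.max() - row
        )
        res = correlate_profile_tracks(toy_block_profile, [tr])
        assert res.matrix[0, 0] == pytest.approx(-1.0)

    def test_matches_independent_pearson_oracle(self, toy_block_profile, rng):
        values = rng.random(toy_block_profile.n_beads) * 3
        starts = toy_block_profile.bin_starts()
        tr = Track.from_arrays(
            toy_block_profile.chrom, starts, starts + toy_block_profile.bin_size_bp, values
        )
        res = correlate_profile_tracks(toy_block_profile, [tr])
        for t in range(2):
            x = toy_block_profile.abundance[t].astype(float)
            expected = np.corrcoef(x, values)[0, 1]
            assert res.matrix[t, 0] == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 50.0), b=st.floats(-5.0, 5.0))
    def test_invariant_under_positive_affine_transform(self, a, b):
        profile = make_block_profile(20, [(0, 10, 0), (10, 20, 1)])
        gen = np.random.default_rng(7)
        values = gen.random(20) * 2
        starts = profile.bin_starts()
        ends = starts + profile.bin_size_bp
        base = correlate_profile_tracks(
            profile, [Track.from_arrays(profile.chrom, starts, ends, values)]
        ).matrix
        scaled = correlate_profile_tracks(
            profile, [Track.from_arrays(profile.chrom, starts, ends, a * values + b)]
        ).matrix
        assert np.allclose(base, scaled, atol=1e-9)

    def test_zero_variance_cell_is_missing_not_fatal(self, toy_block_profile):
        starts = toy_block_profile.bin_starts()
        flat = Track.from_arrays(
            toy_block_profile.chrom, starts, starts + toy_block_profile.bin_size_bp,
            np.full(toy_block_profile.n_beads, 2.0),
        )
        res = correlate_profile_tracks(toy_block_profile, [flat])
        assert np.isnan(res.matrix[:, 0]).all()

    def test_too_few_shared_bins_is_missing(self, toy_block_profile):
        tr = make_track([("chrS", 0, 2 * BIN, 1.0)])  # covers only 2 bins
        res = correlate_profile_tracks(toy_block_profile, [tr])
        assert np.isnan(res.matrix[:, 0]).all()
        assert res.n_bins[0, 0] == 2


class TestBedgraphIO:
    def test_roundtrip(self, tmp_path, toy_block_profile):
        tr = synth_track(toy_block_profile, 1, noise_sd=0.3, seed=5)
        path = tmp_path / "sig.bedgraph"
        tr.write_bedgraph(path, header_lines=["provenance"])
        back = read_bedgraph(path)
        assert np.allclose(back.intervals["value"], tr.intervals["value"])
        assert (back.intervals["start"] == tr.intervals["start"]).all()
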