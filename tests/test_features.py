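"""Feature geometry, encoding, strand orientation, and the signal profiler."""

import numpy as np
import pytest

from g4vivo.features import (
    FeatureConfig,
    atac_feature,
    build_feature_matrix,
    extend_to_region,
    sequence_feature,
    signal_profile,
)
from g4vivo.genome_io import ArrayTrack, DictGenome, GenomicInterval, PeakSet
from g4vivo.labeling import LabeledCandidates

CFG4 = FeatureConfig(flank=2, window=1)  # 4 bp region, 4 windows


class TestExtendToRegion:
    def test_center_anchored_window(self):
        cfg = FeatureConfig(flank=1000, window=10)
        region = extend_to_region(GenomicInterval("chr1", 1000, 1030), cfg)
        assert (region.start, region.end) == (15, 2015)

    def test_fixed_point(self):
        cfg = FeatureConfig(flank=1000, window=10)
        iv = GenomicInterval("chr1", 500, 2500, "+")
        region = extend_to_region(iv, cfg)
        assert (region.start, region.end, region.strand) == (500, 2500, "+")

    def test_length_invariant_on_random_inputs(self, rng):
        cfg = FeatureConfig(flank=1000, window=10)
        for _ in range(100):
            start = int(rng.integers(0, 10_000))
            iv = GenomicInterval("c", start, start + int(rng.integers(1, 500)))
            assert extend_to_region(iv, cfg).length == 2000

    def test_negative_start_allowed_near_origin(self):
        region = extend_to_region(GenomicInterval("c", 0, 10), FeatureConfig())
        assert region.start == -995


class TestFeatureConfig:
    def test_window_must_divide_region(self):
        with pytest.raises(ValueError):
            FeatureConfig(flank=1000, window=13)

    def test_default_geometry(self):
        cfg = FeatureConfig()
        assert (cfg.n_windows, cfg.region_length) == (200, 2000)


class TestAtacFeature:
    def test_constant_track(self):
        cfg = FeatureConfig(flank=1000, window=10)
        track = ArrayTrack({"c": np.full(3000, 2.0)})
        out = atac_feature(GenomicInterval("c", 100, 2100), track, cfg)
        assert out.shape == (200,) and np.allclose(out, 2.0)

    def test_empty_track_gives_zeros(self):
        cfg = FeatureConfig(flank=1000, window=10)
        track = ArrayTrack({"c": np.zeros(3000)})
        out = atac_feature(GenomicInterval("c", 0, 2000), track, cfg)
        assert not out.any()

    def test_piecewise_track_matches_per_base_mean_oracle(self, rng):
        cfg = FeatureConfig(flank=50, window=10)
        arr = rng.normal(size=2000)
        arr[rng.random(2000) < 0.5] = 0.0
        track = ArrayTrack({"c": arr})
        padded = np.r_[np.zeros(200), arr, np.zeros(200)]
        for _ in range(20):
            start = int(rng.integers(-100, 2000))
            region = GenomicInterval("c", start, start + 100)
            got = atac_feature(region, track, cfg)
            want = [
                padded[start + 200 + i * 10 : start + 200 + (i + 1) * 10].mean()
                for i in range(10)
            ]
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_linear_in_track_scale(self, rng):
        cfg = FeatureConfig(flank=20, window=5)
        arr = rng.random(200)
        region = GenomicInterval("c", 50, 90)
        a = atac_feature(region, ArrayTrack({"c": arr}), cfg)
        b = atac_feature(region, ArrayTrack({"c": 3.5 * arr}), cfg)
        np.testing.assert_allclose(b, 3.5 * a)

    def test_minus_strand_reverses_vector(self):
        cfg = FeatureConfig(flank=2, window=2)
        track = ArrayTrack({"c": np.array([1.0, 1.0, 9.0, 9.0])})
        plus = atac_feature(GenomicInterval("c", 0, 4, "+"), track, cfg)
        minus = atac_feature(GenomicInterval("c", 0, 4, "-"), track, cfg)
        np.testing.assert_allclose(minus, plus[::-1])

    def test_strand_orient_off_keeps_order(self):
        cfg = FeatureConfig(flank=2, window=2, strand_orient=False)
        track = ArrayTrack({"c": np.array([1.0, 1.0, 9.0, 9.0])})
        minus = atac_feature(GenomicInterval("c", 0, 4, "-"), track, cfg)
        np.testing.assert_allclose(minus, [1.0, 9.0])


class TestSequenceFeature:
    genome = DictGenome({"c": "ATCGNNATCG"})

    def test_ordinal_mapping(self):
        out = sequence_feature(GenomicInterval("c", 0, 4), self.genome, CFG4)
        assert out.tolist() == [0, 1, 2, 3]  # A T C G

    def test_unknown_bases_map_to_extra_category(self):
        out = sequence_feature(GenomicInterval("c", 3, 7), self.genome, CFG4)
        assert out.tolist() == [3, 4, 4, 0]

    def test_minus_strand_reverse_complements(self):
        # fetched "ATCG", revcomp "CGAT" -> [2,3,0,1]
        out = sequence_feature(GenomicInterval("c", 0, 4, "-"), self.genome, CFG4)
        assert out.tolist() == [2, 3, 0, 1]

    def test_padding_encodes_as_unknown(self):
        out = sequence_feature(GenomicInterval("c", -2, 2), self.genome, CFG4)
        assert out.tolist() == [4, 4, 0, 1]

    def test_double_orientation_is_involution(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=40))
        genome = DictGenome({"c": seq})
        cfg = FeatureConfig(flank=10, window=5)
        region = GenomicInterval("c", 10, 30, "-")
        once = sequence_feature(region, genome, cfg)
        # re-encoding the reverse complement of the oriented fetch restores it
        comp = {0: 1, 1: 0, 2: 3, 3: 2}
        twice = np.array([comp[int(b)] for b in once[::-1]])
        plus = sequence_feature(GenomicInterval("c", 10, 30, "+"), genome, cfg)
        np.testing.assert_array_equal(twice, plus)


class TestBuildFeatureMatrix:
    @pytest.fixture()
    def inputs(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        genome = DictGenome({"chr1": seq})
        track = ArrayTrack({"chr1": rng.random(5000)})
        ivs = [
            GenomicInterval("chr1", 1200, 1230, "+"),
            GenomicInterval("chr1", 2400, 2425, "-"),
            GenomicInterval("chr1", 3300, 3340, "."),
        ]
        cands = LabeledCandidates(ivs, np.array([1, 0, 0]))
        return cands, track, genome

    def test_default_shape_and_categorical_flags(self, inputs):
        fm = build_feature_matrix(*inputs)
        assert fm.data.shape == (3, 2200)
        assert fm.categorical_indices == list(range(200, 2200))

    def test_atac_only_mode(self, inputs):
        cands, track, genome = inputs
        fm = build_feature_matrix(cands, track, None, mode="atac")
        assert fm.data.shape == (3, 200) and not fm.categorical_mask.any()

    def test_seq_only_mode(self, inputs):
        cands, _, genome = inputs
        fm = build_feature_matrix(cands, None, genome, mode="seq")
        assert fm.data.shape == (3, 2000) and fm.categorical_mask.all()

    def test_rows_equal_single_entry_composition(self, inputs):
        cands, track, genome = inputs
        cfg = FeatureConfig()
        fm = build_feature_matrix(cands, track, genome, cfg)
        for i, iv in enumerate(cands.candidates):
            region = extend_to_region(iv, cfg)
            want = np.r_[
                atac_feature(region, track, cfg),
                sequence_feature(region, genome, cfg),
            ]
            np.testing.assert_allclose(fm.data[i], want)

    def test_subset_matches_direct_build(self, inputs):
        cands, track, genome = inputs
        both = build_feature_matrix(cands, track, genome)
        atac = build_feature_matrix(cands, track, None, mode="atac")
        np.testing.assert_allclose(both.subset("atac").data, atac.data)

    def test_chromosome_mismatch_lists_offenders(self, inputs):
        cands, track, genome = inputs
        bad = LabeledCandidates(
            cands.candidates + [GenomicInterval("chrUn_x", 0, 10)],
            np.r_[cands.labels, 0],
        )
        with pytest.raises(ValueError, match="chrUn_x"):
            build_feature_matrix(bad, track, genome)


class TestSignalProfile:
    def test_constant_track_gives_flat_profile(self):
        track = ArrayTrack({"c": np.ones(4000)})
        sites = PeakSet([GenomicInterval("c", 2000, 2010)])
        prof = signal_profile(sites, track, flank=100, binsize=10)
        assert prof.shape == (20,) and np.allclose(prof, 1.0)

    def test_mirrored_signals_average_symmetric(self):
        # two sites with mirror-image ramps; the mean profile is symmetric
        ramp = np.arange(200, dtype=float)
        track = ArrayTrack({"c": np.r_[ramp, ramp[::-1], np.zeros(400)]})
        sites = PeakSet(
            [GenomicInterval("c", 95, 105), GenomicInterval("c", 295, 305)]
        )
        prof = signal_profile(sites, track, flank=50, binsize=10)
        np.testing.assert_allclose(prof, prof[::-1])

    def test_matrix_mean_equals_mean_mode(self, rng):
        track = ArrayTrack({"c": rng.random(3000)})
        sites = PeakSet(
            [GenomicInterval("c", int(p), int(p) + 10) for p in rng.integers(500, 2500, 5)]
        )
        mat = signal_profile(sites, track, flank=100, binsize=20,
                             aggregate="per_site_matrix")
        mean = signal_profile(sites, track, flank=100, binsize=20)
        assert mat.shape == (5, 10)
        np.testing.assert_allclose(mat.mean(axis=0), mean)

    def test_empty_sites_error(self):
        with pytest.raises(ValueError):
            signal_profile(PeakSet([]), ArrayTrack({"c": np.zeros(10)}), 10, 5)
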