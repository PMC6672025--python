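"""CNV protocol: rdep, segmentation recovery, curation rule, breakpoints,
and the partition property of the overlap matrix Y."""

import numpy as np
import pytest

from clonaltrace import cnv_segments as cs
from clonaltrace import synthetic_tumor as st
from clonaltrace.errors import ConfigurationError
from clonaltrace.variant_matrix import CohortVariantMatrix, SomaticVariant

GAIN_21MB = ("8", 124_448_804, 146_364_022, 2, 1, True)


class TestRdep:
    def test_ratio(self):
        assert cs.compute_rdep(2.0e8, 1.0e8) == pytest.approx(2.0)
        assert cs.compute_rdep(5, 5) == pytest.approx(1.0)

    def test_scale_invariance(self):
        assert cs.compute_rdep(3e8, 2e8) == pytest.approx(cs.compute_rdep(3e5, 2e5))

    def test_zero_normal_total(self):
        with pytest.raises(ValueError):
            cs.compute_rdep(1e8, 0)


class TestSegmentation:
    def test_diploid_null_retains_nothing(self):
        snps = st.simulate_het_snps(2000, ["t1"], depth_mean=200, seed=0)
        segs = cs.segment_allelic(snps, threshold=0.3, rdep={"t1": 1.0})
        assert segs["t1"] == []

    def test_one_copy_gain_recovered(self):
        # the 21.9-Mb truncal-gain geometry: M=2, m=1 over chr8q
        snps = st.simulate_het_snps(3000, ["t1"], cnv_truth=[GAIN_21MB],
                                    depth_mean=200, seed=3)
        segs = cs.segment_allelic(snps, threshold=0.3, rdep={"t1": 1.0})["t1"]
        assert len(segs) == 1
        assert segs[0].major["t1"] == pytest.approx(2.0, abs=0.15)
        assert segs[0].minor["t1"] == pytest.approx(1.0, abs=0.15)
        assert segs[0].se_major["t1"] > 0 and segs[0].se_minor["t1"] > 0

    def test_huge_threshold_empty(self):
        snps = st.simulate_het_snps(1500, ["t1"], cnv_truth=[GAIN_21MB],
                                    depth_mean=200, seed=3)
        segs = cs.segment_allelic(snps, threshold=10.0, rdep={"t1": 1.0})
        assert segs["t1"] == []

    def test_short_chromosome_skipped_with_warning(self):
        snps = st.simulate_het_snps(5, ["t1"], depth_mean=100, seed=0)
        with pytest.warns(UserWarning, match="skipped"):
            segs = cs.segment_allelic(snps, threshold=0.3, rdep={"t1": 1.0})
        assert segs["t1"] == []


class TestCuration:
    def _seg(self, sample, M, m):
        return cs.CnvSegment(chrom="8", start=100, end=200,
                             major={sample: M}, minor={sample: m},
                             se_major={sample: 0.05}, se_minor={sample: 0.05})

    def test_major_above_two_retained(self):
        out = cs.curate_segments({"t1": [self._seg("t1", 2.4, 1.0)]})
        assert len(out) == 1

    def test_neutralish_dropped(self):
        out = cs.curate_segments({"t1": [self._seg("t1", 1.5, 0.8)],
                                  "t2": [self._seg("t2", 1.4, 0.9)]})
        assert out == []

    def test_minor_below_half_in_one_sample_suffices(self):
        out = cs.curate_segments({"t1": [self._seg("t1", 1.0, 0.3)],
                                  "t2": [self._seg("t2", 1.2, 0.9)]})
        assert len(out) == 1

    def test_overlapping_qualifying_segments_merge_to_maximal_region(self):
        a = cs.CnvSegment(chrom="8", start=100, end=300, major={"t1": 2.5},
                          minor={"t1": 1.0}, se_major={"t1": .05}, se_minor={"t1": .05})
        b = cs.CnvSegment(chrom="8", start=250, end=500, major={"t2": 2.6},
                          minor={"t2": 1.0}, se_major={"t2": .05}, se_minor={"t2": .05})
        out = cs.curate_segments({"t1": [a], "t2": [b]})
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (100, 500)


class TestHarmonize:
    def test_median_breakpoint_snapped_to_nearest_snp(self):
        pos = np.array([500, 1101, 2000, 3000, 4000, 5000, 6000, 7000, 8000,
                        9000, 10000, 11000], dtype=np.int64)
        n = len(pos)
        rng = np.random.default_rng(0)
        depth = rng.poisson(200, n)
        a = rng.binomial(depth, 0.5)
        snps = cs.HetSnpCounts(chrom=np.full(n, "8", dtype=object), pos=pos,
                               normal_a=a, normal_b=depth - a,
                               tumor={"t1": (a, depth - a)})
        region = cs.CnvSegment(chrom="8", start=1000, end=11000)
        seg = cs.CnvSegment(chrom="8", start=1000, end=11000, major={"t1": 3.0},
                            minor={"t1": 1.0}, se_major={"t1": .05}, se_minor={"t1": .05})
        per_sample = {
            "t1": [cs.CnvSegment(chrom="8", start=1000, end=11000, major={"t1": 3.0},
                                 minor={"t1": 1.0}, se_major={"t1": .05},
                                 se_minor={"t1": .05})],
            "t2": [cs.CnvSegment(chrom="8", start=1200, end=11000, major={"t2": 3.0},
                                 minor={"t2": 1.0}, se_major={"t2": .05},
                                 se_minor={"t2": .05})],
            "t3": [cs.CnvSegment(chrom="8", start=1100, end=11000, major={"t3": 3.0},
                                 minor={"t3": 1.0}, se_major={"t3": .05},
                                 se_minor={"t3": .05})],
        }
        out = cs.harmonize_breakpoints([region], per_sample, snps,
                                       threshold=-1.0, rdep={"t1": 1.0})
        # median start 1100 snaps to the SNP at 1101
        assert out[0].start == 1101

    def test_second_pass_recovers_boundaries_near_truth(self):
        gain3 = ("8", 124_448_804, 146_364_022, 3, 1, True)
        rdep = {s: 1.0 for s in ("t1", "t2", "t3")}
        snps = st.simulate_het_snps(3000, list(rdep), cnv_truth=[gain3],
                                    depth_mean=200, seed=11)
        final = cs.run_two_pass_curation(snps, rdep=rdep)
        assert len(final) == 1
        pos = snps.pos
        ti = (np.searchsorted(pos, gain3[1]), np.searchsorted(pos, gain3[2], "right") - 1)
        est = (np.searchsorted(pos, final[0].start), np.searchsorted(pos, final[0].end))
        assert abs(est[0] - ti[0]) <= 5
        assert abs(est[1] - ti[1]) <= 5
        # second pass reports every sample with uncertainties
        for s in rdep:
            assert final[0].major[s] > 2.0
            assert final[0].se_major[s] > 0


class TestBundle:
    def _matrix(self, positions):
        variants = [SomaticVariant("8", p, "A", "T") for p in positions]
        M = len(variants)
        return CohortVariantMatrix(
            variants=variants, samples=["normal", "t1"], normal_sample="normal",
            alt_counts=np.full((M, 2), 10), ref_counts=np.full((M, 2), 90))

    def _segment(self):
        return cs.CnvSegment(chrom="8", start=1000, end=2000, major={"t1": 3.0},
                             minor={"t1": 1.0}, se_major={"t1": .05},
                             se_minor={"t1": .05})

    def test_inclusive_overlap_and_no_cnv_column(self):
        m = self._matrix([1000, 2000, 2001, 500])
        bundle = cs.build_bundle([self._segment()], m, rdep={"t1": 1.2})
        Y = bundle.Y.to_numpy()
        seg_col, rest_col = 0, 1
        assert Y[0, seg_col] == 1  # exact start is inside
        assert Y[1, seg_col] == 1  # exact end is inside
        assert Y[2, rest_col] == 1
        assert Y[3, rest_col] == 1
        assert np.all(Y.sum(axis=1) == 1)  # partition property

    def test_overlapping_curated_regions_rejected(self):
        m = self._matrix([1500])
        s1 = self._segment()
        s2 = cs.CnvSegment(chrom="8", start=1500, end=2500, major={"t1": 2.6},
                           minor={"t1": 1.0}, se_major={"t1": .05}, se_minor={"t1": .05})
        with pytest.raises(ConfigurationError):
            cs.build_bundle([s1, s2], m, rdep={"t1": 1.0})

    def test_round_trip_tsv(self, tmp_path):
        snps = st.simulate_het_snps(200, ["t1", "t2"], depth_mean=150, seed=1)
        p = snps.write_tsv(tmp_path / "snps.tsv")
        back = cs.HetSnpCounts.read_tsv(p)
        assert back.samples == snps.samples
        assert np.array_equal(back.pos, snps.pos)
        assert np.array_equal(back.tumor["t1"][0], snps.tumor["t1"][0])
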