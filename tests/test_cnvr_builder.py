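import numpy as np
import pytest

from admixcnv import build_cnvrs, classify_cnvr, intersect_points
from admixcnv.cnvr_builder import cnvr_intervals
from admixcnv.io_formats import ValidationError

from conftest import make_segment


class TestMerging:
    def test_any_base_overlap_merges(self, tiny_manifest):
        segs = [
            make_segment(sample_id="S1", start=100, end=200),
            make_segment(sample_id="S2", start=150, end=300),
        ]
        cnvrs = build_cnvrs(segs, tiny_manifest, min_freq=0.0)
        assert [(c.start, c.end) for c in cnvrs.cnvrs] == [(100, 300)]

    def test_abutting_half_open_intervals_do_not_merge(self, tiny_manifest):
        segs = [
            make_segment(sample_id="S1", start=100, end=200),
            make_segment(sample_id="S2", start=200, end=300),
        ]
        cnvrs = build_cnvrs(segs, tiny_manifest, min_freq=0.0)
        assert len(cnvrs) == 2

    def test_transitive_single_linkage(self, tiny_manifest):
        # A overlaps B, B overlaps C, A does not overlap C -> one region
        segs = [
            make_segment(sample_id="S1", start=100, end=200),
            make_segment(sample_id="S2", start=180, end=400),
            make_segment(sample_id="S3", start=350, end=500),
        ]
        cnvrs = build_cnvrs(segs, tiny_manifest, min_freq=0.0)
        assert [(c.start, c.end) for c in cnvrs.cnvrs] == [(100, 500)]

    def test_merging_is_order_independent(self, kept_segments, noisefree_dataset):
        rng = np.random.default_rng(0)
        shuffled = list(kept_segments)
        rng.shuffle(shuffled)
        a = build_cnvrs(kept_segments, noisefree_dataset.manifest)
        b = build_cnvrs(shuffled, noisefree_dataset.manifest)
        assert cnvr_intervals(a) == cnvr_intervals(b)
        assert a.state_matrix().equals(b.state_matrix())

    def test_idempotence_on_cnvr_intervals(self, kept_segments,
                                           noisefree_dataset):
        built = build_cnvrs(kept_segments, noisefree_dataset.manifest,
                            min_freq=0.0)
        pseudo = [
            make_segment(sample_id="S1", chrom=c, start=s, end=e)
            for c, s, e in cnvr_intervals(built)
        ]
        from admixcnv import SampleManifest
        from admixcnv.io_formats import ManifestEntry
        manifest = SampleManifest([ManifestEntry("S1", "P", "other")])
        rebuilt = build_cnvrs(pseudo, manifest, min_freq=0.0,
                              allow_unfiltered=True)
        assert cnvr_intervals(rebuilt) == cnvr_intervals(built)

    def test_unfiltered_segment_rejected(self, tiny_manifest):
        bad = make_segment(lod=2.0)
        with pytest.raises(ValidationError, match="filter"):
            build_cnvrs([bad], tiny_manifest)

    def test_sample_frequency_threshold_drops_rare_regions(self, tiny_manifest):
        # called in 1 of 5 samples = 20% < 25% threshold -> discarded
        segs = [make_segment(sample_id="S1", start=100, end=200)]
        assert len(build_cnvrs(segs, tiny_manifest, min_freq=0.25)) == 0
        assert len(build_cnvrs(segs, tiny_manifest, min_freq=0.20)) == 1


class TestStatesAndFrequencies:
    def test_conflicting_states_resolve_to_largest_overlap(self, tiny_manifest):
        segs = [
            make_segment(sample_id="S1", start=100, end=900, cn_state=1),
            make_segment(sample_id="S1", start=850, end=950, cn_state=3),
            make_segment(sample_id="S2", start=800, end=1000, cn_state=1),
        ]
        cnvrs = build_cnvrs(segs, tiny_manifest, min_freq=0.0)
        (cnvr,) = cnvrs.cnvrs
        assert cnvr.states["S1"] == 1  # the 800 bp member beats the 100 bp one

    def test_state_tie_breaks_toward_extreme_then_loss(self, tiny_manifest):
        segs = [
            make_segment(sample_id="S1", start=0, end=100, cn_state=1),
            make_segment(sample_id="S1", start=50, end=150, cn_state=0),
            make_segment(sample_id="S2", start=0, end=150, cn_state=1),
        ]
        cnvrs = build_cnvrs(segs, tiny_manifest, min_freq=0.0)
        assert cnvrs.cnvrs[0].states["S1"] == 0  # |0-2| > |1-2|

    def test_noise_free_reconstruction_is_exact(self, noisefree_dataset,
                                                kept_segments):
        """Built CNVRs equal the true loci: intervals, states, frequencies."""
        ds = noisefree_dataset
        cnvrs = build_cnvrs(kept_segments, ds.manifest, min_freq=0.05)
        arr = ds.states.to_numpy()
        carrier_frac = (arr != 2).mean(axis=1)
        expected = [
            (i, ds.truth.locus_intervals[i])
            for i in range(len(carrier_frac)) if carrier_frac[i] >= 0.05
        ]
        assert cnvr_intervals(cnvrs) == sorted(iv for _, iv in expected)
        # per-sample states and per-population frequencies match the truth
        interval_to_cnvr = {(c.chrom, c.start, c.end): c for c in cnvrs.cnvrs}
        for locus_idx, interval in expected:
            cnvr = interval_to_cnvr[interval]
            true_states = ds.states.iloc[locus_idx]
            for sample in ds.manifest.sample_ids:
                assert cnvr.states[sample] == true_states[sample]
            for pop in ds.manifest.populations:
                members = ds.manifest.samples_in(pop)
                true_del = np.mean([true_states[s] < 2 for s in members])
                true_dup = np.mean([true_states[s] > 2 for s in members])
                assert cnvrs.del_freq.loc[cnvr.id, pop] == pytest.approx(true_del)
                assert cnvrs.dup_freq.loc[cnvr.id, pop] == pytest.approx(true_dup)

    def test_every_kept_segment_in_exactly_one_candidate(self, kept_segments,
                                                         noisefree_dataset):
        cnvrs = build_cnvrs(kept_segments, noisefree_dataset.manifest,
                            min_freq=0.0)
        member_ids = [i for c in cnvrs.cnvrs for i in c.member_ids]
        assert sorted(member_ids) == list(range(len(kept_segments)))


class TestClassification:
    @pytest.mark.parametrize(
        "states, expected",
        [({"S1": 0, "S2": 1, "S3": 2}, "del"),
         ({"S1": 2, "S2": 3, "S3": 4}, "dup"),
         ({"S1": 1, "S2": 2, "S3": 3}, "gain_loss")],
    )
    def test_class_from_states(self, states, expected):
        from admixcnv.cnvr_builder import CNVR
        cnvr = CNVR("R1", "chr1", 0, 100, [], states)
        assert classify_cnvr(cnvr) == expected

    def test_all_normal_states_cannot_classify(self):
        from admixcnv.cnvr_builder import CNVR
        cnvr = CNVR("R1", "chr1", 0, 100, [], {"S1": 2})
        with pytest.raises(ValidationError):
            classify_cnvr(cnvr)


class TestPointIntersection:
    REGIONS = [("chr1", 100, 200), ("chr1", 500, 600), ("chr2", 0, 50)]

    def test_point_at_start_kept_at_end_dropped(self):
        assert intersect_points([("chr1", 100)], self.REGIONS)
        assert not intersect_points([("chr1", 200)], self.REGIONS)

    def test_order_preserved(self):
        pts = [("chr1", 550), ("chr2", 10), ("chr1", 150)]
        assert intersect_points(pts, self.REGIONS) == pts

    def test_agrees_with_brute_force_on_random_points(self):
        rng = np.random.default_rng(12)
        regions = [
            ("chr%d" % rng.integers(1, 4), int(s), int(s + rng.integers(1, 5_000)))
            for s in rng.integers(0, 1_000_000, size=200)
        ]
        points = [
            ("chr%d" % rng.integers(1, 4), int(p))
            for p in rng.integers(0, 1_000_000, size=10_000)
        ]
        brute = [
            (c, p) for c, p in points
            if any(rc == c and s <= p < e for rc, s, e in regions)
        ]
        assert intersect_points(points, regions) == brute
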