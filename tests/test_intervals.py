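import numpy as np
import pytest

from epiloop import intervals as itv
from epiloop.io import GeneModel, GenomicInterval


def iv(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)


def per_base_presence_oracle(interval_sets, chrom_len):
    """Brute-force oracle: one boolean row per base per sample."""
    samples = list(interval_sets)
    cov = np.zeros((chrom_len, len(samples)), dtype=bool)
    for si, s in enumerate(samples):
        for r in interval_sets[s]:
            cov[r.start : r.end, si] = True
    return cov


def segments_to_per_base(segments, chrom_len, n_samples):
    cov = np.zeros((chrom_len, n_samples), dtype=bool)
    for seg in segments:
        for si, present in enumerate(seg.presence):
            if present:
                cov[seg.interval.start : seg.interval.end, si] = True
    return cov


def random_instance(rng, n_samples, chrom_len=100_000):
    sets = {}
    for s in range(n_samples):
        ivs = []
        for _ in range(int(rng.integers(0, 15))):
            start = int(rng.integers(0, chrom_len - 2000))
            ivs.append(iv("chr1", start, start + int(rng.integers(1, 2000))))
        sets[f"s{s}"] = ivs
    return sets


class TestAtomicSegments:
    def test_boundary_arithmetic(self):
        segs = itv.atomic_segments(
            {"S1": [iv("chr1", 0, 100)], "S2": [iv("chr1", 50, 150)]}
        )
        got = [
            (s.interval.start, s.interval.end, s.presence) for s in segs
        ]
        assert got == [
            (0, 50, (True, False)),
            (50, 100, (True, True)),
            (100, 150, (False, True)),
        ]

    def test_empty_inputs(self):
        assert itv.atomic_segments({}) == []
        assert itv.atomic_segments({"a": [], "b": []}) == []

    def test_matches_per_base_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 9))
            sets = random_instance(rng, n)
            segs = itv.atomic_segments(sets)
            got = segments_to_per_base(segs, 100_000, n)
            assert np.array_equal(got, per_base_presence_oracle(sets, 100_000))
            # segments within a chromosome are disjoint
            prev_end = -1
            for s in segs:
                assert s.interval.start >= prev_end
                prev_end = s.interval.end

    def test_coverage_conservation_after_labelling(self, rng):
        sets = random_instance(rng, 6)
        segs = itv.atomic_segments(sets)
        labelled = itv.classify_segments(
            segs, itv.lost_rule(5), itv.gained_rule(5, 3)
        )
        union_bp = sum(r.length for r in itv.merge_intervals(
            [r for ivs in sets.values() for r in ivs]
        ))
        assert sum(s.interval.length for s in labelled) == union_bp


class TestClassify:
    @pytest.mark.parametrize(
        "control,case_count,expected",
        [
            (True, 0, "lost"),  # present in control, absent in all cases
            (False, 12, "gained"),  # absent in control, >=10/15 cases
            (True, 15, "shared"),
            (False, 5, "other"),
            (True, 9, "other"),  # below the shared recurrence
        ],
    )
    def test_presence_rules(self, control, case_count, expected):
        presence = (control,) + tuple(i < case_count for i in range(15))
        seg = itv.ConsensusSegment(iv("chr1", 0, 100), presence)
        (out,) = itv.classify_segments(
            [seg], itv.lost_rule(15), itv.gained_rule(15, 10)
        )
        assert out.label == expected

    def test_rule_sample_mismatch_rejected(self):
        seg = itv.ConsensusSegment(iv("chr1", 0, 10), (True, True))
        with pytest.raises(ValueError):
            itv.classify_segments(
                [seg], itv.lost_rule(5), itv.gained_rule(5, 3)
            )

    def test_lost_gained_symmetry_under_role_swap(self, rng):
        # 1 control vs 1 case with k=1: swapping the two samples and the
        # rules maps lost <-> gained on the same data.
        for _ in range(20):
            sets = random_instance(rng, 2, chrom_len=20_000)
            lost, gained = itv.lost_rule(1), itv.gained_rule(1, 1)
            fwd = itv.classify_segments(
                itv.atomic_segments(sets, ["s0", "s1"]), lost, gained
            )
            rev = itv.classify_segments(
                itv.atomic_segments(sets, ["s1", "s0"]), lost, gained
            )
            flip = {"lost": "gained", "gained": "lost"}
            fwd_map = {
                (s.interval.start, s.interval.end): s.label
                for s in fwd
                if s.label in flip
            }
            rev_map = {
                (s.interval.start, s.interval.end): flip[s.label]
                for s in rev
                if s.label in flip
            }
            assert fwd_map == rev_map

    @pytest.mark.parametrize(
        "ctrl_a,ctrl_b,case_count,expected",
        [
            (True, False, 0, "lost"),  # present in either control, 0/13 cases
            (False, True, 0, "lost"),
            (False, False, 7, "gained"),  # absent in BOTH controls, >=6/13
            (True, False, 7, "shared"),  # control + recurrent cases
            (True, False, 3, "other"),  # below every quantifier
        ],
    )
    def test_two_control_slots(self, ctrl_a, ctrl_b, case_count, expected):
        """The two-control design (e.g. TF binding vs two normal lines)
        reuses the same quantifiers: lost = present in either control and
        absent in all 13 cases; gained = absent in both and >=6/13."""
        presence = (ctrl_a, ctrl_b) + tuple(i < case_count for i in range(13))
        seg = itv.ConsensusSegment(iv("chr1", 0, 100), presence)
        (out,) = itv.classify_segments(
            [seg],
            itv.lost_rule(13),
            itv.gained_rule(13, 6),
            n_controls=2,
        )
        assert out.label == expected

    def test_min_width_drops_after_merging(self):
        segs = [
            itv.ConsensusSegment(iv("chr1", 0, 3), (True, False)),
            itv.ConsensusSegment(iv("chr1", 3, 6), (True, False)),
        ]
        out = itv.classify_segments(
            segs, itv.lost_rule(1), itv.gained_rule(1, 1), min_width=5
        )
        assert len(out) == 1 and out[0].interval.length == 6


class TestTssAnnotation:
    GENES = [
        GeneModel("gA", iv("chr1", 10000, 14000, strand="+")),  # tss 10000
        GeneModel("gB", iv("chr1", 46000, 50001, strand="-")),  # tss 50000
        GeneModel("gC", iv("chr2", 5000, 9000, strand="-")),  # tss 8999
    ]

    def test_gap_distance_and_zone(self):
        (ann,) = itv.annotate_to_tss([iv("chr1", 9500, 9600)], self.GENES)
        assert (ann.nearest_gene_id, ann.distance_to_tss, ann.zone) == (
            "gA",
            400,
            "proximal",
        )

    def test_distal_far_interval(self):
        (ann,) = itv.annotate_to_tss([iv("chr1", 0, 100)], self.GENES)
        assert ann.distance_to_tss == 9900 and ann.zone == "distal"

    def test_minus_strand_tss_containment(self):
        (ann,) = itv.annotate_to_tss([iv("chr2", 8990, 9010)], self.GENES)
        assert ann.nearest_gene_id == "gC"
        assert ann.distance_to_tss == 0 and ann.zone == "proximal"

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            itv.annotate_to_tss([iv("chr1", 0, 10)], [])

    def test_tie_breaks_lexicographically(self):
        genes = [
            GeneModel("gZ", iv("chr1", 1000, 2000, strand="+")),
            GeneModel("gA", iv("chr1", 3000, 4000, strand="+")),
        ]
        # interval midway: both TSS 500 bp away
        (ann,) = itv.annotate_to_tss([iv("chr1", 1500, 2500)], genes)
        assert ann.nearest_gene_id == "gA"


class TestPromoterWindows:
    def test_symmetric_window(self):
        g = GeneModel("g", iv("chr1", 10000, 12000, strand="+"))
        (w,) = itv.promoter_windows([g], window=2000)
        assert (w.start, w.end) == (8000, 12000)

    def test_clipped_at_zero(self):
        g = GeneModel("g", iv("chr1", 500, 2500, strand="+"))
        (w,) = itv.promoter_windows([g], window=2000)
        assert (w.start, w.end) == (0, 2500)

    def test_overlapping_windows_kept_per_gene(self):
        genes = [
            GeneModel("g1", iv("chr1", 10000, 12000, strand="+")),
            GeneModel("g2", iv("chr1", 11000, 13000, strand="+")),
        ]
        ws = itv.promoter_windows(genes)
        assert len(ws) == 2 and ws[0].overlaps(ws[1])
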