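import numpy as np
import pytest

from epiloop import loops as lp
from epiloop.io import GeneModel, GenomicInterval, LoopCall


def call(s, a0, a1, b0, b1, count=2, fdr=0.001, sample="s1", chrom="chr1"):
    return LoopCall(
        sample,
        GenomicInterval(chrom, a0, a1),
        GenomicInterval(chrom, b0, b1),
        count,
        fdr,
    )


class TestFilterAndSpan:
    def test_low_count_removed(self):
        assert lp.filter_loops([call("s", 0, 1000, 50000, 51000, count=1)]) == []

    def test_short_span_removed(self):
        assert lp.filter_loops([call("s", 0, 1000, 4000, 5000)]) == []

    def test_all_filters_pass(self):
        c = call("s", 0, 1000, 50000, 51000, count=3, fdr=0.005)
        assert lp.filter_loops([c]) == [c]

    def test_missing_fdr_warns_but_keeps(self):
        c = call("s", 0, 1000, 50000, 51000, count=3, fdr=None)
        with pytest.warns(UserWarning, match="FDR"):
            assert lp.filter_loops([c]) == [c]

    def test_span_is_midpoint_distance(self):
        c = call("s", 0, 1000, 100000, 101000)
        assert lp.loop_span(c) == 100000

    def test_span_zero_for_identical_anchors(self):
        c = call("s", 500, 1500, 500, 1500)
        assert lp.loop_span(c) == 0

    def test_span_invariant_under_anchor_swap(self):
        a = call("s", 0, 1000, 80000, 81000)
        b = call("s", 80000, 81000, 0, 1000)  # canonicalized on construction
        assert lp.loop_span(a) == lp.loop_span(b)


class TestUnifyAnchors:
    def test_overlapping_anchors_merge(self):
        calls = [
            call("x", 0, 100, 50000, 51000, sample="s1"),
            call("x", 50, 150, 50000, 51000, sample="s2"),
        ]
        anchors, loops = lp.unify_anchors(calls, max_gap=500)
        left = [a for a in anchors if a.interval.start == 0]
        assert len(left) == 1 and left[0].interval.end == 150
        assert len(loops) == 1
        assert loops[0].counts == {"s1": 2, "s2": 2}

    def test_gap_beyond_max_keeps_separate(self):
        calls = [
            call("x", 0, 100, 50000, 51000, sample="s1"),
            call("x", 700, 800, 50000, 51000, sample="s2"),  # gap 600
        ]
        anchors, loops = lp.unify_anchors(calls, max_gap=500)
        assert len(anchors) == 3 and len(loops) == 2

    def test_chain_merges_by_single_linkage(self):
        # a-b-c with pairwise gaps 400: transitive closure -> one anchor
        calls = [
            call("x", 0, 100, 50000, 51000, sample="s1"),
            call("x", 500, 600, 50000, 51000, sample="s2"),
            call("x", 1000, 1100, 50000, 51000, sample="s3"),
        ]
        anchors, loops = lp.unify_anchors(calls, max_gap=400)
        left = [a for a in anchors if a.interval.start == 0]
        assert len(left) == 1 and left[0].interval.end == 1100
        assert len(loops) == 1

    def test_single_linkage_matches_bruteforce_closure(self, rng):
        for _ in range(20):
            ivs = []
            for _ in range(25):
                s = int(rng.integers(0, 30_000))
                ivs.append(GenomicInterval("chr1", s, s + int(rng.integers(50, 800))))
            clusters = lp._single_linkage_clusters(ivs, max_gap=300)
            # brute force: union-find over pairwise gap <= 300
            parent = list(range(len(ivs)))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(len(ivs)):
                for j in range(i + 1, len(ivs)):
                    gap = max(
                        ivs[j].start - ivs[i].end, ivs[i].start - ivs[j].end
                    )
                    if gap <= 300:
                        parent[find(i)] = find(j)
            ref = {}
            for i, r in enumerate(ivs):
                ref.setdefault(find(i), set()).add(r)
            got = [set(c) for c in clusters]
            assert sorted(map(len, got)) == sorted(map(len, ref.values()))
            assert {frozenset(c) for c in got} == {
                frozenset(v) for v in ref.values()
            }

    def test_sample_order_invariance(self, rng):
        calls = [
            call("x", int(s), int(s) + 100, int(s) + 20000, int(s) + 21000,
                 sample=f"s{i%3}", count=int(rng.integers(2, 6)))
            for i, s in enumerate(rng.integers(0, 50_000, 15))
        ]
        a1, l1 = lp.unify_anchors(calls, sample_ids=["s0", "s1", "s2"])
        a2, l2 = lp.unify_anchors(calls[::-1], sample_ids=["s0", "s1", "s2"])
        assert [a.interval for a in a1] == [a.interval for a in a2]
        assert [(l.loop_id, l.counts) for l in l1] == [
            (l.loop_id, l.counts) for l in l2
        ]


def unified(counts, a=(0, 1000), b=(50000, 51000)):
    ua = lp.UnifiedAnchor("A1", GenomicInterval("chr1", *a), ())
    ub = lp.UnifiedAnchor("A2", GenomicInterval("chr1", *b), ())
    return lp.UnifiedLoop("L1", ua, ub, counts, 50000)


class TestDifferentialCalling:
    RULE = lp.LoopDiffRule("ctrl", tuple(f"gb{i}" for i in range(14)))

    def counts(self, ctrl, case_values):
        d = {"ctrl": ctrl}
        for i in range(14):
            d[f"gb{i}"] = case_values[i] if i < len(case_values) else 0
        return d

    def test_lost_rule(self):
        (out,) = lp.call_differential_loops(
            [unified(self.counts(3, []))], self.RULE
        )
        assert out.diff_label == "lost"

    def test_gained_rule_nine_of_fourteen(self):
        (out,) = lp.call_differential_loops(
            [unified(self.counts(0, [2] * 9))], self.RULE
        )
        assert out.diff_label == "gained"

    def test_neither_rule_is_other(self):
        (out,) = lp.call_differential_loops(
            [unified(self.counts(2, [2] * 5))], self.RULE
        )
        assert out.diff_label == "other"

    def test_shared_requires_recurrence(self):
        (out,) = lp.call_differential_loops(
            [unified(self.counts(4, [3] * 10))], self.RULE
        )
        assert out.diff_label == "shared"

    def test_control_below_min_count_not_lost(self):
        (out,) = lp.call_differential_loops(
            [unified(self.counts(1, []))], self.RULE
        )
        assert out.diff_label == "other"

    def test_missing_sample_rejected(self):
        loop = unified({"ctrl": 2})
        with pytest.raises(ValueError):
            lp.call_differential_loops([loop], self.RULE)

    def test_every_loop_gets_exactly_one_label(self, rng):
        loops = [
            unified(self.counts(int(rng.integers(0, 5)),
                                list(rng.integers(0, 5, 14))))
            for _ in range(200)
        ]
        out = lp.call_differential_loops(loops, self.RULE)
        labels = [l.diff_label for l in out]
        assert all(l in ("lost", "gained", "shared", "other") for l in labels)
        assert len(out) == 200


class TestClassifyLoops:
    WINDOWS = [
        GenomicInterval("chr1", 0, 2000, name="g1"),
        GenomicInterval("chr1", 49000, 53000, name="g2"),
    ]

    def test_both_promoter_is_pp(self):
        loop = unified({"s": 2})
        out, table = lp.classify_loops([loop], self.WINDOWS)
        assert out[0].cls == "P-P"

    def test_one_distal_is_pe(self):
        loop = unified({"s": 2}, b=(200000, 201000))
        out, _ = lp.classify_loops([loop], self.WINDOWS)
        assert out[0].cls == "P-E"

    def test_no_promoter_is_ee(self):
        loop = unified({"s": 2}, a=(100000, 101000), b=(200000, 201000))
        out, _ = lp.classify_loops([loop], self.WINDOWS)
        assert out[0].cls == "E-E"

    def test_class_stable_under_added_disjoint_windows(self):
        loop = unified({"s": 2}, a=(100000, 101000), b=(200000, 201000))
        out1, _ = lp.classify_loops([loop], self.WINDOWS)
        cls1 = out1[0].cls
        extra = self.WINDOWS + [GenomicInterval("chr1", 300000, 304000)]
        out2, _ = lp.classify_loops([loop], extra)
        assert out2[0].cls == cls1


class TestMultiAnchor:
    def make(self, edges):
        loops = []
        for i, (u, v) in enumerate(edges):
            ua = lp.UnifiedAnchor(u, GenomicInterval("chr1", 1, 2), ())
            ub = lp.UnifiedAnchor(v, GenomicInterval("chr1", 5, 6), ())
            loops.append(lp.UnifiedLoop(f"L{i}", ua, ub, {}, 0))
        return loops

    def test_shared_anchor_flags_both(self):
        loops = self.make([("a1", "a2"), ("a2", "a3")])
        flags, hubs, _ = lp.multi_anchor_flags(loops)
        assert flags == {"L0": True, "L1": True}
        assert len(hubs) == 1

    def test_isolated_loop_not_flagged(self):
        loops = self.make([("a1", "a2"), ("a4", "a5")])
        flags, hubs, _ = lp.multi_anchor_flags(loops)
        assert flags["L1"] is False and hubs == []

    def test_matches_degree_oracle_on_random_graphs(self, rng):
        for _ in range(30):
            n_anchors = int(rng.integers(3, 12))
            edges = [
                (f"a{rng.integers(n_anchors)}", f"a{rng.integers(n_anchors)}")
                for _ in range(int(rng.integers(1, 15)))
            ]
            edges = [(u, v) for u, v in edges if u != v]
            if not edges:
                continue
            loops = self.make(edges)
            flags, _, _ = lp.multi_anchor_flags(loops)
            degree = {}
            for u, v in edges:
                degree[u] = degree.get(u, 0) + 1
                degree[v] = degree.get(v, 0) + 1
            for loop, (u, v) in zip(loops, edges):
                assert flags[loop.loop_id] == (degree[u] >= 2 or degree[v] >= 2)


class TestLengthComparison:
    def stub(self, span):
        ua = lp.UnifiedAnchor("x", GenomicInterval("chr1", 1, 2), ())
        return lp.UnifiedLoop("L", ua, ua, {}, int(span))

    def test_identical_sets_p_one(self):
        a = [self.stub(s) for s in (10000, 20000, 30000)]
        res = lp.compare_loop_lengths(a, [self.stub(l.span_bp) for l in a])
        assert res.test.p_value == 1.0

    def test_large_shift_tiny_p(self, rng):
        lost = [self.stub(s) for s in rng.normal(254000, 30000, 500)]
        gained = [self.stub(s) for s in rng.normal(114000, 30000, 500)]
        res = lp.compare_loop_lengths(lost, gained)
        assert res.test.p_value < 1e-10
        assert res.median_lost > res.median_gained

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            lp.compare_loop_lengths([], [self.stub(1)])


class TestGenesAtAnchors:
    def test_overlap_with_core_degs(self):
        genes = [
            GeneModel("g1", GenomicInterval("chr1", 500, 3000, strand="+")),
            GeneModel("g2", GenomicInterval("chr1", 900000, 903000, strand="+")),
        ]
        loop = unified({"s": 2})
        loop.diff_label = "gained"
        hits, degs = lp.genes_at_differential_anchors([loop], genes, {"g1", "g9"})
        assert hits == {"g1"} and degs == {"g1"}

    def test_gene_desert_anchor_contributes_nothing(self):
        genes = [GeneModel("g1", GenomicInterval("chr2", 0, 1000, strand="+"))]
        loop = unified({"s": 2})
        loop.diff_label = "lost"
        hits, degs = lp.genes_at_differential_anchors([loop], genes, {"g1"})
        assert hits == set() and degs == set()
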