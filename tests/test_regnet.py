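import numpy as np
import pytest
from scipy import stats as sps

from epiloop import regnet, stats
from epiloop.io import GeneModel, GenomicInterval, MotifPWM


def pwm_from_consensus(consensus, p=0.9, motif_id="m"):
    rows = []
    q = (1 - p) / 3
    for base in consensus:
        row = [q] * 4
        row["ACGT".index(base)] = p
        rows.append(row)
    return MotifPWM(motif_id, np.array(rows))


def hit(motif, chrom, start, width=2, strand="+", score=5.0):
    return regnet.MotifHit(
        motif, GenomicInterval(chrom, start, start + width, strand), score
    )


class TestScanPwm:
    def test_consensus_score_in_bits(self):
        pwm = pwm_from_consensus("AC")
        hits = regnet.scan_pwm({"chr1": "ACGT"}, pwm, threshold_bits=3.0)
        plus = [h for h in hits if h.interval.strand == "+"]
        assert len(plus) == 1 and plus[0].interval.start == 0
        assert plus[0].score == pytest.approx(2 * np.log2(0.9 / 0.25), rel=1e-12)

    def test_palindrome_hits_both_strands_symmetrically(self):
        pwm = pwm_from_consensus("ACGT")  # reverse complement of itself
        hits = regnet.scan_pwm({"chr1": "ttACGTtt"}, pwm, threshold_bits=7.0)
        strands = sorted(h.interval.strand for h in hits)
        assert strands == ["+", "-"]
        assert len({h.interval.start for h in hits}) == 1

    def test_threshold_above_max_yields_nothing(self):
        pwm = pwm_from_consensus("ACGT")
        assert regnet.scan_pwm({"chr1": "ACGT"}, pwm, pwm.max_score() + 1) == []

    def test_windows_with_n_skipped(self):
        pwm = pwm_from_consensus("AC")
        hits = regnet.scan_pwm({"chr1": "ANACAN"}, pwm, threshold_bits=3.0)
        assert [h.interval.start for h in hits if h.interval.strand == "+"] == [2]

    def test_motif_wider_than_sequence_is_not_an_error(self):
        pwm = pwm_from_consensus("ACGTACGT")
        assert regnet.scan_pwm({"chr1": "ACG"}, pwm, 0.0) == []

    def test_agrees_with_bruteforce_scorer(self, rng):
        bases = "ACGT"
        seq = "".join(rng.choice(list(bases), 2000))
        pwm = MotifPWM("r", rng.dirichlet(np.ones(4), size=6))
        lom = pwm.log_odds()
        got = {
            (h.interval.start, h.interval.strand): h.score
            for h in regnet.scan_pwm({"c": seq}, pwm, threshold_bits=-10.0)
        }
        # brute force, summing positions in the same ascending order
        for strand in "+-":
            mat = lom if strand == "+" else pwm.reverse_complement().log_odds()
            for i in range(len(seq) - 6 + 1):
                score = 0.0
                for j in range(6):
                    score += mat[j, bases.index(seq[i + j])]
                if score >= -10.0:
                    assert got[(i, strand)] == score  # exact fp equality


class TestEnrichment:
    def regions(self, chrom, n, start=0, step=1000, width=500):
        return [
            GenomicInterval(chrom, start + i * step, start + i * step + width)
            for i in range(n)
        ]

    def test_extreme_enrichment_exact_p(self):
        targets = self.regions("chr1", 5)
        background = self.regions("chr2", 15)
        hits = {"m": [hit("m", "chr1", r.start + 10) for r in targets]}
        (res,) = regnet.motif_enrichment(targets, background, hits)
        assert res.p_value == pytest.approx(1 / 15504, rel=1e-9)
        assert (res.targets_with_hit, res.background_with_hit) == (5, 0)

    def test_equal_frequency_not_enriched(self):
        targets = self.regions("chr1", 10)
        background = self.regions("chr2", 10)
        hits = {
            "m": [hit("m", "chr1", targets[i].start + 5) for i in range(5)]
            + [hit("m", "chr2", background[i].start + 5) for i in range(5)]
        }
        (res,) = regnet.motif_enrichment(targets, background, hits)
        assert res.p_value >= 0.5

    def test_no_hits_anywhere_p_one(self):
        (res,) = regnet.motif_enrichment(
            self.regions("chr1", 5), self.regions("chr2", 5), {"m": []}
        )
        assert res.p_value == 1.0

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            regnet.motif_enrichment(self.regions("chr1", 5), [], {"m": []})

    def test_null_pvalues_uniform_under_random_labels(self, rng):
        """Permutation null: random target labels -> uniform p (KS)."""
        all_regions = self.regions("chr1", 40)
        flagged = set(rng.choice(40, size=20, replace=False))
        hits = {
            "m": [hit("m", "chr1", all_regions[i].start + 5) for i in flagged]
        }
        pvals = []
        for _ in range(400):
            idx = rng.permutation(40)
            targets = [all_regions[i] for i in idx[:10]]
            background = [all_regions[i] for i in idx[10:]]
            (res,) = regnet.motif_enrichment(targets, background, hits)
            pvals.append(res.p_value)
        # discrete hypergeometric p-values are super-uniform; require
        # P(p <= a) <= a within Monte-Carlo slack
        p = np.asarray(pvals)
        for a in (0.01, 0.05, 0.2):
            assert (p <= a).mean() <= a + 3 * np.sqrt(a * (1 - a) / p.size)


class TestSelectKeyTfs:
    ENR = [
        regnet.EnrichmentResult("m_in", 5, 5, 0, 20, 0.005),
        regnet.EnrichmentResult("m_notdeg", 5, 5, 0, 20, 0.005),
        regnet.EnrichmentResult("m_weak", 3, 5, 5, 20, 0.02),
    ]
    MAP = {"m_in": "gene1", "m_notdeg": "gene2", "m_weak": "gene3"}

    def test_selection_rule(self):
        out = regnet.select_key_tfs(self.ENR, self.MAP, {"gene1", "gene3"})
        assert out == ["m_in"]  # enriched AND differentially expressed

    def test_unmapped_motif_warns_and_skips(self):
        enr = [regnet.EnrichmentResult("m_x", 5, 5, 0, 20, 0.001)]
        with pytest.warns(UserWarning, match="mapping"):
            assert regnet.select_key_tfs(enr, {}, {"g"}) == []


class TestAssignTargets:
    GENES = [
        GeneModel("g7", GenomicInterval("chr1", 10000, 13000, strand="+")),
        GeneModel("g8", GenomicInterval("chr1", 60000, 63000, strand="+")),
    ]

    def test_proximal_edge(self):
        gained = [GenomicInterval("chr1", 8000, 9000)]
        edges = regnet.assign_targets(
            {"tf": [hit("tf", "chr1", 8494, width=10)]}, gained, self.GENES
        )
        (e,) = edges
        assert (e.gene_id, e.zone) == ("g7", "proximal")
        assert e.tss_distance == pytest.approx(10000 - 8499, abs=1)

    def test_distal_edge(self):
        gained = [GenomicInterval("chr1", 30000, 31000)]
        (e,) = regnet.assign_targets(
            {"tf": [hit("tf", "chr1", 30000, width=10)]}, gained, self.GENES
        )
        assert e.zone == "distal"

    def test_hit_outside_gained_regions_makes_no_edge(self):
        gained = [GenomicInterval("chr1", 8000, 9000)]
        edges = regnet.assign_targets(
            {"tf": [hit("tf", "chr1", 20000, width=10)]}, gained, self.GENES
        )
        assert edges == []


class TestCommonTargets:
    def edge(self, tf, gene):
        return regnet.TFTargetEdge(
            tf,
            gene,
            GenomicInterval("chr1", 0, 100),
            hit(tf, "chr1", 10),
            50,
            "proximal",
        )

    def test_thirty_three_of_forty_seven(self):
        a = [self.edge("A", f"g{i}") for i in range(47)]
        b = [self.edge("B", f"g{i}") for i in range(33)] + [
            self.edge("B", f"x{i}") for i in range(20)
        ]
        res = regnet.common_targets(a, b)
        assert len(res.overlap) == 33
        assert round(100 * res.fraction_of_a, 1) == 70.2

    def test_identical_sets_full_overlap(self):
        a = [self.edge("A", "g1"), self.edge("A", "g1")]  # duplicates collapse
        b = [self.edge("B", "g1")]
        assert regnet.common_targets(a, b).fraction_of_a == 1.0

    def test_disjoint_sets(self):
        a = [self.edge("A", "g1")]
        b = [self.edge("B", "g2")]
        assert regnet.common_targets(a, b).fraction_of_a == 0.0

    def test_empty_a_undefined(self):
        assert regnet.common_targets([], [self.edge("B", "g")]).fraction_of_a is None


class TestMotifPairDistance:
    def region(self, start=0, end=1000):
        return GenomicInterval("chr1", start, end)

    def test_midpoint_arithmetic(self):
        # target pair midpoints 100 and 156 -> 56; background pair 200 apart
        ha = [hit("a", "chr1", 99), hit("a", "chr1", 2099)]
        hb = [hit("b", "chr1", 155), hit("b", "chr1", 2299)]
        res = regnet.motif_pair_distance(
            ha, hb, [self.region()], [self.region(2000, 3000)]
        )
        assert res.target_distances == (56,)
        assert res.background_distances == (200,)

    def test_region_with_single_motif_skipped_and_counted(self):
        ha = [hit("a", "chr1", 100), hit("a", "chr1", 2100)]
        hb = [hit("b", "chr1", 150)]
        res = regnet.motif_pair_distance(
            ha,
            hb,
            [self.region(), self.region(2000, 3000)],  # second lacks motif b
            [self.region(0, 1000)],
        )
        assert res.skipped_targets == 1

    def test_no_contributing_region_rejected(self):
        with pytest.raises(ValueError):
            regnet.motif_pair_distance(
                [hit("a", "chr1", 100)], [], [self.region()], [self.region()]
            )
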