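"""Motif scanning and the transcription-factor regulatory-network stage:
enrichment of motifs in gained regions, TF selection by DEG intersection,
target-gene assignment near TSSs, common-target overlap and the motif-pair
distance statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import stats
from .io import GeneModel, GenomicInterval, MotifPWM
from .intervals import _tss_index, nearest_tss


@dataclass(frozen=True)
class MotifHit:
    """A log-odds PWM match at a genomic position (either strand)."""

    motif_id: str
    interval: GenomicInterval  # strand-aware, length = motif width
    score: float  # bits


@dataclass(frozen=True)
class EnrichmentResult:
    motif_id: str
    targets_with_hit: int
    targets_total: int
    background_with_hit: int
    background_total: int
    p_value: float
    q_value: float | None = None


@dataclass(frozen=True)
class TFTargetEdge:
    """TF -> gene link: a motif hit inside a gained region near the TSS."""

    tf_id: str
    gene_id: str
    evidence_region: GenomicInterval
    hit: MotifHit
    tss_distance: int
    zone: str  # 'proximal' or 'distal'


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return codes


def _scan_one_strand(
    codes: np.ndarray, lom: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Scores of every window of len(lom) against the log-odds matrix;
    windows containing non-ACGT characters are masked out."""
    width = lom.shape[0]
    n = codes.size - width + 1
    if n <= 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(width):  # ascending j: summation order matches brute force
        c = codes[j : j + n]
        bad = c < 0
        valid &= ~bad
        scores += lom[j, np.where(bad, 0, c)]
    pos = np.nonzero(valid)[0]
    return scores[pos], pos


def scan_pwm(
    sequences: Mapping[str, str], pwm: MotifPWM, threshold_bits: float
) -> list[MotifHit]:
    """Scan both strands of each sequence with the PWM log-odds score
    sum_j log2(p_j(base)/bg(base)); hits with score >= threshold are
    returned with forward-genome coordinates."""
    if not np.isfinite(threshold_bits):
        raise ValueError("threshold must be finite")
    hits: list[MotifHit] = []
    lom_fwd = pwm.log_odds()
    lom_rev = pwm.reverse_complement().log_odds()
    width = pwm.width
    for chrom in sorted(sequences):
        codes = _encode(sequences[chrom].upper())
        for strand, lom in (("+", lom_fwd), ("-", lom_rev)):
            scores, pos = _scan_one_strand(codes, lom)
            keep = scores >= threshold_bits
            for p, s in zip(pos[keep], scores[keep]):
                hits.append(
                    MotifHit(
                        pwm.motif_id,
                        GenomicInterval(
                            chrom, int(p), int(p) + width, strand, pwm.motif_id
                        ),
                        float(s),
                    )
                )
    hits.sort(key=lambda h: (h.interval.sort_key(), h.interval.strand))
    return hits


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def _regions_with_hit(
    regions: Sequence[GenomicInterval], hits: Sequence[MotifHit]
) -> int:
    return sum(
        any(r.contains(h.interval) for h in hits) for r in regions
    )


def _region_hit_flags(
    regions: Sequence[GenomicInterval], hits: Sequence[MotifHit]
) -> np.ndarray:
    by_chrom: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.interval.chrom, []).append(h)
    flags = np.zeros(len(regions), dtype=bool)
    for i, r in enumerate(regions):
        for h in by_chrom.get(r.chrom, []):
            if r.contains(h.interval):
                flags[i] = True
                break
    return flags


def motif_enrichment(
    target_regions: Sequence[GenomicInterval],
    background_regions: Sequence[GenomicInterval],
    hits_by_motif: Mapping[str, Sequence[MotifHit]],
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of motif-bearing regions among targets.

    A region carries a motif iff >=1 hit lies fully inside it.  With N =
    targets + background regions, K = regions with a hit anywhere, n =
    targets, k = targets with a hit, p = P(X >= k); q-values are BH across
    motifs.  The background must not include the targets.
    """
    if not background_regions:
        raise ValueError("empty background region set")
    results = []
    n_t, n_b = len(target_regions), len(background_regions)
    for motif_id in sorted(hits_by_motif):
        hits = hits_by_motif[motif_id]
        k = int(_region_hit_flags(target_regions, hits).sum())
        b = int(_region_hit_flags(background_regions, hits).sum())
        p = stats.hypergeom_upper_tail(n_t + n_b, k + b, n_t, k)
        results.append(EnrichmentResult(motif_id, k, n_t, b, n_b, p))
    q = stats.bh_adjust([r.p_value for r in results])
    return [
        EnrichmentResult(
            r.motif_id,
            r.targets_with_hit,
            r.targets_total,
            r.background_with_hit,
            r.background_total,
            r.p_value,
            float(qv),
        )
        for r, qv in zip(results, q)
    ]


def select_key_tfs(
    enrichment: Sequence[EnrichmentResult],
    motif_to_gene: Mapping[str, str],
    core_degs: Iterable[str],
    alpha: float = 0.01,
) -> list[str]:
    """TFs whose motif is enriched (p < alpha) and whose own gene belongs
    to the core DEG set.  Motifs without a gene mapping are excluded with
    a warning."""
    core = set(core_degs)
    selected = []
    for r in enrichment:
        if r.p_value >= alpha:
            continue
        gene = motif_to_gene.get(r.motif_id)
        if gene is None:
            warnings.warn(f"motif {r.motif_id} has no gene mapping; excluded")
            continue
        if gene in core:
            selected.append(r.motif_id)
    return sorted(selected)


# ---------------------------------------------------------------------------
# target assignment
# ---------------------------------------------------------------------------


def assign_targets(
    tf_hits: Mapping[str, Sequence[MotifHit]],
    gained_regions: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    window: int = 2000,
) -> list[TFTargetEdge]:
    """Create TF->gene edges for every motif hit inside a gained region.

    The target gene is the nearest TSS to the hit midpoint (lexicographic
    tie-break); genes whose TSS is equidistant within 1 bp each receive an
    edge.  Zone is proximal iff |distance| < window.
    """
    index = _tss_index(genes)
    edges: list[TFTargetEdge] = []
    for tf_id in sorted(tf_hits):
        for h in tf_hits[tf_id]:
            region = next(
                (r for r in gained_regions if r.contains(h.interval)), None
            )
            if region is None:
                continue
            mid = GenomicInterval(
                h.interval.chrom, h.interval.midpoint, h.interval.midpoint + 1
            )
            gid, dist = nearest_tss(mid, index)
            if gid is None:
                continue
            dmin = abs(dist)
            positions, ids = index[h.interval.chrom]
            for tss, gene_id in zip(positions, ids):
                d = tss - h.interval.midpoint
                if abs(abs(d) - dmin) <= 1:
                    edges.append(
                        TFTargetEdge(
                            tf_id,
                            gene_id,
                            region,
                            h,
                            int(d),
                            "proximal" if abs(d) < window else "distal",
                        )
                    )
    for e in edges:  # containment audit: every edge's hit inside its region
        assert e.evidence_region.contains(e.hit.interval)
    return edges


@dataclass(frozen=True)
class CommonTargets:
    targets_a: frozenset[str]
    targets_b: frozenset[str]
    overlap: frozenset[str]
    fraction_of_a: float | None  # |A & B| / |A|; None when A is empty


def common_targets(
    edges_a: Sequence[TFTargetEdge],
    edges_b: Sequence[TFTargetEdge],
    restrict_to: Iterable[str] | None = None,
) -> CommonTargets:
    """Overlap of two TFs' target-gene sets (set semantics; duplicate edges
    are irrelevant), optionally restricted to a gene set such as the core
    DEGs."""
    a = {e.gene_id for e in edges_a}
    b = {e.gene_id for e in edges_b}
    if restrict_to is not None:
        allowed = set(restrict_to)
        a &= allowed
        b &= allowed
    overlap = a & b
    frac = len(overlap) / len(a) if a else None
    return CommonTargets(frozenset(a), frozenset(b), frozenset(overlap), frac)


# ---------------------------------------------------------------------------
# motif-pair distances
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifPairDistanceResult:
    target_distances: tuple[int, ...]
    background_distances: tuple[int, ...]
    target_median: float
    background_median: float
    target_iqr: tuple[float, float]
    background_iqr: tuple[float, float]
    skipped_targets: int
    skipped_background: int
    test: stats.TestResult


def _per_region_min_distance(
    regions: Sequence[GenomicInterval],
    hits_a: Sequence[MotifHit],
    hits_b: Sequence[MotifHit],
) -> tuple[list[int], int]:
    dists: list[int] = []
    skipped = 0
    for r in regions:
        mids_a = [h.interval.midpoint for h in hits_a if r.contains(h.interval)]
        mids_b = [h.interval.midpoint for h in hits_b if r.contains(h.interval)]
        if not mids_a or not mids_b:
            skipped += 1
            continue
        dists.append(min(abs(a - b) for a in mids_a for b in mids_b))
    return dists, skipped


def motif_pair_distance(
    hits_a: Sequence[MotifHit],
    hits_b: Sequence[MotifHit],
    target_regions: Sequence[GenomicInterval],
    background_regions: Sequence[GenomicInterval],
) -> MotifPairDistanceResult:
    """Per-region minimum midpoint distance between two motifs, compared
    between target regions and a background region set by a two-sided
    Wilcoxon rank-sum test; regions lacking either motif are skipped and
    counted."""
    td, ts = _per_region_min_distance(target_regions, hits_a, hits_b)
    bd, bs = _per_region_min_distance(background_regions, hits_a, hits_b)
    if not td or not bd:
        raise ValueError("no region with both motifs on one side")
    test = stats.wilcoxon_rank_sum(td, bd, mode="auto")
    return MotifPairDistanceResult(
        tuple(td),
        tuple(bd),
        float(np.median(td)),
        float(np.median(bd)),
        (float(np.percentile(td, 25)), float(np.percentile(td, 75))),
        (float(np.percentile(bd, 25)), float(np.percentile(bd, 75))),
        ts,
        bs,
        test,
    )
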