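"""Multi-sample interval segmentation and presence/absence differential calls.

The central operation mirrors multi-way interval intersection (bedtools
multiinter semantics): the union of all samples' peaks is partitioned into
maximal segments of constant per-sample presence, and each segment is then
labelled by quantifier rules of the form "present in the control and absent
in all n cases" (lost) or "absent in the control and present in at least k
of n cases" (gained).
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import GeneModel, GenomicInterval

LABELS = ("lost", "gained", "shared", "other")


@dataclass(frozen=True)
class PresenceRule:
    """A quantifier over the control slot(s) and the case presence count.

    control_required: the segment must be present in >=1 control (True) or
    absent from every control (False).  case_mode 'absent_in_all' demands
    zero case presence; 'present_in_at_least_k' demands >= case_min of
    case_total cases.
    """

    control_required: bool
    case_min: int
    case_total: int
    case_mode: str

    def __post_init__(self) -> None:
        if self.case_mode not in ("absent_in_all", "present_in_at_least_k"):
            raise ValueError(f"unknown case_mode {self.case_mode!r}")
        if not (0 <= self.case_min <= self.case_total):
            raise ValueError(
                f"case_min {self.case_min} outside [0, {self.case_total}]"
            )

    def matches(self, control_presence: Sequence[bool], case_presence: Sequence[bool]) -> bool:
        if len(case_presence) != self.case_total:
            raise ValueError(
                f"rule expects {self.case_total} cases, got {len(case_presence)}"
            )
        ctrl_ok = any(control_presence) if self.control_required else not any(
            control_presence
        )
        if not ctrl_ok:
            return False
        if self.case_mode == "absent_in_all":
            return not any(case_presence)
        return sum(case_presence) >= self.case_min


def lost_rule(n_cases: int) -> PresenceRule:
    """Control-specific: present in the control, absent in all cases."""
    return PresenceRule(True, 0, n_cases, "absent_in_all")


def gained_rule(n_cases: int, k: int) -> PresenceRule:
    """Case-recurrent: absent from every control, present in >=k of n cases."""
    return PresenceRule(False, k, n_cases, "present_in_at_least_k")


@dataclass(frozen=True)
class ConsensusSegment:
    """A genomic segment with one presence bit per sample (controls first)."""

    interval: GenomicInterval
    presence: tuple[bool, ...]
    label: str | None = None


@dataclass(frozen=True)
class TssAnnotation:
    interval: GenomicInterval
    nearest_gene_id: str | None
    distance_to_tss: int | None  # signed; positive = TSS right of interval
    zone: str  # 'proximal' or 'distal'


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of possibly-overlapping intervals, per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=GenomicInterval.sort_key)
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def atomic_segments(
    interval_sets: Mapping[str, Sequence[GenomicInterval]],
    sample_order: Sequence[str] | None = None,
) -> list[ConsensusSegment]:
    """Partition the union of all samples' intervals into maximal segments
    of constant presence.

    Presence means >=1 bp overlap.  Adjacent segments with identical
    presence vectors are merged; the output covers exactly the union of the
    inputs.  ``sample_order`` fixes the presence-vector index (controls
    first by the package convention); it defaults to the mapping order.
    """
    samples = list(sample_order) if sample_order is not None else list(interval_sets)
    missing = set(samples) - set(interval_sets)
    if missing:
        raise ValueError(f"sample_order references unknown samples {sorted(missing)}")
    merged = {s: merge_intervals(interval_sets[s]) for s in samples}
    chroms = sorted({iv.chrom for ivs in merged.values() for iv in ivs})
    segments: list[ConsensusSegment] = []
    for chrom in chroms:
        bounds: set[int] = set()
        per_sample: list[list[GenomicInterval]] = []
        for s in samples:
            ivs = [iv for iv in merged[s] if iv.chrom == chrom]
            per_sample.append(ivs)
            for iv in ivs:
                bounds.add(iv.start)
                bounds.add(iv.end)
        cuts = np.array(sorted(bounds), dtype=np.int64)
        if cuts.size < 2:
            continue
        n_seg = cuts.size - 1
        presence = np.zeros((n_seg, len(samples)), dtype=bool)
        for si, ivs in enumerate(per_sample):
            for iv in ivs:
                i0 = int(np.searchsorted(cuts, iv.start))
                i1 = int(np.searchsorted(cuts, iv.end))
                presence[i0:i1, si] = True
        covered = presence.any(axis=1)
        # merge runs of identical presence over contiguous covered segments
        run_start: int | None = None
        for i in range(n_seg + 1):
            boundary = (
                i == n_seg
                or not covered[i]
                or (run_start is not None and not np.array_equal(presence[i], presence[run_start]))
            )
            if run_start is not None and boundary:
                segments.append(
                    ConsensusSegment(
                        GenomicInterval(chrom, int(cuts[run_start]), int(cuts[i])),
                        tuple(bool(b) for b in presence[run_start]),
                    )
                )
                run_start = None
            if i < n_seg and covered[i] and run_start is None:
                run_start = i
    return segments


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_segments(
    segments: Sequence[ConsensusSegment],
    lost: PresenceRule,
    gained: PresenceRule,
    n_controls: int = 1,
    min_width: int = 1,
) -> list[ConsensusSegment]:
    """Label each segment lost/gained/shared/other.

    The first ``n_controls`` presence slots are controls, the rest cases.
    'shared' means present in the control(s) with case recurrence at least
    the gained threshold; everything matching neither quantifier nor the
    shared pattern is 'other'.  Adjacent same-label segments are merged and
    merged segments narrower than ``min_width`` are dropped.
    """
    labelled: list[ConsensusSegment] = []
    for seg in segments:
        ctrl = seg.presence[:n_controls]
        cases = seg.presence[n_controls:]
        if lost.matches(ctrl, cases):
            lab = "lost"
        elif gained.matches(ctrl, cases):
            lab = "gained"
        elif any(ctrl) and sum(cases) >= gained.case_min:
            lab = "shared"
        else:
            lab = "other"
        labelled.append(replace(seg, label=lab))
    # merge touching same-label neighbours
    merged: list[ConsensusSegment] = []
    for seg in labelled:
        if (
            merged
            and merged[-1].label == seg.label
            and merged[-1].interval.chrom == seg.interval.chrom
            and merged[-1].interval.end == seg.interval.start
        ):
            prev = merged.pop()
            merged.append(
                ConsensusSegment(
                    GenomicInterval(
                        seg.interval.chrom, prev.interval.start, seg.interval.end
                    ),
                    prev.presence if prev.presence == seg.presence else tuple(
                        a or b for a, b in zip(prev.presence, seg.presence)
                    ),
                    seg.label,
                )
            )
        else:
            merged.append(seg)
    return [s for s in merged if s.interval.length >= min_width]


# ---------------------------------------------------------------------------
# TSS-relative annotation
# ---------------------------------------------------------------------------


def _tss_index(genes: Sequence[GeneModel]) -> dict[str, tuple[list[int], list[str]]]:
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    out: dict[str, tuple[list[int], list[str]]] = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        out[chrom] = ([p[0] for p in pairs], [p[1] for p in pairs])
    return out


def _signed_distance(iv: GenomicInterval, tss: int) -> int:
    """0 when the interval contains the TSS, else the signed bp gap
    (positive when the TSS lies right of the interval)."""
    if iv.start <= tss < iv.end:
        return 0
    if tss >= iv.end:
        return tss - iv.end
    return tss - iv.start  # negative


def nearest_tss(
    iv: GenomicInterval, index: Mapping[str, tuple[list[int], list[str]]]
) -> tuple[str | None, int | None]:
    if iv.chrom not in index:
        return None, None
    positions, ids = index[iv.chrom]
    lo = bisect_left(positions, iv.start) - 1
    hi = bisect_right(positions, iv.end) + 1
    best: tuple[int, str] | None = None
    for i in range(max(lo, 0), min(hi, len(positions))):
        d = _signed_distance(iv, positions[i])
        key = (abs(d), ids[i])
        if best is None or key < (abs(best[0]), best[1]):
            best = (d, ids[i])
    assert best is not None
    return best[1], best[0]


def annotate_to_tss(
    intervals: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    window: int = 2000,
) -> list[TssAnnotation]:
    """Annotate each interval with its nearest strand-aware TSS.

    Zone is 'proximal' when |distance| < window (the <2 kb promoter rule),
    'distal' otherwise.  Nearest-gene ties break to the lexicographically
    smallest gene_id.  Intervals on chromosomes without genes get no
    nearest gene and are distal.
    """
    if not genes:
        raise ValueError("empty gene list")
    index = _tss_index(genes)
    out: list[TssAnnotation] = []
    for iv in intervals:
        gid, dist = nearest_tss(iv, index)
        if gid is None:
            out.append(TssAnnotation(iv, None, None, "distal"))
        else:
            zone = "proximal" if abs(dist) < window else "distal"
            out.append(TssAnnotation(iv, gid, dist, zone))
    return out


def promoter_windows(
    genes: Sequence[GeneModel], window: int = 2000
) -> list[GenomicInterval]:
    """One symmetric window [tss-window, tss+window) per gene, clipped at 0;
    overlapping windows of nearby genes are intentionally kept unmerged."""
    return [
        GenomicInterval(
            g.chrom, max(0, g.tss - window), g.tss + window, name=g.gene_id
        )
        for g in genes
    ]
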