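"""HiChIP loop post-processing: filtering, cross-sample anchor unification,
differential calling, promoter/enhancer classification, multi-anchor hubs
and loop-length statistics.

Loop span is the distance between anchor midpoints throughout; 'absent'
means a unified count of zero (a loop missing from a sample's file has
implicit count 0).
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import stats
from .io import GeneModel, GenomicInterval, LoopCall
from .intervals import promoter_windows as _promoter_windows

LOOP_CLASSES = ("P-P", "P-E", "E-E")


@dataclass(frozen=True)
class UnifiedAnchor:
    """A cross-sample anchor: the merged span of single-linkage-clustered
    per-sample anchor intervals."""

    anchor_id: str
    interval: GenomicInterval
    members: tuple[GenomicInterval, ...]
    is_promoter: bool | None = None


@dataclass
class UnifiedLoop:
    loop_id: str
    anchor_a: UnifiedAnchor
    anchor_b: UnifiedAnchor
    counts: dict[str, int]  # per sample; 0 when absent
    span_bp: int
    cls: str | None = None
    diff_label: str | None = None
    multi_anchor: bool = False


@dataclass(frozen=True)
class LoopDiffRule:
    """Presence/absence quantifiers for differential loops.

    lost: control count >= min_count and every case count 0.
    gained: control count 0 and >= case_min cases with count >= min_count.
    """

    control_sample: str
    case_samples: tuple[str, ...]
    min_count: int = 2
    case_min: int = 8

    def __post_init__(self) -> None:
        if self.min_count < 0 or self.case_min < 0:
            raise ValueError("thresholds must be non-negative")
        if self.case_min > len(self.case_samples):
            raise ValueError(
                f"case_min {self.case_min} exceeds {len(self.case_samples)} cases"
            )


# ---------------------------------------------------------------------------


def loop_span(call: LoopCall) -> int:
    """Distance between anchor midpoints (floor division)."""
    if call.anchor_a.chrom != call.anchor_b.chrom:
        raise ValueError("span undefined for inter-chromosomal loops")
    return abs(call.anchor_a.midpoint - call.anchor_b.midpoint)


def filter_loops(
    calls: Iterable[LoopCall],
    min_count: int = 2,
    max_fdr: float = 0.01,
    min_length: int = 5000,
) -> list[LoopCall]:
    """Keep calls with count >= min_count, FDR < max_fdr (when present) and
    span >= min_length."""
    calls = list(calls)
    if any(c.fdr is None for c in calls) and max_fdr is not None:
        warnings.warn("some calls carry no FDR; the FDR filter is skipped for them")
    out = []
    for c in calls:
        if c.count < min_count:
            continue
        if max_fdr is not None and c.fdr is not None and not (c.fdr < max_fdr):
            continue
        if loop_span(c) < min_length:
            continue
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# anchor unification
# ---------------------------------------------------------------------------


def _single_linkage_clusters(
    intervals: list[GenomicInterval], max_gap: int
) -> list[list[GenomicInterval]]:
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    clusters: list[list[GenomicInterval]] = []
    cur: list[GenomicInterval] = []
    cur_end = -1
    for iv in ivs:
        if cur and iv.start - cur_end > max_gap:
            clusters.append(cur)
            cur = []
        cur.append(iv)
        cur_end = max(cur_end, iv.end)
    if cur:
        clusters.append(cur)
    return clusters


def unify_anchors(
    calls: Sequence[LoopCall],
    max_gap: int = 500,
    sample_ids: Sequence[str] | None = None,
) -> tuple[list[UnifiedAnchor], list[UnifiedLoop]]:
    """Merge anchors across samples (single linkage, gap <= max_gap per
    chromosome) and collapse calls mapping to the same unified anchor pair
    into one loop with per-sample counts (within-sample duplicates summed).

    ``sample_ids`` fixes the count-vector key set; samples without any call
    then appear with count 0.
    """
    if sample_ids is None:
        sample_ids = sorted({c.sample_id for c in calls})
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for c in calls:
        by_chrom.setdefault(c.anchor_a.chrom, []).extend(
            [c.anchor_a, c.anchor_b]
        )
    anchors: list[UnifiedAnchor] = []
    for chrom in sorted(by_chrom):
        # dedupe identical member intervals to keep clusters small
        unique = sorted(set(by_chrom[chrom]), key=GenomicInterval.sort_key)
        for cluster in _single_linkage_clusters(unique, max_gap):
            span = GenomicInterval(
                chrom, cluster[0].start, max(iv.end for iv in cluster)
            )
            anchors.append(
                UnifiedAnchor("", span, tuple(cluster))
            )
    anchors.sort(key=lambda a: a.interval.sort_key())
    anchors = [
        UnifiedAnchor(f"A{i:06d}", a.interval, a.members, a.is_promoter)
        for i, a in enumerate(anchors)
    ]
    member_to_anchor: dict[GenomicInterval, UnifiedAnchor] = {}
    for a in anchors:
        for m in a.members:
            member_to_anchor[m] = a

    grouped: dict[tuple[str, str], dict[str, int]] = {}
    pair_anchors: dict[tuple[str, str], tuple[UnifiedAnchor, UnifiedAnchor]] = {}
    for c in calls:
        ua, ub = member_to_anchor[c.anchor_a], member_to_anchor[c.anchor_b]
        if ub.interval.sort_key() < ua.interval.sort_key():
            ua, ub = ub, ua
        key = (ua.anchor_id, ub.anchor_id)
        counts = grouped.setdefault(key, {s: 0 for s in sample_ids})
        if c.sample_id not in counts:
            raise ValueError(f"call from unlisted sample {c.sample_id!r}")
        counts[c.sample_id] += c.count
        pair_anchors[key] = (ua, ub)
    loops: list[UnifiedLoop] = []
    for i, key in enumerate(sorted(grouped)):
        ua, ub = pair_anchors[key]
        loops.append(
            UnifiedLoop(
                f"L{i:06d}",
                ua,
                ub,
                grouped[key],
                abs(ua.interval.midpoint - ub.interval.midpoint),
            )
        )
    return anchors, loops


# ---------------------------------------------------------------------------
# differential calling and classification
# ---------------------------------------------------------------------------


def call_differential_loops(
    loops: Sequence[UnifiedLoop], rule: LoopDiffRule
) -> list[UnifiedLoop]:
    """Label each unified loop lost/gained/shared/other in place.

    'shared' mirrors the gained recurrence: present in the control and in
    >= case_min cases; loops matching no pattern are 'other'.
    """
    for lp in loops:
        missing = {rule.control_sample, *rule.case_samples} - set(lp.counts)
        if missing:
            raise ValueError(f"loop {lp.loop_id} lacks counts for {sorted(missing)}")
        ctrl = lp.counts[rule.control_sample]
        case_present = sum(
            lp.counts[s] >= rule.min_count for s in rule.case_samples
        )
        case_any = any(lp.counts[s] > 0 for s in rule.case_samples)
        if ctrl >= rule.min_count and not case_any:
            lp.diff_label = "lost"
        elif ctrl == 0 and case_present >= rule.case_min:
            lp.diff_label = "gained"
        elif ctrl >= rule.min_count and case_present >= rule.case_min:
            lp.diff_label = "shared"
        else:
            lp.diff_label = "other"
    return list(loops)


def _window_index(windows: Sequence[GenomicInterval]):
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for w in windows:
        tmp.setdefault(w.chrom, []).append((w.start, w.end))
    for chrom, pairs in tmp.items():
        pairs.sort()
        starts = [p[0] for p in pairs]
        # running max of ends lets a single bisect answer overlap queries
        max_ends: list[int] = []
        m = 0
        for _, e in pairs:
            m = max(m, e)
            max_ends.append(m)
        by_chrom[chrom] = (starts, max_ends)
    return by_chrom


def _overlaps_any(iv: GenomicInterval, index) -> bool:
    if iv.chrom not in index:
        return False
    starts, max_ends = index[iv.chrom]
    i = bisect_right(starts, iv.end - 1)
    return i > 0 and max_ends[i - 1] > iv.start


def classify_loops(
    loops: Sequence[UnifiedLoop],
    promoter_windows: Sequence[GenomicInterval],
) -> tuple[list[UnifiedLoop], pd.DataFrame]:
    """Assign P-P / P-E / E-E classes and tabulate class by diff label.

    An anchor is a promoter anchor iff its merged span overlaps at least
    one promoter window; the contingency table covers lost and gained
    loops with per-label fractions.
    """
    index = _window_index(promoter_windows)
    for lp in loops:
        flags = []
        for a_name in ("anchor_a", "anchor_b"):
            a: UnifiedAnchor = getattr(lp, a_name)
            isp = _overlaps_any(a.interval, index)
            setattr(lp, a_name, UnifiedAnchor(a.anchor_id, a.interval, a.members, isp))
            flags.append(isp)
        n_p = sum(flags)
        lp.cls = "P-P" if n_p == 2 else ("P-E" if n_p == 1 else "E-E")
    rows = []
    for label in ("lost", "gained"):
        sub = [lp for lp in loops if lp.diff_label == label]
        total = len(sub)
        for cls in LOOP_CLASSES:
            n = sum(lp.cls == cls for lp in sub)
            rows.append(
                {
                    "diff_label": label,
                    "class": cls,
                    "count": n,
                    "fraction": n / total if total else np.nan,
                }
            )
    return list(loops), pd.DataFrame(rows)


def multi_anchor_flags(
    loops: Sequence[UnifiedLoop],
) -> tuple[dict[str, bool], list[set[str]], dict[str, float]]:
    """Flag loops sharing an anchor with another loop and find hubs.

    Anchors are nodes, loops are edges; a loop is multi-anchor iff either
    endpoint is used by >=2 loops, and hubs are connected components with
    >=2 edges.  The summary reports the multi-anchor fraction and the P-P
    fraction among gained multi-anchor loops.
    """
    g = nx.MultiGraph()
    for lp in loops:
        g.add_edge(lp.anchor_a.anchor_id, lp.anchor_b.anchor_id, key=lp.loop_id)
    flags: dict[str, bool] = {}
    for lp in loops:
        flags[lp.loop_id] = (
            g.degree(lp.anchor_a.anchor_id) >= 2
            or g.degree(lp.anchor_b.anchor_id) >= 2
        )
        lp.multi_anchor = flags[lp.loop_id]
    hubs = [
        set(comp)
        for comp in nx.connected_components(g)
        if g.subgraph(comp).number_of_edges() >= 2
    ]
    hubs.sort(key=lambda s: sorted(s)[0])
    n = len(loops)
    gained_ma = [lp for lp in loops if lp.diff_label == "gained" and lp.multi_anchor]
    summary = {
        "fraction_multi_anchor": (sum(flags.values()) / n) if n else float("nan"),
        "gained_multi_anchor_pp_fraction": (
            sum(lp.cls == "P-P" for lp in gained_ma) / len(gained_ma)
            if gained_ma
            else float("nan")
        ),
    }
    return flags, hubs, summary


# ---------------------------------------------------------------------------
# statistics on labelled loops
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LengthComparison:
    median_lost: float
    median_gained: float
    iqr_lost: tuple[float, float]
    iqr_gained: tuple[float, float]
    test: stats.TestResult


def compare_loop_lengths(
    lost_loops: Sequence[UnifiedLoop], gained_loops: Sequence[UnifiedLoop]
) -> LengthComparison:
    """Medians/IQRs of loop spans and a two-sided Welch t between the lost
    and gained span distributions.  When several marks or conditions are
    compared, apply bh_adjust to the collected p-values (the family is the
    caller's)."""
    if not lost_loops or not gained_loops:
        raise ValueError("both loop sets must be non-empty")
    a = np.array([lp.span_bp for lp in lost_loops], dtype=float)
    b = np.array([lp.span_bp for lp in gained_loops], dtype=float)
    return LengthComparison(
        float(np.median(a)),
        float(np.median(b)),
        (float(np.percentile(a, 25)), float(np.percentile(a, 75))),
        (float(np.percentile(b, 25)), float(np.percentile(b, 75))),
        stats.welch_t(a, b),
    )


def genes_at_differential_anchors(
    loops: Sequence[UnifiedLoop],
    genes: Sequence[GeneModel],
    core_degs: Iterable[str],
    window: int = 2000,
) -> tuple[set[str], set[str]]:
    """Genes whose TSS window overlaps any anchor of a lost/gained loop,
    and their intersection with the core DEG set."""
    windows = _promoter_windows(genes, window)
    hits: set[str] = set()
    diff_anchors = [
        a.interval
        for lp in loops
        if lp.diff_label in ("lost", "gained")
        for a in (lp.anchor_a, lp.anchor_b)
    ]
    index = _window_index_named(windows)
    for iv in diff_anchors:
        hits.update(_overlapping_names(iv, index))
    return hits, hits & set(core_degs)


def _window_index_named(windows: Sequence[GenomicInterval]):
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append((w.start, w.end, w.name or ""))
    for v in by_chrom.values():
        v.sort()
    return by_chrom


def _overlapping_names(iv: GenomicInterval, index) -> list[str]:
    out = []
    for start, end, name in index.get(iv.chrom, []):
        if start >= iv.end:
            break
        if end > iv.start:
            out.append(name)
    return out


def loops_table(loops: Sequence[UnifiedLoop], sample_ids: Sequence[str]) -> pd.DataFrame:
    """Flat per-loop table (sidecar for the unified BEDPE)."""
    rows = []
    for lp in loops:
        row = {
            "loop_id": lp.loop_id,
            "chrom": lp.anchor_a.interval.chrom,
            "start_a": lp.anchor_a.interval.start,
            "end_a": lp.anchor_a.interval.end,
            "start_b": lp.anchor_b.interval.start,
            "end_b": lp.anchor_b.interval.end,
            "span_bp": lp.span_bp,
            "class": lp.cls,
            "diff_label": lp.diff_label,
            "multi_anchor": lp.multi_anchor,
        }
        for s in sample_ids:
            row[f"count_{s}"] = lp.counts.get(s, 0)
        rows.append(row)
    return pd.DataFrame(rows)
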