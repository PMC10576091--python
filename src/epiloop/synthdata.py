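"""Synthetic multi-omics data with planted ground truth.

The generator emulates the statistical structure of a one-control,
many-case chromatin study on a desk-sized toy genome: per-sample peak sets
with planted control-only (lost) and case-recurrent (gained) regions,
per-sample loop sets with long-range lost loops and short-range gained
promoter-hub loops, negative-binomial count matrices with a planted core
DEG set, and genome sequence carrying two planted TF motifs at a fixed
spacing in target promoters versus a wider spread in background promoter
peaks.

With the noise dials at zero (the default), every downstream stage can
recover its planted truth exactly; that separability is the point of the
generator.  All randomness flows from a single integer seed through one
numpy Generator, and every output file is written in sorted order, so a
given (config, seed) is byte-reproducible.
"""

from __future__ import annotations

import json
from bisect import bisect_left
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as eio
from .io import GeneModel, GenomicInterval, LoopCall

MOTIF_A_CONSENSUS = "ATCGGTACTTGC"
MOTIF_B_CONSENSUS = "CAGTTGCAAGTC"
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the generator; defaults define the default study
    conditions (1 control vs 15 case lines for regions, 14 for loops)."""

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    gc_fraction: float = 0.41
    n_genes: int = 400
    gene_min_len: int = 2000
    gene_max_len: int = 8000
    margin: int = 50_000
    slot_step: int = 2500
    # regions
    n_cases_regions: int = 15
    n_shared_peaks: int = 1500
    n_lost_regions: int = 40
    n_gained_regions: int = 60
    region_gained_k_min: int = 10
    peak_min_width: int = 300
    peak_max_width: int = 1200
    peak_jitter_bp: int = 0
    dropout_p: float = 0.0
    # loops
    n_cases_loops: int = 14
    n_shared_loops: int = 400
    n_lost_loops: int = 50
    n_gained_loops: int = 80
    loop_case_k_min: int = 8
    lost_span_median: int = 254_000
    gained_span_median: int = 114_000
    span_sigma: float = 0.35
    gained_pp_fraction: float = 0.85
    lost_pp_fraction: float = 0.134
    hub_edges: int = 4
    anchor_halfwidth: int = 500
    loop_fdr: float = 0.001
    # expression
    n_core_degs: int = 100
    n_sporadic_degs: int = 50
    deg_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    reps_per_line: int = 3
    base_mean_meanlog: float = 6.0
    base_mean_sdlog: float = 1.0
    # regulatory network
    n_tf_targets: int = 25
    n_deg_at_anchor: int = 20
    n_background_promoter_peaks: int = 60
    target_spacing: int = 56
    background_spacing_median: int = 124
    promoter_peak_width: int = 400

    def __post_init__(self) -> None:
        if min(
            self.n_lost_regions,
            self.n_gained_regions,
            self.n_lost_loops,
            self.n_gained_loops,
            self.n_core_degs,
        ) < 0:
            raise ValueError("planted counts must be non-negative")
        for frac in (self.gained_pp_fraction, self.lost_pp_fraction, self.dropout_p):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.lost_span_median <= 0 or self.gained_span_median <= 0:
            raise ValueError("span medians must be positive")
        if not (0 <= self.region_gained_k_min <= self.n_cases_regions):
            raise ValueError("region k outside [0, n]")
        if not (0 <= self.loop_case_k_min <= self.n_cases_loops):
            raise ValueError("loop k outside [0, n]")


TINY = dict(
    chrom_sizes={"chr1": 1_200_000, "chr2": 1_200_000},
    n_genes=100,
    margin=30_000,
    n_shared_peaks=200,
    n_lost_regions=8,
    n_gained_regions=12,
    n_shared_loops=60,
    n_lost_loops=10,
    n_gained_loops=20,
    lost_span_median=120_000,
    gained_span_median=60_000,
    hub_edges=3,
    n_core_degs=20,
    n_sporadic_degs=10,
    n_tf_targets=8,
    n_deg_at_anchor=5,
    n_background_promoter_peaks=20,
)

STRESS = dict(
    chrom_sizes={"chr1": 8_000_000, "chr2": 8_000_000, "chr3": 8_000_000},
    n_genes=900,
    n_shared_peaks=4000,
    n_lost_regions=80,
    n_gained_regions=120,
    n_shared_loops=1200,
    n_lost_loops=100,
    n_gained_loops=160,
    n_core_degs=150,
    n_sporadic_degs=80,
)


def preset(name: str, seed: int) -> SynthConfig:
    if name == "default":
        return SynthConfig(seed=seed)
    if name == "tiny":
        return SynthConfig(seed=seed, **TINY)
    if name == "stress":
        return SynthConfig(seed=seed, **STRESS)
    raise ValueError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------

_TRUTH_KEYS = {
    "config",
    "samples",
    "regions",
    "loops",
    "expression",
    "regnet",
}


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream recovery checks."""

    config: dict
    samples: dict
    regions: dict  # lost/gained: [[chrom, start, end], ...]
    loops: dict  # lost/gained: [{chrom, a, b, span, cls, hub}, ...]
    expression: dict  # core_degs, sporadic_degs, log2fc directions
    regnet: dict  # tf genes, targets, planted hits, spacings

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        missing = _TRUTH_KEYS - set(d)
        extra = set(d) - _TRUTH_KEYS
        if missing or extra:
            raise ValueError(
                f"invalid truth file: missing {sorted(missing)}, extra {sorted(extra)}"
            )
        for key in ("lost", "gained"):
            if key not in d["regions"] or key not in d["loops"]:
                raise ValueError(f"truth regions/loops lack {key!r}")
        if "core_degs" not in d["expression"]:
            raise ValueError("truth expression lacks core_degs")
        return cls(**{k: d[k] for k in sorted(_TRUTH_KEYS)})


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def generate_genome(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[list[GeneModel], dict[str, str]]:
    """Place genes on evenly spaced jittered slots (both strands) and draw
    random sequence at the configured GC content."""
    chroms = sorted(config.chrom_sizes)
    genes: list[GeneModel] = []
    per_chrom = config.n_genes // len(chroms)
    leftover = config.n_genes - per_chrom * len(chroms)
    idx = 0
    for ci, chrom in enumerate(chroms):
        size = config.chrom_sizes[chrom]
        n_here = per_chrom + (1 if ci < leftover else 0)
        if n_here == 0:
            continue
        usable = size - 2 * config.margin
        slot = usable // max(n_here, 1)
        if slot < config.gene_max_len + 4000:
            raise ValueError(f"{n_here} genes do not fit chromosome {chrom}")
        for i in range(n_here):
            tss = config.margin + i * slot + int(rng.integers(0, max(slot // 4, 1)))
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(config.gene_min_len, config.gene_max_len + 1))
            if strand == "+":
                start, end = tss, min(tss + length, size)
            else:
                start, end = max(tss - length + 1, 0), tss + 1
            idx += 1
            genes.append(
                GeneModel(f"g{idx:04d}", GenomicInterval(chrom, start, end, strand))
            )
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences = {}
    for chrom in chroms:
        draws = rng.choice(4, size=config.chrom_sizes[chrom], p=probs)
        sequences[chrom] = bytes(letters[draws]).decode("ascii")
    return genes, sequences


def _intergenic_slots(
    config: SynthConfig, genes: Sequence[GeneModel], rng: np.random.Generator
) -> dict[str, list[int]]:
    """Candidate placement positions >=3.5 kb from every TSS, spaced so
    that features placed on distinct slots can never touch."""
    tss_by_chrom: dict[str, list[int]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
    for v in tss_by_chrom.values():
        v.sort()
    slots: dict[str, list[int]] = {}
    for chrom in sorted(config.chrom_sizes):
        size = config.chrom_sizes[chrom]
        tss = tss_by_chrom.get(chrom, [])
        keep = []
        for p in range(config.margin, size - config.margin, config.slot_step):
            i = bisect_left(tss, p)
            near = min(
                abs(p - tss[j]) for j in (i - 1, i) if 0 <= j < len(tss)
            ) if tss else config.margin
            if near >= 3500:
                keep.append(p)
        slots[chrom] = keep
    return slots


class _SlotPool:
    """Deterministic pool of placement positions, supporting both random
    draws and nearest-to-a-coordinate draws."""

    def __init__(self, slots: dict[str, list[int]], rng: np.random.Generator):
        self.rng = rng
        self.slots = {c: sorted(v) for c, v in slots.items()}

    def take_random(self, chrom: str | None = None) -> tuple[str, int]:
        chroms = [c for c, v in sorted(self.slots.items()) if v]
        if chrom is not None:
            chroms = [chrom] if self.slots.get(chrom) else []
        if not chroms:
            raise ValueError("slot pool exhausted")
        c = chroms[int(self.rng.integers(len(chroms)))]
        i = int(self.rng.integers(len(self.slots[c])))
        return c, self.slots[c].pop(i)

    def take_nearest(self, chrom: str, coord: int) -> int:
        arr = self.slots.get(chrom)
        if not arr:
            raise ValueError(f"slot pool exhausted on {chrom}")
        i = bisect_left(arr, coord)
        best = min(
            (j for j in (i - 1, i) if 0 <= j < len(arr)),
            key=lambda j: abs(arr[j] - coord),
        )
        return arr.pop(best)


class _GenePool:
    """Per-chromosome pool of genes, drawable randomly or by proximity."""

    def __init__(self, genes: Sequence[GeneModel], rng: np.random.Generator):
        self.rng = rng
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in sorted(genes, key=lambda g: (g.chrom, g.tss)):
            self.by_chrom.setdefault(g.chrom, []).append(g)

    def remaining(self) -> list[GeneModel]:
        return [g for v in self.by_chrom.values() for g in v]

    def take_random(self, chrom: str | None = None) -> GeneModel:
        chroms = [c for c, v in sorted(self.by_chrom.items()) if v]
        if chrom is not None:
            chroms = [chrom] if self.by_chrom.get(chrom) else []
        if not chroms:
            raise ValueError("gene pool exhausted")
        c = chroms[int(self.rng.integers(len(chroms)))]
        i = int(self.rng.integers(len(self.by_chrom[c])))
        return self.by_chrom[c].pop(i)

    def take_nearest(self, chrom: str, coord: int) -> GeneModel:
        arr = self.by_chrom.get(chrom)
        if not arr:
            raise ValueError(f"gene pool exhausted on {chrom}")
        i = bisect_left([g.tss for g in arr], coord)
        best = min(
            (j for j in (i - 1, i) if 0 <= j < len(arr)),
            key=lambda j: abs(arr[j].tss - coord),
        )
        return arr.pop(best)


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------


def _jittered(
    iv: GenomicInterval, jitter: int, rng: np.random.Generator
) -> GenomicInterval:
    if jitter <= 0:
        return iv
    ds = int(rng.integers(-jitter, jitter + 1))
    de = int(rng.integers(-jitter, jitter + 1))
    start = max(0, iv.start + ds)
    end = max(start + 50, iv.end + de)
    return GenomicInterval(iv.chrom, start, end)


def generate_peak_sets(
    config: SynthConfig,
    pool: _SlotPool,
    target_genes: Sequence[GeneModel],
    background_genes: Sequence[GeneModel],
    rng: np.random.Generator,
) -> tuple[dict[str, list[GenomicInterval]], dict]:
    """Per-sample peak sets with planted lost and gained regions.

    Shared peaks (intergenic plus 'common promoter peaks' at the background
    genes) appear in every sample; lost regions only in the control; each
    gained region in k ~ Uniform[k_min, n] randomly chosen cases and never
    in the control.  The first ``n_tf_targets`` gained regions sit at the
    target genes' promoters so the regulatory-network stage has evidence
    regions.
    """
    half = config.promoter_peak_width // 2

    def promoter_peak(g: GeneModel) -> GenomicInterval:
        return GenomicInterval(g.chrom, g.tss - half, g.tss + half)

    def random_peak() -> GenomicInterval:
        chrom, p = pool.take_random()
        w = int(rng.integers(config.peak_min_width, config.peak_max_width + 1))
        return GenomicInterval(chrom, p - w // 2, p - w // 2 + w)

    shared = [promoter_peak(g) for g in background_genes]
    shared += [
        random_peak() for _ in range(config.n_shared_peaks - len(shared))
    ]
    gained = [promoter_peak(g) for g in target_genes]
    gained += [
        random_peak() for _ in range(config.n_gained_regions - len(gained))
    ]
    lost = [random_peak() for _ in range(config.n_lost_regions)]

    samples = ["control"] + [f"case{i+1:02d}" for i in range(config.n_cases_regions)]
    gained_carriers: list[list[str]] = []
    for _ in gained:
        k = int(rng.integers(config.region_gained_k_min, config.n_cases_regions + 1))
        chosen = rng.choice(config.n_cases_regions, size=k, replace=False)
        gained_carriers.append(sorted(samples[1 + int(i)] for i in chosen))

    peak_sets: dict[str, list[GenomicInterval]] = {s: [] for s in samples}
    for s in samples:
        for iv in shared:
            peak_sets[s].append(iv)
        if s == "control":
            peak_sets[s].extend(lost)
        else:
            for iv, carriers in zip(gained, gained_carriers):
                if s in carriers:
                    peak_sets[s].append(iv)
        # noise: jitter then dropout, applied per sample
        out = []
        for iv in peak_sets[s]:
            if config.dropout_p > 0 and rng.random() < config.dropout_p:
                continue
            out.append(_jittered(iv, config.peak_jitter_bp, rng))
        peak_sets[s] = sorted(out, key=GenomicInterval.sort_key)
    truth = {
        "lost": [[iv.chrom, iv.start, iv.end] for iv in lost],
        "gained": [[iv.chrom, iv.start, iv.end] for iv in gained],
        "gained_carriers": gained_carriers,
        "target_promoter_regions": [
            [iv.chrom, iv.start, iv.end]
            for iv in (promoter_peak(g) for g in target_genes)
        ],
        "background_promoter_regions": [
            [iv.chrom, iv.start, iv.end]
            for iv in (promoter_peak(g) for g in background_genes)
        ],
    }
    return peak_sets, truth


# ---------------------------------------------------------------------------
# loops
# ---------------------------------------------------------------------------


def _anchor_at(chrom: str, center: int, halfwidth: int) -> GenomicInterval:
    return GenomicInterval(chrom, center - halfwidth, center + halfwidth)


def generate_loop_sets(
    config: SynthConfig,
    anchor_genes: _GenePool,
    pool: _SlotPool,
    rng: np.random.Generator,
) -> tuple[dict[str, list[LoopCall]], dict, list[str]]:
    """Per-sample loop call sets with planted lost (long-range) and gained
    (short-range, promoter-hub) loops plus shared loops.

    Gained P-P loops are organized in star-shaped hubs (one promoter
    anchor reused by ``hub_edges`` loops).  Spans are drawn log-normally
    around the configured medians and realized on the nearest available
    promoter/slot positions; the truth records the realized geometry.
    Returns the per-sample calls, the truth record, and the list of gene
    ids used as differential promoter anchors.
    """
    hw = config.anchor_halfwidth
    samples = ["control"] + [f"case{i+1:02d}" for i in range(config.n_cases_loops)]
    chroms = sorted(config.chrom_sizes)

    def draw_span(median: int) -> int:
        return int(median * np.exp(rng.normal(0.0, config.span_sigma)))

    def pick_side(a: int, span: int, lo: int, hi: int) -> int:
        """Prefer a direction in which the span fits inside the margins,
        so realized spans are not clipped short near chromosome ends."""
        fits = [s for s in (1, -1) if lo <= a + s * span <= hi]
        if not fits:
            fits = [1, -1]
        return fits[int(rng.integers(len(fits)))]

    used_promoter_genes: list[str] = []
    planted: list[dict] = []  # label, chrom, centers, cls, hub

    # gained P-P hubs
    n_gained_pp = round(config.gained_pp_fraction * config.n_gained_loops)
    hub_id = 0
    made = 0
    while made < n_gained_pp:
        edges = min(config.hub_edges, n_gained_pp - made)
        chrom = chroms[hub_id % len(chroms)]
        center = anchor_genes.take_random(chrom)
        used_promoter_genes.append(center.gene_id)
        for _ in range(edges):
            span = draw_span(config.gained_span_median)
            lo, hi = config.margin, config.chrom_sizes[chrom] - config.margin
            side = pick_side(center.tss, span, lo, hi)
            want = min(max(center.tss + side * span, lo), hi)
            sat = anchor_genes.take_nearest(chrom, want)
            used_promoter_genes.append(sat.gene_id)
            planted.append(
                dict(
                    label="gained",
                    chrom=chrom,
                    a=center.tss,
                    b=sat.tss,
                    cls="P-P",
                    hub=f"H{hub_id:03d}",
                )
            )
            made += 1
        hub_id += 1

    def planted_loop(label: str, cls: str, median: int) -> dict:
        span = draw_span(median)
        chrom = chroms[int(rng.integers(len(chroms)))]
        lo, hi = config.margin, config.chrom_sizes[chrom] - config.margin
        if cls[0] == "P":
            a_gene = anchor_genes.take_random(chrom)
            used_promoter_genes.append(a_gene.gene_id)
            a = a_gene.tss
        else:
            _, a = pool.take_random(chrom)
        side = pick_side(a, span, lo, hi)
        want = min(max(a + side * span, lo), hi)
        if cls[2] == "P":
            b_gene = anchor_genes.take_nearest(chrom, want)
            used_promoter_genes.append(b_gene.gene_id)
            b = b_gene.tss
        else:
            b = pool.take_nearest(chrom, want)
        return dict(label=label, chrom=chrom, a=a, b=b, cls=cls, hub=None)

    # remaining gained loops: split P-E / E-E
    n_rest = config.n_gained_loops - n_gained_pp
    for i in range(n_rest):
        cls = "P-E" if i % 3 != 2 else "E-E"
        planted.append(planted_loop("gained", cls, config.gained_span_median))
    # lost loops
    n_lost_pp = round(config.lost_pp_fraction * config.n_lost_loops)
    for i in range(config.n_lost_loops):
        if i < n_lost_pp:
            cls = "P-P"
        else:
            cls = "P-E" if i % 2 == 0 else "E-E"
        planted.append(planted_loop("lost", cls, config.lost_span_median))

    # carriers and counts
    for rec in planted:
        rec["span"] = abs(rec["a"] - rec["b"])
        if rec["span"] < 6000:
            raise ValueError(
                "anchor placement budget exhausted: realized span too short"
            )
        if rec["label"] == "gained":
            k = int(rng.integers(config.loop_case_k_min, config.n_cases_loops + 1))
            chosen = rng.choice(config.n_cases_loops, size=k, replace=False)
            rec["carriers"] = sorted(samples[1 + int(i)] for i in chosen)
        else:
            rec["carriers"] = ["control"]
        rec["counts"] = {
            s: int(rng.integers(2, 10)) for s in rec["carriers"]
        }

    # shared loops over a recycled pool of sites
    n_sites = max(20, config.n_shared_loops // 6)
    shared_sites: dict[str, list[int]] = {c: [] for c in chroms}
    for i in range(n_sites):
        if i % 3 == 0:
            g = anchor_genes.take_random()
            shared_sites[g.chrom].append(g.tss)
        else:
            c, p = pool.take_random()
            shared_sites[c].append(p)
    shared: list[dict] = []
    guard = 0
    while len(shared) < config.n_shared_loops and guard < 50 * config.n_shared_loops:
        guard += 1
        c = chroms[int(rng.integers(len(chroms)))]
        sites = shared_sites[c]
        if len(sites) < 2:
            continue
        i, j = rng.choice(len(sites), size=2, replace=False)
        a, b = sites[int(i)], sites[int(j)]
        if abs(a - b) < 6000:
            continue
        count = {s: int(rng.integers(2, 10)) for s in samples}
        shared.append(dict(chrom=c, a=a, b=b, counts=count))

    calls: dict[str, list[LoopCall]] = {s: [] for s in samples}
    for rec in planted + shared:
        for s, n in rec["counts"].items():
            calls[s].append(
                LoopCall(
                    s,
                    _anchor_at(rec["chrom"], rec["a"], hw),
                    _anchor_at(rec["chrom"], rec["b"], hw),
                    n,
                    config.loop_fdr,
                )
            )
    for s in samples:
        calls[s].sort(key=lambda c: c.anchor_a.sort_key() + c.anchor_b.sort_key())

    truth = {
        "lost": [
            {k: rec[k] for k in ("chrom", "a", "b", "span", "cls", "hub")}
            for rec in planted
            if rec["label"] == "lost"
        ],
        "gained": [
            {k: rec[k] for k in ("chrom", "a", "b", "span", "cls", "hub")}
            for rec in planted
            if rec["label"] == "gained"
        ],
        "anchor_halfwidth": hw,
        "gained_pp_fraction": n_gained_pp / config.n_gained_loops
        if config.n_gained_loops
        else float("nan"),
        "n_shared": len(shared),
    }
    return calls, truth, used_promoter_genes


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def nb_draw(
    mu, dispersion: float, size, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial draws via the gamma-Poisson mixture:
    lambda ~ Gamma(1/dispersion, mu*dispersion), X ~ Poisson(lambda)."""
    lam = rng.gamma(1.0 / dispersion, np.multiply(mu, dispersion), size=size)
    return rng.poisson(lam)


def generate_counts(
    config: SynthConfig,
    gene_ids: Sequence[str],
    core_degs: Sequence[str],
    sporadic_degs: Sequence[str],
    rng: np.random.Generator,
) -> tuple[eio.CountMatrix, dict]:
    """Negative-binomial count matrix for 1 control + n case lines with
    ``reps_per_line`` replicates each.

    Core DEGs are shifted by +-deg_log2fc in every case line; sporadic
    DEGs in a random strict subset of lines (they must never survive the
    all-comparisons intersection).
    """
    genes = list(gene_ids)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids")
    n_lines = config.n_cases_regions
    lines = ["control"] + [f"case{i+1:02d}" for i in range(n_lines)]
    base = np.exp(
        rng.normal(config.base_mean_meanlog, config.base_mean_sdlog, len(genes))
    )
    gi = {g: i for i, g in enumerate(genes)}
    direction = {}
    for g in core_degs:
        direction[g] = 1 if rng.random() < 0.5 else -1
    sporadic_lines = {}
    for g in sporadic_degs:
        direction[g] = 1 if rng.random() < 0.5 else -1
        k = int(rng.integers(1, max(2, n_lines // 2)))
        chosen = rng.choice(n_lines, size=k, replace=False)
        sporadic_lines[g] = sorted(lines[1 + int(i)] for i in chosen)
    cols = {}
    fc = 2.0 ** config.deg_log2fc
    for line in lines:
        mu = base.copy()
        if line != "control":
            for g in core_degs:
                mu[gi[g]] = base[gi[g]] * (fc if direction[g] > 0 else 1.0 / fc)
            for g, carriers in sporadic_lines.items():
                if line in carriers:
                    mu[gi[g]] = base[gi[g]] * (fc if direction[g] > 0 else 1.0 / fc)
        for r in range(config.reps_per_line):
            cols[f"{line}_rep{r+1}"] = nb_draw(
                mu, config.nb_dispersion, len(genes), rng
            )
    df = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    groups = {c: c.rsplit("_rep", 1)[0] for c in df.columns}
    cm = eio.CountMatrix(df, groups)
    truth = {
        "core_degs": sorted(core_degs),
        "sporadic_degs": sorted(sporadic_degs),
        "directions": {g: int(d) for g, d in sorted(direction.items())},
        "sporadic_lines": sporadic_lines,
    }
    return cm, truth


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------


def _spacing_multiset(median: int, n: int, min_spacing: int) -> list[int]:
    """A multiset of spacings symmetric around ``median`` (so the sample
    median equals it exactly), 4 bp apart, never below ``min_spacing`` so
    the two motifs cannot overwrite each other."""
    max_steps = max(1, (median - min_spacing) // 4)
    out = []
    for i in range(n):
        d = 4 * ((i // 2) % max_steps + 1)
        out.append(median + d if i % 2 == 0 else median - d)
    if n % 2 == 1:
        out[-1] = median
    return out


def plant_motifs(
    config: SynthConfig,
    sequences: dict[str, str],
    target_regions: Sequence[GenomicInterval],
    background_regions: Sequence[GenomicInterval],
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[tuple[str, np.ndarray]], dict]:
    """Write the two TF consensus sequences into target and background
    promoter peaks and scrub accidental consensus matches elsewhere.

    In target regions the pair sits at exactly ``target_spacing`` bp
    (midpoint to midpoint); in background regions the spacings form a
    multiset symmetric around ``background_spacing_median``.  The emitted
    PFMs put almost all weight on the consensus, so a scan thresholded at
    the maximum score finds exactly the planted sites.
    """
    a_cons, b_cons = MOTIF_A_CONSENSUS, MOTIF_B_CONSENSUS
    width = len(a_cons)
    seqs = {c: list(s) for c, s in sequences.items()}
    planted: dict[str, list[list]] = {"TFA": [], "TFB": []}
    spacings = _spacing_multiset(
        config.background_spacing_median, len(background_regions), width + 4
    )

    def write_at(chrom: str, pos: int, s: str) -> None:
        seqs[chrom][pos : pos + len(s)] = list(s)

    for region in target_regions:
        a_start = region.start + 50
        b_start = a_start + config.target_spacing
        if b_start + width > region.end:
            raise ValueError("motif pair does not fit target region")
        write_at(region.chrom, a_start, a_cons)
        write_at(region.chrom, b_start, b_cons)
        planted["TFA"].append([region.chrom, a_start])
        planted["TFB"].append([region.chrom, b_start])
    for region, spacing in zip(background_regions, spacings):
        a_start = region.start + 40
        b_start = a_start + spacing
        if b_start + width > region.end:
            raise ValueError("motif pair does not fit background region")
        write_at(region.chrom, a_start, a_cons)
        write_at(region.chrom, b_start, b_cons)
        planted["TFA"].append([region.chrom, a_start])
        planted["TFB"].append([region.chrom, b_start])

    planted_ivs = {
        (chrom, pos, pos + width)
        for hits in planted.values()
        for chrom, pos in hits
    }

    def scrub() -> int:
        """Mutate accidental consensus occurrences; returns how many."""
        n_fixed = 0
        for chrom in sorted(seqs):
            text = "".join(seqs[chrom])
            for pattern in (a_cons, b_cons, _revcomp(a_cons), _revcomp(b_cons)):
                start = 0
                while True:
                    p = text.find(pattern, start)
                    if p < 0:
                        break
                    start = p + 1
                    if (chrom, p, p + width) in planted_ivs and pattern in (
                        a_cons,
                        b_cons,
                    ):
                        continue
                    # mutate one base outside every planted interval
                    for off in range(width):
                        q = p + off
                        inside = any(
                            c == chrom and s <= q < e for c, s, e in planted_ivs
                        )
                        if not inside:
                            cur = seqs[chrom][q]
                            seqs[chrom][q] = "A" if cur != "A" else "C"
                            n_fixed += 1
                            break
                    else:
                        raise ValueError("accidental match inside planted sites")
                    text = "".join(seqs[chrom])
        return n_fixed

    for _ in range(10):
        if scrub() == 0:
            break
    else:
        raise ValueError("could not scrub accidental motif matches")

    def pfm(consensus: str) -> np.ndarray:
        counts = np.ones((4, len(consensus)))
        for j, base in enumerate(consensus):
            counts["ACGT".index(base), j] = 997.0
        return counts

    pfms = [("TFA", pfm(a_cons)), ("TFB", pfm(b_cons))]
    truth = {
        "planted_hits": {
            k: [list(x) for x in sorted(map(tuple, v))] for k, v in planted.items()
        },
        "target_spacing": config.target_spacing,
        "background_spacings": sorted(spacings),
        "motif_width": width,
        "consensus": {"TFA": a_cons, "TFB": b_cons},
    }
    out_seqs = {c: "".join(v) for c, v in seqs.items()}
    return out_seqs, pfms, truth


# ---------------------------------------------------------------------------
# top-level generation
# ---------------------------------------------------------------------------


def generate_all(config: SynthConfig, outdir: str | Path) -> GroundTruth:
    """Generate the full dataset into ``outdir`` and return (and write)
    the ground truth.

    Emits genome.fa, genes.bed, per-sample peak BEDs and loop BEDPEs with
    manifests, counts.tsv, motifs.pfm, motif_gene_map.tsv, gene_sets.gmt,
    a ready-to-run pipeline config.yaml, and truth.json.
    """
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    (outdir / "loops").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    genes, sequences = generate_genome(config, rng)
    slot_pool = _SlotPool(_intergenic_slots(config, genes, rng), rng)
    gene_pool = _GenePool(genes, rng)

    # 1. loops first: they consume promoter-anchor genes
    loop_calls, loop_truth, diff_anchor_gene_ids = generate_loop_sets(
        config, gene_pool, slot_pool, rng
    )
    diff_anchor_gene_ids = sorted(set(diff_anchor_gene_ids))

    # 2. gene roles
    if config.n_deg_at_anchor > len(diff_anchor_gene_ids):
        raise ValueError("n_deg_at_anchor exceeds available anchor genes")
    deg_at_anchor = sorted(
        str(g)
        for g in rng.choice(
            diff_anchor_gene_ids, size=config.n_deg_at_anchor, replace=False
        )
    )
    target_genes = sorted(
        (gene_pool.take_random() for _ in range(config.n_tf_targets)),
        key=lambda g: g.gene_id,
    )
    tfa_gene = gene_pool.take_random()
    tfb_gene = gene_pool.take_random()
    n_other = config.n_core_degs - config.n_deg_at_anchor - config.n_tf_targets - 2
    if n_other < 0:
        raise ValueError("n_core_degs too small for planted roles")
    other_core = sorted(
        gene_pool.take_random().gene_id for _ in range(n_other)
    )
    core_degs = sorted(
        set(deg_at_anchor)
        | {g.gene_id for g in target_genes}
        | {tfa_gene.gene_id, tfb_gene.gene_id}
        | set(other_core)
    )
    sporadic = sorted(
        gene_pool.take_random().gene_id for _ in range(config.n_sporadic_degs)
    )
    background_genes = sorted(
        (gene_pool.take_random() for _ in range(config.n_background_promoter_peaks)),
        key=lambda g: g.gene_id,
    )

    # 3. peaks
    peak_sets, region_truth = generate_peak_sets(
        config, slot_pool, target_genes, background_genes, rng
    )

    # 4. counts
    cm, expr_truth = generate_counts(
        config, [g.gene_id for g in genes], core_degs, sporadic, rng
    )

    # 5. motifs
    target_regions = [
        GenomicInterval(c, s, e) for c, s, e in region_truth["target_promoter_regions"]
    ]
    background_regions = [
        GenomicInterval(c, s, e)
        for c, s, e in region_truth["background_promoter_regions"]
    ]
    sequences, pfms, motif_truth = plant_motifs(
        config, sequences, target_regions, background_regions, rng
    )
    motif_truth["tf_genes"] = {"TFA": tfa_gene.gene_id, "TFB": tfb_gene.gene_id}
    motif_truth["target_genes"] = [g.gene_id for g in target_genes]
    motif_truth["deg_at_anchor"] = list(deg_at_anchor)

    # 6. write everything
    eio.write_fasta(sequences, outdir / "genome.fa")
    eio.write_gene_models(genes, outdir / "genes.bed")
    rows = []
    for sample in sorted(peak_sets):
        eio.write_bed(peak_sets[sample], outdir / "peaks" / f"{sample}.bed")
        rows.append(
            dict(
                sample=sample,
                role="control" if sample == "control" else "case",
                path=f"peaks/{sample}.bed",
            )
        )
    pd.DataFrame(rows).to_csv(outdir / "peaks_manifest.tsv", sep="\t", index=False)
    rows = []
    for sample in sorted(loop_calls):
        eio.write_bedpe(loop_calls[sample], outdir / "loops" / f"{sample}.bedpe")
        rows.append(
            dict(
                sample=sample,
                role="control" if sample == "control" else "case",
                path=f"loops/{sample}.bedpe",
            )
        )
    pd.DataFrame(rows).to_csv(outdir / "loops_manifest.tsv", sep="\t", index=False)
    eio.write_counts(cm, outdir / "counts.tsv")
    eio.write_pfm(pfms, outdir / "motifs.pfm")
    with open(outdir / "motif_gene_map.tsv", "w") as fh:
        fh.write("motif_id\tgene_id\n")
        for motif_id, gid in sorted(motif_truth["tf_genes"].items()):
            fh.write(f"{motif_id}\t{gid}\n")
    # small gene sets for over-representation analysis
    universe = [g.gene_id for g in genes]
    planted_set = core_degs[: max(5, len(core_degs) // 2)]
    decoy = [g for g in universe if g not in set(core_degs)][: len(planted_set)]
    with open(outdir / "gene_sets.gmt", "w") as fh:
        fh.write("PLANTED_CORE\tsynthetic\t" + "\t".join(planted_set) + "\n")
        fh.write("DECOY_SET\tsynthetic\t" + "\t".join(decoy) + "\n")

    truth = GroundTruth(
        config=asdict(config),
        samples={
            "regions": ["control"]
            + [f"case{i+1:02d}" for i in range(config.n_cases_regions)],
            "loops": ["control"]
            + [f"case{i+1:02d}" for i in range(config.n_cases_loops)],
        },
        regions=region_truth,
        loops=loop_truth,
        expression=expr_truth,
        regnet=motif_truth,
    )
    write_truth(truth, outdir / "truth.json")
    _write_pipeline_config(config, outdir)
    return truth


def _write_pipeline_config(config: SynthConfig, outdir: Path) -> None:
    import yaml

    cfg = {
        "peaks_manifest": "peaks_manifest.tsv",
        "loops_manifest": "loops_manifest.tsv",
        "genes": "genes.bed",
        "genes_format": "bed6",
        "counts": "counts.tsv",
        "fasta": "genome.fa",
        "pfms": "motifs.pfm",
        "motif_gene_map": "motif_gene_map.tsv",
        "gene_sets": "gene_sets.gmt",
        "control_line": "control",
        "alpha_p": 0.01,
        "alpha_q": 0.01,
        "region_gained_k": config.region_gained_k_min,
        "region_n_cases": config.n_cases_regions,
        "loop_gained_k": config.loop_case_k_min,
        "loop_n_cases": config.n_cases_loops,
        "loop_min_count": 2,
        "loop_max_fdr": 0.01,
        "loop_min_length": 5000,
        "promoter_window": 2000,
        "anchor_max_gap": 500,
        "scan_threshold_fraction": 1.0,
        "seed": config.seed,
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
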