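"""End-to-end orchestration: validate a single config, run every stage in
dependency order (expression / regions / loops, then the regulatory
network, then gene-set enrichment), and emit output files plus a
machine-readable run report whose hash is reproducible for a given
parameter set and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import expression, intervals, loops as lp, regnet, stats
from . import io as eio
from .io import GenomicInterval

log = logging.getLogger("epiloop")

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Paths and thresholds of a full run.

    Thresholds default to the study rules: dual DE cutoff p<0.01 and
    FDR<0.01, gained-region recurrence 10 of 15, gained-loop recurrence 8
    of 14 with count >= 2, loop filters (count >= 2, FDR < 0.01, length >=
    5000 bp), the <2 kb TSS promoter window, 500 bp anchor merge gap.
    """

    peaks_manifest: str
    loops_manifest: str
    genes: str
    counts: str
    genes_format: str = "bed6"
    fasta: str | None = None
    pfms: str | None = None
    motif_gene_map: str | None = None
    gene_sets: str | None = None
    control_line: str = "control"
    alpha_p: float = 0.01
    alpha_q: float = 0.01
    min_row_sum: int = 10
    region_gained_k: int = 10
    region_n_cases: int = 15
    loop_gained_k: int = 8
    loop_n_cases: int = 14
    loop_min_count: int = 2
    loop_max_fdr: float = 0.01
    loop_min_length: int = 5000
    promoter_window: int = 2000
    anchor_max_gap: int = 500
    scan_threshold_fraction: float = 0.8
    de_method: str = "moderated_t"
    seed: int = 0
    outdir: str = "epiloop_out"

    def config_hash(self) -> str:
        """Stable hash of parameters and seed; file paths enter by basename
        only so the hash survives relocation of inputs and outputs."""
        d = asdict(self)
        d.pop("outdir")  # where results land does not change what they are
        for key in _PATH_KEYS:
            if d[key] is not None:
                d[key] = os.path.basename(str(d[key]))
        text = json.dumps(d, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


_PATH_KEYS = (
    "peaks_manifest",
    "loops_manifest",
    "genes",
    "counts",
    "fasta",
    "pfms",
    "motif_gene_map",
    "gene_sets",
)


def validate_config(raw: Mapping, base_dir: str | Path = ".") -> PipelineConfig:
    """Fill defaults, resolve relative paths, and reject inconsistent
    thresholds with actionable messages."""
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    base = Path(base_dir)
    for key in _PATH_KEYS:
        val = getattr(cfg, key)
        if val is not None and not os.path.isabs(val):
            setattr(cfg, key, str(base / val))
    if cfg.region_gained_k > cfg.region_n_cases:
        raise ValueError(
            f"region rule k={cfg.region_gained_k} exceeds n={cfg.region_n_cases}"
        )
    if cfg.loop_gained_k > cfg.loop_n_cases:
        raise ValueError(
            f"loop rule k={cfg.loop_gained_k} exceeds n={cfg.loop_n_cases}"
        )
    if cfg.promoter_window <= 0:
        raise ValueError("promoter window must be positive")
    if not (0.0 < cfg.scan_threshold_fraction <= 1.0):
        raise ValueError("scan threshold fraction must be in (0, 1]")
    for key in ("peaks_manifest", "loops_manifest", "genes", "counts"):
        if not os.path.exists(getattr(cfg, key)):
            raise FileNotFoundError(f"{key}: {getattr(cfg, key)} does not exist")
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw, base_dir=Path(path).parent)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def run_expression_stage(cfg: PipelineConfig) -> dict:
    cm = eio.read_counts(cfg.counts)
    cm = expression.filter_low_count_genes(cm, cfg.min_row_sum)
    lines = sorted({c.rsplit("_rep", 1)[0] for c in cm.sample_ids})
    if cfg.control_line not in lines:
        raise ValueError(f"control line {cfg.control_line!r} not in counts")
    case_lines = [l for l in lines if l != cfg.control_line]
    by_line = {
        l: [c for c in cm.sample_ids if c.rsplit("_rep", 1)[0] == l] for l in lines
    }
    comparisons = []
    for line in case_lines:
        comparisons.append(
            expression.pairwise_de(
                cm,
                by_line[line],
                by_line[cfg.control_line],
                alpha_p=cfg.alpha_p,
                alpha_q=cfg.alpha_q,
                comparison_id=f"{line}_vs_{cfg.control_line}",
                method=cfg.de_method,
            )
        )
    core, pattern_table = expression.intersect_de_sets(
        [c.significant for c in comparisons]
    )
    return {
        "count_matrix": cm,
        "comparisons": comparisons,
        "core": core,
        "pattern_table": pattern_table,
        "case_lines": case_lines,
    }


def run_regions_stage(cfg: PipelineConfig, genes) -> dict:
    manifest = eio.read_manifest(cfg.peaks_manifest)
    controls = list(manifest.loc[manifest.role == "control", "sample"])
    cases = sorted(manifest.loc[manifest.role == "case", "sample"])
    if len(cases) != cfg.region_n_cases:
        raise ValueError(
            f"peaks manifest has {len(cases)} cases, config says {cfg.region_n_cases}"
        )
    order = controls + cases
    sets = {
        row["sample"]: eio.read_bed(row["path"])
        for _, row in manifest.iterrows()
    }
    segments = intervals.atomic_segments(sets, sample_order=order)
    labelled = intervals.classify_segments(
        segments,
        intervals.lost_rule(len(cases)),
        intervals.gained_rule(len(cases), cfg.region_gained_k),
        n_controls=len(controls),
    )
    lost = [s.interval for s in labelled if s.label == "lost"]
    gained = [s.interval for s in labelled if s.label == "gained"]
    shared = [s.interval for s in labelled if s.label == "shared"]
    annotations = intervals.annotate_to_tss(
        lost + gained, genes, window=cfg.promoter_window
    )
    return {
        "segments": labelled,
        "lost": lost,
        "gained": gained,
        "shared": shared,
        "annotations": annotations,
        "samples": order,
    }


def run_loops_stage(cfg: PipelineConfig, genes, core_degs) -> dict:
    manifest = eio.read_manifest(cfg.loops_manifest)
    controls = list(manifest.loc[manifest.role == "control", "sample"])
    if len(controls) != 1:
        raise ValueError("loops manifest must have exactly one control sample")
    cases = sorted(manifest.loc[manifest.role == "case", "sample"])
    if len(cases) != cfg.loop_n_cases:
        raise ValueError(
            f"loops manifest has {len(cases)} cases, config says {cfg.loop_n_cases}"
        )
    calls = []
    for _, row in manifest.iterrows():
        calls.extend(eio.read_bedpe(row["path"], sample_id=row["sample"]))
    filtered = lp.filter_loops(
        calls,
        min_count=cfg.loop_min_count,
        max_fdr=cfg.loop_max_fdr,
        min_length=cfg.loop_min_length,
    )
    anchors, unified = lp.unify_anchors(
        filtered, max_gap=cfg.anchor_max_gap, sample_ids=controls + cases
    )
    rule = lp.LoopDiffRule(
        controls[0], tuple(cases), cfg.loop_min_count, cfg.loop_gained_k
    )
    unified = lp.call_differential_loops(unified, rule)
    windows = intervals.promoter_windows(genes, cfg.promoter_window)
    unified, contingency = lp.classify_loops(unified, windows)
    diff = [u for u in unified if u.diff_label in ("lost", "gained")]
    flags, hubs, hub_summary = lp.multi_anchor_flags(diff)
    lost = [u for u in unified if u.diff_label == "lost"]
    gained = [u for u in unified if u.diff_label == "gained"]
    length_cmp = (
        lp.compare_loop_lengths(lost, gained) if lost and gained else None
    )
    anchor_genes, anchor_degs = lp.genes_at_differential_anchors(
        unified, genes, core_degs, window=cfg.promoter_window
    )
    return {
        "unified": unified,
        "lost": lost,
        "gained": gained,
        "contingency": contingency,
        "hubs": hubs,
        "hub_summary": hub_summary,
        "length_comparison": length_cmp,
        "anchor_genes": anchor_genes,
        "anchor_degs": anchor_degs,
        "samples": controls + cases,
    }


def run_regnet_stage(
    cfg: PipelineConfig,
    genes,
    core_degs,
    gained_regions: Sequence[GenomicInterval],
    shared_regions: Sequence[GenomicInterval],
) -> dict:
    if not (cfg.fasta and cfg.pfms):
        return {}
    sequences = eio.read_fasta(cfg.fasta)
    pwms = eio.read_pfm(cfg.pfms)
    hits_by_motif = {}
    for pwm in pwms:
        threshold = cfg.scan_threshold_fraction * pwm.max_score()
        hits_by_motif[pwm.motif_id] = regnet.scan_pwm(sequences, pwm, threshold)
    windows = intervals.promoter_windows(genes, cfg.promoter_window)
    widx = lp._window_index(windows)
    gained_prox = [r for r in gained_regions if lp._overlaps_any(r, widx)]
    # enrichment background: every non-differential (shared) region;
    # motif-pair background: the common peaks at promoters genome-wide
    background = [r for r in shared_regions if lp._overlaps_any(r, widx)]
    enrichment = regnet.motif_enrichment(
        gained_prox, list(shared_regions), hits_by_motif
    )
    motif_to_gene = {}
    if cfg.motif_gene_map:
        mg = pd.read_csv(cfg.motif_gene_map, sep="\t")
        motif_to_gene = dict(zip(mg["motif_id"], mg["gene_id"]))
    key_tfs = regnet.select_key_tfs(
        enrichment, motif_to_gene, core_degs, alpha=0.01
    )
    edges = regnet.assign_targets(
        hits_by_motif, list(gained_regions), genes, window=cfg.promoter_window
    )
    common = None
    if len(key_tfs) >= 2:
        a, b = key_tfs[0], key_tfs[1]
        common = regnet.common_targets(
            [e for e in edges if e.tf_id == a],
            [e for e in edges if e.tf_id == b],
            restrict_to=core_degs,
        )
    pair = None
    motifs = sorted(hits_by_motif)
    if len(motifs) >= 2 and gained_prox and background:
        try:
            pair = regnet.motif_pair_distance(
                hits_by_motif[motifs[0]],
                hits_by_motif[motifs[1]],
                gained_prox,
                background,
            )
        except ValueError:
            pair = None
    return {
        "hits": hits_by_motif,
        "enrichment": enrichment,
        "key_tfs": key_tfs,
        "edges": edges,
        "common": common,
        "pair_distance": pair,
        "gained_proximal": gained_prox,
        "background_promoter": background,
    }


def ora_gene_sets(
    gene_list: Sequence[str],
    universe: Sequence[str],
    gmt_sets: Mapping[str, set],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list against gene
    sets, BH-corrected across sets and sorted by q then name."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    genes = set(gene_list) & uni
    rows = []
    for name in sorted(gmt_sets):
        members = gmt_sets[name] & uni
        if not members:
            continue
        k = len(genes & members)
        p = stats.hypergeom_upper_tail(len(uni), len(members), len(genes), k)
        rows.append(
            dict(gene_set=name, set_size=len(members), overlap=k, pvalue=p)
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["qvalue"] = stats.bh_adjust(df["pvalue"].to_numpy())
    df["significant"] = (df["pvalue"] < alpha) & (df["qvalue"] < alpha)
    return df.sort_values(["qvalue", "gene_set"], ignore_index=True)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages, write outputs under cfg.outdir, and return the
    run report (also written as report.json).

    Rerunning with the same inputs and seed produces an identical report
    hash.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("config hash %s; thresholds: p<%g, q<%g, region %d/%d, loop %d/%d",
             cfg.config_hash(), cfg.alpha_p, cfg.alpha_q,
             cfg.region_gained_k, cfg.region_n_cases,
             cfg.loop_gained_k, cfg.loop_n_cases)

    genes = eio.read_gene_models(cfg.genes, cfg.genes_format)

    log.info("stage: expression")
    expr = run_expression_stage(cfg)
    core = expr["core"]
    de_dir = outdir / "expression"
    de_dir.mkdir(exist_ok=True)
    de_table = pd.concat([c.table for c in expr["comparisons"]], ignore_index=True)
    de_table.to_csv(de_dir / "de_results.tsv", sep="\t", index=False)
    with open(de_dir / "core_degs.txt", "w") as fh:
        for g in sorted(core.genes):
            fh.write(g + "\n")
    expr["pattern_table"].to_csv(
        de_dir / "intersection_patterns.tsv", sep="\t", index=False
    )

    log.info("stage: regions")
    reg = run_regions_stage(cfg, genes)
    reg_dir = outdir / "regions"
    reg_dir.mkdir(exist_ok=True)
    for label in ("lost", "gained", "shared"):
        eio.write_bed(
            [
                GenomicInterval(iv.chrom, iv.start, iv.end, name=label)
                for iv in reg[label]
            ],
            reg_dir / f"{label}.bed",
        )
    with open(reg_dir / "presence.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tlabel\t" + "\t".join(reg["samples"]) + "\n")
        for seg in reg["segments"]:
            bits = "\t".join(str(int(b)) for b in seg.presence)
            fh.write(
                f"{seg.interval.chrom}\t{seg.interval.start}\t{seg.interval.end}"
                f"\t{seg.label}\t{bits}\n"
            )

    log.info("stage: loops")
    loop = run_loops_stage(cfg, genes, core.genes)
    loop_dir = outdir / "loops"
    loop_dir.mkdir(exist_ok=True)
    lp.loops_table(loop["unified"], loop["samples"]).to_csv(
        loop_dir / "unified_loops.tsv", sep="\t", index=False
    )
    loop["contingency"].to_csv(
        loop_dir / "class_by_label.tsv", sep="\t", index=False
    )
    with open(loop_dir / "hubs.tsv", "w") as fh:
        fh.write("hub_id\tanchor_ids\n")
        for i, hub in enumerate(loop["hubs"]):
            fh.write(f"hub{i:04d}\t" + ",".join(sorted(hub)) + "\n")

    log.info("stage: regulatory network")
    rn = run_regnet_stage(
        cfg, genes, core.genes, reg["gained"], reg["shared"]
    )
    rn_dir = outdir / "regnet"
    rn_dir.mkdir(exist_ok=True)
    if rn:
        with open(rn_dir / "enrichment.tsv", "w") as fh:
            fh.write(
                "motif_id\ttargets_with_hit\ttargets_total\t"
                "background_with_hit\tbackground_total\tpvalue\tqvalue\n"
            )
            for r in rn["enrichment"]:
                fh.write(
                    f"{r.motif_id}\t{r.targets_with_hit}\t{r.targets_total}\t"
                    f"{r.background_with_hit}\t{r.background_total}\t"
                    f"{r.p_value:.6g}\t{r.q_value:.6g}\n"
                )
        with open(rn_dir / "edges.tsv", "w") as fh:
            fh.write("tf\tgene\tchrom\tstart\tend\tdistance\tzone\n")
            for e in sorted(
                rn["edges"], key=lambda e: (e.tf_id, e.gene_id, e.hit.interval.start)
            ):
                fh.write(
                    f"{e.tf_id}\t{e.gene_id}\t{e.hit.interval.chrom}\t"
                    f"{e.hit.interval.start}\t{e.hit.interval.end}\t"
                    f"{e.tss_distance}\t{e.zone}\n"
                )

    ora_table = None
    if cfg.gene_sets:
        log.info("stage: gene-set enrichment")
        gmt = eio.read_gmt(cfg.gene_sets)
        ora_table = ora_gene_sets(
            sorted(core.genes), expr["count_matrix"].gene_ids, gmt
        )
        ora_table.to_csv(outdir / "ora.tsv", sep="\t", index=False)

    report = _build_report(cfg, expr, reg, loop, rn, ora_table)
    _self_audit(report, outdir)
    text = json.dumps(report, sort_keys=True, indent=1)
    report["report_hash"] = hashlib.sha256(text.encode()).hexdigest()[:16]
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return report


def _build_report(cfg, expr, reg, loop, rn, ora_table) -> dict:
    core = expr["core"]
    length = loop["length_comparison"]
    conting = loop["contingency"]

    def frac(label, cls):
        sel = conting[(conting.diff_label == label) & (conting["class"] == cls)]
        return float(sel["fraction"].iloc[0]) if len(sel) else float("nan")

    report = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "expression": {
            "n_comparisons": len(expr["comparisons"]),
            "n_genes_tested": len(expr["count_matrix"].gene_ids),
            "core_deg_count": len(core.genes),
            "de_method": expr["comparisons"][0].method if expr["comparisons"] else None,
        },
        "regions": {
            "lost": len(reg["lost"]),
            "gained": len(reg["gained"]),
            "shared": len(reg["shared"]),
        },
        "loops": {
            "unified": len(loop["unified"]),
            "lost": len(loop["lost"]),
            "gained": len(loop["gained"]),
            "gained_pp_fraction": frac("gained", "P-P"),
            "lost_enhancer_fraction": (
                frac("lost", "P-E") + frac("lost", "E-E")
                if loop["lost"]
                else float("nan")
            ),
            "median_span_lost": length.median_lost if length else None,
            "median_span_gained": length.median_gained if length else None,
            "length_p_value": length.test.p_value if length else None,
            "n_hubs": len(loop["hubs"]),
            "fraction_multi_anchor": loop["hub_summary"]["fraction_multi_anchor"],
            "anchor_genes": len(loop["anchor_genes"]),
            "anchor_degs": len(loop["anchor_degs"]),
        },
        "regnet": {},
        "ora": {},
    }
    if rn:
        report["regnet"] = {
            "n_motifs": len(rn["hits"]),
            "key_tfs": rn["key_tfs"],
            "n_edges": len(rn["edges"]),
            "common_target_fraction": (
                rn["common"].fraction_of_a if rn["common"] else None
            ),
            "pair_median_target": (
                rn["pair_distance"].target_median if rn["pair_distance"] else None
            ),
            "pair_median_background": (
                rn["pair_distance"].background_median if rn["pair_distance"] else None
            ),
            "pair_p_value": (
                rn["pair_distance"].test.p_value if rn["pair_distance"] else None
            ),
        }
    if ora_table is not None and not ora_table.empty:
        report["ora"] = {
            "n_sets": int(len(ora_table)),
            "top_set": str(ora_table.iloc[0]["gene_set"]),
            "top_q": float(ora_table.iloc[0]["qvalue"]),
        }
    return report


def _self_audit(report: dict, outdir: Path) -> None:
    """Recount emitted files against the report (end-of-run audit)."""
    lost = sum(1 for _ in open(outdir / "regions" / "lost.bed"))
    gained = sum(1 for _ in open(outdir / "regions" / "gained.bed"))
    if lost != report["regions"]["lost"] or gained != report["regions"]["gained"]:
        raise RuntimeError("self-audit failed: region files disagree with report")
    with open(outdir / "expression" / "core_degs.txt") as fh:
        n_core = sum(1 for _ in fh)
    if n_core != report["expression"]["core_deg_count"]:
        raise RuntimeError("self-audit failed: core DEG file disagrees with report")
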