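"""Count normalization, pairwise differential expression, and the core-DEG
intersection across many case-vs-control comparisons.

The differential test is a documented stand-in for a negative-binomial Wald
engine: counts are normalized by median-of-ratios size factors, and genes
are tested on log2(normalized + 1) with an empirical-Bayes moderated t that
pools variance information across genes (so, like the count-model engines,
each gene's test borrows strength from the whole transcriptome).  The
stand-in nature is recorded in every result's metadata, and externally
computed DE tables in the same schema can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from . import stats
from .io import CountMatrix

DE_COLUMNS = ["comparison_id", "gene_id", "log2fc", "pvalue", "qvalue"]


@dataclass(frozen=True)
class DEComparison:
    """Per-gene effect sizes and p/q values for one pairwise comparison."""

    comparison_id: str
    table: pd.DataFrame  # columns: gene_id, log2fc, pvalue, qvalue, significant
    significant: frozenset[str]
    method: str
    alpha_p: float
    alpha_q: float


@dataclass(frozen=True)
class CoreDegSet:
    """Genes significant in every (or >=k of the) pairwise comparisons."""

    genes: frozenset[str]
    n_comparisons: int
    rule: str  # 'all' or 'at_least_k'
    k: int | None = None


def filter_low_count_genes(cm: CountMatrix, min_row_sum: int = 10) -> CountMatrix:
    """Drop genes whose total count over all samples is below the cutoff."""
    totals = cm.counts.sum(axis=1)
    kept = cm.counts.loc[totals >= min_row_sum]
    if kept.empty:
        raise ValueError("all genes removed by the row-sum filter")
    return CountMatrix(kept.copy(), dict(cm.sample_groups))


def size_factors_median_ratios(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    The per-gene reference is the geometric mean across samples, using only
    genes with all counts positive; each sample's factor is the median of
    its ratios to the reference over those genes.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no gene has positive counts in every sample")
    ref_counts = counts[all_positive]
    log_geo = np.log(ref_counts).mean(axis=1)
    factors = np.exp(np.median(np.log(ref_counts) - log_geo[:, None], axis=0))
    return pd.Series(factors, index=cm.counts.columns, name="size_factor")


def normalized_counts(cm: CountMatrix) -> pd.DataFrame:
    return cm.counts / size_factors_median_ratios(cm)


def pairwise_de(
    cm: CountMatrix,
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    alpha_p: float = 0.01,
    alpha_q: float = 0.01,
    comparison_id: str | None = None,
    method: str = "moderated_t",
) -> DEComparison:
    """Test every gene for differential expression, case vs control.

    Size factors are computed on the compared samples, log2 fold change is
    the ratio of mean normalized counts with a 0.5 pseudo-count (case over
    control), p-values come from the chosen test on log2(normalized + 1)
    and q-values from Benjamini-Hochberg within this comparison.  A gene is
    significant iff p < alpha_p AND q < alpha_q.
    """
    if len(case_samples) < 2 or len(control_samples) < 2:
        raise ValueError("need >=2 replicates per side")
    cols = list(case_samples) + list(control_samples)
    missing = set(cols) - set(cm.sample_ids)
    if missing:
        raise ValueError(f"unknown samples {sorted(missing)}")
    sub = CountMatrix(cm.counts[cols].copy())
    norm = normalized_counts(sub)
    case = norm[list(case_samples)].to_numpy()
    ctrl = norm[list(control_samples)].to_numpy()
    log2fc = np.log2((case.mean(axis=1) + 0.5) / (ctrl.mean(axis=1) + 0.5))
    a = np.log2(case + 1.0)
    b = np.log2(ctrl + 1.0)
    if method == "moderated_t":
        t, p, _ = stats.moderated_t_test(a, b)
    elif method == "welch":
        res = [stats.welch_t(a[i], b[i]) for i in range(a.shape[0])]
        t = np.array([r.statistic for r in res])
        p = np.array([r.p_value for r in res])
    else:
        raise ValueError(f"unknown method {method!r}")
    q = stats.bh_adjust(p)
    if comparison_id is None:
        comparison_id = "case_vs_control"
    table = pd.DataFrame(
        {
            "comparison_id": comparison_id,
            "gene_id": sub.gene_ids,
            "log2fc": log2fc,
            "pvalue": p,
            "qvalue": q,
        }
    )
    table["significant"] = (table["pvalue"] < alpha_p) & (table["qvalue"] < alpha_q)
    sig = frozenset(table.loc[table["significant"], "gene_id"])
    return DEComparison(
        comparison_id,
        table,
        sig,
        method=f"{method} on log2(median-of-ratios normalized + 1); "
        "stand-in for a negative-binomial Wald engine",
        alpha_p=alpha_p,
        alpha_q=alpha_q,
    )


def intersect_de_sets(
    sets: Sequence[Iterable[str]], rule: str = "all", k: int | None = None
) -> tuple[CoreDegSet, pd.DataFrame]:
    """Intersect per-comparison significant-gene sets into the core set,
    and tabulate the sizes of all observed exclusive membership patterns
    (UpSet-style).
    """
    if not sets:
        raise ValueError("need >=1 significant set")
    frozen = [frozenset(s) for s in sets]
    n = len(frozen)
    if rule == "all":
        core = frozenset.intersection(*frozen)
        k_eff = n
    elif rule == "at_least_k":
        if k is None or not (1 <= k <= n):
            raise ValueError("at_least_k requires 1 <= k <= number of sets")
        counts: dict[str, int] = {}
        for s in frozen:
            for g in s:
                counts[g] = counts.get(g, 0) + 1
        core = frozenset(g for g, c in counts.items() if c >= k)
        k_eff = k
    else:
        raise ValueError(f"unknown rule {rule!r}")
    patterns: dict[tuple[bool, ...], int] = {}
    for g in frozenset.union(*frozen) if any(frozen) else frozenset():
        pat = tuple(g in s for s in frozen)
        patterns[pat] = patterns.get(pat, 0) + 1
    table = pd.DataFrame(
        {
            "pattern": ["".join("1" if b else "0" for b in pat) for pat in patterns],
            "count": list(patterns.values()),
        }
    ).sort_values(["count", "pattern"], ascending=[False, True], ignore_index=True)
    return CoreDegSet(core, n, rule, k_eff if rule == "at_least_k" else None), table


def signature_distance(
    expr: pd.DataFrame, gene_subset: Iterable[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Euclidean sample-to-sample distances over a gene signature.

    ``expr`` is genes x samples on a log scale.  Returns the symmetric
    distance matrix and the leaf order of an average-linkage dendrogram;
    samples are pre-sorted by id so the order is deterministic.
    """
    subset = sorted(set(gene_subset))
    if not subset:
        raise ValueError("empty gene subset")
    missing = set(subset) - set(expr.index)
    if missing:
        raise ValueError(f"genes absent from matrix: {sorted(missing)[:5]}")
    samples = sorted(expr.columns)
    mat = expr.loc[subset, samples].to_numpy(dtype=float).T
    dist = stats.euclidean_distance_matrix(mat)
    linkage = average(squareform(dist, checks=False))
    order = [samples[i] for i in leaves_list(linkage)]
    ddf = pd.DataFrame(dist, index=samples, columns=samples)
    return ddf, order


def coexpression(expr_a, expr_b) -> stats.TestResult:
    """Pearson co-expression of two genes across samples."""
    return stats.pearson_corr(expr_a, expr_b)
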