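# Methods

This note documents the models, rules, numerical choices and limitations
behind `epiloop`, in the order the pipeline runs them.

## Coordinate conventions

All coordinates are 0-based half-open (BED convention) everywhere inside
the package. GTF gene lines (1-based, closed) are converted once, in the
reader. The TSS of a gene is the 5′ end of its locus: `start` on the plus
strand, `end − 1` on the minus strand. Output files are sorted by
(chromosome, start) with plain byte-wise ordering of chromosome names so
repeated runs are byte-identical.

## Differential chromatin regions

`intervals.atomic_segments` partitions the union of all samples' peaks
into maximal segments of constant per-sample presence using a boundary
sweep over coordinate-compressed cut points (the semantics of multi-way
interval intersection). "Present" means ≥ 1 bp overlap; no overlap
fraction is imposed. Segments are classified by quantifier rules:

* lost — present in ≥ 1 control, absent from every case;
* gained — absent from every control, present in ≥ k of n cases
  (default 10 of 15; configurable, so a design with two control slots and
  a 6-of-13 recurrence threshold reuses the same machinery);
* shared — present in control with case recurrence at least the gained
  threshold. The recurrence requirement (rather than "any case") keeps
  the shared label symmetric with the gained rule; segments matching no
  pattern are "other".

Adjacent same-label segments are merged; a minimum-width filter exists
but defaults to 1 bp (off). Classification operates at the segment level:
a gained call refers to the precise sub-interval absent in control, not
to whole peaks.

Promoter windows are symmetric, `[tss − w, tss + w)` with w = 2000 bp,
clipped at zero. The "< 2 kb" promoter rule is stated without sidedness
in the field's annotation tools; symmetric is their common convention.
TSS distance for an interval is 0 when it contains the TSS, else the
signed gap from the nearest interval edge (positive when the TSS lies
rightward); nearest-gene ties break to the lexicographically smallest
gene id.

## Differential loops

Loop calls are filtered before anything else: count ≥ 2, FDR < 0.01 when
an FDR column is present (skipped with a warning otherwise), midpoint
span ≥ 5000 bp. Loop span is defined as the distance between anchor
midpoints throughout — this is stable under anchor widening, which
matters because anchors are then unified across samples by single-linkage
clustering with a 500 bp maximum gap (both defaults configurable). Calls
from different samples mapping to one unified anchor pair become a single
loop with per-sample counts; within-sample duplicates are summed
(conservative toward "present"). A loop absent from a sample's file has
count 0; "absent" in the rules below means exactly count 0.

Differential labels use the same quantifier structure as regions: lost =
control ≥ 2 and all 14 cases 0; gained = control 0 and ≥ 8 of 14 cases
≥ 2; shared = control ≥ 2 with gained-level case recurrence; else other.
An anchor is a promoter anchor iff its unified span overlaps any promoter
window, giving P-P, P-E, E-E classes. On the loop graph (anchors = nodes,
loops = edges) a loop is multi-anchor iff either endpoint has degree ≥ 2;
hubs are connected components with ≥ 2 edges. Lost-vs-gained span
distributions are summarized by median and IQR and compared with a
two-sided Welch t; when several marks or conditions are analyzed the
caller collects the p-values and applies BH across that family.

## Differential expression stand-in

The paper-grade engine for this step is a negative-binomial Wald test;
its internals are out of scope here and externally computed DE tables in
the same schema (comparison, gene, log2FC, p, q) can be substituted. The
built-in stand-in preserves the decision structure:

1. median-of-ratios size factors (reference = per-gene geometric mean
   over samples restricted to genes with all counts positive);
2. log2 fold change of mean normalized counts with a 0.5 pseudo-count;
3. per-gene p-values from an **empirical-Bayes moderated t** on
   log2(normalized + 1): gene-wise pooled variances are shrunk toward a
   scaled-inverse-chi-square prior fitted across all genes by matching
   moments of log s² (Newton/Brent inversion of the trigamma function),
   and the t statistic gains the prior degrees of freedom d0;
4. BH within the comparison; significant iff p < 0.01 and q < 0.01.

The moderation is the deliberate design choice of this package. A plain
per-gene Welch t at 2–3 replicates has only 2–4 estimated degrees of
freedom; its per-comparison power against a 4-fold change at the
dispersion floor of typical RNA-seq (CV² ≈ 0.05) plateaus near 0.78, and
a core set defined as the intersection of 15 such comparisons then loses
most true members (recall ≈ 0.1–0.2 in simulation). Pooling variance
information across genes — exactly what count-model engines do via shared
dispersion — restores per-comparison power to ≈ 0.999 while keeping the
observed type-I error at p < 0.01 within [0.005, 0.02] on
negative-binomial null data. `method="welch"` remains available for
comparison. FDR is computed per comparison (the family is always an
explicit argument, never global).

The core DEG set is the plain intersection of the per-comparison
significant sets (an ≥ k-of-m rule is also provided); the membership
table enumerates the sizes of all observed exclusive membership patterns,
UpSet-style. Signature distances are Euclidean over a gene subset of
log-scale normalized expression (log2(normalized + 1) approximating a
variance-stabilized transform), with a deterministic average-linkage leaf
order (samples pre-sorted by id).

## Regulatory network

PWM scanning scores every window on both strands with
Σ log2(p_base / bg_base), skipping windows containing N; zero
probabilities are floored at 1e-4 before the log. The default hit
threshold is 80% of the PWM's maximum attainable score (the synthetic
configuration uses 100%, where only exact consensus matches score). Motif
enrichment counts regions containing ≥ 1 hit and uses the exact
hypergeometric upper tail with N = targets + background, with BH across
motifs; the default background is the non-differential (shared) region
set of the same assay. Key TFs are motifs with raw enrichment p < 0.01
whose own gene is in the core DEG set (the motif→gene mapping is an
explicit input). Target edges connect a TF to the nearest-TSS gene of
every hit inside a gained region, split proximal/distal at 2 kb; genes
equidistant within 1 bp each receive an edge. The motif-pair statistic
takes, per region containing ≥ 1 hit of each motif, the minimum midpoint
distance between hits, and compares targets against the common promoter
peaks genome-wide by a two-sided Wilcoxon test (exact enumeration below a
combined n of 20, tie-corrected normal approximation above).

## Statistics

* `bh_adjust` — textbook step-up, q_(i) = min over the tail of m·p_(j)/j,
  clipped at 1, input order preserved. Never applied globally; the family
  is the caller's.
* `hypergeom_upper_tail` — log-gamma evaluation, verified against
  rational-arithmetic enumeration for every configuration with N ≤ 30 in
  the test suite.
* `wilcoxon_rank_sum` — exact mode counts the full permutation null by
  subset-sum dynamic programming over doubled midranks (ties handled
  exactly); automatic below combined n = 20 so small region sets get
  exact p-values. Normal mode is tie-corrected with continuity
  correction.
* p-values are reported as computed and never floored.

## Synthetic data

The generator emulates the statistical structure of a one-control,
many-case chromatin study at roughly 1/500 scale: 2 × 5 Mb chromosomes,
400 genes, ~1.5k shared peaks per sample, ~500 loops per sample, 48 count
columns. Defaults are the study conditions: 15 case lines for regions and
expression and 14 for loops; 40 lost / 60 gained regions with per-region
recurrence k ~ Uniform[10, 15] (so the k-of-n boundary is exercised); 50
lost loops with log-normal spans around a 254 kb median vs 80 gained
around 114 kb (σ = 0.35); 85% of gained loops promoter-promoter,
organized as star-shaped hubs of 4 loops sharing a promoter anchor; 86.6%
of lost loops involving a non-promoter anchor; 100 core DEGs at
|log2FC| = 2 with NB dispersion 0.05 (gamma-Poisson sampling) and 3
replicates per line, plus 50 "sporadic" DEGs shifted in only a strict
subset of lines that must never survive the intersection; two planted TF
motifs spaced exactly 56 bp apart in 25 target promoters versus a
symmetric multiset of spacings with median exactly 124 bp in 60
background promoter peaks. Base expression means are log-normal
(meanlog 6, sdlog 1), a typical bulk RNA-seq depth profile.

Placement is collision-free by construction: genes sit on jittered
evenly-spaced slots (~25 kb apart), peaks and distal loop anchors occupy
a 2.5 kb grid of positions ≥ 3.5 kb from every TSS, and loop spans are
realized on the nearest available promoter/slot position (the truth file
records realized geometry, so recovered medians equal the truth's medians
exactly; realized medians deviate from the nominal 254/114 kb only by the
grid quantization). Planted consensus occurrences elsewhere in the random
genome are scrubbed by single-base mutation so a maximum-score scan finds
exactly the planted sites. Two noise dials exist — peak coordinate jitter
and peak dropout — and default to zero: the noise-free configuration is
the acceptance surface, where every stage must recover its planted truth
perfectly, and increasing dropout degrades gained-region recall
monotonically (tested).

What the generator does not emulate: read-level noise, irregular peak
shapes, overlapping features, copy-number structure, correlated
replicates, or anchor jitter across samples. Passing the planted-truth
tests therefore demonstrates correctness of the rule logic and
statistics, not robustness to real-data messiness beyond the dropout and
jitter dials.

## Pipeline and determinism

One YAML config holds every path and threshold; validation fills
defaults and rejects inconsistencies (k > n, non-positive windows,
missing files) with actionable messages. Stages run in dependency order
(expression ∥ regions ∥ loops → regulatory network → gene-set ORA), each
writing its files under the output directory; the run report records all
counts, medians and test results plus a config hash and a report hash. A
self-audit recounts the emitted region and core-DEG files against the
report at the end of every run. The config hash covers parameters and
seed with file paths reduced to basenames — so the same analysis in a
different directory hashes identically — and all randomness flows from
the single seed through one numpy Generator, giving byte-identical
outputs for identical (config, seed).

Problem sizes used by the test and acceptance runs (the package's own
choices): the default preset above for end-to-end recovery; a separate
2000-gene instance for DE power and calibration; 200 random 100 kb
instances for the segmentation oracle; all N ≤ 30 for the hypergeometric
oracle; the tiny preset (2 × 1.2 Mb) for determinism runs.

## Known limitations

* The DE stand-in assumes roughly homoscedastic log-scale counts within
  a comparison; strong mean-variance trends (very low counts) would call
  for a trended prior, which is not implemented.
* Only intra-chromosomal loops are supported.
* The shared/other split beyond lost/gained is a package convention
  (recurrence-based), not an externally standardized definition.
* Gene-set ORA treats gene sets as given; no ontology is bundled.
* Nearest-gene TSS assignment ignores genes on other chromosomes; an
  interval on a gene-free chromosome gets no gene and counts as distal.
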