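"""Readers and writers for the flat-file formats the pipeline consumes.

All genomic coordinates are 0-based half-open (BED convention) everywhere
inside the package; GTF input (1-based, closed) is converted at this
boundary and nowhere else.  Output files are sorted by (chrom, start) with
plain byte-wise (C-locale) ordering of chromosome names so that repeated
runs are byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STRANDS = {"+", "-", "."}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic region, the atom of all region math."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end <= start ({self.end} <= {self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class LoopCall:
    """One chromatin loop call from one sample (BEDPE line).

    Anchors are stored in canonical genomic order; only intra-chromosomal
    loops are supported.
    """

    sample_id: str
    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    count: int
    fdr: float | None = None

    def __post_init__(self) -> None:
        if self.anchor_a.chrom != self.anchor_b.chrom:
            raise ValueError(
                "inter-chromosomal loop "
                f"{self.anchor_a.chrom}:{self.anchor_b.chrom}"
            )
        if self.count < 0:
            raise ValueError("negative loop count")
        if self.fdr is not None and not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr {self.fdr} outside [0, 1]")
        if self.anchor_b.sort_key() < self.anchor_a.sort_key():
            a, b = self.anchor_b, self.anchor_a
            object.__setattr__(self, "anchor_a", a)
            object.__setattr__(self, "anchor_b", b)


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with a strand-aware transcription start site."""

    gene_id: str
    locus: GenomicInterval

    def __post_init__(self) -> None:
        if self.locus.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand required for TSS")

    @property
    def tss(self) -> int:
        """5' end of the locus: start on +, end-1 on -."""
        return self.locus.start if self.locus.strand == "+" else self.locus.end - 1

    @property
    def chrom(self) -> str:
        return self.locus.chrom


@dataclass
class CountMatrix:
    """Raw integer counts, genes x samples, with optional group labels."""

    counts: pd.DataFrame  # index = gene ids, columns = sample ids
    sample_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()]
            raise ValueError(f"duplicate gene ids: {sorted(set(dups))[:5]}")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class MotifPWM:
    """Position probability matrix over A, C, G, T with a background model."""

    motif_id: str
    matrix: np.ndarray  # (width, 4) probabilities
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("matrix must be (width, 4)")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("matrix rows must each sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self, floor: float = 1e-4) -> np.ndarray:
        """log2(p/bg) per position/base; zero probabilities floored."""
        p = np.maximum(self.matrix, floor)
        return np.log2(p / self.background)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def reverse_complement(self) -> "MotifPWM":
        return MotifPWM(
            self.motif_id,
            self.matrix[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            self.pseudocount,
        )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line


def read_bed(path: str | Path, min_columns: int = 3) -> list[GenomicInterval]:
    """Read a BED file into intervals, preserving file order."""
    out: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < min_columns:
            raise FormatError(
                f"{path}: line {lineno}: {len(fields)} fields < {min_columns}"
            )
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(
                f"{path}: line {lineno}: non-integer coordinate"
            ) from exc
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score = None
        if len(fields) > 4 and fields[4] not in (".", ""):
            score = float(fields[4])
        strand = fields[5] if len(fields) > 5 else "."
        if strand not in STRANDS:
            raise FormatError(
                f"{path}: line {lineno}: unknown strand {strand!r}"
            )
        try:
            out.append(
                GenomicInterval(fields[0], start, end, strand, name, score)
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    rows = sorted(intervals, key=GenomicInterval.sort_key)
    with open(path, "w") as fh:
        for iv in rows:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields.append(iv.name if iv.name is not None else ".")
                fields.append(
                    format(iv.score, "g") if iv.score is not None else "0"
                )
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------


def read_bedpe(
    path: str | Path,
    sample_id: str | None = None,
    allow_interchrom: bool = False,
) -> list[LoopCall]:
    """Read a 7-8 column BEDPE of loop calls for one sample.

    Column 7 is the integer read-pair support, optional column 8 an FDR.
    Inter-chromosomal lines are rejected unless ``allow_interchrom`` (then
    they are skipped).
    """
    if sample_id is None:
        sample_id = Path(path).stem
    out: list[LoopCall] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 7:
            raise FormatError(f"{path}: line {lineno}: BEDPE needs >=7 columns")
        c1, c2 = fields[0], fields[3]
        if c1 != c2:
            if allow_interchrom:
                continue
            raise FormatError(
                f"{path}: line {lineno}: inter-chromosomal loop {c1}/{c2}"
            )
        try:
            a = GenomicInterval(c1, int(fields[1]), int(fields[2]))
            b = GenomicInterval(c2, int(fields[4]), int(fields[5]))
            count = int(fields[6])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
        fdr = None
        if len(fields) > 7 and fields[7] not in (".", ""):
            fdr = float(fields[7])
        try:
            out.append(LoopCall(sample_id, a, b, count, fdr))
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bedpe(calls: Iterable[LoopCall], path: str | Path) -> None:
    rows = sorted(
        calls,
        key=lambda c: c.anchor_a.sort_key() + c.anchor_b.sort_key(),
    )
    with open(path, "w") as fh:
        for c in rows:
            fields = [
                c.anchor_a.chrom,
                str(c.anchor_a.start),
                str(c.anchor_a.end),
                c.anchor_b.chrom,
                str(c.anchor_b.start),
                str(c.anchor_b.end),
                str(c.count),
            ]
            if c.fdr is not None:
                fields.append(repr(c.fdr))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def read_gene_models(path: str | Path, format: str = "bed6") -> list[GeneModel]:
    """Read gene models from BED6 or from the gene lines of a GTF.

    The GTF's 1-based closed coordinates are converted to 0-based half-open
    here, at the boundary.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    if format == "bed6":
        for iv in read_bed(path, min_columns=6):
            if iv.strand not in ("+", "-"):
                raise FormatError(f"{path}: gene {iv.name}: missing strand")
            if iv.name is None:
                raise FormatError(f"{path}: BED6 gene line without a name")
            if iv.name in seen:
                raise FormatError(f"{path}: duplicate gene_id {iv.name!r}")
            seen.add(iv.name)
            genes.append(GeneModel(iv.name, iv))
    elif format == "gtf":
        for lineno, line in _data_lines(path):
            fields = line.split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            chrom, start, end, strand = (
                fields[0],
                int(fields[3]) - 1,
                int(fields[4]),
                fields[6],
            )
            if strand not in ("+", "-"):
                raise FormatError(f"{path}: line {lineno}: missing strand")
            gene_id = None
            for attr in fields[8].split(";"):
                attr = attr.strip()
                if attr.startswith("gene_id"):
                    gene_id = attr.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                raise FormatError(f"{path}: line {lineno}: no gene_id attribute")
            if gene_id in seen:
                raise FormatError(f"{path}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            genes.append(
                GeneModel(gene_id, GenomicInterval(chrom, start, end, strand))
            )
    else:
        raise ValueError(f"unknown gene model format {format!r}")
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    write_bed(
        (
            GenomicInterval(
                g.locus.chrom,
                g.locus.start,
                g.locus.end,
                g.locus.strand,
                g.gene_id,
                0.0,
            )
            for g in genes
        ),
        path,
    )


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def read_counts(
    path: str | Path, sample_groups: Mapping[str, str] | None = None
) -> CountMatrix:
    """Read a tab-separated counts matrix (first column gene id, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: empty counts matrix")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise FormatError(f"{path}: counts must be integers")
        df = df.round().astype(np.int64)
    return CountMatrix(df, dict(sample_groups or {}))


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# PFM (JASPAR-style), GMT, FASTA
# ---------------------------------------------------------------------------


def _parse_pfm_row(line: str) -> np.ndarray:
    # accepts "A [ 9 1 0 ]" and bare "9 1 0"
    body = line
    if "[" in line:
        body = line[line.index("[") + 1 : line.rindex("]")]
    elif line[:1] in "ACGT":
        body = line[1:]
    vals = np.array([float(tok) for tok in body.split()])
    if (vals < 0).any():
        raise FormatError("negative PFM counts")
    return vals


def read_pfm(path: str | Path, pseudocount: float = 0.0) -> list[MotifPWM]:
    """Read JASPAR-style position frequency matrices.

    Counts c are turned into probabilities (c + p) / (sum(c) + 4 p) with the
    given pseudocount p, column by column.
    """
    motifs: list[MotifPWM] = []
    header: str | None = None
    rows: list[np.ndarray] = []

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        if len(rows) != 4:
            raise FormatError(f"motif {header}: expected 4 rows, got {len(rows)}")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise FormatError(f"motif {header}: ragged rows")
        counts = np.vstack(rows).T  # (width, 4) in A,C,G,T row order
        col_sums = counts.sum(axis=1, keepdims=True)
        denom = col_sums + 4.0 * pseudocount
        if (denom == 0).any():
            raise FormatError(f"motif {header}: zero column sum, no pseudocount")
        probs = (counts + pseudocount) / denom
        motifs.append(MotifPWM(header, probs, pseudocount=pseudocount))
        header, rows = None, []

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0]
            else:
                if header is None:
                    raise FormatError(f"{path}: PFM row before any '>' header")
                rows.append(_parse_pfm_row(line))
    flush()
    return motifs


def write_pfm(
    motifs: Sequence[tuple[str, np.ndarray]], path: str | Path
) -> None:
    """Write raw count matrices (4 x width, rows A C G T) in JASPAR style."""
    with open(path, "w") as fh:
        for motif_id, counts in motifs:
            fh.write(f">{motif_id}\n")
            for base, row in zip("ACGT", np.asarray(counts)):
                vals = " ".join(format(v, "g") for v in row)
                fh.write(f"{base} [ {vals} ]\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {lineno}: GMT needs >=3 columns")
        name = fields[0]
        if name in sets:
            raise FormatError(f"{path}: duplicate gene set {name!r}")
        sets[name] = {g for g in fields[2:] if g}
    return sets


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest: TSV with columns sample, role, path.

    Roles are 'control' or 'case'; relative paths are resolved against the
    manifest's directory.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "role", "path"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: manifest needs columns {sorted(required)}")
    bad = set(df["role"]) - {"control", "case"}
    if bad:
        raise FormatError(f"{path}: unknown roles {sorted(bad)}")
    if df["sample"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    base = Path(path).parent
    df["path"] = [
        str(p) if os.path.isabs(p) else str(base / p) for p in df["path"]
    ]
    return df
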