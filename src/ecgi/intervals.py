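"""Genomic interval data model, overlap engine and BED/bedGraph I/O.

All coordinates are 0-based half-open (BED convention). Inputs in other
conventions must be converted at the reader. Two intervals overlap iff they
share at least one base pair; chromosome names are matched verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

UNASSIGNED = "unassigned"


class ParseError(ValueError):
    """Malformed input line; message carries the file and line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        # floor midpoint; even-length regions have no true center
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-aware transcription start site.

    ``coding`` mirrors the refGene convention of "NM_"-prefixed accessions
    for protein-coding transcripts; only coding genes define promoter CGIs.
    """

    interval: GenomicInterval
    gene_id: str
    coding: bool = True

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff a and b share >= 1 bp (half-open convention)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def promoter_window(gene: GeneModel, flank: int = 1000) -> GenomicInterval:
    """Symmetric window of ``flank`` bp either side of the strand-aware TSS.

    The window is [tss - flank, tss + flank + 1), clipped at 0, so a region
    at distance exactly ``flank`` from the TSS still overlaps it.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    tss = gene.tss
    return GenomicInterval(
        gene.chrom, max(0, tss - flank), tss + flank + 1, gene.interval.strand,
        name=gene.gene_id,
    )


class IntervalIndex:
    """Overlap index over a fixed interval set.

    Supports vectorised any-overlap flags (sorted starts + running max of
    ends per chromosome) and per-query listing of overlapping member indices
    (interval tree). Both answer the brute-force half-open overlap contract.
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self.intervals = list(intervals)
        self._starts: dict[str, np.ndarray] = {}
        self._maxend: dict[str, np.ndarray] = {}
        self._trees: dict[str, IntervalTree] | None = None  # built lazily
        self._by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for i, iv in enumerate(self.intervals):
            self._by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
        for chrom, rows in self._by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            self._starts[chrom] = starts
            self._maxend[chrom] = np.maximum.accumulate(ends)

    def __len__(self) -> int:
        return len(self.intervals)

    def any_overlap(self, query: GenomicInterval) -> bool:
        starts = self._starts.get(query.chrom)
        if starts is None:
            return False
        k = int(np.searchsorted(starts, query.end, side="left"))
        return k > 0 and self._maxend[query.chrom][k - 1] > query.start

    def any_overlap_many(
        self, chroms: Sequence[str], starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Vectorised any-overlap over parallel (chrom, start, end) arrays."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        out = np.zeros(len(starts), dtype=bool)
        chrom_arr = np.asarray(chroms, dtype=object)
        for chrom in np.unique(chrom_arr):
            mask = chrom_arr == chrom
            s_starts = self._starts.get(chrom)
            if s_starts is None:
                continue
            k = np.searchsorted(s_starts, ends[mask], side="left")
            ok = k > 0
            maxend = self._maxend[chrom]
            hit = np.zeros(int(mask.sum()), dtype=bool)
            hit[ok] = maxend[k[ok] - 1] > starts[mask][ok]
            out[mask] = hit
        return out

    def overlapping(self, query: GenomicInterval) -> list[int]:
        """Indices (into the construction order) of members overlapping query."""
        if self._trees is None:
            self._trees = {}
            for chrom, rows in self._by_chrom.items():
                tree = IntervalTree()
                for s, e, i in rows:
                    tree.addi(s, e, i)
                self._trees[chrom] = tree
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.overlap(query.start, query.end))


def intersect_flags(
    queries: Sequence[GenomicInterval], subjects: Sequence[GenomicInterval]
) -> list[bool]:
    """For each query, whether it overlaps at least one subject."""
    if not subjects:
        return [False] * len(queries)
    index = IntervalIndex(subjects)
    if not queries:
        return []
    flags = index.any_overlap_many(
        [q.chrom for q in queries],
        np.array([q.start for q in queries], dtype=np.int64),
        np.array([q.end for q in queries], dtype=np.int64),
    )
    return [bool(f) for f in flags]


def nearest_gene(region: GenomicInterval, genes: Sequence[GeneModel]) -> str:
    """Gene whose TSS is closest to the region midpoint, on the same chromosome.

    Ties break toward the smaller TSS coordinate, then the lexicographically
    smaller gene_id. Returns ``"unassigned"`` when the chromosome has no gene.
    """
    mid = region.center
    best: tuple[int, int, str] | None = None
    for g in genes:
        if g.chrom != region.chrom:
            continue
        key = (abs(g.tss - mid), g.tss, g.gene_id)
        if best is None or key < best:
            best = key
    return UNASSIGNED if best is None else best[2]


# ---------------------------------------------------------------------------
# File I/O: BED3/BED6, bedGraph, refGene-style gene tables


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6; column 4 (name) and column 6 (strand) are honored."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand, name))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path, extra=None) -> None:
    """Write BED6 (+ optional extra column per interval, e.g. a class label)."""
    extra = list(extra) if extra is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            row = [iv.chrom, str(iv.start), str(iv.end), iv.name or ".", "0", iv.strand]
            if extra is not None:
                row.append(str(extra[i]))
            fh.write("\t".join(row) + "\n")


def read_genes(path) -> list[GeneModel]:
    """Read a refGene-style tab table: gene_id, chrom, strand, txStart, txEnd, coding.

    ``coding`` is 1/0 or an accession prefix test upstream; "NM" also accepted.
    """
    out: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns")
            gene_id, chrom, strand, s, e, coding = fields[:6]
            try:
                iv = GenomicInterval(chrom, int(s), int(e), strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            out.append(GeneModel(iv, gene_id, coding in ("1", "NM", "True", "true")))
    return out


def write_genes(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(
                "\t".join(
                    [g.gene_id, iv.chrom, iv.strand, str(iv.start), str(iv.end),
                     "1" if g.coding else "0"]
                )
                + "\n"
            )


@dataclass
class CoverageTrack:
    """bedGraph-style piecewise-constant coverage; uncovered bases are 0.

    Segments must be non-overlapping within a chromosome (checked on load).
    """

    starts: dict[str, np.ndarray] = field(default_factory=dict)
    ends: dict[str, np.ndarray] = field(default_factory=dict)
    values: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_segments(cls, segments: Iterable[tuple[str, int, int, float]]) -> "CoverageTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, s, e, v in segments:
            if not 0 <= s < e:
                raise ValueError(f"invalid coverage segment {chrom}:{s}-{e}")
            by_chrom.setdefault(chrom, []).append((s, e, v))
        track = cls()
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping coverage segments on {chrom}")
            track.starts[chrom] = starts
            track.ends[chrom] = ends
            track.values[chrom] = np.array([r[2] for r in rows], dtype=float)
        return track

    @classmethod
    def read_bedgraph(cls, path) -> "CoverageTrack":
        segs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 columns")
                try:
                    segs.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
        return cls.from_segments(segs)

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.starts):
                for s, e, v in zip(self.starts[chrom], self.ends[chrom], self.values[chrom]):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")

    def integral_to(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Integral of coverage over [0, p) for each position p (vectorised)."""
        positions = np.asarray(positions, dtype=float)
        starts = self.starts.get(chrom)
        if starts is None:
            return np.zeros(positions.shape, dtype=float)
        ends = self.ends[chrom]
        vals = self.values[chrom]
        cum = np.concatenate([[0.0], np.cumsum((ends - starts) * vals)])
        k = np.searchsorted(ends, positions, side="right")
        out = cum[k]
        partial = k < len(starts)
        kp = k[partial]
        frac = np.clip(positions[partial] - starts[kp], 0, None)
        out[partial] += frac * vals[kp]
        return out

    def window_integral(self, chrom: str, start: int, end: int) -> float:
        """Integral of coverage over [start, end) in value*bp units."""
        starts = self.starts.get(chrom)
        if starts is None or start >= end:
            return 0.0
        ends = self.ends[chrom]
        vals = self.values[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(ov * vals[lo:hi]))
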