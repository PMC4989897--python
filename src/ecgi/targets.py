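"""ChIA-PET link filtering and enhancer-to-gene target assignment.

Links are undirected two-anchor interactions with a tag count; only links
with tag count >= 3 (the default significance filter) are used. A region
targets a gene when one anchor of a filtered link overlaps the region and
the other anchor overlaps the gene's promoter window. When interaction data
are unavailable, targets fall back to the nearest gene by TSS distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import (
    GeneModel,
    GenomicInterval,
    IntervalIndex,
    ParseError,
    nearest_gene,
    promoter_window,
    UNASSIGNED,
)
from .stats import RankTestResult, rank_sum_test, signed_rank_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChiaLink:
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    tag_count: int

    def __post_init__(self) -> None:
        if self.tag_count < 1:
            raise ValueError("tag_count must be >= 1")


@dataclass(frozen=True)
class TargetAssignment:
    region_id: str
    gene_id: str
    tag_count: int
    evidence: str  # "chia" or "nearest"


def read_links(path) -> list[ChiaLink]:
    """Read a BEDPE-like TSV: chrom1,start1,end1,chrom2,start2,end2,tag_count."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ParseError(f"{path}:{lineno}: expected 7 columns")
            try:
                a1 = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                a2 = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
                out.append(ChiaLink(a1, a2, int(fields[6])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_links(links: Sequence[ChiaLink], path) -> None:
    with open(path, "w") as fh:
        for ln in links:
            a, b = ln.anchor1, ln.anchor2
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t{ln.tag_count}\n"
            )


def filter_links(links: Sequence[ChiaLink], min_tags: int = 3) -> list[ChiaLink]:
    """Keep links with tag_count >= min_tags, preserving order."""
    if min_tags < 1:
        raise ValueError("min_tags must be >= 1")
    return [ln for ln in links if ln.tag_count >= min_tags]


def region_ids(regions: Sequence[GenomicInterval]) -> list[str]:
    return [r.name or f"region_{i}" for i, r in enumerate(regions)]


def assign_targets(
    regions: Sequence[GenomicInterval],
    links: Sequence[ChiaLink],
    genes: Sequence[GeneModel],
    flank: int = 1000,
    aggregate: str = "max",
) -> list[TargetAssignment]:
    """Assign target genes to regions via chromatin-interaction links.

    A (region, gene) pair is assigned when some link has one anchor
    overlapping the region and the other overlapping the gene's +/-flank
    promoter window; anchors are interchangeable. The pair's tag count
    aggregates supporting links by ``max`` (default) or ``sum``.
    """
    if aggregate not in ("max", "sum"):
        raise ValueError("aggregate must be 'max' or 'sum'")
    ids = region_ids(regions)
    region_idx = IntervalIndex(regions)
    promoters = [promoter_window(g, flank) for g in genes]
    promoter_idx = IntervalIndex(promoters)
    gene_ids = [g.gene_id for g in genes]

    pair_tags: dict[tuple[str, str], int] = {}
    for ln in links:
        for region_anchor, gene_anchor in ((ln.anchor1, ln.anchor2), (ln.anchor2, ln.anchor1)):
            r_hits = region_idx.overlapping(region_anchor)
            if not r_hits:
                continue
            g_hits = promoter_idx.overlapping(gene_anchor)
            for ri in r_hits:
                for gi in g_hits:
                    key = (ids[ri], gene_ids[gi])
                    if key in pair_tags:
                        if aggregate == "max":
                            pair_tags[key] = max(pair_tags[key], ln.tag_count)
                        else:
                            pair_tags[key] += ln.tag_count
                    else:
                        pair_tags[key] = ln.tag_count
    return [
        TargetAssignment(rid, gid, tags, "chia")
        for (rid, gid), tags in sorted(pair_tags.items())
    ]


def assign_nearest(
    regions: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> list[TargetAssignment]:
    """Nearest-gene fallback when no interaction data are available."""
    out = []
    for rid, region in zip(region_ids(regions), regions):
        gid = nearest_gene(region, genes)
        if gid != UNASSIGNED:
            out.append(TargetAssignment(rid, gid, 0, "nearest"))
    return out


def target_multiplicity(
    assignments: Sequence[TargetAssignment],
) -> tuple[float, float]:
    """Fractions of assigned regions targeting one gene vs two or more.

    Computed over regions with at least one target; the two fractions sum
    to 1.
    """
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.region_id] = counts.get(a.region_id, 0) + 1
    if not counts:
        raise ValueError("no region has an assigned target")
    n = len(counts)
    n_single = sum(1 for c in counts.values() if c == 1)
    return n_single / n, 1.0 - n_single / n


def compare_link_strength(
    strengths_a, strengths_b, paired: bool = False
) -> RankTestResult:
    """Compare per-pair interaction tag counts between two region classes.

    The two pair sets are unpaired samples, so the primary method is the
    two-sample rank-sum test; a paired signed-rank variant is available for
    equal-length samples via ``paired=True``.
    """
    a = np.asarray(strengths_a, dtype=float)
    b = np.asarray(strengths_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal sample sizes")
        res = signed_rank_test(a - b)
        return RankTestResult(
            res.statistic, res.p_greater, res.p_less, res.p_two_sided,
            "signed-rank:" + res.method, res.degenerate,
        )
    return rank_sum_test(a, b)


def expression_fold_change(
    assignments: Sequence[TargetAssignment],
    expr_a: Mapping[str, float],
    expr_b: Mapping[str, float],
    pseudocount: float = 0.1,
) -> dict[str, float]:
    """Per-target-gene expression fold change (A over B) with a pseudocount.

    Genes missing from either table are excluded with a logged warning.
    """
    folds: dict[str, float] = {}
    missing = 0
    for gid in sorted({a.gene_id for a in assignments}):
        if gid not in expr_a or gid not in expr_b:
            missing += 1
            continue
        ra, rb = float(expr_a[gid]), float(expr_b[gid])
        if ra < 0 or rb < 0:
            raise ValueError(f"negative expression value for {gid}")
        folds[gid] = (ra + pseudocount) / (rb + pseudocount)
    if missing:
        logger.warning("expression_fold_change: %d target genes missing from tables", missing)
    return folds
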