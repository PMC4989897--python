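"""Permutation enrichment of regulator targeting and Fisher gene-set tests.

The permutation null replaces the query regions (eCGIs or typical
enhancers) with the same number of random DNA segments — by default length-
and chromosome-matched — and recounts how many distinct transcription-
regulator genes the interaction links connect them to. The empirical
p-value uses add-one smoothing, so it can never be 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import GeneModel, GenomicInterval, IntervalIndex, promoter_window
from .stats import FisherResult, fisher_exact_2x2
from .targets import ChiaLink


@dataclass(frozen=True)
class PermutationResult:
    observed: int
    null_counts: np.ndarray
    p_value: float
    direction: str  # greater, less or two_sided

    @property
    def n_perm(self) -> int:
        return len(self.null_counts)


def random_segments(
    template_regions: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    excluded: Sequence[GenomicInterval] | None = None,
    rng: np.random.Generator | int | None = None,
    match_length: bool = True,
    max_rejections: int = 10_000,
) -> list[GenomicInterval]:
    """One uniform random segment per template, on the template's chromosome.

    Segments keep their template's length unless ``match_length`` is False,
    in which case every segment gets the median template length (count-only
    matching). Segments overlapping ``excluded`` are rejected and redrawn.
    """
    rng = np.random.default_rng(rng)
    excluded_idx = IntervalIndex(excluded) if excluded else None
    median_len = int(np.median([t.length for t in template_regions])) if template_regions else 0
    out = []
    for t in template_regions:
        length = t.length if match_length else median_len
        size = chrom_sizes.get(t.chrom)
        if size is None or length >= size:
            raise ValueError(f"template {t.chrom}:{t.start}-{t.end} cannot be placed")
        for _ in range(max_rejections):
            start = int(rng.integers(0, size - length + 1))
            seg = GenomicInterval(t.chrom, start, start + length)
            if excluded_idx is None or not excluded_idx.any_overlap(seg):
                out.append(seg)
                break
        else:
            raise RuntimeError(
                f"could not place a random segment for {t.chrom}:{t.start}-{t.end} "
                f"after {max_rejections} rejections"
            )
    return out


class _LinkPromoterHits:
    """Precomputed (link anchor -> regulator promoter) hits.

    Promoter overlaps do not change across permutations, so each link is
    reduced once to rows of (counter-anchor coordinates, hit gene index);
    each permutation then only needs vectorised counter-anchor-vs-region
    overlap flags.
    """

    def __init__(
        self,
        links: Sequence[ChiaLink],
        genes: Sequence[GeneModel],
        counted_ids: set[str],
        flank: int,
    ):
        promoter_idx = IntervalIndex([promoter_window(g, flank) for g in genes])
        gene_list = [g.gene_id for g in genes]
        chroms, starts, ends, gene_idx = [], [], [], []
        id_of: dict[str, int] = {}
        for ln in links:
            for gene_anchor, other in ((ln.anchor1, ln.anchor2), (ln.anchor2, ln.anchor1)):
                for gi in promoter_idx.overlapping(gene_anchor):
                    gid = gene_list[gi]
                    if gid not in counted_ids:
                        continue
                    chroms.append(other.chrom)
                    starts.append(other.start)
                    ends.append(other.end)
                    gene_idx.append(id_of.setdefault(gid, len(id_of)))
        self.chroms = np.asarray(chroms, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.gene_idx = np.asarray(gene_idx, dtype=np.int64)

    def count_distinct_genes(self, regions: Sequence[GenomicInterval]) -> int:
        if len(self.gene_idx) == 0 or not regions:
            return 0
        idx = IntervalIndex(regions)
        flags = idx.any_overlap_many(self.chroms, self.starts, self.ends)
        return int(np.unique(self.gene_idx[flags]).size)


def count_regulator_targets(
    regions: Sequence[GenomicInterval],
    links: Sequence[ChiaLink],
    genes: Sequence[GeneModel],
    regulator_ids: set[str],
    flank: int = 1000,
) -> int:
    """Distinct regulator genes targeted by ``regions`` via the links."""
    hits = _LinkPromoterHits(links, genes, set(regulator_ids), flank)
    return hits.count_distinct_genes(regions)


def permutation_enrichment(
    regions: Sequence[GenomicInterval],
    links: Sequence[ChiaLink],
    genes: Sequence[GeneModel],
    regulator_ids: set[str],
    chrom_sizes: Mapping[str, int],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    flank: int = 1000,
    direction: str = "greater",
    excluded: Sequence[GenomicInterval] | None = None,
    match_length: bool = True,
) -> PermutationResult:
    """Permutation test for regulator-gene targeting enrichment.

    observed = number of distinct regulator genes targeted by the regions;
    each permutation replaces the regions with random, length- and
    chromosome-matched segments and recounts. The empirical p uses add-one
    smoothing: p(greater) = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not regulator_ids:
        raise ValueError("regulator_ids must be non-empty")
    if direction not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown direction {direction!r}")
    rng = np.random.default_rng(seed)
    hits = _LinkPromoterHits(links, genes, set(regulator_ids), flank)
    observed = hits.count_distinct_genes(regions)
    null_counts = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        perm = random_segments(
            regions, chrom_sizes, excluded=excluded, rng=rng, match_length=match_length
        )
        null_counts[i] = hits.count_distinct_genes(perm)
    p_greater = (1 + int(np.sum(null_counts >= observed))) / (1 + n_perm)
    p_less = (1 + int(np.sum(null_counts <= observed))) / (1 + n_perm)
    if direction == "greater":
        p = p_greater
    elif direction == "less":
        p = p_less
    else:
        p = min(1.0, 2 * min(p_greater, p_less))
    return PermutationResult(observed, null_counts, p, direction)


def fisher_enrichment(
    hit_genes: set[str], category: set[str], universe: set[str]
) -> FisherResult:
    """Two-sided Fisher's exact test for category enrichment among hits.

    Table rows are (hit, non-hit) and columns (in category, not in
    category), over the gene universe.
    """
    if not universe:
        raise ValueError("empty universe")
    if not hit_genes <= universe:
        raise ValueError("hit_genes must be a subset of the universe")
    if not category <= universe:
        raise ValueError("category must be a subset of the universe")
    a = len(hit_genes & category)
    b = len(hit_genes - category)
    c = len(category - hit_genes)
    d = len(universe) - a - b - c
    return fisher_exact_2x2([[a, b], [c, d]])


def read_gene_list(path) -> set[str]:
    """One gene id per line; '#'-prefixed comments and blank lines skipped."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out
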