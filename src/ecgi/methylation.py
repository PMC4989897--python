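"""Differential DNA methylation at CpG resolution and region level.

Beta values are methylation fractions in [0, 1]; the differential
methylation of a CpG is dm = beta_tumor - beta_normal. A region is called
hypermethylated when the mean dm of its CpGs strictly exceeds a threshold
(0.5 for cell-line contrasts, 0.1 for clinical contrasts); an any-CpG mode
is available for the alternative aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalIndex
from .stats import RankTestResult, SignedRankResult, rank_sum_test, signed_rank_test
from .targets import TargetAssignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MethylSite:
    """One CpG (single-bp position on the C) with betas in both conditions."""

    position: GenomicInterval
    beta_normal: float
    beta_tumor: float

    def __post_init__(self) -> None:
        if self.position.length != 1:
            raise ValueError("CpG position must be a width-1 interval")
        for name, beta in (("beta_normal", self.beta_normal), ("beta_tumor", self.beta_tumor)):
            if not 0 <= beta <= 1:
                raise ValueError(
                    f"{name}={beta} out of [0,1] at "
                    f"{self.position.chrom}:{self.position.start}"
                )

    @property
    def dm(self) -> float:
        return self.beta_tumor - self.beta_normal


@dataclass(frozen=True)
class RegionMethylation:
    region_id: str
    n_cpgs: int
    mean_dm: float
    hyper: bool = False


def read_beta_table(path) -> pd.DataFrame:
    """TSV of (chrom, position, beta), 450K-style one value per CpG site."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["chrom", "position", "beta"]
    )
    return df


def differential_methylation(
    betas_normal: pd.DataFrame, betas_tumor: pd.DataFrame
) -> list[MethylSite]:
    """Per-CpG dm over positions present with a valid beta in both conditions.

    Unmatched or missing-beta positions are dropped (count logged). Betas
    outside [0,1] are an error naming the offending position.
    """
    frames = []
    for cond, df in (("normal", betas_normal), ("tumor", betas_tumor)):
        df = df.dropna(subset=["beta"])
        bad = df[(df["beta"] < 0) | (df["beta"] > 1)]
        if len(bad):
            row = bad.iloc[0]
            raise ValueError(
                f"beta out of [0,1] at {row['chrom']}:{int(row['position'])} ({cond})"
            )
        frames.append(df.set_index(["chrom", "position"])["beta"])
    normal, tumor = frames
    merged = pd.concat([normal, tumor], axis=1, keys=["normal", "tumor"], join="inner")
    dropped = len(betas_normal) + len(betas_tumor) - 2 * len(merged)
    if dropped:
        logger.info("differential_methylation: dropped %d unmatched/missing rows", dropped)
    sites = [
        MethylSite(GenomicInterval(chrom, int(pos), int(pos) + 1), row["normal"], row["tumor"])
        for (chrom, pos), row in merged.iterrows()
    ]
    return sites


def aggregate_region_dm(
    sites: Sequence[MethylSite], regions: Sequence[GenomicInterval]
) -> list[RegionMethylation]:
    """Mean dm per region over contained CpGs; CpG-free regions are dropped."""
    idx = IntervalIndex([s.position for s in sites])
    dms = np.array([s.dm for s in sites])
    out = []
    n_empty = 0
    for i, region in enumerate(regions):
        hit = idx.overlapping(region)
        if not hit:
            n_empty += 1
            continue
        out.append(
            RegionMethylation(
                region.name or f"region_{i}", len(hit), float(np.mean(dms[hit]))
            )
        )
    if n_empty:
        logger.info("aggregate_region_dm: %d regions without CpGs dropped", n_empty)
    return out


def select_hypermethylated(
    region_dm: Sequence[RegionMethylation],
    threshold: float = 0.5,
    mode: str = "mean",
    sites: Sequence[MethylSite] | None = None,
    regions: Sequence[GenomicInterval] | None = None,
) -> list[RegionMethylation]:
    """Regions whose dm strictly exceeds ``threshold`` (hyper flag set).

    ``mode='mean'`` (default) compares the region's mean dm; ``mode='any'``
    selects regions containing at least one CpG with dm > threshold, which
    requires passing the sites and regions.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if mode == "mean":
        return [
            RegionMethylation(r.region_id, r.n_cpgs, r.mean_dm, hyper=True)
            for r in region_dm
            if r.mean_dm > threshold
        ]
    if mode == "any":
        if sites is None or regions is None:
            raise ValueError("mode='any' requires sites and regions")
        idx = IntervalIndex([s.position for s in sites])
        dms = np.array([s.dm for s in sites])
        by_id = {r.region_id: r for r in region_dm}
        out = []
        for i, region in enumerate(regions):
            rid = region.name or f"region_{i}"
            if rid not in by_id:
                continue
            hit = idx.overlapping(region)
            if hit and np.any(dms[hit] > threshold):
                r = by_id[rid]
                out.append(RegionMethylation(r.region_id, r.n_cpgs, r.mean_dm, hyper=True))
        return out
    raise ValueError(f"unknown mode {mode!r}")


def class_dm_contrast(
    ecgi_dm: Sequence[RegionMethylation], pcgi_dm: Sequence[RegionMethylation]
) -> tuple[RankTestResult, float, float]:
    """Rank-sum contrast of region mean dm between two CGI classes.

    Returns (test result, median dm of first class, median of second).
    """
    if not ecgi_dm or not pcgi_dm:
        raise ValueError("both classes must be non-empty")
    a = [r.mean_dm for r in ecgi_dm]
    b = [r.mean_dm for r in pcgi_dm]
    return rank_sum_test(a, b), float(np.median(a)), float(np.median(b))


@dataclass(frozen=True)
class SilencingResult:
    fold_changes: dict[str, float]  # per target gene, tumor/normal
    one_sample: SignedRankResult  # log-folds < 0 among hyper-region targets
    hyper_vs_other: RankTestResult | None  # vs targets of non-hyper regions

    @property
    def median_fold(self) -> float:
        return float(np.median(list(self.fold_changes.values())))


def target_silencing(
    hyper_regions: Sequence[RegionMethylation],
    assignments: Sequence[TargetAssignment],
    expr_normal: Mapping[str, float],
    expr_tumor: Mapping[str, float],
    pseudocount: float = 0.1,
) -> SilencingResult:
    """Expression change of genes targeted by hypermethylated regions.

    fold = (tumor + pc) / (normal + pc) per target gene; the one-sample
    signed-rank test asks whether log folds are negative, and a two-sample
    rank-sum test contrasts folds of hyper-region targets against targets
    of the remaining regions (None when the latter are absent).
    """
    hyper_ids = {r.region_id for r in hyper_regions}

    def folds_for(gene_ids):
        out = {}
        for gid in sorted(gene_ids):
            if gid in expr_normal and gid in expr_tumor:
                en, et = float(expr_normal[gid]), float(expr_tumor[gid])
                if en < 0 or et < 0:
                    raise ValueError(f"negative expression value for {gid}")
                out[gid] = (et + pseudocount) / (en + pseudocount)
        return out

    hyper_targets = {a.gene_id for a in assignments if a.region_id in hyper_ids}
    other_targets = {a.gene_id for a in assignments if a.region_id not in hyper_ids}
    other_targets -= hyper_targets
    folds = folds_for(hyper_targets)
    if not folds:
        raise ValueError("no hyper region has an assigned target with expression")
    one_sample = signed_rank_test(np.log(list(folds.values())))
    other_folds = folds_for(other_targets)
    contrast = (
        rank_sum_test(list(folds.values()), list(other_folds.values()))
        if other_folds
        else None
    )
    return SilencingResult(folds, one_sample, contrast)


def dm_matrix(
    sites: Sequence[MethylSite],
    regions: Sequence[GenomicInterval],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Long-form table of differentially methylated CpGs inside regions.

    Rows are (region_id, chrom, position, dm) for in-region CpGs with
    |dm| > threshold — the matrix behind a heatmap, left to external
    rendering. ``threshold=0`` keeps every in-region CpG.
    """
    idx = IntervalIndex([s.position for s in sites])
    rows = []
    for i, region in enumerate(regions):
        rid = region.name or f"region_{i}"
        for si in idx.overlapping(region):
            s = sites[si]
            if abs(s.dm) > threshold:
                rows.append((rid, s.position.chrom, s.position.start, s.dm))
    return pd.DataFrame(rows, columns=["region_id", "chrom", "position", "dm"])
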