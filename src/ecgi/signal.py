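"""Binned mean-signal metaprofiles around region centers and per-region
signal summaries, plus the paired tumor-vs-normal signal-loss test.

Coverage is piecewise-constant (bedGraph semantics); uncovered bases count
as zero signal, so bin means are bp-weighted over the full bin width. A
region's center is floor((start+end)/2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import CoverageTrack, GenomicInterval
from .stats import SignedRankResult, signed_rank_test


@dataclass(frozen=True)
class Metaprofile:
    region_set_name: str
    track_name: str
    flank: int
    n_bins: int
    bin_values: np.ndarray
    n_regions: int

    def offsets_bp(self) -> np.ndarray:
        """Offset of each bin center from the region center, in bp."""
        width = 2 * self.flank / self.n_bins
        return -self.flank + width * (np.arange(self.n_bins) + 0.5)

    def to_rows(self):
        return [
            (i, float(off), float(v))
            for i, (off, v) in enumerate(zip(self.offsets_bp(), self.bin_values))
        ]


def metaprofile(
    regions: Sequence[GenomicInterval],
    coverage: CoverageTrack,
    flank: int = 5000,
    n_bins: int = 200,
    region_set_name: str = "regions",
    track_name: str = "track",
) -> Metaprofile:
    """Mean coverage in ``n_bins`` equal bins over [center-flank, center+flank).

    Per region, each bin's value is its bp-weighted mean coverage; bins are
    then averaged across regions. Bins that fall entirely before the
    chromosome start are undefined for that region and excluded from the
    cross-region average; a bin straddling position 0 averages over its
    defined part only.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if n_bins <= 0:
        raise ValueError("n_bins must be positive")
    if not regions:
        raise ValueError("empty region list")
    width = 2 * flank / n_bins
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for region in regions:
        center = region.center
        edges = center - flank + width * np.arange(n_bins + 1)
        clipped = np.clip(edges, 0, None)
        widths = np.diff(clipped)
        cum = coverage.integral_to(region.chrom, clipped)
        integrals = np.diff(cum)
        defined = widths > 0
        sums[defined] += integrals[defined] / widths[defined]
        counts[defined] += 1
    values = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    return Metaprofile(region_set_name, track_name, flank, n_bins, values, len(regions))


def region_signal(
    regions: Sequence[GenomicInterval], coverage: CoverageTrack
) -> np.ndarray:
    """bp-weighted mean coverage over each region's own span (no flank)."""
    out = np.empty(len(regions))
    for i, r in enumerate(regions):
        out[i] = coverage.window_integral(r.chrom, r.start, r.end) / r.length
    return out


@dataclass(frozen=True)
class SignalLossResult:
    deltas: np.ndarray  # tumor - normal, per region
    test: SignedRankResult

    @property
    def p_loss(self) -> float:
        """One-sided p for a signal reduction in tumor."""
        return self.test.p_less

    @property
    def degenerate(self) -> bool:
        return self.test.degenerate


def signal_loss_test(
    regions: Sequence[GenomicInterval],
    coverage_normal: CoverageTrack,
    coverage_tumor: CoverageTrack,
) -> SignalLossResult:
    """Paired signed-rank test for per-region signal loss (tumor vs normal)."""
    if len(regions) < 2:
        raise ValueError("need at least two regions")
    deltas = region_signal(regions, coverage_tumor) - region_signal(
        regions, coverage_normal
    )
    return SignalLossResult(deltas, signed_rank_test(deltas))
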