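"""CpG-island classification and typical-enhancer calling.

CGIs are partitioned into four classes by a fixed decision cascade:

1. pCGI          — overlaps the +/-1 kb promoter window of a protein-coding gene;
2. orphan_inactive — orphan CGI lacking H3K27ac or DHS peak overlap;
3. npCGI         — active orphan CGI overlapping transcription-start evidence
                   (a CAGE TSS, or a de-novo transcript promoter window);
4. eCGI          — active orphan CGI with no transcription-start evidence.

Promoter status trumps activity; activity trumps transcript evidence. Typical
enhancers are H3K27ac-harboring DHS peaks that overlap no CGI and no
transcription-start evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .intervals import (
    GeneModel,
    GenomicInterval,
    IntervalIndex,
    promoter_window,
)

CGI_CLASSES = ("pCGI", "npCGI", "eCGI", "orphan_inactive")


@dataclass(frozen=True)
class CGIRecord:
    interval: GenomicInterval
    cgi_id: str
    label: str
    gc_percent: float | None = None
    cpg_obs_exp: float | None = None

    def __post_init__(self) -> None:
        if self.label not in CGI_CLASSES:
            raise ValueError(f"unknown CGI class {self.label!r}")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class TypicalEnhancer:
    interval: GenomicInterval
    source_peak_id: str


class MissingTrackError(ValueError):
    """A required evidence track was not supplied."""


def _tss_windows(
    cage_tss: Sequence[GenomicInterval],
    denovo_tss: Sequence[GenomicInterval],
    flank: int,
) -> list[GenomicInterval]:
    """CAGE TSSs are used as given; de-novo transcript TSSs get the same
    +/-flank promoter window as annotated genes."""
    windows = list(cage_tss)
    for t in denovo_tss:
        windows.append(
            GenomicInterval(t.chrom, max(0, t.start - flank), t.end + flank, t.strand, t.name)
        )
    return windows


def classify_cgis(
    cgis: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    h3k27ac_peaks: Sequence[GenomicInterval],
    dhs_peaks: Sequence[GenomicInterval],
    cage_tss: Sequence[GenomicInterval],
    denovo_tss: Sequence[GenomicInterval],
    flank: int = 1000,
) -> list[CGIRecord]:
    """Apply the classification cascade to every CGI.

    Returns one :class:`CGIRecord` per input CGI, in input order. CGI ids are
    taken from the interval names, falling back to ``CGI_<i>``.
    """
    for track, name in ((h3k27ac_peaks, "h3k27ac"), (dhs_peaks, "dhs")):
        if track is None:
            raise MissingTrackError(f"required track missing: {name}")
    promoters = IntervalIndex(
        [promoter_window(g, flank) for g in genes if g.coding]
    )
    k27 = IntervalIndex(h3k27ac_peaks)
    dhs = IntervalIndex(dhs_peaks)
    tss_ev = IntervalIndex(_tss_windows(cage_tss, denovo_tss, flank))

    records = []
    for i, cgi in enumerate(cgis):
        cgi_id = cgi.name or f"CGI_{i}"
        if promoters.any_overlap(cgi):
            label = "pCGI"
        elif not (k27.any_overlap(cgi) and dhs.any_overlap(cgi)):
            label = "orphan_inactive"
        elif tss_ev.any_overlap(cgi):
            label = "npCGI"
        else:
            label = "eCGI"
        records.append(CGIRecord(cgi, cgi_id, label))
    return records


def call_typical_enhancers(
    h3k27ac_peaks: Sequence[GenomicInterval],
    dhs_peaks: Sequence[GenomicInterval],
    cage_tss: Sequence[GenomicInterval],
    denovo_tss: Sequence[GenomicInterval],
    cgis: Sequence[GenomicInterval],
    flank: int = 1000,
) -> list[TypicalEnhancer]:
    """DHS peaks that harbor H3K27ac but avoid CGIs and TSS evidence.

    Enhancer coordinates are the DHS peak coordinates; H3K27ac is a required
    overlapping mark.
    """
    k27 = IntervalIndex(h3k27ac_peaks)
    cgi_idx = IntervalIndex(cgis)
    tss_ev = IntervalIndex(_tss_windows(cage_tss, denovo_tss, flank))
    out = []
    for i, peak in enumerate(dhs_peaks):
        if not k27.any_overlap(peak):
            continue
        if cgi_idx.any_overlap(peak) or tss_ev.any_overlap(peak):
            continue
        out.append(TypicalEnhancer(peak, peak.name or f"DHS_{i}"))
    return out


def sequence_stats(sequence: str) -> tuple[int, float, float]:
    """Length, GC percent and Gardiner-Garden CpG observed/expected ratio.

    Ns are excluded: the effective length is the non-N base count and CpG
    dinucleotides involving an N are not counted. A zero C or G count gives
    an obs/exp ratio of 0.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over A/C/G/T/N")
    n_c = seq.count("C")
    n_g = seq.count("G")
    eff_len = len(seq) - seq.count("N")
    if eff_len == 0:
        return len(seq), 0.0, 0.0
    n_cpg = sum(1 for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G")
    gc_percent = 100.0 * (n_c + n_g) / eff_len
    obs_exp = (n_cpg * eff_len) / (n_c * n_g) if n_c and n_g else 0.0
    return len(seq), gc_percent, obs_exp


def cell_specific_sets(
    regions_a: Sequence[CGIRecord], regions_b: Sequence[CGIRecord]
) -> dict:
    """Cell-type-specific and shared eCGI sets, matched by cgi_id.

    ``a_specific_pct`` is the share of cell A's eCGIs that are A-specific:
    100 * |a_specific| / (|a_specific| + |common|); likewise for B.
    """
    ids_a = [r.cgi_id for r in regions_a]
    ids_b = [r.cgi_id for r in regions_b]
    for label, ids in (("A", ids_a), ("B", ids_b)):
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate cgi_id in list {label}")
    set_a, set_b = set(ids_a), set(ids_b)
    common = set_a & set_b
    a_specific = set_a - common
    b_specific = set_b - common
    n_a = len(a_specific) + len(common)
    n_b = len(b_specific) + len(common)
    return {
        "a_specific": a_specific,
        "b_specific": b_specific,
        "common": common,
        "a_specific_pct": 100.0 * len(a_specific) / n_a if n_a else 0.0,
        "b_specific_pct": 100.0 * len(b_specific) / n_b if n_b else 0.0,
    }


def class_counts(records: Sequence[CGIRecord]) -> dict[str, int]:
    counts = {c: 0 for c in CGI_CLASSES}
    for r in records:
        counts[r.label] += 1
    return counts
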