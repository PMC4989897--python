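"""Synthetic multi-track epigenome with planted ground truth.

Generates an internally consistent toy dataset — genes, CpG islands,
H3K27ac/DHS peaks, CAGE and de-novo TSS evidence, coverage tracks,
ChIA-PET links, methylation betas and expression tables — in which every
quantity the pipeline estimates is planted by construction:

* CGI class labels follow the classification cascade exactly when
  ``peak_dropout`` is 0 (pCGIs sit on coding-gene promoters, npCGIs carry a
  CAGE TSS, eCGIs carry both peaks and no TSS evidence, inactive orphans
  lack at least one peak);
* each eCGI is looped to one or several same-chromosome gene promoters,
  preferring transcription-regulator genes by ``regulator_enrichment``;
* a chosen set of eCGIs is hypermethylated in the tumor condition
  (``planted_dm`` + Gaussian CpG noise) with expression of their target
  genes divided by ``silencing_fold`` and peak coverage halved.

Entities are laid out on a slot grid (one entity per 20 kb slot) so that no
planted element contaminates another's promoter window or peak overlap; the
identifiability of the planted labels is therefore exact at zero noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import CGI_CLASSES
from .intervals import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    write_bed,
    write_genes,
)
from .targets import ChiaLink, write_links

SLOT_BP = 20_000


def _default_chrom_sizes() -> dict[str, int]:
    return {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}


def _default_class_mix() -> dict[str, float]:
    return {"pCGI": 0.50, "npCGI": 0.15, "eCGI": 0.20, "orphan_inactive": 0.15}


@dataclass
class SynthConfig:
    seed: int = 17
    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    n_genes: int = 400
    n_cgis: int = 600
    class_mix: dict[str, float] = field(default_factory=_default_class_mix)
    frac_multi_target: float = 0.6
    regulator_enrichment: float = 3.0
    n_hyper_ecgis: int = 30
    planted_dm: float = 0.6
    dm_noise_sd: float = 0.05
    silencing_fold: float = 3.0
    peak_dropout: float = 0.0
    tag_count_shift: int = 2
    # secondary knobs
    n_typical_enhancers: int = 100
    frac_regulator_genes: float = 0.25
    frac_coding: float = 0.85
    cpgs_per_cgi: int = 25
    bg_cpg_rate: float = 1 / 2000  # background CpG density outside CGIs
    up_fold: float = 4.0  # cell-A over cell-B expression for eCGI targets
    expr_log2_sd: float = 0.3
    signal_loss_factor: float = 0.5  # tumor coverage multiplier at hyper eCGIs
    flank: int = 1000

    def validate(self) -> None:
        if set(self.class_mix) != set(CGI_CLASSES):
            raise ValueError(f"class_mix must cover exactly {CGI_CLASSES}")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1 (got {total})")
        if any(v < 0 for v in self.class_mix.values()):
            raise ValueError("class_mix proportions must be non-negative")
        if not 0 <= self.peak_dropout <= 1:
            raise ValueError("peak_dropout must be a probability")
        if self.silencing_fold <= 1 or self.up_fold <= 1:
            raise ValueError("fold parameters must exceed 1")


@dataclass
class GroundTruth:
    cgi_labels: dict[str, str] = field(default_factory=dict)
    ecgi_targets: dict[str, set[str]] = field(default_factory=dict)
    hyper_ecgis: set[str] = field(default_factory=set)
    silenced_genes: set[str] = field(default_factory=set)
    regulator_genes: set[str] = field(default_factory=set)
    tsg_genes: set[str] = field(default_factory=set)
    oncogenes: set[str] = field(default_factory=set)

    def to_jsonable(self) -> dict:
        return {
            "cgi_labels": dict(sorted(self.cgi_labels.items())),
            "ecgi_targets": {k: sorted(v) for k, v in sorted(self.ecgi_targets.items())},
            "hyper_ecgis": sorted(self.hyper_ecgis),
            "silenced_genes": sorted(self.silenced_genes),
            "regulator_genes": sorted(self.regulator_genes),
            "tsg_genes": sorted(self.tsg_genes),
            "oncogenes": sorted(self.oncogenes),
        }

    @classmethod
    def from_jsonable(cls, d: Mapping) -> "GroundTruth":
        return cls(
            cgi_labels=dict(d["cgi_labels"]),
            ecgi_targets={k: set(v) for k, v in d["ecgi_targets"].items()},
            hyper_ecgis=set(d["hyper_ecgis"]),
            silenced_genes=set(d["silenced_genes"]),
            regulator_genes=set(d["regulator_genes"]),
            tsg_genes=set(d["tsg_genes"]),
            oncogenes=set(d["oncogenes"]),
        )


def write_manifest(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_jsonable(json.load(fh))


@dataclass
class SyntheticDataset:
    config: SynthConfig
    genes: list[GeneModel]
    cgis: list[GenomicInterval]
    h3k27ac_peaks: list[GenomicInterval]
    dhs_peaks: list[GenomicInterval]
    cage_tss: list[GenomicInterval]
    denovo_tss: list[GenomicInterval]
    links: list[ChiaLink]
    betas_normal: pd.DataFrame
    betas_tumor: pd.DataFrame
    expr_normal: dict[str, float]
    expr_tumor: dict[str, float]
    expr_cell_b: dict[str, float]
    coverage: dict[str, CoverageTrack]
    truth: GroundTruth

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return self.config.chrom_sizes

    def cgis_labeled(self, label: str) -> list[GenomicInterval]:
        return [c for c in self.cgis if self.truth.cgi_labels[c.name] == label]

    def write(self, outdir) -> dict[str, str]:
        """Emit every layer in the formats the pipeline reads; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}

        def p(name: str) -> str:
            paths[name.split(".")[0]] = str(outdir / name)
            return str(outdir / name)

        write_bed(self.cgis, p("cgis.bed"))
        write_genes(self.genes, p("genes.tsv"))
        write_bed(self.h3k27ac_peaks, p("h3k27ac.bed"))
        write_bed(self.dhs_peaks, p("dhs.bed"))
        write_bed(self.cage_tss, p("cage_tss.bed"))
        write_bed(self.denovo_tss, p("denovo_tss.bed"))
        write_links(self.links, p("links.bedpe"))
        for cond, df in (("normal", self.betas_normal), ("tumor", self.betas_tumor)):
            df.to_csv(p(f"beta_{cond}.tsv"), sep="\t", header=False, index=False)
        for name, table in (
            ("expression_normal", self.expr_normal),
            ("expression_tumor", self.expr_tumor),
            ("expression_cellB", self.expr_cell_b),
        ):
            with open(p(f"{name}.tsv"), "w") as fh:
                for gid in sorted(table):
                    fh.write(f"{gid}\t{table[gid]:.6g}\n")
        for name, track in self.coverage.items():
            track.write_bedgraph(p(f"{name}.bedgraph"))
        with open(p("chrom_sizes.tsv"), "w") as fh:
            for chrom, size in sorted(self.config.chrom_sizes.items()):
                fh.write(f"{chrom}\t{size}\n")
        for list_name, gene_set in (
            ("regulators", self.truth.regulator_genes),
            ("tsg", self.truth.tsg_genes),
            ("oncogenes", self.truth.oncogenes),
        ):
            with open(p(f"{list_name}.txt"), "w") as fh:
                for gid in sorted(gene_set):
                    fh.write(gid + "\n")
        write_manifest(self.truth, p("ground_truth.json"))
        return paths


def _apportion(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n items to the class mix."""
    keys = list(CGI_CLASSES)
    raw = np.array([mix[k] * n for k in keys])
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    return dict(zip(keys, base.tolist()))


def generate(config: SynthConfig) -> SyntheticDataset:
    """Build the full dataset in memory; deterministic given config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    # dedicated stream for peak dropout: varying peak_dropout then leaves the
    # rest of the dataset untouched and makes dropped-eCGI sets nested in p
    rng_drop = np.random.default_rng([config.seed, 1])
    counts = _apportion(config.n_cgis, config.class_mix)
    n_orphan = counts["npCGI"] + counts["eCGI"] + counts["orphan_inactive"]

    # --- slot grid: one entity per slot, so planted overlaps are exact
    slots = [
        (chrom, i * SLOT_BP)
        for chrom, size in sorted(config.chrom_sizes.items())
        for i in range(size // SLOT_BP)
    ]
    n_needed = config.n_genes + n_orphan + config.n_typical_enhancers
    if n_needed > len(slots):
        raise ValueError(
            f"infeasible placement: {n_needed} entities for {len(slots)} slots; "
            "increase chrom_sizes or reduce counts"
        )
    slot_order = rng.permutation(len(slots))
    cursor = 0

    def take_slots(n: int) -> list[tuple[str, int]]:
        nonlocal cursor
        chosen = [slots[i] for i in slot_order[cursor : cursor + n]]
        cursor += n
        return chosen

    # --- genes, CAGE/de-novo TSS evidence at their promoters
    genes: list[GeneModel] = []
    cage: list[GenomicInterval] = []
    denovo: list[GenomicInterval] = []
    n_coding = int(round(config.frac_coding * config.n_genes))
    for i, (chrom, s0) in enumerate(take_slots(config.n_genes)):
        strand = "+" if rng.random() < 0.5 else "-"
        tss = s0 + SLOT_BP // 2
        length = int(rng.integers(2000, 8000))
        if strand == "+":
            iv = GenomicInterval(chrom, tss, tss + length, strand)
        else:
            iv = GenomicInterval(chrom, tss - length + 1, tss + 1, strand)
        gid = f"GENE_{i:04d}"
        genes.append(GeneModel(iv, gid, coding=i < n_coding))
        cage.append(GenomicInterval(chrom, tss - 25, tss + 25, strand, f"cage_{gid}"))
        if rng.random() < 0.5:
            denovo.append(GenomicInterval(chrom, tss - 10, tss + 10, strand, f"dn_{gid}"))
    coding_genes = [g for g in genes if g.coding]
    if counts["pCGI"] > len(coding_genes):
        raise ValueError("not enough coding genes to host the requested pCGIs")

    # --- CGIs per class
    cgis: list[GenomicInterval] = []
    labels: dict[str, str] = {}
    h3k27ac: list[GenomicInterval] = []
    dhs: list[GenomicInterval] = []

    def add_peaks(chrom: str, lo: int, hi: int, who: str, dropout: bool) -> None:
        """Plant a DHS and an H3K27ac peak covering [lo, hi)."""
        drop_k27 = drop_dhs = False
        if dropout:
            u, side = rng_drop.random(), rng_drop.random()
            if u < config.peak_dropout:
                if side < 0.5:
                    drop_k27 = True
                else:
                    drop_dhs = True
        if not drop_dhs:
            dhs.append(GenomicInterval(chrom, max(0, lo - 100), hi + 100, ".", f"dhs_{who}"))
        if not drop_k27:
            h3k27ac.append(
                GenomicInterval(chrom, max(0, lo - 200), hi + 200, ".", f"k27_{who}")
            )

    cgi_i = 0

    def new_cgi(chrom: str, center: int, label: str) -> GenomicInterval:
        nonlocal cgi_i
        length = int(rng.integers(500, 2000))
        start = max(0, center - length // 2)
        cgi = GenomicInterval(chrom, start, start + length, ".", f"CGI_{cgi_i:04d}")
        cgi_i += 1
        cgis.append(cgi)
        labels[cgi.name] = label
        return cgi

    # pCGIs sit on coding-gene promoters (and are active, as real promoters are)
    host_idx = rng.choice(len(coding_genes), size=counts["pCGI"], replace=False)
    for gi in host_idx:
        g = coding_genes[int(gi)]
        offset = int(rng.integers(-400, 401))
        cgi = new_cgi(g.chrom, g.tss + offset, "pCGI")
        add_peaks(cgi.chrom, cgi.start, cgi.end, cgi.name, dropout=False)

    for chrom, s0 in take_slots(counts["npCGI"]):
        cgi = new_cgi(chrom, s0 + SLOT_BP // 2, "npCGI")
        add_peaks(cgi.chrom, cgi.start, cgi.end, cgi.name, dropout=False)
        mid = cgi.center
        cage.append(GenomicInterval(chrom, mid - 25, mid + 25, ".", f"cage_{cgi.name}"))

    for chrom, s0 in take_slots(counts["eCGI"]):
        cgi = new_cgi(chrom, s0 + SLOT_BP // 2, "eCGI")
        add_peaks(cgi.chrom, cgi.start, cgi.end, cgi.name, dropout=True)

    for chrom, s0 in take_slots(counts["orphan_inactive"]):
        cgi = new_cgi(chrom, s0 + SLOT_BP // 2, "orphan_inactive")
        # at most one of the two required marks
        roll = rng.random()
        if roll < 1 / 3:
            dhs.append(GenomicInterval(chrom, cgi.start, cgi.end, ".", f"dhs_{cgi.name}"))
        elif roll < 2 / 3:
            h3k27ac.append(GenomicInterval(chrom, cgi.start, cgi.end, ".", f"k27_{cgi.name}"))

    # --- typical enhancers: DHS+H3K27ac pairs away from CGIs and TSSs
    typical: list[GenomicInterval] = []
    for i, (chrom, s0) in enumerate(take_slots(config.n_typical_enhancers)):
        c = s0 + SLOT_BP // 2
        peak = GenomicInterval(chrom, c - 500, c + 500, ".", f"TE_{i:04d}")
        typical.append(peak)
        dhs.append(peak)
        h3k27ac.append(GenomicInterval(chrom, c - 600, c + 600, ".", f"k27_TE_{i:04d}"))

    # --- gene categories
    gene_ids = [g.gene_id for g in genes]
    n_reg = int(round(config.frac_regulator_genes * config.n_genes))
    regulators = set(
        np.array(gene_ids)[rng.choice(config.n_genes, size=n_reg, replace=False)].tolist()
    )

    # --- ChIA-PET links: eCGIs loop to same-chromosome promoters with
    #     regulator preference and elevated tag counts
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    links: list[ChiaLink] = []
    ecgi_targets: dict[str, set[str]] = {}

    def promoter_anchor(g: GeneModel) -> GenomicInterval:
        return GenomicInterval(g.chrom, max(0, g.tss - 100), g.tss + 101)

    ecgi_list = [c for c in cgis if labels[c.name] == "eCGI"]
    for cgi in ecgi_list:
        cands = genes_by_chrom.get(cgi.chrom, [])
        if not cands:
            continue
        n_t = 1 if rng.random() >= config.frac_multi_target else int(rng.integers(2, 4))
        n_t = min(n_t, len(cands))
        w = np.array(
            [config.regulator_enrichment if g.gene_id in regulators else 1.0 for g in cands]
        )
        chosen = rng.choice(len(cands), size=n_t, replace=False, p=w / w.sum())
        targets = set()
        for ci in np.sort(chosen):
            g = cands[int(ci)]
            targets.add(g.gene_id)
            tags = 3 + config.tag_count_shift + int(rng.poisson(1.0))
            anchor_r = GenomicInterval(cgi.chrom, cgi.start, min(cgi.end, cgi.start + 200))
            links.append(ChiaLink(anchor_r, promoter_anchor(g), tags))
        ecgi_targets[cgi.name] = targets

    # typical enhancers loop with no regulator preference and baseline tags
    for peak in typical:
        cands = genes_by_chrom.get(peak.chrom, [])
        if not cands:
            continue
        n_t = 1 if rng.random() >= 0.2 else 2
        chosen = rng.choice(len(cands), size=min(n_t, len(cands)), replace=False)
        for ci in np.sort(chosen):
            g = cands[int(ci)]
            tags = 3 + int(rng.poisson(1.0))
            anchor_r = GenomicInterval(peak.chrom, peak.start, peak.start + 200)
            links.append(ChiaLink(anchor_r, promoter_anchor(g), tags))

    # sub-threshold noise links exercising the tag-count filter
    chroms = sorted(config.chrom_sizes)
    for _ in range(len(ecgi_list)):
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = config.chrom_sizes[chrom]
        s1 = int(rng.integers(0, size - 200))
        s2 = int(rng.integers(0, size - 200))
        links.append(
            ChiaLink(
                GenomicInterval(chrom, s1, s1 + 200),
                GenomicInterval(chrom, s2, s2 + 200),
                int(rng.integers(1, 3)),
            )
        )

    # --- methylation: CpGs in CGIs plus sparse background CpGs
    hyper_n = min(config.n_hyper_ecgis, len(ecgi_list))
    hyper_ids = {
        ecgi_list[int(i)].name
        for i in rng.choice(len(ecgi_list), size=hyper_n, replace=False)
    }
    rows = []  # (chrom, pos, beta_normal, beta_tumor)
    for cgi in cgis:
        pos = np.unique(
            np.linspace(cgi.start, cgi.end - 1, config.cpgs_per_cgi).round().astype(int)
        )
        bn = rng.beta(1.5, 15.0, size=pos.size)
        shift = config.planted_dm if cgi.name in hyper_ids else 0.0
        bt = np.clip(bn + shift + rng.normal(0, config.dm_noise_sd, size=pos.size), 0, 1)
        for p_, a, b in zip(pos, bn, bt):
            rows.append((cgi.chrom, int(p_), float(a), float(b)))
    cgi_idx_pos = {(r[0], r[1]) for r in rows}
    for chrom in chroms:
        size = config.chrom_sizes[chrom]
        n_bg = int(size * config.bg_cpg_rate)
        pos = np.unique(rng.integers(0, size, size=n_bg))
        bn = rng.beta(8.0, 2.0, size=pos.size)
        bt = np.clip(bn + rng.normal(0, config.dm_noise_sd, size=pos.size), 0, 1)
        for p_, a, b in zip(pos, bn, bt):
            if (chrom, int(p_)) not in cgi_idx_pos:
                rows.append((chrom, int(p_), float(a), float(b)))
    rows.sort(key=lambda r: (r[0], r[1]))
    betas_normal = pd.DataFrame(
        [(c, p_, round(a, 6)) for c, p_, a, _ in rows], columns=["chrom", "position", "beta"]
    )
    betas_tumor = pd.DataFrame(
        [(c, p_, round(b, 6)) for c, p_, _, b in rows], columns=["chrom", "position", "beta"]
    )

    # --- expression: silencing of hyper-eCGI targets in tumor; cell-B
    #     down-shift of all eCGI targets (so A-specific targets are up in A)
    silenced = set().union(*(ecgi_targets[c] for c in hyper_ids if c in ecgi_targets)) \
        if hyper_ids else set()
    all_targets = set().union(*ecgi_targets.values()) if ecgi_targets else set()
    expr_normal: dict[str, float] = {}
    expr_tumor: dict[str, float] = {}
    expr_cell_b: dict[str, float] = {}
    for g in genes:
        base = float(2 ** rng.normal(np.log2(10.0), 2.0))
        expr_normal[g.gene_id] = base
        tumor = base / (config.silencing_fold if g.gene_id in silenced else 1.0)
        expr_tumor[g.gene_id] = tumor * float(2 ** rng.normal(0, config.expr_log2_sd))
        cell_b = base / (config.up_fold if g.gene_id in all_targets else 1.0)
        expr_cell_b[g.gene_id] = cell_b * float(2 ** rng.normal(0, config.expr_log2_sd))

    # --- gene categories for the Fisher stage: TSGs overlap silenced genes
    non_silenced = sorted(set(gene_ids) - silenced)
    n_extra = len(silenced)
    extra = rng.choice(len(non_silenced), size=min(n_extra, len(non_silenced)), replace=False)
    tsg = set(silenced) | {non_silenced[int(i)] for i in extra}
    onco_pool = sorted(set(non_silenced) - tsg)
    n_onco = min(max(20, len(tsg)), len(onco_pool))
    onco = {onco_pool[int(i)] for i in rng.choice(len(onco_pool), size=n_onco, replace=False)}

    # --- coverage tracks: flat peak-height segments; tumor loses signal at
    #     hypermethylated eCGIs
    hyper_index = {c.name for c in ecgi_list if c.name in hyper_ids}
    hyper_ivs = [c for c in ecgi_list if c.name in hyper_index]

    def build_tracks(peaks: list[GenomicInterval]):
        segs_n, segs_t = [], []
        for peak in peaks:
            h = float(rng.uniform(5.0, 15.0))
            segs_n.append((peak.chrom, peak.start, peak.end, round(h, 4)))
            lost = any(
                peak.chrom == c.chrom and peak.start < c.end and c.start < peak.end
                for c in hyper_ivs
            )
            h_t = h * config.signal_loss_factor if lost else h
            segs_t.append((peak.chrom, peak.start, peak.end, round(h_t, 4)))
        return CoverageTrack.from_segments(segs_n), CoverageTrack.from_segments(segs_t)

    dhs_n, dhs_t = build_tracks(dhs)
    k27_n, k27_t = build_tracks(h3k27ac)

    truth = GroundTruth(
        cgi_labels=labels,
        ecgi_targets=ecgi_targets,
        hyper_ecgis=hyper_ids,
        silenced_genes=silenced,
        regulator_genes=regulators,
        tsg_genes=tsg,
        oncogenes=onco,
    )
    return SyntheticDataset(
        config=config,
        genes=genes,
        cgis=cgis,
        h3k27ac_peaks=h3k27ac,
        dhs_peaks=dhs,
        cage_tss=cage,
        denovo_tss=denovo,
        links=links,
        betas_normal=betas_normal,
        betas_tumor=betas_tumor,
        expr_normal=expr_normal,
        expr_tumor=expr_tumor,
        expr_cell_b=expr_cell_b,
        coverage={
            "dhs_normal": dhs_n,
            "dhs_tumor": dhs_t,
            "h3k27ac_normal": k27_n,
            "h3k27ac_tumor": k27_t,
        },
        truth=truth,
    )
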