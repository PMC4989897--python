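"""End-to-end orchestration: classification, enhancer calling, profiles,
targets, enrichment and methylation from a single config.

Stages run in a fixed order and share one seed; every random step draws
from a generator seeded by ``config.seed``, so a rerun with identical
inputs produces a byte-identical report. Stages whose inputs are absent
are skipped and marked as such in the report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify as cls
from . import enrichment as enr
from . import methylation as meth
from . import signal as sig
from . import targets as tgt
from .intervals import CoverageTrack, read_bed, read_genes, write_bed

logger = logging.getLogger(__name__)

REQUIRED_TRACKS = ("cgis", "genes", "h3k27ac", "dhs", "cage_tss", "denovo_tss")


class ConfigurationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # input paths (required)
    cgis: str = ""
    genes: str = ""
    h3k27ac: str = ""
    dhs: str = ""
    cage_tss: str = ""
    denovo_tss: str = ""
    # optional layers
    links: str | None = None
    chrom_sizes: str | None = None
    regulators: str | None = None
    tsg: str | None = None
    oncogenes: str | None = None
    beta_normal: str | None = None
    beta_tumor: str | None = None
    expression_normal: str | None = None
    expression_tumor: str | None = None
    expression_cell_b: str | None = None
    coverage: dict[str, str] = field(default_factory=dict)
    # constants
    flank: int = 1000
    profile_flank: int = 5000
    n_bins: int = 200
    min_tags: int = 3
    n_perm: int = 1000
    dm_threshold_cell: float = 0.5
    dm_threshold_clinical: float = 0.1
    pseudocount: float = 0.1
    seed: int = 17

    @classmethod
    def from_yaml(cls_, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls_(**raw)

    def validate(self) -> None:
        for name in REQUIRED_TRACKS:
            value = getattr(self, name)
            if not value:
                raise ConfigurationError(f"missing required track: {name}")
            if not Path(value).exists():
                raise ConfigurationError(f"required track {name} not found: {value}")


def _read_expr(path) -> dict[str, float]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gid, value = line.split("\t")[:2]
            out[gid] = float(value)
    return out


def _read_chrom_sizes(path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split("\t")[:2]
                out[chrom] = int(size)
    return out


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every applicable stage; write and return the JSON report."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": []}

    def stage(name):
        t0 = time.perf_counter()
        report["stages"].append(name)
        logger.info("stage %s starting", name)
        return t0

    def done(name, t0):
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)

    # --- classification
    t0 = stage("classify")
    cgis = read_bed(config.cgis)
    genes = read_genes(config.genes)
    records = cls.classify_cgis(
        cgis,
        genes,
        read_bed(config.h3k27ac),
        read_bed(config.dhs),
        read_bed(config.cage_tss),
        read_bed(config.denovo_tss),
        flank=config.flank,
    )
    counts = cls.class_counts(records)
    report["class_counts"] = counts
    report["n_cgis"] = len(records)
    write_bed(
        [r.interval for r in records],
        outdir / "cgi_classes.bed",
        extra=[r.label for r in records],
    )
    ecgis = [r.interval for r in records if r.label == "eCGI"]
    pcgis = [r.interval for r in records if r.label == "pCGI"]
    done("classify", t0)

    # --- typical enhancers
    t0 = stage("typical_enhancers")
    typical = cls.call_typical_enhancers(
        read_bed(config.h3k27ac),
        read_bed(config.dhs),
        read_bed(config.cage_tss),
        read_bed(config.denovo_tss),
        cgis,
        flank=config.flank,
    )
    report["n_typical_enhancers"] = len(typical)
    write_bed([t.interval for t in typical], outdir / "typical_enhancers.bed")
    done("typical_enhancers", t0)

    # --- signal metaprofiles
    if config.coverage and ecgis:
        t0 = stage("profiles")
        profiles = {}
        for track_name, path in sorted(config.coverage.items()):
            track = CoverageTrack.read_bedgraph(path)
            for set_name, regions in (
                ("eCGI", ecgis),
                ("typical_enhancer", [t.interval for t in typical]),
                ("pCGI", pcgis),
            ):
                if not regions:
                    continue
                prof = sig.metaprofile(
                    regions, track, config.profile_flank, config.n_bins,
                    region_set_name=set_name, track_name=track_name,
                )
                key = f"{set_name}:{track_name}"
                profiles[key] = float(np.mean(prof.bin_values))
                with open(outdir / f"profile_{set_name}_{track_name}.tsv", "w") as fh:
                    for i, off, v in prof.to_rows():
                        fh.write(f"{i}\t{off:g}\t{v:.6g}\n")
        report["profile_mean_signal"] = profiles
        done("profiles", t0)

    # --- targets
    assignments: list[tgt.TargetAssignment] = []
    if config.links:
        t0 = stage("targets")
        links = tgt.filter_links(tgt.read_links(config.links), config.min_tags)
        report["n_links_filtered"] = len(links)
        assignments = tgt.assign_targets(ecgis, links, genes, flank=config.flank)
        with open(outdir / "target_assignments.tsv", "w") as fh:
            for a in assignments:
                fh.write(f"{a.region_id}\t{a.gene_id}\t{a.tag_count}\t{a.evidence}\n")
        if assignments:
            single, multiple = tgt.target_multiplicity(assignments)
            report["ecgi_fraction_single"] = round(single, 6)
            report["ecgi_fraction_multiple"] = round(multiple, 6)
        te_assign = tgt.assign_targets(
            [t.interval for t in typical], links, genes, flank=config.flank
        )
        if assignments and te_assign:
            res = tgt.compare_link_strength(
                [a.tag_count for a in assignments], [a.tag_count for a in te_assign]
            )
            report["link_strength_p_greater"] = float(res.p_greater)
        done("targets", t0)

    # --- expression fold change across cell types
    if assignments and config.expression_normal and config.expression_cell_b:
        t0 = stage("expression_fold")
        folds = tgt.expression_fold_change(
            assignments,
            _read_expr(config.expression_normal),
            _read_expr(config.expression_cell_b),
            pseudocount=config.pseudocount,
        )
        if folds:
            report["target_fold_vs_cell_b_median"] = float(
                np.median(list(folds.values()))
            )
        done("expression_fold", t0)

    # --- permutation enrichment of regulator targeting
    if config.links and config.regulators and config.chrom_sizes and ecgis:
        t0 = stage("enrichment")
        regulators = enr.read_gene_list(config.regulators)
        sizes = _read_chrom_sizes(config.chrom_sizes)
        links = tgt.filter_links(tgt.read_links(config.links), config.min_tags)
        rng = np.random.default_rng(config.seed)
        perm = enr.permutation_enrichment(
            ecgis, links, genes, regulators, sizes,
            n_perm=config.n_perm, seed=rng, flank=config.flank,
        )
        report["regulator_perm"] = {
            "observed": perm.observed,
            "null_mean": float(np.mean(perm.null_counts)),
            "p_greater": perm.p_value,
        }
        if typical:
            perm_te = enr.permutation_enrichment(
                [t.interval for t in typical], links, genes, regulators, sizes,
                n_perm=config.n_perm, seed=rng, flank=config.flank, direction="less",
            )
            report["regulator_perm_typical"] = {
                "observed": perm_te.observed,
                "null_mean": float(np.mean(perm_te.null_counts)),
                "p_less": perm_te.p_value,
            }
        np.savetxt(outdir / "perm_null_counts.tsv", perm.null_counts, fmt="%d")
        done("enrichment", t0)

    # --- methylation
    if config.beta_normal and config.beta_tumor and ecgis:
        t0 = stage("methylation")
        sites = meth.differential_methylation(
            meth.read_beta_table(config.beta_normal),
            meth.read_beta_table(config.beta_tumor),
        )
        ecgi_dm = meth.aggregate_region_dm(sites, ecgis)
        pcgi_dm = meth.aggregate_region_dm(sites, pcgis)
        hyper = meth.select_hypermethylated(ecgi_dm, config.dm_threshold_cell)
        report["n_hyper_ecgis"] = len(hyper)
        report["hyper_ecgi_ids"] = sorted(r.region_id for r in hyper)
        if ecgi_dm and pcgi_dm:
            contrast, med_e, med_p = meth.class_dm_contrast(ecgi_dm, pcgi_dm)
            report["class_dm_contrast"] = {
                "p_greater": float(contrast.p_greater),
                "median_ecgi_dm": round(med_e, 6),
                "median_pcgi_dm": round(med_p, 6),
            }
        with open(outdir / "region_methylation.tsv", "w") as fh:
            hyper_ids = {r.region_id for r in hyper}
            for r in ecgi_dm:
                fh.write(
                    f"{r.region_id}\t{r.n_cpgs}\t{r.mean_dm:.6g}\t"
                    f"{int(r.region_id in hyper_ids)}\n"
                )
        matrix = meth.dm_matrix(sites, ecgis, config.dm_threshold_cell)
        matrix.to_csv(outdir / "dm_matrix.tsv", sep="\t", index=False)

        # target silencing; nearest-gene fallback when no interaction data
        if hyper and config.expression_normal and config.expression_tumor:
            silo_assign = assignments or tgt.assign_nearest(ecgis, genes)
            try:
                silencing = meth.target_silencing(
                    hyper,
                    silo_assign,
                    _read_expr(config.expression_normal),
                    _read_expr(config.expression_tumor),
                    pseudocount=config.pseudocount,
                )
            except ValueError:
                silencing = None
            if silencing is not None:
                report["silencing"] = {
                    "median_fold": round(silencing.median_fold, 6),
                    "p_down": float(silencing.one_sample.p_less),
                    "n_targets": len(silencing.fold_changes),
                }
                hyper_targets = set(silencing.fold_changes)
                for cat_name, cat_path in (("tsg", config.tsg), ("oncogene", config.oncogenes)):
                    if cat_path:
                        universe = {g.gene_id for g in genes}
                        res = enr.fisher_enrichment(
                            hyper_targets & universe,
                            enr.read_gene_list(cat_path) & universe,
                            universe,
                        )
                        if np.isnan(res.odds_ratio):
                            odds = None
                        elif np.isinf(res.odds_ratio):
                            odds = "inf"  # strict JSON has no Infinity literal
                        else:
                            odds = round(res.odds_ratio, 6)
                        report[f"fisher_{cat_name}"] = {
                            "odds_ratio": odds,
                            "p_value": float(res.p_value),
                        }
        # signal loss at hypermethylated eCGIs
        if hyper and config.coverage:
            hyper_ids = {r.region_id for r in hyper}
            hyper_ivs = [iv for iv in ecgis if (iv.name or "") in hyper_ids]
            loss = {}
            for mark in ("dhs", "h3k27ac"):
                cn, ct = config.coverage.get(f"{mark}_normal"), config.coverage.get(
                    f"{mark}_tumor"
                )
                if cn and ct and len(hyper_ivs) >= 2:
                    res = sig.signal_loss_test(
                        hyper_ivs,
                        CoverageTrack.read_bedgraph(cn),
                        CoverageTrack.read_bedgraph(ct),
                    )
                    loss[mark] = {
                        "mean_delta": round(float(np.mean(res.deltas)), 6),
                        "p_loss": float(res.p_loss),
                    }
            if loss:
                report["signal_loss"] = loss
        done("methylation", t0)

    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
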