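"""Tumor hypermethylation of eCGIs and its consequences.

Computes per-CpG differential methylation (tumor minus normal beta),
aggregates it per region, selects hypermethylated eCGIs (mean dm > 0.5),
contrasts eCGI vs pCGI methylation change, tests silencing of the
hypermethylated eCGIs' target genes, tests the loss of DHS/H3K27ac signal
at those islands, and runs the Fisher enrichment of targets on the tumor
suppressor and oncogene lists.

Writes tables and a summary under results/methylation/.
"""

import json
from pathlib import Path

from ecgi.enrichment import fisher_enrichment, read_gene_list
from ecgi.intervals import CoverageTrack, read_bed, read_genes
from ecgi.methylation import (
    aggregate_region_dm,
    class_dm_contrast,
    differential_methylation,
    dm_matrix,
    read_beta_table,
    select_hypermethylated,
    target_silencing,
)
from ecgi.signal import signal_loss_test
from ecgi.targets import assign_targets, filter_links, read_links

DATA = Path("results/dataset")
CLS = Path("results/classification")
OUT = Path("results/methylation")


def _read_expr(path):
    return {
        line.split("\t")[0]: float(line.split("\t")[1])
        for line in path.read_text().splitlines()
        if line.strip()
    }


def main() -> None:
    if not CLS.exists():
        raise SystemExit("run analysis/02_classify.py first")
    OUT.mkdir(parents=True, exist_ok=True)

    with open(CLS / "cgi_classes.bed") as fh:
        label_of = {l.split("\t")[3]: l.rstrip().split("\t")[6] for l in fh}
    labeled = read_bed(CLS / "cgi_classes.bed")
    ecgis = [iv for iv in labeled if label_of[iv.name] == "eCGI"]
    pcgis = [iv for iv in labeled if label_of[iv.name] == "pCGI"]

    sites = differential_methylation(
        read_beta_table(DATA / "beta_normal.tsv"), read_beta_table(DATA / "beta_tumor.tsv")
    )
    ecgi_dm = aggregate_region_dm(sites, ecgis)
    pcgi_dm = aggregate_region_dm(sites, pcgis)
    hyper = select_hypermethylated(ecgi_dm, threshold=0.5)
    hyper_ids = {r.region_id for r in hyper}

    with open(OUT / "region_methylation.tsv", "w") as fh:
        fh.write("region_id\tn_cpgs\tmean_dm\thyper\n")
        for r in ecgi_dm:
            fh.write(f"{r.region_id}\t{r.n_cpgs}\t{r.mean_dm:.6g}\t{int(r.region_id in hyper_ids)}\n")
    dm_matrix(sites, ecgis, threshold=0.5).to_csv(
        OUT / "dm_matrix.tsv", sep="\t", index=False
    )

    contrast, med_e, med_p = class_dm_contrast(ecgi_dm, pcgi_dm)
    summary = {
        "n_hyper_ecgis": len(hyper),
        "ecgi_vs_pcgi_dm": {
            "median_ecgi_dm": round(med_e, 4),
            "median_pcgi_dm": round(med_p, 4),
            "p_greater": float(contrast.p_greater),
        },
    }

    genes = read_genes(DATA / "genes.tsv")
    links = filter_links(read_links(DATA / "links.bedpe"), min_tags=3)
    assigns = assign_targets(ecgis, links, genes)
    sil = target_silencing(
        hyper, assigns,
        _read_expr(DATA / "expression_normal.tsv"),
        _read_expr(DATA / "expression_tumor.tsv"),
    )
    summary["silencing"] = {
        "n_targets": len(sil.fold_changes),
        "median_fold": round(sil.median_fold, 3),
        "p_down": float(sil.one_sample.p_less),
    }

    hyper_ivs = [iv for iv in ecgis if iv.name in hyper_ids]
    for mark in ("dhs", "h3k27ac"):
        res = signal_loss_test(
            hyper_ivs,
            CoverageTrack.read_bedgraph(DATA / f"{mark}_normal.bedgraph"),
            CoverageTrack.read_bedgraph(DATA / f"{mark}_tumor.bedgraph"),
        )
        summary[f"signal_loss_{mark}"] = {
            "mean_delta": round(float(res.deltas.mean()), 3),
            "p_loss": float(res.p_loss),
        }

    universe = {g.gene_id for g in genes}
    for cat in ("tsg", "oncogenes"):
        res = fisher_enrichment(
            set(sil.fold_changes), read_gene_list(DATA / f"{cat}.txt") & universe, universe
        )
        summary[f"fisher_{cat}"] = {"p_value": float(res.p_value)}

    (OUT / "summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
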