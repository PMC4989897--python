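"""Assign target genes to eCGIs and typical enhancers through filtered
ChIA-PET links (tag count >= 3), then contrast the two enhancer classes:
interaction strength (rank-sum on per-pair tag counts), target multiplicity
(single vs multiple targets) and cross-cell expression fold change of eCGI
targets.

Writes the assignment tables and a summary under results/targets/.
"""

import json
from pathlib import Path

import numpy as np

from ecgi.intervals import read_bed, read_genes
from ecgi.targets import (
    assign_targets,
    compare_link_strength,
    expression_fold_change,
    filter_links,
    read_links,
    target_multiplicity,
)

DATA = Path("results/dataset")
CLS = Path("results/classification")
OUT = Path("results/targets")


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

    genes = read_genes(DATA / "genes.tsv")
    links = filter_links(read_links(DATA / "links.bedpe"), min_tags=3)
    labeled = read_bed(CLS / "cgi_classes.bed")
    with open(CLS / "cgi_classes.bed") as fh:
        label_of = {l.split("\t")[3]: l.rstrip().split("\t")[6] for l in fh}
    ecgis = [iv for iv in labeled if label_of[iv.name] == "eCGI"]
    typical = read_bed(CLS / "typical_enhancers.bed")

    summary = {"n_links_filtered": len(links)}
    assignments = {}
    for name, regions in (("ecgi", ecgis), ("typical_enhancer", typical)):
        assigns = assign_targets(regions, links, genes)
        assignments[name] = assigns
        with open(OUT / f"{name}_assignments.tsv", "w") as fh:
            fh.write("region_id\tgene_id\ttag_count\tevidence\n")
            for a in assigns:
                fh.write(f"{a.region_id}\t{a.gene_id}\t{a.tag_count}\t{a.evidence}\n")
        single, multiple = target_multiplicity(assigns)
        summary[f"{name}_fraction_single"] = round(single, 3)
        summary[f"{name}_fraction_multiple"] = round(multiple, 3)

    strength = compare_link_strength(
        [a.tag_count for a in assignments["ecgi"]],
        [a.tag_count for a in assignments["typical_enhancer"]],
    )
    summary["tag_count_ecgi_gt_typical_p"] = float(strength.p_greater)

    folds = expression_fold_change(
        assignments["ecgi"],
        _read_expr(DATA / "expression_normal.tsv"),
        _read_expr(DATA / "expression_cellB.tsv"),
    )
    summary["ecgi_target_fold_vs_cellB_median"] = round(
        float(np.median(list(folds.values()))), 3
    )
    (OUT / "summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
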