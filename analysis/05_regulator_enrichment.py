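"""Permutation test for transcription-regulator targeting.

For eCGIs (and typical enhancers for contrast) the observed number of
distinct regulator genes reached through ChIA-PET links is compared to the
counts obtained when the regions are replaced by 1000 sets of random,
length- and chromosome-matched DNA segments.

Writes the null-count distributions and a summary under results/enrichment/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from ecgi.enrichment import permutation_enrichment, read_gene_list
from ecgi.intervals import read_bed, read_genes
from ecgi.targets import filter_links, read_links

DATA = Path("results/dataset")
CLS = Path("results/classification")
OUT = Path("results/enrichment")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--n-perm", type=int, default=1000)
    parser.add_argument("--seed", type=int, default=17)
    args = parser.parse_args()
    if not CLS.exists():
        raise SystemExit("run analysis/02_classify.py first")
    OUT.mkdir(parents=True, exist_ok=True)

    genes = read_genes(DATA / "genes.tsv")
    links = filter_links(read_links(DATA / "links.bedpe"), min_tags=3)
    regulators = read_gene_list(DATA / "regulators.txt")
    sizes = {
        line.split("\t")[0]: int(line.split("\t")[1])
        for line in (DATA / "chrom_sizes.tsv").read_text().splitlines()
    }
    with open(CLS / "cgi_classes.bed") as fh:
        label_of = {l.split("\t")[3]: l.rstrip().split("\t")[6] for l in fh}
    ecgis = [iv for iv in read_bed(CLS / "cgi_classes.bed") if label_of[iv.name] == "eCGI"]
    typical = read_bed(CLS / "typical_enhancers.bed")

    summary = {}
    rng = np.random.default_rng(args.seed)
    for name, regions, direction in (
        ("ecgi", ecgis, "greater"),
        ("typical_enhancer", typical, "greater"),
    ):
        res = permutation_enrichment(
            regions, links, genes, regulators, sizes,
            n_perm=args.n_perm, seed=rng, direction=direction,
        )
        np.savetxt(OUT / f"null_counts_{name}.tsv", res.null_counts, fmt="%d")
        summary[name] = {
            "observed_regulators": res.observed,
            "null_mean": round(float(np.mean(res.null_counts)), 2),
            "p_greater": res.p_value,
        }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
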