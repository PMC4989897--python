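"""Classify CGIs into pCGI / npCGI / eCGI / inactive-orphan classes and
call typical enhancers, then score the calls against the planted labels.

Reads results/dataset/ (run 01_simulate.py first); writes the labeled CGI
track, the typical-enhancer track and a per-class count summary under
results/classification/.
"""

import json
from pathlib import Path

from ecgi.classify import call_typical_enhancers, class_counts, classify_cgis
from ecgi.intervals import read_bed, read_genes, write_bed
from ecgi.synth import read_manifest

DATA = Path("results/dataset")
OUT = Path("results/classification")


def main() -> None:
    if not DATA.exists():
        raise SystemExit("results/dataset missing - run analysis/01_simulate.py first")
    OUT.mkdir(parents=True, exist_ok=True)

    cgis = read_bed(DATA / "cgis.bed")
    genes = read_genes(DATA / "genes.tsv")
    k27 = read_bed(DATA / "h3k27ac.bed")
    dhs = read_bed(DATA / "dhs.bed")
    cage = read_bed(DATA / "cage_tss.bed")
    denovo = read_bed(DATA / "denovo_tss.bed")

    records = classify_cgis(cgis, genes, k27, dhs, cage, denovo)
    write_bed(
        [r.interval for r in records], OUT / "cgi_classes.bed",
        extra=[r.label for r in records],
    )
    typical = call_typical_enhancers(k27, dhs, cage, denovo, cgis)
    write_bed([t.interval for t in typical], OUT / "typical_enhancers.bed")

    truth = read_manifest(DATA / "ground_truth.json")
    agree = sum(r.label == truth.cgi_labels[r.cgi_id] for r in records)
    summary = {
        "class_counts": class_counts(records),
        "n_typical_enhancers": len(typical),
        "label_accuracy_pct": round(100 * agree / len(records), 2),
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
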