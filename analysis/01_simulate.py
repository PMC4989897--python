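"""Generate the synthetic epigenome used by the downstream analyses.

Writes every data layer (CGIs, genes, peaks, TSS evidence, ChIA-PET links,
methylation betas, expression, coverage tracks, gene categories) plus the
ground-truth manifest to results/dataset/.

Run from the repository root:  python analysis/01_simulate.py [--seed 17]
"""

import argparse
import json
from pathlib import Path

from ecgi.synth import SynthConfig, generate

OUT = Path("results/dataset")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=17)
    args = parser.parse_args()

    config = SynthConfig(seed=args.seed)
    ds = generate(config)
    paths = ds.write(OUT)

    labels = list(ds.truth.cgi_labels.values())
    summary = {
        "seed": args.seed,
        "n_cgis": len(ds.cgis),
        "class_counts": {c: labels.count(c) for c in sorted(set(labels))},
        "n_genes": len(ds.genes),
        "n_links": len(ds.links),
        "n_hyper_ecgis": len(ds.truth.hyper_ecgis),
        "n_files": len(paths),
    }
    print(json.dumps(summary, indent=1))
    print(f"dataset written to {OUT}/")


if __name__ == "__main__":
    main()
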