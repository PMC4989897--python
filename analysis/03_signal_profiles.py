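"""Metaprofiles of DHS and H3K27ac coverage around eCGIs, typical enhancers
and pCGIs (+/-5 kb from the region center, 50 bp bins).

Reads results/dataset/ and results/classification/; writes one TSV per
(region set, track) pair under results/profiles/ and prints the mean signal
at the central bin for each, which shows the planted enrichment of both
marks at active elements.
"""

import json
from pathlib import Path

from ecgi.intervals import CoverageTrack, read_bed
from ecgi.signal import metaprofile

DATA = Path("results/dataset")
CLS = Path("results/classification")
OUT = Path("results/profiles")


def main() -> None:
    if not CLS.exists():
        raise SystemExit("run analysis/02_classify.py first")
    OUT.mkdir(parents=True, exist_ok=True)

    labeled = {}
    with open(CLS / "cgi_classes.bed") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            labeled.setdefault(fields[6], []).append(fields[3])
    by_name = {iv.name: iv for iv in read_bed(CLS / "cgi_classes.bed")}
    region_sets = {
        "eCGI": [by_name[n] for n in labeled.get("eCGI", [])],
        "pCGI": [by_name[n] for n in labeled.get("pCGI", [])],
        "typical_enhancer": read_bed(CLS / "typical_enhancers.bed"),
    }

    center_signal = {}
    for track_name in ("dhs_normal", "h3k27ac_normal"):
        track = CoverageTrack.read_bedgraph(DATA / f"{track_name}.bedgraph")
        for set_name, regions in region_sets.items():
            if not regions:
                continue
            prof = metaprofile(regions, track, flank=5000, n_bins=200,
                               region_set_name=set_name, track_name=track_name)
            with open(OUT / f"{set_name}_{track_name}.tsv", "w") as fh:
                fh.write("bin\toffset_bp\tmean_signal\n")
                for i, off, v in prof.to_rows():
                    fh.write(f"{i}\t{off:g}\t{v:.6g}\n")
            mid = prof.n_bins // 2
            center_signal[f"{set_name}:{track_name}"] = round(
                float(prof.bin_values[mid]), 3
            )
    print(json.dumps({"center_bin_mean_signal": center_signal}, indent=1))


if __name__ == "__main__":
    main()
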