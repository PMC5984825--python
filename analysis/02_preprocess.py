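#!/usr/bin/env python
"""Renormalize the raw matrix: detection filter, log2, quantile normalization.

Keeps probes detected (p < 0.05) in at least half of the autism samples or
half of the control samples, then log2-transforms and quantile-normalizes,
and runs advisory inter-array QC (mean Pearson correlation <= 0.85 or late
dendrogram singleton).  Writes results/preprocess/.
"""

import argparse
from pathlib import Path

from cortexsig import io, pipeline


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    data = args.out / "data"
    raw, _ = io.read_expression(data / "expression_raw.tsv")
    det, _ = io.read_expression(data / "detection.tsv")
    meta = io.read_metadata(data / "metadata.csv")
    pre = pipeline.preprocess_step(raw, det, meta, args.out / "preprocess")
    report = pre["report"]
    print(f"detection filter kept {report.probes_out} / {report.probes_in} probes")
    if report.samples_flagged:
        print("QC flagged:", report.samples_flagged)
    else:
        print("QC flagged no samples")


if __name__ == "__main__":
    main()
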