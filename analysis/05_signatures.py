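#!/usr/bin/env python
"""Pathway signatures: construction, group tests, and the correlation null.

Builds the synapse pathway (down genes in the synapse term) and the
mitochondria pathway (down genes in the mitochondrion term, minus synapse
pathway and the m12-like module), scores their per-sample mean signatures,
tests the mitochondria signature by Welch t-test and covariate-adjusted
logistic regression, and judges the mito-synapse correlation against
B random gene sets of the synapse pathway's size.  Writes results/signatures/.
"""

import argparse
from pathlib import Path

from cortexsig import io, pipeline


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--B", type=int, default=10000)
    args = ap.parse_args()

    norm, _ = io.read_expression(args.out / "preprocess" / "expression_norm.tsv")
    meta = io.read_metadata(args.out / "data" / "metadata.csv")
    down = (args.out / "de" / "genes_down.txt").read_text().split()
    terms = io.read_gmt(args.out / "data" / "annotation_terms.gmt")

    sig = pipeline.signature_step(norm, meta, down, terms, args.out / "signatures",
                                  b_null=args.B, seed=args.seed + 3)
    s = sig["summary"]
    print(f"mitochondria pathway: {s['mitochondria_n_genes']} genes; "
          f"synapse pathway: {s['synapse_n_genes']} genes")
    print(f"mitochondria signature: t = {s['mito_ttest_t']:.2f} (p = {s['mito_ttest_p']:.2g}); "
          f"logistic coef = {s['mito_logistic_coef']:.2f} (p = {s['mito_logistic_p']:.2g})")
    print(f"mito-synapse Pearson r = {s['mito_synapse_r']:.3f}; "
          f"greater correlation than all but "
          f"{100 * s['exceed_frac']:.2f}% of {s['null_B']} random "
          f"{s['null_set_size']}-gene sets")


if __name__ == "__main__":
    main()
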