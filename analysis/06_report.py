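#!/usr/bin/env python
"""Render figures: clustered heatmap, signature boxplots, correlation scatter.

Each figure gets a TSV twin of exactly the plotted values under
results/figures/.
"""

import argparse
from pathlib import Path

from cortexsig import io, report, signatures


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    import pandas as pd

    norm, _ = io.read_expression(args.out / "preprocess" / "expression_norm.tsv")
    meta = io.read_metadata(args.out / "data" / "metadata.csv")
    frame = pd.read_csv(args.out / "signatures" / "signature_scores.tsv", sep="\t",
                        index_col=0)
    sig_mito = signatures.SignatureScore("mitochondria", frame["mitochondria"], (), ())
    sig_syn = signatures.SignatureScore("synapse", frame["synapse"], (), ())

    # rebuild the mitochondria pathway from the signature step's gene usage
    down = (args.out / "de" / "genes_down.txt").read_text().split()
    terms = io.read_gmt(args.out / "data" / "annotation_terms.gmt")
    synapse = signatures.build_pathway(signatures.PathwaySpec(
        base=frozenset(down), include=terms["synapse_term"].genes, name="synapse"))
    mito = signatures.build_pathway(signatures.PathwaySpec(
        base=frozenset(down), include=terms["mitochondria_term"].genes,
        exclusions=(synapse.genes, terms["m12_like"].genes), name="mitochondria"))

    written = report.render_figures({
        "expression": norm, "pathway": mito, "meta": meta,
        "signatures": [sig_mito, sig_syn],
        "scatter": (sig_mito, sig_syn),
    }, args.out / "figures")
    print(f"wrote {len(written)} files to {args.out / 'figures'}:")
    for p in written:
        print(" ", p.name)


if __name__ == "__main__":
    main()
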