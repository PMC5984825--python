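#!/usr/bin/env python
"""Over-representation of the downregulated genes and annotation clustering.

Tests the down list against the planted+decoy gene-set collection with the
EASE-penalized hypergeometric tail (background: all genes in the matrix),
then groups enriched terms into kappa-similarity annotation clusters at
medium stringency.  Writes results/enrichment/.
"""

import argparse
from pathlib import Path

from cortexsig import enrichment, io


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    down = (args.out / "de" / "genes_down.txt").read_text().split()
    norm, _ = io.read_expression(args.out / "preprocess" / "expression_norm.tsv")
    # planted sets + decoys, plus the broader annotation-style terms so the
    # kappa clustering has overlapping term families to find
    collection = io.read_gmt(args.out / "data" / "genesets.gmt")
    for term in io.read_gmt(args.out / "data" / "annotation_terms.gmt"):
        collection.add(term)
    background = list(norm.index)

    out_dir = args.out / "enrichment"
    out_dir.mkdir(parents=True, exist_ok=True)
    res = enrichment.enrich_collection(down, collection, background)
    res.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
    print(f"{len(res)} terms with overlap >= 1; top term: "
          f"{res.iloc[0]['term']} (EASE p = {res.iloc[0]['ease_p']:.3g}, "
          f"fold = {res.iloc[0]['fold_enrichment']:.2f})"
          if len(res) else "no overlapping terms")

    if len(res) >= 2:
        clusters = enrichment.cluster_terms(res, collection, background)
        enrichment.clusters_to_frame(clusters).to_csv(
            out_dir / "clusters.tsv", sep="\t", index=False)
        print(f"{len(clusters)} annotation clusters; " + "; ".join(
            f"cluster {i + 1} (score {c.enrichment_score:.2f}): {', '.join(c.terms[:4])}"
            for i, c in enumerate(clusters[:3])))


if __name__ == "__main__":
    main()
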