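#!/usr/bin/env python
"""Generate the synthetic case-control cortical cohort.

Writes raw intensities, detection p-values, sample metadata, ground truth,
the planted+decoy gene-set collection and annotation-style term sets under
results/data/.  The cohort mirrors a paired-region post-mortem design:
15 autism and 16 control subjects, frontal and temporal cortex each, with a
planted -0.5 log2 down-shift on a 50-gene mitochondria-like set and a
100-gene synapse-like set linked through a shared latent factor.
"""

import argparse
from pathlib import Path

from cortexsig import pipeline, simulate


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-genes", type=int, default=12632)
    args = ap.parse_args()

    config = simulate.default_config(n_genes=args.n_genes, seed=args.seed)
    sim = pipeline.simulate_step(args.out / "data", config)
    meta = sim["meta"]
    print(f"wrote {args.out / 'data'}: {config.n_genes} genes x {len(meta)} samples "
          f"({(meta.diagnosis == 'autism').sum()} autism / "
          f"{(meta.diagnosis == 'control').sum()} control)")
    print(f"planted sets: " + ", ".join(
        f"{ps.name} ({len(ps.genes)} genes, delta={ps.delta}, loading={ps.loading})"
        for ps in config.planted_sets))


if __name__ == "__main__":
    main()
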