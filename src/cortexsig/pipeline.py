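"""End-to-end driver: simulate -> preprocess -> DE -> signatures -> null -> report.

Every step writes deterministic plain-text outputs (TSV/CSV/GMT/JSON), so a
run is reproducible byte for byte from its seed.  The numbered scripts under
``analysis/`` call the individual ``*_step`` functions; ``run_all`` chains
them for programmatic use and reproducibility checks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, io, preprocess, signatures, simulate
from .report import render_figures


def simulate_step(out_dir: Path, config: simulate.SimConfig,
                  n_decoys: int = 100, decoy_size: int = 50) -> dict:
    """Generate the dataset, gene-set collection and annotation terms."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw, det, meta, truth = simulate.generate_dataset(config)
    io.write_expression(raw, out_dir / "expression_raw.tsv")
    io.write_expression(det, out_dir / "detection.tsv")
    io.write_metadata(meta, out_dir / "metadata.csv")
    pd.DataFrame({"delta": truth.delta, "loading": truth.loading}).to_csv(
        out_dir / "truth_genes.csv", index_label="gene_id")
    truth.factor.to_frame().to_csv(out_dir / "truth_factor.csv", index_label="sample_id")
    collection = simulate.generate_geneset_collection(
        config, n_decoys=n_decoys, decoy_size=decoy_size, seed=config.seed + 1)
    io.write_gmt(collection, out_dir / "genesets.gmt")
    terms = simulate.make_annotation_terms(config, seed=config.seed + 2)
    io.write_gmt(terms, out_dir / "annotation_terms.gmt")
    return {"raw": raw, "detection": det, "meta": meta, "truth": truth,
            "collection": collection, "terms": terms}


def preprocess_step(raw, det, meta, out_dir: Path) -> dict:
    """Detection filter -> log2 -> quantile normalization -> advisory QC."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    filtered = preprocess.detection_filter(raw, det, meta)
    norm = preprocess.quantile_normalize(preprocess.log2_transform(filtered))
    qc = preprocess.interarray_qc(norm)
    report = preprocess.PreprocessReport(
        probes_in=raw.shape[0], probes_out=norm.shape[0],
        samples_flagged=qc.samples_flagged,
        parameters={"p_thresh": 0.05, "fraction": 0.5, **qc.parameters})
    io.write_expression(norm, out_dir / "expression_norm.tsv")
    report.to_json(out_dir / "preprocess_report.json")
    return {"norm": norm, "report": report}


def de_step(norm, meta, out_dir: Path) -> dict:
    """Pooled covariate-adjusted DE plus region-restricted reruns."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res = diffexpr.run_de(norm, meta)
    res.to_csv(out_dir / "de_all.tsv", sep="\t", index_label="gene_id")
    up, down = diffexpr.split_updown(res)
    Path(out_dir / "genes_up.txt").write_text("\n".join(up) + "\n")
    Path(out_dir / "genes_down.txt").write_text("\n".join(down) + "\n")
    stratified = {}
    overlap = {}
    for region in ("frontal", "temporal"):
        spec = diffexpr.DesignSpec(region=region)
        r = diffexpr.run_de(norm, meta, spec, adjust=False)
        r.to_csv(out_dir / f"de_{region}.tsv", sep="\t", index_label="gene_id")
        # region reruns are unadjusted: with halved samples nothing survives BH
        u, d = diffexpr.split_updown(r, p_col="p_raw")
        stratified[region] = {"up": u, "down": d}
        overlap[region] = {
            "up_pct": 100.0 * len(set(up) & set(u)) / len(up) if up else float("nan"),
            "down_pct": 100.0 * len(set(down) & set(d)) / len(down) if down else float("nan"),
        }
    return {"results": res, "up": up, "down": down,
            "stratified": stratified, "overlap": overlap}


def signature_step(norm, meta, down, terms, out_dir: Path,
                   b_null: int = 10000, seed: int = 0) -> dict:
    """Build exclusion-filtered pathways, score and test their signatures,
    and run the size-matched random-set correlation null."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    down = frozenset(down)
    synapse = signatures.build_pathway(signatures.PathwaySpec(
        base=down, include=terms["synapse_term"].genes, name="synapse"))
    mito = signatures.build_pathway(signatures.PathwaySpec(
        base=down, include=terms["mitochondria_term"].genes,
        exclusions=(synapse.genes, terms["m12_like"].genes), name="mitochondria"))
    sig_mito = signatures.signature_scores(norm, mito)
    sig_syn = signatures.signature_scores(norm, synapse)
    t, t_p = signatures.signature_ttest(sig_mito, meta)
    coef, logit_p = signatures.signature_logistic(sig_mito, meta)
    r = signatures.pathway_correlation(sig_mito, sig_syn)
    null = signatures.random_set_null(norm, fixed=mito, reference=synapse,
                                      B=b_null, seed=seed)
    scores = pd.DataFrame({"mitochondria": sig_mito.values, "synapse": sig_syn.values})
    scores.to_csv(out_dir / "signature_scores.tsv", sep="\t", index_label="sample_id")
    null.to_frame().to_csv(out_dir / "null_correlations.tsv", sep="\t", index=False)
    summary = {
        "mitochondria_n_genes": len(mito),
        "synapse_n_genes": len(synapse),
        "mito_ttest_t": t, "mito_ttest_p": t_p,
        "mito_logistic_coef": coef, "mito_logistic_p": logit_p,
        "mito_synapse_r": r,
        "null_B": null.b, "null_set_size": null.set_size,
        "exceed_frac": null.exceed_frac,
    }
    with open(out_dir / "signature_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"mito": mito, "synapse": synapse, "sig_mito": sig_mito,
            "sig_syn": sig_syn, "null": null, "summary": summary}


def run_all(out_dir, seed: int, config: simulate.SimConfig | None = None,
            b_null: int = 10000, n_decoys: int = 100, decoy_size: int = 50,
            write_figures: bool = True) -> dict:
    """Run the whole pipeline into ``out_dir``; returns the summary dict."""
    out_dir = Path(out_dir)
    if config is None:
        config = simulate.default_config(seed=seed)
    else:
        config = simulate.with_seed(config, seed)
    sim = simulate_step(out_dir / "data", config, n_decoys=n_decoys, decoy_size=decoy_size)
    pre = preprocess_step(sim["raw"], sim["detection"], sim["meta"], out_dir / "preprocess")
    de = de_step(pre["norm"], sim["meta"], out_dir / "de")
    sig = signature_step(pre["norm"], sim["meta"], de["down"], sim["terms"],
                         out_dir / "signatures", b_null=b_null, seed=seed + 3)
    summary = {
        "n_genes": config.n_genes,
        "n_samples": int(sim["meta"].shape[0]),
        "probes_after_filter": pre["report"].probes_out,
        "n_up": len(de["up"]), "n_down": len(de["down"]),
        "overlap": de["overlap"],
        **sig["summary"],
    }
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if write_figures:
        render_figures({
            "expression": pre["norm"], "pathway": sig["mito"], "meta": sim["meta"],
            "signatures": [sig["sig_mito"], sig["sig_syn"]],
            "scatter": (sig["sig_mito"], sig["sig_syn"]),
        }, out_dir / "figures")
    return summary
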