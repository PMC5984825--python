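"""Figures and their plain-text twins.

Heatmaps show gene-wise z-scored expression with rows and columns ordered
by average-linkage hierarchical clustering on Euclidean distance; boxplots
show a pathway signature by diagnosis; scatterplots show one signature
against another with the Pearson correlation printed.  Every figure writes
a TSV twin of exactly the plotted values, so figures are reproducible in
data terms even if rendering details change.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import GeneSet
from .signatures import SignatureScore, pathway_correlation

logger = logging.getLogger(__name__)


def heatmap_matrix(m: pd.DataFrame, pathway: GeneSet, method: str = "average"):
    """Z-score pathway genes by row and cluster rows and columns.

    Constant rows are excluded with a warning (their z-score is undefined).
    Returns ``(z, row_order, col_order)`` with orders as label lists from
    average-linkage clustering on Euclidean distance; scipy's deterministic
    tie handling (input order) makes the result reproducible for a given
    input.
    """
    present = [g for g in sorted(pathway.genes) if g in m.index]
    sub = m.loc[present]
    sd = sub.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("heatmap_matrix: %d constant gene rows excluded", int(constant.sum()))
        sub = sub.loc[~constant]
        sd = sd[~constant]
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        raise ValueError("heatmap needs >= 2 non-constant pathway genes and >= 2 samples")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    row_link = hierarchy.linkage(pdist(z.to_numpy()), method=method)
    col_link = hierarchy.linkage(pdist(z.to_numpy().T), method=method)
    row_order = [z.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [z.columns[i] for i in hierarchy.leaves_list(col_link)]
    return z.loc[row_order, col_order], row_order, col_order


def _save(fig, path):
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def _render_heatmap(z: pd.DataFrame, meta: pd.DataFrame | None, out_dir: Path,
                    name: str) -> list:
    paths = []
    tsv = out_dir / f"{name}_values.tsv"
    z.to_csv(tsv, sep="\t", index_label="gene_id")
    paths.append(tsv)
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-3, vmax=3, interpolation="nearest")
    ax.set_xlabel("samples (clustered)")
    ax.set_ylabel("genes (clustered)")
    ax.set_yticks([])
    if meta is not None:
        diag = meta.loc[z.columns, "diagnosis"]
        ax.set_xticks(range(len(z.columns)))
        ax.set_xticklabels(["A" if d == "autism" else "C" for d in diag], fontsize=5)
    else:
        ax.set_xticks([])
    fig.colorbar(im, ax=ax, label="z-score (by gene)")
    png = out_dir / f"{name}.png"
    _save(fig, png)
    paths.append(png)
    return paths


def _render_boxplot(score: SignatureScore, meta: pd.DataFrame, out_dir: Path) -> list:
    paths = []
    df = pd.DataFrame({"sample_id": score.values.index,
                       "diagnosis": meta.loc[score.values.index, "diagnosis"].to_numpy(),
                       "signature": score.values.to_numpy()})
    tsv = out_dir / f"signature_{score.name}_boxplot.tsv"
    df.to_csv(tsv, sep="\t", index=False)
    paths.append(tsv)
    fig, ax = plt.subplots(figsize=(4, 4))
    groups = [df.loc[df["diagnosis"] == d, "signature"] for d in ("control", "autism")]
    ax.boxplot(groups, tick_labels=["control", "autism"])
    ax.set_ylabel(f"mean {score.name} expression (log2)")
    png = out_dir / f"signature_{score.name}_boxplot.png"
    _save(fig, png)
    paths.append(png)
    return paths


def _render_scatter(a: SignatureScore, b: SignatureScore, meta: pd.DataFrame | None,
                    out_dir: Path) -> list:
    paths = []
    r = pathway_correlation(a, b)
    b_label = b.name if b.name != a.name else b.name + "_y"
    df = pd.DataFrame({"sample_id": a.values.index,
                       a.name: a.values.to_numpy(), b_label: b.values.to_numpy()})
    tsv = out_dir / f"signature_scatter_{a.name}_vs_{b.name}.tsv"
    df.to_csv(tsv, sep="\t", index=False)
    paths.append(tsv)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    if meta is not None:
        colors = np.where(meta.loc[a.values.index, "diagnosis"] == "autism", "tab:blue", "tab:red")
        ax.scatter(a.values, b.values, c=colors, s=20)
    else:
        ax.scatter(a.values, b.values, s=20)
    ax.set_xlabel(f"mean {a.name} expression (log2)")
    ax.set_ylabel(f"mean {b.name} expression (log2)")
    ax.set_title(f"cor = {r:.2f}")
    png = out_dir / f"signature_scatter_{a.name}_vs_{b.name}.png"
    _save(fig, png)
    paths.append(png)
    return paths


def render_figures(bundle: dict, out_dir) -> list:
    """Render all available figures from a results bundle.

    Recognised bundle keys (all optional; missing ones are skipped with a
    warning):

    * ``"expression"`` (DataFrame) with ``"pathway"`` (GeneSet) — heatmap;
    * ``"signatures"`` (list of SignatureScore) with ``"meta"`` — boxplots;
    * ``"scatter"`` ((SignatureScore, SignatureScore)) — scatterplot.

    Returns the list of written paths (each figure plus its TSV twin).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = bundle.get("meta")
    written: list = []
    if "expression" in bundle and "pathway" in bundle:
        try:
            z, _, _ = heatmap_matrix(bundle["expression"], bundle["pathway"])
            written += _render_heatmap(z, meta, out_dir, f"heatmap_{bundle['pathway'].name}")
        except ValueError as exc:
            logger.warning("render_figures: heatmap skipped (%s)", exc)
    else:
        logger.warning("render_figures: no expression/pathway; heatmap skipped")
    if "signatures" in bundle and meta is not None:
        for score in bundle["signatures"]:
            written += _render_boxplot(score, meta, out_dir)
    else:
        logger.warning("render_figures: no signatures/meta; boxplots skipped")
    if "scatter" in bundle:
        a, b = bundle["scatter"]
        written += _render_scatter(a, b, meta, out_dir)
    else:
        logger.warning("render_figures: no scatter pair; scatterplot skipped")
    return written
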