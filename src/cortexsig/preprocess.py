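"""Renormalization pipeline for raw array intensities.

Order of operations mirrors standard two-colour-free microarray practice:
detection-based probe filtering on the raw scale, log2 transform, quantile
normalization, then advisory inter-array QC.  Probe-to-gene collapsing is a
separate step because the list-mode rule (drop genes measured by several
probes) applies only to enrichment input lists, not to matrices.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .exceptions import AlignmentError, ConfigError
from .io import DIAGNOSIS_LEVELS

logger = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    """What a preprocessing step did: counts, flagged samples, parameters."""

    probes_in: int
    probes_out: int
    samples_flagged: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.probes_out > self.probes_in:
            raise ValueError("probes_out cannot exceed probes_in")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def detection_filter(raw: pd.DataFrame, det: pd.DataFrame, meta: pd.DataFrame,
                     p_thresh: float = 0.05, fraction: float = 0.5) -> pd.DataFrame:
    """Keep probes detected (p < ``p_thresh``, strict) in at least
    ``ceil(fraction * n)`` of the autism samples or of the control samples.

    ``fraction=0`` keeps every probe; ``fraction=1`` requires detection in
    every sample of at least one group.  Probe order is preserved.
    """
    if not raw.index.equals(det.index) or list(raw.columns) != list(det.columns):
        raise AlignmentError("raw and detection matrices are not aligned")
    missing = [s for s in raw.columns if s not in meta.index]
    if missing:
        raise AlignmentError(f"samples without metadata: {missing[:10]}")
    diagnosis = meta.loc[list(raw.columns), "diagnosis"]
    if diagnosis.isna().any() or not set(diagnosis) <= set(DIAGNOSIS_LEVELS):
        raise ValueError("diagnosis labels missing or invalid")
    detected = det.to_numpy() < p_thresh
    keep = np.zeros(raw.shape[0], dtype=bool)
    for level in DIAGNOSIS_LEVELS:
        cols = (diagnosis == level).to_numpy()
        n_group = int(cols.sum())
        need = math.ceil(fraction * n_group)
        keep |= detected[:, cols].sum(axis=1) >= need
    out = raw.loc[keep]
    logger.info("detection_filter: kept %d / %d probes", out.shape[0], raw.shape[0])
    return out


def log2_transform(raw: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """log2(max(x, floor)); negative intensities are an error."""
    values = raw.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative intensities cannot be log-transformed")
    return pd.DataFrame(np.log2(np.maximum(values, floor)),
                        index=raw.index, columns=raw.columns)


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the common per-rank across-sample means.

    Ties within a column receive the mean of the reference values at their
    tied ranks, so the defining property sorted(col_i) == sorted(col_j)
    holds exactly in the tie-free case and up to tie-averaging otherwise.
    """
    X = m.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if np.isnan(X).any():
        raise ValueError("quantile normalization requires a complete matrix")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # average reference values over tied observations
        out[:, j] = pd.Series(assigned).groupby(col, sort=False).transform("mean").to_numpy()
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def _first_merge_heights(link: np.ndarray, n: int) -> np.ndarray:
    """Height at which each original leaf first merges into the tree."""
    heights = np.full(n, np.nan)
    for a, b, height, _ in link:
        for node in (int(a), int(b)):
            if node < n and np.isnan(heights[node]):
                heights[node] = height
    return heights


def interarray_qc(m: pd.DataFrame, r_thresh: float = 0.85,
                  cluster_outliers: bool = True,
                  iqr_factor: float = 1.5) -> PreprocessReport:
    """Advisory inter-array QC.

    Flags a sample when its mean Pearson correlation with all other samples
    is <= ``r_thresh``, when its column has zero variance (correlation
    undefined), or when it joins an average-linkage (1 - r) dendrogram as a
    late singleton (first-merge height above Q3 + ``iqr_factor``*IQR of all
    merge heights).  Flags are advisory; nothing is removed here.
    """
    n = m.shape[1]
    if n < 3:
        raise ValueError("inter-array QC needs at least 3 samples")
    flagged: dict[str, str] = {}
    X = m.to_numpy(dtype=float)
    sd = X.std(axis=0)
    constant = sd == 0
    for idx in np.flatnonzero(constant):
        flagged[m.columns[idx]] = "zero variance"
    ok = ~constant
    labels = [m.columns[i] for i in np.flatnonzero(ok)]
    if ok.sum() >= 3:
        corr = np.corrcoef(X[:, ok], rowvar=False)
        mean_corr = (corr.sum(axis=1) - 1.0) / (corr.shape[0] - 1)
        for lab, r in zip(labels, mean_corr):
            if r <= r_thresh:
                flagged.setdefault(lab, f"mean interarray correlation {r:.3f} <= {r_thresh}")
        if cluster_outliers and ok.sum() >= 4:
            dist = np.clip(1.0 - corr, 0.0, None)
            np.fill_diagonal(dist, 0.0)
            link = hierarchy.linkage(squareform(dist, checks=False), method="average")
            heights = _first_merge_heights(link, len(labels))
            merge_h = link[:, 2]
            q1, q3 = np.percentile(merge_h, [25, 75])
            cutoff = q3 + iqr_factor * (q3 - q1)
            for lab, h in zip(labels, heights):
                if h > cutoff:
                    flagged.setdefault(lab, f"hierarchical-clustering outlier (merge height {h:.3f})")
    return PreprocessReport(
        probes_in=m.shape[0], probes_out=m.shape[0],
        samples_flagged=flagged,
        parameters={"r_thresh": r_thresh, "iqr_factor": iqr_factor,
                    "cluster_outliers": cluster_outliers})


def collapse_probes(m: pd.DataFrame, gene_map: pd.DataFrame, seed: int,
                    mode: str = "matrix", matrix_collapse: str = "max_mean") -> pd.DataFrame:
    """Collapse probe-level rows to gene-level rows.

    Probes mapping to several genes get one gene chosen uniformly at random
    (seeded, hence reproducible).  Genes then measured by several probes are
    handled by mode:

    * ``"list"`` — the gene is dropped entirely (the rule used when building
      enrichment input lists, so no genomic feature is over-represented);
    * ``"matrix"`` — one probe is kept per gene, by default the one with the
      highest mean intensity (``matrix_collapse="max_mean"``).
    """
    if mode not in ("matrix", "list"):
        raise ConfigError(f"mode: unknown value {mode!r}")
    lookup: dict[str, list[str]] = {}
    for probe, gene in zip(gene_map["probe_id"], gene_map["gene_id"]):
        lookup.setdefault(probe, []).append(gene)
    covered = [p for p in m.index if p in lookup]
    if not covered:
        raise ValueError("gene map covers no probe in the matrix")
    rng = np.random.default_rng(seed)
    chosen: dict[str, str] = {}
    for probe in covered:  # matrix order => deterministic draw sequence
        genes = sorted(set(lookup[probe]))
        chosen[probe] = genes[0] if len(genes) == 1 else genes[rng.integers(len(genes))]
    sub = m.loc[covered]
    gene_of = pd.Series([chosen[p] for p in covered], index=sub.index)
    counts = gene_of.value_counts()
    if mode == "list":
        keep = gene_of.map(counts) == 1
        dropped = sorted(counts.index[counts > 1])
        if dropped:
            logger.info("collapse_probes(list): dropped %d multi-probe genes", len(dropped))
        out = sub.loc[keep].copy()
        out.index = pd.Index(gene_of[keep], name="gene_id")
        return out
    if matrix_collapse != "max_mean":
        raise ConfigError(f"matrix_collapse: unknown value {matrix_collapse!r}")
    means = sub.mean(axis=1)
    best_probe: dict[str, str] = {}
    for probe in covered:  # first probe wins ties, by input order
        g = gene_of[probe]
        if g not in best_probe or means[probe] > means[best_probe[g]]:
            best_probe[g] = probe
    keep_probes = [best_probe[g] for g in dict.fromkeys(gene_of)]  # preserve order
    out = sub.loc[keep_probes].copy()
    out.index = pd.Index([gene_of[p] for p in keep_probes], name="gene_id")
    logger.info("collapse_probes(matrix): %d probes -> %d genes", len(covered), out.shape[0])
    return out
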