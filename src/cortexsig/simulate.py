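"""Synthetic case-control cortical expression datasets with known truth.

The generator emulates a paired-region post-mortem brain microarray design:
case and control subjects each contribute a frontal and a temporal cortex
sample, subject-level covariates (RIN, PMI, age, sex) are shared by a
subject's samples, and expression follows

    x[g, s] = mu_g + delta_g * 1{case_s} + lambda_g * f_s
              + sum_c gamma_c * cov_{c,s} + eps,    eps ~ N(0, noise_sd)

on the log2 scale, with raw intensities 2**x.  ``delta_g`` plants a
case-control shift on designated gene sets; ``lambda_g`` loads genes on a
shared latent factor ``f_s``, which induces correlation between pathway
signatures.  Detection p-values are < 0.05 except at randomly chosen
failure positions.  Everything is driven by one seeded generator, so a
config reproduces its dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import GeneSet, GeneSetCollection

#: Covariate keys accepted by ``SimConfig.covariate_effects``.  ``sex`` acts
#: on the male indicator; ``region`` on the temporal indicator.
COVARIATE_KEYS = ("RIN", "PMI", "age", "sex", "region")


@dataclass(frozen=True)
class PlantedSet:
    """A gene set with a planted group effect and latent-factor loading."""

    name: str
    genes: tuple
    delta: float = 0.0    # case-minus-control shift, log2 units
    loading: float = 0.0  # log2 units per factor SD


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset (defaults: see ``default_config``)."""

    n_genes: int = 2000
    n_subjects_case: int = 15
    n_subjects_control: int = 16
    regions_per_subject: int = 2
    baseline_mean: float = 8.0   # log2 units
    baseline_sd: float = 1.5     # log2 units
    noise_sd: float = 0.5        # log2 units
    planted_sets: tuple = ()
    factor_sd: float = 1.0
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    detection_fail_rate: float = 0.05
    seed: int = 0
    allow_overlapping_sets: bool = False

    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:05d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        for name in ("n_genes", "n_subjects_case", "n_subjects_control"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be > 0")
        if self.regions_per_subject not in (1, 2):
            raise ConfigError("regions_per_subject: must be 1 or 2")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd: must be > 0")
        if self.baseline_sd < 0:
            raise ConfigError("baseline_sd: must be >= 0")
        if self.factor_sd < 0:
            raise ConfigError("factor_sd: must be >= 0")
        if not 0 <= self.detection_fail_rate < 1:
            raise ConfigError("detection_fail_rate: must be in [0, 1)")
        bad = set(self.covariate_effects) - set(COVARIATE_KEYS)
        if bad:
            raise ConfigError(f"covariate_effects: unknown keys {sorted(bad)}")
        genes = set(self.gene_ids())
        claimed: set[str] = set()
        for ps in self.planted_sets:
            members = set(ps.genes)
            if not members <= genes:
                raise ConfigError(f"planted_sets: set {ps.name!r} has members outside the gene universe")
            if claimed & members and not self.allow_overlapping_sets:
                raise ConfigError(f"planted_sets: set {ps.name!r} overlaps another planted set")
            claimed |= members


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    delta: pd.Series       # planted effect per gene (log2)
    loading: pd.Series     # factor loading per gene
    factor: pd.Series      # latent factor value per sample
    seed: int


def _truncated_normal(rng, mean, sd, size, lower=0.0):
    out = rng.normal(mean, sd, size)
    while True:
        bad = out <= lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))


def generate_metadata(config: SimConfig, rng) -> pd.DataFrame:
    rows = []
    subjects = ([("autism", f"A{i + 1:02d}") for i in range(config.n_subjects_case)]
                + [("control", f"C{i + 1:02d}") for i in range(config.n_subjects_control)])
    n_sub = len(subjects)
    rin = _truncated_normal(rng, 7.5, 1.0, n_sub)
    pmi = _truncated_normal(rng, 20.0, 8.0, n_sub)
    age = rng.uniform(5.0, 60.0, n_sub)
    sex = np.where(rng.random(n_sub) < 0.8, "M", "F")
    regions = ("frontal", "temporal")[: config.regions_per_subject]
    for i, (diagnosis, subject) in enumerate(subjects):
        for region in regions:
            rows.append({
                "sample_id": f"{subject}_{region[0].upper()}",
                "subject_id": subject, "diagnosis": diagnosis,
                "RIN": rin[i], "PMI": pmi[i], "age": age[i],
                "sex": sex[i], "region": region,
            })
    return pd.DataFrame(rows).set_index("sample_id")


def _covariate_design(meta: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "RIN": meta["RIN"].astype(float),
        "PMI": meta["PMI"].astype(float),
        "age": meta["age"].astype(float),
        "sex": (meta["sex"] == "M").astype(float),
        "region": (meta["region"] == "temporal").astype(float),
    })


def generate_dataset(config: SimConfig):
    """Generate ``(raw, detection, meta, truth)`` for a config.

    ``raw`` holds intensities ``2**x`` so that the preprocessing chain
    (detection filter, log2, quantile normalization) applies exactly as to
    real array data; ``truth`` is on the log2 scale of ``x``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta = generate_metadata(config, rng)
    genes = config.gene_ids()
    n_genes, n_samples = len(genes), len(meta)

    mu = rng.normal(config.baseline_mean, config.baseline_sd, n_genes)
    delta = pd.Series(0.0, index=pd.Index(genes, name="gene_id"))
    loading = pd.Series(0.0, index=delta.index)
    for ps in config.planted_sets:
        delta.loc[list(ps.genes)] += ps.delta
        loading.loc[list(ps.genes)] += ps.loading
    factor = pd.Series(rng.normal(0.0, config.factor_sd, n_samples),
                       index=meta.index, name="factor")

    case = (meta["diagnosis"] == "autism").to_numpy(dtype=float)
    cov = _covariate_design(meta)
    cov_shift = np.zeros(n_samples)
    for key, gamma in config.covariate_effects.items():
        cov_shift += gamma * cov[key].to_numpy()

    signal = (mu[:, None]
              + np.outer(delta.to_numpy(), case)
              + np.outer(loading.to_numpy(), factor.to_numpy())
              + cov_shift[None, :]
              + rng.normal(0.0, config.noise_sd, (n_genes, n_samples)))
    raw = pd.DataFrame(np.exp2(signal), index=delta.index, columns=meta.index)

    fail = rng.random((n_genes, n_samples)) < config.detection_fail_rate
    det_ok = rng.uniform(0.0, 0.05, (n_genes, n_samples))
    det_bad = rng.uniform(0.05, 1.0, (n_genes, n_samples))
    detection = pd.DataFrame(np.where(fail, det_bad, det_ok),
                             index=delta.index, columns=meta.index)

    truth = SyntheticTruth(delta=delta, loading=loading, factor=factor, seed=config.seed)
    return raw, detection, meta, truth


def generate_geneset_collection(config: SimConfig, n_decoys: int, decoy_size: int,
                                seed: int) -> GeneSetCollection:
    """Planted sets plus ``n_decoys`` random sets of ``decoy_size`` genes.

    Decoys are sampled without replacement within each set; with
    ``n_decoys=0`` the collection is exactly the planted sets.
    """
    if decoy_size > config.n_genes:
        raise ConfigError("decoy_size: exceeds n_genes")
    if n_decoys < 0:
        raise ConfigError("n_decoys: must be >= 0")
    genes = np.array(config.gene_ids())
    rng = np.random.default_rng(seed)
    collection = GeneSetCollection()
    for ps in config.planted_sets:
        collection.add(GeneSet.from_members(ps.name, ps.genes, "planted set"))
    width = max(3, len(str(n_decoys)))
    for i in range(n_decoys):
        members = rng.choice(genes, size=decoy_size, replace=False)
        collection.add(GeneSet.from_members(f"decoy_{i + 1:0{width}d}", members, "random decoy set"))
    return collection


def make_annotation_terms(config: SimConfig, seed: int, padding: int = 30) -> GeneSetCollection:
    """Annotation-style term sets for pathway construction.

    For each planted set, emits a term containing the planted genes plus
    ``padding`` random non-planted genes (an annotation term is broader than
    the genes responding in any one study).  For a planted set named
    ``synapse`` an additional ``m12_like`` co-expression-module term is
    emitted: a random 40% of the synapse genes plus ``padding`` randoms,
    mirroring an exclusion list that partially overlaps the pathway.
    """
    rng = np.random.default_rng(seed)
    genes = np.array(config.gene_ids())
    planted_all = set().union(*(set(ps.genes) for ps in config.planted_sets)) \
        if config.planted_sets else set()
    unplanted = np.array(sorted(set(genes) - planted_all))
    collection = GeneSetCollection()
    for ps in config.planted_sets:
        pad = rng.choice(unplanted, size=min(padding, len(unplanted)), replace=False)
        collection.add(GeneSet.from_members(
            f"{ps.name}_term", list(ps.genes) + list(pad), "annotation term"))
        if ps.name == "synapse":
            core = rng.choice(np.array(sorted(ps.genes)),
                              size=max(1, int(0.6 * len(ps.genes))), replace=False)
            pad2 = rng.choice(unplanted, size=min(padding, len(unplanted)), replace=False)
            collection.add(GeneSet.from_members(
                "m12_like", list(core) + list(pad2), "co-expression module exclusion list"))
    return collection


def planted_defaults(n_genes: int, delta_mito: float = -0.5, delta_synapse: float = -0.5,
                     loading: float = 0.3) -> tuple:
    """The two study-condition pathways: a 50-gene mitochondria-like set and
    a 100-gene synapse-like set, both down in cases, sharing a latent factor."""
    if n_genes < 150:
        raise ConfigError("n_genes: need >= 150 genes for the default planted sets")
    ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    return (
        PlantedSet("mitochondria", tuple(ids[:50]), delta=delta_mito, loading=loading),
        PlantedSet("synapse", tuple(ids[50:150]), delta=delta_synapse, loading=loading),
    )


#: Modest covariate slopes (log2 units per covariate unit) in plausible
#: brain-bank ranges; configurable per dataset.
DEFAULT_COVARIATE_EFFECTS = {
    "RIN": 0.05, "PMI": -0.005, "age": -0.002, "sex": 0.05, "region": 0.1,
}


def default_config(n_genes: int = 12632, seed: int = 0, **overrides) -> SimConfig:
    """Study-condition config: 15 case / 16 control subjects, two cortical
    regions each, planted down-shift of -0.5 log2 on both pathways and a
    shared latent factor linking their signatures."""
    cfg = SimConfig(
        n_genes=n_genes,
        planted_sets=planted_defaults(n_genes),
        covariate_effects=dict(DEFAULT_COVARIATE_EFFECTS),
        seed=seed,
        **overrides,
    )
    cfg.validate()
    return cfg


def null_config(n_genes: int = 2000, seed: int = 0, **overrides) -> SimConfig:
    """Full null: the same design and named pathways, but no planted shifts,
    no latent-factor loadings, and no covariate effects on expression.

    The zeroed covariate slopes matter: with nonzero slopes a subject's two
    region samples share an expression shift, and pooled two-sample tests on
    62 non-independent samples would not be calibrated for reasons unrelated
    to the code under test.
    """
    cfg = SimConfig(
        n_genes=n_genes,
        planted_sets=planted_defaults(n_genes, delta_mito=0.0, delta_synapse=0.0, loading=0.0),
        covariate_effects={},
        seed=seed,
        **overrides,
    )
    cfg.validate()
    return cfg


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
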