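"""Pathway construction, mean-signature scoring, and the random-set null.

A pathway signature is the per-sample unweighted mean of the log2 expression
of the pathway's genes — a one-number-per-sample summary of pathway
activity.  Group differences are tested by a two-sample t-test and by a
covariate-adjusted logistic regression of diagnosis on the signature.  The
correlation between two pathway signatures is judged against an empirical
null built from many random gene sets of exactly the reference pathway's
size, drawn without replacement from all genes in the matrix; the exceedance
fraction is the share of random sets whose signature correlates with the
fixed pathway more strongly (strict >) than the reference does.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import FitError
from .io import GeneSet

logger = logging.getLogger(__name__)

_NULL_CHUNK = 512  # internal batch size for null draws; fixed for determinism


@dataclass
class PathwaySpec:
    """Exclusion-filtered pathway: (base & include) minus the exclusions."""

    base: frozenset
    include: frozenset
    exclusions: tuple = ()
    name: str = "pathway"


def build_pathway(spec: PathwaySpec) -> GeneSet:
    """Apply the set algebra of a :class:`PathwaySpec`; provenance is logged."""
    base, include = set(spec.base), set(spec.include)
    result = base & include
    n_overlap = len(result)
    for excl in spec.exclusions:
        result -= set(excl)
    logger.info("build_pathway %r: |base|=%d, |base & include|=%d, after %d exclusions=%d",
                spec.name, len(base), n_overlap, len(spec.exclusions), len(result))
    if not result:
        raise ValueError(
            f"pathway {spec.name!r} is empty after intersection/exclusion; "
            "check the base list, include term, and exclusion sets")
    return GeneSet(name=spec.name, genes=frozenset(result))


@dataclass
class SignatureScore:
    """Per-sample mean expression of a pathway's genes."""

    name: str
    values: pd.Series         # index: sample ids
    genes_used: tuple
    genes_requested: tuple


def signature_scores(m: pd.DataFrame, pathway: GeneSet) -> SignatureScore:
    """Unweighted per-sample mean over the pathway genes present in ``m``."""
    requested = tuple(sorted(pathway.genes))
    used = tuple(g for g in requested if g in m.index)
    if not used:
        raise ValueError(f"no gene of pathway {pathway.name!r} is present in the matrix")
    if len(used) < len(requested):
        logger.info("signature_scores %r: %d of %d genes absent from matrix",
                    pathway.name, len(requested) - len(used), len(requested))
    values = m.loc[list(used)].mean(axis=0)
    values.name = pathway.name
    return SignatureScore(name=pathway.name, values=values,
                          genes_used=used, genes_requested=requested)


def _split_groups(score: SignatureScore, meta: pd.DataFrame,
                  collapse_subjects: bool = False):
    meta = meta.loc[score.values.index]
    vals = score.values
    if collapse_subjects:
        df = pd.DataFrame({"v": vals, "subject": meta["subject_id"],
                           "diagnosis": meta["diagnosis"]})
        df = df.groupby("subject").agg({"v": "mean", "diagnosis": "first"})
        return (df.loc[df["diagnosis"] == "autism", "v"].to_numpy(),
                df.loc[df["diagnosis"] == "control", "v"].to_numpy())
    return (vals[meta["diagnosis"] == "autism"].to_numpy(),
            vals[meta["diagnosis"] == "control"].to_numpy())


def signature_ttest(score: SignatureScore, meta: pd.DataFrame,
                    equal_var: bool = False, collapse_subjects: bool = False):
    """Two-sided two-sample t-test of the signature, autism vs control.

    Welch by default; ``collapse_subjects`` first averages a subject's
    samples so paired regions do not count twice.
    Returns ``(t, p)``; negative t means lower in autism.
    """
    aut, ctrl = _split_groups(score, meta, collapse_subjects)
    if len(aut) < 2 or len(ctrl) < 2:
        raise ValueError("each diagnosis group needs >= 2 observations")
    if np.ptp(aut) == 0 and np.ptp(ctrl) == 0 and aut.mean() == ctrl.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(aut, ctrl, equal_var=equal_var)
    return float(t), float(p)


def signature_logistic(score: SignatureScore, meta: pd.DataFrame,
                       covariates=("RIN", "PMI", "age", "sex", "region")):
    """Logistic regression of diagnosis on the signature plus covariates.

    Returns ``(coefficient, p)`` for the signature term (per log2 unit,
    Wald p).  Raises :class:`FitError` on separation, rank deficiency, or
    non-convergence.
    """
    meta = meta.loc[score.values.index]
    y = (meta["diagnosis"] == "autism").to_numpy(dtype=float)
    cols = {"signature": score.values.to_numpy()}
    for cov in covariates:
        if cov == "sex":
            cols["sex"] = (meta["sex"] == "M").to_numpy(dtype=float)
        elif cov == "region":
            cols["region"] = (meta["region"] == "temporal").to_numpy(dtype=float)
        else:
            cols[cov] = meta[cov].to_numpy(dtype=float)
    X = sm.add_constant(pd.DataFrame(cols, index=score.values.index), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise FitError("logistic design is rank deficient")
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    fit = None
    last_exc: Exception | None = None
    for method in ("newton", "bfgs"):  # bfgs rescues flat-likelihood cases
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                candidate = sm.Logit(y, X).fit(disp=0, maxiter=500, method=method)
        except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
            last_exc = exc
            continue
        if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
            raise FitError("logistic fit failed: complete or quasi-complete separation")
        if candidate.mle_retvals.get("converged", False):
            fit = candidate
            break
    if fit is None:
        if last_exc is not None:
            raise FitError(f"logistic fit failed: {last_exc}") from last_exc
        raise FitError("logistic fit did not converge")
    if not np.isfinite(fit.bse["signature"]) or fit.bse["signature"] > 1e3:
        raise FitError("logistic fit is unstable (near-separation)")
    return float(fit.params["signature"]), float(fit.pvalues["signature"])


def pathway_correlation(a: SignatureScore, b: SignatureScore) -> float:
    """Pearson correlation of two signatures across their shared samples."""
    if not a.values.index.equals(b.values.index):
        raise ValueError("signatures are over different samples or orders")
    x, y = a.values.to_numpy(), b.values.to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("cannot correlate a constant signature")
    return float(stats.pearsonr(x, y)[0])


@dataclass
class NullCorrelationResult:
    """Observed signature correlation against a size-matched random-set null."""

    observed_r: float
    null_r: np.ndarray
    exceed_frac: float
    b: int
    set_size: int
    seed: int

    def permutation_p(self) -> float:
        """(#{null >= observed} + 1) / (B + 1), a proper permutation p."""
        return (int((self.null_r >= self.observed_r).sum()) + 1) / (self.b + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"null_r": self.null_r})


def random_set_null(m: pd.DataFrame, fixed: GeneSet, reference: GeneSet,
                    B: int = 10000, seed: int = 0,
                    exclude_fixed: bool = False) -> NullCorrelationResult:
    """Correlation of the fixed pathway with B random size-matched gene sets.

    The observed statistic is corr(signature(fixed), signature(reference));
    each null draw replaces the reference by a uniformly sampled
    (without replacement) gene set of the same effective size (reference
    genes present in the matrix).  ``exclude_fixed`` removes the fixed
    pathway's genes from the sampling pool.  Seeded and chunk-deterministic:
    the same seed reproduces the null vector bit for bit.
    """
    sig_fixed = signature_scores(m, fixed)
    sig_ref = signature_scores(m, reference)
    size = len(sig_ref.genes_used)
    observed = pathway_correlation(sig_fixed, sig_ref)

    pool = m.index if not exclude_fixed else m.index[~m.index.isin(list(fixed.genes))]
    if size > len(pool):
        raise ValueError(f"reference size {size} exceeds the {len(pool)}-gene sampling pool")
    X = m.loc[pool].to_numpy(dtype=float)

    f = sig_fixed.values.to_numpy()
    f = f - f.mean()
    f_norm = float(np.sqrt((f ** 2).sum()))
    if f_norm == 0:
        raise ValueError("fixed signature is constant")

    rng = np.random.default_rng(seed)
    null_r = np.empty(B)
    done = 0
    while done < B:
        c = min(_NULL_CHUNK, B - done)
        keys = rng.random((c, X.shape[0]))
        idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
        sigs = X[idx].mean(axis=1)                       # c x n_samples
        sigs -= sigs.mean(axis=1, keepdims=True)
        norms = np.sqrt((sigs ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            null_r[done:done + c] = (sigs @ f) / (norms * f_norm)
        done += c
    exceed = float((null_r > observed).mean())
    return NullCorrelationResult(observed_r=observed, null_r=null_r,
                                 exceed_frac=exceed, b=B, set_size=size, seed=seed)
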