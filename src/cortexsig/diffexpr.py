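"""Per-gene covariate-adjusted linear models with empirical-Bayes moderation.

Each gene is fit by ordinary least squares against a shared design matrix
(diagnosis plus technical/demographic covariates).  Residual variances are
then shrunk toward a pooled prior by the classic empirical-Bayes scheme:
hyperparameters (d0, s0^2) are estimated by moment-matching on the log
residual variances (digamma/trigamma inversion), the posterior variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and the moderated t uses d0 + d_g degrees of freedom.  d0 = 0 recovers the
ordinary t; d0 = +inf pins every gene to s0^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .exceptions import FitError
from .io import align

DEFAULT_COVARIATES = ("RIN", "PMI", "age", "sex", "region")


@dataclass
class DesignSpec:
    """Design of the per-gene model: diagnosis plus optional covariates.

    ``region`` restricts the fit to one cortical region; the region
    covariate is then dropped automatically (it would be constant).
    """

    covariates: tuple = DEFAULT_COVARIATES
    region: str | None = None


@dataclass
class EBayesParams:
    """Prior degrees of freedom and prior variance of the variance model."""

    d0: float          # may be math.inf
    s0_sq: float

    def __post_init__(self):
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if self.s0_sq <= 0:
            raise ValueError("s0_sq must be > 0")


def build_design(meta: pd.DataFrame, spec: DesignSpec) -> pd.DataFrame:
    """Encode the design matrix; raises on rank deficiency, naming columns."""
    cols = {"intercept": np.ones(len(meta))}
    cols["diagnosis"] = (meta["diagnosis"] == "autism").to_numpy(dtype=float)
    for cov in spec.covariates:
        if cov == "sex":
            cols["sex"] = (meta["sex"] == "M").to_numpy(dtype=float)
        elif cov == "region":
            if spec.region is None:
                cols["region"] = (meta["region"] == "temporal").to_numpy(dtype=float)
        elif cov in ("RIN", "PMI", "age"):
            cols[cov] = meta[cov].to_numpy(dtype=float)
        else:
            raise FitError(f"unknown covariate {cov!r}")
    X = pd.DataFrame(cols, index=meta.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns beyond the rank via pivoted QR
        from scipy.linalg import qr
        _, _, piv = qr(X.to_numpy(), pivoting=True)
        collinear = sorted(X.columns[i] for i in piv[rank:])
        raise FitError(f"design matrix is rank deficient; collinear columns: {collinear}")
    return X


def fit_gene_models(m: pd.DataFrame, meta: pd.DataFrame,
                    spec: DesignSpec = DesignSpec()) -> pd.DataFrame:
    """OLS per gene against the shared design.

    Returns a DataFrame indexed by gene with columns ``beta`` (diagnosis
    coefficient, autism minus control), ``sigma`` (residual SD),
    ``df_resid``, ``stdev_unscaled`` (sqrt of the unscaled coefficient
    variance) and ``mean_expr``.
    """
    m, meta = align(m, meta)
    if spec.region is not None:
        keep = meta["region"] == spec.region
        if not keep.any():
            raise FitError(f"no samples in region {spec.region!r}")
        meta = meta.loc[keep]
        m = m[meta.index.tolist()]
    X = build_design(meta, spec)
    n, p = X.shape
    if n <= p:
        raise FitError(f"need more samples ({n}) than design columns ({p})")
    Xv = X.to_numpy()
    xtx_inv = np.linalg.inv(Xv.T @ Xv)
    hat = xtx_inv @ Xv.T                      # p x n
    Y = m.to_numpy(dtype=float)               # genes x n
    coef = Y @ hat.T                          # genes x p
    resid = Y - coef @ Xv.T
    df_resid = n - p
    sigma2 = (resid ** 2).sum(axis=1) / df_resid
    j = X.columns.get_loc("diagnosis")
    return pd.DataFrame({
        "beta": coef[:, j],
        "sigma": np.sqrt(sigma2),
        "df_resid": float(df_resid),
        "stdev_unscaled": math.sqrt(xtx_inv[j, j]),
        "mean_expr": Y.mean(axis=1),
    }, index=m.index)


def _trigamma_inverse(target: float) -> float:
    """Solve trigamma(y) = target for y > 0 (Newton on the inverse scale)."""
    if target <= 0:
        return math.inf
    if target > 1e7:
        return 1.0 / math.sqrt(target)
    if target < 1e-6:
        return 1.0 / target
    y = 0.5 + 1.0 / target
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / target) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def estimate_ebayes(sigma2: np.ndarray, df_resid: float) -> EBayesParams:
    """Moment-match (d0, s0^2) from per-gene residual variances.

    Works on e_g = log(s_g^2) - digamma(d/2) + log(d/2): its mean identifies
    s0^2 and its excess variance over trigamma(d/2) identifies d0.  When the
    observed spread is no larger than the sampling noise, d0 = +inf (complete
    shrinkage).
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    ok = sigma2 > 0
    if not ok.any():
        raise FitError("all residual variances are zero; cannot moderate")
    e = np.log(sigma2[ok]) - digamma(df_resid / 2.0) + math.log(df_resid / 2.0)
    e_bar = float(e.mean())
    excess = float(e.var(ddof=1)) - float(polygamma(1, df_resid / 2.0))
    if excess <= 0:
        # spread no larger than sampling noise: complete shrinkage to the
        # plain average variance
        return EBayesParams(d0=math.inf, s0_sq=float(sigma2[ok].mean()))
    y = _trigamma_inverse(excess)
    d0 = 2.0 * y
    s0_sq = math.exp(e_bar + float(digamma(y)) - math.log(y))
    return EBayesParams(d0=d0, s0_sq=s0_sq)


def ebayes_moderate(fits: pd.DataFrame, params: EBayesParams | None = None) -> pd.DataFrame:
    """Add moderated t and raw p to a ``fit_gene_models`` frame.

    When ``params`` is omitted they are estimated from the data (requires at
    least 10 genes).
    """
    sigma2 = fits["sigma"].to_numpy() ** 2
    df_resid = fits["df_resid"].to_numpy(dtype=float)
    if params is None:
        if len(fits) < 10:
            raise FitError("need >= 10 genes to estimate moderation hyperparameters")
        if len(np.unique(df_resid)) != 1:
            raise FitError("hyperparameter estimation assumes a shared residual df")
        params = estimate_ebayes(sigma2, float(df_resid[0]))
    d0, s0_sq = params.d0, params.s0_sq
    if math.isinf(d0):
        s2_post = np.full_like(sigma2, s0_sq)
    elif d0 == 0:
        s2_post = sigma2
    else:
        s2_post = (d0 * s0_sq + df_resid * sigma2) / (d0 + df_resid)
    df_total = df_resid + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = fits["beta"].to_numpy() / (np.sqrt(s2_post) * fits["stdev_unscaled"].to_numpy())
    p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    out = fits.copy()
    out["t_mod"] = t_mod
    out["p_raw"] = p_raw
    out.attrs["ebayes"] = params
    return out


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de(m: pd.DataFrame, meta: pd.DataFrame, spec: DesignSpec = DesignSpec(),
           params: EBayesParams | None = None, adjust: bool = True) -> pd.DataFrame:
    """Fit, moderate, and (optionally) BH-adjust; one row per gene.

    ``adjust=False`` reports raw p only (used for region-restricted reruns
    where, with few samples, nothing survives multiplicity correction and
    adjusted p-values would be uninformative).
    """
    fits = fit_gene_models(m, meta, spec)
    res = ebayes_moderate(fits, params)
    res["p_adj"] = adjust_bh(res["p_raw"].to_numpy()) if adjust else np.nan
    return res


def split_updown(results: pd.DataFrame, p_adj_thresh: float = 0.05,
                 fc_thresh: float | None = None, p_col: str = "p_adj"):
    """Split significant genes into (up, down) lists by the sign of beta.

    ``fc_thresh`` additionally requires a linear-scale fold change
    ``2**|beta| > fc_thresh``.  Lists are gene-deduplicated and sorted.
    """
    if results.empty:
        raise ValueError("no results to split")
    sig = results[p_col] < p_adj_thresh
    if fc_thresh is not None:
        sig &= np.exp2(results["beta"].abs()) > fc_thresh
    up = sorted(set(results.index[sig & (results["beta"] > 0)]))
    down = sorted(set(results.index[sig & (results["beta"] < 0)]))
    return up, down
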