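"""Bulk deconvolution against an RGEP by weighted robust linear regression.

Per sample we solve a non-negative least-squares problem in which gene
weights are updated by iteratively reweighted least squares under a robust
loss (Tukey bisquare or Huber), followed by sum-to-one renormalization of
the estimated cell-type proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import pearsonr

from .rgep import RGEP

__all__ = [
    "DeconvOptions",
    "DeconvResult",
    "DeconvMetrics",
    "deconvolve",
    "evaluate_deconv",
    "aggregate_types",
]

TUKEY_C = 4.685
HUBER_C = 1.345


@dataclass
class DeconvOptions:
    robust_loss: str = "tukey_bisquare"   # 'tukey_bisquare' | 'huber' | 'none'
    max_iter: int = 50
    tol: float = 1e-6
    nonneg: bool = True
    sum_to_one: bool = True

    def validate(self) -> None:
        if self.robust_loss not in ("tukey_bisquare", "huber", "none"):
            raise ValueError("robust_loss must be 'tukey_bisquare', 'huber' or 'none'")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class DeconvResult:
    proportions: pd.DataFrame      # samples x cell types
    residual_norm: pd.Series       # per sample
    weights: pd.DataFrame          # genes x samples, final robust weights
    converged: pd.Series           # per sample


@dataclass
class DeconvMetrics:
    pearson_r_pooled: float
    pearson_r_per_sample: pd.Series
    rmse: float


def _robust_weights(resid: np.ndarray, loss: str) -> np.ndarray:
    s = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    if s <= 0:
        return np.ones_like(resid)
    u = resid / s
    if loss == "tukey_bisquare":
        w = np.where(np.abs(u) < TUKEY_C, (1 - (u / TUKEY_C) ** 2) ** 2, 0.0)
    else:  # huber
        w = np.minimum(1.0, HUBER_C / np.maximum(np.abs(u), 1e-300))
    if w.sum() == 0:
        return np.ones_like(resid)
    return w


def _solve(B: np.ndarray, y: np.ndarray, w: np.ndarray, nonneg: bool) -> np.ndarray:
    sw = np.sqrt(w)
    if nonneg:
        p, _ = nnls(B * sw[:, None], y * sw)
    else:
        p, *_ = np.linalg.lstsq(B * sw[:, None], y * sw, rcond=None)
    return p


def _check_collinear(B: np.ndarray, types: list[str]) -> None:
    Bc = B - B.mean(axis=0)
    norms = np.linalg.norm(Bc, axis=0)
    if (norms == 0).any():
        dup = [types[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"constant RGEP columns: {dup}")
    corr = (Bc / norms).T @ (Bc / norms)
    iu = np.triu_indices_from(corr, k=1)
    bad = np.flatnonzero(corr[iu] > 1 - 1e-10)
    if bad.size:
        pairs = [(types[iu[0][b]], types[iu[1][b]]) for b in bad]
        raise ValueError(f"collinear (duplicated) RGEP columns: {pairs}")


def deconvolve(
    bulk: pd.DataFrame, rgep: RGEP, options: DeconvOptions | None = None
) -> DeconvResult:
    """Estimate cell-type proportions of each bulk sample.

    The bulk matrix must be on a linear scale comparable to the RGEP (a
    uniform scale factor between the two is absorbed by the final
    renormalization).  Per sample: IRLS with robust gene weights around an
    NNLS inner solve, then division by the coefficient sum so the
    proportions sit on the unit simplex.
    """
    opts = options or DeconvOptions()
    opts.validate()
    shared = [g for g in rgep.signature_genes if g in bulk.index]
    if len(shared) < 2:
        raise ValueError("fewer than 2 genes shared between bulk and RGEP signature")
    if len(shared) < 0.5 * len(rgep.signature_genes):
        warnings.warn(
            f"only {len(shared)}/{len(rgep.signature_genes)} signature genes found in bulk"
        )
    B = rgep.profile.loc[shared].to_numpy(dtype=float)
    types = rgep.cell_types
    _check_collinear(B, types)

    Y = bulk.loc[shared].to_numpy(dtype=float)
    n_samples = Y.shape[1]
    P = np.zeros((n_samples, len(types)))
    rnorm = np.zeros(n_samples)
    Wfinal = np.ones((len(shared), n_samples))
    conv = np.zeros(n_samples, dtype=bool)

    for j in range(n_samples):
        y = Y[:, j]
        w = np.ones(len(shared))
        converged = opts.robust_loss == "none"
        p = _solve(B, y, w, opts.nonneg)
        if opts.robust_loss != "none":
            for _ in range(opts.max_iter):
                resid = y - B @ p
                w_new = _robust_weights(resid, opts.robust_loss)
                p = _solve(B, y, w_new, opts.nonneg)
                if np.max(np.abs(w_new - w)) < opts.tol:
                    converged = True
                    w = w_new
                    break
                w = w_new
        resid = y - B @ p
        rnorm[j] = float(np.linalg.norm(resid))
        Wfinal[:, j] = w
        conv[j] = converged
        if opts.sum_to_one:
            tot = p.sum()
            if tot <= 0:
                raise ValueError(f"sample {bulk.columns[j]!r}: all-zero solution")
            p = p / tot
        P[j] = p

    return DeconvResult(
        proportions=pd.DataFrame(P, index=bulk.columns, columns=types),
        residual_norm=pd.Series(rnorm, index=bulk.columns),
        weights=pd.DataFrame(Wfinal, index=shared, columns=bulk.columns),
        converged=pd.Series(conv, index=bulk.columns),
    )


def evaluate_deconv(truth, result: DeconvResult | pd.DataFrame) -> DeconvMetrics:
    """Pooled Pearson r and RMSE between true and estimated proportions."""
    true_df = truth.proportions if hasattr(truth, "proportions") else truth
    est_df = result.proportions if isinstance(result, DeconvResult) else result
    if sorted(true_df.index) != sorted(est_df.index) or sorted(true_df.columns) != sorted(
        est_df.columns
    ):
        raise ValueError("truth and estimate must share sample and cell-type labels")
    est_df = est_df.loc[true_df.index, true_df.columns]
    t = true_df.to_numpy(dtype=float)
    e = est_df.to_numpy(dtype=float)
    pooled = float(pearsonr(t.ravel(), e.ravel()).statistic)
    per_sample = pd.Series(
        [float(pearsonr(t[i], e[i]).statistic) for i in range(t.shape[0])],
        index=true_df.index,
    )
    rmse = float(np.sqrt(np.mean((t - e) ** 2)))
    return DeconvMetrics(pearson_r_pooled=pooled, pearson_r_per_sample=per_sample, rmse=rmse)


def aggregate_types(proportions: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    """Sum fine-type proportions into lineages; the simplex is preserved."""
    unmapped = [t for t in proportions.columns if t not in mapping]
    if unmapped:
        raise ValueError(f"types missing from lineage mapping: {unmapped}")
    return proportions.T.groupby(proportions.columns.map(mapping)).sum().T
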