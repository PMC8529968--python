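"""Gene-set / cell-proportion association screen.

For each gene set g and cell type C, the Pearson correlation r_gC between
the set's per-sample activation scores and the type's estimated proportions
is Fisher Z-transformed and summed across cell types,

    zbar_g = 1/2 * sum_C ln((1 + r_gC) / (1 - r_gC)),

then robustly standardized across all screened sets,

    S_g = (zbar_g - median(z)) / (1.4826 * MAD(z)),

with MAD the raw median absolute deviation about the median.  Two-sided
p-values from the standard normal select sets at p < alpha (default 0.01).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "correlate_sets_types",
    "fisher_aggregate",
    "standardize_mad",
    "select_sets",
    "associate",
]

MAD_CONSTANT = 1.4826
CLIP = 1 - 1e-7


def correlate_sets_types(
    activations: pd.DataFrame, proportions: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation across samples per (gene set, cell type) pair.

    ``activations`` is gene sets x samples; ``proportions`` is samples x cell
    types.  Samples are aligned on their shared ids.  Sets with any undefined
    correlation (constant activation or constant proportion column) are
    excluded from downstream aggregation and returned in the dropped list.
    """
    shared = [s for s in activations.columns if s in proportions.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    A = activations[shared].to_numpy(dtype=float)          # sets x n
    P = proportions.loc[shared].to_numpy(dtype=float)      # n x types

    A = A - A.mean(axis=1, keepdims=True)
    P = P - P.mean(axis=0, keepdims=True)
    a_sd = np.sqrt((A**2).sum(axis=1))
    p_sd = np.sqrt((P**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (A @ P) / np.outer(a_sd, p_sd)

    r_df = pd.DataFrame(R, index=activations.index, columns=proportions.columns)
    bad = r_df.index[r_df.isna().any(axis=1)].tolist()
    if bad:
        warnings.warn(
            f"{len(bad)} gene sets with undefined correlations excluded from aggregation"
        )
    return r_df, bad


def fisher_aggregate(r: pd.DataFrame, clip: float = CLIP) -> tuple[pd.Series, int]:
    """Aggregated Fisher Z per gene set: 1/2 * sum_C ln((1+r)/(1-r)).

    Correlations at |r| >= 1 are clipped to ``clip`` to keep the transform
    finite; the number of clipped entries is returned.
    """
    R = r.to_numpy(dtype=float)
    n_clipped = int((np.abs(R) >= 1).sum())
    Rc = np.clip(R, -clip, clip)
    zbar = 0.5 * np.log((1 + Rc) / (1 - Rc)).sum(axis=1)
    return pd.Series(zbar, index=r.index, name="zbar"), n_clipped


def standardize_mad(zbar: pd.Series) -> pd.Series:
    """Robust standardization S = (z - median(z)) / (1.4826 * MAD(z))."""
    z = zbar.to_numpy(dtype=float)
    if len(np.unique(z)) < 2:
        raise ValueError("standardization needs >= 2 distinct values")
    med = np.median(z)
    mad = np.median(np.abs(z - med))
    if mad == 0:
        raise ValueError("MAD of aggregated correlations is 0: degenerate screen")
    return pd.Series((z - med) / (MAD_CONSTANT * mad), index=zbar.index, name="S")


def select_sets(S: pd.Series, alpha: float = 0.01, two_sided: bool = True) -> pd.DataFrame:
    """p-values from the standard normal and the p < alpha selection flag."""
    s = S.to_numpy(dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("S contains non-finite values")
    if two_sided:
        p = 2 * ndtr(-np.abs(s))
    else:
        p = ndtr(-s)
    return pd.DataFrame({"S": s, "p": p, "selected": p < alpha}, index=S.index)


def associate(
    activations: pd.DataFrame,
    proportions: pd.DataFrame,
    alpha: float = 0.01,
    two_sided: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Full screen: correlations, Fisher-Z aggregation, MAD standardization, selection.

    Returns the association table (per set: r per type, zbar, S, p, selected)
    and a run report (dropped sets, clipped correlation count).
    """
    r_df, dropped = correlate_sets_types(activations, proportions)
    r_ok = r_df.drop(index=dropped)
    if len(r_ok) < 2:
        raise ValueError("fewer than 2 gene sets with defined correlations")
    zbar, n_clipped = fisher_aggregate(r_ok)
    S = standardize_mad(zbar)
    sel = select_sets(S, alpha=alpha, two_sided=two_sided)
    table = pd.concat(
        [r_ok.add_prefix("r_"), zbar.rename("zbar"), sel], axis=1
    )
    report = {
        "n_sets": int(len(r_df)),
        "n_screened": int(len(r_ok)),
        "dropped_sets": dropped,
        "n_clipped": n_clipped,
        "alpha": alpha,
        "n_selected": int(sel["selected"].sum()),
    }
    return table, report
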