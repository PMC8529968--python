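"""Reference gene-expression profile (RGEP) construction from labeled cells.

QC filtering, library-size normalization, one-vs-rest marker selection,
signature-gene union, and per-type averaging.  The RGEP is a
signature-gene x cell-type matrix of mean expression used as the basis of
bulk deconvolution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "QCThresholds",
    "MarkerCriteria",
    "RGEP",
    "qc_filter_cells",
    "normalize_sc",
    "normalize_bulk",
    "cpm",
    "find_markers",
    "merge_signature_sets",
    "build_rgep",
]


@dataclass
class QCThresholds:
    """Inclusive keep-bounds on expressed genes and total UMIs per cell."""

    min_genes: int = 200
    max_genes: int = 3000
    min_umis: int = 500
    max_umis: int = 10000

    def validate(self) -> None:
        if not (0 < self.min_genes < self.max_genes):
            raise ValueError("need 0 < min_genes < max_genes")
        if not (0 < self.min_umis < self.max_umis):
            raise ValueError("need 0 < min_umis < max_umis")


@dataclass
class MarkerCriteria:
    """One-vs-rest marker thresholds (natural-log fold change scale)."""

    logfc_threshold: float = 0.5
    min_pct: float = 0.1
    max_adj_p: float = 0.05

    def validate(self) -> None:
        if self.logfc_threshold < 0:
            raise ValueError("logfc_threshold must be >= 0")
        if not 0.0 <= self.min_pct <= 1.0:
            raise ValueError("min_pct must lie in [0, 1]")


@dataclass
class RGEP:
    """Signature-gene x cell-type matrix of mean expression."""

    profile: pd.DataFrame
    scale: str = "linear_cpm"

    @property
    def signature_genes(self) -> list[str]:
        return list(self.profile.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.profile.columns)

    def __post_init__(self) -> None:
        if self.profile.index.duplicated().any():
            raise ValueError("duplicate gene ids in RGEP")
        if (self.profile.to_numpy() > 0).sum(axis=0).min() == 0:
            raise ValueError("every RGEP column needs a strictly positive entry")
        if self.scale not in ("linear_cpm", "lognorm"):
            raise ValueError("scale must be 'linear_cpm' or 'lognorm'")

    def to_tsv(self, path, sidecar: str | None = None) -> None:
        self.profile.to_csv(path, sep="\t", index_label="gene")
        if sidecar:
            with open(sidecar, "w") as fh:
                json.dump({"scale": self.scale,
                           "n_signature_genes": len(self.signature_genes),
                           "cell_types": self.cell_types}, fh, indent=1)

    @classmethod
    def from_tsv(cls, path, scale: str = "linear_cpm") -> "RGEP":
        return cls(profile=pd.read_csv(path, sep="\t", index_col=0), scale=scale)


def qc_filter_cells(
    counts: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[pd.DataFrame, pd.Index]:
    """Keep cells with expressed-gene and UMI totals inside the bounds (inclusive)."""
    thr = thresholds or QCThresholds()
    thr.validate()
    if counts.size == 0:
        raise ValueError("empty count matrix")
    X = counts.to_numpy()
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    n_genes = (X > 0).sum(axis=0)
    n_umis = X.sum(axis=0)
    keep = (
        (n_genes >= thr.min_genes) & (n_genes <= thr.max_genes)
        & (n_umis >= thr.min_umis) & (n_umis <= thr.max_umis)
    )
    kept = counts.columns[keep]
    return counts.loc[:, kept], kept


def normalize_sc(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Per-cell log normalization: ln(1 + scale * count / cell_total)."""
    totals = counts.to_numpy().sum(axis=0)
    if (totals == 0).any():
        bad = list(counts.columns[totals == 0])
        raise ValueError(f"cells with zero total counts (QC should have removed them): {bad[:5]}")
    return np.log1p(scale * counts / totals)


def cpm(counts: pd.DataFrame, scale: float = 1e6) -> pd.DataFrame:
    """Linear counts-per-million per column."""
    totals = counts.to_numpy().sum(axis=0)
    if (totals == 0).any():
        raise ValueError("column with zero total counts")
    return scale * counts / totals


def normalize_bulk(counts: pd.DataFrame, scale: float = 1e6) -> pd.DataFrame:
    """Per-sample CPM followed by natural-log: ln(1 + 1e6 * count / total)."""
    return np.log1p(cpm(counts, scale=scale))


def _ranksum_p(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per gene (columns), exact for tiny groups."""
    n1, n2 = x_in.shape[0], x_out.shape[0]
    exact_ok = max(n1, n2) <= 10
    ps = np.empty(x_in.shape[1])
    for j in range(x_in.shape[1]):
        a, b = x_in[:, j], x_out[:, j]
        method = "exact" if exact_ok and len(np.unique(np.concatenate([a, b]))) == n1 + n2 else "asymptotic"
        ps[j] = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    return ps


def find_markers(
    norm: pd.DataFrame,
    labels: pd.Series,
    criteria: MarkerCriteria | None = None,
) -> pd.DataFrame:
    """One-vs-rest marker table per cell type.

    A gene is reported for a type iff its natural-log fold change of mean
    linear expression (expm1 of the log-normalized values, pseudocount 1)
    is >= ``logfc_threshold`` (up-regulated in the type), the fraction of
    expressing cells reaches ``min_pct`` on at least one side, and the
    BH-adjusted two-sided rank-sum p-value is <= ``max_adj_p``.
    """
    crit = criteria or MarkerCriteria()
    crit.validate()
    labels = labels.loc[norm.columns]
    type_counts = labels.value_counts()
    if len(type_counts) < 2:
        raise ValueError("find_markers needs at least 2 cell types")

    lin = np.expm1(norm.to_numpy())  # back to linear normalized scale
    expressed = norm.to_numpy() > 0
    rows = []
    for ctype in type_counts.index:
        if type_counts[ctype] < 3:
            warnings.warn(f"cell type {ctype!r} has < 3 cells; skipped")
            continue
        in_mask = (labels == ctype).to_numpy()
        m_in = lin[:, in_mask].mean(axis=1)
        m_out = lin[:, ~in_mask].mean(axis=1)
        lfc = np.log(m_in + 1.0) - np.log(m_out + 1.0)
        pct_in = expressed[:, in_mask].mean(axis=1)
        pct_out = expressed[:, ~in_mask].mean(axis=1)
        cand = (lfc >= crit.logfc_threshold) & (np.maximum(pct_in, pct_out) >= crit.min_pct)
        if not cand.any():
            continue
        idx = np.flatnonzero(cand)
        ps = _ranksum_p(norm.to_numpy()[idx][:, in_mask].T, norm.to_numpy()[idx][:, ~in_mask].T)
        adj = multipletests(ps, method="fdr_bh")[1]
        for k, gi in enumerate(idx):
            if adj[k] <= crit.max_adj_p:
                rows.append((ctype, norm.index[gi], lfc[gi], pct_in[gi], pct_out[gi], ps[k], adj[k]))

    return pd.DataFrame(
        rows, columns=["cell_type", "gene", "logfc", "pct_in", "pct_out", "p", "adj_p"]
    )


def merge_signature_sets(
    lists: list[list[str]], universe: list[str] | None = None
) -> tuple[list[str], list[str]]:
    """Order-stable deduplicated union of gene lists.

    If ``universe`` is given (the expression matrix's genes), the union is
    restricted to it and the absent genes are reported as dropped.
    """
    union = list(dict.fromkeys(g for lst in lists for g in lst))
    dropped: list[str] = []
    if universe is not None:
        present = set(universe)
        dropped = [g for g in union if g not in present]
        union = [g for g in union if g in present]
    if not union:
        raise ValueError("signature-gene union is empty")
    return union, dropped


def build_rgep(
    counts: pd.DataFrame,
    labels: pd.Series,
    signature_genes: list[str],
    scale: str = "linear_cpm",
) -> RGEP:
    """Average expression per cell type over the signature genes.

    ``scale='linear_cpm'`` averages per-cell CPM (the mixing model for
    deconvolution is linear in expression); ``'lognorm'`` averages
    ln(1 + 1e4 * count / total) instead.
    """
    labels = labels.loc[counts.columns]
    missing = [g for g in signature_genes if g not in counts.index]
    if missing:
        raise ValueError(f"signature genes absent from matrix: {missing[:5]}")
    if scale == "linear_cpm":
        expr = cpm(counts)
    elif scale == "lognorm":
        expr = normalize_sc(counts)
    else:
        raise ValueError("scale must be 'linear_cpm' or 'lognorm'")
    profile = expr.T.groupby(labels).mean().T
    empty = [t for t in profile.columns if (labels == t).sum() == 0]
    if empty:
        raise ValueError(f"cell types with zero cells: {empty}")
    return RGEP(profile=profile.loc[signature_genes], scale=scale)
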