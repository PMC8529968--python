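"""Readers/writers for the pipeline's on-disk formats.

Single-cell pools are written as MatrixMarket MTX plus genes/barcodes/labels
TSVs; bulk matrices, proportions and survival tables as plain TSV; ground
truth as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .sim import CellPool

__all__ = [
    "write_pool",
    "read_pool",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_survival_tsv",
    "read_survival_tsv",
    "write_json",
    "read_json",
]


def write_pool(pool: CellPool, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(pool.counts.to_numpy()))
    pd.Series(pool.gene_ids).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(pool.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    pool.labels.rename("cell_type").to_frame().to_csv(outdir / "labels.tsv", sep="\t")
    write_json(
        {"types": pool.types, "truth": pool.truth, "qc_fail_cells": pool.qc_fail_cells},
        outdir / "truth.json",
    )


def read_pool(indir) -> CellPool:
    indir = Path(indir)
    counts = np.asarray(spio.mmread(indir / "matrix.mtx").todense()).astype(np.int64)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    labels = pd.read_csv(indir / "labels.tsv", sep="\t", index_col=0)["cell_type"]
    truth = read_json(indir / "truth.json")
    return CellPool(
        counts=pd.DataFrame(counts, index=genes, columns=cells),
        labels=labels,
        types=truth["types"],
        truth=truth["truth"],
        qc_fail_cells=truth.get("qc_fail_cells", []),
    )


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_survival_tsv(surv: pd.DataFrame, path) -> None:
    surv.to_csv(path, sep="\t", index=False)


def read_survival_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
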