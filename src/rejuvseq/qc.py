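"""Cell- and gene-level quality control, and per-cell log-normalization.

QC follows the snRNA-seq convention for nuclei data: cells are kept when
their detected-feature count and total count fall inside open intervals
("fewer than / more than" bounds are strict, so boundary values survive),
and mitochondrial genes — identified by gene-name prefix, ``mt-`` for mouse,
matched case-insensitively — are dropped entirely *after* cell filtering,
since nuclei should not contain mitochondrial transcripts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError


@dataclass(frozen=True)
class QCThresholds:
    """Open-interval bounds on detected features and total counts per cell.

    Defaults: 500 < features < 8000 and 500 < counts < 20000 are inclusive
    (a cell with exactly 500 features is retained).
    """

    min_features: int = 500
    max_features: int = 8000
    min_counts: int = 500
    max_counts: int = 20000
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if self.min_features > self.max_features:
            raise ConfigError("min_features must be <= max_features")
        if self.min_counts > self.max_counts:
            raise ConfigError("min_counts must be <= max_counts")


@dataclass
class QCReport:
    """Number of cells/genes removed by each rule, in application order."""

    n_removed: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": list(self.n_removed), "n_removed": list(self.n_removed.values())}
        )


def qc_filter(
    adata: ad.AnnData,
    thresholds: QCThresholds | None = None,
    exclude_barcodes: set[str] | None = None,
) -> tuple[ad.AnnData, QCReport]:
    """Apply cell QC, then remove mitochondrial genes.

    Cells failing any rule are removed; rules use strict inequalities, so a
    cell with exactly ``min_features`` detected features is retained.  Gene
    removal happens after cell filtering, so detected-feature counts include
    mitochondrial genes.  An explicit ``exclude_barcodes`` list models the
    manual removal of known low-quality cells.

    Returns the filtered copy and a :class:`QCReport`; removing every cell
    is reported as a warning, not an error.
    """
    thr = thresholds or QCThresholds()
    X = sp.csr_matrix(adata.X)
    n_features = np.asarray((X > 0).sum(axis=1)).ravel()
    n_counts = np.asarray(X.sum(axis=1)).ravel()

    report = QCReport()
    keep = np.ones(adata.n_obs, dtype=bool)
    for rule, bad in [
        ("features_below_min", n_features < thr.min_features),
        ("features_above_max", n_features > thr.max_features),
        ("counts_below_min", n_counts < thr.min_counts),
        ("counts_above_max", n_counts > thr.max_counts),
    ]:
        report.n_removed[rule] = int(np.sum(bad & keep))
        keep &= ~bad
    if exclude_barcodes:
        bad = np.asarray(adata.obs_names.isin(sorted(exclude_barcodes)))
        report.n_removed["excluded_barcode"] = int(np.sum(bad & keep))
        keep &= ~bad

    mito = np.array(
        [g.lower().startswith(thr.mito_prefix.lower()) for g in adata.var_names]
    )
    report.n_removed["mitochondrial_gene"] = int(mito.sum())

    out = adata[keep, ~mito].copy()
    if out.n_obs == 0:
        warnings.warn("qc_filter removed every cell", stacklevel=2)
    return out, report


def normalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Total-count scale to ``scale`` per cell, then log1p.

    Raw counts are preserved in ``.layers['counts']``; ``.X`` becomes
    log1p(counts / cell_total * scale).  A cell with zero total counts maps
    to an all-zero row rather than NaN.
    """
    out = adata.copy()
    counts = sp.csr_matrix(out.X, dtype=np.float64)
    out.layers["counts"] = counts.copy()
    totals = np.asarray(counts.sum(axis=1)).ravel()
    factors = np.divide(
        scale, totals, out=np.zeros_like(totals, dtype=np.float64), where=totals > 0
    )
    norm = sp.diags(factors) @ counts
    norm.data = np.log1p(norm.data)
    out.X = sp.csr_matrix(norm)
    out.uns["normalization"] = {"scale": float(scale)}
    return out
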