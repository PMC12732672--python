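"""Per-cell-type two-group differential expression.

The test is the standard single-cell marker recipe: genes are gated on
detection (``min_pct`` in at least one group, ``min_cells_feature`` across
both groups combined), effect size is the log2 ratio of group means of
``expm1``-backtransformed log-normalized expression with a pseudocount of 1
(the avg_log2FC dialect of the Seurat toolkit), significance is a two-sided
Wilcoxon rank-sum test, and multiple testing is controlled per contrast per
cell type with Benjamini–Hochberg over exactly the tested genes.

A gene is a DEG when ``|avg_log2FC| > lfc_threshold`` (default 0.25) and
``p_adj < alpha`` (default 0.05).  Positive avg_log2FC means higher in
``group_a``; for the SEA contrast (Iso-P8 vs Iso-R1) that is "up in aged".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import ContractError
from .io import REJ, SEA

#: Exact rank-sum enumeration is used when both groups are at most this
#: large and the pooled values contain no ties; a tie-corrected,
#: continuity-corrected normal approximation otherwise.
EXACT_CUTOFF = 25


@dataclass(frozen=True)
class ContrastSpec:
    """A named two-group contrast within one (organ, cell_type) scope.

    ``group_a`` is the numerator/direction reference: positive fold changes
    are higher in ``group_a``.  ``cell_type``/``organ`` of ``None`` pool all
    cells (the organ-level contrast).
    """

    group_a: str
    group_b: str
    name: str = ""
    cell_type: str | None = None
    organ: str | None = None

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ContractError("contrast groups must differ")

    @classmethod
    def sea(cls, cell_type: str | None = None, organ: str | None = None) -> "ContrastSpec":
        """Senescence acceleration: aged (Iso-P8) vs young control (Iso-R1)."""
        return cls(*SEA, name="SEA", cell_type=cell_type, organ=organ)

    @classmethod
    def rej(cls, cell_type: str | None = None, organ: str | None = None) -> "ContrastSpec":
        """Rejuvenation: intervened (Het-P8) vs aged (Iso-P8)."""
        return cls(*REJ, name="REJ", cell_type=cell_type, organ=organ)

    def reversed_spec(self) -> "ContrastSpec":
        return replace(self, group_a=self.group_b, group_b=self.group_a)


@dataclass(frozen=True)
class DEParams:
    min_pct: float = 0.1
    min_cells_feature: int = 5
    lfc_threshold: float = 0.25
    alpha: float = 0.05


@dataclass
class DEGTable:
    """All tested genes of one contrast, with their statistics and flags."""

    contrast: ContrastSpec
    params: DEParams
    records: pd.DataFrame = field(repr=False)

    @property
    def degs(self) -> pd.DataFrame:
        return self.records[self.records["is_deg"].astype(bool)]


def _group_mask(adata: ad.AnnData, spec: ContrastSpec, group: str) -> np.ndarray:
    mask = (adata.obs["group"] == group).to_numpy()
    if spec.cell_type is not None:
        mask &= (adata.obs["cell_type"] == spec.cell_type).to_numpy()
    if spec.organ is not None and "organ" in adata.obs:
        mask &= (adata.obs["organ"] == spec.organ).to_numpy()
    return mask


def _split(adata: ad.AnnData, spec: ContrastSpec) -> tuple[np.ndarray, np.ndarray]:
    masks = []
    for group in (spec.group_a, spec.group_b):
        mask = _group_mask(adata, spec, group)
        if not mask.any():
            raise ContractError(
                f"contrast {spec.name or spec.group_a + '/' + spec.group_b}: "
                f"no cells for group {group!r} "
                f"(cell_type={spec.cell_type!r}, organ={spec.organ!r})"
            )
        masks.append(mask)
    return masks[0], masks[1]


def test_gate(
    adata: ad.AnnData,
    spec: ContrastSpec,
    min_pct: float = 0.1,
    min_cells_feature: int = 5,
) -> pd.Index:
    """Genes worth testing: detected in >= min_pct of cells in at least one
    group and in >= min_cells_feature cells across both groups combined."""
    mask_a, mask_b = _split(adata, spec)
    X = sp.csr_matrix(adata.X)
    det_a = np.asarray((X[mask_a] > 0).sum(axis=0)).ravel()
    det_b = np.asarray((X[mask_b] > 0).sum(axis=0)).ravel()
    pct_a = det_a / mask_a.sum()
    pct_b = det_b / mask_b.sum()
    ok = ((pct_a >= min_pct) | (pct_b >= min_pct)) & (det_a + det_b >= min_cells_feature)
    return adata.var_names[ok]


def fold_change_from_means(mean_expm1_a: np.ndarray, mean_expm1_b: np.ndarray) -> np.ndarray:
    """log2(mean expm1 + 1) difference — the Seurat avg_log2FC dialect."""
    return np.log2(mean_expm1_a + 1.0) - np.log2(mean_expm1_b + 1.0)


def fold_change(
    adata: ad.AnnData, spec: ContrastSpec, gene: str, dialect: str = "expm1"
) -> float:
    """avg_log2FC of one gene (group_a over group_b) on log-normalized data.

    ``dialect='expm1'`` (default) backtransforms before averaging;
    ``dialect='mean_log'`` is the pure difference of mean log values divided
    by log(2).
    """
    mask_a, mask_b = _split(adata, spec)
    col = adata[:, gene].X
    vals = np.asarray(col.todense() if sp.issparse(col) else col).ravel()
    a, b = vals[mask_a], vals[mask_b]
    if dialect == "expm1":
        return float(fold_change_from_means(np.expm1(a).mean(), np.expm1(b).mean()))
    if dialect == "mean_log":
        return float((a.mean() - b.mean()) / np.log(2))
    raise ValueError(f"unknown fold-change dialect {dialect!r}")


def wilcoxon_test(values_a, values_b) -> float:
    """Two-sided Mann–Whitney/Wilcoxon rank-sum p-value.

    Exact enumeration when both groups have <= EXACT_CUTOFF observations and
    the pooled sample is tie-free; tie-corrected normal approximation with
    continuity correction otherwise.  Degenerate input (every pooled value
    identical) returns p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ContractError("wilcoxon_test requires nonempty groups")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = np.unique(pooled).size == pooled.size
    if a.size <= EXACT_CUTOFF and b.size <= EXACT_CUTOFF and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def _wilcoxon_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p for matrices (genes x cells per group).

    Matches :func:`wilcoxon_test` gene by gene; the common large-group case
    is vectorized through scipy's axis support.
    """
    n_a, n_b = A.shape[1], B.shape[1]
    if n_a <= EXACT_CUTOFF and n_b <= EXACT_CUTOFF:
        return np.array([wilcoxon_test(A[i], B[i]) for i in range(A.shape[0])])
    with np.errstate(invalid="ignore", divide="ignore"):
        res = scipy.stats.mannwhitneyu(
            A, B, alternative="two-sided", method="asymptotic", axis=1
        )
    p = np.asarray(res.pvalue, dtype=float)
    constant = np.all(np.concatenate([A, B], axis=1) == A[:, :1], axis=1)
    p[constant | np.isnan(p)] = 1.0
    return p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def find_degs(
    adata: ad.AnnData,
    spec: ContrastSpec,
    params: DEParams | None = None,
    dialect: str = "expm1",
) -> DEGTable:
    """Gate, test and flag every gene of one contrast.

    ``adata`` must hold log-normalized expression in ``.X`` and group labels
    (plus cell_type/organ when the spec restricts them) in ``.obs``.
    Deterministic: rows are ordered by (p_adj, gene).
    """
    params = params or DEParams()
    genes = test_gate(adata, spec, params.min_pct, params.min_cells_feature)
    mask_a, mask_b = _split(adata, spec)
    sub = adata[:, genes]
    X = sp.csr_matrix(sub.X)
    A = np.asarray(X[mask_a].todense())
    B = np.asarray(X[mask_b].todense())

    pct_a = (A > 0).mean(axis=0)
    pct_b = (B > 0).mean(axis=0)
    if dialect == "expm1":
        lfc = fold_change_from_means(np.expm1(A).mean(axis=0), np.expm1(B).mean(axis=0))
    elif dialect == "mean_log":
        lfc = (A.mean(axis=0) - B.mean(axis=0)) / np.log(2)
    else:
        raise ValueError(f"unknown fold-change dialect {dialect!r}")

    p = _wilcoxon_matrix(A.T, B.T)
    p_adj = bh_adjust(p)
    is_deg = (np.abs(lfc) > params.lfc_threshold) & (p_adj < params.alpha)
    direction = np.where(~is_deg, "none", np.where(lfc > 0, "up", "down"))

    records = pd.DataFrame(
        {
            "gene": np.asarray(genes),
            "avg_log2FC": lfc,
            "pct_a": pct_a,
            "pct_b": pct_b,
            "p_value": p,
            "p_adj": p_adj,
            "is_deg": is_deg,
            "direction": direction,
        }
    ).sort_values(["p_adj", "gene"], kind="mergesort", ignore_index=True)
    return DEGTable(contrast=spec, params=params, records=records)
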