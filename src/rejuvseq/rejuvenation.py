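"""Downstream rejuvenation statistics.

Given SEA (aged vs young control) and REJ (intervened vs aged) DEG tables
for the same scope, an aging DEG is

* **reversed** when its REJ estimate has the opposite sign and
  ``|rej avg_log2FC| > 0.1`` — an effect-size gate only;
* **rescued** when the REJ estimate is an opposite-direction REJ DEG, i.e.
  opposite sign, ``|rej avg_log2FC| > 0.25`` and ``rej p_adj < alpha``.

Rescued genes therefore always form a subset of reversed genes.  An optional
flag adds the significance requirement to the reversed class as well, to
probe sensitivity to that stricter reading.

The module also implements the transcriptional-noise coefficient of
variation (CV of per-gene absolute group-mean differences over highly
variable genes), Pearson group similarity over a DEG union, cross-subtype
DEG module assignment, and the expression-bin-controlled per-cell gene-set
identity score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .de import DEGTable
from .errors import ContractError


def round_half_up(x: float) -> int:
    """Display rounding for percentages: 23.5 -> 24, never banker's."""
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# reversed / rescued classification and reversal ratios
# ---------------------------------------------------------------------------

def classify_reversal(
    sea: DEGTable,
    rej: DEGTable,
    reverse_lfc: float = 0.1,
    rescue_lfc: float = 0.25,
    alpha: float = 0.05,
    require_rej_significance: bool = False,
) -> pd.DataFrame:
    """Classify every SEA DEG as not_reversed / reversed / rescued.

    SEA DEGs absent from the REJ tested set are not_reversed.  Scopes of the
    two tables must match.
    """
    if not (0 < reverse_lfc <= rescue_lfc):
        raise ContractError("need 0 < reverse_lfc <= rescue_lfc")
    for attr in ("cell_type", "organ"):
        if getattr(sea.contrast, attr) != getattr(rej.contrast, attr):
            raise ContractError(
                f"SEA and REJ tables disagree on {attr}: "
                f"{getattr(sea.contrast, attr)!r} vs {getattr(rej.contrast, attr)!r}"
            )

    sea_degs = sea.degs.set_index("gene")
    rej_all = rej.records.set_index("gene")
    out = pd.DataFrame(
        {
            "gene": sea_degs.index,
            "sea_direction": sea_degs["direction"].to_numpy(),
            "sea_lfc": sea_degs["avg_log2FC"].to_numpy(),
        }
    )
    joined = rej_all.reindex(sea_degs.index)
    out["rej_lfc"] = joined["avg_log2FC"].to_numpy()
    out["rej_p_adj"] = joined["p_adj"].to_numpy()

    tested = out["rej_lfc"].notna().to_numpy()
    rej_lfc = out["rej_lfc"].fillna(0.0).to_numpy()
    rej_p = out["rej_p_adj"].fillna(1.0).to_numpy()
    opposite = np.sign(rej_lfc) == -np.sign(out["sea_lfc"].to_numpy())
    significant = rej_p < alpha

    reversed_ = tested & opposite & (np.abs(rej_lfc) > reverse_lfc)
    if require_rej_significance:
        reversed_ &= significant
    rescued = tested & opposite & (np.abs(rej_lfc) > rescue_lfc) & significant
    rescued &= reversed_  # rescued ⊆ reversed under every flag combination

    out["status"] = np.where(rescued, "rescued", np.where(reversed_, "reversed", "not_reversed"))
    return out


@dataclass
class ReversalReport:
    """Reversed/rescued counts and percentages for one scope.

    Percentages are exact fractions (``*_exact``); ``*_display`` applies
    round-half-up to integer percent.  A direction with zero SEA DEGs has
    undefined (None/NaN) percentages rather than 0.
    """

    scope: str
    n_up: int
    n_up_reversed: int
    n_up_rescued: int
    n_down: int
    n_down_reversed: int
    n_down_rescued: int

    @staticmethod
    def _pct(k: int, n: int) -> float | None:
        return 100.0 * k / n if n else None

    @property
    def pct_up_reversed(self):
        return self._pct(self.n_up_reversed, self.n_up)

    @property
    def pct_down_reversed(self):
        return self._pct(self.n_down_reversed, self.n_down)

    @property
    def pct_up_rescued(self):
        return self._pct(self.n_up_rescued, self.n_up)

    @property
    def pct_down_rescued(self):
        return self._pct(self.n_down_rescued, self.n_down)

    def to_row(self) -> dict:
        def disp(p):
            return round_half_up(p) if p is not None else None

        return {
            "scope": self.scope,
            "n_up": self.n_up,
            "n_up_reversed": self.n_up_reversed,
            "pct_up_reversed_exact": self.pct_up_reversed,
            "pct_up_reversed_display": disp(self.pct_up_reversed),
            "n_up_rescued": self.n_up_rescued,
            "pct_up_rescued_exact": self.pct_up_rescued,
            "pct_up_rescued_display": disp(self.pct_up_rescued),
            "n_down": self.n_down,
            "n_down_reversed": self.n_down_reversed,
            "pct_down_reversed_exact": self.pct_down_reversed,
            "pct_down_reversed_display": disp(self.pct_down_reversed),
            "n_down_rescued": self.n_down_rescued,
            "pct_down_rescued_exact": self.pct_down_rescued,
            "pct_down_rescued_display": disp(self.pct_down_rescued),
        }


def reversal_ratio(statuses: pd.DataFrame, scope: str = "") -> ReversalReport:
    """Count reversed/rescued SEA DEGs per direction for one scope."""
    if len(statuses) == 0:
        raise ContractError(f"no SEA DEG statuses for scope {scope!r}")
    counts = {}
    for direction in ("up", "down"):
        sub = statuses[statuses["sea_direction"] == direction]
        counts[f"n_{direction}"] = len(sub)
        counts[f"n_{direction}_reversed"] = int(
            sub["status"].isin(["reversed", "rescued"]).sum()
        )
        counts[f"n_{direction}_rescued"] = int((sub["status"] == "rescued").sum())
    return ReversalReport(scope=scope, **counts)


# ---------------------------------------------------------------------------
# highly variable genes and the CV noise statistic
# ---------------------------------------------------------------------------

def select_hvg(adata: ad.AnnData, cells=None, n: int = 1500) -> pd.Index:
    """Top-``n`` genes by variance-stabilized standardized variance.

    Per-gene variance is standardized against a mean–variance trend fitted
    in log10 space (quadratic polynomial over genes with positive mean and
    variance), in the spirit of the vst ranking.  Uses raw counts from
    ``.layers['counts']`` when present, else ``.X``.  Constant genes are
    never selected; fewer than ``n`` eligible genes returns them all with a
    warning.  Ties break deterministically by gene identifier.
    """
    sub = adata[cells] if cells is not None else adata
    if sub.n_obs < 2:
        raise ContractError("select_hvg needs at least 2 cells")
    X = sub.layers["counts"] if "counts" in sub.layers else sub.X
    X = sp.csr_matrix(X)
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean**2) * X.shape[0] / (X.shape[0] - 1)
    # guard against catastrophic cancellation marking constant genes variable
    constant = (
        np.asarray(X.max(axis=0).todense()).ravel()
        == np.asarray(X.min(axis=0).todense()).ravel()
    )
    var[constant] = 0.0

    eligible = (var > 0) & (mean > 0)
    if eligible.sum() < n:
        warnings.warn(
            f"only {int(eligible.sum())} positive-variance genes available "
            f"(requested {n})",
            stacklevel=2,
        )
    lm = np.log10(mean[eligible])
    lv = np.log10(var[eligible])
    if eligible.sum() >= 3 and np.unique(lm).size >= 3:
        coef = np.polyfit(lm, lv, deg=2)
        expected = 10 ** np.polyval(coef, lm)
    else:  # too few genes to fit a trend; fall back to raw variance
        expected = np.ones(int(eligible.sum()))
    std_var = np.full(adata.n_vars, -np.inf)
    std_var[eligible] = var[eligible] / expected

    order = pd.DataFrame(
        {"gene": sub.var_names, "std_var": std_var}
    ).sort_values(["std_var", "gene"], ascending=[False, True], kind="mergesort")
    order = order[np.isfinite(order["std_var"])]
    return pd.Index(order["gene"].head(n))


def cv_statistic(
    adata: ad.AnnData,
    cell_type: str,
    group_a: str,
    group_b: str,
    hvgs: pd.Index,
) -> float:
    """CV (sd x 1/mean, sample sd) of per-HVG |group-mean| differences.

    Means are over log-normalized expression within cells of ``cell_type``.
    Returns NaN (the undefined marker) when the mean difference is zero.
    """
    if len(hvgs) == 0:
        raise ContractError("empty HVG set")
    ct = (adata.obs["cell_type"] == cell_type).to_numpy()
    masks = []
    for g in (group_a, group_b):
        m = ct & (adata.obs["group"] == g).to_numpy()
        if m.sum() < 2:
            raise ContractError(f"group {g!r} has fewer than 2 {cell_type!r} cells")
        masks.append(m)
    X = sp.csr_matrix(adata[:, hvgs].X)
    mean_a = np.asarray(X[masks[0]].mean(axis=0)).ravel()
    mean_b = np.asarray(X[masks[1]].mean(axis=0)).ravel()
    d = np.abs(mean_a - mean_b)
    if d.mean() == 0:
        return float("nan")
    return float(np.std(d, ddof=1) / d.mean())


@dataclass
class NoiseReport:
    """Transcriptional-change CV for one cell type.

    ``cv_aged`` compares young control vs aged (Iso-R1 / Iso-P8),
    ``cv_intervened`` young control vs intervened aged (Iso-R1 / Het-P8),
    both on the same HVG set; ``delta_cv = cv_aged - cv_intervened``.
    """

    cell_type: str
    cv_aged: float
    cv_intervened: float
    n_hvg: int

    @property
    def delta_cv(self) -> float:
        return self.cv_aged - self.cv_intervened

    def to_row(self) -> dict:
        return {
            "cell_type": self.cell_type,
            "cv_aged": self.cv_aged,
            "cv_intervened": self.cv_intervened,
            "delta_cv": self.delta_cv,
            "n_hvg": self.n_hvg,
        }


def cv_delta(
    adata: ad.AnnData, cell_type: str, hvgs: pd.Index | None = None, n_hvg: int = 1500
) -> NoiseReport:
    """CV(Iso-R1 vs Iso-P8) minus CV(Iso-R1 vs Het-P8) on one HVG set.

    When ``hvgs`` is None they are selected from the cell type's cells
    (all groups pooled).
    """
    if hvgs is None:
        cells = (adata.obs["cell_type"] == cell_type).to_numpy()
        hvgs = select_hvg(adata, cells=cells, n=n_hvg)
    cv_aged = cv_statistic(adata, cell_type, "Iso-R1", "Iso-P8", hvgs)
    cv_int = cv_statistic(adata, cell_type, "Iso-R1", "Het-P8", hvgs)
    return NoiseReport(
        cell_type=cell_type, cv_aged=cv_aged, cv_intervened=cv_int, n_hvg=len(hvgs)
    )


# ---------------------------------------------------------------------------
# group similarity
# ---------------------------------------------------------------------------

def group_similarity(
    adata: ad.AnnData,
    cell_type: str | None,
    gene_set,
    groups=("Iso-R1", "Iso-P8", "Het-P8"),
    scaled: bool = False,
) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-group mean expression vectors.

    Vectors are means of log-normalized expression over ``gene_set`` within
    cells of ``cell_type`` (all cells when None).  Zero-variance vectors
    yield NaN entries.  ``scaled=True`` returns a row-standardized copy for
    display instead of the raw symmetric matrix.
    """
    gene_set = pd.Index(gene_set)
    if len(gene_set) < 2:
        raise ContractError("group_similarity needs >= 2 genes")
    base = np.ones(adata.n_obs, dtype=bool)
    if cell_type is not None:
        base &= (adata.obs["cell_type"] == cell_type).to_numpy()
    X = sp.csr_matrix(adata[:, gene_set].X)
    vectors = {}
    for g in groups:
        m = base & (adata.obs["group"] == g).to_numpy()
        if not m.any():
            raise ContractError(f"no {cell_type!r} cells in group {g!r}")
        vectors[g] = np.asarray(X[m].mean(axis=0)).ravel()
    V = np.vstack([vectors[g] for g in groups])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(V)
    zero_var = V.std(axis=1) == 0
    corr[zero_var, :] = np.nan
    corr[:, zero_var] = np.nan
    np.fill_diagonal(corr, np.where(zero_var, np.nan, 1.0))
    df = pd.DataFrame(corr, index=list(groups), columns=list(groups))
    if scaled:
        mu = df.mean(axis=1)
        sd = df.std(axis=1, ddof=1)
        df = df.sub(mu, axis=0).div(sd, axis=0)
    return df


# ---------------------------------------------------------------------------
# cross-subtype DEG modules
# ---------------------------------------------------------------------------

def assign_modules(sea_tables: dict[str, DEGTable]) -> pd.DataFrame:
    """Map each (gene, direction) to the subset of subtypes calling it a DEG.

    ``sea_tables`` maps subtype name -> its SEA DEGTable; subtype order (and
    hence module numbering) follows the dict's insertion order.  Module ids
    are canonical: up-modules first, membership subsets in binary order with
    bit *i* marking the *i*-th subtype, so for S subtypes ids run
    1..2^S-1 (up) and 2^S-1+1..2(2^S-1) (down) — at most 14 modules for
    S = 3.  A gene can hold one up- and one down-assignment (in disjoint
    subtype sets), never two of the same direction.
    """
    if len(sea_tables) < 2:
        raise ContractError("assign_modules needs >= 2 subtype tables")
    subtypes = list(sea_tables)
    n_subsets = 2 ** len(subtypes) - 1
    membership: dict[tuple[str, str], int] = {}
    for i, name in enumerate(subtypes):
        degs = sea_tables[name].degs
        for gene, direction in zip(degs["gene"], degs["direction"]):
            key = (gene, direction)
            membership[key] = membership.get(key, 0) | (1 << i)

    rows = []
    for (gene, direction), bits in sorted(membership.items()):
        members = [s for i, s in enumerate(subtypes) if bits & (1 << i)]
        module_id = bits if direction == "up" else n_subsets + bits
        rows.append(
            {
                "gene": gene,
                "direction": direction,
                "member_subtypes": ",".join(members),
                "module_id": module_id,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "direction", "member_subtypes", "module_id"])


# ---------------------------------------------------------------------------
# per-cell gene-set identity score
# ---------------------------------------------------------------------------

def identity_score(
    adata: ad.AnnData,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    _control_pool: list | None = None,
) -> pd.Series:
    """Per-cell identity score: mean set expression minus matched control.

    Genes are ranked by dataset-wide mean log-normalized expression and cut
    into ``n_bins`` equal-frequency bins; for each set gene, ``n_ctrl``
    control genes are drawn with replacement (seeded) from its bin, and the
    score is mean(set) - mean(control draws, with multiplicity).  The score
    is invariant to adding a constant to all genes of a cell.

    ``_control_pool`` overrides the drawn controls (testing hook).
    """
    gene_set = pd.Index(gene_set)
    if len(gene_set) == 0:
        raise ContractError("empty gene set")
    missing = gene_set.difference(adata.var_names)
    if len(missing):
        raise ContractError(f"gene set members absent from matrix: {list(missing)[:5]}")

    X = sp.csr_matrix(adata.X)
    gene_mean = np.asarray(X.mean(axis=0)).ravel()
    # stable rank: mean ascending, gene id as deterministic tie-break
    order = np.lexsort((np.asarray(adata.var_names), gene_mean))
    bins = np.array_split(order, n_bins)
    bin_of = np.empty(adata.n_vars, dtype=int)
    for b, idx in enumerate(bins):
        bin_of[idx] = b

    var_index = pd.Index(adata.var_names)
    set_idx = var_index.get_indexer(gene_set)
    if _control_pool is not None:
        ctrl_idx = var_index.get_indexer(pd.Index(_control_pool))
    else:
        rng = np.random.default_rng(seed)
        draws = [rng.choice(bins[bin_of[g]], size=n_ctrl, replace=True) for g in set_idx]
        ctrl_idx = np.concatenate(draws)

    set_mean = np.asarray(X[:, set_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(X[:, ctrl_idx].mean(axis=1)).ravel()
    return pd.Series(set_mean - ctrl_mean, index=adata.obs_names, name="score")
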