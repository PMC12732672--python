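"""Reading and writing the on-disk formats the pipeline touches.

Counts travel as a 10x-style triplet: a Matrix-Market coordinate file with
genes as rows and cells as columns, plus one-identifier-per-line ``features``
and ``barcodes`` sidecars (tab-delimited sidecars are accepted; the first
column is used).  In memory everything is an :class:`anndata.AnnData` with
cells as ``obs`` and genes as ``var`` — the transposition happens here and
nowhere else.

Cell metadata is a TSV with columns ``barcode``, ``sample_id``, ``group``,
``organ`` and ``cell_type``; ``group`` must come from the four parabiosis
arms (Iso-R1, Iso-P8, Het-R1, Het-P8).
"""

from __future__ import annotations

import gzip
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import DimensionError, FormatError

#: The four parabiosis arms: isochronic young control, isochronic aged,
#: heterochronic young partner, heterochronic aged (intervened) animal.
GROUPS = ("Iso-R1", "Iso-P8", "Het-R1", "Het-P8")

#: Contrast shorthand used throughout: SEA = senescence acceleration
#: (aged vs young control), REJ = rejuvenation (intervened vs aged).
SEA = ("Iso-P8", "Iso-R1")
REJ = ("Het-P8", "Iso-P8")

ANNOTATION_COLUMNS = ("barcode", "sample_id", "group", "organ", "cell_type")


def _read_ids(path: str | Path) -> list[str]:
    """One identifier per line; first tab-delimited field if there are more."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return ids


def read_matrix(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> ad.AnnData:
    """Read a genes x cells Matrix-Market triplet into an AnnData (cells x genes).

    Duplicate coordinate entries are summed, per the coordinate-format
    convention.  Values must be nonnegative integers.

    Raises
    ------
    DimensionError
        If a sidecar's length disagrees with the Matrix-Market header.
    FormatError
        If any entry is negative or non-integral, or identifiers repeat.
    """
    mat = scipy.io.mmread(str(matrix_path))
    if not sp.issparse(mat):  # dense array-format .mtx
        mat = sp.coo_matrix(mat)
    data = np.asarray(mat.data if hasattr(mat, "data") else mat)
    if data.size and (np.any(data < 0) or np.any(data != np.floor(data))):
        raise FormatError(f"{matrix_path}: counts must be nonnegative integers")

    genes = _read_ids(features_path)
    barcodes = _read_ids(barcodes_path)
    if len(genes) != mat.shape[0]:
        raise DimensionError(
            f"features file lists {len(genes)} genes but matrix header "
            f"declares {mat.shape[0]} rows"
        )
    if len(barcodes) != mat.shape[1]:
        raise DimensionError(
            f"barcodes file lists {len(barcodes)} cells but matrix header "
            f"declares {mat.shape[1]} columns"
        )
    if len(set(genes)) != len(genes):
        raise FormatError("duplicate gene identifiers in features file")
    if len(set(barcodes)) != len(barcodes):
        raise FormatError("duplicate cell barcodes in barcodes file")

    # tocsr() sums duplicate COO entries; transpose to cells x genes
    counts = sp.csr_matrix(mat.T.tocsr(), dtype=np.float64)
    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    return adata


def write_matrix(adata: ad.AnnData, out_dir: str | Path, layer: str | None = None) -> None:
    """Write counts back out as matrix.mtx + features.tsv + barcodes.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = adata.layers[layer] if layer else adata.X
    mat = sp.coo_matrix(X.T)  # back to genes x cells on disk
    scipy.io.mmwrite(str(out / "matrix.mtx"), mat, field="integer")
    (out / "features.tsv").write_text("\n".join(adata.var_names) + "\n")
    (out / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")


def read_annotation(metadata_path: str | Path) -> pd.DataFrame:
    """Read and validate the cell-metadata TSV.

    Returns a DataFrame indexed by barcode with columns sample_id, group,
    organ, cell_type.  Unknown group labels, missing columns and duplicate
    barcodes are hard errors naming the offender.
    """
    df = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata is missing required column(s): {missing}")
    dup = df["barcode"][df["barcode"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate barcode(s) in metadata: {sorted(set(dup))[:5]}")
    bad = sorted(set(df["group"]) - set(GROUPS))
    if bad:
        raise FormatError(
            f"unknown group label(s) {bad}; expected one of {list(GROUPS)}"
        )
    return df.set_index("barcode")[list(ANNOTATION_COLUMNS[1:])]


def attach_annotation(adata: ad.AnnData, ann: pd.DataFrame) -> ad.AnnData:
    """Subset to annotated barcodes and copy annotation columns into .obs."""
    keep = adata.obs_names.intersection(ann.index)
    out = adata[keep].copy()
    out.obs = out.obs.join(ann, how="left")
    return out


def read_barcode_list(path: str | Path) -> set[str]:
    """Plain one-barcode-per-line exclusion list."""
    return {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }
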