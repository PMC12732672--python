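"""End-to-end orchestration and summary reporting.

``run_pipeline`` chains QC -> normalization -> per-scope SEA/REJ
differential expression -> reversed/rescued classification -> reversal
ratios -> transcriptional-noise CV -> group similarity -> cross-subtype
modules -> optional identity scores, writing one TSV per stage plus a
summary table of the ring-chart quantities (Rev-Up % / Rev-Down % per
scope) and a JSON manifest recording every parameter and seed.  Identical
configuration yields byte-identical outputs.

``verify_printed_ratios`` is a self-check of the ratio arithmetic against
the published organ-level reference counts bundled below.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import pandas as pd

from . import io as rio
from .de import ContrastSpec, DEGTable, DEParams, find_degs
from .errors import ConfigError, ContractError
from .qc import QCThresholds, normalize, qc_filter
from .rejuvenation import (
    assign_modules,
    classify_reversal,
    cv_delta,
    group_similarity,
    identity_score,
    reversal_ratio,
    round_half_up,
)
from .simulate import SimConfig, simulate

log = logging.getLogger("rejuvseq")

#: Published organ-level reference counts (aged-vs-young DEG totals and the
#: number reversed after intervention) used by :func:`verify_printed_ratios`:
#: (organ, direction, n_degs, n_reversed, printed_pct).
PRINTED_REVERSAL_COUNTS = (
    ("brain", "up", 424, 203, 48),
    ("brain", "down", 1515, 357, 24),
    ("liver", "up", 1670, 1086, 65),
    ("liver", "down", 1818, 459, 25),
    ("heart", "up", 723, 462, 64),
    ("heart", "down", 513, 388, 76),
)

#: (organ, printed total DEG count) — must equal the up + down sums above.
PRINTED_ORGAN_TOTALS = (("brain", 1939), ("liver", 3488), ("heart", 1236))


def verify_printed_ratios() -> pd.DataFrame:
    """Recompute the published display percentages and organ totals.

    Applies the same round-half-up display rounding the reversal reports
    use to the bundled (total, reversed) pairs, and sums the per-direction
    DEG counts; returns an expected-vs-computed table with an ``ok`` flag.
    """
    rows = []
    for organ, direction, n, n_rev, printed in PRINTED_REVERSAL_COUNTS:
        computed = round_half_up(100.0 * n_rev / n)
        rows.append(
            {
                "check": f"{organ}_rev_{direction}_pct",
                "expected": printed,
                "computed": computed,
                "ok": computed == printed,
            }
        )
    sums = {
        organ: sum(n for o, _, n, _, _ in PRINTED_REVERSAL_COUNTS if o == organ)
        for organ, _ in PRINTED_ORGAN_TOTALS
    }
    for organ, printed_total in PRINTED_ORGAN_TOTALS:
        rows.append(
            {
                "check": f"{organ}_total_degs",
                "expected": printed_total,
                "computed": sums[organ],
                "ok": sums[organ] == printed_total,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; mirrored by the CLI flags."""

    out_dir: str = "rejuvseq_out"
    # input mode: either a simulation config, or paths to a count bundle
    sim: SimConfig | None = None
    matrix_path: str | None = None
    features_path: str | None = None
    barcodes_path: str | None = None
    metadata_path: str | None = None
    exclude_barcodes_path: str | None = None
    # stage parameters
    qc: QCThresholds = field(default_factory=QCThresholds)
    de: DEParams = field(default_factory=DEParams)
    reverse_lfc: float = 0.1
    rescue_lfc: float = 0.25
    require_rej_significance: bool = False
    n_hvg: int = 1500
    normalize_scale: float = 1e4
    identity_gene_sets: dict[str, list[str]] = field(default_factory=dict)
    score_seed: int = 0
    skip_qc: bool = False

    def validate(self) -> None:
        paths = [self.matrix_path, self.features_path, self.barcodes_path, self.metadata_path]
        if self.sim is None and any(p is None for p in paths):
            raise ConfigError(
                "either a simulation config or all of matrix/features/barcodes/"
                "metadata paths must be given"
            )
        for p in paths + [self.exclude_barcodes_path]:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if not (0 < self.reverse_lfc <= self.rescue_lfc):
            raise ConfigError("need 0 < reverse_lfc <= rescue_lfc")


def _load(cfg: RunConfig) -> ad.AnnData:
    if cfg.sim is not None:
        log.info("simulating counts: %s", cfg.sim)
        adata, truth = simulate(cfg.sim)
        adata.uns["truth"] = truth
        return adata
    log.info("reading matrix %s", cfg.matrix_path)
    adata = rio.read_matrix(cfg.matrix_path, cfg.features_path, cfg.barcodes_path)
    ann = rio.read_annotation(cfg.metadata_path)
    return rio.attach_annotation(adata, ann)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write the report bundle; returns a result dict
    with the in-memory tables (keys: summary, reversal, noise, degs, ...)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    adata = _load(cfg)
    truth = adata.uns.pop("truth", None)
    if truth is not None:
        _write_tsv(truth, out / "truth.tsv")

    if cfg.skip_qc:
        filtered = adata
    else:
        excl = (
            rio.read_barcode_list(cfg.exclude_barcodes_path)
            if cfg.exclude_barcodes_path
            else None
        )
        filtered, qc_report = qc_filter(adata, cfg.qc, exclude_barcodes=excl)
        _write_tsv(qc_report.to_frame(), out / "qc_report.tsv")
        log.info("QC: %d -> %d cells", adata.n_obs, filtered.n_obs)
    norm = normalize(filtered, scale=cfg.normalize_scale)

    cell_types = list(dict.fromkeys(norm.obs["cell_type"]))
    organ = norm.obs["organ"].iloc[0] if "organ" in norm.obs else None

    degs: dict[tuple[str, str], DEGTable] = {}
    statuses: dict[str, pd.DataFrame] = {}
    summary_rows, reversal_rows, noise_rows = [], [], []
    for ct in cell_types:
        sea = find_degs(norm, ContrastSpec.sea(cell_type=ct), cfg.de)
        rej = find_degs(norm, ContrastSpec.rej(cell_type=ct), cfg.de)
        degs[(ct, "SEA")], degs[(ct, "REJ")] = sea, rej
        for name, table in (("SEA", sea), ("REJ", rej)):
            _write_tsv(table.records, out / f"deg_{organ}_{ct}_{name}.tsv")

        status = classify_reversal(
            sea,
            rej,
            reverse_lfc=cfg.reverse_lfc,
            rescue_lfc=cfg.rescue_lfc,
            alpha=cfg.de.alpha,
            require_rej_significance=cfg.require_rej_significance,
        )
        statuses[ct] = status
        if len(status):
            report = reversal_ratio(status, scope=f"{organ}/{ct}")
            reversal_rows.append(report.to_row())
            summary_rows.append(
                {
                    "scope": report.scope,
                    "n_sea_degs": report.n_up + report.n_down,
                    "rev_up_pct": report.to_row()["pct_up_reversed_display"],
                    "rev_down_pct": report.to_row()["pct_down_reversed_display"],
                }
            )
        noise_rows.append(cv_delta(norm, ct, n_hvg=cfg.n_hvg).to_row())

        union = pd.Index(sea.degs["gene"]).union(rej.degs["gene"])
        if len(union) >= 2:
            sim_df = group_similarity(norm, ct, union)
            sim_df.to_csv(out / f"similarity_{ct}.tsv", sep="\t", float_format="%.10g")

    reversal_df = pd.DataFrame(reversal_rows)
    _write_tsv(reversal_df, out / "reversal_report.tsv")
    noise_df = pd.DataFrame(noise_rows)
    _write_tsv(noise_df, out / "noise.tsv")
    summary_df = pd.DataFrame(summary_rows)
    _write_tsv(summary_df, out / "summary.tsv")

    modules_df = None
    if len(cell_types) >= 2:
        modules_df = assign_modules({ct: degs[(ct, "SEA")] for ct in cell_types})
        _write_tsv(modules_df, out / "modules.tsv")

    score_frames = []
    for set_name, gene_list in cfg.identity_gene_sets.items():
        scores = identity_score(norm, gene_list, seed=cfg.score_seed)
        score_frames.append(
            pd.DataFrame(
                {"barcode": scores.index, "set": set_name, "score": scores.to_numpy()}
            )
        )
    if score_frames:
        _write_tsv(pd.concat(score_frames, ignore_index=True), out / "scores.tsv")

    manifest = {
        "config": _manifest_dict(cfg),
        "n_cells_input": int(adata.n_obs),
        "n_cells_after_qc": int(filtered.n_obs),
        "cell_types": cell_types,
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {
        "adata": norm,
        "degs": degs,
        "statuses": statuses,
        "reversal": reversal_df,
        "noise": noise_df,
        "summary": summary_df,
        "modules": modules_df,
        "truth": truth,
    }


def _manifest_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _manifest_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _manifest_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_manifest_dict(v) for v in obj]
    return obj
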