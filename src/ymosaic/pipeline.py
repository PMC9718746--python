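"""End-to-end orchestration: annotate -> QC -> genotype -> composition ->
dosage -> differential expression -> ddPCR cross-check, from one YAML config.

Every output carries a provenance header (tool version, config hash, master
seed); per-stage seeds are derived deterministically from the master seed so
the whole report is reproducible from a single number. Optional stages
(dropout-reference calibration, reference dosage comparison, ddPCR) are
skipped, and marked as skipped, when their inputs are absent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from . import annotation_io as aio
from . import composition as comp
from . import ddpcr as ddp
from . import diffexp as de
from . import dosage as dos
from . import genotyping as gt
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]


class QcThresholds(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_genes: int = Field(200, ge=0)
    min_umi: int = Field(500, ge=0)
    max_mito_fraction: float = Field(0.10, ge=0.0, le=1.0)


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    # mandatory inputs
    matrix: str
    barcodes: str
    features: str
    cell_types: str
    annotation: str
    annotation_format: str = "tsv"

    # optional inputs
    reference_matrix: str | None = None
    reference_barcodes: str | None = None
    reference_features: str | None = None
    reference_ratios: str | None = None  # TSV: label, y_sum, x_sum (per donor)
    ddpcr_table: str | None = None
    malignancy_list: str | None = None

    # parameters
    qc: QcThresholds = QcThresholds()
    min_y_umi: int = Field(1, ge=1)
    n_perm: int = Field(10000, ge=100)
    alpha: float = Field(0.05, gt=0.0, le=1.0)
    de_mode: str = "per_type"
    min_frac_expressing: float = Field(0.1, ge=0.0, le=1.0)
    y_copies_per_positive_cell: float = Field(3.0, gt=0.0)
    seed: int = 0
    outdir: str = "ymosaic_out"

    @field_validator("annotation_format")
    @classmethod
    def _fmt(cls, v):
        if v not in ("tsv", "gtf"):
            raise ValueError("annotation_format must be 'tsv' or 'gtf'")
        return v

    @field_validator("de_mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("per_type", "aggregate"):
            raise ValueError("de_mode must be 'per_type' or 'aggregate'")
        return v

    def required_paths(self) -> dict:
        return {
            "matrix": self.matrix,
            "barcodes": self.barcodes,
            "features": self.features,
            "cell_types": self.cell_types,
            "annotation": self.annotation,
        }


def validate_config(path) -> PipelineConfig:
    """Load + validate a YAML config; checks that mandatory inputs exist."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        cfg = PipelineConfig(**raw)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigurationError(f"invalid pipeline config {path}: {exc}") from exc
    for key, p in cfg.required_paths().items():
        if not Path(p).exists():
            raise ConfigurationError(f"config key {key!r}: path {p} does not exist")
    return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(cfg: PipelineConfig) -> dict:
    return {"tool": "ymosaic", "version": __version__,
            "config_sha256": _config_hash(cfg), "seed": cfg.seed}


def _write_tsv(df: pd.DataFrame, path: Path, prov: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ymosaic v{prov['version']} config={prov['config_sha256']} seed={prov['seed']}\n")
        df.to_csv(fh, sep="\t", index=False)


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    state = np.random.SeedSequence(master).generate_state(n)
    return [int(s % (2**31)) for s in state]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all configured stages; returns (and writes) the summary dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(cfg)
    seeds = _stage_seeds(cfg.seed)
    summary: dict = {"provenance": prov, "stages": {}}

    with open(outdir / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)

    # --- load & QC -------------------------------------------------------
    cm = aio.read_mtx_triplet(cfg.matrix, cfg.barcodes, cfg.features)
    labels = aio.read_cell_labels(cfg.cell_types)
    ann = aio.read_gene_annotation(cfg.annotation, format=cfg.annotation_format)
    panel = aio.build_gene_panel(ann)
    cm_f, cells = aio.qc_filter(
        cm,
        labels,
        min_genes=cfg.qc.min_genes,
        min_umi=cfg.qc.min_umi,
        max_mito_fraction=cfg.qc.max_mito_fraction,
    )
    _write_tsv(cells, outdir / "qc_cells.tsv", prov)
    summary["stages"]["qc"] = {
        "n_input_cells": int(cm.n_cells),
        "n_cells": int(cm_f.n_cells),
        "median_genes": float(cells["n_genes"].median()),
        "median_umi": float(cells["total_umi"].median()),
        "y_panel_size": len(panel.y_genes),
        "x_panel_size": len(panel.x_genes),
    }

    # --- genotyping ------------------------------------------------------
    callset = gt.call_genotype(cm_f, panel, min_y_umi=cfg.min_y_umi)
    reference_cm = None
    if cfg.reference_matrix:
        reference_cm = aio.read_mtx_triplet(
            cfg.reference_matrix, cfg.reference_barcodes, cfg.reference_features
        )
        fnr = gt.estimate_false_negative_rate(reference_cm, panel, min_y_umi=cfg.min_y_umi)
        callset = gt.apply_fnr_correction(callset, fnr, seed=seeds[1])
    _write_tsv(callset.calls, outdir / "genotype_calls.tsv", prov)
    summary["stages"]["genotyping"] = callset.summary()
    summary["stages"]["genotyping"]["fnr_reference"] = (
        "used" if reference_cm is not None else "skipped"
    )

    # --- composition -----------------------------------------------------
    result = comp.permutation_test_composition(
        cells[["barcode", "cell_type"]],
        callset,
        n_perm=cfg.n_perm,
        seed=seeds[2],
        alpha=cfg.alpha,
    )
    _write_tsv(result.table, outdir / "composition.tsv", prov)
    summary["stages"]["composition"] = {
        "pooled_fraction": result.pooled_fraction,
        "n_perm": result.n_perm,
        "n_types": int(len(result.table)),
        "n_significant": int(result.table["significant"].sum()),
        "q_values": dict(
            zip(result.table["cell_type"], result.table["q_value"].round(6))
        ),
    }

    # --- dosage ----------------------------------------------------------
    xyyy_mask = (callset.calls["call"] == gt.CALL_XYYY).to_numpy()
    ratio = dos.yx_ratio(cm_f, xyyy_mask, panel, label="case_48XYYY")
    dosage_summary = {"case": ratio.to_dict()}
    ref_rows = []
    if cfg.reference_ratios:
        ref_df = pd.read_csv(cfg.reference_ratios, sep="\t", comment="#")
        for _, row in ref_df.iterrows():
            ref_rows.append(
                dos.DosageRatio(
                    label=str(row["label"]),
                    y_sum=int(row["y_sum"]),
                    x_sum=int(row["x_sum"]),
                    ratio=row["y_sum"] / row["x_sum"],
                    n_cells=int(row.get("n_cells", 0)),
                )
            )
    elif reference_cm is not None:
        ref_rows.append(
            dos.yx_ratio(
                reference_cm, np.ones(reference_cm.n_cells, dtype=bool), panel,
                label="reference",
            )
        )
    if len(ref_rows) >= 2:
        dosage_summary["comparison"] = dos.compare_to_reference(ratio, ref_rows)
    else:
        dosage_summary["comparison"] = "skipped"
    _write_tsv(
        pd.DataFrame([ratio.to_dict()] + [r.to_dict() for r in ref_rows]),
        outdir / "dosage.tsv",
        prov,
    )
    summary["stages"]["dosage"] = dosage_summary

    # --- differential expression ----------------------------------------
    degs = de.de_test_all(
        cm_f,
        callset,
        cells[["barcode", "cell_type"]],
        mode=cfg.de_mode,
        annotations=ann,
        min_frac_expressing=cfg.min_frac_expressing,
        alpha=cfg.alpha,
    )
    flagged = de.flag_malignancy_genes(degs, cfg.malignancy_list)
    annotated = flagged.attrs.get("annotated", degs)
    _write_tsv(annotated, outdir / "de_genes.tsv", prov)
    summary["stages"]["diffexp"] = {
        "mode": cfg.de_mode,
        "n_degs": int(len(annotated)),
        "n_unique_genes": int(annotated["gene_id"].nunique()) if len(annotated) else 0,
        "n_flagged_malignancy": int(len(flagged)),
        "flagged_symbols": sorted(flagged["symbol"].unique()) if len(flagged) else [],
    }

    # --- ddPCR cross-check ------------------------------------------------
    if cfg.ddpcr_table:
        wells = ddp.read_ddpcr_table(cfg.ddpcr_table)
        est = ddp.estimate_fraction(
            wells, y_copies_per_positive_cell=cfg.y_copies_per_positive_cell
        )
        summary["stages"]["ddpcr"] = est.to_dict()
        summary["stages"]["ddpcr"]["abs_diff_vs_scrna_f_hat"] = abs(
            est.f_ddpcr - callset.f_hat
        )
        with open(outdir / "ddpcr_estimate.json", "w") as fh:
            json.dump({"provenance": prov, **est.to_dict()}, fh, indent=2)
    else:
        summary["stages"]["ddpcr"] = "skipped"

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    logger.info("pipeline complete: %s", outdir / "summary.json")
    return summary
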