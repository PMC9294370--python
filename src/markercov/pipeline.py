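"""End-to-end pipeline: (simulate | read) → QC → normalize → (cluster | load
labels) → signatures → markers → reports.

The pipeline is configured by a flat dict (JSON-serializable); every stage
logs its input/output dimensions and a failure aborts with a stage-named
error. The run metadata written at the end suffices to re-run identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import anndata as ad
import pandas as pd

from . import __version__
from .cluster import cluster_cells, load_labels
from .io import read_counts
from .markers import MarkerCombo, MarkerSelector
from .preprocess import DispersionHVG, ScaledPCA, normalize_log
from .qc import QCReport, qc_filter
from .report import CompositionReport, composition_report, export_tables
from .simulate import SimConfig, generate_counts

logger = logging.getLogger("markercov")

__all__ = ["PipelineResult", "run_pipeline", "default_config"]


@dataclasses.dataclass
class PipelineResult:
    adata: ad.AnnData
    labels: pd.Series
    qc_report: QCReport
    signatures: dict[str, pd.DataFrame]
    stats: dict[str, pd.DataFrame]
    combos: dict[str, MarkerCombo]
    composition: CompositionReport
    metadata: dict[str, Any]


def default_config() -> dict:
    return {
        "input": None,               # directory (10x triplet) or dense TSV
        "simulate": None,            # SimConfig kwargs; used when input is None
        "labels": None,              # TSV path; None -> cluster
        "qc": {"min_cells_per_gene": 3, "min_genes_per_cell": 200,
               "max_mito_fraction": 0.30, "max_hemoglobin_fraction": 0.05},
        "exclude_barcodes": None,    # file with one barcode per line (doublets)
        "normalize": {"scale": 10000.0},
        "hvg": {"n": 2000, "n_bins": 20},
        "pca": {"n_compute": 100, "n_use": 50, "clip": 10.0},
        "cluster": {"resolution": 0.4, "k": 20, "seed": 0},
        "signature": {"padj": 0.01, "lfc": 2.0, "prefilter": 10.0},
        "markers": {"pct_in_min": 60.0, "k": 5},
        "groups": None,              # group name -> [cluster labels]
        "out": None,                 # export directory; None -> no files
    }


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.perf_counter()
            try:
                r = fn(*a, **kw)
            except Exception as e:
                raise StageError(f"[{name}] {e}") from e
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return r
        return wrapped
    return deco


def run_pipeline(config: Mapping[str, Any]) -> PipelineResult:
    """Execute all stages described by ``config`` (see :func:`default_config`)."""
    cfg = default_config()
    for k, v in config.items():
        if isinstance(v, Mapping) and isinstance(cfg.get(k), dict):
            cfg[k] = {**cfg[k], **v}
        else:
            cfg[k] = v

    @_stage("input")
    def _input():
        if cfg["input"] is not None:
            a = read_counts(cfg["input"])
            logger.info("read %d cells x %d genes", a.n_obs, a.n_vars)
            return a
        if cfg["simulate"] is not None:
            sim = SimConfig(**cfg["simulate"])
            a, _truth = generate_counts(sim)
            logger.info("simulated %d cells x %d genes", a.n_obs, a.n_vars)
            return a
        raise ValueError("config needs 'input' or 'simulate'")

    adata = _input()

    @_stage("qc")
    def _qc(a):
        hook = None
        if cfg["exclude_barcodes"]:
            hook = [l.strip() for l in open(cfg["exclude_barcodes"]) if l.strip()]
        return qc_filter(a, doublet_hook=hook, **cfg["qc"])

    adata, qc_report = _qc(adata)
    logger.info("post-QC: %d cells x %d genes", adata.n_obs, adata.n_vars)

    @_stage("labels")
    def _labels(a):
        if cfg["labels"] is not None:
            return load_labels(cfg["labels"], a.obs_names)
        norm = normalize_log(a, scale=cfg["normalize"]["scale"])
        hvg = DispersionHVG(n_top=min(cfg["hvg"]["n"], a.n_vars),
                            n_bins=cfg["hvg"]["n_bins"]).fit(norm)
        V = hvg.transform(norm)
        emb = ScaledPCA(n_compute=cfg["pca"]["n_compute"], n_use=cfg["pca"]["n_use"],
                        clip=cfg["pca"]["clip"],
                        random_state=cfg["cluster"]["seed"]).fit(V).transform(V)
        return cluster_cells(
            emb, resolution=cfg["cluster"]["resolution"],
            n_neighbors=cfg["cluster"]["k"], seed=cfg["cluster"]["seed"],
            index=a.obs_names,
        )

    labels = _labels(adata)
    logger.info("%d clusters", labels.nunique())

    @_stage("signatures")
    def _sigs(a, lab):
        sel = MarkerSelector(
            pct_in_min=cfg["markers"]["pct_in_min"], k=cfg["markers"]["k"],
            padj_max=cfg["signature"]["padj"], lfc_min=cfg["signature"]["lfc"],
            prefilter_pct=cfg["signature"]["prefilter"],
        ).fit(a, lab)
        return sel

    sel = _sigs(adata, labels)

    @_stage("report")
    def _report(lab):
        return composition_report(labels=lab, groups=cfg["groups"])

    comp = _report(labels)

    band = {
        cl: (None if s is None else {"mu": s.mu, "sigma": s.sigma})
        for cl, s in sel.signature_model_.band_schemes_.items()
    }
    metadata = {
        "package_version": __version__,
        "config": {k: v for k, v in cfg.items() if k != "out"},
        "band_schemes": band,
        "n_cells": int(adata.n_obs),
        "n_genes": int(adata.n_vars),
        "qc_report": qc_report.to_dict(),
    }
    result = PipelineResult(
        adata=adata,
        labels=labels,
        qc_report=qc_report,
        signatures=sel.signature_model_.signatures_,
        stats=sel.signature_model_.stats_,
        combos=sel.combos_,
        composition=comp,
        metadata=metadata,
    )
    if cfg["out"]:
        sizes = labels.value_counts().to_dict()
        export_tables(
            cfg["out"], composition=comp, signatures=result.signatures,
            combos=result.combos, cluster_sizes=sizes, metadata=metadata,
        )
        logger.info("exports written to %s", cfg["out"])
    return result


def load_config(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
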