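"""Composition summaries and deterministic table exports.

Percent-style exports are rounded half-up at 2 dp to match printed-table
conventions; full-precision values are kept in a parallel machine-readable
JSON. Exports are byte-identical across repeated runs on identical inputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .markers import MarkerCombo

__all__ = ["CompositionReport", "composition_report", "export_tables"]


@dataclasses.dataclass
class CompositionReport:
    """Per-cluster cell counts and percentages, plus optional group sums.

    ``per_cluster`` has columns cluster, n_cells, pct; ``groups`` (may be
    empty) has group, n_cells, pct. Percentages are stored at full precision;
    use :meth:`rounded` for the printed 2-dp half-up form. Group percentages
    are computed from summed counts before any rounding.
    """

    per_cluster: pd.DataFrame
    groups: pd.DataFrame
    total: int

    def rounded(self) -> "CompositionReport":
        pc = self.per_cluster.copy()
        pc["pct"] = [round_half_up(v, 2) for v in pc["pct"]]
        gr = self.groups.copy()
        if len(gr):
            gr["pct"] = [round_half_up(v, 2) for v in gr["pct"]]
        return CompositionReport(pc, gr, self.total)


def composition_report(
    labels=None,
    groups: Mapping[str, Sequence[str]] | None = None,
    counts: Mapping[str, int] | None = None,
) -> CompositionReport:
    """Cluster composition from per-cell labels or precomputed counts.

    Exactly one of ``labels`` (per-cell label sequence/Series) or ``counts``
    (cluster → cell count) must be given. ``groups`` maps a group name to a
    list of member clusters; every member must exist.
    """
    if (labels is None) == (counts is None):
        raise ValueError("provide exactly one of labels or counts")
    if counts is None:
        vc = pd.Series(list(labels)).value_counts()
        counts = {str(k): int(v) for k, v in vc.items()}
    if not counts:
        raise ValueError("no clusters")
    total = sum(counts.values())
    per_cluster = pd.DataFrame(
        {
            "cluster": list(counts.keys()),
            "n_cells": list(counts.values()),
        }
    )
    per_cluster["pct"] = per_cluster["n_cells"] / total * 100.0
    rows = []
    for name, members in (groups or {}).items():
        unknown = [m for m in members if m not in counts]
        if unknown:
            raise ValueError(f"group {name!r} references unknown clusters: {unknown}")
        n = sum(counts[m] for m in members)
        rows.append({"group": name, "n_cells": n, "pct": n / total * 100.0})
    return CompositionReport(
        per_cluster=per_cluster,
        groups=pd.DataFrame(rows, columns=["group", "n_cells", "pct"]),
        total=total,
    )


def _fmt_pct(v: float) -> str:
    if np.isinf(v):
        return "inf"
    return f"{round_half_up(v, 2):.2f}"


def _signature_tsv(sig: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("Gene\tAvg_in\tLFCio\tPCTin\tPCTout\tPCTin/PCTout\tp\tpadj\n")
        for _, r in sig.iterrows():
            p_raw = r.get("p", np.nan)
            padj_raw = r.get("padj", np.nan)
            vals = [
                str(r["gene"]),
                _fmt_pct(r["avg_in"]),
                _fmt_pct(r["lfcio"]),
                _fmt_pct(r["pct_in"]),
                _fmt_pct(r["pct_out"]),
                _fmt_pct(r["ratio"]),
                "" if pd.isna(p_raw) else f"{p_raw:.3e}",
                "" if pd.isna(padj_raw) else f"{padj_raw:.3e}",
            ]
            fh.write("\t".join(vals) + "\n")


def export_tables(
    out_dir,
    composition: CompositionReport | None = None,
    signatures: Mapping[str, pd.DataFrame] | None = None,
    combos: Mapping[str, MarkerCombo] | None = None,
    cluster_sizes: Mapping[str, int] | None = None,
    metadata: dict | None = None,
) -> list[Path]:
    """Write composition/signature/marker TSVs and run-metadata JSON.

    Deterministic: repeated calls on identical inputs produce byte-identical
    files. Returns the list of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if composition is not None:
        p = out / "composition.tsv"
        with open(p, "w") as fh:
            fh.write("cluster\tn_cells\tpct\n")
            for _, r in composition.per_cluster.iterrows():
                fh.write(f"{r['cluster']}\t{int(r['n_cells'])}\t{_fmt_pct(r['pct'])}\n")
            for _, r in composition.groups.iterrows():
                fh.write(f"[group] {r['group']}\t{int(r['n_cells'])}\t{_fmt_pct(r['pct'])}\n")
        written.append(p)
        pj = out / "composition.json"
        with open(pj, "w") as fh:
            json.dump(
                {
                    "total": composition.total,
                    "per_cluster": composition.per_cluster.to_dict(orient="records"),
                    "groups": composition.groups.to_dict(orient="records"),
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")
        written.append(pj)

    for cl, sig in sorted((signatures or {}).items()):
        p = out / f"signature_{cl}.tsv"
        _signature_tsv(sig, p)
        written.append(p)

    if combos is not None:
        p = out / "markers.tsv"
        with open(p, "w") as fh:
            fh.write("cell_type\tn_cells\tmarker_genes\tUICC\n")
            for cl in sorted(combos):
                c = combos[cl]
                n = "" if cluster_sizes is None else str(cluster_sizes.get(cl, ""))
                fh.write(f"{cl}\t{n}\t{', '.join(c.genes)}\t{_fmt_pct(c.uicc)}\n")
        written.append(p)

    if metadata is not None:
        p = out / "run_metadata.json"
        with open(p, "w") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        written.append(p)
    return written
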