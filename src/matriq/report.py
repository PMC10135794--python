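"""Presentation artifacts: heatmap matrices, top-isoform selection, summaries.

The canonical heatmap artifact is a numeric matrix TSV (bit-exact testable);
rendering colored figures from it is deliberately out of scope.  Protein
cells are tri-state (-1 significant decrease, 0 no significant change,
+1 significant increase); phospho cells are percent changes.  Column order
is fixed: pain, DTMP, LR.  Rows are ordered alphabetically by entity id.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import AnalysisConfig, CountSummary
from .quant import round_half_up

HEATMAP_COLUMNS = ("pain", "DTMP", "LR")


def encode_protein_heatmap(
    quants: pd.DataFrame, cfg: AnalysisConfig
) -> pd.DataFrame:
    """Tri-state matrix from a tidy protein quantification table.

    cell = sign(log2_fc) where the contrast's p < alpha, else 0 (an exact
    zero fold change has no direction and stays 0).
    """
    fc = quants.pivot(index="entity_id", columns="contrast", values="log2_fc")
    pv = quants.pivot(index="entity_id", columns="contrast", values="p_value")
    cells = np.sign(fc).where((pv < cfg.alpha), 0.0).fillna(0.0).astype(int)
    cells = cells.reindex(columns=list(HEATMAP_COLUMNS)).fillna(0).astype(int)
    return cells.sort_index()


def encode_phospho_heatmap(quants: pd.DataFrame) -> pd.DataFrame:
    """Signed percent-change matrix for phospho isoforms (pain, DTMP, LR)."""
    mat = quants.pivot(index="entity_id", columns="contrast", values="percent_change")
    return mat.reindex(columns=list(HEATMAP_COLUMNS)).sort_index()


def select_top_isoforms(quants: pd.DataFrame, per_protein: int = 1) -> list[str]:
    """The isoform(s) with the largest |pain percent change| per phosphoprotein.

    Ties break lexicographically on isoform id.  Isoforms lacking a pain
    quantification are not eligible.
    """
    pain = quants[quants["contrast"] == "pain"].copy()
    pain["magnitude"] = pain["percent_change"].abs()
    pain = pain.sort_values(
        ["protein_id", "magnitude", "entity_id"], ascending=[True, False, True]
    )
    return list(pain.groupby("protein_id", sort=True).head(per_protein)["entity_id"])


def heatmap_counts(matrix: pd.DataFrame) -> dict:
    """Per-contrast counts of -1/+1 cells of a tri-state matrix."""
    return {
        c: {"down": int((matrix[c] == -1).sum()), "up": int((matrix[c] == 1).sum())}
        for c in matrix.columns
    }


def _format_records(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    for c in out.columns:
        if out[c].dtype == bool:
            out[c] = out[c].map({True: "true", False: "false"})
    return out


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def summary_payload(
    summaries: Mapping[str, CountSummary],
    cfg: AnalysisConfig,
    seed: int | None = None,
    rollups: pd.DataFrame | None = None,
    venn: Mapping | None = None,
    heatmaps: Mapping[str, dict] | None = None,
) -> dict:
    """Machine-readable run summary.

    Overall percentages are reported raw and rounded half-up to one decimal;
    per-category percentages inside rollups are integers.
    """
    payload: dict = {
        "config": {
            "affected_threshold": cfg.affected_threshold,
            "alpha": cfg.alpha,
            "overshoot_allowed": cfg.overshoot_allowed,
        },
        "seed": seed,
        "totals": {},
    }
    for kind, s in summaries.items():
        d = s.to_dict()
        for k in ("pct_affected", "pct_backreg_DTMP", "pct_backreg_LR"):
            d[k] = None if d[k] is None else round_half_up(d[k], 1)
        payload["totals"][kind] = d
    if rollups is not None:
        payload["rollups"] = rollups.where(pd.notna(rollups), None).to_dict(orient="records")
    if venn is not None:
        payload["venn"] = dict(venn)
    if heatmaps is not None:
        payload["heatmaps"] = {k: v for k, v in heatmaps.items()}
    return payload


def write_summary(
    out_dir: str | Path,
    *,
    records: pd.DataFrame | None = None,
    rollups: pd.DataFrame | None = None,
    protein_heatmap: pd.DataFrame | None = None,
    phospho_heatmap: pd.DataFrame | None = None,
    summaries: Mapping[str, CountSummary] | None = None,
    cfg: AnalysisConfig | None = None,
    seed: int | None = None,
    venn: Mapping | None = None,
) -> dict:
    """Write classification.tsv, category_rollup.tsv, heatmap TSVs, summary.json.

    Deterministic: identical inputs produce byte-identical files.  Returns
    the summary payload that was written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if records is not None:
        _format_records(records).to_csv(out / "classification.tsv", sep="\t", index=False)
    if rollups is not None:
        rollups.to_csv(out / "category_rollup.tsv", sep="\t", index=False)
    if protein_heatmap is not None:
        protein_heatmap.to_csv(out / "heatmap.tsv", sep="\t", index_label="entity_id")
    if phospho_heatmap is not None:
        phospho_heatmap.to_csv(
            out / "phospho_heatmap.tsv",
            sep="\t",
            index_label="entity_id",
            float_format="%.1f",
        )
    heatmaps = None
    if protein_heatmap is not None:
        heatmaps = {"protein_tristate": heatmap_counts(protein_heatmap)}
    payload = summary_payload(
        summaries or {}, cfg or AnalysisConfig(), seed=seed, rollups=rollups,
        venn=venn, heatmaps=heatmaps,
    )
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return payload
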