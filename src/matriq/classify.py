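"""Affected / back-regulated classification rules.

Two rule sets share one record shape:

* **Phospho-isoforms** (threshold-gated; duplicates admit no significance
  test): an isoform is *affected* when its pain-contrast linear ratio changes
  by at least ``affected_threshold`` (default 10%), i.e. r <= 0.90 or
  r >= 1.10.  It is *back-regulated* by a treatment when it is affected and
  the treatment-contrast ratio changes by at least the threshold in the
  direction opposite to the pain effect — i.e. back toward uninjured levels.

* **Proteins** (significance-gated; peptides provide replication): *affected*
  means the pain-contrast t-test has p < alpha; *back-regulated* means
  affected plus a significant treatment change with sign opposite to the pain
  fold change.

A treatment change that meets the magnitude/significance gate in the *same*
direction as the pain effect is recorded as *further modulated*, never as
back-regulated.  By default a reversal may overshoot past uninjured levels
and still count (``overshoot_allowed``); disabling it vetoes reversals whose
net level vs. the uninjured group crosses the threshold on the far side.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Iterable, Mapping

import pandas as pd

TREATMENTS = ("DTMP", "LR")

#: The "at least" rules are boundary-inclusive; ratios are compared with this
#: relative tolerance so that e.g. r = 0.90 (|r - 1| = 0.0999...98 in binary)
#: still counts as exactly a 10% change.
_BOUNDARY_RTOL = 1e-12


def _meets(dev: float, thr: float) -> bool:
    return abs(dev) >= thr * (1.0 - _BOUNDARY_RTOL)


@dataclass(frozen=True)
class AnalysisConfig:
    """Decision-rule parameters.

    affected_threshold: minimum fractional change of the linear ratio (0.10
        means "at least a 10% change", boundary inclusive).
    alpha: per-test significance level for the protein path.
    overshoot_allowed: whether a reversal past uninjured levels still counts.
    """

    affected_threshold: float = 0.10
    alpha: float = 0.05
    overshoot_allowed: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.affected_threshold < 1.0:
            raise ValueError("affected_threshold must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


DEFAULT_CONFIG = AnalysisConfig()


@dataclass
class ClassificationRecord:
    entity_id: str
    entity_kind: str  # "protein" | "phospho_isoform"
    classifiable: bool = True
    pain_direction: str = "none"  # "up" | "down" | "none"
    affected: bool = False
    backreg_DTMP: bool = False
    backreg_LR: bool = False
    further_modulated_DTMP: bool = False
    further_modulated_LR: bool = False
    protein_id: str | None = None


@dataclass
class CountSummary:
    """Aggregate totals over a homogeneous set of classification records."""

    n_total: int
    n_affected: int
    n_backreg_DTMP: int
    n_backreg_LR: int

    @property
    def pct_affected(self) -> float:
        return 100.0 * self.n_affected / self.n_total if self.n_total else float("nan")

    @property
    def pct_backreg_DTMP(self) -> float:
        return 100.0 * self.n_backreg_DTMP / self.n_affected if self.n_affected else float("nan")

    @property
    def pct_backreg_LR(self) -> float:
        return 100.0 * self.n_backreg_LR / self.n_affected if self.n_affected else float("nan")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("pct_affected", "pct_backreg_DTMP", "pct_backreg_LR"):
            v = getattr(self, k)
            d[k] = None if math.isnan(v) else v
        return d


def _direction(x: float) -> str:
    if x > 0:
        return "up"
    if x < 0:
        return "down"
    return "none"


def _overshoot(r_pain: float, r_treat: float, cfg: AnalysisConfig) -> bool:
    # net treated level relative to uninjured: r_pain * r_treat
    net = r_pain * r_treat
    if r_pain > 1.0:
        return net < 1.0 - cfg.affected_threshold
    return net > 1.0 + cfg.affected_threshold


def classify_phospho(
    entity_id: str,
    ratios: Mapping[str, float],
    cfg: AnalysisConfig = DEFAULT_CONFIG,
    protein_id: str | None = None,
) -> ClassificationRecord:
    """Apply the 10%-rule classification to one phospho-isoform.

    ``ratios`` maps contrast names ("pain", "DTMP", "LR") to linear ratios.
    A missing or non-finite contrast yields an unclassifiable record.
    """
    rec = ClassificationRecord(entity_id, "phospho_isoform", protein_id=protein_id)
    vals = {c: ratios.get(c, float("nan")) for c in ("pain",) + TREATMENTS}
    if any(not math.isfinite(v) for v in vals.values()):
        rec.classifiable = False
        return rec
    thr = cfg.affected_threshold
    r_pain = vals["pain"]
    pain_dev = r_pain - 1.0
    rec.affected = _meets(pain_dev, thr) and pain_dev != 0.0
    rec.pain_direction = _direction(pain_dev) if rec.affected else "none"
    if not rec.affected:
        return rec
    for t in TREATMENTS:
        dev = vals[t] - 1.0
        if not _meets(dev, thr) or dev == 0.0:
            continue
        opposite = (dev > 0) != (pain_dev > 0)
        if opposite:
            if cfg.overshoot_allowed or not _overshoot(r_pain, vals[t], cfg):
                setattr(rec, f"backreg_{t}", True)
        else:
            setattr(rec, f"further_modulated_{t}", True)
    return rec


def classify_protein(
    entity_id: str,
    log2_fc: Mapping[str, float],
    p_value: Mapping[str, float],
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> ClassificationRecord:
    """Apply the significance-gated classification to one protein.

    ``log2_fc`` and ``p_value`` map contrast names to values; an undefined
    (NaN/missing) pain p-value makes the record unclassifiable, an undefined
    treatment p-value simply never reaches significance.
    """
    rec = ClassificationRecord(entity_id, "protein", protein_id=entity_id)
    p_pain = p_value.get("pain", float("nan"))
    fc_pain = log2_fc.get("pain", float("nan"))
    if not (math.isfinite(p_pain) and math.isfinite(fc_pain)):
        rec.classifiable = False
        return rec
    rec.affected = p_pain < cfg.alpha and fc_pain != 0.0
    rec.pain_direction = _direction(fc_pain) if rec.affected else "none"
    if not rec.affected:
        return rec
    for t in TREATMENTS:
        p_t = p_value.get(t, float("nan"))
        fc_t = log2_fc.get(t, float("nan"))
        if not (math.isfinite(p_t) and math.isfinite(fc_t)):
            continue
        if p_t >= cfg.alpha or fc_t == 0.0:
            continue
        opposite = (fc_t > 0) != (fc_pain > 0)
        if opposite:
            if cfg.overshoot_allowed or not _overshoot(
                2.0**fc_pain, 2.0**fc_t, cfg
            ):
                setattr(rec, f"backreg_{t}", True)
        else:
            setattr(rec, f"further_modulated_{t}", True)
    return rec


def records_frame(records: Iterable[ClassificationRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def summarize_records(records: pd.DataFrame) -> CountSummary:
    return CountSummary(
        n_total=int(len(records)),
        n_affected=int(records["affected"].sum()),
        n_backreg_DTMP=int(records["backreg_DTMP"].sum()),
        n_backreg_LR=int(records["backreg_LR"].sum()),
    )


def classify_dataset(
    quants: pd.DataFrame,
    entity_kind: str,
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[pd.DataFrame, CountSummary]:
    """Classify every entity of a tidy quantification table.

    ``quants`` is the output of :func:`matriq.quant.quantify_proteins` or
    :func:`matriq.quant.quantify_phospho`.  Returns the per-entity record
    table (sorted by entity id) and the aggregate :class:`CountSummary`.
    """
    if quants.empty:
        raise ValueError("empty quantification table")
    if entity_kind not in ("protein", "phospho_isoform"):
        raise ValueError(f"unknown entity kind {entity_kind!r}")
    records: list[ClassificationRecord] = []
    if entity_kind == "phospho_isoform":
        ratio = quants.pivot(index="entity_id", columns="contrast", values="linear_ratio")
        parent = (
            quants.drop_duplicates("entity_id").set_index("entity_id")["protein_id"]
            if "protein_id" in quants.columns
            else pd.Series(dtype=object)
        )
        for eid, row in ratio.sort_index().iterrows():
            records.append(
                classify_phospho(eid, row.to_dict(), cfg, protein_id=parent.get(eid))
            )
    else:
        fc = quants.pivot(index="entity_id", columns="contrast", values="log2_fc")
        pv = quants.pivot(index="entity_id", columns="contrast", values="p_value")
        for eid in sorted(fc.index):
            records.append(
                classify_protein(eid, fc.loc[eid].to_dict(), pv.loc[eid].to_dict(), cfg)
            )
    frame = records_frame(records)
    return frame, summarize_records(frame)
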