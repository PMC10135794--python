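"""Fold-change quantification for pooled TMT proteomic and phosphoproteomic data.

A pooled isobaric design leaves a single reporter channel per experimental
group, so replication lives below the group level: peptides within a protein
on the proteomic side, technical runs on the phosphoproteomic side.  This
module turns peptide-level log2 intensities and isoform-level run intensities
into per-entity fold changes for the three canonical contrasts of the
injury/stimulation design:

* ``pain``  -- untreated injured vs. uninjured (NoSCS / NoSNI)
* ``DTMP``  -- multiplexed stimulation vs. untreated injured (DTMP / NoSCS)
* ``LR``    -- conventional 50 Hz stimulation vs. untreated injured (LRSCS / NoSCS)

Proteomic significance is a one-sample two-tailed t-test of the per-peptide
log2 ratios against zero (df = n_peptides - 1).  Phospho quantification has no
significance test (duplicate technical runs); instead each group's linear-scale
coefficient of variation is propagated into the ratio CV as
sqrt(cv_num**2 + cv_den**2).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class GroupLabel(str, Enum):
    """The four pooled channels of the experiment."""

    NO_SNI = "NoSNI"
    NO_SCS = "NoSCS"
    DTMP = "DTMP"
    LRSCS = "LRSCS"


#: Canonical channel order.
GROUPS: tuple[str, ...] = tuple(g.value for g in GroupLabel)


@dataclass(frozen=True)
class Contrast:
    """A ratio of two pooled channels, numerator / denominator."""

    name: str
    numerator: str
    denominator: str

    def swapped(self) -> "Contrast":
        return Contrast(f"{self.name}_rev", self.denominator, self.numerator)


PAIN = Contrast("pain", "NoSCS", "NoSNI")
DTMP_VS_NOSCS = Contrast("DTMP", "DTMP", "NoSCS")
LR_VS_NOSCS = Contrast("LR", "LRSCS", "NoSCS")

#: The canonical contrast set, in reporting order.
CONTRASTS: tuple[Contrast, ...] = (PAIN, DTMP_VS_NOSCS, LR_VS_NOSCS)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of the printed tables)."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent_change(log2_fc: float) -> float:
    """Convert a log2 fold change to a percent change, 100 * (2**fc - 1)."""
    return 100.0 * (2.0 ** float(log2_fc) - 1.0)


def propagate_cv(cv_num: float, cv_den: float) -> float:
    """CV of a ratio from the CVs of numerator and denominator.

    cv_fc = sqrt(cv_num**2 + cv_den**2); symmetric, monotone, and never below
    either input.
    """
    if cv_num < 0 or cv_den < 0:
        raise ValueError("coefficients of variation must be nonnegative")
    return math.hypot(cv_num, cv_den)


# ---------------------------------------------------------------------------
# channel normalization
# ---------------------------------------------------------------------------

def normalize_channels(table: pd.DataFrame) -> pd.DataFrame:
    """Median-center each group's log2 intensities onto the grand median.

    The grand median is the median of the four per-group medians (unweighted
    by group size).  Robust alignment for pooled isobaric channels:
    within-group rank order is untouched and every per-group median of
    ``log2_intensity`` afterwards equals the grand median.  Idempotent to
    floating tolerance; any constant per-group shift of the input changes the
    output by at most a global constant, which cancels in every contrast.
    """
    if table.empty:
        raise ValueError("peptide table is empty")
    for g in GROUPS:
        if not (table["group"] == g).any():
            raise ValueError(f"group {g!r} has no rows")
    medians = table.groupby("group")["log2_intensity"].median()
    grand = float(np.median(medians))
    out = table.copy()
    offsets = grand - medians
    out["log2_intensity"] = table["log2_intensity"] + table["group"].map(offsets).astype(float)
    return out


# ---------------------------------------------------------------------------
# proteomic path: peptide deltas -> protein fold change + t-test
# ---------------------------------------------------------------------------

def peptide_deltas(table: pd.DataFrame, protein_id: str, contrast: Contrast) -> np.ndarray:
    """Per-peptide log2 ratios for one protein and contrast.

    Only uniquely assigned peptides measured in both channels contribute.
    """
    sub = table[(table["protein_id"] == protein_id) & table["unique_assignment"]]
    wide = sub.pivot_table(index="peptide_id", columns="group", values="log2_intensity")
    for g in (contrast.numerator, contrast.denominator):
        if g not in wide.columns:
            return np.array([])
    return (wide[contrast.numerator] - wide[contrast.denominator]).dropna().to_numpy()


def protein_fold_change(table: pd.DataFrame, protein_id: str, contrast: Contrast) -> dict | None:
    """Fold change of one protein for one contrast, or None if unquantifiable."""
    deltas = peptide_deltas(table, protein_id, contrast)
    if deltas.size == 0:
        return None
    fc = float(np.mean(deltas))
    return {
        "entity_id": protein_id,
        "contrast": contrast.name,
        "log2_fc": fc,
        "linear_ratio": 2.0**fc,
        "percent_change": percent_change(fc),
        "n_peptides": int(deltas.size),
    }


#: Sample standard deviations of log2 deltas below this are treated as zero
#: (constant deltas up to double-precision rounding): the t-test is undefined,
#: not astronomically significant.
ZERO_SD_TOL = 1e-9


def protein_t_test(deltas: Sequence[float]) -> float:
    """Two-tailed one-sample t-test of mean(deltas) against 0.

    Returns NaN (untestable) for n < 2 or (numerically) zero sample variance;
    raises on an empty input.
    """
    d = np.asarray(deltas, dtype=float)
    if d.size == 0:
        raise ValueError("no peptide deltas to test")
    if d.size < 2 or np.std(d, ddof=1) < ZERO_SD_TOL:
        return float("nan")
    return float(stats.ttest_1samp(d, 0.0).pvalue)


def quantify_proteins(
    table: pd.DataFrame, contrasts: Iterable[Contrast] = CONTRASTS
) -> pd.DataFrame:
    """Protein-level quantification table (tidy: one row per protein x contrast).

    Columns: entity_id, contrast, log2_fc, linear_ratio, percent_change,
    p_value, n_peptides.  ``p_value`` is NaN when the protein is untestable
    for that contrast (single peptide or zero delta variance).  Proteins with
    no co-measured unique peptide for a contrast are simply absent for it.
    """
    used = table[table["unique_assignment"]]
    wide = used.pivot_table(
        index=["protein_id", "peptide_id"], columns="group", values="log2_intensity"
    )
    frames = []
    for c in contrasts:
        if c.numerator not in wide.columns or c.denominator not in wide.columns:
            continue
        deltas = (wide[c.numerator] - wide[c.denominator]).dropna()
        if deltas.empty:
            continue
        grp = deltas.groupby(level="protein_id")
        n = grp.size()
        mean = grp.mean()
        sd = grp.std(ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = mean / (sd / np.sqrt(n))
            p = 2.0 * stats.t.sf(np.abs(t_stat), n - 1)
        p = pd.Series(p, index=mean.index)
        p[(n < 2) | (sd < ZERO_SD_TOL) | sd.isna()] = np.nan
        frames.append(
            pd.DataFrame(
                {
                    "entity_id": mean.index,
                    "contrast": c.name,
                    "log2_fc": mean.to_numpy(),
                    "linear_ratio": 2.0 ** mean.to_numpy(),
                    "percent_change": 100.0 * (2.0 ** mean.to_numpy() - 1.0),
                    "p_value": p.to_numpy(),
                    "n_peptides": n.to_numpy(),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "entity_id",
                "contrast",
                "log2_fc",
                "linear_ratio",
                "percent_change",
                "p_value",
                "n_peptides",
            ]
        )
    return pd.concat(frames, ignore_index=True).sort_values(
        ["entity_id", "contrast"], ignore_index=True
    )


# ---------------------------------------------------------------------------
# phospho path: run-paired ratios + CV propagation
# ---------------------------------------------------------------------------

def phospho_fold_change(table: pd.DataFrame, isoform_id: str, contrast: Contrast) -> dict | None:
    """Fold change of one phospho-isoform for one contrast.

    Per-run linear ratios are formed by pairing runs on ``run_id``; the fold
    change is the mean of the per-run log2 ratios.  Each group's CV is the
    n-1 standard deviation over runs of the linear intensities divided by
    their mean.  Returns None when either group is missing a run.
    """
    sub = table[table["isoform_id"] == isoform_id]
    n_runs = table["run_id"].nunique()
    wide = sub.pivot_table(index="run_id", columns="group", values="intensity")
    for g in (contrast.numerator, contrast.denominator):
        if g not in wide.columns or wide[g].dropna().size != n_runs:
            return None
    ratios = wide[contrast.numerator] / wide[contrast.denominator]
    fc = float(np.mean(np.log2(ratios)))
    cvs = {}
    for side, g in (("num", contrast.numerator), ("den", contrast.denominator)):
        vals = wide[g]
        cvs[side] = float(vals.std(ddof=1) / vals.mean())
    return {
        "entity_id": isoform_id,
        "contrast": contrast.name,
        "log2_fc": fc,
        "linear_ratio": 2.0**fc,
        "percent_change": percent_change(fc),
        "cv_num": cvs["num"],
        "cv_den": cvs["den"],
        "cv_fc": propagate_cv(cvs["num"], cvs["den"]),
        "n_runs": int(n_runs),
    }


def quantify_phospho(
    table: pd.DataFrame, contrasts: Iterable[Contrast] = CONTRASTS
) -> pd.DataFrame:
    """Isoform-level quantification (tidy: one row per isoform x contrast).

    Columns: entity_id, protein_id, contrast, log2_fc, linear_ratio,
    percent_change, cv_num, cv_den, cv_fc, n_runs.  Isoforms missing a run in
    either channel of a contrast are absent for that contrast.
    """
    n_runs = table["run_id"].nunique()
    parent = table.drop_duplicates("isoform_id").set_index("isoform_id")["protein_id"]
    wide = table.pivot_table(
        index=["isoform_id", "run_id"], columns="group", values="intensity"
    )
    # per-(isoform, group) linear CV over runs
    gstat = table.groupby(["isoform_id", "group"])["intensity"].agg(["mean", "std", "count"])
    cv = (gstat["std"] / gstat["mean"]).unstack("group")
    complete = gstat["count"].unstack("group") == n_runs

    frames = []
    for c in contrasts:
        if c.numerator not in wide.columns or c.denominator not in wide.columns:
            continue
        log_ratio = np.log2(wide[c.numerator] / wide[c.denominator])
        grp = log_ratio.groupby(level="isoform_id")
        ok = (grp.count() == n_runs) & complete.get(c.numerator, False) & complete.get(
            c.denominator, False
        )
        mean = grp.mean()[ok]
        if mean.empty:
            continue
        cvn = cv[c.numerator].reindex(mean.index)
        cvd = cv[c.denominator].reindex(mean.index)
        frames.append(
            pd.DataFrame(
                {
                    "entity_id": mean.index,
                    "protein_id": parent.reindex(mean.index).to_numpy(),
                    "contrast": c.name,
                    "log2_fc": mean.to_numpy(),
                    "linear_ratio": 2.0 ** mean.to_numpy(),
                    "percent_change": 100.0 * (2.0 ** mean.to_numpy() - 1.0),
                    "cv_num": cvn.to_numpy(),
                    "cv_den": cvd.to_numpy(),
                    "cv_fc": np.hypot(cvn.to_numpy(), cvd.to_numpy()),
                    "n_runs": n_runs,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "entity_id",
                "protein_id",
                "contrast",
                "log2_fc",
                "linear_ratio",
                "percent_change",
                "cv_num",
                "cv_den",
                "cv_fc",
                "n_runs",
            ]
        )
    return pd.concat(frames, ignore_index=True).sort_values(
        ["entity_id", "contrast"], ignore_index=True
    )
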