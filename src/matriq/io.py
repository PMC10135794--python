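"""TSV/JSON readers and writers, validation, configuration, pipeline driver.

All tabular artifacts are tab-separated UTF-8 with a header row and "."
decimals.  Readers validate eagerly and report every offending line (1-based,
counting the header) before raising, so a malformed file yields one complete
diagnostic rather than a stream of partial failures.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass

import pandas as pd
import yaml

from . import categorize, classify, quant, report

logger = logging.getLogger("matriq")

_SITE_RE = re.compile(r"^([A-Z])([0-9]+)$")
_BOOL = {"true": True, "1": True, "false": False, "0": False}
_GROUPS = set(quant.GROUPS)


class ValidationError(ValueError):
    """Raised when an input file fails validation; carries per-line messages."""

    def __init__(self, path, errors: list[str]):
        self.path = str(path)
        self.errors = errors
        preview = "; ".join(errors[:5])
        more = "" if len(errors) <= 5 else f" (+{len(errors) - 5} more)"
        super().__init__(f"{path}: {preview}{more}")


def parse_site(text: str) -> tuple[str, int]:
    """Parse a phospho-site token like "S1126" into (residue, position)."""
    m = _SITE_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed site {text!r} (expected e.g. 'S1126')")
    return m.group(1), int(m.group(2))


def _read_tsv(path, columns: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise ValidationError(path, [str(exc)]) from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(path, [f"missing columns: {missing}"])
    # drop trailing fully-empty lines
    df = df[~(df == "").all(axis=1)].reset_index(drop=True)
    return df


def _line(i: int) -> int:
    return i + 2  # 1-based, after the header row


def read_peptide_table(path) -> pd.DataFrame:
    """Read and validate a peptide-level proteomic table.

    Columns: protein_id, peptide_id, group, log2_intensity, unique_assignment.
    """
    df = _read_tsv(path, ("protein_id", "peptide_id", "group", "log2_intensity",
                          "unique_assignment"))
    errors: list[str] = []
    for i, g in enumerate(df["group"]):
        if g not in _GROUPS:
            errors.append(f"line {_line(i)}: unknown group label {g!r}")
    intensity = pd.to_numeric(df["log2_intensity"], errors="coerce")
    for i in intensity.index[intensity.isna()]:
        errors.append(f"line {_line(i)}: non-numeric intensity {df['log2_intensity'][i]!r}")
    flags = df["unique_assignment"].str.lower().map(_BOOL)
    for i in flags.index[flags.isna()]:
        errors.append(f"line {_line(i)}: bad unique_assignment {df['unique_assignment'][i]!r}")
    dup = df.duplicated(["protein_id", "peptide_id", "group"], keep=False)
    for i in df.index[dup & ~df.duplicated(["protein_id", "peptide_id", "group"])]:
        errors.append(
            f"line {_line(i)}: duplicate key "
            f"({df['protein_id'][i]}, {df['peptide_id'][i]}, {df['group'][i]})"
        )
    if errors:
        raise ValidationError(path, errors)
    out = df[["protein_id", "peptide_id", "group"]].copy()
    out["log2_intensity"] = intensity
    out["unique_assignment"] = flags.astype(bool)
    return out


def read_phospho_table(path) -> pd.DataFrame:
    """Read and validate a phospho-isoform intensity table.

    Columns: protein_id, isoform_id, sites (semicolon-separated tokens like
    "S1126"), run_id, group, intensity.  Requires every group to carry the
    same set of >= 2 run ids.
    """
    df = _read_tsv(path, ("protein_id", "isoform_id", "sites", "run_id", "group",
                          "intensity"))
    errors: list[str] = []
    for i, g in enumerate(df["group"]):
        if g not in _GROUPS:
            errors.append(f"line {_line(i)}: unknown group label {g!r}")
    intensity = pd.to_numeric(df["intensity"], errors="coerce")
    for i in intensity.index[intensity.isna()]:
        errors.append(f"line {_line(i)}: non-numeric intensity {df['intensity'][i]!r}")
    for i in intensity.index[intensity <= 0]:
        errors.append(f"line {_line(i)}: intensity must be positive")
    sites: list[list[str]] = []
    for i, s in enumerate(df["sites"]):
        tokens = [t for t in s.split(";") if t]
        if not tokens:
            errors.append(f"line {_line(i)}: empty site list")
        for t in tokens:
            try:
                parse_site(t)
            except ValueError as exc:
                errors.append(f"line {_line(i)}: {exc}")
        sites.append(tokens)
    dup = df.duplicated(["isoform_id", "run_id", "group"], keep=False)
    for i in df.index[dup & ~df.duplicated(["isoform_id", "run_id", "group"])]:
        errors.append(f"line {_line(i)}: duplicate key "
                      f"({df['isoform_id'][i]}, {df['run_id'][i]}, {df['group'][i]})")
    if not errors:
        run_sets = df.groupby("group")["run_id"].agg(lambda s: frozenset(s))
        if len(set(run_sets)) > 1:
            errors.append("groups carry different run_id sets")
        elif len(run_sets) and len(next(iter(set(run_sets)))) < 2:
            errors.append("fewer than 2 technical runs")
    if errors:
        raise ValidationError(path, errors)
    out = df[["protein_id", "isoform_id", "run_id", "group"]].copy()
    out["sites"] = sites
    out["intensity"] = intensity
    return out


def read_annotation(path) -> pd.DataFrame:
    """Read and validate a category annotation table.

    Columns: protein_id, categories (semicolon-separated subset of
    structural/adhesion/junction/signaling), source (ontology | literature).
    """
    df = _read_tsv(path, ("protein_id", "categories", "source"))
    errors: list[str] = []
    cats: list[frozenset[str]] = []
    for i, text in enumerate(df["categories"]):
        tokens = frozenset(t for t in text.split(";") if t)
        if not tokens:
            errors.append(f"line {_line(i)}: empty categories field")
        unknown = tokens - categorize.CATEGORIES
        if unknown:
            errors.append(f"line {_line(i)}: unknown categories {sorted(unknown)}")
        cats.append(tokens)
    for i, s in enumerate(df["source"]):
        if s not in ("ontology", "literature"):
            errors.append(f"line {_line(i)}: unknown source {s!r}")
    dup = df.duplicated("protein_id", keep=False)
    for i in df.index[dup & ~df.duplicated("protein_id")]:
        errors.append(f"line {_line(i)}: duplicate protein_id {df['protein_id'][i]!r}")
    if errors:
        raise ValidationError(path, errors)
    out = df[["protein_id", "source"]].copy()
    out["categories"] = cats
    return out[["protein_id", "categories", "source"]]


def write_annotation(ann: pd.DataFrame, path) -> None:
    out = ann.copy()
    out["categories"] = out["categories"].map(lambda s: ";".join(sorted(s)))
    out.to_csv(path, sep="\t", index=False)


def read_classification(path) -> pd.DataFrame:
    """Read back a classification.tsv written by :mod:`matriq.report`."""
    df = _read_tsv(path, ("entity_id", "entity_kind", "classifiable", "pain_direction",
                          "affected", "backreg_DTMP", "backreg_LR"))
    errors: list[str] = []
    for col in ("classifiable", "affected", "backreg_DTMP", "backreg_LR",
                "further_modulated_DTMP", "further_modulated_LR"):
        if col not in df.columns:
            continue
        parsed = df[col].str.lower().map(_BOOL)
        for i in parsed.index[parsed.isna()]:
            errors.append(f"line {_line(i)}: bad boolean {df[col][i]!r} in {col}")
        df[col] = parsed
    if errors:
        raise ValidationError(path, errors)
    if "protein_id" in df.columns:
        df["protein_id"] = df["protein_id"].replace("", None)
    return df


def read_summary(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# configuration + pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration (YAML-compatible key/value file)."""

    peptide_table: str | None = None
    phospho_table: str | None = None
    annotation: str | None = None
    out_dir: str = "results"
    affected_threshold: float = 0.10
    alpha: float = 0.05
    overshoot_allowed: bool = True
    seed: int | None = None
    log_level: str = "INFO"

    def analysis_config(self) -> classify.AnalysisConfig:
        return classify.AnalysisConfig(
            affected_threshold=self.affected_threshold,
            alpha=self.alpha,
            overshoot_allowed=self.overshoot_allowed,
        )


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(path, [f"unknown config keys: {sorted(unknown)}"])
    return PipelineConfig(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """normalize -> quantify -> classify -> categorize -> report.

    Validates and reads every input before writing anything, so a bad input
    leaves no partial outputs.  Returns the summary payload.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
    if config.peptide_table is None and config.phospho_table is None:
        raise ValueError("config names neither a peptide nor a phospho table")
    cfg = config.analysis_config()

    peptides = phospho = ann = None
    if config.peptide_table:
        peptides = read_peptide_table(config.peptide_table)
        logger.info("read: %d peptide rows, %d proteins",
                    len(peptides), peptides["protein_id"].nunique())
    if config.phospho_table:
        phospho = read_phospho_table(config.phospho_table)
        logger.info("read: %d phospho rows, %d isoforms",
                    len(phospho), phospho["isoform_id"].nunique())
    if config.annotation:
        ann = read_annotation(config.annotation)
        logger.info("read: %d annotated proteins", len(ann))

    summaries: dict[str, classify.CountSummary] = {}
    record_frames = []
    protein_heatmap = phospho_heatmap = None
    rollup_frames = []
    venn = None

    if peptides is not None:
        normalized = quant.normalize_channels(peptides)
        pquant = quant.quantify_proteins(normalized)
        logger.info("quant: %d proteins quantified", pquant["entity_id"].nunique())
        precords, psummary = classify.classify_dataset(pquant, "protein", cfg)
        logger.info("classify: proteins affected %d / %d",
                    psummary.n_affected, psummary.n_total)
        summaries["protein"] = psummary
        record_frames.append(precords)
        protein_heatmap = report.encode_protein_heatmap(pquant, cfg)
        if ann is not None:
            roll, unannotated = categorize.rollup_by_category(precords, ann, "protein")
            rollup_frames.append(roll)
            if unannotated:
                logger.warning("categorize: %d unannotated proteins", len(unannotated))

    if phospho is not None:
        fquant = quant.quantify_phospho(phospho)
        logger.info("quant: %d isoforms quantified", fquant["entity_id"].nunique())
        frecords, fsummary = classify.classify_dataset(fquant, "phospho_isoform", cfg)
        logger.info("classify: isoforms affected %d / %d",
                    fsummary.n_affected, fsummary.n_total)
        summaries["phospho_isoform"] = fsummary
        record_frames.append(frecords)
        top = report.select_top_isoforms(fquant)
        phospho_heatmap = report.encode_phospho_heatmap(
            fquant[fquant["entity_id"].isin(top)]
        )
        if ann is not None:
            roll, unannotated = categorize.rollup_by_category(
                frecords, ann, "phospho_isoform"
            )
            rollup_frames.append(roll)
            if unannotated:
                logger.warning("categorize: %d unannotated isoforms", len(unannotated))

    if ann is not None:
        venn = categorize.venn_counts(ann).to_dict()

    records = pd.concat(record_frames, ignore_index=True)
    rollups = pd.concat(rollup_frames, ignore_index=True) if rollup_frames else None
    payload = report.write_summary(
        config.out_dir,
        records=records,
        rollups=rollups,
        protein_heatmap=protein_heatmap,
        phospho_heatmap=phospho_heatmap,
        summaries=summaries,
        cfg=cfg,
        seed=config.seed,
        venn=venn,
    )
    logger.info("report: wrote outputs to %s", config.out_dir)
    return payload
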