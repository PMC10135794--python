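import numpy as np
import pandas as pd
import pytest

from matriq import GROUPS


def peptide_table(values: dict[str, dict[str, list[float]]], unique=None) -> pd.DataFrame:
    """Build a peptide table from {protein: {group: [log2 intensities]}}."""
    rows = []
    for pid, groups in values.items():
        for g, intensities in groups.items():
            for j, v in enumerate(intensities):
                pep = f"{pid}_pep{j + 1}"
                rows.append(
                    {
                        "protein_id": pid,
                        "peptide_id": pep,
                        "group": g,
                        "log2_intensity": float(v),
                        "unique_assignment": True
                        if unique is None
                        else unique.get(pep, True),
                    }
                )
    return pd.DataFrame(rows)


def phospho_table(values: dict[str, dict[str, list[float]]], protein=None) -> pd.DataFrame:
    """Build a phospho table from {isoform: {group: [per-run intensities]}}."""
    rows = []
    for iso, groups in values.items():
        pid = (protein or {}).get(iso, iso.split("@")[0])
        for g, intensities in groups.items():
            for r, v in enumerate(intensities):
                rows.append(
                    {
                        "protein_id": pid,
                        "isoform_id": iso,
                        "sites": ["S100"],
                        "run_id": f"run{r + 1}",
                        "group": g,
                        "intensity": float(v),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def balanced_peptides():
    """Four-group table, 3 peptides/protein, already median-aligned."""
    rng = np.random.default_rng(11)
    vals = {}
    for i in range(4):
        base = rng.normal(17, 1, size=3)
        vals[f"P{i}"] = {g: list(base + rng.normal(0, 0.1, size=3)) for g in GROUPS}
    return peptide_table(vals)
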