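"""Synthetic benchmark generator with planted classification ground truth.

Emulates the input tables of a 4-group pooled TMT design — one reporter
channel per group (NoSNI, NoSCS, DTMP, LRSCS), peptide-level replication
within proteins on the proteomic side, duplicate technical runs on the
phospho side — while planting, per entity, a known class from the
affected / back-regulated taxonomy so that the downstream pipeline can be
verified against exact ground truth.

Planted classes
---------------
``unaffected``, or ``up``/``down`` (direction of the pain-model effect)
optionally suffixed with ``_dtmp``, ``_lr`` or ``_dtmp_lr`` for the
treatments that reverse it.  Planted linear ratios sit a multiplicative
``margin`` beyond the 10% decision boundary: an up-regulation is placed at
1.10 * (1 + margin), a down-regulation at 0.90 / (1 + margin), so both sit
log2(1 + margin) beyond their boundary on the log2 scale.  Noise is
multiplicative log-normal: each measured intensity is its planted mean times
2**eps with eps ~ Normal(0, noise_sd).

Proteomic determinism
---------------------
On the proteomic path significance comes from a t-test, so a *null* contrast
realized with independent noise would still come out significant in ~alpha of
cases.  To keep planted truth exactly recoverable, a contrast with no planted
effect copies the reference channel's peptide intensities verbatim (deltas
identically zero -> the t-test is undefined -> deterministically not
significant), while planted effects receive an independently calibrated shift
large enough that detection is essentially certain.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .quant import GROUPS

TREATMENT_GROUPS = {"dtmp": "DTMP", "lr": "LRSCS"}

#: All planted classes.
PLANTED_CLASSES: tuple[str, ...] = (
    "unaffected",
    "up",
    "up_dtmp",
    "up_lr",
    "up_dtmp_lr",
    "down",
    "down_dtmp",
    "down_lr",
    "down_dtmp_lr",
)


@dataclass(frozen=True)
class PlantedSpec:
    """Free parameters of the generator.

    class_counts must sum to n_entities; margin is the multiplicative
    distance of planted ratios beyond the 10% boundary; noise_sd is the
    log2-scale standard deviation of measurement noise; peptides_per_protein
    is the inclusive range peptide counts are drawn from (proteomic only);
    n_runs is the technical-run count (phospho only); protein_shift, if set,
    overrides the power-calibrated proteomic log2 shift.
    """

    n_entities: int
    class_counts: Mapping[str, int]
    margin: float = 0.25
    noise_sd: float = 0.05
    peptides_per_protein: tuple[int, int] = (4, 10)
    n_runs: int = 2
    n_proteins: int | None = None
    protein_shift: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.class_counts) - set(PLANTED_CLASSES)
        if unknown:
            raise ValueError(f"unknown planted classes: {sorted(unknown)}")
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be nonnegative")
        if sum(self.class_counts.values()) != self.n_entities:
            raise ValueError(
                f"class_counts sum to {sum(self.class_counts.values())}, "
                f"expected n_entities = {self.n_entities}"
            )
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ValueError("invalid peptides_per_protein range")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")


@dataclass
class SyntheticDataset:
    """A generated input table plus its planted truth."""

    table: pd.DataFrame
    truth: dict[str, str]  # entity id -> planted class
    spec: PlantedSpec
    kind: str  # "proteomic" | "phospho"

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"entity_id": list(self.truth), "planted_class": list(self.truth.values())}
        )

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table = self.table.copy()
        if "sites" in table.columns:
            table["sites"] = table["sites"].map(";".join)
        name = "peptides.tsv" if self.kind == "proteomic" else "phospho.tsv"
        table.to_csv(out / name, sep="\t", index=False)
        self.truth_frame().to_csv(out / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# planted compositions
# ---------------------------------------------------------------------------

def planted_composition(
    n_total: int,
    n_affected: int,
    n_backreg_dtmp: int,
    n_backreg_lr: int,
    up_fraction: float = 0.5,
) -> dict[str, int]:
    """Build class counts realizing aggregate totals.

    The two treatment back-regulated sets are nested as far as possible
    (overlap = min of the two counts); affected entities are split
    up/down by ``up_fraction`` within each treatment stratum.
    """
    if not 0 <= n_backreg_dtmp <= n_affected or not 0 <= n_backreg_lr <= n_affected:
        raise ValueError("back-regulated counts must lie within the affected count")
    if not 0 <= n_affected <= n_total:
        raise ValueError("affected count must lie within the total")
    both = min(n_backreg_dtmp, n_backreg_lr)
    strata = {
        "_dtmp_lr": both,
        "_dtmp": n_backreg_dtmp - both,
        "_lr": n_backreg_lr - both,
        "": n_affected - n_backreg_dtmp - n_backreg_lr + both,
    }
    counts: dict[str, int] = {"unaffected": n_total - n_affected}
    for suffix, n in strata.items():
        n_up = int(round(n * up_fraction))
        counts["up" + suffix] = n_up
        counts["down" + suffix] = n - n_up
    return {k: v for k, v in counts.items() if v > 0 or k == "unaffected"}


#: Benchmark compositions: aggregate classification totals used throughout
#: the test suite.  Values are (n_total, n_affected, n_backreg_DTMP,
#: n_backreg_LR) plus the parent-protein count for phospho sets.
PHOSPHO_OVERALL = dict(n_total=883, n_affected=738, n_backreg_dtmp=559, n_backreg_lr=428)
PHOSPHO_OVERALL_PROTEINS = 93
PHOSPHO_CATEGORY_COMPOSITIONS: dict[str, dict] = {
    "structural": dict(n_total=69, n_affected=56, n_backreg_dtmp=46, n_backreg_lr=29, n_proteins=12),
    "adhesion": dict(n_total=111, n_affected=92, n_backreg_dtmp=75, n_backreg_lr=59, n_proteins=17),
    "junction": dict(n_total=790, n_affected=664, n_backreg_dtmp=509, n_backreg_lr=390, n_proteins=70),
    "signaling": dict(n_total=394, n_affected=325, n_backreg_dtmp=237, n_backreg_lr=197, n_proteins=58),
}
#: The proteomic benchmark realizes the reported reversal percentages
#: (83% DTMP, 67% LR of pain-affected proteins) over 186 ECM proteins.
PROTEOMIC_ECM = dict(n_total=186, n_affected=100, n_backreg_dtmp=83, n_backreg_lr=67)

#: Overlap-diagram fixture: circle sizes and intersections of the three
#: functional classes (structural / adhesion+junction / signaling).
VENN_ECM = dict(
    n_structural=48,
    n_adhesion_junction=112,
    n_signaling=102,
    overlaps={
        ("structural", "adhesion_junction"): 7,
        ("structural", "signaling"): 15,
        ("adhesion_junction", "signaling"): 69,
        ("structural", "adhesion_junction", "signaling"): 4,
    },
)


def benchmark_phospho_spec(
    composition: Mapping[str, int] = PHOSPHO_OVERALL,
    noise_sd: float = 0.0,
    margin: float = 0.25,
    n_proteins: int | None = PHOSPHO_OVERALL_PROTEINS,
    seed: int = 0,
) -> PlantedSpec:
    """A PlantedSpec for a benchmark phospho composition."""
    comp = {k: v for k, v in composition.items() if k != "n_proteins"}
    n_proteins = composition.get("n_proteins", n_proteins)
    return PlantedSpec(
        n_entities=comp["n_total"],
        class_counts=planted_composition(**comp),
        margin=margin,
        noise_sd=noise_sd,
        n_proteins=n_proteins,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# planted ratios
# ---------------------------------------------------------------------------

def planted_ratios(cls: str, threshold: float, margin: float) -> dict[str, float]:
    """Linear group ratios (pain, DTMP, LR contrasts) for a planted class."""
    up = (1.0 + threshold) * (1.0 + margin)
    down = (1.0 - threshold) / (1.0 + margin)
    r = {"pain": 1.0, "DTMP": 1.0, "LR": 1.0}
    if cls == "unaffected":
        return r
    parts = cls.split("_")
    direction = parts[0]
    r["pain"] = up if direction == "up" else down
    reverse = down if direction == "up" else up
    for t in parts[1:]:
        r[{"dtmp": "DTMP", "lr": "LR"}[t]] = reverse
    return r


def _assign_classes(spec: PlantedSpec) -> list[str]:
    # deterministic (seed-independent) assignment: the same spec plants the
    # same truth labels under every seed, only noise realizations differ
    return [c for c in PLANTED_CLASSES for _ in range(spec.class_counts.get(c, 0))]


# ---------------------------------------------------------------------------
# phospho generator
# ---------------------------------------------------------------------------

def generate_phospho_dataset(spec: PlantedSpec, threshold: float = 0.10) -> SyntheticDataset:
    """Generate an isoform-level intensity table with planted classes.

    Every channel of every run gets an independent log-normal noise factor;
    at noise_sd = 0 the per-run ratios equal the planted ratios exactly.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _assign_classes(spec)
    n = spec.n_entities
    n_prot = spec.n_proteins or max(1, round(n / 9))
    prot_ids = [f"PROT{i + 1:04d}" for i in range(n_prot)]
    rows = []
    truth: dict[str, str] = {}
    residues = np.array(list("STY"))
    for i, cls in enumerate(labels):
        pid = prot_ids[i % n_prot]
        iso = f"{pid}_p{i // n_prot + 1}"
        truth[iso] = cls
        n_sites = int(rng.integers(1, 4))
        sites = [
            f"{rng.choice(residues)}{int(rng.integers(1, 1500))}" for _ in range(n_sites)
        ]
        base = 2.0 ** rng.normal(17.0, 1.5)
        r = planted_ratios(cls, threshold, spec.margin)
        means = {
            "NoSNI": base,
            "NoSCS": base * r["pain"],
            "DTMP": base * r["pain"] * r["DTMP"],
            "LRSCS": base * r["pain"] * r["LR"],
        }
        for run in range(1, spec.n_runs + 1):
            for g in GROUPS:
                eps = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
                rows.append(
                    {
                        "protein_id": pid,
                        "isoform_id": iso,
                        "sites": sites,
                        "run_id": f"run{run}",
                        "group": g,
                        "intensity": means[g] * 2.0**eps,
                    }
                )
    table = pd.DataFrame(rows)
    return SyntheticDataset(table=table, truth=truth, spec=spec, kind="phospho")


# ---------------------------------------------------------------------------
# proteomic generator
# ---------------------------------------------------------------------------

def calibrated_shift(
    noise_sd: float,
    n_peptides: int,
    margin: float,
    alpha: float = 0.05,
    beta: float = 1e-6,
) -> float:
    """Log2 shift guaranteeing detection by the peptide-level t-test.

    Peptide deltas between two independently noisy channels have standard
    deviation noise_sd * sqrt(2); the classical power calculation gives a
    shift of (t_{1-alpha/2} + t_{1-beta}) * sd / sqrt(k) for a miss rate of
    beta.  The result is inflated by (1 + margin) and floored at
    log2(1.10 * (1 + margin)) so the fold change also clears the 10% rule.
    """
    floor = math.log2(1.10 * (1.0 + margin))
    if noise_sd == 0:
        return floor
    df = n_peptides - 1
    need = (
        (stats.t.ppf(1 - alpha / 2, df) + stats.t.ppf(1 - beta, df))
        * noise_sd
        * math.sqrt(2.0)
        / math.sqrt(n_peptides)
        * (1.0 + margin)
    )
    return max(floor, need)


def generate_proteomic_dataset(spec: PlantedSpec) -> SyntheticDataset:
    """Generate a peptide-level log2 intensity table with planted classes.

    Planted effects are common log2 shifts across a protein's peptides with
    independent per-channel noise; planted-null contrasts copy the reference
    channel verbatim (see module docstring).
    """
    rng = np.random.default_rng(spec.seed)
    labels = _assign_classes(spec)
    lo, hi = spec.peptides_per_protein
    rows = []
    truth: dict[str, str] = {}
    for i, cls in enumerate(labels):
        pid = f"PROT{i + 1:04d}"
        truth[pid] = cls
        k = int(rng.integers(lo, hi + 1))
        base = rng.normal(17.0, 1.5, size=k)

        def noisy(shifted: np.ndarray) -> np.ndarray:
            if spec.noise_sd > 0:
                return shifted + rng.normal(0.0, spec.noise_sd, size=k)
            return shifted.copy()

        delta = (
            spec.protein_shift
            if spec.protein_shift is not None
            else calibrated_shift(spec.noise_sd, k, spec.margin)
        )
        ref = noisy(base)
        channels = {"NoSNI": ref}
        parts = cls.split("_")
        if cls == "unaffected":
            channels["NoSCS"] = ref.copy()
        else:
            sign = 1.0 if parts[0] == "up" else -1.0
            channels["NoSCS"] = noisy(base + sign * delta)
            reversal = -sign * delta
        for key, group in TREATMENT_GROUPS.items():
            if cls != "unaffected" and key in parts[1:]:
                channels[group] = noisy(base + sign * delta + reversal)
            else:
                channels[group] = channels["NoSCS"].copy()
        for j in range(k):
            for g in GROUPS:
                rows.append(
                    {
                        "protein_id": pid,
                        "peptide_id": f"{pid}_pep{j + 1}",
                        "group": g,
                        "log2_intensity": channels[g][j],
                        "unique_assignment": True,
                    }
                )
    table = pd.DataFrame(rows)
    return SyntheticDataset(table=table, truth=truth, spec=spec, kind="proteomic")


# ---------------------------------------------------------------------------
# annotation generator
# ---------------------------------------------------------------------------

def generate_annotation(
    n_structural: int,
    n_adhesion_junction: int,
    n_signaling: int,
    overlaps: Mapping[tuple, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Annotation table realizing exact circle sizes and intersections.

    ``overlaps`` maps the three pairwise tuples and the triple tuple of
    group names ("structural", "adhesion_junction", "signaling") to counts.
    The adhesion/junction circle annotates its proteins with both the
    adhesion and junction categories.  Raises on an infeasible
    (inclusion-exclusion negative) specification.
    """
    names = ("structural", "adhesion_junction", "signaling")
    sizes = dict(zip(names, (n_structural, n_adhesion_junction, n_signaling)))
    ov = {tuple(sorted(k)): v for k, v in overlaps.items()}
    triple = ov.get(tuple(sorted(names)), 0)
    pair = {}
    for a, b in (("structural", "adhesion_junction"), ("structural", "signaling"),
                 ("adhesion_junction", "signaling")):
        pair[(a, b)] = ov.get(tuple(sorted((a, b))), 0)
        if pair[(a, b)] < triple:
            raise ValueError(f"pairwise overlap {a}&{b} smaller than the triple overlap")
    regions: dict[tuple[str, ...], int] = {names: triple}
    for (a, b), nab in pair.items():
        regions[(a, b)] = nab - triple
    for name in names:
        others = [p for p in pair if name in p]
        exclusive = sizes[name] - sum(pair[p] for p in others) + triple
        if exclusive < 0:
            raise ValueError(f"group {name!r} overlaps exceed its size")
        regions[(name,)] = exclusive
    group_cats = {
        "structural": {"structural"},
        "adhesion_junction": {"adhesion", "junction"},
        "signaling": {"signaling"},
    }
    rng = np.random.default_rng(seed)
    n_total = sum(regions.values())
    ids = [f"ECM{i + 1:04d}" for i in range(n_total)]
    rng.shuffle(ids)
    rows = []
    it = iter(ids)
    for region, count in regions.items():
        cats: set[str] = set()
        for g in region:
            cats |= group_cats[g]
        for _ in range(count):
            rows.append(
                {
                    "protein_id": next(it),
                    "categories": frozenset(cats),
                    "source": "literature" if rng.random() < 0.05 else "ontology",
                }
            )
    return pd.DataFrame(rows).sort_values("protein_id", ignore_index=True)


def uniform_annotation(protein_ids, category: str, source: str = "ontology") -> pd.DataFrame:
    """Annotate every given protein with a single category (rollup fixtures)."""
    return pd.DataFrame(
        {
            "protein_id": sorted(set(protein_ids)),
            "categories": [frozenset({category})] * len(set(protein_ids)),
            "source": source,
        }
    )
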