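"""Matrisome category rollups and overlap (Venn) counts.

Annotations assign each protein a nonempty subset of the four functional
categories -- structural, adhesion, junction, signaling -- sourced from an
ontology search or the literature.  Entities may belong to several
categories; a rollup therefore counts each entity once per category it
belongs to, so category totals may sum to more than the number of distinct
entities.  Phospho-isoforms inherit every category of their parent protein.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

from .quant import round_half_up

#: The recognized functional categories.
CATEGORIES: frozenset[str] = frozenset({"structural", "adhesion", "junction", "signaling"})

#: The three circles of the overlap diagram: the adhesion and junction
#: categories are pooled into one adhesion/junction class.
VENN_GROUPS: dict[str, frozenset[str]] = {
    "structural": frozenset({"structural"}),
    "adhesion_junction": frozenset({"adhesion", "junction"}),
    "signaling": frozenset({"signaling"}),
}


def _category_sets(ann: pd.DataFrame) -> pd.Series:
    """protein_id -> frozenset of categories, with validation."""
    sets = {}
    for pid, cats in zip(ann["protein_id"], ann["categories"]):
        cats = frozenset(cats)
        if not cats:
            raise ValueError(f"protein {pid!r} has an empty category set")
        unknown = cats - CATEGORIES
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)} for protein {pid!r}")
        sets[pid] = cats
    return pd.Series(sets, dtype=object)


@dataclass
class VennCounts:
    """Exact set-arithmetic overlap counts for a list of named groups."""

    sizes: dict[str, int]
    pairwise: dict[tuple[str, str], int]
    common: int  # intersection of all groups (the triple overlap for 3)
    union: int

    def to_dict(self) -> dict:
        return {
            "sizes": dict(self.sizes),
            "pairwise": {"&".join(k): v for k, v in self.pairwise.items()},
            "common": self.common,
            "union": self.union,
        }


def venn_counts(
    ann: pd.DataFrame, groups: Mapping[str, Iterable[str]] = VENN_GROUPS
) -> VennCounts:
    """Group sizes, pairwise intersections and the overall intersection.

    ``groups`` maps a group name to the category set defining membership;
    a protein belongs to a group when its annotation intersects that set.
    """
    if not groups:
        raise ValueError("no groups given")
    sets = _category_sets(ann)
    members: dict[str, set[str]] = {}
    for name, cats in groups.items():
        cats = frozenset(cats)
        unknown = cats - CATEGORIES
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)} in group {name!r}")
        members[name] = {pid for pid, s in sets.items() if s & cats}
    names = list(members)
    sizes = {n: len(members[n]) for n in names}
    pairwise = {
        (a, b): len(members[a] & members[b]) for a, b in combinations(names, 2)
    }
    common = set.intersection(*members.values())
    union = set.union(*members.values())
    return VennCounts(sizes=sizes, pairwise=pairwise, common=len(common), union=len(union))


def rollup_by_category(
    records: pd.DataFrame,
    ann: pd.DataFrame,
    level: str,
    categories: Iterable[str] = ("structural", "adhesion", "junction", "signaling"),
) -> tuple[pd.DataFrame, list[str]]:
    """Per-category classification totals, plus the unannotated entities.

    ``records`` is a classification record table; for ``level ==
    "phospho_isoform"`` its ``protein_id`` column names the parent protein,
    whose categories the isoform inherits.  Percentages are rounded half-up
    to the nearest integer (the convention of the per-category tables):
    pct_affected is over n_total, pct_backreg_* over n_affected.
    """
    if level not in ("protein", "phospho_isoform"):
        raise ValueError(f"unknown level {level!r}")
    categories = list(categories)
    unknown = set(categories) - CATEGORIES
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    sets = _category_sets(ann)
    annotated = records["protein_id"].isin(sets.index)
    unannotated = sorted(records.loc[~annotated, "entity_id"])
    kept = records[annotated]
    rows = []
    for cat in categories:
        in_cat = kept["protein_id"].map(lambda p: cat in sets[p])
        sub = kept[in_cat]
        n_total = int(len(sub))
        n_aff = int(sub["affected"].sum())
        n_d = int(sub["backreg_DTMP"].sum())
        n_l = int(sub["backreg_LR"].sum())
        rows.append(
            {
                "category": cat,
                "level": level,
                "n_total": n_total,
                "n_proteins": int(sub["protein_id"].nunique()),
                "n_affected": n_aff,
                "n_backreg_DTMP": n_d,
                "n_backreg_LR": n_l,
                "pct_affected": round_half_up(100.0 * n_aff / n_total) if n_total else None,
                "pct_backreg_DTMP": round_half_up(100.0 * n_d / n_aff) if n_aff else None,
                "pct_backreg_LR": round_half_up(100.0 * n_l / n_aff) if n_aff else None,
            }
        )
    return pd.DataFrame(rows), unannotated
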