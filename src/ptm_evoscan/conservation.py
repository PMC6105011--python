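"""Complete-conservation and new-emergence calls for PTM-site residues.

A site residue is completely conserved at a clade level when, in its family
alignment, the human residue is matched (strict mode) or class-compatible
(class mode) in every ortholog row of that level's species, with no gaps.
A residue is newly emerged at a level when it is conserved there but not at
the immediately wider (more ancient) level.  Column-quality masks can
exclude low-quality alignment columns, which can only remove conservation,
never add it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel_io import (
    ACETYL_CLASS,
    METHYL_CLASS,
    CladeHierarchy,
    ColumnMask,
    FamilyAlignment,
    PtmSite,
    ResidueClass,
    ValidationError,
    singleton_class,
)
from .orthology_clades import NEW, OLD
from .region_annotation import ResidueAnnotation

__all__ = [
    "STRICT",
    "CLASS",
    "ConservationCall",
    "residue_class_for",
    "column_conserved",
    "call_conservation",
    "apply_column_mask",
    "build_call_table",
    "conserved_site_table",
    "table1_summary",
    "residue_conservation_map",
    "write_call_table",
]

STRICT = "strict"
CLASS = "class"

DEFAULT_MASK_MIN = 5.0
DEFAULT_MASK_MAX = 10.0

#: Modification types counted as MAU.
MAU = ("methylation", "acetylation", "ubiquitination")


@dataclass(frozen=True)
class ConservationCall:
    """Conservation status of one site residue at one clade level."""

    protein_id: str
    position: int
    level: str
    conserved: bool
    newly_emerged: bool
    class_used: str
    n_species_checked: int
    masked: bool = False

    def __post_init__(self) -> None:
        if self.newly_emerged and not self.conserved:
            raise ValidationError(
                f"{self.protein_id}:{self.position}@{self.level}: "
                "newly_emerged requires conserved"
            )
        if self.conserved and self.n_species_checked < 1:
            raise ValidationError(
                f"{self.protein_id}:{self.position}@{self.level}: "
                "conserved with zero species checked"
            )


def residue_class_for(ptm_type: str, human_residue: str, mode: str) -> ResidueClass:
    """Residue class used for a site under the given mode.

    Strict mode always uses the singleton of the human residue.  Class mode
    allows K<->R for methylation and K->{A,G,M,S,T} for acetylation; other
    modifications have no substitution allowance and stay strict.
    """
    if mode == STRICT:
        return singleton_class(human_residue)
    if mode != CLASS:
        raise ValidationError(f"unknown mode {mode!r}")
    if ptm_type == "methylation":
        return METHYL_CLASS
    if ptm_type == "acetylation":
        return ACETYL_CLASS
    return singleton_class(human_residue)


def column_conserved(
    alignment: FamilyAlignment,
    column: int,
    species_subset: Iterable[str],
    residue_class: ResidueClass | None = None,
    mode: str = STRICT,
) -> tuple[bool, int]:
    """Is an alignment column completely conserved over a species subset?

    Considers the human row plus every ortholog row whose species is in the
    subset; species without a row are ignored.  Strict mode requires every
    character to equal the human residue; class mode requires membership in
    ``residue_class``.  Gaps break conservation in both modes, and a subset
    with no ortholog rows is never conserved.

    Returns (conserved, number of ortholog rows checked).
    """
    human = alignment.column(column)
    rows = [
        alignment.column(column, sp)
        for sp in species_subset
        if sp in alignment.ortholog_rows
    ]
    n_checked = len(rows)
    if n_checked == 0 or human == FamilyAlignment.GAP:
        return False, n_checked
    if mode == STRICT:
        ok = all(ch == human for ch in rows)
    elif mode == CLASS:
        if residue_class is None:
            raise ValidationError("class mode requires a residue_class")
        ok = human in residue_class and all(
            ch != FamilyAlignment.GAP and ch in residue_class for ch in rows
        )
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return ok, n_checked


def apply_column_mask(
    scores: Sequence[float] | np.ndarray,
    min_score: float = DEFAULT_MASK_MIN,
    max_score: float = DEFAULT_MASK_MAX,
) -> ColumnMask:
    """Build a retain/discard mask from per-column quality scores in [0, 10]."""
    scores = tuple(float(s) for s in scores)
    for i, s in enumerate(scores, start=1):
        if not 0.0 <= s <= 10.0:
            raise ValidationError(f"column {i}: score {s} outside [0, 10]")
    retained = tuple(min_score <= s <= max_score for s in scores)
    return ColumnMask(scores, retained)


def call_conservation(
    site: PtmSite,
    alignment: FamilyAlignment,
    hierarchy: CladeHierarchy,
    mask: ColumnMask | None = None,
    mode: str = STRICT,
) -> list[ConservationCall]:
    """Conservation calls for one site at every level, innermost first.

    Levels where the protein is not included (no ortholog species in the
    level) are skipped.  ``newly_emerged`` is true at a level iff the site
    is conserved there but not at the immediately wider level; it is always
    false at the outermost level.
    """
    column = alignment.position_to_column(site.position)
    rclass = residue_class_for(site.ptm_type, site.residue, mode)
    masked = mask is not None and not mask.is_retained(column)

    per_level: list[tuple[str, bool, int]] = []
    for name, species in hierarchy.levels:
        subset = species - {hierarchy.reference_species}
        conserved, n_checked = column_conserved(
            alignment, column, subset, rclass, mode
        )
        if masked:
            conserved = False
        per_level.append((name, conserved, n_checked))

    calls = []
    included_species = alignment.species
    for i, (name, conserved, n_checked) in enumerate(per_level):
        level_species = hierarchy.levels[i][1] - {hierarchy.reference_species}
        if not (included_species & level_species):
            continue  # protein not included at this level
        if i + 1 < len(per_level):
            newly = conserved and not per_level[i + 1][1]
        else:
            newly = False
        calls.append(
            ConservationCall(
                site.protein_id,
                site.position,
                name,
                conserved,
                newly,
                rclass.name,
                n_checked,
                masked,
            )
        )
    return calls


def build_call_table(
    sites: Iterable[PtmSite],
    alignments: Mapping[str, FamilyAlignment],
    hierarchy: CladeHierarchy,
    annotations: Mapping[str, ResidueAnnotation],
    mode: str = STRICT,
    masks: Mapping[str, ColumnMask] | None = None,
) -> pd.DataFrame:
    """One row per (site, included level) with region and protein context.

    Sites whose protein lacks an alignment are skipped (no orthologs were
    found, so the protein is not included anywhere).
    """
    rows = []
    age_cache: dict[tuple[str, str], str] = {}
    for site in sites:
        if site.protein_id not in alignments:
            continue
        alignment = alignments[site.protein_id]
        ann = annotations[site.protein_id]
        region = ann.label_at(site.position)
        mask = masks.get(site.protein_id) if masks else None
        for call in call_conservation(site, alignment, hierarchy, mask, mode):
            key = (site.protein_id, call.level)
            if key not in age_cache:
                outside = hierarchy.outermost - hierarchy.species_at(call.level)
                age_cache[key] = OLD if alignment.species & outside else NEW
            rows.append(
                {
                    "protein_id": site.protein_id,
                    "position": site.position,
                    "residue": site.residue,
                    "ptm_type": site.ptm_type,
                    "level": call.level,
                    "region": region,
                    "conserved": call.conserved,
                    "newly_emerged": call.newly_emerged,
                    "masked": call.masked,
                    "class_used": call.class_used,
                    "n_species_checked": call.n_species_checked,
                    "age_class": age_cache[key],
                    "histone": ann.histone,
                    "fb": bool(ann.fb[site.position - 1]),
                    "homopeptide": bool(ann.homopeptide[site.position - 1]),
                    "prion_like": ann.prion_like,
                }
            )
    columns = [
        "protein_id", "position", "residue", "ptm_type", "level", "region",
        "conserved", "newly_emerged", "masked", "class_used",
        "n_species_checked", "age_class", "histone", "fb", "homopeptide",
        "prion_like",
    ]
    return pd.DataFrame(rows, columns=columns)


def conserved_site_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Aggregate calls per (level, region, ptm_type, residue letter).

    Reports totals, conserved and newly-emerged counts, splits by protein
    age class and histone flag, and protein-level "has >= 1 conserved site"
    counts.
    """
    if calls.empty:
        return pd.DataFrame(
            columns=[
                "level", "region", "ptm_type", "residue", "n_total",
                "n_conserved", "n_newly_emerged", "n_total_old",
                "n_conserved_old", "n_total_new", "n_conserved_new",
                "n_total_histone", "n_conserved_histone", "proteins_total",
                "proteins_conserved",
            ]
        )
    rows = []
    for (level, region, ptm_type, residue), grp in calls.groupby(
        ["level", "region", "ptm_type", "residue"], sort=True
    ):
        old = grp[grp.age_class == OLD]
        new = grp[grp.age_class == NEW]
        hist = grp[grp.histone]
        cons = grp[grp.conserved]
        rows.append(
            {
                "level": level,
                "region": region,
                "ptm_type": ptm_type,
                "residue": residue,
                "n_total": len(grp),
                "n_conserved": int(grp.conserved.sum()),
                "n_newly_emerged": int(grp.newly_emerged.sum()),
                "n_total_old": len(old),
                "n_conserved_old": int(old.conserved.sum()),
                "n_total_new": len(new),
                "n_conserved_new": int(new.conserved.sum()),
                "n_total_histone": len(hist),
                "n_conserved_histone": int(hist.conserved.sum()),
                "proteins_total": grp.protein_id.nunique(),
                "proteins_conserved": cons.protein_id.nunique(),
            }
        )
    return pd.DataFrame(rows)


def table1_summary(calls: pd.DataFrame, level: str) -> pd.DataFrame:
    """Conserved-fraction summary at one level, one row per site category.

    Categories: all MAU residues (distinct residues with any MAU type),
    then (methylation, K), (methylation, R), (acetylation, K),
    (ubiquitination, K).  For each category and region: conserved/total
    residue counts and proteins-with-conserved/total protein counts.
    """
    at_level = calls[(calls.level == level) & calls.ptm_type.isin(MAU)]
    rows = []

    def summarize(label: str, sub: pd.DataFrame) -> None:
        for region in ("ordered", "disordered"):
            reg = sub[sub.region == region]
            per_residue = reg.groupby(["protein_id", "position"]).conserved.any()
            n_total = len(per_residue)
            n_conserved = int(per_residue.sum())
            proteins_total = reg.protein_id.nunique()
            proteins_conserved = reg[reg.conserved].protein_id.nunique()
            rows.append(
                {
                    "category": label,
                    "region": region,
                    "conserved_residues": n_conserved,
                    "total_residues": n_total,
                    "proteins_with_conserved": proteins_conserved,
                    "total_proteins": proteins_total,
                }
            )

    summarize("all_mau", at_level)
    for label, ptm_type, residue in (
        ("methylation_K", "methylation", "K"),
        ("methylation_R", "methylation", "R"),
        ("acetylation_K", "acetylation", "K"),
        ("ubiquitination_K", "ubiquitination", "K"),
    ):
        summarize(
            label,
            at_level[(at_level.ptm_type == ptm_type) & (at_level.residue == residue)],
        )
    return pd.DataFrame(rows)


def residue_conservation_map(
    alignment: FamilyAlignment,
    hierarchy: CladeHierarchy,
    positions: Iterable[int],
    mask: ColumnMask | None = None,
) -> dict[tuple[int, str], bool]:
    """Strict conservation of arbitrary human positions at every level.

    Used to build the "all conserved residues of a letter" background for
    the enrichment stage.  Returns (position, level name) -> bool.
    """
    positions = list(positions)
    out: dict[tuple[int, str], bool] = {}
    ref = hierarchy.reference_species
    if not positions:
        return out
    columns = [alignment.position_to_column(p) for p in positions]
    human = np.array([alignment.column(c) for c in columns])
    species_order = sorted(alignment.ortholog_rows)
    if species_order:
        rows = np.array(
            [[alignment.column(c, sp) for c in columns] for sp in species_order]
        )
        match = rows == human[None, :]
    for name, level_species in hierarchy.levels:
        subset = level_species - {ref}
        members = [i for i, sp in enumerate(species_order) if sp in subset]
        if members:
            conserved = match[members, :].all(axis=0)
        else:
            conserved = np.zeros(len(columns), dtype=bool)
        for pos, col, ok in zip(positions, columns, conserved):
            if mask is not None and not mask.is_retained(col):
                ok = False
            out[(pos, name)] = bool(ok)
    return out


def write_call_table(path: str | Path, calls: pd.DataFrame) -> None:
    calls.to_csv(path, sep="\t", index=False)
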