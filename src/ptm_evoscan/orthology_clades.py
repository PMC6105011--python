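"""Reciprocal-best-hit orthology, clade inclusion and protein age classes.

Best hits are chosen by lowest e-value, ties broken by highest bitscore;
remaining ties give no call.  A protein is included at a clade level when it
has an ortholog in at least one of that level's species (the reference
species itself does not count), and is "new" at a level when none of its
ortholog species falls outside that level.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .datamodel_io import CladeHierarchy, HitRecord, ValidationError

__all__ = [
    "OrthologMap",
    "best_hits",
    "reciprocal_best_hits",
    "clade_inclusion",
    "protein_age_class",
    "write_ortholog_map",
    "read_ortholog_map",
]

DEFAULT_EVALUE_MAX = 1e-4

NEW = "new"
OLD = "old"


class OrthologMap:
    """Mapping (human protein, species) -> subject id, one entry max."""

    def __init__(self) -> None:
        self.entries: dict[tuple[str, str], str] = {}

    def add(self, protein_id: str, species: str, subject_id: str) -> None:
        key = (protein_id, species)
        if key in self.entries and self.entries[key] != subject_id:
            raise ValidationError(
                f"conflicting ortholog for {protein_id!r} in {species!r}"
            )
        self.entries[key] = subject_id

    def species_with_ortholog(self, protein_id: str) -> frozenset[str]:
        return frozenset(sp for (pid, sp) in self.entries if pid == protein_id)

    def proteins(self) -> frozenset[str]:
        return frozenset(pid for (pid, _) in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrthologMap):
            return NotImplemented
        return self.entries == other.entries


def best_hits(hits: Iterable[HitRecord]) -> dict[str, str]:
    """Best subject per query by (lowest e-value, highest bitscore).

    Self-hits are discarded first; queries whose top two candidates tie on
    both criteria get no call.
    """
    by_query: dict[str, list[HitRecord]] = {}
    for hit in hits:
        if hit.query_id == hit.subject_id:
            continue
        by_query.setdefault(hit.query_id, []).append(hit)
    out: dict[str, str] = {}
    for query, candidates in by_query.items():
        candidates.sort(key=lambda h: (h.evalue, -h.bitscore))
        top = candidates[0]
        if len(candidates) > 1:
            second = candidates[1]
            if (second.evalue, second.bitscore) == (top.evalue, top.bitscore):
                continue  # ambiguous best: no call
        out[query] = top.subject_id
    return out


def reciprocal_best_hits(
    hits_forward: Iterable[HitRecord],
    hits_backward: Iterable[HitRecord],
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> dict[str, str]:
    """Reciprocal best hits for one species pair.

    A pair (h, s) is accepted iff s is h's best forward hit and h is s's
    best backward hit, and both best hits have e-value < evalue_max.
    """

    def filtered_best(hits: Iterable[HitRecord]) -> dict[str, str]:
        chosen = best_hits(hits)
        by_pair = {
            (h.query_id, h.subject_id): h
            for h in hits
            if h.query_id != h.subject_id
        }
        return {
            q: s
            for q, s in chosen.items()
            if by_pair[(q, s)].evalue < evalue_max
        }

    hits_forward = list(hits_forward)
    hits_backward = list(hits_backward)
    forward = filtered_best(hits_forward)
    backward = filtered_best(hits_backward)
    return {
        h: s for h, s in forward.items() if backward.get(s) == h
    }


def clade_inclusion(
    ortholog_map: OrthologMap, hierarchy: CladeHierarchy, level: str
) -> frozenset[str]:
    """Human proteins with >= 1 ortholog among the level's species."""
    species = hierarchy.species_at(level) - {hierarchy.reference_species}
    return frozenset(
        pid
        for (pid, sp) in ortholog_map.entries
        if sp in species
    )


def protein_age_class(
    ortholog_map: OrthologMap,
    hierarchy: CladeHierarchy,
    level: str,
    protein_id: str,
) -> str:
    """Classify an included protein as ``new`` or ``old`` at a level.

    New iff the protein has no ortholog in any species outside the level's
    set, where "outside" means the outermost level's species minus the
    level's species.  At the outermost level every included protein is new
    by vacuity.
    """
    if protein_id not in clade_inclusion(ortholog_map, hierarchy, level):
        raise ValidationError(
            f"{protein_id!r} is not included at level {level!r}"
        )
    outside = hierarchy.outermost - hierarchy.species_at(level)
    present = ortholog_map.species_with_ortholog(protein_id)
    return OLD if present & outside else NEW


def write_ortholog_map(path: str | Path, ortholog_map: OrthologMap) -> None:
    """Serialize as three-column text (protein, species, subject)."""
    with open(path, "w") as fh:
        fh.write("#protein_id\tspecies\tsubject_id\n")
        for (pid, sp) in sorted(ortholog_map.entries):
            fh.write(f"{pid}\t{sp}\t{ortholog_map.entries[(pid, sp)]}\n")


def read_ortholog_map(path: str | Path) -> OrthologMap:
    out = OrthologMap()
    with open(path) as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.startswith("#"):
                continue
            pid, sp, subject = stripped.split("\t")[:3]
            out.add(pid, sp, subject)
    return out
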