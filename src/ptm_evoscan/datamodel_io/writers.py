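"""Writers mirroring the readers, used by the synthetic generator and CLI.

Every write/read pair round-trips the in-memory value exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .types import CladeHierarchy, FamilyAlignment, HitRecord, Interval, ProteinSequence, PtmSite

__all__ = [
    "write_fasta",
    "write_alignment",
    "write_ptm_sites",
    "write_hit_table",
    "write_clade_config",
    "write_bed_intervals",
    "write_disorder_scores",
    "write_column_scores",
    "write_id_list",
]

_WRAP = 60


def _wrap(seq: str) -> str:
    return "\n".join(seq[i : i + _WRAP] for i in range(0, len(seq), _WRAP))


def write_fasta(path: str | Path, sequences: Iterable[ProteinSequence]) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.protein_id}\n{_wrap(seq.residues)}\n")


def write_alignment(
    path: str | Path, alignment: FamilyAlignment, reference_species: str = "homo_sapiens"
) -> None:
    with open(path, "w") as fh:
        fh.write(f">{reference_species}|{alignment.protein_id}\n")
        fh.write(_wrap(alignment.human_row) + "\n")
        for species in sorted(alignment.ortholog_rows):
            fh.write(f">{species}|{alignment.protein_id}_{species}\n")
            fh.write(_wrap(alignment.ortholog_rows[species]) + "\n")


def write_ptm_sites(path: str | Path, sites: Iterable[PtmSite]) -> None:
    with open(path, "w") as fh:
        fh.write("#protein_id\tposition\tresidue\tptm_type\n")
        for site in sites:
            fh.write(f"{site.protein_id}\t{site.position}\t{site.residue}\t{site.ptm_type}\n")


def write_hit_table(path: str | Path, hits: Iterable[HitRecord]) -> None:
    """Write 12-column tabular hits; unused columns are filled with 0."""
    with open(path, "w") as fh:
        for h in hits:
            filler = "\t".join(["0"] * 8)
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{filler}\t{h.evalue:g}\t{h.bitscore:g}\n"
            )


def write_clade_config(path: str | Path, hierarchy: CladeHierarchy) -> None:
    data = {
        "reference_species": hierarchy.reference_species,
        "levels": [
            {"name": name, "species": sorted(spp)} for name, spp in hierarchy.levels
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_bed_intervals(
    path: str | Path, intervals: Mapping[str, Iterable[Interval]]
) -> None:
    """Write 1-based inclusive intervals back out as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for protein_id in sorted(intervals):
            for iv in intervals[protein_id]:
                fh.write(f"{protein_id}\t{iv.start - 1}\t{iv.end}\t{iv.label}\n")


def write_disorder_scores(
    path: str | Path, scores: Mapping[str, np.ndarray]
) -> None:
    with open(path, "w") as fh:
        fh.write("#protein_id\tposition\tscore\n")
        for protein_id in sorted(scores):
            for i, score in enumerate(scores[protein_id], start=1):
                fh.write(f"{protein_id}\t{i}\t{score:.4f}\n")


def write_column_scores(path: str | Path, scores: Iterable[float]) -> None:
    with open(path, "w") as fh:
        for i, score in enumerate(scores, start=1):
            fh.write(f"{i}\t{score:.4f}\n")


def write_id_list(path: str | Path, ids: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for item in sorted(ids):
            fh.write(f"{item}\n")
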