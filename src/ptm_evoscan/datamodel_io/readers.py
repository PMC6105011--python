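"""Readers for every external format the pipeline consumes.

Coordinates on disk follow each format's native convention (BED is 0-based
half-open); everything is converted to the internal 1-based inclusive model
here and nowhere else.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml
from Bio import SeqIO

from .types import (
    CladeHierarchy,
    FamilyAlignment,
    FormatError,
    HitRecord,
    Interval,
    ProteinSequence,
    PtmSite,
    ValidationError,
    normalize_ptm_type,
)

__all__ = [
    "read_fasta",
    "read_alignment",
    "read_ptm_sites",
    "read_hit_table",
    "read_clade_config",
    "read_bed_intervals",
    "read_disorder_scores",
    "read_column_scores",
    "read_id_list",
]


def _check_fasta_syntax(path: Path) -> None:
    """Light syntax pass so errors can name the offending line."""
    header_line = None
    saw_seq = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if header_line is not None and not saw_seq:
                    raise FormatError(
                        f"{path}: record at line {header_line} has an empty sequence"
                    )
                if stripped == ">":
                    raise FormatError(f"{path}: malformed header at line {lineno}")
                header_line = lineno
                saw_seq = False
            else:
                if header_line is None:
                    raise FormatError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                saw_seq = True
    if header_line is not None and not saw_seq:
        raise FormatError(
            f"{path}: record at line {header_line} has an empty sequence"
        )


def read_fasta(path: str | Path, species: str = "homo_sapiens") -> list[ProteinSequence]:
    """Read a FASTA file into a list of :class:`ProteinSequence`.

    Sequences are uppercased; record order is preserved.  An empty file
    yields an empty list.
    """
    path = Path(path)
    _check_fasta_syntax(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinSequence(rec.id, str(rec.seq).upper(), species=species)
        )
    return records


def read_alignment(path: str | Path) -> FamilyAlignment:
    """Read one family alignment from aligned FASTA.

    The first record is the reference (human) row.  Headers encode species
    as ``species|sequence_id``.  Rows must have equal length and at most one
    ortholog per species is allowed.
    """
    path = Path(path)
    _check_fasta_syntax(path)
    rows = list(SeqIO.parse(str(path), "fasta"))
    if not rows:
        raise FormatError(f"{path}: alignment file is empty")
    lengths = {len(r.seq) for r in rows}
    if len(lengths) > 1:
        raise ValidationError(
            f"{path}: rows have unequal lengths {sorted(lengths)}"
        )

    def split_header(header: str) -> tuple[str, str]:
        if "|" not in header:
            raise FormatError(
                f"{path}: header {header!r} is not of the form species|sequence_id"
            )
        species, seq_id = header.split("|", 1)
        return species, seq_id

    _, protein_id = split_header(rows[0].id)
    ortholog_rows: dict[str, str] = {}
    for rec in rows[1:]:
        species, _ = split_header(rec.id)
        if species in ortholog_rows:
            raise ValidationError(
                f"{path}: duplicate species {species!r} (at most one ortholog per species)"
            )
        ortholog_rows[species] = str(rec.seq)
    return FamilyAlignment(protein_id, str(rows[0].seq), ortholog_rows)


def read_ptm_sites(
    path: str | Path,
    sequences: Mapping[str, ProteinSequence] | Iterable[ProteinSequence],
) -> list[PtmSite]:
    """Read and validate a tab-separated PTM site table.

    Columns: protein_id, 1-based position, residue, ptm_type.  Rows are
    de-duplicated on (protein_id, position, ptm_type); every surviving site
    is checked against its sequence.  Lines starting with ``#`` are skipped.
    """
    path = Path(path)
    if not isinstance(sequences, Mapping):
        sequences = {s.protein_id: s for s in sequences}
    sites: list[PtmSite] = []
    seen: set[tuple[str, int, str]] = set()
    bad_rows: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got {len(fields)}"
                )
            protein_id, pos_str, residue, ptm_raw = fields[:4]
            try:
                position = int(pos_str)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer position {pos_str!r}"
                ) from None
            if protein_id not in sequences:
                raise ValidationError(
                    f"{path}:{lineno}: unknown protein id {protein_id!r}"
                )
            seq = sequences[protein_id]
            residue = residue.upper()
            if not (1 <= position <= len(seq)) or seq.residue_at(position) != residue:
                bad_rows.append(
                    f"line {lineno}: {protein_id} position {position} residue "
                    f"{residue!r} does not match sequence"
                )
                continue
            site = PtmSite(protein_id, position, residue, normalize_ptm_type(ptm_raw))
            if site.key in seen:
                continue
            seen.add(site.key)
            sites.append(site)
    if bad_rows:
        raise ValidationError(
            f"{path}: {len(bad_rows)} site row(s) failed residue validation:\n  "
            + "\n  ".join(bad_rows)
        )
    return sites


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tabular similarity hit file (BLAST outfmt-6 dialect).

    Only columns 1 (query), 2 (subject), 11 (e-value) and 12 (bitscore) are
    used; the rest are ignored.
    """
    path = Path(path)
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected >=12 columns, got {len(fields)}"
                )
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric evalue/bitscore"
                ) from None
            hits.append(HitRecord(fields[0], fields[1], evalue, bitscore))
    return hits


def read_clade_config(path: str | Path) -> CladeHierarchy:
    """Read a nested-clade hierarchy from a YAML config.

    Expected structure::

        reference_species: homo_sapiens
        levels:                     # innermost first
          - name: Apes
            species: [homo_sapiens, pan_troglodytes]
          - name: Primates
            species: [homo_sapiens, pan_troglodytes, macaca_mulatta]
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "levels" not in data:
        raise FormatError(f"{path}: expected a mapping with a 'levels' key")
    reference = data.get("reference_species", "homo_sapiens")
    levels = []
    for entry in data["levels"]:
        if not isinstance(entry, dict) or "name" not in entry or "species" not in entry:
            raise FormatError(
                f"{path}: each level needs 'name' and 'species' keys, got {entry!r}"
            )
        levels.append((str(entry["name"]), frozenset(map(str, entry["species"]))))
    return CladeHierarchy(levels, reference_species=reference)


def read_bed_intervals(path: str | Path) -> dict[str, list[Interval]]:
    """Read BED (0-based half-open) into per-protein 1-based inclusive intervals."""
    path = Path(path)
    out: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 BED columns, got {len(fields)}"
                )
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end0 <= start0:
                raise FormatError(
                    f"{path}:{lineno}: empty or inverted interval [{start0}, {end0})"
                )
            label = fields[3] if len(fields) > 3 else ""
            out.setdefault(fields[0], []).append(Interval(start0 + 1, end0, label))
    return out


def read_disorder_scores(
    path: str | Path, sequences: Mapping[str, ProteinSequence]
) -> dict[str, np.ndarray]:
    """Read per-residue scores (protein_id, 1-based position, score in [0,1]).

    Returns one float array per protein, length equal to the sequence;
    positions absent from the file score 0.
    """
    path = Path(path)
    out = {
        pid: np.zeros(len(seq), dtype=float) for pid, seq in sequences.items()
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            pid = fields[0]
            if pid not in out:
                raise ValidationError(f"{path}:{lineno}: unknown protein id {pid!r}")
            try:
                position = int(fields[1])
                score = float(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric position/score") from None
            if not 0.0 <= score <= 1.0:
                raise ValidationError(
                    f"{path}:{lineno}: disorder score {score} outside [0, 1]"
                )
            if not 1 <= position <= len(out[pid]):
                raise ValidationError(
                    f"{path}:{lineno}: position {position} outside sequence {pid!r}"
                )
            out[pid][position - 1] = score
    return out


def read_column_scores(path: str | Path) -> np.ndarray:
    """Read per-column quality scores as (1-based column index, score) rows."""
    path = Path(path)
    entries: dict[int, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            try:
                column = int(fields[0])
                score = float(fields[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric column/score") from None
            entries[column] = score
    if not entries:
        return np.zeros(0, dtype=float)
    n = max(entries)
    if set(entries) != set(range(1, n + 1)):
        raise FormatError(f"{path}: column indices are not contiguous from 1")
    return np.array([entries[c] for c in range(1, n + 1)], dtype=float)


def read_id_list(path: str | Path) -> set[str]:
    """Read a plain-text id list, one id per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}
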