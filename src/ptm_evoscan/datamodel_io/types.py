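"""Core domain types shared by every pipeline stage.

All residue coordinates are 1-based and inclusive.  Interval files on disk
use BED conventions (0-based, half-open) and are converted at the I/O
boundary, never internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "AMINO_ACIDS",
    "MAU_TYPES",
    "ProteinSequence",
    "PtmSite",
    "Interval",
    "HitRecord",
    "CladeHierarchy",
    "FamilyAlignment",
    "ColumnMask",
    "ResidueClass",
    "EnrichmentResult",
    "METHYL_CLASS",
    "ACETYL_CLASS",
    "DEFAULT_LEVEL_NAMES",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Canonical modification-type names used throughout the pipeline.
MAU_TYPES = ("methylation", "acetylation", "ubiquitination")

KNOWN_PTM_TYPES = MAU_TYPES + ("phosphorylation",)

#: Level names for the default eleven-level hierarchy, innermost first.
DEFAULT_LEVEL_NAMES = (
    "Apes",
    "Primates",
    "Supraprimates",
    "Eutherians",
    "Mammals",
    "Tetrapods",
    "Vertebrates",
    "Chordates",
    "Deuterostomes",
    "Metazoans",
    "Eukaryotes",
)


class FormatError(ValueError):
    """A file did not conform to its expected on-disk format."""


class ValidationError(ValueError):
    """Parsed data violated a cross-record consistency rule."""


def normalize_ptm_type(raw: str) -> str:
    """Map a raw modification-type string to a canonical name.

    Known types pass through; anything else is preserved as
    ``other:<name>`` so rare PTMs flow through the same machinery.
    """
    name = raw.strip().lower()
    if name in KNOWN_PTM_TYPES:
        return name
    if name.startswith("other:"):
        return name
    return f"other:{name}"


@dataclass(frozen=True)
class ProteinSequence:
    """A protein's identifier and amino-acid string (1-based positions)."""

    protein_id: str
    residues: str
    species: str = "homo_sapiens"

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValidationError(f"{self.protein_id}: empty sequence")
        bad = set(self.residues) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValidationError(
                f"{self.protein_id}: invalid residue code(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise ValidationError(
                f"{self.protein_id}: position {position} outside 1..{len(self.residues)}"
            )
        return self.residues[position - 1]


@dataclass(frozen=True)
class PtmSite:
    """One experimentally annotated modification at one residue."""

    protein_id: str
    position: int
    residue: str
    ptm_type: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"{self.protein_id}: site position {self.position} must be >= 1"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.protein_id, self.position, self.ptm_type)


@dataclass(frozen=True)
class Interval:
    """A 1-based inclusive span with a free-text label."""

    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValidationError(f"bad interval [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class HitRecord:
    """One similarity hit: query, subject, e-value, bitscore."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(
                f"{self.query_id}->{self.subject_id}: negative evalue"
            )


class CladeHierarchy:
    """A strictly nested series of taxonomic levels, innermost first.

    Every level's species set is a strict subset of the next, and the
    reference species belongs to every level.
    """

    def __init__(
        self,
        levels: list[tuple[str, frozenset[str]]],
        reference_species: str = "homo_sapiens",
    ) -> None:
        if not levels:
            raise ValidationError("hierarchy must have at least one level")
        self.reference_species = reference_species
        self.levels = [(name, frozenset(spp)) for name, spp in levels]
        for name, spp in self.levels:
            if reference_species not in spp:
                raise ValidationError(
                    f"level {name!r} does not contain reference species "
                    f"{reference_species!r}"
                )
        for (inner_name, inner), (outer_name, outer) in zip(
            self.levels, self.levels[1:]
        ):
            if not inner < outer:
                raise ValidationError(
                    f"level {inner_name!r} is not a strict subset of {outer_name!r}"
                )

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.levels]

    @property
    def outermost(self) -> frozenset[str]:
        return self.levels[-1][1]

    def __len__(self) -> int:
        return len(self.levels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CladeHierarchy):
            return NotImplemented
        return (
            self.levels == other.levels
            and self.reference_species == other.reference_species
        )

    def species_at(self, level: str) -> frozenset[str]:
        for name, spp in self.levels:
            if name == level:
                return spp
        raise KeyError(f"unknown level {level!r}")

    def level_index(self, level: str) -> int:
        try:
            return self.names.index(level)
        except ValueError:
            raise KeyError(f"unknown level {level!r}") from None

    def wider_level(self, level: str) -> str | None:
        """Name of the immediately wider (more ancient) level, or None."""
        i = self.level_index(level)
        return self.names[i + 1] if i + 1 < len(self.levels) else None


class FamilyAlignment:
    """An MSA of one reference protein plus at most one ortholog per species.

    The first row is the reference ("human") row; de-gapping it must
    reproduce the protein's sequence.  A position->column map is built on
    construction (both 1-based).
    """

    GAP = "-"

    def __init__(
        self,
        protein_id: str,
        human_row: str,
        ortholog_rows: dict[str, str],
    ) -> None:
        self.protein_id = protein_id
        self.human_row = human_row.upper()
        self.ortholog_rows = {sp: row.upper() for sp, row in ortholog_rows.items()}
        self.n_columns = len(self.human_row)
        for sp, row in self.ortholog_rows.items():
            if len(row) != self.n_columns:
                raise ValidationError(
                    f"{protein_id}: row for {sp!r} has length {len(row)}, "
                    f"expected {self.n_columns}"
                )
        # 1-based human position -> 1-based column
        self._pos_to_col = [
            c + 1 for c, ch in enumerate(self.human_row) if ch != self.GAP
        ]
        if not self._pos_to_col:
            raise ValidationError(f"{protein_id}: human row is all gaps")

    @property
    def human_sequence(self) -> str:
        return self.human_row.replace(self.GAP, "")

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.ortholog_rows)

    def position_to_column(self, position: int) -> int:
        """Alignment column (1-based) holding the given human position."""
        if not 1 <= position <= len(self._pos_to_col):
            raise ValidationError(
                f"{self.protein_id}: position {position} outside "
                f"1..{len(self._pos_to_col)}"
            )
        return self._pos_to_col[position - 1]

    def column(self, column: int, species: str | None = None) -> str:
        """Character in a 1-based column for the human row or one species."""
        row = self.human_row if species is None else self.ortholog_rows[species]
        return row[column - 1]


@dataclass(frozen=True)
class ColumnMask:
    """Per-column quality scores in [0, 10] plus a retained flag."""

    scores: tuple[float, ...]
    retained: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.retained):
            raise ValidationError("scores and retained differ in length")

    def is_retained(self, column: int) -> bool:
        """Retained status for a 1-based column."""
        return self.retained[column - 1]


@dataclass(frozen=True)
class ResidueClass:
    """A named set of interchangeable one-letter residue codes."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"residue class {self.name!r} is empty")

    def __contains__(self, residue: str) -> bool:
        return residue in self.members


#: Methylation can move between lysine and arginine.
METHYL_CLASS = ResidueClass("METHYL", frozenset("KR"))
#: Acetylation tolerates substitution of K by A, G, M, S or T.
ACETYL_CLASS = ResidueClass("ACETYL", frozenset("KAGMST"))


def singleton_class(residue: str) -> ResidueClass:
    """Strict-mode residue class: just the residue itself."""
    return ResidueClass(residue, frozenset(residue))


@dataclass(frozen=True)
class EnrichmentResult:
    """One hypergeometric test: counts, both tail P-values, and the call."""

    name: str
    k: int  # sample successes
    n: int  # sample size
    K: int  # population successes
    N: int  # population size
    p_enrich: float
    p_deplete: float
    alpha_corrected: float
    call: str  # enriched | depleted | not_significant
    warning: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K) and self.n <= self.N and self.K <= self.N):
            raise ValidationError(
                f"{self.name}: inconsistent counts k={self.k} n={self.n} "
                f"K={self.K} N={self.N}"
            )
        if self.call not in ("enriched", "depleted", "not_significant"):
            raise ValidationError(f"{self.name}: bad call {self.call!r}")
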