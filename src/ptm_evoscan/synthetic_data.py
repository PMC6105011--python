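"""Truth-labelled synthetic input bundles for end-to-end testing.

The generator emits every external format the pipeline consumes (FASTA,
site tables, BED intervals, disorder scores, hit tables, family alignments,
clade config) with controllable statistical structure: nested species
clades, per-level conservation probabilities for site vs background
columns, ortholog presence, gaps, and region composition.

Conservation is generated level-wise outward with "once broken, stays
broken", so the generated truth satisfies the same nesting invariant the
conservation caller must reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .datamodel_io import (
    AMINO_ACIDS,
    DEFAULT_LEVEL_NAMES,
    CladeHierarchy,
    FamilyAlignment,
    HitRecord,
    Interval,
    ProteinSequence,
    PtmSite,
    ValidationError,
    write_alignment,
    write_bed_intervals,
    write_clade_config,
    write_disorder_scores,
    write_fasta,
    write_hit_table,
    write_id_list,
    write_ptm_sites,
)

__all__ = [
    "GeneratorParams",
    "FamilyBundle",
    "generate_hierarchy",
    "generate_family",
    "generate_bundle",
    "simulate_null_counts",
]

_SITE_LETTERS = {
    "methylation": "KR",
    "acetylation": "K",
    "ubiquitination": "K",
}


def _broadcast(value, n_levels: int, name: str) -> tuple[float, ...]:
    if isinstance(value, (int, float)):
        values = (float(value),) * n_levels
    else:
        values = tuple(float(v) for v in value)
        if len(values) != n_levels:
            raise ValidationError(
                f"{name}: expected {n_levels} per-level values, got {len(values)}"
            )
    for v in values:
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name}: probability {v} outside [0, 1]")
    return values


@dataclass(frozen=True)
class GeneratorParams:
    """Full parameterization of one synthetic bundle; the seed fixes it all."""

    seed: int = 0
    n_species_per_level: tuple[int, ...] = (2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 22)
    n_proteins: int = 50
    length_range: tuple[int, int] = (200, 400)
    fraction_disordered: float = 0.4
    ptm_density: Mapping[str, float] = field(
        default_factory=lambda: {
            "methylation": 1.0,
            "acetylation": 2.0,
            "ubiquitination": 2.0,
        }
    )
    p_conserve_site: float | tuple[float, ...] = 0.9
    p_conserve_background: float | tuple[float, ...] = 0.6
    gap_rate: float = 0.02
    gap_avoid_fraction: float = 0.0
    protect_site_columns: bool = True
    ortholog_presence: float | tuple[float, ...] = 0.9
    fb_fraction: float = 0.3
    homopeptide_rate: float = 0.5
    prion_fraction: float = 0.1
    histone_fraction: float = 0.05
    reference_species: str = "homo_sapiens"

    @property
    def n_levels(self) -> int:
        return len(self.n_species_per_level)


@dataclass
class FamilyBundle:
    """Everything generated for one protein family, plus its truth labels."""

    sequence: ProteinSequence
    sites: list[PtmSite]
    ordered_intervals: list[Interval]
    fb_intervals: list[Interval]
    disorder_scores: np.ndarray
    alignment: FamilyAlignment
    present_species: frozenset[str]
    prion_like: bool
    histone: bool
    #: (position, level name) -> realized conservation bit, site positions only
    truth_conservation: dict[tuple[int, str], bool]
    #: region label per site position at generation time
    truth_regions: dict[int, str]


def generate_hierarchy(params: GeneratorParams) -> CladeHierarchy:
    """Nested species sets with synthetic ids, innermost level first."""
    counts = params.n_species_per_level
    if any(c < 2 for c in counts):
        raise ValidationError("each level needs >= 2 species (reference + 1)")
    if any(b <= a for a, b in zip(counts, counts[1:])):
        raise ValidationError(
            f"species counts must be strictly increasing, got {counts}"
        )
    if len(counts) == len(DEFAULT_LEVEL_NAMES):
        names = DEFAULT_LEVEL_NAMES
    else:
        names = tuple(f"level_{i:02d}" for i in range(len(counts)))
    all_species = [f"sp{i:04d}" for i in range(counts[-1] - 1)]
    levels = [
        (name, frozenset([params.reference_species] + all_species[: c - 1]))
        for name, c in zip(names, counts)
    ]
    return CladeHierarchy(levels, reference_species=params.reference_species)


def _species_depths(hierarchy: CladeHierarchy) -> dict[str, int]:
    """Index of the innermost level containing each non-reference species."""
    depths: dict[str, int] = {}
    for i, (_, spp) in enumerate(hierarchy.levels):
        for sp in spp:
            if sp != hierarchy.reference_species:
                depths.setdefault(sp, i)
    return depths


def _draw_sequence(rng: np.random.Generator, length: int, disordered_start: int) -> list[str]:
    aas = list(AMINO_ACIDS)
    seq = [aas[i] for i in rng.integers(0, 20, size=length)]
    # boost K/R in the disordered span so PTM-site letters are plentiful there
    for i in range(disordered_start - 1, length):
        if rng.random() < 0.3:
            seq[i] = "K" if rng.random() < 0.6 else "R"
    return seq


def generate_family(
    params: GeneratorParams,
    protein_index: int,
    hierarchy: CladeHierarchy | None = None,
) -> FamilyBundle:
    """Generate one protein family deterministically from (seed, index)."""
    if hierarchy is None:
        hierarchy = generate_hierarchy(params)
    n_levels = len(hierarchy)
    p_site = _broadcast(params.p_conserve_site, n_levels, "p_conserve_site")
    p_bg = _broadcast(params.p_conserve_background, n_levels, "p_conserve_background")
    presence = _broadcast(params.ortholog_presence, n_levels, "ortholog_presence")
    depths = _species_depths(hierarchy)

    rng = np.random.default_rng([params.seed, protein_index])
    protein_id = f"prot{protein_index:04d}"
    lo, hi = params.length_range
    length = int(rng.integers(lo, hi + 1))
    ordered_len = max(1, round(length * (1.0 - params.fraction_disordered)))
    ordered_len = min(ordered_len, length - 1) if params.fraction_disordered > 0 else length
    disordered_start = ordered_len + 1

    seq = _draw_sequence(rng, length, disordered_start)

    # homopeptide insertions (overwrite a short run with one residue)
    for _ in range(rng.poisson(params.homopeptide_rate)):
        run_len = int(rng.integers(3, 7))
        start = int(rng.integers(0, max(1, length - run_len)))
        seq[start : start + run_len] = [seq[start]] * run_len

    prion_like = bool(rng.random() < params.prion_fraction)
    if prion_like and length - disordered_start >= 30:
        start = disordered_start - 1
        for i in range(start, min(start + 30, length)):
            if rng.random() < 0.85:
                seq[i] = "Q"

    residues = "".join(seq)
    sequence = ProteinSequence(protein_id, residues, species=hierarchy.reference_species)

    ordered_intervals = [Interval(1, ordered_len, "ordered")] if ordered_len >= 1 else []
    disorder_scores = np.where(
        np.arange(1, length + 1) >= disordered_start, 0.95, 0.05
    ).astype(float)

    # PTM sites: each eligible residue drawn to hit the density target
    sites: list[PtmSite] = []
    site_positions: set[int] = set()
    for ptm_type in sorted(params.ptm_density):
        letters = _SITE_LETTERS.get(ptm_type, "K")
        eligible = [i + 1 for i, ch in enumerate(residues) if ch in letters]
        if not eligible:
            continue
        target = params.ptm_density[ptm_type] * length / 100.0
        p_hit = min(1.0, target / len(eligible))
        for pos in eligible:
            if rng.random() < p_hit:
                sites.append(PtmSite(protein_id, pos, residues[pos - 1], ptm_type))
                site_positions.add(pos)

    fb_intervals: list[Interval] = []
    if rng.random() < params.fb_fraction and length - disordered_start >= 12:
        fb_len = int(rng.integers(10, min(31, length - disordered_start + 1)))
        fb_start = int(rng.integers(disordered_start, length - fb_len + 2))
        fb_intervals.append(Interval(fb_start, fb_start + fb_len - 1, "fb"))

    # ortholog presence per species, by the probability at its depth
    present = sorted(
        sp for sp, d in depths.items() if rng.random() < presence[d]
    )

    # per-column conservation depth: first level at which the column breaks
    break_level = np.full(length, n_levels, dtype=int)
    for col in range(length):
        probs = p_site if (col + 1) in site_positions else p_bg
        for lvl in range(n_levels):
            if rng.random() >= probs[lvl]:
                break_level[col] = lvl
                break

    # realize ortholog rows: species at depth d matches human where d < break_level
    rows: dict[str, list[str]] = {}
    aas = list(AMINO_ACIDS)
    for sp in present:
        d = depths[sp]
        row = []
        for col in range(length):
            if d < break_level[col]:
                row.append(residues[col])
            else:
                choices = [a for a in aas if a != residues[col]]
                row.append(choices[int(rng.integers(0, len(choices)))])
        rows[sp] = row

    # gap placement, avoiding protected columns
    protected = np.zeros(length, dtype=bool)
    if params.protect_site_columns:
        for pos in site_positions:
            protected[pos - 1] = True
    if params.gap_avoid_fraction > 0:
        protected |= rng.random(length) < params.gap_avoid_fraction
    if params.gap_rate > 0:
        for sp in present:
            gap_here = rng.random(length) < params.gap_rate
            for col in np.nonzero(gap_here & ~protected)[0]:
                rows[sp][col] = FamilyAlignment.GAP

    alignment = FamilyAlignment(
        protein_id, residues, {sp: "".join(row) for sp, row in rows.items()}
    )

    # realized truth by direct brute-force scan of the generated rows;
    # levels with no ortholog present are omitted (protein not included)
    truth: dict[tuple[int, str], bool] = {}
    for pos in sorted(site_positions):
        col = pos - 1
        for lvl, (name, spp) in enumerate(hierarchy.levels):
            members = [sp for sp in present if depths[sp] <= lvl]
            if not members:
                continue
            truth[(pos, name)] = all(
                rows[sp][col] == residues[col] for sp in members
            )

    truth_regions = {
        pos: ("ordered" if pos <= ordered_len else "disordered")
        for pos in sorted(site_positions)
    }

    histone = protein_index < round(params.n_proteins * params.histone_fraction)

    return FamilyBundle(
        sequence=sequence,
        sites=sites,
        ordered_intervals=ordered_intervals,
        fb_intervals=fb_intervals,
        disorder_scores=disorder_scores,
        alignment=alignment,
        present_species=frozenset(present),
        prion_like=prion_like,
        histone=histone,
        truth_conservation=truth,
        truth_regions=truth_regions,
    )


def generate_bundle(params: GeneratorParams, out_dir: str | Path) -> Path:
    """Write a complete input bundle plus truth labels to a directory."""
    out = Path(out_dir)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    (out / "hits").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    hierarchy = generate_hierarchy(params)
    write_clade_config(out / "clades.yaml", hierarchy)

    families = [
        generate_family(params, i, hierarchy) for i in range(params.n_proteins)
    ]

    write_fasta(out / "proteins.fasta", [f.sequence for f in families])
    write_ptm_sites(out / "sites.tsv", [s for f in families for s in f.sites])
    write_bed_intervals(
        out / "ordered.bed",
        {f.sequence.protein_id: f.ordered_intervals for f in families},
    )
    write_bed_intervals(
        out / "fb.bed",
        {
            f.sequence.protein_id: f.fb_intervals
            for f in families
            if f.fb_intervals
        },
    )
    write_disorder_scores(
        out / "disorder.tsv",
        {f.sequence.protein_id: f.disorder_scores for f in families},
    )
    write_id_list(
        out / "histones.txt",
        [f.sequence.protein_id for f in families if f.histone],
    )

    for fam in families:
        write_alignment(
            out / "alignments" / f"{fam.sequence.protein_id}.afa",
            fam.alignment,
            reference_species=hierarchy.reference_species,
        )

    # hit tables as if post-BLAST: one forward/backward pair per species
    by_species_fwd: dict[str, list[HitRecord]] = {}
    by_species_bwd: dict[str, list[HitRecord]] = {}
    for fam in families:
        pid = fam.sequence.protein_id
        for sp in sorted(fam.present_species):
            subject = f"{pid}_{sp}"
            by_species_fwd.setdefault(sp, []).append(
                HitRecord(pid, subject, 1e-50, 200.0)
            )
            by_species_bwd.setdefault(sp, []).append(
                HitRecord(subject, pid, 1e-48, 198.0)
            )
    for sp in sorted(_species_depths(hierarchy)):
        write_hit_table(out / "hits" / f"{sp}.fwd.tsv", by_species_fwd.get(sp, []))
        write_hit_table(out / "hits" / f"{sp}.bwd.tsv", by_species_bwd.get(sp, []))

    with open(out / "truth" / "conservation.tsv", "w") as fh:
        fh.write("#protein_id\tposition\tlevel\tconserved\tregion\n")
        for fam in families:
            pid = fam.sequence.protein_id
            for (pos, level), bit in sorted(fam.truth_conservation.items()):
                fh.write(
                    f"{pid}\t{pos}\t{level}\t{int(bit)}\t{fam.truth_regions[pos]}\n"
                )
    with open(out / "truth" / "proteins.tsv", "w") as fh:
        fh.write("#protein_id\tprion_like\thistone\tn_species\n")
        for fam in families:
            fh.write(
                f"{fam.sequence.protein_id}\t{int(fam.prion_like)}\t"
                f"{int(fam.histone)}\t{len(fam.present_species)}\n"
            )

    manifest = {"seed": params.seed, "params": _params_dict(params)}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out


def _params_dict(params: GeneratorParams) -> dict:
    d = asdict(params)
    d["n_species_per_level"] = list(params.n_species_per_level)
    d["length_range"] = list(params.length_range)
    d["ptm_density"] = dict(params.ptm_density)
    for key in ("p_conserve_site", "p_conserve_background", "ortholog_presence"):
        if isinstance(d[key], tuple):
            d[key] = list(d[key])
    return d


def simulate_null_counts(
    rng: np.random.Generator,
    n_residues: int,
    site_fraction: float,
    p_conserve: float,
) -> tuple[int, int, int, int]:
    """Draw (k, n, K, N) under the exchangeable null.

    Every residue is a site with probability ``site_fraction`` and conserved
    with the same probability ``p_conserve`` regardless of site status, so
    conditional on n the success count k is exactly hypergeometric.
    """
    is_site = rng.random(n_residues) < site_fraction
    conserved = rng.random(n_residues) < p_conserve
    N = n_residues
    K = int(is_site.sum())
    n = int(conserved.sum())
    k = int((is_site & conserved).sum())
    return k, n, K, N
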