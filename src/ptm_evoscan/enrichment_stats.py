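"""Hypergeometric enrichment/depletion testing and summary tables.

Tail probabilities are computed by exact summation of log-space
hypergeometric terms, so magnitudes far below double underflow in the pmf
are still summed correctly.  Bonferroni families are configuration: one
family per background population, with alpha divided by the family size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datamodel_io import EnrichmentResult, PtmSite, ValidationError
from .region_annotation import ResidueAnnotation

__all__ = [
    "hypergeom_logpmf",
    "hypergeom_tail",
    "hypergeom_tail_log10",
    "bonferroni_threshold",
    "TestSpec",
    "ResidueUniverse",
    "run_test",
    "conserved_mau_enrichment",
    "VennCounts",
    "multi_mau",
    "format_percentage",
    "percentage_summary",
]

MAU = ("methylation", "acetylation", "ubiquitination")

ENRICH = "enrich"
DEPLETE = "deplete"

DEFAULT_ALPHA = 0.05

#: Letters whose residues form the population for each modification type.
PTM_LETTERS = {
    "methylation": ("K", "R"),
    "acetylation": ("K",),
    "ubiquitination": ("K",),
    "multi_mau": ("K", "R"),
}


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if not isinstance(v, (int, np.integer)):
            raise ValidationError(f"{name}={v!r} is not an integer")
    if not (0 <= k <= min(n, K) and n <= N and K <= N and N >= 0):
        raise ValidationError(
            f"inconsistent hypergeometric counts k={k} n={n} K={K} N={N}"
        )


def hypergeom_logpmf(i: int, n: int, K: int, N: int) -> float:
    """log P(X = i) for X ~ Hypergeometric(N, K, n)."""
    if i < max(0, n + K - N) or i > min(n, K):
        return -math.inf
    return (
        _log_comb(K, i)
        + _log_comb(N - K, n - i)
        - _log_comb(N, n)
    )


def _log_comb(a: int, b: int) -> float:
    return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)


def _logsumexp(values: list[float]) -> float:
    m = max(values)
    if m == -math.inf:
        return -math.inf
    return m + math.log(sum(math.exp(v - m) for v in values))


def _tail_log(k: int, n: int, K: int, N: int, direction: str) -> float:
    """Natural-log tail probability by exact summation in log space."""
    lo, hi = max(0, n + K - N), min(n, K)
    if direction == ENRICH:
        support = range(max(k, lo), hi + 1)
    elif direction == DEPLETE:
        support = range(lo, min(k, hi) + 1)
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    terms = [hypergeom_logpmf(i, n, K, N) for i in support]
    if not terms:
        return -math.inf
    return min(_logsumexp(terms), 0.0)


def hypergeom_tail(k: int, n: int, K: int, N: int, direction: str) -> float:
    """P(X >= k) (enrich) or P(X <= k) (deplete), X ~ Hypergeometric(N, K, n)."""
    _check_counts(k, n, K, N)
    return math.exp(_tail_log(k, n, K, N, direction))


def hypergeom_tail_log10(k: int, n: int, K: int, N: int, direction: str) -> float:
    """log10 of the tail probability (survives magnitudes like 1e-82)."""
    _check_counts(k, n, K, N)
    return _tail_log(k, n, K, N, direction) / math.log(10)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Corrected per-test threshold alpha / m for a family of m tests."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha {alpha} outside (0, 1)")
    if m < 1:
        raise ValidationError(f"family size {m} must be >= 1")
    return alpha / m


def _make_call(
    p_enrich: float, p_deplete: float, alpha_corrected: float, direction: str
) -> str:
    if direction in (ENRICH, "both") and p_enrich <= alpha_corrected:
        return "enriched"
    if direction in (DEPLETE, "both") and p_deplete <= alpha_corrected:
        return "depleted"
    return "not_significant"


@dataclass(frozen=True)
class TestSpec:
    """A declarative hypergeometric test over a residue universe.

    ``population``, ``sample`` and ``marker`` are selectors: mappings from
    universe column name to either a required value or a collection of
    allowed values.  The sample selector is applied within the population,
    so the sample is a subset of the population by construction; successes
    are the marker rows.
    """

    __test__ = False  # not a pytest class

    name: str
    population: Mapping[str, object]
    sample: Mapping[str, object]
    marker: Mapping[str, object]
    direction: str = "both"
    family: str = "default"


class ResidueUniverse:
    """One row per (protein, position) with flags used by test selectors.

    Columns: protein_id, position, residue, region, fb, homopeptide,
    prion_like, histone, plus one boolean per modification type seen.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        self.table = table

    @classmethod
    def build(
        cls,
        sequences: Mapping[str, object],
        annotations: Mapping[str, ResidueAnnotation],
        sites: Iterable[PtmSite],
    ) -> "ResidueUniverse":
        site_types: dict[tuple[str, int], set[str]] = {}
        for s in sites:
            site_types.setdefault((s.protein_id, s.position), set()).add(s.ptm_type)
        all_types = sorted({t for ts in site_types.values() for t in ts})
        rows = []
        for protein_id, seq in sequences.items():
            ann = annotations[protein_id]
            residues = getattr(seq, "residues", seq)
            for pos, residue in enumerate(residues, start=1):
                types = site_types.get((protein_id, pos), ())
                row = {
                    "protein_id": protein_id,
                    "position": pos,
                    "residue": residue,
                    "region": ann.label_at(pos),
                    "fb": bool(ann.fb[pos - 1]),
                    "homopeptide": bool(ann.homopeptide[pos - 1]),
                    "prion_like": ann.prion_like,
                    "histone": ann.histone,
                }
                for t in all_types:
                    row[t] = t in types
                row["any_mau"] = any(t in types for t in MAU)
                row["multi_mau"] = len(set(types) & set(MAU)) >= 2
                rows.append(row)
        return cls(pd.DataFrame(rows))

    def select(self, selector: Mapping[str, object]) -> pd.DataFrame:
        mask = pd.Series(True, index=self.table.index)
        for column, wanted in selector.items():
            if column not in self.table.columns:
                raise ValidationError(f"selector references unknown column {column!r}")
            if isinstance(wanted, (list, tuple, set, frozenset)):
                mask &= self.table[column].isin(list(wanted))
            else:
                mask &= self.table[column] == wanted
        return self.table[mask]


def run_test(
    spec: TestSpec,
    universe: ResidueUniverse,
    alpha_corrected: float = DEFAULT_ALPHA,
) -> EnrichmentResult:
    """Materialize counts from the selectors and run the hypergeometric test."""
    population = universe.select(spec.population)
    if population.empty:
        raise ValidationError(
            f"test {spec.name!r}: empty population for selector {dict(spec.population)!r}"
        )
    pop_universe = ResidueUniverse(population)
    sample = pop_universe.select(spec.sample)
    marked_pop = pop_universe.select(spec.marker)
    marked_sample = ResidueUniverse(sample).select(spec.marker)
    k, n = len(marked_sample), len(sample)
    K, N = len(marked_pop), len(population)
    p_enrich = hypergeom_tail(k, n, K, N, ENRICH)
    p_deplete = hypergeom_tail(k, n, K, N, DEPLETE)
    warning = "" if n else f"test {spec.name!r}: empty sample"
    return EnrichmentResult(
        spec.name, k, n, K, N, p_enrich, p_deplete, alpha_corrected,
        _make_call(p_enrich, p_deplete, alpha_corrected, spec.direction),
        warning=warning,
    )


def conserved_mau_enrichment(
    level: str,
    region_label: str,
    ptm_type: str,
    calls: pd.DataFrame,
    universe: ResidueUniverse,
    hierarchy_levels: Mapping[str, frozenset[str]] | None = None,
    included_proteins: frozenset[str] | None = None,
    conserved_map: Mapping[tuple[str, int], bool] | None = None,
    mode: str = "maintained",
    protein_subset: str = "all",
    protein_ages: Mapping[str, str] | None = None,
    alpha_corrected: float = DEFAULT_ALPHA,
) -> EnrichmentResult:
    """Enrichment of PTM sites among conserved residues at one level.

    Sample: conserved (or newly emerged) residues of the modification's
    letter(s) in the region among included proteins of the chosen subset;
    successes are those that are human PTM sites of the type.  Population:
    all residues of the letter(s) in the region among the same proteins;
    population successes are all such sites.

    ``conserved_map`` gives per-(protein, position) conservation of
    non-site residues at the level; site residues take their status from
    ``calls``.
    """
    letters = PTM_LETTERS.get(ptm_type, ("K",))
    status_col = "newly_emerged" if mode == "newly_emerged" else "conserved"

    at_level = calls[calls.level == level]
    if included_proteins is None:
        included_proteins = frozenset(at_level.protein_id.unique())

    table = universe.table
    pop_mask = (
        table.residue.isin(letters)
        & (table.region == region_label)
        & table.protein_id.isin(included_proteins)
    )
    if protein_subset in ("old", "new"):
        if protein_ages is None:
            raise ValidationError("protein_subset by age requires protein_ages")
        wanted = {p for p, a in protein_ages.items() if a == protein_subset}
        pop_mask &= table.protein_id.isin(wanted)
    elif protein_subset == "histone":
        pop_mask &= table.histone
    elif protein_subset == "non-histone":
        pop_mask &= ~table.histone
    elif protein_subset != "all":
        raise ValidationError(f"unknown protein subset {protein_subset!r}")
    population = table[pop_mask]

    marker_col = "any_mau" if ptm_type == "all_mau" else ptm_type
    if marker_col not in population.columns:
        population = population.assign(**{marker_col: False})
    N = len(population)
    K = int(population[marker_col].sum())

    site_status: dict[tuple[str, int], bool] = {}
    for r in at_level.itertuples():
        if not (r.ptm_type == ptm_type or (ptm_type == "all_mau" and r.ptm_type in MAU)):
            continue
        key = (r.protein_id, r.position)
        site_status[key] = site_status.get(key, False) or bool(getattr(r, status_col))

    def residue_in_sample(key: tuple[str, int]) -> bool:
        if key in site_status:
            return site_status[key]
        if conserved_map is not None:
            return bool(conserved_map.get(key, False))
        return False

    if N == 0:
        return EnrichmentResult(
            f"{ptm_type}@{level}/{region_label}", 0, 0, 0, 0, 1.0, 1.0,
            alpha_corrected, "not_significant",
            warning="empty population",
        )
    in_sample = np.fromiter(
        (
            residue_in_sample(key)
            for key in zip(population.protein_id, population.position)
        ),
        dtype=bool,
        count=N,
    )
    sample = population[in_sample]
    n = len(sample)
    k = int(sample[marker_col].sum())
    if n == 0:
        return EnrichmentResult(
            f"{ptm_type}@{level}/{region_label}", 0, 0, K, N, 1.0, 1.0,
            alpha_corrected, "not_significant",
            warning=f"no conserved residues at {level}/{region_label}",
        )
    p_enrich = hypergeom_tail(k, n, K, N, ENRICH)
    p_deplete = hypergeom_tail(k, n, K, N, DEPLETE)
    return EnrichmentResult(
        f"{ptm_type}@{level}/{region_label}", k, n, K, N, p_enrich, p_deplete,
        alpha_corrected, _make_call(p_enrich, p_deplete, alpha_corrected, ENRICH),
    )


@dataclass(frozen=True)
class VennCounts:
    """Disjoint counts of MAU type combinations at distinct residues."""

    region: str
    counts: Mapping[frozenset[str], int]

    def total(self) -> int:
        return sum(self.counts.values())


def multi_mau(
    sites: Iterable[PtmSite],
    annotations: Mapping[str, ResidueAnnotation],
) -> tuple[dict[str, VennCounts], list[tuple[str, int]]]:
    """Venn counts of MAU co-occurrence per region, plus the multi-MAU list.

    Each distinct MAU-modified residue is counted in exactly one cell: the
    full set of MAU types observed at it.  Residues with >= 2 distinct MAU
    types form the multi-MAU site list.
    """
    by_residue: dict[tuple[str, int], set[str]] = {}
    for s in sites:
        if s.ptm_type in MAU:
            by_residue.setdefault((s.protein_id, s.position), set()).add(s.ptm_type)

    cells = [
        frozenset(c)
        for r in (1, 2, 3)
        for c in combinations(MAU, r)
    ]
    per_region: dict[str, dict[frozenset[str], int]] = {}
    multi: list[tuple[str, int]] = []
    for (protein_id, position), types in sorted(by_residue.items()):
        region = annotations[protein_id].label_at(position)
        counts = per_region.setdefault(region, {c: 0 for c in cells})
        counts[frozenset(types)] += 1
        if len(types) >= 2:
            multi.append((protein_id, position))
    return (
        {region: VennCounts(region, counts) for region, counts in per_region.items()},
        multi,
    )


def format_percentage(numerator: int, denominator: int) -> str:
    """Two-decimal percentage string; 'NA' when the denominator is zero."""
    if denominator == 0:
        return "NA"
    return f"{100.0 * numerator / denominator:.2f}%"


def percentage_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Add formatted percentage columns to a Table-1-shaped counts frame.

    Expects columns conserved_residues, total_residues,
    proteins_with_conserved, total_proteins; raw counts are retained
    alongside the formatted cells.
    """
    out = table.copy()
    out["residues_pct"] = [
        format_percentage(c, t)
        for c, t in zip(out.conserved_residues, out.total_residues)
    ]
    out["proteins_pct"] = [
        format_percentage(c, t)
        for c, t in zip(out.proteins_with_conserved, out.total_proteins)
    ]
    return out
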