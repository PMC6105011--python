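"""Per-residue region classification and protein-level flags.

Every residue receives exactly one of the labels ordered / disordered /
unclassified.  Known-structure intervals take precedence over disorder
predictions; residues that are neither are left unclassified and excluded
from downstream analysis.  On top of the labels this module flags
homopeptide runs, folding-on-binding (FB) spans, compositionally biased
(prion-like) proteins and histones.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .datamodel_io import Interval, ProteinSequence, ValidationError
from .datamodel_io.types import AMINO_ACIDS

__all__ = [
    "ORDERED",
    "DISORDERED",
    "UNCLASSIFIED",
    "ResidueAnnotation",
    "BiasCall",
    "classify_residues",
    "find_homopeptides",
    "compositional_bias",
    "prion_like_call",
    "flag_proteins",
    "background_frequencies",
    "annotate_proteins",
]

ORDERED = "ordered"
DISORDERED = "disordered"
UNCLASSIFIED = "unclassified"

#: Residue sets scanned for prion-like compositional bias.
PRION_RESIDUE_SETS = (frozenset("N"), frozenset("Q"), frozenset("NQ"))

DEFAULT_DISORDER_THRESHOLD = 0.5
DEFAULT_BIAS_THRESHOLD = 1e-10
DEFAULT_MIN_WINDOW = 15
DEFAULT_MAX_WINDOW = 500
DEFAULT_HOMOPEPTIDE_MIN_LEN = 3


@dataclass
class ResidueAnnotation:
    """Per-residue labels and flags for one protein."""

    protein_id: str
    labels: np.ndarray  # str array over {ordered, disordered, unclassified}
    fb: np.ndarray = field(default=None)  # type: ignore[assignment]
    homopeptide: np.ndarray = field(default=None)  # type: ignore[assignment]
    prion_like: bool = False
    histone: bool = False

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.fb is None:
            self.fb = np.zeros(n, dtype=bool)
        if self.homopeptide is None:
            self.homopeptide = np.zeros(n, dtype=bool)
        if len(self.fb) != n or len(self.homopeptide) != n:
            raise ValidationError(f"{self.protein_id}: annotation vectors differ in length")

    def __len__(self) -> int:
        return len(self.labels)

    def label_at(self, position: int) -> str:
        """Region label at a 1-based position."""
        return str(self.labels[position - 1])

    def ordered_intervals(self) -> list[Interval]:
        """Maximal runs labelled ordered, as 1-based inclusive intervals."""
        out = []
        pos = 1
        for label, run in groupby(self.labels):
            length = len(list(run))
            if label == ORDERED:
                out.append(Interval(pos, pos + length - 1, ORDERED))
            pos += length
        return out


@dataclass(frozen=True)
class BiasCall:
    """Best compositionally biased window for one residue set."""

    residue_set: frozenset[str]
    best_window: Interval
    p_value: float

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValidationError(f"bias p_value {self.p_value} outside (0, 1]")


def classify_residues(
    seq: ProteinSequence,
    ordered_intervals: Sequence[Interval],
    disorder_scores: np.ndarray | None,
    disorder_threshold: float = DEFAULT_DISORDER_THRESHOLD,
) -> np.ndarray:
    """Label every residue ordered / disordered / unclassified.

    Ordered intervals (known structure) take precedence over disorder
    predictions; otherwise a residue is disordered iff its score reaches the
    threshold, and unclassified when neither applies.
    """
    n = len(seq)
    labels = np.full(n, UNCLASSIFIED, dtype=object)
    if disorder_scores is not None:
        if len(disorder_scores) != n:
            raise ValidationError(
                f"{seq.protein_id}: {len(disorder_scores)} scores for {n} residues"
            )
        labels[np.asarray(disorder_scores, dtype=float) >= disorder_threshold] = DISORDERED
    for iv in ordered_intervals:
        if iv.end > n:
            raise ValidationError(
                f"{seq.protein_id}: interval [{iv.start}, {iv.end}] exceeds length {n}"
            )
        labels[iv.start - 1 : iv.end] = ORDERED
    return labels


def find_homopeptides(
    seq: ProteinSequence | str, min_len: int = DEFAULT_HOMOPEPTIDE_MIN_LEN
) -> list[Interval]:
    """Maximal runs of one identical residue with length >= min_len."""
    if min_len < 2:
        raise ValidationError(f"min_len {min_len} must be >= 2")
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    out = []
    pos = 1
    for residue, run in groupby(residues):
        length = len(list(run))
        if length >= min_len:
            out.append(Interval(pos, pos + length - 1, residue))
        pos += length
    return out


def background_frequencies(
    sequences: Iterable[ProteinSequence],
) -> dict[str, float]:
    """Amino-acid composition of a protein set (X excluded), summing to 1."""
    counts: Counter[str] = Counter()
    for seq in sequences:
        counts.update(ch for ch in seq.residues if ch in AMINO_ACIDS)
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("no standard residues in input set")
    return {aa: counts.get(aa, 0) / total for aa in AMINO_ACIDS}


def compositional_bias(
    seq: ProteinSequence | str,
    residue_set: frozenset[str] | set[str],
    background_freqs: Mapping[str, float],
    min_window: int = DEFAULT_MIN_WINDOW,
    max_window: int = DEFAULT_MAX_WINDOW,
) -> BiasCall:
    """Find the window most biased toward ``residue_set``.

    Scans every contiguous window with length in [min_window, max_window]
    (clipped at the sequence length) and returns the window minimizing the
    binomial upper-tail probability of observing at least the window's count
    of target residues, with per-residue success probability equal to the
    summed background frequency of the set.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    if min_window < 1 or min_window > max_window:
        raise ValidationError(f"bad window bounds [{min_window}, {max_window}]")
    n = len(residues)
    lo = min(min_window, n)
    hi = min(max_window, n)
    p = sum(background_freqs.get(aa, 0.0) for aa in residue_set)
    if not 0 < p < 1:
        raise ValidationError(f"background probability {p} for {sorted(residue_set)}")

    is_target = np.fromiter((ch in residue_set for ch in residues), dtype=int, count=n)
    prefix = np.concatenate([[0], np.cumsum(is_target)])

    best_p = np.inf
    best_start = best_w = None
    for w in range(lo, hi + 1):
        counts = prefix[w:] - prefix[:-w]  # target count per window start
        # P(X >= c) for X ~ Binomial(w, p)
        tails = binom.sf(counts - 1, w, p)
        idx = int(np.argmin(tails))
        if tails[idx] < best_p:
            best_p = float(tails[idx])
            best_start, best_w = idx + 1, w
    assert best_start is not None and best_w is not None
    return BiasCall(
        frozenset(residue_set),
        Interval(best_start, best_start + best_w - 1, "".join(sorted(residue_set))),
        min(best_p, 1.0) if best_p > 0 else 5e-324,
    )


def prion_like_call(
    seq: ProteinSequence | str,
    background_freqs: Mapping[str, float],
    threshold: float = DEFAULT_BIAS_THRESHOLD,
    min_window: int = DEFAULT_MIN_WINDOW,
    max_window: int = DEFAULT_MAX_WINDOW,
) -> tuple[bool, BiasCall]:
    """Protein-level prion-like decision: minimum bias P over {N}, {Q}, {N,Q}."""
    best = min(
        (
            compositional_bias(seq, rs, background_freqs, min_window, max_window)
            for rs in PRION_RESIDUE_SETS
        ),
        key=lambda call: call.p_value,
    )
    return best.p_value <= threshold, best


def flag_proteins(
    annotations: Mapping[str, ResidueAnnotation],
    fb_intervals: Mapping[str, Sequence[Interval]],
    histone_ids: Iterable[str] = (),
) -> Mapping[str, ResidueAnnotation]:
    """Set FB residue flags and histone protein flags in place."""
    for protein_id, intervals in fb_intervals.items():
        if protein_id not in annotations:
            raise ValidationError(f"FB intervals reference unknown protein {protein_id!r}")
        ann = annotations[protein_id]
        for iv in intervals:
            if iv.end > len(ann):
                raise ValidationError(
                    f"{protein_id}: FB interval [{iv.start}, {iv.end}] exceeds length {len(ann)}"
                )
            ann.fb[iv.start - 1 : iv.end] = True
    for protein_id in histone_ids:
        if protein_id not in annotations:
            raise ValidationError(f"histone list references unknown protein {protein_id!r}")
        annotations[protein_id].histone = True
    return annotations


def annotate_proteins(
    sequences: Mapping[str, ProteinSequence],
    ordered_intervals: Mapping[str, Sequence[Interval]],
    disorder_scores: Mapping[str, np.ndarray],
    fb_intervals: Mapping[str, Sequence[Interval]] | None = None,
    histone_ids: Iterable[str] = (),
    disorder_threshold: float = DEFAULT_DISORDER_THRESHOLD,
    bias_threshold: float = DEFAULT_BIAS_THRESHOLD,
    homopeptide_min_len: int = DEFAULT_HOMOPEPTIDE_MIN_LEN,
    background_freqs: Mapping[str, float] | None = None,
    min_window: int = DEFAULT_MIN_WINDOW,
    max_window: int = DEFAULT_MAX_WINDOW,
) -> dict[str, ResidueAnnotation]:
    """Run the full annotation stage over a protein set."""
    if background_freqs is None:
        background_freqs = background_frequencies(sequences.values())
    annotations: dict[str, ResidueAnnotation] = {}
    for protein_id, seq in sequences.items():
        labels = classify_residues(
            seq,
            ordered_intervals.get(protein_id, ()),
            disorder_scores.get(protein_id),
            disorder_threshold,
        )
        ann = ResidueAnnotation(protein_id, labels)
        for iv in find_homopeptides(seq, homopeptide_min_len):
            ann.homopeptide[iv.start - 1 : iv.end] = True
        ann.prion_like, _ = prion_like_call(
            seq, background_freqs, bias_threshold, min_window, max_window
        )
        annotations[protein_id] = ann
    flag_proteins(annotations, fb_intervals or {}, histone_ids)
    return annotations
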