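"""Pipeline orchestration: run config, stage functions, and reporting.

Each stage reads its inputs, writes inspectable tab-separated artifacts
into the run directory, and logs counts at every filtering step.  Stages
are idempotent: identical config and inputs produce byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import conservation as cons
from . import enrichment_stats as stats
from . import orthology_clades as orth
from . import region_annotation as regions
from .datamodel_io import (
    ColumnMask,
    ValidationError,
    read_alignment,
    read_bed_intervals,
    read_clade_config,
    read_column_scores,
    read_disorder_scores,
    read_fasta,
    read_hit_table,
    read_id_list,
    read_ptm_sites,
)

__all__ = ["RunConfig", "load_config", "Pipeline"]

log = logging.getLogger("ptm_evoscan")


@dataclass
class RunConfig:
    """All paths, thresholds and mode flags for one pipeline run."""

    # inputs
    fasta: str = "proteins.fasta"
    sites: str = "sites.tsv"
    ordered_bed: str = "ordered.bed"
    fb_bed: str = "fb.bed"
    disorder_scores: str = "disorder.tsv"
    histones: str = "histones.txt"
    clades: str = "clades.yaml"
    alignments_dir: str = "alignments"
    hits_dir: str = "hits"
    column_scores_dir: str = ""  # optional, per-protein <id>.tsv mask scores
    out_dir: str = "run_out"
    # thresholds
    disorder_threshold: float = 0.5
    evalue_max: float = 1e-4
    bias_threshold: float = 1e-10
    mask_min: float = 5.0
    mask_max: float = 10.0
    homopeptide_min_len: int = 3
    alpha: float = 0.05
    # mode flags
    mode: str = "strict"  # strict | class
    use_mask: bool = False
    histone_handling: str = "include"  # include | exclude
    protein_subset: str = "all"  # all | old | new
    # Bonferroni families: name -> number of tests sharing one background
    bonferroni_families: dict = field(
        default_factory=lambda: {"per_level_series": 11}
    )

    def __post_init__(self) -> None:
        if not 0 <= self.disorder_threshold <= 1:
            raise ValidationError("disorder_threshold outside [0, 1]")
        if self.evalue_max <= 0:
            raise ValidationError("evalue_max must be positive")
        if not 0 < self.bias_threshold <= 1:
            raise ValidationError("bias_threshold outside (0, 1]")
        if not 0 <= self.mask_min <= self.mask_max <= 10:
            raise ValidationError("mask range must satisfy 0 <= min <= max <= 10")
        if self.homopeptide_min_len < 2:
            raise ValidationError("homopeptide_min_len must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha outside (0, 1)")
        if self.mode not in ("strict", "class"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.histone_handling not in ("include", "exclude"):
            raise ValidationError(f"unknown histone_handling {self.histone_handling!r}")
        if self.protein_subset not in ("all", "old", "new"):
            raise ValidationError(f"unknown protein_subset {self.protein_subset!r}")

    def resolve(self, base: str | Path) -> "RunConfig":
        """Return a copy with relative paths anchored at ``base``."""
        base = Path(base)
        updates = {}
        for name in (
            "fasta", "sites", "ordered_bed", "fb_bed", "disorder_scores",
            "histones", "clades", "alignments_dir", "hits_dir",
            "column_scores_dir", "out_dir",
        ):
            value = getattr(self, name)
            if value and not Path(value).is_absolute():
                updates[name] = str(base / value)
        cfg = RunConfig(**{**self.__dict__, **updates})
        return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config, rejecting unknown keys."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config key(s) {sorted(unknown)}")
    cfg = RunConfig(**data)
    return cfg.resolve(path.parent)


def _missing(path: Path, producer: str) -> ValidationError:
    return ValidationError(
        f"missing artifact {path}; run `ptm-evoscan {producer}` first"
    )


class Pipeline:
    """Stage runner bound to one RunConfig."""

    def __init__(self, config: RunConfig) -> None:
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._cache: dict[str, object] = {}

    # -- shared loading (cached per Pipeline instance) ---------------------

    def _load_inputs(self):
        if "inputs" in self._cache:
            return self._cache["inputs"]
        cfg = self.cfg
        sequences = {s.protein_id: s for s in read_fasta(cfg.fasta)}
        sites = read_ptm_sites(cfg.sites, sequences)
        log.info("loaded %d proteins, %d de-duplicated sites", len(sequences), len(sites))
        self._cache["inputs"] = (sequences, sites)
        return sequences, sites

    def _load_annotations(self, sequences):
        if "annotations" in self._cache:
            return self._cache["annotations"]
        cfg = self.cfg
        ordered = read_bed_intervals(cfg.ordered_bed) if Path(cfg.ordered_bed).exists() else {}
        fb = read_bed_intervals(cfg.fb_bed) if cfg.fb_bed and Path(cfg.fb_bed).exists() else {}
        scores = (
            read_disorder_scores(cfg.disorder_scores, sequences)
            if Path(cfg.disorder_scores).exists()
            else {}
        )
        histone_ids = (
            read_id_list(cfg.histones)
            if cfg.histones and Path(cfg.histones).exists()
            else set()
        )
        annotations = regions.annotate_proteins(
            sequences, ordered, scores, fb, histone_ids,
            disorder_threshold=cfg.disorder_threshold,
            bias_threshold=cfg.bias_threshold,
            homopeptide_min_len=cfg.homopeptide_min_len,
        )
        self._cache["annotations"] = annotations
        return annotations

    def _load_alignments(self):
        if "alignments" in self._cache:
            return self._cache["alignments"]
        aln_dir = Path(self.cfg.alignments_dir)
        if not aln_dir.is_dir():
            raise _missing(aln_dir, "simulate")
        alignments = {}
        for path in sorted(aln_dir.glob("*.afa")):
            aln = read_alignment(path)
            alignments[aln.protein_id] = aln
        log.info("loaded %d family alignments", len(alignments))
        self._cache["alignments"] = alignments
        return alignments

    def _load_masks(self, alignments) -> dict[str, ColumnMask] | None:
        cfg = self.cfg
        if not cfg.use_mask:
            return None
        if not cfg.column_scores_dir:
            raise ValidationError("use_mask set but column_scores_dir is empty")
        masks = {}
        for protein_id in alignments:
            path = Path(cfg.column_scores_dir) / f"{protein_id}.tsv"
            if path.exists():
                masks[protein_id] = cons.apply_column_mask(
                    read_column_scores(path), cfg.mask_min, cfg.mask_max
                )
        return masks

    # -- stages ------------------------------------------------------------

    def annotate(self) -> pd.DataFrame:
        sequences, _ = self._load_inputs()
        annotations = self._load_annotations(sequences)
        rows = []
        for pid in sorted(annotations):
            ann = annotations[pid]
            rows.append(
                {
                    "protein_id": pid,
                    "length": len(ann),
                    "n_ordered": int((ann.labels == regions.ORDERED).sum()),
                    "n_disordered": int((ann.labels == regions.DISORDERED).sum()),
                    "n_unclassified": int((ann.labels == regions.UNCLASSIFIED).sum()),
                    "n_fb": int(ann.fb.sum()),
                    "n_homopeptide": int(ann.homopeptide.sum()),
                    "prion_like": ann.prion_like,
                    "histone": ann.histone,
                }
            )
        table = pd.DataFrame(rows)
        table.to_csv(self.out / "annotations.tsv", sep="\t", index=False)
        log.info("annotate: %d proteins, %d prion-like, %d histones",
                 len(table), int(table.prion_like.sum()), int(table.histone.sum()))
        return table

    def orthologs(self) -> orth.OrthologMap:
        hits_dir = Path(self.cfg.hits_dir)
        if not hits_dir.is_dir():
            raise _missing(hits_dir, "simulate")
        ortholog_map = orth.OrthologMap()
        for fwd_path in sorted(hits_dir.glob("*.fwd.tsv")):
            species = fwd_path.name[: -len(".fwd.tsv")]
            bwd_path = hits_dir / f"{species}.bwd.tsv"
            if not bwd_path.exists():
                raise _missing(bwd_path, "simulate")
            pairs = orth.reciprocal_best_hits(
                read_hit_table(fwd_path),
                read_hit_table(bwd_path),
                self.cfg.evalue_max,
            )
            for protein_id, subject in pairs.items():
                ortholog_map.add(protein_id, species, subject)
        orth.write_ortholog_map(self.out / "orthologs.tsv", ortholog_map)
        log.info("orthologs: %d (protein, species) pairs", len(ortholog_map))
        return ortholog_map

    def conserve(self) -> pd.DataFrame:
        sequences, sites = self._load_inputs()
        annotations = self._load_annotations(sequences)
        hierarchy = read_clade_config(self.cfg.clades)
        alignments = self._load_alignments()
        masks = self._load_masks(alignments)
        calls = cons.build_call_table(
            sites, alignments, hierarchy, annotations,
            mode=self.cfg.mode, masks=masks,
        )
        suffix = "masked" if self.cfg.use_mask else "unmasked"
        calls_sorted = calls.sort_values(
            ["protein_id", "position", "ptm_type", "level"]
        ).reset_index(drop=True)
        cons.write_call_table(self.out / f"conservation_calls.{suffix}.tsv", calls_sorted)
        log.info(
            "conserve(%s, %s): %d calls, %d conserved, %d newly emerged",
            self.cfg.mode, suffix, len(calls_sorted),
            int(calls_sorted.conserved.sum()) if len(calls_sorted) else 0,
            int(calls_sorted.newly_emerged.sum()) if len(calls_sorted) else 0,
        )
        return calls_sorted

    def _calls_path(self) -> Path:
        suffix = "masked" if self.cfg.use_mask else "unmasked"
        return self.out / f"conservation_calls.{suffix}.tsv"

    def _load_calls(self) -> pd.DataFrame:
        path = self._calls_path()
        if not path.exists():
            raise _missing(path, "conserve")
        return pd.read_csv(path, sep="\t")

    def enrich(self) -> pd.DataFrame:
        cfg = self.cfg
        sequences, sites = self._load_inputs()
        annotations = self._load_annotations(sequences)
        hierarchy = read_clade_config(cfg.clades)
        alignments = self._load_alignments()
        masks = self._load_masks(alignments)
        calls = self._load_calls()

        if cfg.histone_handling == "exclude":
            keep = {p for p, a in annotations.items() if not a.histone}
            calls = calls[calls.protein_id.isin(keep)]
            sequences = {p: s for p, s in sequences.items() if p in keep}
            sites = [s for s in sites if s.protein_id in keep]
            log.info("enrich: histones excluded, %d proteins remain", len(sequences))

        universe = stats.ResidueUniverse.build(sequences, annotations, sites)

        # strict conservation of every K/R residue, per protein and level
        conserved_by_level: dict[str, dict[tuple[str, int], bool]] = {
            name: {} for name in hierarchy.names
        }
        protein_ages: dict[str, dict[str, str]] = {name: {} for name in hierarchy.names}
        for protein_id, alignment in alignments.items():
            if protein_id not in sequences:
                continue
            kr_positions = [
                i + 1
                for i, ch in enumerate(sequences[protein_id].residues)
                if ch in "KR"
            ]
            mask = masks.get(protein_id) if masks else None
            cmap = cons.residue_conservation_map(alignment, hierarchy, kr_positions, mask)
            for (pos, level), ok in cmap.items():
                conserved_by_level[level][(protein_id, pos)] = ok
            for level in hierarchy.names:
                outside = hierarchy.outermost - hierarchy.species_at(level)
                protein_ages[level][protein_id] = (
                    orth.OLD if alignment.species & outside else orth.NEW
                )

        m = cfg.bonferroni_families.get("per_level_series", len(hierarchy))
        alpha_corrected = stats.bonferroni_threshold(cfg.alpha, m)

        results = []
        ptm_types = ["methylation", "acetylation", "ubiquitination"]
        for level in hierarchy.names:
            included = frozenset(
                pid
                for pid, aln in alignments.items()
                if pid in sequences
                and aln.species & (hierarchy.species_at(level) - {hierarchy.reference_species})
            )
            for region in ("ordered", "disordered"):
                for ptm_type in ptm_types:
                    for mode in ("maintained", "newly_emerged"):
                        res = stats.conserved_mau_enrichment(
                            level, region, ptm_type, calls, universe,
                            included_proteins=included,
                            conserved_map=conserved_by_level[level],
                            mode=mode,
                            protein_subset=cfg.protein_subset,
                            protein_ages=protein_ages[level],
                            alpha_corrected=alpha_corrected,
                        )
                        results.append(
                            {
                                "level": level,
                                "region": region,
                                "ptm_type": ptm_type,
                                "conservation_mode": mode,
                                "k": res.k,
                                "n": res.n,
                                "K": res.K,
                                "N": res.N,
                                "log10_p_enrich": _log10(res.p_enrich),
                                "log10_p_deplete": _log10(res.p_deplete),
                                "alpha_corrected": alpha_corrected,
                                "call": res.call,
                                "warning": res.warning,
                            }
                        )
        table = pd.DataFrame(results)
        table.to_csv(
            self.out / "enrichment.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
        log.info("enrich: %d tests, %d enriched",
                 len(table), int((table.call == "enriched").sum()))
        return table

    def report(self) -> dict[str, pd.DataFrame]:
        cfg = self.cfg
        sequences, sites = self._load_inputs()
        annotations = self._load_annotations(sequences)
        hierarchy = read_clade_config(cfg.clades)
        calls = self._load_calls()
        if cfg.histone_handling == "exclude":
            keep = {p for p, a in annotations.items() if not a.histone}
            calls = calls[calls.protein_id.isin(keep)]
            sites = [s for s in sites if s.protein_id in keep]

        outermost = hierarchy.names[-1]
        table1 = stats.percentage_summary(cons.table1_summary(calls, outermost))
        table1.to_csv(self.out / "table1.tsv", sep="\t", index=False)

        venn, multi_list = stats.multi_mau(sites, annotations)
        venn_rows = []
        for region in sorted(venn):
            for cell, count in sorted(
                venn[region].counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            ):
                venn_rows.append(
                    {
                        "region": region,
                        "types": "+".join(sorted(cell)),
                        "count": count,
                    }
                )
        venn_table = pd.DataFrame(venn_rows)
        venn_table.to_csv(self.out / "venn.tsv", sep="\t", index=False)

        summary = cons.conserved_site_table(calls)
        summary.to_csv(self.out / "conserved_summary.tsv", sep="\t", index=False)
        log.info(
            "report: table1 at %s, %d multi-MAU residues", outermost, len(multi_list)
        )
        return {"table1": table1, "venn": venn_table, "summary": summary}


def _log10(p: float) -> float:
    return float(np.log10(p)) if p > 0 else float("-inf")
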