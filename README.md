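# ptm-evoscan

Conservation analysis of post-translational modification (PTM) sites in
ordered and disordered protein regions across a nested clade hierarchy.

The pipeline annotates each residue of a protein set as ordered,
disordered or unclassified (known-structure intervals take precedence over
disorder predictions), flags homopeptides, folding-on-binding (FB)
regions, compositionally biased (prion-like) proteins and histones, builds
reciprocal-best-hit ortholog maps from similarity hit tables, calls
completely conserved and newly emerged PTM-site residues per clade level
from family alignments (with optional column-quality masking and
residue-class substitution allowance), and tests enrichment/depletion of
PTM sites among conserved residues with exact hypergeometric tails and
Bonferroni correction. A deterministic synthetic-data generator emits
truth-labelled input bundles in every supported format, so the whole
pipeline is testable offline.

## Layout

- `ptm_evoscan.datamodel_io` — domain types and readers/writers (FASTA,
  aligned FASTA, tab-separated site tables, BLAST outfmt-6-style hit
  tables, BED intervals, per-residue/per-column score files, YAML clade
  config).
- `ptm_evoscan.region_annotation` — residue classification, homopeptide
  detection, binomial compositional-bias scoring, protein flags.
- `ptm_evoscan.orthology_clades` — reciprocal best hits, per-clade
  inclusion, old/new protein age classes.
- `ptm_evoscan.conservation` — per-level conservation and new-emergence
  calls, column masks, summary tables.
- `ptm_evoscan.enrichment_stats` — exact log-space hypergeometric tails,
  declarative test specs, conserved-site enrichment, MAU co-occurrence
  (Venn) counts, percentage summaries.
- `ptm_evoscan.synthetic_data` — seeded generator for complete input
  bundles with truth labels.
- `ptm_evoscan.pipeline` / `ptm_evoscan.cli` — run configuration and the
  `ptm-evoscan` command-line interface.

## CLI

Generate a synthetic bundle and run the full pipeline on it:

```sh
ptm-evoscan simulate --out demo --seed 1 --n-proteins 50
ptm-evoscan run --config demo/run.yaml
```

Individual stages (`annotate`, `orthologs`, `conserve`, `enrich`,
`report`) accept the same `--config` plus mode flags:

```sh
ptm-evoscan conserve --config demo/run.yaml --mode class     # K<->R etc.
ptm-evoscan enrich   --config demo/run.yaml --subset old
ptm-evoscan report   --config demo/run.yaml --histones exclude
```

Outputs land in the configured run directory as tab-separated tables
(`conservation_calls.*.tsv`, `enrichment.tsv`, `table1.tsv`, `venn.tsv`).
All thresholds (disorder cut-off 0.5, RBH e-value < 1e-4, bias P <= 1e-10,
column-score range 5–10, homopeptide length >= 3, alpha 0.05) live in the
YAML config and nowhere else.

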