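# ironsift

Longitudinal 16S OTU-table analysis of a low-iron (LI) dietary challenge in
mice, built as a tested, simulation-backed pipeline:

- **I/O & filtering** — mothur `.shared` / `.cons.taxonomy` / plain-TSV
  readers and writers; removal of organellar / non-bacterial /
  domain-unclassified OTUs; rare-OTU filtering (< 100 reads dataset-wide);
  rarefaction to a fixed depth (single hypergeometric draw, seeded).
- **Diversity** — inverse Simpson, richness, Bray-Curtis distance matrices.
- **Ordination & testing** — NMDS (nonmetric SMACOF, Kruskal stress-1,
  multi-start with a classical-scaling warm start) and one-factor PERMANOVA
  (pseudo-F, free label permutation with the add-one convention, plus an
  exact full-enumeration variant for small N).
- **Longitudinal statistics** — paired Wilcoxon signed-rank comparisons of
  consecutive time points with Benjamini-Hochberg (or Bonferroni)
  correction, and comparative-Ct (ΔΔCt) qPCR fold-change analysis.
- **OTU selection** — four techniques for finding the OTUs most affected by
  a treatment transition: random forest (null-calibrated permutation
  importance), indicator value (IndVal) with a permutation test,
  presence-absence prevalence rules, and per-OTU (paired) t-tests with
  multiplicity correction.
- **Selection benchmarking** — scores each technique by the reduction in
  PERMANOVA pseudo-F after removing its selected OTUs and by how few OTUs
  it selects, with paired t-tests between techniques across experimental
  groups and transitions.
- **Sensitivity classification** — labels OTUs as iron-sensitive
  (appreciable at baseline, undetectable in more than half of mice during
  the challenge) and recovered / not recovered under repletion.
- **Synthetic cohorts** — a Dirichlet-multinomial simulator of the cohort
  design (time points T0, B7, B14, LI7, LI14, R7, R14; cages of mice;
  mouse/cage random effects; a global diet-shift perturbation; planted
  sensitive and recovering OTUs) with machine-readable ground truth, plus
  generators for iron measurements and qPCR Ct records.

## CLI

The `ironsift` entry point exposes the pipeline stages as subcommands:

```bash
# simulate a cohort (YAML config with SimulationConfig fields)
ironsift simulate --config sim.yaml --seed 1 --out-dir out/

# stats on a distance matrix
ironsift permanova --distance dist.tsv --metadata meta.tsv \
    --factor timepoint --permutations 999 --seed 1
ironsift nmds --distance dist.tsv --k 2 --out coords.tsv

# alpha diversity + sequential paired Wilcoxon tests
ironsift stats --table otu_table.tsv --metadata meta.tsv --out alpha.tsv

# one selection technique at one transition
ironsift select --table otu_table.tsv --metadata meta.tsv \
    --method rf --from B14 --to LI7 --alpha 0.05 --seed 1 --out sel.json

# pseudo-F reduction achieved by a stored selection
ironsift evaluate --table otu_table.tsv --metadata meta.tsv --selection sel.json

# iron-sensitivity / recovery classification
ironsift classify --table otu_table.tsv --metadata meta.tsv \
    --baseline B7,B14 --li LI7,LI14 --repletion R7,R14 --out calls.tsv

# full pipeline from a YAML config (simulation- or file-backed)
ironsift run --config pipeline.yaml --out-dir results/
```

A pipeline config contains either a `simulation` block (one dict or a list
of per-group dicts) or an `inputs` block (`table`, `metadata`, optional
`taxonomy` paths), plus optional `filtering`, `rarefaction`, `transitions`,
`permanova`, `nmds`, `selection` and `classification` blocks; see
`tests/test_pipeline.py` for a complete example. All outputs (tables,
ordinations, selections, evaluation records, sensitivity calls and a
provenance `manifest.json`) are a pure function of config and seeds.

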