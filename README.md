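# crispramp

Leader-end CRISPR amplicon typing: from demultiplexed paired-end amplicon
reads (FASTQ) to CRISPR-genotype (CT) abundances, leader-end variant
classes and diversity statistics, with a synthetic-data generator that
plants a known genotype/variant structure so every stage is verifiable
end to end.

## What it does

1. **Read processing** (`crispramp.reads`) — sliding-window quality
   trimming (window 4, Q10 for R1 / Q20 for R2 by default), mate-specific
   length filters (200 / 70 nt), base-quality filter (≥ 80% of bases ≥ Q20),
   and overlap merging of pairs (60–301 nt overlap at ≥ 90% identity,
   higher-quality base wins disagreements).
2. **Clustering** (`crispramp.clustering`) — greedy longest-first
   clustering of merged amplicons at 95% identity with 90% coverage of both
   sequences; downstream stages work on representatives weighted by cluster
   size.
3. **Spacer extraction** (`crispramp.spacers`) — mismatch-tolerant
   direct-repeat detection (Hamming ≤ 5 by default, plus one terminal
   partial repeat) and extraction of the ordered leader-end spacers
   (position 1 = newest).
4. **Spacer dictionary** (`crispramp.dictionary`) — unification of spacer
   sequences into numbered identities allowing up to 6 substitutions
   (equal lengths only, abundance-first star topology); ids continue after
   the reference catalog so catalog numbering stays stable.
5. **CT typing** (`crispramp.ct_typing`) — assignment by shared leader-end
   spacer order against a catalog of disjoint repertoires; discard of 1–2
   novel-spacer arrays and of dataset-wide singletons; definition of new
   CTs from arrays with ≥ 3 novel spacers.
6. **Variant classes** (`crispramp.variants`) — per-CT split into
   `origin` / `new_plus` / `proto` / `others` and per-sample variant
   trajectories.
7. **Diversity** (`crispramp.diversity`) — Shannon (natural log),
   bias-corrected Chao1, analytic rarefaction curves.
8. **Protospacer search** (`crispramp.protospacer`) — exhaustive ungapped
   both-strand scan of spacers against user-supplied foreign-element FASTA,
   reported as matches/length.
9. **Simulator** (`crispramp.simulate`) — reference catalogs with
   well-separated disjoint spacers, seasonal per-sample compositions
   (Dirichlet or lognormal walk, optional bottleneck), and paired-end reads
   with substitution errors, decaying qualities (R2 worse than R1) and a
   full ground-truth table. Byte-identical output under a fixed seed.

All thresholds live on `PipelineConfig` (`crispramp.model`); nothing is
hard-coded. The default direct-repeat sequence is a stand-in derived from
the repeat-anchored reverse primer — override `repeat_sequence` for real
locus data.

## CLI

```bash
# generate a synthetic data set (catalog, FASTQ pairs, manifest, truth table)
crispramp simulate --seed 1 --outdir sim/
# run the pipeline on it (or on your own manifest/catalog)
crispramp run --manifest sim/manifest.tsv --catalog sim/catalog.yaml --outdir out/
# figure-ready tables; per-CT variant trajectory with --ct
crispramp report --rundir out/ --ct CT1
# diversity stats from any sample_id/ct/weight table
crispramp diversity --counts counts.tsv
crispramp validate-catalog --catalog sim/catalog.yaml
```

`run` writes, per sample, the attrition table, merged amplicons, clusters,
representatives and extracted spacers, and, pooled: the spacer dictionary,
updated catalog (new CTs included), assignments, variant calls, sample
profiles, diversity/rarefaction tables, and the figure tables (pooled CT
fractions with rare CTs binned at the 1% dominance threshold, dominant-CT
trajectories, per-CT variant fractions, variant trajectories). A run log
records every threshold used and every discard count. Reruns with the same
inputs and seed are byte-identical.

Simulation parameters can be overridden with `--sim-config` (YAML with
`SimulationConfig` field names, e.g. `n_read_pairs`, `error_rate_r1`,
`variant_fractions`).

## Layout

```
src/crispramp/
  model.py        configuration + Read/MergedAmplicon types
  reads.py        trimming, filtering, pair merging
  clustering.py   greedy clustering + pairwise identity
  spacers.py      repeat detection, spacer extraction
  dictionary.py   spacer identity unification, per-amplicon arrays
  ct_typing.py    catalog, CT assignment, singletons, new CTs
  variants.py     leader-end variant classes + trajectories
  diversity.py    Shannon, Chao1, rarefaction
  protospacer.py  spacer vs foreign-element search
  simulate.py     synthetic catalog/composition/read generator
  pipeline.py     orchestration, profiles, report tables
  cli.py          `crispramp` entry point
```
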