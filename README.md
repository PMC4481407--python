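# telofuse

Null models, Monte Carlo simulation and statistics for telomere-fusion
patterns in *Drosophila melanogaster* mitotic metaphases.

Telomere fusions (TFs) join chromosome ends into multicentric chains and
rings. Under a random-involvement null, each fused telomere is equally
likely to be any of the 16 termini of the diploid complement, so the
expected share of fused telomeres per scoring category is simply its member
count over 16 (males: A 50%, XL 6.25%, XR 6.25%, 4th 25%, Y 12.5%). This
package provides:

- **`telofuse.karyotype`** — the male/female telomere complements, per-arm
  subtelomeric chromatin classes (heterochromatin / TAS / fourth-type), the
  five scoring categories and their Eu = {A, XL} / Het = {XR, 4th, Y}
  grouping, plus a marked-Y variant whose YL terminus is euchromatic.
- **`telofuse.null_model`** — exact (rational-arithmetic) expected
  involvement frequencies, expected counts, and conditional Y-ring
  probabilities (1/15 given any Y fusion, 1/6 given a heterochromatic
  partner), each backed by an independent brute-force pair-space
  enumeration oracle.
- **`telofuse.fusion_simulator`** — a seeded generator of synthetic
  metaphases: fusion events drawn sequentially without replacement with
  pair probability ∝ product of telomere weights (heterochromatin-associated
  termini carry weight *w*; *w* = 1 recovers the null exactly), Poisson
  events per cell, STA/DTA labels, chain/ring structure derivation, and
  aggregation into per-category fused-telomere count tables.
- **`telofuse.fusion_stats`** — chi-square goodness of fit against the
  null, Eu/Het aggregation, exact binomial Y-ring excess testing, and
  maximum-likelihood estimation of *w* (depletion-corrected composite
  likelihood) with a seeded bootstrap confidence interval.
- **`telofuse.cli_io` / `telofuse.cli`** — TSV count-table I/O, a
  deterministic analysis report with Holm-adjusted p-values, provenance
  sidecars, programmatic fixtures, and the command-line interface.

## Command line

```sh
# exact null expectation table (per-category %, ring probabilities)
telofuse expectations --sex male

# simulate 10,000 cells with a 5x heterochromatin fusigenicity bias
telofuse simulate --sex male --het-weight 5 --mean-events 1 \
    --cells 10000 --seed 1 --out sim.tsv

# test count tables against the null and estimate the bias weight
telofuse analyze sim.tsv --sex male --seed 1 --out report.tsv
```

Every run with `--out` writes a `<out>.run.yaml` sidecar recording the
resolved configuration and seed; `simulate | analyze` pipelines with fixed
seeds are byte-identical across reruns.

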