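# caretaker

Quantitative toolkit around haploinsufficient-ribosomal-protein-gene (hRPG)
cell competition:

* **caretaker_mc** — Monte-Carlo model of random mutation accumulation in a
  diploid genome of G genes (2G alleles, H of them haploinsufficient), with
  an exact backward-recursion oracle for the *race* probability (does an
  hRPG become heterozygous before any other gene is mutated to
  homozygosity?) and exact/simulated distributions of the number of
  "disturbed" genes (both alleles hit) after M mutations.
* **genome_intervals** — 1-based inclusive (`arm:start..end`) coordinate
  arithmetic, `REF > ALT` sequence-change parsing, frameshift logic,
  gene-midpoint density in fixed-width bins (default 40 kbp) and
  intragenic-percentage computation; BED conversion at the I/O boundary.
* **competition_stats** — per-disc loser/winner twin-spot area ratios,
  genotype summaries (mean, SEM, n), D'Agostino–Pearson omnibus normality
  test, tie-corrected Kruskal-Wallis/Mann-Whitney rank tests, a paired
  ratio t-test on log ratios, and the two-criterion suppressor call
  (ratio increase **and** restored normality).
* **synthetic_data** — deterministic generators for genome annotations
  (non-overlapping genes, hRPG flags spread across arms) and clone-area
  datasets with a tunable elimination strength *e* (ratios near 0 when
  eliminated, near 1 when rescued), so the whole pipeline runs offline.
* **pipeline / cli** — a config-driven end-to-end run plus a verification
  table that recomputes published construct lengths (genomic rescues,
  deletion, mapped interval, 5 bp insertion) from their coordinate pairs.

## CLI

```sh
caretaker race --genes 14000 --hrpg 66 --reps 100000 --seed 1
caretaker race --genes 100 --hrpg 5 --budget 50 --reps 100000 --seed 1
caretaker disturbed --genes 2 --mutations 2          # exact enumeration
caretaker demo --out-dir out/ --seed 0               # full pipeline
caretaker density --bed out/genome.bed --bin-size 40000 --out density.csv
caretaker summarize --in out/clones.csv --out summary.csv
caretaker call --in out/clones.csv --candidate rescued_candidate \
               --control loser_control
caretaker verify-intervals                           # nonzero exit on mismatch
```

`caretaker demo` runs synthetic-data generation → gene density →
mutation-race Monte Carlo → clone statistics, writing CSV/JSON outputs and
a machine-readable `report.json`; outputs are byte-identical for a fixed
seed. A YAML config can override the built-in demo settings
(`--config cfg.yaml`; keys mirror the `RunConfig` dataclass).

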