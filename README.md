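# clonesim

Simulation and analysis of iterated growth-and-passage experiments on
barcoded tumor-cell populations: a population of ~10⁴ lentivirally barcoded
clones is repeatedly grown to a critical size and bottlenecked by passaging
a random aliquot, and the resulting clone-size dynamics (clone loss, Gini
coefficient, major clones) are compared across growth models.

The package provides:

* **`clonesim.tables` / `clonesim.metrics`** — clone-size tables with a fixed
  initial clone count (extinct clones retained as zeros) and the dominance
  statistics: Gini coefficient, clone loss, major-clone count, dominance
  curve.
* **`clonesim.growth`** — three clone-level growth engines: deterministic
  exponential growth, a tau-leaping stochastic birth process, and an
  age-structured cancer-stem-cell model (stem cells with symmetric /
  asymmetric / committed division, differentiated cells that divide at most
  `M` times and then die), plus the doubling-time calibration scan.
* **`clonesim.abm`** — an agent-based model of individually represented
  cells with heritable, mutating division rates, driven by a first-reaction
  event queue; replicates share a master population whose barcode→rate
  assignment is fixed by a dedicated seed.
* **`clonesim.protocol`** — the iterated growth-and-passage experiment:
  initialization from read counts, multivariate-hypergeometric passage
  sampling, per-passage metric collection over replicates, YAML-configured.
* **`clonesim.fitting`** — Gaussian log-likelihood of simulated metric
  trajectories against reference trajectories and the (σ0, σm) grid sweep
  with best-fit selection.
* **`clonesim.barcodes`** — FASTQ barcode counting (exact match, quality
  threshold), reference-library construction with frequency/replicate
  filters, and synthetic-data generators: initial clone-size distributions,
  FASTQ reads with per-base qualities and substitution errors, and a
  spurious-read contamination model confined to the reference library.

## CLI

```bash
# dominance metrics of a (barcode, count) TSV
clonesim metrics counts.tsv

# iterated growth & passage (model/config via YAML; --scale shrinks sizes)
clonesim simulate counts.tsv --config experiment.yaml --outdir out/

# stem-cell doubling-time calibration grid over (M, r_DC)
clonesim doubling-time-scan --m-values 8,10,12 --rdc-values 1.0,1.26,1.5

# likelihood grid sweep of the agent-based model
clonesim fit counts.tsv --reference ref.csv --metric gini --out grid.csv

# sequencing side: count barcodes, build the filtered reference library
clonesim count-barcodes reads.fastq --out counts.tsv
clonesim build-library rep1.tsv rep2.tsv rep3.tsv rep4.tsv --out library.tsv

# synthetic data
clonesim synth-fastq counts.tsv --error-rate 0.01 --out reads.fastq
clonesim contaminate counts.tsv --library library.tsv --rate 0.05 --out noisy.tsv
```

A YAML config mirrors the simulation parameter names, e.g.

```yaml
model: abm
n_pass: 300000
n_crit: 4000000
n_passages: 30
n_replicates: 10
seed: 1
abm:
  r0: 1.0
  sigma0: 0.036
  sigma_m: 0.0018
  n_master: 5000000
  n_init: 300000
  master_seed: 0
```

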