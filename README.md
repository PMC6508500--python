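# farmcpu

An efficient implementation of the FarmCPU method for genome-wide
association studies: an iterative loop that alternates a fast fixed-effect
single-marker scan with bin-based pseudo-QTN covariate selection optimized
by a restricted-likelihood (REML) criterion. The package also ships the
quantitative-trait simulation protocol used to validate it, a file-backed
marker store that is never copied in full, and deterministic parallel
scanning.

## What it does

1. **Scan** every marker with ordinary least squares. The model matrix is
   split into a constant part (intercept, covariates, pseudo-QTN columns)
   that is factorized once, and a per-marker variable part, so each marker
   costs two small projections. Samples with missing phenotypes are
   removed by an index mask — the genotype matrix is never subset or
   copied.
2. **Select** candidate pseudo-QTN sets: partition the genome into
   fixed-width physical bins, keep the best marker per bin, and form one
   candidate set per (bin size, set size) pair.
3. **Optimize**: score each candidate set by the REML log-likelihood of a
   random-effects model whose kinship is built from the pseudo-QTN
   genotypes alone (single 1-D spectral optimization per set), and keep
   the winner.
4. **Repeat** the scan with the winning set as covariates until the set
   stops changing (default cap: 20 iterations). Markers currently serving
   as covariates report their covariate-coefficient tests, so every marker
   has an effect, standard error, t-value and p-value in the output.

## CLI

Simulate a panel and trait (MAF uniform on [0.05, 0.5], adjacent-marker
D' control, geometric QTN effects, heritability-scaled Gaussian noise):

```bash
farmcpu simulate --n 1000 --m 10000 --h2 0.3 --n-qtn 3000 --dprime 0.75 \
    --seed 1 --out sim/
```

Run the association scan:

```bash
farmcpu run --genotypes sim/genotypes.tsv --map sim/map.tsv \
    --phenotype sim/phenotype.tsv --max-iter 20 \
    --workers-scan 4 --workers-reml 4 --out gwas/
```

This writes `results.tsv` (marker, chrom, pos, n_used, effect, se, t, p)
and `history.tsv` (one audit row per iteration). A YAML config file can
mirror any flag via `--config`; explicit flags win. Plot the results:

```bash
farmcpu plot --results gwas/results.tsv --type manhattan --out man.png
farmcpu plot --results gwas/results.tsv --type qq --out qq.png
```

## Python API

```python
from farmcpu import SimulationConfig, simulate_dataset, run_farmcpu, RunConfig

matrix, info, trait = simulate_dataset(SimulationConfig(n=500, m=1000, n_qtn=1, h2=0.9, seed=0))
result = run_farmcpu(matrix, info, trait.y, config=RunConfig())
table = result.to_frame()          # per-marker statistics
history = result.history_frame()   # per-iteration audit trail
```

Genotypes can also be loaded from delimited text
(`farmcpu.load_text_genotypes`), stored in a binary file-backed matrix,
and reattached later without re-parsing (`farmcpu.attach`). Only
double-precision backings are accepted; attaching anything else raises an
error.

## Determinism

Scans and REML model selection produce bitwise-identical results for any
worker count or chunk size: outputs are written into preallocated
per-chunk slots and every per-marker computation uses a fixed operation
order.

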