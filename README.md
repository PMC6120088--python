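# mirbench

Benchmarking quantification bias in small-RNA sequencing library
preparation, with a ground-truth bias simulator.

## The problem

Small-RNA sequencing counts reads to quantify miRNAs, but adapter
ligation captures different sequences with efficiencies spanning orders
of magnitude: some miRNAs end up underrepresented 10,000-fold, others
never appear at all.  The field's standard yardstick is an **equimolar
pool** of synthetic miRNAs — every member should receive an equal share
of reads, so for reference *i* with molar fraction *f<sub>i</sub>* in a
library of assigned depth *D*, the bias statistic is the fold-deviation

```
log2 FD_i = log2( O_i / E_i ),   E_i = D · f_i
```

with *O<sub>i</sub>* the observed count.  References within ±1 log2 unit
(±2-fold) are *accurately quantified*; the percent-unbiased is the
headline number for comparing preparation protocols.  On top of this,
`mirbench` implements cross-kit false-negative/false-positive
attribution (is a disagreement between two kits on a biological sample
explained by either kit's synthetic-pool bias?), detection-sensitivity
curves under equal-depth subsampling, dilution-series Pearson
concordance, and qPCR standard-curve quantification.

Because real benchmark sequencing runs are not reproducible at desk
scale, the package ships a **library-preparation simulator**: per-miRNA
ligation efficiencies with a tunable log2-normal spread, GC-dependent
PCR amplification weights, adapter-dimer contamination, and exact
ground-truth count records — so every pipeline stage is verifiable
against known truth.  It is aimed at method developers and analysts who
need a controlled testbed for small-RNA quantification pipelines.

## Worked example

```python
import mirbench as mb

pool = mb.build_equimolar_pool(n=963, seed=1)            # 963 refs, f_i = 1/963
profile = mb.sample_bias_profile(pool, sigma_log2=3.0, seed=2)
library = mb.simulate_library(pool, profile, depth=500_000, seed=3)

trimmed = mb.trim_adapter(library.reads, mb.DEFAULT_ADAPTER,
                          max_error_rate=0.1, min_length=15)
counts  = mb.count_reads(trimmed.kept, pool)
fdt     = mb.fold_deviation(counts, pool)                # tau = 1.0 (±2-fold)
print(f"under {fdt.percent_under:.1f}%  accurate {fdt.percent_accurate:.1f}%  "
      f"over {fdt.percent_over:.1f}%")
```

Output:

```
under 78.5%  accurate 13.8%  over 7.7%
```

A ligation-bias spread of 3 log2 units leaves only ~14% of the pool
within ±2-fold of its equimolar expectation — most references are
under-represented, a few dominate — which is the signature of a heavily
biased two-adapter protocol.  Rerunning with `sigma_log2=0.5` yields
~79% accurate.  The `examples/` directory has one short script per
capability (simulation, kit comparison with Welch's t-test, FN/FP
attribution, detection curves, dilution/qPCR concordance, and the full
pipeline).

The same stages are available from a shell:

```sh
mirbench simulate --n 963 --depth 500000 --sigma-log2 3 --seed 1 --outdir sim/
mirbench trim sim/library.fastq --out trimmed.fastq
mirbench count trimmed.fastq --pool sim/pool.fasta --out counts.tsv
mirbench bias counts.tsv --pool sim/pool.fasta --out fd.tsv
mirbench run-all --config config.yaml --outdir out/     # whole benchmark
```

`run-all` writes per-replicate count and fold-deviation TSVs, kit
comparison tables, a dilution-series correlation matrix and a JSON
summary, all stamped with the configuration hash; reruns are
byte-identical.

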