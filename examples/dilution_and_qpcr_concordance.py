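"""Concordance across input dilutions and against qPCR quantification.

Simulates a tenfold dilution series (same bias profile, depths scaled
100x/10x/1x), reports pairwise Pearson correlations of the count
vectors, then fits a qPCR standard curve on a synthetic dilution series
and compares sequencing and qPCR abundance ranking for four miRNAs.
"""

import math

import numpy as np

import mirbench as mb

pool = mb.build_equimolar_pool(200, seed=12)
profile = mb.sample_bias_profile(pool, sigma_log2=2.0, seed=13)

tables = []
for i, depth in enumerate((1_000_000, 100_000, 10_000)):
    lib = mb.simulate_library(pool, profile, depth=depth, seed=20 + i,
                              library_id=f"input_{100 // 10**i}ng")
    trimmed = mb.trim_adapter(lib.reads, mb.DEFAULT_ADAPTER, 0.1, 15)
    tables.append(mb.count_reads(trimmed.kept, pool, library_id=lib.library_id))

corr = mb.pairwise_pearson(tables, pool.ref_ids, normalize=True)
for i in range(3):
    for j in range(i + 1, 3):
        print(f"Pearson r {tables[i].library_id} vs {tables[j].library_id}: "
              f"{corr.matrix[i, j]:.3f}")

# qPCR standard curve: tenfold dilutions with perfect doubling per cycle
slope_true = -math.log2(10)
standards = tuple(
    (c, slope_true * math.log10(c) + 4.0) for c in (2e-10 / 10**i for i in range(8))
)
fit = mb.standard_curve_quantify(mb.QpcrPanel("miR-a", 40.0, standards))
print(f"standard curve: slope {fit.slope:.4f} cycles/log10, "
      f"efficiency {100 * fit.efficiency:.1f}%, "
      f"sample estimate {fit.concentration:.2e} M")

seq = {"miR-a": 5000.0, "miR-b": 900.0, "miR-c": 120.0, "miR-d": 15.0}
qpcr = {"miR-a": 2e-10, "miR-b": 5e-11, "miR-c": 8e-12, "miR-d": 9e-13}
match, r = mb.rank_concordance(seq, qpcr)
print(f"rank order sequencing vs qPCR identical: {match}; "
      f"Pearson r on log10 abundance: {r:.3f}")
print("High cross-dilution r shows quantification is robust to input")
print("amount; rank agreement ties sequencing abundance to qPCR.")
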