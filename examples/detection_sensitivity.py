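"""Detection sensitivity under equal-depth subsampling.

A strongly biased preparation pushes many references below the detection
threshold.  This example subsamples a biased and an unbiased simulated
library to the same depths and reports how many references reach at
least 5 reads, plus a small-RNA class composition.
"""

import mirbench as mb

pool = mb.build_equimolar_pool(300, seed=5)
ADAPTER = mb.DEFAULT_ADAPTER

for kit, sigma in [("unbiased", 0.0), ("biased", 3.0)]:
    profile = mb.sample_bias_profile(pool, sigma_log2=sigma, seed=6)
    lib = mb.simulate_library(pool, profile, depth=400_000, seed=7)
    trimmed = mb.trim_adapter(lib.reads, ADAPTER, 0.1, 15)
    curve = mb.detection_curve(
        trimmed.kept, pool, depths=[10_000, 50_000, 200_000],
        min_reads=5, n_draws=10, seed=8,
    )
    line = ", ".join(f"{s.depth//1000}k: {s.n_detected:.0f}" for s in curve)
    print(f"{kit:9s} references detected (>=5 reads) at depth {line}")

# class composition: label a third of the pool as piRNA
class_map = {r: ("piRNA" if i % 3 == 0 else "miRNA") for i, r in enumerate(pool.ref_ids)}
profile = mb.sample_bias_profile(pool, sigma_log2=1.0, seed=6)
lib = mb.simulate_library(pool, profile, depth=100_000, seed=9)
trimmed = mb.trim_adapter(lib.reads, ADAPTER, 0.1, 15)
comp = mb.class_composition(mb.count_reads(trimmed.kept, pool), class_map)
print("read-weighted class composition:",
      ", ".join(f"{k} {v:.1f}%" for k, v in comp.items()))
print("Detection saturates near the pool size for the unbiased kit but")
print("plateaus far lower when ligation bias suppresses many references.")
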