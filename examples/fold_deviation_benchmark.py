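"""Compare two virtual library-prep kits on the equimolar pool.

Simulates triplicate libraries for a low-bias kit (sigma = 0.5 log2
units) and a high-bias kit (sigma = 3), computes per-miRNA fold-deviation
from the equimolar expectation, classifies each reference as under-/
accurately/over-quantified at the conventional +/-2-fold window, and runs
a Welch t-test on the replicate percent-unbiased values.
"""

import mirbench as mb

pool = mb.build_equimolar_pool(963, seed=1)
ADAPTER = mb.DEFAULT_ADAPTER

percent_accurate = {}
for kit, sigma in [("low_bias", 0.5), ("high_bias", 3.0)]:
    profile = mb.sample_bias_profile(pool, sigma_log2=sigma, seed=10)
    percent_accurate[kit] = []
    for rep in range(3):
        lib = mb.simulate_library(pool, profile, depth=300_000, seed=100 + rep)
        trimmed = mb.trim_adapter(lib.reads, ADAPTER, 0.1, 15)
        fdt = mb.fold_deviation(mb.count_reads(trimmed.kept, pool), pool)
        percent_accurate[kit].append(fdt.percent_accurate)
    vals = ", ".join(f"{v:.1f}" for v in percent_accurate[kit])
    print(f"{kit:10s} percent accurately quantified per replicate: {vals}")

t, p = mb.compare_percent_unbiased(
    percent_accurate["low_bias"], percent_accurate["high_bias"]
)
print(f"Welch t = {t:.1f}, two-sided p = {p:.2e}")
print("A large positive t confirms the low-bias kit quantifies more of the")
print("pool within +/-2-fold of its true equimolar share.")
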