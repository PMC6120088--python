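# Methods

## The problem

Small-RNA sequencing quantifies miRNAs by counting reads, but
library-preparation chemistry — above all the ligation of adapters to the
RNA's ends — captures different sequences with wildly different
efficiency.  Individual miRNAs can be underrepresented by several orders
of magnitude relative to their true molar abundance, and protocols differ
enough that the same sample profiled with two kits can disagree more than
two biological conditions do.  The standard way to measure this bias is
an equimolar pool of synthetic miRNAs: every member should receive the
same share of reads, so any deviation is attributable to the
preparation.  `mirbench` implements that benchmark end to end and pairs
it with a bias simulator so every stage can be verified against known
ground truth without sequencing data.

## Simulation model

A library of depth `D` over a pool of `n` references with molar fractions
`f_i` is generated as follows.

**Ligation bias.**  Each reference gets a relative capture efficiency
`e_i = 2^{x_i} / max_j 2^{x_j}` with `x_i ~ Normal(0, sigma)`
independently.  `sigma` is in log2 units; `sigma = 3–4` reproduces the
multi-order-of-magnitude spreads reported for two-adapter ligation
protocols, `sigma = 0` is a bias-free preparation.  The log2-normal form
is a modeling choice: published benchmarks report the *span* of the bias
(up to 10^4-fold), not its distribution, and a multiplicative spread with
a single scale parameter is the simplest family matching that evidence.
The max-normalization makes efficiencies relative (the best-captured
sequence defines 1), which is the only observable quantity — equimolar
benchmarks cannot measure absolute capture rates.

**PCR bias.**  Each reference amplifies with per-cycle duplication
probability `q_i = clamp(q_base + s·(GC_i − 0.5), 0.05, 1)` (default
`q_base = 0.8`, slope `s = 0.3` per GC fraction), giving a deterministic
weight `w_i = (1 + q_i)^c` after `c` cycles (default 12, capped at 25 —
practical protocols stay under 20).  PCR is deterministic rather than a
branching process: amplification noise is small compared to ligation
bias, and deterministic weights keep the per-reference ground truth
(`e_i · w_i`) exact.

**Sequencing sampling.**  Final read counts are one multinomial draw of
`D − n_dimer` reads with probabilities proportional to `f_i · e_i · w_i`,
where `n_dimer = floor(dimer_rate · D)` reads are adapter-dimer
contaminants.  Folding capture and amplification into a single draw keeps
the per-reference sampling variance binomial, so a bias-free profile
produces counts statistically indistinguishable from a uniform
multinomial — the property the benchmark's null case rests on.  A
two-stage draw (molecules, then amplified reads) would double the
variance without changing any expectation; since PCR weights are
deterministic, the single draw is also the exact distribution of the
two-stage model conditional on its weights.

**Reads.**  Each read is the reference sequence (U→T) followed by the 3'
adapter (`TGGAATTCTCGGGTGCCAAGG`, the trimming target used throughout),
truncated to the machine read length (36 or 50 nt).  When insert plus
adapter is shorter than the read, the remainder is filled with a fixed
downstream-primer-context sequence, which is what a sequencer reads past
the adapter; adapter-dimer reads are the adapter followed by the same
filler.  Base qualities are a constant high-quality symbol and sequencing
errors are not modeled: no stage of this analysis consumes qualities, and
error modeling would only blur the ground-truth accounting the simulator
exists to provide.  Consequences for interpretation: passing tests show
the *analysis* is correct under ideal base calls; they do not exercise
mismatch-tolerant counting under real error profiles (the counter's
mismatch tolerance is tested with explicitly mutated reads instead).

All randomness in a simulation flows from a single seeded NumPy
generator; identical arguments give byte-identical FASTQ output.

## Read processing

**Trimming** reproduces 3'-adapter semantics with the parameters of the
conventional cutadapt invocation (`-a TGGAATTCTCGGGTGCCAAGG -m 15`,
error rate 0.1): the best occurrence of the adapter — the full adapter
anywhere, or an adapter prefix (≥ 3 nt) reaching the read's 3' end — is
found allowing substitutions and indels at ≤ `floor(0.1 · L)` errors for
an aligned adapter length `L`, preferring longer matches, then leftmost.
The match and everything 3' of it are removed; reads with no qualifying
occurrence are kept untrimmed (the quoted command has no
discard-untrimmed flag) and trimmed reads under 15 nt are discarded.
The implementation is a per-start dynamic program over the
(adapter × read-suffix) edit matrix with per-sequence memoization;
the test suite checks it read-for-read against an independent
brute-force enumerator of every occurrence position and length.

**Counting** assigns a trimmed read to a reference when the read equals
the reference over their common prefix with at most `max_mismatches`
substitutions (0 by default, ≤ 2 allowed) and a 3' length difference of
at most 2 nt, which tolerates templated 3' isomiR raggedness.  Mature
miRNA counting against a known pool needs no gapped genome alignment,
and the exact rule makes ground-truth oracles possible — equivalence
with any particular aligner's counts is deliberately not claimed.  Among
equally good matches (fewest mismatches, then smallest length
difference) a read is split `1/k` to each of `k` references: fractional
counting is deterministic and order-independent, so count tables may
hold rationals.

**Subsampling** is uniform without replacement, order-stable and
seed-deterministic; it operates on trimmed reads so that "equal depth"
means equal analyzable reads, and detection comparisons between
libraries are made at a common subsampled depth (200,000 by default).

## Bias statistics

For a library with assigned depth `D`, each reference's fold-deviation
is `log2(O_i / E_i)` with `E_i = D · f_i`.  Using assigned rather than
raw depth makes the statistic scale-free and confines it to pool
members.  Classes at threshold `tau` (default 1.0 log2 units, the
±2-fold convention; boundaries inclusive, so `log2_fd = ±tau` counts as
accurate): `under`, `accurate`, `over`, plus `undetected` for zero
counts.  Undetected references are floored at `log2(0.5 / E_i)` for
plotting only and count toward the under-represented percentage — an
unobserved pool member is maximally under-quantified, not missing data.
Percentages are over all pool members and sum to 100.

Replicates are summarized two ways: percent-unbiased is computed per
replicate (that is what the two-sample test needs), while a kit-level
fold-deviation table takes the per-reference mean of replicate `log2_fd`
values.  Whether pooling or averaging better matches any particular
published figure is unknowable from outside; the convention here is
stated, not claimed.

Kit comparison on percent-unbiased uses Welch's t-test (two-sided).  No
equal-variance assumption is defensible for three replicates of
different chemistries; at `n = 3` the difference from the pooled test is
negligible anyway.  Two constant, equal groups raise an error rather
than fabricate a p-value.

## Cross-kit FN/FP attribution

For a shared biological sample profiled by kit X and a reference kit,
abundances are normalized to reads per million assigned and compared as
`diff_log2 = log2((RPM_x + pc) / (RPM_ref + pc))`, with a pseudocount of
0.5 raw reads scaled into each library's RPM units — undetected miRNAs
stay finite and penalized.  The evaluation set is an explicit reference
list (in practice the pool-overlap subset of high-confidence miRNAs).

Attribution (threshold `tau_d = 1.0` on the difference, `tau_pool = 1.0`
on pool accuracy): differences within `tau_d` are concordant; a
reference kit X reports too low is a false negative of X if X
under-detects it in the synthetic pool, or a false positive of the
reference kit if that kit over-detects it; symmetrically for the other
direction.  When *both* kits qualify — one under-, the other over-biased
past `tau_pool` — the kit with the larger absolute pool bias is called,
preferring the FN interpretation on an exact tie.  This keeps the rule
exactly antisymmetric under swapping the kits, which a focal-kit-first
rule is not; the rule is this package's formalization and is recorded in
every output's metadata.

## Detection and concordance

Detection counts references at or above a read threshold (presets 5 and
10); detection-vs-depth curves average over `n_draws` (default 10)
independent subsamples per depth.  Class composition is read-weighted
over assigned reads with unlabeled references pooled as "other"; class
maps are user-supplied TSV.

Dilution-series concordance is the Pearson correlation of per-reference
count vectors between libraries (raw counts by convention; an RPM option
exists for unequal depths — the pipeline's dilution stage uses it since
its depths differ 100-fold by construction).  Zero-variance vectors are
flagged explicitly rather than yielding silent NaNs.

qPCR absolute quantification fits `Cq = slope · log10(conc) + intercept`
by least squares to a standard dilution series (≥ 3 points, strictly
decreasing concentrations; log10 because dilution series are tenfold),
inverts at the sample Cq, and reports efficiency `10^(−1/slope) − 1`;
a non-negative slope is an error.  Sequencing-vs-qPCR agreement is
reported both as exact rank-order agreement and as Pearson r on log10
abundances (published comparisons do not always state which scale was
used, so both are emitted).

## Pipeline

`run_benchmark` executes pool construction, per-kit replicate
simulation, trimming, counting, subsampling, fold-deviation, t-tests,
FN/FP attribution and the dilution series in dependency order.  The
configuration is a flat YAML schema (version 1, unknown keys rejected);
every artifact records the SHA-256 config hash, and a rerun with the
same configuration is byte-identical.  Per-stage seeds are derived by
hashing (base seed, stage, replicate) so stages are independent streams
and all below 2^31.

## Problem sizes and defaults

The package defaults mirror the benchmark's standard conditions: a
963-member equimolar pool of 19–24-nt sequences, triplicate libraries,
36-nt single-end reads, 200,000-read subsampling, detection at ≥ 5
reads, ±2-fold accuracy window, tenfold dilution steps.  The test suite
and the acceptance script exercise depths up to 2×10^6 reads per
library — deep enough that binomial noise at `E_i ≈ 2,000` cannot
produce 2-fold deviations, so accuracy percentages reflect bias, not
sampling — and smaller pools (50–300 members) where the contract under
test does not depend on pool size.

## Known limitations

- No sequencing-error or quality model; the counter's mismatch tolerance
  is exercised only by constructed tests.
- Ligation bias is sequence-independent in form (log2-normal per
  reference); real bias correlates with secondary structure and end
  chemistry, so the simulator reproduces the *magnitude* of bias, not
  its sequence determinants.
- PCR stochasticity (jackpotting) is not modeled; at < 20 cycles and
  ≥ 10^5 input molecules this is a second-order effect.
- The FN/FP decision rule is one defensible formalization; published
  figures built on unpublished rules cannot be reproduced exactly.
- Real-data artifacts (PhiX spike-ins, UMIs, isomiR taxonomy beyond 3'
  length tolerance) are out of scope.
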