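import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mirbench import (
    DEFAULT_ADAPTER,
    ReadSet,
    ReferencePool,
    count_reads,
    sample_bias_profile,
    simulate_library,
    subsample_reads,
    trim_adapter,
)
from mirbench.errors import InsufficientDepthError, InvalidArgumentError
from oracles import brute_force_trim

ADAPTER = DEFAULT_ADAPTER


def _reads(seqs):
    return ReadSet.from_records(
        (f"r{i}", s, "I" * len(s)) for i, s in enumerate(seqs)
    )


def _random_read_with_adapter(rng, read_len=36):
    """A read with a planted adapter occurrence (full, partial-3',
    errored, or absent)."""
    bases = "ACGT"
    kind = rng.integers(4)
    insert_len = int(rng.integers(5, 30))
    insert = "".join(bases[i] for i in rng.integers(4, size=insert_len))
    if kind == 0:  # full adapter
        read = insert + ADAPTER
    elif kind == 1:  # partial adapter at 3' end
        read = insert + ADAPTER[: int(rng.integers(3, len(ADAPTER)))]
    elif kind == 2:  # full adapter with up to 2 errors
        ad = list(ADAPTER)
        for _ in range(int(rng.integers(1, 3))):
            pos = int(rng.integers(len(ad)))
            ad[pos] = bases[int(rng.integers(4))]
        read = insert + "".join(ad)
    else:  # no adapter
        read = "".join(bases[i] for i in rng.integers(4, size=read_len))
    read = (read + "".join(bases[i] for i in rng.integers(4, size=read_len)))[:read_len]
    return read


class TestTrimAdapter:
    def test_exact_adapter_occurrence_trimmed(self):
        insert = "ACGTACGTACGTACGTACGTAC"  # 22 nt
        read = (insert + ADAPTER)[:36]
        result = trim_adapter(_reads([read]), ADAPTER, 0.1, 15)
        assert result.kept.sequences == [insert]
        assert result.n_trimmed == 1

    def test_short_insert_discarded_at_min_length(self):
        read = ("ACGTACGTACGT" + ADAPTER + "AACTCCAGTCAC")[:36]  # 12 nt insert
        result = trim_adapter(_reads([read]), ADAPTER, 0.1, 15)
        assert len(result.kept) == 0
        assert result.n_discarded_short == 1
        assert result.n_trimmed == 1

    def test_adapter_free_read_kept_untrimmed(self):
        read = "ACCTTACCAGTCATTACGATCAGTTACCAGTCATTA"
        result = trim_adapter(_reads([read]), ADAPTER, 0.1, 15)
        assert result.kept.sequences == [read]
        assert result.n_untrimmed == 1

    def test_quality_trimmed_with_sequence(self):
        insert = "ACGTACGTACGTACGTACGTAC"
        read = (insert + ADAPTER)[:36]
        rs = ReadSet.from_records([("r0", read, "".join(chr(33 + i % 40) for i in range(36)))])
        result = trim_adapter(rs, ADAPTER, 0.1, 15)
        assert len(result.kept.qualities[0]) == len(insert)

    def test_empty_adapter_rejected(self):
        with pytest.raises(InvalidArgumentError):
            trim_adapter(_reads(["ACGT" * 9]), "", 0.1, 15)

    def test_bookkeeping_invariant(self):
        rng = np.random.default_rng(17)
        reads = _reads([_random_read_with_adapter(rng) for _ in range(300)])
        result = trim_adapter(reads, ADAPTER, 0.1, 15)
        assert result.n_input == len(result.kept) + result.n_discarded_short
        assert result.n_trimmed + result.n_untrimmed == result.n_input

    def test_matches_brute_force_oracle_on_planted_reads(self):
        """Seeded reads with planted full/partial/errored/absent adapters
        trim identically to an exhaustive enumeration of occurrence
        positions and lengths."""
        rng = np.random.default_rng(23)
        seqs = [_random_read_with_adapter(rng) for _ in range(300)]
        result = trim_adapter(_reads(seqs), ADAPTER, 0.1, min_length=1)
        expected = [brute_force_trim(s, ADAPTER, 0.1) for s in seqs]
        got = dict(zip(result.kept.ids, result.kept.sequences))
        full = [got.get(f"r{i}", "") for i in range(len(seqs))]
        # min_length=1 keeps everything except empty inserts; rebuild those
        expected = [e if len(e) >= 1 else "" for e in expected]
        assert full == expected

    def test_trimming_is_idempotent_on_adapter_free_inserts(self):
        rng = np.random.default_rng(29)
        seqs = [_random_read_with_adapter(rng) for _ in range(200)]
        once = trim_adapter(_reads(seqs), ADAPTER, 0.1, 15)
        twice = trim_adapter(once.kept, ADAPTER, 0.1, 15)
        # reads whose trimmed insert still matches the adapter by chance are
        # legitimately re-trimmed; exclude them via the oracle
        stable = [
            i
            for i, s in enumerate(once.kept.sequences)
            if brute_force_trim(s, ADAPTER, 0.1) == s
        ]
        assert [twice.kept.sequences[twice.kept.ids.index(once.kept.ids[i])]
                for i in stable if once.kept.ids[i] in twice.kept.ids] == [
            once.kept.sequences[i] for i in stable
        ]


class TestCountReads:
    def test_exact_match_counted(self, small_pool):
        seq = small_pool.entries[0].dna
        table = count_reads(_reads([seq]), small_pool, max_mismatches=0)
        assert table.get(small_pool.entries[0].ref_id) == 1
        assert table.unassigned == 0

    def test_hamming_one_unassigned_at_zero_mismatches(self, small_pool):
        seq = list(small_pool.entries[0].dna)
        seq[0] = "A" if seq[0] != "A" else "C"
        table = count_reads(_reads(["".join(seq)]), small_pool, max_mismatches=0)
        assert table.depth == 0
        assert table.unassigned == 1

    def test_hamming_one_assigned_with_tolerance(self, small_pool):
        seq = list(small_pool.entries[0].dna)
        seq[0] = "A" if seq[0] != "A" else "C"
        table = count_reads(_reads(["".join(seq)]), small_pool, max_mismatches=1)
        assert table.get(small_pool.entries[0].ref_id) == 1

    def test_three_prime_length_tolerance(self, small_pool):
        entry = small_pool.entries[0]
        table = count_reads(_reads([entry.dna[:-2]]), small_pool, max_mismatches=0)
        assert table.get(entry.ref_id) == 1

    def test_fractional_multimapping(self):
        pool = ReferencePool.from_sequences(
            ["ACGTACGTACGTACGTACGTA", "ACGTACGTACGTACGTACGTAGG"], ids=["a", "b"]
        )
        # read is 1 nt longer than 'a' and 1 nt shorter than 'b': equal best
        table = count_reads(_reads(["ACGTACGTACGTACGTACGTAG"]), pool, max_mismatches=0)
        assert table.get("a") == pytest.approx(0.5)
        assert table.get("b") == pytest.approx(0.5)

    def test_totals_invariant(self, small_pool, biased_library):
        trimmed = trim_adapter(biased_library.reads, ADAPTER, 0.1, 15)
        table = count_reads(trimmed.kept, small_pool)
        assert table.depth + table.unassigned == pytest.approx(len(trimmed.kept))

    def test_empty_read_set_yields_zero_table(self, small_pool):
        table = count_reads(ReadSet(), small_pool)
        assert table.depth == 0
        assert table.unassigned == 0

    def test_error_free_simulated_reads_match_truth(self, small_pool, biased_library):
        """Simulator truth is recovered exactly after trim + count."""
        trimmed = trim_adapter(biased_library.reads, ADAPTER, 0.1, 15)
        table = count_reads(trimmed.kept, small_pool)
        for ref_id, truth in biased_library.true_counts.items():
            assert table.get(ref_id) == pytest.approx(truth)

    def test_tsv_roundtrip(self, small_pool, unbiased_library, tmp_path):
        trimmed = trim_adapter(unbiased_library.reads, ADAPTER, 0.1, 15)
        table = count_reads(trimmed.kept, small_pool, library_id="lib1")
        table.to_tsv(tmp_path / "c.tsv")
        from mirbench import CountTable

        back = CountTable.from_tsv(tmp_path / "c.tsv")
        assert back.library_id == "lib1"
        assert back.counts == table.counts
        assert back.unassigned == table.unassigned


class TestSubsampleReads:
    def test_full_depth_is_identity(self, unbiased_library):
        sub = subsample_reads(unbiased_library.reads, len(unbiased_library.reads), seed=1)
        assert sub.sequences == unbiased_library.reads.sequences

    def test_exact_target_size(self, unbiased_library):
        sub = subsample_reads(unbiased_library.reads, 20_000, seed=1)
        assert len(sub) == 20_000

    def test_order_stable(self, unbiased_library):
        sub = subsample_reads(unbiased_library.reads, 1000, seed=3)
        positions = [int(i.split(":")[1]) for i in sub.ids]
        assert positions == sorted(positions)

    def test_deterministic_per_seed(self, unbiased_library):
        a = subsample_reads(unbiased_library.reads, 5000, seed=4)
        b = subsample_reads(unbiased_library.reads, 5000, seed=4)
        c = subsample_reads(unbiased_library.reads, 5000, seed=5)
        assert a.ids == b.ids
        assert a.ids != c.ids

    def test_overdraw_raises_naming_both_numbers(self):
        rs = _reads(["ACGT" * 9] * 10)
        with pytest.raises(InsufficientDepthError, match="20.*10|10.*20"):
            subsample_reads(rs, 20)

    def test_sampled_share_matches_hypergeometric(self):
        """A reference holding 30% of reads keeps, on average over seeds,
        a 30% share after 10x subsampling (3 SE tolerance)."""
        n, k = 5000, 1500
        seqs = ["A" * 20] * k + ["C" * 20] * (n - k)
        rs = _reads(seqs)
        target = 500
        shares = []
        for seed in range(60):
            sub = subsample_reads(rs, target, seed=seed)
            shares.append(sum(1 for s in sub.sequences if s[0] == "A") / target)
        p = k / n
        # variance of the hypergeometric share of one draw, then the SE of
        # the mean across seeds
        var_share = p * (1 - p) * (n - target) / (n - 1) / target
        se = math.sqrt(var_share / len(shares))
        assert abs(np.mean(shares) - p) <= 3 * se

    def test_nested_subsampling_is_uniform(self):
        """Subsampling to D1 then D2 matches direct subsampling to D2 in
        the marked-read share (distributional check)."""
        n, k = 4000, 1200
        seqs = ["A" * 20] * k + ["C" * 20] * (n - k)
        rs = _reads(seqs)
        d1, d2 = 2000, 400
        nested, direct = [], []
        for seed in range(40):
            s1 = subsample_reads(rs, d1, seed=seed)
            s2 = subsample_reads(s1, d2, seed=seed + 1000)
            nested.append(sum(1 for s in s2.sequences if s[0] == "A") / d2)
            sd = subsample_reads(rs, d2, seed=seed + 2000)
            direct.append(sum(1 for s in sd.sequences if s[0] == "A") / d2)
        p = k / n
        var_share = p * (1 - p) * (n - d2) / (n - 1) / d2
        se = math.sqrt(var_share / 40)
        assert abs(np.mean(nested) - p) <= 3 * se
        assert abs(np.mean(nested) - np.mean(direct)) <= 4 * se
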