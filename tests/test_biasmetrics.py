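import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mirbench import (
    CountTable,
    ReferencePool,
    build_equimolar_pool,
    classify_bias,
    compare_percent_unbiased,
    fold_deviation,
    mean_fold_deviation,
)
from mirbench.biasmetrics import FoldDeviationTable
from mirbench.errors import (
    DegenerateVarianceError,
    EmptyLibraryError,
    InvalidArgumentError,
)
from oracles import tally_bias_classes, welch_t


def _table(counts: dict, library_id="lib"):
    return CountTable(library_id=library_id, counts=dict(counts))


@pytest.fixture(scope="module")
def pool10():
    return build_equimolar_pool(10, seed=3)


class TestFoldDeviation:
    def test_perfectly_uniform_counts_give_zero_fd(self, pool10):
        table = _table({r: 100 for r in pool10.ref_ids})
        fdt = fold_deviation(table, pool10)
        assert np.allclose(fdt.data["log2_fd"], 0.0)
        assert fdt.percent_accurate == 100.0

    def test_quarter_of_expected_is_minus_two(self):
        pool = build_equimolar_pool(963, seed=1)
        counts = {r: 1000 for r in pool.ref_ids}
        low = pool.ref_ids[0]
        counts[low] = 250
        counts[pool.ref_ids[1]] = 1750  # keep depth at 963,000
        fdt = fold_deviation(_table(counts), pool)
        assert fdt.log2_fd(low) == pytest.approx(-2.0)
        row = fdt.data[fdt.data["ref_id"] == low]
        assert row["bias_class"].iloc[0] == "under"
        assert row["expected"].iloc[0] == pytest.approx(1000.0)

    def test_scale_invariance(self, pool10):
        rng = np.random.default_rng(5)
        counts = {r: int(c) for r, c in zip(pool10.ref_ids, rng.integers(10, 1000, 10))}
        fd1 = fold_deviation(_table(counts), pool10).data["log2_fd"]
        fd2 = fold_deviation(
            _table({r: 7 * c for r, c in counts.items()}), pool10
        ).data["log2_fd"]
        np.testing.assert_allclose(fd1, fd2)

    def test_monotone_in_own_count(self, pool10):
        base = {r: 100 for r in pool10.ref_ids}
        target = pool10.ref_ids[0]
        fds = []
        for c in (50, 100, 200, 400):
            counts = dict(base)
            counts[target] = c
            fds.append(fold_deviation(_table(counts), pool10).log2_fd(target))
        assert fds == sorted(fds)

    def test_zero_count_is_undetected_and_floored(self, pool10):
        counts = {r: 100 for r in pool10.ref_ids}
        counts[pool10.ref_ids[0]] = 0
        fdt = fold_deviation(_table(counts), pool10)
        row = fdt.data.iloc[0]
        assert row["bias_class"] == "undetected"
        assert row["log2_fd"] == pytest.approx(math.log2(0.5 / row["expected"]))
        # undetected members count toward percent_under, not percent_accurate
        assert fdt.percent_under == pytest.approx(10.0)
        assert fdt.percent_accurate == pytest.approx(90.0)

    def test_empty_library_rejected(self, pool10):
        with pytest.raises(EmptyLibraryError):
            fold_deviation(_table({r: 0 for r in pool10.ref_ids}), pool10)

    def test_percentages_sum_to_100(self, pool10):
        rng = np.random.default_rng(8)
        counts = {r: int(c) for r, c in zip(pool10.ref_ids, rng.integers(0, 500, 10))}
        fdt = fold_deviation(_table(counts), pool10)
        total = fdt.percent_under + fdt.percent_accurate + fdt.percent_over
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_expected_counts_sum_to_depth(self, pool10):
        rng = np.random.default_rng(9)
        counts = {r: int(c) for r, c in zip(pool10.ref_ids, rng.integers(1, 500, 10))}
        fdt = fold_deviation(_table(counts), pool10)
        assert fdt.data["expected"].sum() == pytest.approx(sum(counts.values()))


class TestClassifyBias:
    def test_three_band_classification(self, pool10):
        fdt = _fdt_from_fds([-3, 0, 2] + [0] * 7, pool10)
        out = classify_bias(fdt, tau=1.0)
        classes = list(out.data["bias_class"][:3])
        assert classes == ["under", "accurate", "over"]
        assert out.percent_accurate == pytest.approx(100 * 8 / 10)

    def test_boundary_is_inclusive(self, pool10):
        fdt = _fdt_from_fds([-1.0, 1.0] + [0] * 8, pool10)
        out = classify_bias(fdt, tau=1.0)
        assert set(out.data["bias_class"][:2]) == {"accurate"}

    def test_nonpositive_tau_rejected(self, pool10):
        fdt = _fdt_from_fds([0] * 10, pool10)
        with pytest.raises(InvalidArgumentError):
            classify_bias(fdt, tau=0.0)

    def test_percentages_match_brute_force_tally(self):
        pool = build_equimolar_pool(963, seed=2)
        rng = np.random.default_rng(12)
        counts = {r: int(c) for r, c in zip(pool.ref_ids, rng.integers(0, 4000, 963))}
        fdt = fold_deviation(_table(counts), pool)
        for tau in (0.5, 1.0, 2.0):
            out = classify_bias(fdt, tau)
            detected = fdt.data["observed"].to_numpy() > 0
            expected = tally_bias_classes(
                fdt.data["log2_fd"].to_numpy(), detected, tau
            )
            assert out.percent_under == pytest.approx(expected["under"])
            assert out.percent_accurate == pytest.approx(expected["accurate"])
            assert out.percent_over == pytest.approx(expected["over"])

    @given(st.lists(st.floats(-8, 8), min_size=5, max_size=60), st.floats(0.2, 3))
    def test_percentages_always_sum_to_100(self, fds, tau):
        pool = build_equimolar_pool(len(fds), seed=1)
        out = classify_bias(_fdt_from_fds(fds, pool), tau)
        assert out.percent_under + out.percent_accurate + out.percent_over == pytest.approx(
            100.0
        )


def _fdt_from_fds(fds, pool):
    data = pd.DataFrame(
        {
            "ref_id": pool.ref_ids,
            "observed": [100.0] * len(fds),
            "expected": [100.0] * len(fds),
            "log2_fd": fds,
            "bias_class": ["accurate"] * len(fds),
        }
    )
    return classify_bias(FoldDeviationTable("t", data, tau=1.0), 1.0)


class TestMeanFoldDeviation:
    def test_mean_of_replicates(self, pool10):
        t1 = _fdt_from_fds([1.0] * 10, pool10)
        t2 = _fdt_from_fds([3.0] * 10, pool10)
        merged = mean_fold_deviation([t1, t2])
        assert np.allclose(merged.data["log2_fd"], 2.0)
        assert set(merged.data["bias_class"]) == {"over"}


class TestComparePercentUnbiased:
    def test_matches_hand_coded_welch(self):
        a, b = [70.0, 72.0, 74.0], [30.0, 32.0, 34.0]
        t, p = compare_percent_unbiased(a, b)
        t_ref, p_ref = welch_t(a, b)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_antisymmetry(self):
        a, b = [70.0, 75.0, 71.0], [40.0, 42.0, 39.0]
        t1, p1 = compare_percent_unbiased(a, b)
        t2, p2 = compare_percent_unbiased(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_identical_groups_give_t0_p1(self):
        a = [50.0, 55.0, 60.0]
        t, p = compare_percent_unbiased(a, list(a))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_equal_constants_raise(self):
        with pytest.raises(DegenerateVarianceError):
            compare_percent_unbiased([50.0, 50.0], [50.0, 50.0])

    def test_single_replicate_rejected(self):
        with pytest.raises(InvalidArgumentError):
            compare_percent_unbiased([50.0], [40.0, 41.0])

    @given(
        st.lists(st.floats(0, 100), min_size=3, max_size=6),
        st.lists(st.floats(0, 100), min_size=3, max_size=6),
    )
    def test_welch_agrees_with_formula_on_random_groups(self, a, b):
        if np.std(a) == 0 and np.std(b) == 0:
            return
        t, p = compare_percent_unbiased(a, b)
        if math.isinf(t):
            return
        t_ref, p_ref = welch_t(a, b)
        assert t == pytest.approx(t_ref, abs=1e-8)
        assert p == pytest.approx(p_ref, abs=1e-8)
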