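"""Quantification-bias metrics for equimolar-pool libraries.

The central statistic is the per-reference fold-deviation from expectation:

    log2_fd_i = log2(O_i / E_i),   E_i = depth * f_i

where ``O_i`` is the observed count, ``depth`` the total assigned count of
the library and ``f_i`` the reference's expected molar fraction (``1/n``
for an equimolar pool).  References are classified against a symmetric
threshold ``tau`` (default 1 log2 unit, i.e. the conventional +/-2-fold
window):

* ``accurate``   if  -tau <= log2_fd <= tau  (boundaries inclusive)
* ``under``      if  log2_fd < -tau
* ``over``       if  log2_fd >  tau
* ``undetected`` if  O_i = 0; counted as under-represented in the summary
  percentages (an undetected pool member is maximally under-represented),
  with log2_fd floored at log2(0.5 / E_i) for plotting only.

The percent of accurately quantified references ("percent unbiased") is
the headline number for comparing library-preparation protocols;
replicate-level percentages from two protocols are compared with a Welch
two-sample t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateVarianceError,
    EmptyLibraryError,
    InvalidArgumentError,
)
from .pool import ReferencePool
from .readproc import CountTable

DEFAULT_TAU = 1.0

CLASS_UNDER = "under"
CLASS_ACCURATE = "accurate"
CLASS_OVER = "over"
CLASS_UNDETECTED = "undetected"


@dataclass
class FoldDeviationTable:
    """Per-reference fold-deviations plus class-composition percentages.

    ``data`` columns: ref_id, observed, expected, log2_fd, bias_class.
    ``log2_fd`` for undetected references is the plotting floor, not a
    measurement.  Percentages are over all pool members; undetected
    members count toward ``percent_under``.
    """

    library_id: str
    data: pd.DataFrame
    tau: float = DEFAULT_TAU

    @property
    def percent_under(self) -> float:
        n = len(self.data)
        mask = self.data["bias_class"].isin([CLASS_UNDER, CLASS_UNDETECTED])
        return 100.0 * mask.sum() / n

    @property
    def percent_accurate(self) -> float:
        n = len(self.data)
        return 100.0 * (self.data["bias_class"] == CLASS_ACCURATE).sum() / n

    @property
    def percent_over(self) -> float:
        n = len(self.data)
        return 100.0 * (self.data["bias_class"] == CLASS_OVER).sum() / n

    def log2_fd(self, ref_id: str) -> float:
        row = self.data.loc[self.data["ref_id"] == ref_id]
        if row.empty:
            raise KeyError(ref_id)
        return float(row["log2_fd"].iloc[0])

    def fd_map(self) -> dict[str, float]:
        return dict(zip(self.data["ref_id"], self.data["log2_fd"]))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "library_id": self.library_id,
                    "percent_under": self.percent_under,
                    "percent_accurate": self.percent_accurate,
                    "percent_over": self.percent_over,
                    "depth": float(self.data["observed"].sum()),
                    "tau": self.tau,
                }
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "library_id", self.library_id)
        out.to_csv(path, sep="\t", index=False)


def fold_deviation(
    counts: CountTable,
    pool: ReferencePool,
    zero_policy: str = "undetected",
    tau: float = DEFAULT_TAU,
) -> FoldDeviationTable:
    """Compute per-reference log2(observed/expected) against pool fractions.

    ``depth`` is the table's total assigned count, so expected counts sum
    to depth and the statistic is invariant to overall library size.

    ``zero_policy``:
      * ``"undetected"`` (default): zero-count references get class
        ``undetected`` and a plotting floor of ``log2(0.5 / E_i)``.
      * ``"floor"``: zero counts are replaced by 0.5 reads and classified
        like any other value.
    """
    if zero_policy not in ("undetected", "floor"):
        raise InvalidArgumentError(f"unknown zero_policy {zero_policy!r}")
    # pool members absent from the table's universe count as zeros
    depth = counts.depth
    if depth <= 0:
        raise EmptyLibraryError(
            f"library {counts.library_id!r} has zero assigned reads"
        )
    observed = np.array([counts.get(r) for r in pool.ref_ids], dtype=float)
    expected = depth * pool.fractions
    with np.errstate(divide="ignore"):
        if zero_policy == "floor":
            log2_fd = np.log2(np.maximum(observed, 0.5) / expected)
        else:
            log2_fd = np.where(
                observed > 0,
                np.log2(np.maximum(observed, 1e-300) / expected),
                np.log2(0.5 / expected),
            )
    data = pd.DataFrame(
        {
            "ref_id": pool.ref_ids,
            "observed": observed,
            "expected": expected,
            "log2_fd": log2_fd,
            "bias_class": _classify(observed, log2_fd, tau, zero_policy),
        }
    )
    return FoldDeviationTable(library_id=counts.library_id, data=data, tau=tau)


def _classify(
    observed: np.ndarray, log2_fd: np.ndarray, tau: float, zero_policy: str
) -> list[str]:
    if tau <= 0:
        raise InvalidArgumentError(f"tau must be > 0, got {tau}")
    out = []
    for o, fd in zip(observed, log2_fd):
        if o == 0 and zero_policy == "undetected":
            out.append(CLASS_UNDETECTED)
        elif fd < -tau:
            out.append(CLASS_UNDER)
        elif fd > tau:
            out.append(CLASS_OVER)
        else:
            out.append(CLASS_ACCURATE)
    return out


def classify_bias(fdt: FoldDeviationTable, tau: float) -> FoldDeviationTable:
    """Reclassify an existing table at a new threshold ``tau`` (inclusive
    boundaries); percentages are recomputed over all pool members."""
    if tau <= 0:
        raise InvalidArgumentError(f"tau must be > 0, got {tau}")
    data = fdt.data.copy()
    # preserve undetected flags; reclassify everything else at the new tau
    log2_fd = data["log2_fd"].to_numpy()
    undetected = data["bias_class"] == CLASS_UNDETECTED
    classes = np.where(
        log2_fd < -tau, CLASS_UNDER, np.where(log2_fd > tau, CLASS_OVER, CLASS_ACCURATE)
    )
    classes = np.where(undetected, CLASS_UNDETECTED, classes)
    data["bias_class"] = classes
    return FoldDeviationTable(library_id=fdt.library_id, data=data, tau=tau)


def mean_fold_deviation(tables: Sequence[FoldDeviationTable], tau: float | None = None) -> FoldDeviationTable:
    """Protocol-level table: per-reference mean of per-replicate log2_fd.

    A reference undetected in every replicate stays undetected; otherwise
    the mean is over all replicates' (possibly floored) log2_fd values.
    Observed/expected columns are averaged for reference.
    """
    if not tables:
        raise InvalidArgumentError("need at least one replicate table")
    tau = tables[0].tau if tau is None else tau
    ref_ids = list(tables[0].data["ref_id"])
    fd = np.mean([t.data["log2_fd"].to_numpy() for t in tables], axis=0)
    obs = np.mean([t.data["observed"].to_numpy() for t in tables], axis=0)
    exp = np.mean([t.data["expected"].to_numpy() for t in tables], axis=0)
    all_undet = np.all(
        [t.data["bias_class"].to_numpy() == CLASS_UNDETECTED for t in tables], axis=0
    )
    classes = np.where(
        fd < -tau, CLASS_UNDER, np.where(fd > tau, CLASS_OVER, CLASS_ACCURATE)
    )
    classes = np.where(all_undet, CLASS_UNDETECTED, classes)
    data = pd.DataFrame(
        {
            "ref_id": ref_ids,
            "observed": obs,
            "expected": exp,
            "log2_fd": fd,
            "bias_class": classes,
        }
    )
    lib_id = "+".join(t.library_id for t in tables)
    return FoldDeviationTable(library_id=lib_id, data=data, tau=tau)


def compare_percent_unbiased(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Welch two-sample t-test on replicate percent-unbiased values.

    Returns ``(t, p)`` with a two-sided p-value.  Raises
    :class:`DegenerateVarianceError` when both groups are constant and
    equal, where no p-value is defined.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidArgumentError("each group needs at least 2 replicates")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            raise DegenerateVarianceError(
                "both groups are constant and equal; the t statistic is undefined"
            )
        # constant but different: infinite separation
        return (math.inf if a.mean() > b.mean() else -math.inf, 0.0)
    with warnings.catch_warnings():
        # near-identical replicate percentages are an expected regime for
        # low-bias preparations; scipy warns about precision loss there
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
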