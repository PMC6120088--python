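"""Cross-protocol differential quantification and FN/FP attribution.

When the same biological sample is profiled with two library-preparation
protocols, per-miRNA abundances can differ by orders of magnitude.  If
each protocol has also been characterized on an equimolar synthetic pool,
discordance on the biological sample can be attributed to preparation
bias: a miRNA that protocol X reports much lower than the reference
protocol, *and* that X under-detects in the synthetic pool, is a false
negative of X; one that X reports much higher and over-detects in the
pool is a false positive of X.

Attribution rule (this package's formalization; emitted in output
metadata): with ``d = diff_log2`` (protocol X minus reference, RPM
normalized) and pool fold-deviations ``b_x``, ``b_ref``:

* ``|d| <= tau_d``                      -> concordant
* ``d < -tau_d`` and ``b_x  < -tau_pool`` -> FN_x
* ``d < -tau_d`` and ``b_ref >  tau_pool`` -> FP_ref
* ``d >  tau_d`` and ``b_x  >  tau_pool`` -> FP_x
* ``d >  tau_d`` and ``b_ref < -tau_pool`` -> FN_ref
* otherwise                              -> unattributed

The direction of biological-sample discordance must agree with the
direction of the called protocol's synthetic-pool bias.  When both
protocols qualify (one under-, the other over-biased beyond
``tau_pool``), the attribution goes to the protocol with the larger
absolute pool bias, preferring the under-detection (FN) call on an
exact tie — this keeps the rule exactly antisymmetric under swapping
the two protocols.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataConsistencyError, InvalidArgumentError
from .biasmetrics import FoldDeviationTable
from .readproc import CountTable

DEFAULT_TAU_D = 1.0
DEFAULT_TAU_POOL = 1.0
DEFAULT_PSEUDOCOUNT = 0.5

CALL_CONCORDANT = "concordant"
CALL_FN_X = "FN_x"
CALL_FP_X = "FP_x"
CALL_FN_REF = "FN_ref"
CALL_FP_REF = "FP_ref"
CALL_UNATTRIBUTED = "unattributed"

ATTRIBUTION_RULE = (
    "discordance direction must match the called kit's synthetic-pool bias; "
    "if both kits qualify, the larger absolute pool bias wins (FN on ties)"
)


@dataclass
class KitComparison:
    """Per-reference cross-protocol comparison.

    ``data`` columns: ref_id, diff_log2, pool_fd_x, pool_fd_ref, call.
    Rates are percentages of the evaluated set attributed to the focal
    protocol (X).
    """

    kit_x: str
    kit_ref: str
    data: pd.DataFrame
    tau_d: float = DEFAULT_TAU_D
    tau_pool: float = DEFAULT_TAU_POOL

    def _pct(self, call: str) -> float:
        return 100.0 * (self.data["call"] == call).sum() / len(self.data)

    @property
    def fn_rate(self) -> float:
        return self._pct(CALL_FN_X)

    @property
    def fp_rate(self) -> float:
        return self._pct(CALL_FP_X)

    @property
    def concordant_rate(self) -> float:
        return self._pct(CALL_CONCORDANT)

    @property
    def unattributed_rate(self) -> float:
        return self._pct(CALL_UNATTRIBUTED)

    def call_map(self) -> dict[str, str]:
        return dict(zip(self.data["ref_id"], self.data["call"]))

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "kit_x", self.kit_x)
        out.insert(1, "kit_ref", self.kit_ref)
        with open(path, "w") as fh:
            fh.write(f"# attribution_rule: {ATTRIBUTION_RULE}\n")
            fh.write(f"# tau_d: {self.tau_d}\ttau_pool: {self.tau_pool}\n")
            out.to_csv(fh, sep="\t", index=False)


def differential_quantification(
    counts_x: CountTable,
    counts_ref: CountTable,
    eval_set: list[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """log2 fold-difference of RPM-normalized abundances (X minus reference).

    Each library is normalized to reads per million assigned; the
    pseudocount (raw reads) is scaled to each library's RPM units before
    the ratio, keeping undetected references finite and penalized.
    Restricted to ``eval_set``.
    """
    if not eval_set:
        raise InvalidArgumentError("eval_set must be nonempty")
    depth_x, depth_ref = counts_x.depth, counts_ref.depth
    if depth_x <= 0 or depth_ref <= 0:
        raise InvalidArgumentError("both count tables need nonzero depth")
    pc_x = pseudocount * 1e6 / depth_x
    pc_ref = pseudocount * 1e6 / depth_ref
    rpm_x = np.array([counts_x.get(r) * 1e6 / depth_x for r in eval_set])
    rpm_ref = np.array([counts_ref.get(r) * 1e6 / depth_ref for r in eval_set])
    with np.errstate(divide="ignore"):
        diff = np.log2(rpm_x + pc_x) - np.log2(rpm_ref + pc_ref)
    return pd.Series(diff, index=pd.Index(eval_set, name="ref_id"), name="diff_log2")


def attribute_fn_fp(
    diff: pd.Series,
    pool_fdt_x: FoldDeviationTable,
    pool_fdt_ref: FoldDeviationTable,
    tau_d: float = DEFAULT_TAU_D,
    tau_pool: float = DEFAULT_TAU_POOL,
    kit_x: str = "kit_x",
    kit_ref: str = "kit_ref",
) -> KitComparison:
    """Attribute biological-sample discordance to preparation bias.

    ``diff`` is the output of :func:`differential_quantification`; the two
    fold-deviation tables characterize each protocol on the synthetic
    pool.  See the module docstring for the decision rule.
    """
    if tau_d <= 0 or tau_pool <= 0:
        raise InvalidArgumentError("tau_d and tau_pool must be > 0")
    fd_x = pool_fdt_x.fd_map()
    fd_ref = pool_fdt_ref.fd_map()
    missing = [r for r in diff.index if r not in fd_x or r not in fd_ref]
    if missing:
        raise DataConsistencyError(
            f"references missing from pool tables: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    rows = []
    for ref_id, d in diff.items():
        bx, bref = fd_x[ref_id], fd_ref[ref_id]
        if abs(d) <= tau_d:
            call = CALL_CONCORDANT
        elif d < -tau_d:
            fn_ok = bx < -tau_pool
            fp_ok = bref > tau_pool
            if fn_ok and fp_ok:
                call = CALL_FN_X if abs(bx) >= abs(bref) else CALL_FP_REF
            elif fn_ok:
                call = CALL_FN_X
            elif fp_ok:
                call = CALL_FP_REF
            else:
                call = CALL_UNATTRIBUTED
        else:
            fp_ok = bx > tau_pool
            fn_ok = bref < -tau_pool
            if fp_ok and fn_ok:
                call = CALL_FP_X if abs(bx) > abs(bref) else CALL_FN_REF
            elif fp_ok:
                call = CALL_FP_X
            elif fn_ok:
                call = CALL_FN_REF
            else:
                call = CALL_UNATTRIBUTED
        rows.append(
            {
                "ref_id": ref_id,
                "diff_log2": float(d),
                "pool_fd_x": bx,
                "pool_fd_ref": bref,
                "call": call,
            }
        )
    return KitComparison(
        kit_x=kit_x,
        kit_ref=kit_ref,
        data=pd.DataFrame(rows),
        tau_d=tau_d,
        tau_pool=tau_pool,
    )
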