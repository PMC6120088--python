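"""Concordance analyses: cross-library Pearson correlation and
sequencing-vs-qPCR comparison via standard-curve absolute quantification.

Dilution-series robustness is assessed as the Pearson correlation of raw
per-reference read counts between libraries prepared from different input
amounts (raw counts by convention; an RPM option exists for cross-depth
comparisons).  qPCR absolute quantification fits the standard-curve model

    Cq = slope * log10(concentration) + intercept

to a dilution series of the synthetic target, inverts it at the sample's
Cq, and reports the amplification efficiency ``10^(-1/slope) - 1``
(slope -3.3219 cycles/log10 corresponds to perfect doubling, 100%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError, StandardCurveError
from .readproc import CountTable


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix with zero-variance libraries flagged."""

    library_ids: list[str]
    matrix: np.ndarray
    zero_variance: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.library_ids, columns=self.library_ids)

    def r(self, lib_a: str, lib_b: str) -> float:
        i = self.library_ids.index(lib_a)
        j = self.library_ids.index(lib_b)
        return float(self.matrix[i, j])


def pairwise_pearson(
    tables: Sequence[CountTable],
    ref_universe: Sequence[str],
    normalize: bool = False,
) -> CorrelationMatrix:
    """Pearson correlation between libraries over a shared universe.

    Count vectors are raw by default (``normalize=True`` switches to
    reads per million assigned); references absent from a table count 0.
    Libraries with zero variance over the universe are flagged and their
    matrix entries set to NaN rather than silently propagated.
    """
    if len(tables) < 2:
        raise InvalidArgumentError("need at least 2 count tables")
    if not ref_universe:
        raise InvalidArgumentError("ref_universe must be nonempty")
    vectors = []
    for t in tables:
        v = np.array([t.get(r) for r in ref_universe], dtype=float)
        if normalize:
            if t.depth <= 0:
                raise InvalidArgumentError(f"{t.library_id}: zero depth")
            v = v * 1e6 / t.depth
        vectors.append(v)
    lib_ids = [t.library_id for t in tables]
    k = len(tables)
    flagged = [lib_ids[i] for i, v in enumerate(vectors) if np.std(v) == 0]
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if lib_ids[i] in flagged or lib_ids[j] in flagged:
                mat[i, j] = mat[j, i] = np.nan
            else:
                r = np.corrcoef(vectors[i], vectors[j])[0, 1]
                mat[i, j] = mat[j, i] = r
    return CorrelationMatrix(library_ids=lib_ids, matrix=mat, zero_variance=flagged)


@dataclass(frozen=True)
class QpcrPanel:
    """One miRNA's qPCR measurements: the sample Cq and a standard
    dilution series of (known molar concentration, Cq) pairs with
    strictly decreasing concentrations."""

    mirna: str
    cq_sample: float
    standards: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.standards) < 3:
            raise InvalidArgumentError(
                f"{self.mirna}: need >= 3 standard points, got {len(self.standards)}"
            )
        concs = [c for c, _ in self.standards]
        if any(c <= 0 for c in concs):
            raise InvalidArgumentError(f"{self.mirna}: concentrations must be > 0")
        if any(b >= a for a, b in zip(concs, concs[1:])):
            raise InvalidArgumentError(
                f"{self.mirna}: standards must be strictly decreasing in concentration"
            )


@dataclass(frozen=True)
class StandardCurveFit:
    slope: float       # cycles per log10 concentration (negative)
    intercept: float   # cycles
    concentration: float  # estimated sample concentration, molar
    efficiency: float  # per-cycle amplification efficiency, fraction
    r_squared: float


def standard_curve_quantify(panel: QpcrPanel) -> StandardCurveFit:
    """Fit Cq = slope * log10(conc) + intercept and invert at the sample Cq.

    Raises :class:`StandardCurveError` when the fitted slope is
    non-negative (more template must mean a lower Cq).
    """
    log_conc = np.log10([c for c, _ in panel.standards])
    cq = np.array([q for _, q in panel.standards])
    fit = stats.linregress(log_conc, cq)
    if fit.slope >= 0:
        raise StandardCurveError(
            f"{panel.mirna}: standard-curve slope {fit.slope:.4f} is non-negative"
        )
    conc = 10.0 ** ((panel.cq_sample - fit.intercept) / fit.slope)
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurveFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        concentration=float(conc),
        efficiency=float(efficiency),
        r_squared=float(fit.rvalue**2),
    )


def read_qpcr_panels(path) -> list[QpcrPanel]:
    """Read panels from TSV: columns mirna, cq_sample, concentration, cq
    (one row per standard point, repeated mirna/cq_sample)."""
    df = pd.read_csv(path, sep="\t")
    required = {"mirna", "cq_sample", "concentration", "cq"}
    if not required <= set(df.columns):
        raise InvalidArgumentError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    panels = []
    for mirna, grp in df.groupby("mirna", sort=False):
        grp = grp.sort_values("concentration", ascending=False)
        panels.append(
            QpcrPanel(
                mirna=str(mirna),
                cq_sample=float(grp["cq_sample"].iloc[0]),
                standards=tuple(zip(grp["concentration"], grp["cq"])),
            )
        )
    return panels


def rank_concordance(
    seq_abundance: Mapping[str, float], qpcr_abundance: Mapping[str, float]
) -> tuple[bool, float]:
    """Compare sequencing and qPCR abundance: exact rank-order agreement
    plus Pearson r on log10 abundances.

    Raises on mismatched key sets, listing the symmetric difference.
    """
    keys_seq, keys_q = set(seq_abundance), set(qpcr_abundance)
    if keys_seq != keys_q:
        raise InvalidArgumentError(
            f"mismatched miRNA sets; symmetric difference: "
            f"{sorted(keys_seq ^ keys_q)}"
        )
    if len(keys_seq) < 2:
        raise InvalidArgumentError("need at least 2 shared miRNAs")
    keys = sorted(keys_seq)
    a = np.array([seq_abundance[k] for k in keys], dtype=float)
    b = np.array([qpcr_abundance[k] for k in keys], dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise InvalidArgumentError("abundances must be positive for log comparison")
    rank_match = bool(np.array_equal(np.argsort(np.argsort(a)), np.argsort(np.argsort(b))))
    r = float(np.corrcoef(np.log10(a), np.log10(b))[0, 1])
    return rank_match, r
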