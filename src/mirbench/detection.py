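"""Detection sensitivity and small-RNA class composition.

Detection is defined by a read-count threshold: a reference is detected
in a library when its assigned count reaches ``min_reads`` (conventional
presets: 5 for cross-protocol comparisons at equal depth, 10 for
detection-vs-depth curves).  Because deeper libraries trivially detect
more, libraries are compared after subsampling to equal depth; a
detection-vs-depth curve repeats that at several depths, averaging over
independent subsample draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDepthError, InvalidArgumentError
from .pool import ReferencePool
from .readproc import CountTable, count_reads, subsample_reads
from .reads import ReadSet

OTHER_CLASS = "other"


@dataclass
class DetectionSummary:
    library_id: str
    depth: int
    min_reads: int
    n_detected: float  # mean over draws; a count for a single draw
    n_draws: int = 1
    sd: float = 0.0


def count_detected(counts: CountTable, min_reads: int = 5) -> int:
    """Number of references with at least ``min_reads`` assigned reads."""
    if min_reads < 1:
        raise InvalidArgumentError(f"min_reads must be >= 1, got {min_reads}")
    return int(sum(1 for c in counts.counts.values() if c >= min_reads))


def detection_curve(
    reads: ReadSet,
    pool: ReferencePool,
    depths: Sequence[int],
    min_reads: int = 10,
    n_draws: int = 10,
    seed: int = 0,
    max_mismatches: int = 0,
) -> list[DetectionSummary]:
    """Mean detected references at each subsampling depth.

    For each depth, draws ``n_draws`` independent subsamples of the
    (already trimmed) reads, counts against the pool, and averages the
    number of detected references.  Deterministic per ``seed``.
    """
    if n_draws < 1:
        raise InvalidArgumentError(f"n_draws must be >= 1, got {n_draws}")
    for depth in depths:
        if depth > len(reads):
            raise InsufficientDepthError(
                f"depth {depth} exceeds library size {len(reads)}"
            )
    rng = np.random.default_rng(seed)
    out = []
    for depth in depths:
        detected = []
        for _ in range(n_draws):
            sub = subsample_reads(reads, depth, seed=int(rng.integers(2**31)))
            table = count_reads(sub, pool, max_mismatches=max_mismatches)
            detected.append(count_detected(table, min_reads))
        out.append(
            DetectionSummary(
                library_id="curve",
                depth=int(depth),
                min_reads=min_reads,
                n_detected=float(np.mean(detected)),
                n_draws=n_draws,
                sd=float(np.std(detected, ddof=1)) if n_draws > 1 else 0.0,
            )
        )
    return out


def class_composition(
    counts: CountTable, class_map: Mapping[str, str]
) -> dict[str, float]:
    """Read-weighted percentage of assigned reads per small-RNA class.

    References absent from ``class_map`` fall into the ``"other"`` class.
    Percentages sum to 100 over the assigned reads.
    """
    depth = counts.depth
    if depth <= 0:
        return {}
    totals: dict[str, float] = {}
    for ref_id, c in counts.counts.items():
        if c == 0:
            continue
        cls = class_map.get(ref_id, OTHER_CLASS)
        totals[cls] = totals.get(cls, 0.0) + c
    return {cls: 100.0 * t / depth for cls, t in sorted(totals.items())}


def read_class_map(path) -> dict[str, str]:
    """Read a two-column TSV (ref_id, class) into a mapping."""
    df = pd.read_csv(path, sep="\t")
    if not {"ref_id", "class"} <= set(df.columns):
        raise InvalidArgumentError(f"{path}: expected columns ref_id, class")
    return dict(zip(df["ref_id"].astype(str), df["class"].astype(str)))


def summaries_frame(summaries: Sequence[DetectionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "library_id": s.library_id,
                "depth": s.depth,
                "min_reads": s.min_reads,
                "n_detected": s.n_detected,
                "n_draws": s.n_draws,
                "sd": s.sd,
            }
            for s in summaries
        ]
    )
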