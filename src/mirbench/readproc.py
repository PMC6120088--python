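"""FASTQ read processing: 3' adapter trimming, reference counting, subsampling.

The trimmer reproduces classic 3'-adapter semantics: the best occurrence of
the adapter — either the full adapter anywhere in the read, or a prefix of
the adapter running into the read's 3' end — is located allowing errors
(substitutions and indels at unit cost) at a rate of at most
``max_error_rate`` per aligned adapter base, and the match plus everything
3' of it is removed.  Occurrences are preferred by longer adapter match
first, then leftmost start.  Reads with no qualifying occurrence are kept
untrimmed; trimmed reads shorter than ``min_length`` are discarded.

Counting uses a prefix-anchored ungapped matcher: a trimmed read is
assigned to a reference when it equals the reference sequence up to
``max_mismatches`` substitutions over their common prefix with a 3' length
difference of at most ``length_tolerance`` nt.  A read matching k
references equally well is counted 1/k to each (fractional counting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from .errors import InsufficientDepthError, InvalidArgumentError
from .pool import ReferencePool
from .reads import ReadSet

DEFAULT_MAX_ERROR_RATE = 0.1
DEFAULT_MIN_LENGTH = 15
DEFAULT_MIN_OVERLAP = 3
DEFAULT_LENGTH_TOLERANCE = 2


# --------------------------------------------------------------------------
# adapter trimming
# --------------------------------------------------------------------------

@dataclass
class TrimResult:
    kept: ReadSet
    n_input: int
    n_trimmed: int
    n_untrimmed: int
    n_discarded_short: int

    def report_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "n_input": self.n_input,
                    "n_trimmed": self.n_trimmed,
                    "n_untrimmed": self.n_untrimmed,
                    "n_discarded_short": self.n_discarded_short,
                    "n_kept": len(self.kept),
                }
            ]
        )


@lru_cache(maxsize=262_144)
def _find_trim_point(
    seq: str, adapter: str, max_error_rate: float, min_overlap: int
) -> int:
    """Start position of the best qualifying adapter occurrence, or -1.

    A candidate is an adapter prefix of length ``L`` (``min_overlap <= L
    <= len(adapter)``) aligned to ``seq[s:e]`` with Levenshtein errors
    ``<= floor(max_error_rate * L)``; for ``L < len(adapter)`` the
    alignment must reach the read's 3' end (``e == len(seq)``).
    Preference: larger ``L`` first, then smaller ``s``.  Since the removed
    portion is ``seq[s:]``, only ``s`` matters for the result.
    """
    n, m = len(seq), len(adapter)
    full_budget = int(max_error_rate * m)
    # leftmost qualifying start per adapter prefix length (end-anchored)
    best_start = [-1] * (m + 1)
    for s in range(n):
        t = n - s
        target = seq[s:]
        prev = list(range(t + 1))
        full_min = None
        for i in range(1, m + 1):
            ai = adapter[i - 1]
            cur = [i] + [0] * t
            for j in range(1, t + 1):
                cur[j] = min(
                    prev[j - 1] + (ai != target[j - 1]),
                    prev[j] + 1,
                    cur[j - 1] + 1,
                )
            if i == m:
                full_min = min(cur)
            elif i >= min_overlap and best_start[i] < 0 and cur[t] <= int(max_error_rate * i):
                best_start[i] = s
            prev = cur
        if full_min is not None and full_min <= full_budget:
            # longest possible match; s ascending, so this is leftmost
            return s
    for L in range(m - 1, min_overlap - 1, -1):
        if best_start[L] >= 0:
            return best_start[L]
    return -1


def trim_adapter(
    reads: ReadSet,
    adapter: str,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
    min_length: int = DEFAULT_MIN_LENGTH,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> TrimResult:
    """Trim the 3' adapter from every read (see module docstring).

    Returns a :class:`TrimResult` whose ``kept`` set holds trimmed reads
    and untrimmed reads of length >= ``min_length``; shorter results are
    discarded and counted in ``n_discarded_short``.
    """
    if not adapter:
        raise InvalidArgumentError("adapter must be nonempty")
    if not (0.0 <= max_error_rate < 0.5):
        raise InvalidArgumentError(
            f"max_error_rate must be in [0, 0.5), got {max_error_rate}"
        )
    if min_length < 1:
        raise InvalidArgumentError(f"min_length must be >= 1, got {min_length}")
    adapter = adapter.upper()

    kept = ReadSet()
    n_trimmed = n_untrimmed = n_short = 0
    for rid, seq, qual in zip(reads.ids, reads.sequences, reads.qualities):
        s = _find_trim_point(seq.upper(), adapter, max_error_rate, min_overlap)
        if s < 0:
            n_untrimmed += 1
            out_seq, out_qual = seq, qual
        else:
            n_trimmed += 1
            out_seq, out_qual = seq[:s], qual[:s]
        if len(out_seq) < min_length:
            n_short += 1
        else:
            kept.append(rid, out_seq, out_qual)
    return TrimResult(
        kept=kept,
        n_input=len(reads),
        n_trimmed=n_trimmed,
        n_untrimmed=n_untrimmed,
        n_discarded_short=n_short,
    )


# --------------------------------------------------------------------------
# reference counting
# --------------------------------------------------------------------------

@dataclass
class CountTable:
    """Per-library read counts over a reference universe.

    ``counts`` maps ref_id -> count; counts are rational under fractional
    multimapping, so the value type is float.  ``depth`` is the total
    assigned count; ``unassigned`` the number of reads matching no
    reference.
    """

    library_id: str
    counts: dict[str, float]
    unassigned: int = 0

    @property
    def depth(self) -> float:
        return sum(self.counts.values())

    def get(self, ref_id: str) -> float:
        return self.counts.get(ref_id, 0.0)

    def to_frame(self):
        import pandas as pd

        depth = self.depth
        return pd.DataFrame(
            {
                "library_id": self.library_id,
                "ref_id": list(self.counts),
                "count": list(self.counts.values()),
                "depth": depth,
                "unassigned": self.unassigned,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        required = {"library_id", "ref_id", "count", "unassigned"}
        if not required <= set(df.columns):
            raise InvalidArgumentError(
                f"{path}: missing columns {sorted(required - set(df.columns))}"
            )
        lib_ids = df["library_id"].unique()
        if len(lib_ids) != 1:
            raise InvalidArgumentError(
                f"{path}: expected one library_id, found {list(lib_ids)}"
            )
        return cls(
            library_id=str(lib_ids[0]),
            counts=dict(zip(df["ref_id"].astype(str), df["count"].astype(float))),
            unassigned=int(df["unassigned"].iloc[0]),
        )


def _hamming_prefix(a: str, b: str, limit: int) -> int:
    """Substitutions over the common prefix, early-exiting past ``limit``."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def count_reads(
    reads: ReadSet,
    pool: ReferencePool,
    max_mismatches: int = 0,
    length_tolerance: int = DEFAULT_LENGTH_TOLERANCE,
    library_id: str = "library",
) -> CountTable:
    """Assign trimmed reads to pool references and count them.

    A read matches a reference when their length difference is at most
    ``length_tolerance`` nt (the 3' end may be ragged) and the common
    prefix has at most ``max_mismatches`` substitutions.  Among matching
    references only the best (fewest mismatches, then smallest length
    difference) are counted; equal bests share the read fractionally.
    """
    if len(pool) == 0:
        raise InvalidArgumentError("pool must be nonempty")
    if max_mismatches not in (0, 1, 2):
        raise InvalidArgumentError(
            f"max_mismatches must be 0, 1 or 2, got {max_mismatches}"
        )

    exact: dict[str, list[str]] = {}
    by_length: dict[int, list[tuple[str, str]]] = {}
    for entry in pool:
        seq = entry.dna
        exact.setdefault(seq, []).append(entry.ref_id)
        by_length.setdefault(len(seq), []).append((entry.ref_id, seq))

    counts: dict[str, float] = {entry.ref_id: 0.0 for entry in pool}
    unassigned = 0
    assign_cache: dict[str, tuple[str, ...]] = {}

    for seq in reads.sequences:
        seq = seq.upper()
        hit = assign_cache.get(seq)
        if hit is None:
            ids = exact.get(seq)
            if ids is not None and max_mismatches == 0:
                hit = tuple(ids)
            else:
                best: tuple[int, int] | None = None
                winners: list[str] = []
                for L in range(
                    len(seq) - length_tolerance, len(seq) + length_tolerance + 1
                ):
                    for ref_id, ref_seq in by_length.get(L, ()):
                        mm = _hamming_prefix(seq, ref_seq, max_mismatches)
                        if mm > max_mismatches:
                            continue
                        score = (mm, abs(len(seq) - L))
                        if best is None or score < best:
                            best, winners = score, [ref_id]
                        elif score == best:
                            winners.append(ref_id)
                hit = tuple(winners)
            assign_cache[seq] = hit
        if hit:
            share = 1.0 / len(hit)
            for ref_id in hit:
                counts[ref_id] += share
        else:
            unassigned += 1
    return CountTable(library_id=library_id, counts=counts, unassigned=unassigned)


# --------------------------------------------------------------------------
# subsampling
# --------------------------------------------------------------------------

def subsample_reads(reads: ReadSet, target_depth: int, seed: int = 0) -> ReadSet:
    """Uniform sample of exactly ``target_depth`` reads without replacement.

    Output preserves the input order of the selected reads and is
    deterministic for a fixed ``seed``.
    """
    if target_depth < 0:
        raise InvalidArgumentError(f"target_depth must be >= 0, got {target_depth}")
    if target_depth > len(reads):
        raise InsufficientDepthError(
            f"cannot subsample {target_depth} reads from a library of "
            f"{len(reads)} reads"
        )
    if target_depth == len(reads):
        return reads.select(range(len(reads)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=target_depth, replace=False)
    idx.sort()
    return reads.select(idx.tolist())
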