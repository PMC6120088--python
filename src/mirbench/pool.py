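"""Reference pools of small-RNA sequences with expected molar fractions.

A :class:`ReferencePool` models a defined mixture of mature small-RNA
sequences, such as a commercial equimolar validation pool, where every
member's molar fraction is known.  Expected read counts for a library of
depth ``D`` follow directly as ``E_i = D * f_i``, which is what makes such
pools usable as ground truth for quantification-bias benchmarking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import GenerationError, InvalidArgumentError

_RNA_TO_DNA = str.maketrans("Uu", "Tt")
_POOL_ALPHABET = frozenset("ACGTU")

MIN_REF_LENGTH = 15
MAX_REF_LENGTH = 35


@dataclass(frozen=True)
class PoolEntry:
    ref_id: str
    sequence: str
    expected_fraction: float

    @property
    def dna(self) -> str:
        """Sequence in DNA alphabet (U -> T), uppercase."""
        return self.sequence.upper().translate(_RNA_TO_DNA)

    @property
    def gc_content(self) -> float:
        s = self.dna
        return (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class ReferencePool:
    """An ordered collection of reference sequences with molar fractions.

    Invariants enforced on construction: unique ids, sequence lengths in
    [15, 35] nt over the {A,C,G,T,U} alphabet, positive fractions summing
    to 1 (within 1e-9).
    """

    entries: tuple[PoolEntry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [e.ref_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise InvalidArgumentError("reference pool ids must be unique")
        for e in self.entries:
            if not (MIN_REF_LENGTH <= len(e.sequence) <= MAX_REF_LENGTH):
                raise InvalidArgumentError(
                    f"{e.ref_id}: sequence length {len(e.sequence)} outside "
                    f"[{MIN_REF_LENGTH}, {MAX_REF_LENGTH}]"
                )
            if not set(e.sequence.upper()) <= _POOL_ALPHABET:
                raise InvalidArgumentError(
                    f"{e.ref_id}: sequence contains characters outside ACGTU"
                )
            if not e.expected_fraction > 0:
                raise InvalidArgumentError(
                    f"{e.ref_id}: expected_fraction must be > 0"
                )
        if self.entries:
            total = math.fsum(e.expected_fraction for e in self.entries)
            if abs(total - 1.0) > 1e-9:
                raise InvalidArgumentError(
                    f"expected fractions sum to {total!r}, not 1"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def ref_ids(self) -> list[str]:
        return [e.ref_id for e in self.entries]

    @property
    def fractions(self) -> np.ndarray:
        return np.array([e.expected_fraction for e in self.entries])

    def entry(self, ref_id: str) -> PoolEntry:
        for e in self.entries:
            if e.ref_id == ref_id:
                return e
        raise KeyError(ref_id)

    @classmethod
    def from_sequences(
        cls,
        sequences: Sequence[str],
        ids: Sequence[str] | None = None,
        fractions: Sequence[float] | None = None,
    ) -> "ReferencePool":
        """Build a pool from parallel lists; equimolar if fractions omitted."""
        n = len(sequences)
        if ids is None:
            width = max(3, len(str(n)))
            ids = [f"ref{i:0{width}d}" for i in range(1, n + 1)]
        if fractions is None:
            fractions = [1.0 / n] * n
        return cls(
            tuple(
                PoolEntry(i, s.upper(), f)
                for i, s, f in zip(ids, sequences, fractions)
            )
        )

    # ---- persistence: FASTA + sidecar fraction TSV -----------------------

    def to_fasta(self, fasta_path: str | Path, tsv_path: str | Path | None = None) -> None:
        """Write sequences as FASTA and fractions as a sidecar TSV.

        The TSV has columns ``ref_id`` and ``fraction``; it defaults to the
        FASTA path with a ``.fractions.tsv`` suffix.
        """
        fasta_path = Path(fasta_path)
        with open(fasta_path, "w") as fh:
            for e in self.entries:
                fh.write(f">{e.ref_id}\n{e.sequence}\n")
        if tsv_path is None:
            tsv_path = fasta_path.with_suffix(".fractions.tsv")
        with open(tsv_path, "w") as fh:
            fh.write("ref_id\tfraction\n")
            for e in self.entries:
                fh.write(f"{e.ref_id}\t{e.expected_fraction!r}\n")

    @classmethod
    def from_fasta(
        cls, fasta_path: str | Path, tsv_path: str | Path | None = None
    ) -> "ReferencePool":
        """Read a pool from FASTA; fractions from a sidecar TSV if present,
        otherwise equimolar."""
        from Bio import SeqIO

        fasta_path = Path(fasta_path)
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
        if not records:
            raise InvalidArgumentError(f"no sequences in {fasta_path}")
        if tsv_path is None:
            candidate = fasta_path.with_suffix(".fractions.tsv")
            tsv_path = candidate if candidate.exists() else None
        fractions = None
        if tsv_path is not None:
            frac_map: dict[str, float] = {}
            with open(tsv_path) as fh:
                header = fh.readline()
                if not header.startswith("ref_id"):
                    raise InvalidArgumentError(
                        f"{tsv_path}: expected header 'ref_id\\tfraction'"
                    )
                for line in fh:
                    rid, frac = line.rstrip("\n").split("\t")
                    frac_map[rid] = float(frac)
            fractions = [frac_map[r.id] for r in records]
        return cls.from_sequences(
            [str(r.seq) for r in records], [r.id for r in records], fractions
        )


def build_equimolar_pool(
    n: int,
    length_low: int = 19,
    length_high: int = 24,
    gc_range: tuple[float, float] = (0.2, 0.8),
    seed: int = 0,
) -> ReferencePool:
    """Generate ``n`` distinct random sequences at equal molar fractions.

    Emulates a synthetic equimolar validation pool: sequence lengths are
    drawn uniformly from ``[length_low, length_high]`` and base composition
    is biased per sequence so GC content spans ``gc_range``.  Deterministic
    for a fixed ``seed``.

    Raises
    ------
    InvalidArgumentError
        if ``n < 1`` or the length window falls outside [15, 35].
    GenerationError
        if ``n`` distinct sequences cannot be produced (e.g. ``n`` exceeds
        the number of distinct sequences of the requested lengths).
    """
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    if not (MIN_REF_LENGTH <= length_low <= length_high <= MAX_REF_LENGTH):
        raise InvalidArgumentError(
            f"need {MIN_REF_LENGTH} <= length_low <= length_high <= "
            f"{MAX_REF_LENGTH}, got [{length_low}, {length_high}]"
        )
    gc_lo, gc_hi = gc_range
    if not (0.0 <= gc_lo <= gc_hi <= 1.0):
        raise InvalidArgumentError(f"invalid gc_range {gc_range}")
    # crude capacity check: 4^L distinct sequences exist per length
    capacity = sum(4 ** L for L in range(length_low, length_high + 1))
    if n > capacity:
        raise GenerationError(
            f"cannot draw {n} distinct sequences of length "
            f"[{length_low}, {length_high}] ({capacity} exist)"
        )

    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    seen: set[str] = set()
    max_attempts = 200 * n + 10_000
    attempts = 0
    while len(seqs) < n:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"failed to generate {n} distinct sequences after "
                f"{max_attempts} attempts"
            )
        L = int(rng.integers(length_low, length_high + 1))
        gc = float(rng.uniform(gc_lo, gc_hi))
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=L, p=p)])
        if seq in seen:
            continue
        seen.add(seq)
        seqs.append(seq)
    return ReferencePool.from_sequences(seqs)
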