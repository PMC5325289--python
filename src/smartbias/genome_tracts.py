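"""Homopolymer (poly dN) tract detection and the genome-wide tract census.

Template-switching (SMART) DNA library preparation is biased toward fragments
that already carry a genomic poly dT run near their 3' end.  Everything
downstream of that observation needs two primitives: finding exact maximal
homopolymer runs, and finding mismatch-tolerant runs (a bounded number of
non-matching bases inside an otherwise homopolymeric stretch), plus a census
of how many tracts of each base and length the genome contains, which is the
expected distribution that read-end enrichment is normalized against.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True, order=True)
class TractInterval:
    """One homopolymer run on the genome, half-open coordinates.

    ``n_mismatches`` counts non-``base`` characters inside the interval; it is
    0 for exact tracts and may exceed the scanner's per-window budget for
    merged tolerant tracts (the merge unions overlapping qualifying windows).
    """

    chrom: str
    start: int
    end: int
    base: str
    n_mismatches: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty tract interval [{self.start},{self.end})")
        if self.base not in VALID_BASES:
            raise ValueError(f"invalid tract base {self.base!r}")


def _as_byte_array(sequence: str) -> np.ndarray:
    return np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)


def _check_base(base: str) -> str:
    base = base.upper()
    if base not in VALID_BASES:
        raise ValueError(f"base must be one of {VALID_BASES}, got {base!r}")
    return base


def find_exact_tracts(
    sequence: str, base: str, min_len: int, chrom: str = "seq"
) -> list[TractInterval]:
    """Every maximal run of ``base`` with length >= ``min_len``.

    Runs are maximal (flanked by a different character or the sequence edge),
    non-overlapping and returned sorted by start.  ``N`` never matches.
    """
    base = _check_base(base)
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if not sequence:
        return []
    arr = _as_byte_array(sequence)
    mask = arr == ord(base)
    # run boundaries from transitions in the padded mask
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    keep = (ends - starts) >= min_len
    return [
        TractInterval(chrom, int(s), int(e), base, 0)
        for s, e in zip(starts[keep], ends[keep])
    ]


def find_tolerant_tracts(
    sequence: str,
    base: str,
    min_len: int,
    max_mm: int,
    chrom: str = "seq",
) -> list[TractInterval]:
    """Mismatch-tolerant tracts as merged maximal qualifying windows.

    A window qualifies when it has length >= ``min_len``, starts and ends with
    ``base``, contains at most ``max_mm`` non-``base`` characters and no ``N``.
    The reported intervals are the union of all qualifying windows, merged
    when they overlap or touch; a genomic position is covered by the output
    iff it is covered by some qualifying window.  With ``max_mm == 0`` the
    output equals :func:`find_exact_tracts`.
    """
    base = _check_base(base)
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    if min_len <= max_mm:
        raise ValueError("min_len must exceed max_mm")
    if not sequence:
        return []
    arr = _as_byte_array(sequence)
    is_base = arr == ord(base)
    is_n = arr == ord("N")
    n = arr.size

    # prefix sums over [0, i): mismatches (non-base, non-N) and N's
    mm_prefix = np.concatenate(([0], np.cumsum((~is_base) & (~is_n))))
    n_prefix = np.concatenate(([0], np.cumsum(is_n)))
    # rightmost base position at or before each index (-1 if none)
    last_base = np.maximum.accumulate(
        np.where(is_base, np.arange(n), -1)
    )

    starts = np.flatnonzero(is_base)
    if starts.size == 0:
        return []
    # furthest window end per start under the mismatch and N budgets
    j_mm = np.searchsorted(mm_prefix, mm_prefix[starts] + max_mm, side="right") - 1
    j_n = np.searchsorted(n_prefix, n_prefix[starts], side="right") - 1
    j = np.minimum(j_mm, j_n)
    # retract to end on a matching base
    ends = last_base[np.maximum(j - 1, 0)] + 1
    ok = (ends - starts) >= min_len
    starts, ends = starts[ok], ends[ok]
    if starts.size == 0:
        return []

    # merge overlapping or touching intervals (starts are sorted)
    cummax_end = np.maximum.accumulate(ends)
    new_group = np.concatenate(([True], starts[1:] > cummax_end[:-1]))
    first_idx = np.flatnonzero(new_group)
    last_idx = np.append(first_idx[1:], starts.size) - 1
    merged = []
    for fi, li in zip(first_idx, last_idx):
        s = int(starts[fi])
        e = int(cummax_end[li])
        mm = int(mm_prefix[e] - mm_prefix[s])
        merged.append(TractInterval(chrom, s, e, base, mm))
    return merged


def scan_genome(
    genome: Mapping[str, str],
    base: str,
    min_len: int,
    max_mm: int = 0,
) -> list[TractInterval]:
    """Tract scan over every contig of a genome dict, exact or tolerant."""
    out: list[TractInterval] = []
    for chrom, seq in genome.items():
        if max_mm == 0:
            out.extend(find_exact_tracts(seq, base, min_len, chrom=chrom))
        else:
            out.extend(find_tolerant_tracts(seq, base, min_len, max_mm, chrom=chrom))
    return out


@dataclass
class TractCensus:
    """Genome-wide counts of exact maximal tracts, by base and exact length.

    ``exact[(base, length)]`` is the number of maximal runs of exactly that
    length.  Cumulative (>= threshold) counts are derived, so both readings
    of a length threshold are available.
    """

    exact: dict[tuple[str, int], int] = field(default_factory=dict)
    genome_size: int = 0

    def count_exact(self, base: str, length: int) -> int:
        return self.exact.get((base.upper(), length), 0)

    def count_at_least(self, base: str, min_len: int) -> int:
        b = base.upper()
        return sum(c for (bb, ln), c in self.exact.items() if bb == b and ln >= min_len)

    def coverage_at_least(self, base: str, min_len: int) -> int:
        """Total base pairs covered by tracts of ``base`` with length >= min_len."""
        b = base.upper()
        return sum(
            ln * c for (bb, ln), c in self.exact.items() if bb == b and ln >= min_len
        )

    def to_frame(self, thresholds: Iterable[int]) -> pd.DataFrame:
        rows = [
            {
                "base": b,
                "length_threshold": t,
                "count_exact": self.count_exact(b, t),
                "count_at_least": self.count_at_least(b, t),
            }
            for b in VALID_BASES
            for t in thresholds
        ]
        return pd.DataFrame(rows)


def tract_census(
    genome: Mapping[str, str] | str | Path,
    min_len_range: tuple[int, int] = (5, 30),
) -> TractCensus:
    """Count exact maximal tracts of every base across the genome.

    ``min_len_range`` is (lo, hi) inclusive; tracts of length >= lo are
    tallied by exact length (lengths above hi are kept too, so cumulative
    counts are correct at every threshold >= lo).
    """
    if not isinstance(genome, Mapping):
        genome = read_fasta(genome)
    lo, hi = min_len_range
    if hi < lo:
        raise ValueError("empty min_len_range")
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    census = TractCensus(genome_size=sum(len(s) for s in genome.values()))
    for base in VALID_BASES:
        for tr in scan_genome(genome, base, lo):
            key = (base, tr.length)
            census.exact[key] = census.exact.get(key, 0) + 1
    return census


# ---------------------------------------------------------------------------
# I/O helpers

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-record) FASTA into {name: uppercase sequence}."""
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def tracts_to_bed(tracts: Iterable[TractInterval], path: str | Path) -> None:
    """Write tracts as 6-column BED (name = base, score = n_mismatches, strand '+')."""
    with open(path, "w") as fh:
        for t in sorted(tracts):
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.base}\t{t.n_mismatches}\t+\n")


def read_tracts_bed(path: str | Path) -> list[TractInterval]:
    tracts = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            score = int(f[4]) if len(f) > 4 else 0
            tracts.append(TractInterval(f[0], int(f[1]), int(f[2]), f[3], score))
    return tracts
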