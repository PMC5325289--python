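"""Null constructions: coordinate-shift randomization and random fragments.

Shifting every fragment by a fixed offset preserves the library's internal
structure (per-chromosome counts, lengths, strand mix) while destroying any
sequence-specific positioning, so tract adjacency measured on shifted data
estimates the unbiased background.  The random-fragment simulation instead
asks how often a fragment with the library's length distribution would
contain a long poly dA/dT tract purely by chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_tracts import TractInterval, scan_genome
from .read_ends import _ensure_frame

DEFAULT_SHIFT_OFFSETS = (500, 1000, 10000)


@dataclass
class ShiftConfig:
    """Shift-randomization settings; offsets wrap within each chromosome."""

    offsets: tuple[int, ...] = DEFAULT_SHIFT_OFFSETS

    def __post_init__(self) -> None:
        if any(o <= 0 for o in self.offsets):
            raise ValueError("shift offsets must be positive")


def shift_fragments(
    fragments,
    offset: int,
    chrom_sizes: Mapping[str, int],
) -> tuple[pd.DataFrame, int]:
    """Translate every fragment by +offset, wrapping within its chromosome.

    Fragments that would straddle the chromosome origin after wrapping are
    dropped (and counted in the returned int); lengths and strands are
    preserved.  For offsets much smaller than the chromosome the retained
    set is >= 99% of the input.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    df = _ensure_frame(fragments)
    for chrom in pd.unique(df["chrom"]):
        if chrom not in chrom_sizes:
            raise ValueError(f"no chromosome size for {chrom!r}")
        if offset >= chrom_sizes[chrom]:
            raise ValueError(
                f"offset {offset} >= length of chromosome {chrom!r}"
            )
    sizes = df["chrom"].map(chrom_sizes).to_numpy(np.int64)
    start = df["start"].to_numpy(np.int64)
    length = df["end"].to_numpy(np.int64) - start
    new_start = (start + offset) % sizes
    keep = new_start + length <= sizes
    out = df.loc[keep].copy()
    out["start"] = new_start[keep]
    out["end"] = new_start[keep] + length[keep]
    return out.reset_index(drop=True), int((~keep).sum())


def simulate_random_fragments(
    genome: Mapping[str, str],
    length_sample: Sequence[int],
    n: int,
    seed: int | np.random.Generator = 0,
    min_len: int = 12,
    tracts: Sequence[TractInterval] | None = None,
) -> float:
    """Fraction of random genomic fragments containing a poly dA/dT tract.

    Draws ``n`` fragments with starts uniform over valid positions and
    lengths resampled from ``length_sample``, and reports the fraction whose
    span overlaps any poly dA or poly dT tract of length >= ``min_len``
    (scanned from the genome unless ``tracts`` is supplied).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lengths = np.asarray(length_sample, dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("length_sample is empty")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    chroms = list(genome)
    clens = np.array([len(genome[c]) for c in chroms], dtype=np.int64)
    if lengths.min() > clens.max():
        raise ValueError("every sampled length exceeds every contig")

    if tracts is None:
        tracts = scan_genome(genome, "A", min_len) + scan_genome(genome, "T", min_len)
    # merged A/T interval arrays per chromosome for overlap queries
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in chroms:
        ivs = sorted(
            (t.start, t.end)
            for t in tracts
            if t.chrom == c and t.base in ("A", "T") and t.length >= min_len
        )
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged, dtype=np.int64).reshape(-1, 2)
        per_chrom[c] = (arr[:, 0], arr[:, 1])

    draw_len = rng.choice(lengths, size=n, replace=True)
    ci = rng.choice(len(chroms), size=n, p=clens / clens.sum())
    hits = 0
    total = 0
    for k, c in enumerate(chroms):
        sel = ci == k
        L = draw_len[sel]
        ok = L <= clens[k]
        L = L[ok]
        if L.size == 0:
            continue
        starts = (rng.random(L.size) * (clens[k] - L + 1)).astype(np.int64)
        ends = starts + L
        t_start, t_end = per_chrom[c]
        if t_start.size:
            lo = np.searchsorted(t_end, starts, side="right")
            hi = np.searchsorted(t_start, ends, side="left")
            hits += int((hi > lo).sum())
        total += L.size
    if total == 0:
        raise ValueError("no fragment fit on any contig")
    return hits / total
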