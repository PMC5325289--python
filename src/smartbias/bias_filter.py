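"""The recommended mitigation: drop reads adjacent to tolerant poly dA/dT tracts.

Internal priming parks second-read ends against genomic poly dT (forward) or
poly dA (reverse) runs — including runs interrupted by one or two other
bases.  Removing every fragment whose tail-side window touches such a
mismatch-tolerant tract (length >= 12, up to 2 mismatches by default)
removes the biased reads at the cost of discarding a fraction of the
library, which the report quantifies together with the before/after
coincident-end cluster fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_tracts import TractInterval, scan_genome
from .read_ends import _ensure_frame, adjacency_mask, end_position_clusters


@dataclass
class FilterReport:
    """Cost accounting for the adjacency filter."""

    n_input: int
    n_removed: int
    cluster_before: float | None
    cluster_after: float | None
    min_len: int
    max_mm: int
    distance: int
    both_strands: bool

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0


def filter_reads(
    fragments,
    genome: Mapping[str, str] | None = None,
    tracts: Sequence[TractInterval] | None = None,
    min_len: int = 12,
    max_mm: int = 2,
    distance: int = 1,
    both_strands: bool = False,
    min_cluster: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Remove fragments whose tail window touches a tolerant poly dA/dT tract.

    Strand-specific by default (poly dT for '+' fragments, poly dA for '-',
    matching the priming mechanism); ``both_strands`` removes fragments near
    either tract type.  Supply either a genome to scan or precomputed
    tolerant ``tracts``.  Returns (kept, removed, report); the removed frame
    is the auditable rejects set.
    """
    df = _ensure_frame(fragments)
    if tracts is None:
        if genome is None:
            raise ValueError("need a genome or a precomputed tract set")
        tracts = scan_genome(genome, "A", min_len, max_mm) + scan_genome(
            genome, "T", min_len, max_mm
        )
    tracts = [t for t in tracts if t.base in ("A", "T") and t.length >= min_len]
    if both_strands:
        strand_base = {"+": ["A", "T"], "-": ["A", "T"]}
    else:
        strand_base = {"+": ["T"], "-": ["A"]}
    mask = adjacency_mask(df, tracts, distance=distance, strand_base=strand_base)

    kept = df.loc[~mask].reset_index(drop=True)
    removed = df.loc[mask].reset_index(drop=True)

    def _cluster(frame: pd.DataFrame) -> float | None:
        if frame.empty:
            return None
        frac, _ = end_position_clusters(frame, min_cluster=min_cluster)
        return frac

    report = FilterReport(
        n_input=len(df),
        n_removed=int(mask.sum()),
        cluster_before=_cluster(df),
        cluster_after=_cluster(kept),
        min_len=min_len,
        max_mm=max_mm,
        distance=distance,
        both_strands=both_strands,
    )
    return kept, removed, report
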