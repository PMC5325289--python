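"""Independent brute-force oracles used to validate the fast implementations.

These deliberately use different algorithms from the package: regex scans,
full window enumeration with position marking, and quadratic all-pairs
interval checks.
"""

from __future__ import annotations

import re
from collections import Counter

import numpy as np


def exact_tracts_oracle(seq: str, base: str, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of ``base`` with length >= min_len, via regex."""
    pattern = re.compile(f"{base}{{{min_len},}}")
    return [(m.start(), m.end()) for m in pattern.finditer(seq.upper())]


def tolerant_coverage_oracle(
    seq: str, base: str, min_len: int, max_mm: int
) -> np.ndarray:
    """Boolean coverage of all qualifying tolerant windows, by enumeration.

    A window [i, j) qualifies if j - i >= min_len, seq[i] == seq[j-1] == base,
    it contains no N, and at most max_mm non-base characters.  Every
    qualifying window is enumerated and its span marked.
    """
    s = seq.upper()
    n = len(s)
    covered = np.zeros(n, dtype=bool)
    for i in range(n):
        if s[i] != base:
            continue
        mm = 0
        j = i
        while j < n:
            c = s[j]
            if c == "N":
                break
            if c != base:
                mm += 1
                if mm > max_mm:
                    break
            j += 1
            if c == base and j - i >= min_len:
                covered[i:j] = True
    return covered


def quadratic_adjacency_oracle(
    fragments: list[tuple[str, int, int, str]],
    tracts: list[tuple[str, int, int, str, int]],
    distance: int,
) -> dict[int, set[tuple[str, int]]]:
    """All-pairs overlap of tail-extended fragment windows with tracts.

    Returns {fragment index: {(tract base, tract length), ...}}.
    """
    hits: dict[int, set[tuple[str, int]]] = {}
    for fi, (fc, fs, fe, strand) in enumerate(fragments):
        if strand == "+":
            ws, we = fs, fe + distance
        else:
            ws, we = fs - distance, fe
        for tc, ts, te, tb, _ in tracts:
            if tc == fc and ts < we and te > ws:
                hits.setdefault(fi, set()).add((tb, te - ts))
    return hits


def cluster_fraction_oracle(
    keys: list[tuple], min_cluster: int
) -> float:
    """Fraction of items whose key occurs >= min_cluster times (hash tally)."""
    counts = Counter(keys)
    hit = sum(c for c in counts.values() if c >= min_cluster)
    return hit / len(keys)
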