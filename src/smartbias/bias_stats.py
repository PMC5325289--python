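"""Headline bias statistics: fold ratios, normalized enrichment, chi-squared
goodness of fit with Cramér's phi, information content, fragment lengths.

The central comparison: how often do fragment tail ends sit adjacent to poly
dN tracts of each base, relative to how often the genome offers such tracts.
Counts are expressed per million fragments and normalized by the genomic
tract census; the deviation of the observed base distribution from the
census-expected one is summarized by a chi-squared goodness-of-fit statistic,
and — because at sequencing depth any deviation is "significant" — by the
Cramér's phi effect size, phi_c = sqrt(chi2 / (N (k-1))).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_tracts import VALID_BASES, TractCensus, TractInterval
from .read_ends import (
    AdjacencyTable,
    _ensure_frame,
    adjacency_mask,
    tail_ends,
)

STRANDS = ("+", "-")


# ---------------------------------------------------------------------------
# Chi-squared goodness of fit and effect size

def cramers_phi(chi2: float, n: int, k: int) -> float:
    """Cramér's phi effect size for a goodness-of-fit chi-squared.

    phi_c = sqrt(chi2 / (N (k-1))); 0 for a perfect fit, 1 at the
    chi2 = N (k-1) bound.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < 1:
        raise ValueError("N must be >= 1")
    if chi2 < 0:
        raise ValueError("chi2 must be >= 0")
    return math.sqrt(chi2 / (n * (k - 1)))


@dataclass
class GofResult:
    """Chi-squared goodness-of-fit summary with Cramér's phi."""

    chi2: float
    N: int
    k: int
    phi: float
    p_value: float
    dropped_categories: tuple[str, ...] = ()

    @property
    def dof(self) -> int:
        return self.k - 1


def goodness_of_fit(
    observed: Mapping[str, int], expected_weights: Mapping[str, float]
) -> GofResult:
    """GOF of observed category counts against expected proportions.

    ``expected_weights`` need not be normalized (e.g. genomic tract counts).
    Categories with zero expected weight and zero observed count are dropped
    (and recorded); a zero-weight category with observations is an error.
    A zero total observed count yields the degenerate chi2 = 0, phi = 0.
    """
    cats = list(observed)
    dropped = tuple(
        c for c in cats if expected_weights.get(c, 0) == 0 and observed[c] == 0
    )
    for c in cats:
        if expected_weights.get(c, 0) == 0 and observed[c] > 0:
            raise ValueError(f"category {c!r} observed but has zero expected weight")
    cats = [c for c in cats if c not in dropped]
    if len(cats) < 2:
        raise ValueError("need >= 2 categories with expected weight")
    obs = np.array([observed[c] for c in cats], dtype=float)
    w = np.array([expected_weights[c] for c in cats], dtype=float)
    n = obs.sum()
    if n == 0:
        return GofResult(0.0, 0, len(cats), 0.0, 1.0, dropped)
    exp = w / w.sum() * n
    chi2, p = stats.chisquare(obs, f_exp=exp)
    return GofResult(
        float(chi2), int(n), len(cats), cramers_phi(float(chi2), int(n), len(cats)),
        float(p), dropped,
    )


# ---------------------------------------------------------------------------
# Fold-ratio-by-length curve

def fold_ratio_by_length(
    table: AdjacencyTable,
    lengths: Sequence[int],
    cumulative: bool = False,
    low_count: int = 100,
) -> pd.DataFrame:
    """Strand fold ratio of adjacent-fragment counts per base and tract length.

    For T, C and G the forward/reverse count ratio is reported; for A the
    reverse/forward ratio (the bias runs toward poly dT on the forward strand
    and poly dA on the reverse).  ``cumulative`` switches from exact-length to
    >=length counts.  A zero denominator gets a +1 pseudocount on both counts
    and the point is flagged; points whose paired counts sum below
    ``low_count`` are flagged ``sparse`` (their ratio is sampling noise).
    """
    rows = []
    for base in VALID_BASES:
        for ln in lengths:
            if cumulative:
                fwd = table.count_at_least(base, "+", ln)
                rev = table.count_at_least(base, "-", ln)
            else:
                fwd = table.count_exact(base, "+", ln)
                rev = table.count_exact(base, "-", ln)
            num, den = (rev, fwd) if base == "A" else (fwd, rev)
            pseudo = den == 0
            ratio = (num + 1) / (den + 1) if pseudo else num / den
            rows.append(
                {
                    "base": base,
                    "length": ln,
                    "fwd": fwd,
                    "rev": rev,
                    "ratio": ratio,
                    "pseudocount": pseudo,
                    "sparse": (fwd + rev) < low_count,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Census-normalized enrichment

@dataclass
class EnrichmentReport:
    """Per (base, strand) adjacency enrichment, census-normalized, with GOF.

    ``normalized`` is fragments-per-million per genomic tract; it is NaN
    (flagged in ``undefined``) where the census has no tract of that base.
    """

    frame: pd.DataFrame
    gof: dict[str, GofResult]
    min_len: int
    undefined: tuple[tuple[str, str], ...] = ()

    def to_json(self) -> str:
        payload = {
            "min_len": self.min_len,
            "rows": self.frame.to_dict(orient="records"),
            "gof": {
                s: {
                    "chi2": g.chi2,
                    "N": g.N,
                    "k": g.k,
                    "dof": g.dof,
                    "phi": g.phi,
                    "p_value": g.p_value,
                }
                for s, g in self.gof.items()
            },
        }
        return json.dumps(payload, indent=2, allow_nan=True)


def normalized_enrichment(
    table: AdjacencyTable,
    census: TractCensus,
    min_len: int = 12,
    use_coverage: bool = False,
    joint: bool = False,
) -> EnrichmentReport:
    """Adjacent counts per million fragments, normalized by the tract census.

    Per (base, strand): the count of fragments adjacent to tracts of that
    base with length >= ``min_len``, scaled to per-million-fragments, then
    divided by the genomic number of such tracts (or their base-pair coverage
    with ``use_coverage``).  A chi-squared GOF compares the observed 4-base
    count vector per strand (or jointly over 8 base x strand categories with
    ``joint``) against the census-proportional expectation.
    """
    if table.n_fragments == 0:
        raise ValueError("empty adjacency table")
    weight = census.coverage_at_least if use_coverage else census.count_at_least
    rows = []
    undefined = []
    for strand in STRANDS:
        for base in VALID_BASES:
            count = table.count_at_least(base, strand, min_len)
            per_million = count / table.n_fragments * 1e6
            g = weight(base, min_len)
            if g == 0:
                norm = float("nan")
                undefined.append((base, strand))
            else:
                norm = per_million / g
            rows.append(
                {
                    "base": base,
                    "strand": strand,
                    "count": count,
                    "per_million": per_million,
                    "census": g,
                    "normalized": norm,
                }
            )
    frame = pd.DataFrame(rows)
    gof: dict[str, GofResult] = {}
    if joint:
        obs = {
            f"{b}{s}": table.count_at_least(b, s, min_len)
            for s in STRANDS
            for b in VALID_BASES
        }
        wts = {f"{b}{s}": weight(b, min_len) for s in STRANDS for b in VALID_BASES}
        gof["joint"] = goodness_of_fit(obs, wts)
    else:
        for strand in STRANDS:
            obs = {b: table.count_at_least(b, strand, min_len) for b in VALID_BASES}
            wts = {b: weight(b, min_len) for b in VALID_BASES}
            gof[strand] = goodness_of_fit(obs, wts)
    return EnrichmentReport(frame, gof, min_len, tuple(undefined))


# ---------------------------------------------------------------------------
# Information content around read ends

@dataclass
class InfoMatrix:
    """Base frequencies and information content around sampled read ends.

    Positions run -w..w-1 relative to the end coordinate; frequencies are of
    the forward-genome sequence.  ``bits = 2 - H`` with H the Shannon entropy
    (base 2) of the four-base frequency vector.
    """

    freqs: pd.DataFrame  # index: offset, columns A,C,G,T
    bits: pd.Series
    n_used: int
    n_skipped_edge: int

    def to_frame(self) -> pd.DataFrame:
        out = self.freqs.copy()
        out.columns = [f"f{b}" for b in out.columns]
        out["bits"] = self.bits
        return out.reset_index(names="offset")


def column_bits(freqs: np.ndarray) -> np.ndarray:
    """2 - Shannon entropy (bits) per frequency row; rows must sum to 1."""
    f = np.asarray(freqs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(f > 0, f * np.log2(f), 0.0).sum(axis=-1)
    return 2.0 - h


def info_content(
    ends: pd.DataFrame,
    genome: Mapping[str, str],
    w: int = 10,
    sample: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict[str, InfoMatrix]:
    """Per-strand base frequency / information matrix around end coordinates.

    ``ends`` needs columns chrom, pos, strand.  For each strand, up to
    ``sample`` ends are drawn without replacement (all of them when fewer are
    available) and the 2w bp of forward-genome sequence centered on each end
    is tabulated.  Ends within w of a contig edge are skipped and counted.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out: dict[str, InfoMatrix] = {}
    offsets = np.arange(-w, w)
    for strand in STRANDS:
        sub = ends[ends["strand"] == strand]
        if len(sub) == 0:
            continue
        take = min(sample, len(sub))
        pick = sub.iloc[rng.choice(len(sub), size=take, replace=False)]
        counts = np.zeros((2 * w, 4), dtype=np.int64)
        base_idx = {ord(b): i for i, b in enumerate(VALID_BASES)}
        n_used = n_edge = 0
        for chrom, pos in zip(pick["chrom"], pick["pos"]):
            seq = genome[chrom]
            if pos - w < 0 or pos + w > len(seq):
                n_edge += 1
                continue
            window = seq[pos - w : pos + w]
            for j, ch in enumerate(window.upper()):
                i = base_idx.get(ord(ch))
                if i is not None:
                    counts[j, i] += 1
            n_used += 1
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            freqs = np.where(totals > 0, counts / totals, 0.25)
        fdf = pd.DataFrame(freqs, index=offsets, columns=list(VALID_BASES))
        bits = pd.Series(column_bits(freqs), index=offsets, name="bits")
        out[strand] = InfoMatrix(fdf, bits, n_used, n_edge)
    return out


def tail_end_table(fragments) -> pd.DataFrame:
    """chrom/pos/strand frame of tail-end coordinates, for info_content."""
    df = _ensure_frame(fragments)
    return pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "pos": tail_ends(df),
            "strand": df["strand"].to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# Fragment-length comparison

def fragment_length_compare(
    fragments,
    tracts: Sequence[TractInterval],
    distance: int = 1,
    min_len: int = 12,
) -> tuple[float, float, float, float]:
    """Welch t-test of fragment lengths, split by tail-end tract adjacency.

    Internal priming truncates fragments at the genomic run, so fragments
    whose tail ends abut poly dA/dT tracts are expected to be shorter.
    Returns (mean_adjacent, mean_other, t, p).  Two constant equal groups
    (zero pooled variance) return t = 0, p = 1.
    """
    df = _ensure_frame(fragments)
    at_tracts = [t for t in tracts if t.base in ("A", "T") and t.length >= min_len]
    mask = adjacency_mask(df, at_tracts, distance=distance)
    lengths = (df["end"] - df["start"]).to_numpy(float)
    adj, other = lengths[mask], lengths[~mask]
    if len(adj) < 2:
        raise ValueError("adjacent group has < 2 fragments")
    if len(other) < 2:
        raise ValueError("non-adjacent group has < 2 fragments")
    if np.var(adj) == 0 and np.var(other) == 0:
        if adj.mean() == other.mean():
            return float(adj.mean()), float(other.mean()), 0.0, 1.0
    t, p = stats.ttest_ind(adj, other, equal_var=False)
    return float(adj.mean()), float(other.mean()), float(t), float(p)
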