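"""Synthetic genomes and SMART/ligation libraries with exact truth labels.

The generator produces (i) a genome whose only long homopolymer runs are
planted at known positions — the background is resampled so no accidental
run reaches 8 bp — with the planting skewed so poly dA/dT tracts outnumber
poly dC/dG roughly 100:1, as in the human genome; and (ii) sequencing
libraries over that genome.  The SMART library emulates the internal-priming
mechanism: with probability ``p_internal`` a fragment is captured at a
genomic poly dT run (tail orientation) of length >= ``l_prime`` instead of
at its TdT-appended tail, parking its tail end against the run's 5' edge and
truncating the fragment.  A ligation library is the same process with the
mechanism switched off, i.e. the unbiased negative control.

Every stochastic decision is recorded in a truth table, so adjacency
fractions, fold ratios, filter recall and fragment-length effects can all be
checked against planted ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome_tracts import VALID_BASES, TractInterval
from .read_ends import FRAGMENT_COLUMNS

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome and libraries.

    Defaults: a 1 Mb uniform-composition genome; planted tract rates per Mb
    of A:330, T:330, C:3.3, G:3.3 (the ~100:1 A/T vs C/G genomic skew);
    planted lengths 8 + geometric so tracts >= 12 are well represented;
    sonication-like fragment lengths ~ Normal(220, 60) truncated at the read
    length; 2 x 50 bp reads; internal priming at poly dT runs >= 12,
    truncating fragments by ~40 bp.
    """

    genome_length: int = 1_000_000
    base_comp: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    tracts_per_mb: Mapping[str, float] = field(
        default_factory=lambda: {"A": 330.0, "C": 3.3, "G": 3.3, "T": 330.0}
    )
    tract_len_min: int = 8
    tract_len_geom_p: float = 0.35
    tract_len_max: int = 30
    frag_len_mean: float = 220.0
    frag_len_sd: float = 60.0
    read_len: int = 50
    n_fragments: int = 100_000
    p_internal: float = 0.0
    l_prime: int = 12
    internal_shorten: int = 40
    p_gap: float = 0.0
    edge_margin: int = 2000
    chrom_name: str = "chr1"

    def __post_init__(self) -> None:
        if not 0 <= self.p_internal <= 1:
            raise ValueError("p_internal must be in [0, 1]")
        if not 0 <= self.p_gap <= 1:
            raise ValueError("p_gap must be in [0, 1]")
        if abs(sum(self.base_comp) - 1) > 1e-9:
            raise ValueError("base_comp must sum to 1")
        if self.genome_length < 10 * self.frag_len_mean:
            raise ValueError("genome_length must dwarf the mean fragment length")
        if self.tract_len_min < 1 or self.tract_len_max < self.tract_len_min:
            raise ValueError("invalid planted tract length range")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Genome generation

def _run_boundaries(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Starts and ends of maximal equal-character runs."""
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [arr.size]))
    return starts, ends

def _replacement_base(arr: np.ndarray, pos: int, rng: np.random.Generator) -> int:
    """A base differing from arr[pos] and both neighbors (no run can form or grow)."""
    excluded = {int(arr[pos])}
    if pos > 0:
        excluded.add(int(arr[pos - 1]))
    if pos < arr.size - 1:
        excluded.add(int(arr[pos + 1]))
    choices = [b for b in range(4) if b not in excluded]
    return int(choices[rng.integers(len(choices))])


def _break_long_runs(
    arr: np.ndarray,
    rng: np.random.Generator,
    max_run: int,
    protect: set[tuple[int, int]] | None = None,
) -> None:
    """Resample characters so no unprotected run exceeds ``max_run``.

    ``protect`` holds (start, end) spans of planted tracts, which are left
    intact.  Replacements always differ from both neighbors, so a single
    sweep cannot create new long runs; the loop is defensive.
    """
    protect = protect or set()
    for _ in range(20):
        starts, ends = _run_boundaries(arr)
        lens = ends - starts
        offending = [
            (int(s), int(e))
            for s, e in zip(starts[lens > max_run], ends[lens > max_run])
            if (int(s), int(e)) not in protect
        ]
        if not offending:
            return
        for s, e in offending:
            for p in range(s + max_run, e, max_run + 1):
                arr[p] = _replacement_base(arr, p, rng)
    raise RuntimeError("failed to break long background runs")


def make_genome(
    config: SimConfig, seed: int | np.random.Generator = 0
) -> tuple[dict[str, str], list[TractInterval]]:
    """Generate a genome with planted homopolymer tracts and its truth list.

    The background is i.i.d. at ``base_comp`` with every accidental run of
    >= 8 bp broken by resampling, so scanning the output recovers exactly the
    planted tracts at lengths >= 8.  Planted tracts are flanked by a
    different base (maximality) and kept ``edge_margin`` away from contig
    ends so simulated fragments anchored at them stay on the contig.
    """
    rng = _rng(seed)
    G = config.genome_length
    arr = rng.choice(4, size=G, p=list(config.base_comp)).astype(np.uint8)
    _break_long_runs(arr, rng, config.tract_len_min - 1)

    # plan non-overlapping placements (1 bp flank gap between planted spans)
    n_per_base = {
        b: int(round(config.tracts_per_mb.get(b, 0.0) * G / 1e6)) for b in VALID_BASES
    }
    todo: list[tuple[str, int]] = []
    for b in VALID_BASES:
        raw = config.tract_len_min + rng.geometric(
            config.tract_len_geom_p, size=n_per_base[b]
        ) - 1
        for ln in np.minimum(raw, config.tract_len_max):
            todo.append((b, int(ln)))
    order = rng.permutation(len(todo))

    import bisect

    placed_starts: list[int] = []
    placed_ends: list[int] = []
    truth: list[TractInterval] = []
    lo_limit = max(config.edge_margin, 1)
    for i in order:
        base, ln = todo[i]
        hi_limit = G - config.edge_margin - ln
        if hi_limit <= lo_limit:
            raise ValueError("genome too small for planted tract placement")
        for _ in range(200):
            s = int(rng.integers(lo_limit, hi_limit))
            e = s + ln
            j = bisect.bisect_left(placed_starts, s)
            ok = (j == 0 or placed_ends[j - 1] + 2 <= s) and (
                j == len(placed_starts) or e + 2 <= placed_starts[j]
            )
            if ok:
                placed_starts.insert(j, s)
                placed_ends.insert(j, e)
                truth.append(TractInterval(config.chrom_name, s, e, base, 0))
                break
        else:
            raise ValueError("infeasible planting density: no room for tracts")

    base_to_idx = {b: i for i, b in enumerate(VALID_BASES)}
    for t in truth:
        arr[t.start : t.end] = base_to_idx[t.base]
    for t in truth:  # flanks: maximality without seeding new runs
        for p in (t.start - 1, t.end):
            if 0 <= p < G:
                arr[p] = _replacement_base_excluding(
                    arr, p, base_to_idx[t.base], rng
                )

    protect = {(t.start, t.end) for t in truth}
    _break_long_runs(arr, rng, config.tract_len_min - 1, protect=protect)

    seq = _BASE_BYTES[arr].tobytes().decode("ascii")
    truth.sort()
    return {config.chrom_name: seq}, truth


def _replacement_base_excluding(
    arr: np.ndarray, pos: int, tract_base: int, rng: np.random.Generator
) -> int:
    excluded = {tract_base}
    if pos > 0:
        excluded.add(int(arr[pos - 1]))
    if pos < arr.size - 1:
        excluded.add(int(arr[pos + 1]))
    choices = [b for b in range(4) if b not in excluded]
    return int(choices[rng.integers(len(choices))])


# ---------------------------------------------------------------------------
# Library simulation

TRUTH_COLUMNS = [
    "primed_internally",
    "tract_start",
    "tract_end",
    "tract_base",
    "orig_start",
    "orig_end",
]


def simulate_smart_library(
    genome: Mapping[str, str],
    truth_tracts: Sequence[TractInterval],
    config: SimConfig,
    seed: int | np.random.Generator = 0,
    p_internal: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a SMART (template-switching) paired-end library.

    Fragments are drawn uniformly on both strands with Normal(mean, sd)
    lengths truncated to [read_len, mean + 5 sd].  With probability
    ``p_internal`` a fragment is instead captured at a genomic run in tail
    orientation — a poly dT tract (length >= l_prime) for '+' fragments, a
    poly dA tract for '-' — chosen uniformly among qualifying tracts: its
    tail end is placed against the run's 5' edge and its length is the drawn
    length minus ``internal_shorten`` (never below read_len), modeling the
    truncation the priming imposes.  Returns (fragments, truth) frames;
    truth records the priming decision, tract, and pre-truncation span.
    """
    rng = _rng(seed)
    if p_internal is None:
        p_internal = config.p_internal
    chroms = list(genome)
    clens = np.array([len(genome[c]) for c in chroms], dtype=np.int64)
    n = config.n_fragments
    rl = config.read_len

    L = np.clip(
        np.rint(rng.normal(config.frag_len_mean, config.frag_len_sd, n)),
        rl,
        config.frag_len_mean + 5 * config.frag_len_sd,
    ).astype(np.int64)
    fwd = rng.random(n) < 0.5
    internal = rng.random(n) < p_internal

    qual = {
        "+": [t for t in truth_tracts if t.base == "T" and t.length >= config.l_prime],
        "-": [t for t in truth_tracts if t.base == "A" and t.length >= config.l_prime],
    }
    for strand, ts in qual.items():
        if p_internal > 0 and not ts:
            warnings.warn(
                f"no qualifying poly d{'T' if strand == '+' else 'A'} runs "
                f">= {config.l_prime}; internal priming inert on {strand} strand"
            )
            internal[fwd if strand == "+" else ~fwd] = False

    chrom_idx = rng.choice(len(chroms), size=n, p=clens / clens.sum())
    start = np.zeros(n, dtype=np.int64)
    end = np.zeros(n, dtype=np.int64)
    orig_start = np.zeros(n, dtype=np.int64)
    orig_end = np.zeros(n, dtype=np.int64)
    tract_start = np.full(n, -1, dtype=np.int64)
    tract_end = np.full(n, -1, dtype=np.int64)
    tract_base = np.full(n, "", dtype=object)

    # uniform (tail-primed) placement
    uni = ~internal
    cl = clens[chrom_idx[uni]]
    L_u = np.minimum(L[uni], cl)
    s_u = np.floor(rng.random(uni.sum()) * (cl - L_u + 1)).astype(np.int64)
    start[uni] = s_u
    end[uni] = s_u + L_u
    orig_start[uni] = s_u
    orig_end[uni] = s_u + L_u

    chrom_pos = {c: i for i, c in enumerate(chroms)}
    for strand, is_strand in (("+", fwd), ("-", ~fwd)):
        sel = internal & is_strand
        m = int(sel.sum())
        if m == 0:
            continue
        ts = qual[strand]
        pick = rng.integers(0, len(ts), size=m)
        t_s = np.array([ts[i].start for i in pick], dtype=np.int64)
        t_e = np.array([ts[i].end for i in pick], dtype=np.int64)
        t_chrom = np.array([chrom_pos[ts[i].chrom] for i in pick], dtype=np.int64)
        Lt = np.maximum(L[sel] - config.internal_shorten, rl)
        if strand == "+":
            e = t_s  # tail end abuts the run's 5' edge
            s = np.maximum(e - Lt, 0)
            bad = (e - s) < rl
            o_s, o_e = s, s + L[sel]
        else:
            s = t_e  # reverse-strand tail end; run is poly dA upstream
            e = np.minimum(s + Lt, clens[t_chrom])
            bad = (e - s) < rl
            o_s, o_e = e - L[sel], e
        if bad.any():  # tract too close to a contig edge: fall back to uniform
            idx = np.flatnonzero(sel)[bad]
            internal[idx] = False
            cl = clens[chrom_idx[idx]]
            L_b = np.minimum(L[idx], cl)
            s_b = np.floor(rng.random(len(idx)) * (cl - L_b + 1)).astype(np.int64)
            start[idx], end[idx] = s_b, s_b + L_b
            orig_start[idx], orig_end[idx] = s_b, s_b + L_b
        good = ~bad
        idx = np.flatnonzero(sel)[good]
        start[idx], end[idx] = s[good], e[good]
        orig_start[idx], orig_end[idx] = o_s[good], o_e[good]
        chrom_idx[idx] = t_chrom[good]
        tract_start[idx], tract_end[idx] = t_s[good], t_e[good]
        tract_base[idx] = "T" if strand == "+" else "A"

    has_gap = rng.random(n) < config.p_gap
    fragments = pd.DataFrame(
        {
            "chrom": np.array(chroms, dtype=object)[chrom_idx],
            "start": start,
            "end": end,
            "strand": np.where(fwd, "+", "-"),
            "paired": True,
            "has_gap": has_gap,
        }
    )
    truth = pd.DataFrame(
        {
            "primed_internally": internal,
            "tract_start": tract_start,
            "tract_end": tract_end,
            "tract_base": tract_base,
            "orig_start": orig_start,
            "orig_end": orig_end,
        }
    )
    return fragments, truth


def simulate_ligation_library(
    genome: Mapping[str, str],
    config: SimConfig,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unbiased (ligation-style) library: same process, no internal priming."""
    return simulate_smart_library(genome, [], config, seed=seed, p_internal=0.0)


# ---------------------------------------------------------------------------
# SAM emission

def write_fragments_sam(
    fragments: pd.DataFrame,
    genome: Mapping[str, str],
    read_len: int,
    path: str | Path,
) -> None:
    """Write fragments as coordinate-sorted paired-end SAM records.

    Each fragment yields a proper pair of ``read_len`` reads from its two
    ends; a fragment flagged ``has_gap`` carries a 1 bp deletion in its
    second read's CIGAR (for gap-diagnostic round trips).  Sequences are
    taken from the genome, error-free.
    """
    chroms = list(genome)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    segs = []
    gap_col = (
        fragments["has_gap"]
        if "has_gap" in fragments
        else pd.Series(False, index=fragments.index)
    )
    for i, (chrom, s, e, strand, gap) in enumerate(
        zip(
            fragments["chrom"],
            fragments["start"],
            fragments["end"],
            fragments["strand"],
            gap_col,
        )
    ):
        s, e = int(s), int(e)
        seq = genome[chrom]
        rl = min(read_len, e - s)
        left_seq = seq[s : s + rl]
        right_seq = seq[e - rl : e]
        if strand == "+":
            r1 = (s, False, 0x63, left_seq)  # 99: paired,proper,mate rev,first
            r2 = (e - rl, True, 0x93, right_seq)  # 147
        else:
            r1 = (e - rl, True, 0x53, right_seq)  # 83
            r2 = (s, False, 0xA3, left_seq)  # 163
        for mate, (pos, rev, flag, rseq) in enumerate((r1, r2)):
            a = pysam.AlignedSegment()
            a.query_name = f"frag{i}"
            a.flag = flag
            a.reference_id = tid[chrom]
            a.reference_start = pos
            a.mapping_quality = 42
            if gap and mate == 1 and rl > 2:
                half = rl // 2
                a.cigarstring = f"{half}M1D{rl - half}M"
            else:
                a.cigarstring = f"{rl}M"
            a.query_sequence = rseq
            a.next_reference_id = tid[chrom]
            a.next_reference_start = r2[0] if mate == 0 else r1[0]
            a.template_length = (e - s) if not rev else -(e - s)
            segs.append(a)
    segs.sort(key=lambda a: (a.reference_id, a.reference_start))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for a in segs:
            out.write(a)
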