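"""Fragment ingestion, hygiene filters, and read-end / tract adjacency.

A sequenced fragment is reduced to its outer genomic span plus strand.  The
end where the poly dT tail was appended during library prep (the 3' end of
the captured molecule, sequenced by the second read) is the *tail end*: for a
``+`` fragment it is the rightmost coordinate, for a ``-`` fragment the
leftmost.  The bias signature of template-switching libraries is an excess of
tail ends sitting immediately 5' of genomic poly dT (forward strand) or poly
dA (reverse strand) runs.

Fragment collections are plain pandas DataFrames with columns
``chrom, start, end, strand`` (optionally ``paired`` and ``has_gap``), so
million-fragment libraries stay vectorized; :class:`FragmentRecord` is the
single-record view.

Adjacency follows ``bedtools window`` arithmetic: a ``+`` fragment is counted
for a tract iff the tract overlaps ``[start, end + distance)``, a ``-``
fragment iff the tract overlaps ``[start - distance, end)`` (half-open
overlap, i.e. at the default ``distance=1`` a tract beginning at the base
immediately after the tail end counts, as does any tract overlapping the
fragment body).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome_tracts import VALID_BASES, TractInterval

FRAGMENT_COLUMNS = ["chrom", "start", "end", "strand"]


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced fragment: outer span, strand, and derived ends."""

    chrom: str
    start: int
    end: int
    strand: str
    paired: bool = True
    has_gap: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty fragment [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def tail_end(self) -> int:
        """Coordinate of the tailed (second-read 3') end."""
        return self.end if self.strand == "+" else self.start

    @property
    def first_end(self) -> int:
        """Coordinate of the opposite (first-read 5') end."""
        return self.start if self.strand == "+" else self.end


def fragments_to_frame(records: Iterable[FragmentRecord]) -> pd.DataFrame:
    rows = [
        (r.chrom, r.start, r.end, r.strand, r.paired, r.has_gap) for r in records
    ]
    return pd.DataFrame(
        rows, columns=FRAGMENT_COLUMNS + ["paired", "has_gap"]
    ).astype({"start": np.int64, "end": np.int64})


def frame_to_fragments(df: pd.DataFrame) -> list[FragmentRecord]:
    paired = df["paired"] if "paired" in df else pd.Series(True, index=df.index)
    gap = df["has_gap"] if "has_gap" in df else pd.Series(False, index=df.index)
    return [
        FragmentRecord(c, int(s), int(e), st, bool(p), bool(g))
        for c, s, e, st, p, g in zip(
            df["chrom"], df["start"], df["end"], df["strand"], paired, gap
        )
    ]


def _ensure_frame(fragments) -> pd.DataFrame:
    if isinstance(fragments, pd.DataFrame):
        return fragments
    return fragments_to_frame(fragments)


def tail_ends(df: pd.DataFrame) -> np.ndarray:
    """Vectorized tail-end coordinate: ``end`` for '+', ``start`` for '-'."""
    return np.where(df["strand"].to_numpy() == "+", df["end"], df["start"])


def first_ends(df: pd.DataFrame) -> np.ndarray:
    return np.where(df["strand"].to_numpy() == "+", df["start"], df["end"])


# ---------------------------------------------------------------------------
# Loading

def load_fragments(
    path: str | Path,
    mode: Literal["paired", "single"] = "paired",
    mapq_min: int = 10,
) -> pd.DataFrame:
    """Load aligned fragments from SAM/BAM or BED6 into a fragment frame.

    SAM/BAM: unmapped, secondary, supplementary and low-MAPQ (multi-mapping
    proxy) alignments are excluded.  In paired mode each proper pair yields
    one fragment spanning the outer coordinates, with strand taken from read
    1's orientation; pairs whose mate information is unusable are skipped and
    counted in the frame's ``.attrs['n_skipped']``.  In single mode every
    primary read becomes a fragment covering its own span.

    BED input must carry the 6th (strand) column.
    """
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bedpe", ".tsv", ".txt"):
        return _load_bed(path)
    return _load_alignments(path, mode=mode, mapq_min=mapq_min)


def _load_bed(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BED fragment input requires a strand column (BED6)")
    df = df.iloc[:, [0, 1, 2, 5]]
    df.columns = FRAGMENT_COLUMNS
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError(f"{path}: strand column must be '+'/'-'")
    return df.astype({"start": np.int64, "end": np.int64})


def _load_alignments(path: Path, mode: str, mapq_min: int) -> pd.DataFrame:
    sam_mode = "rb" if path.suffix.lower() == ".bam" else "r"
    rows = []
    n_skipped = 0
    with pysam.AlignmentFile(str(path), sam_mode, check_sq=False) as fh:
        so = fh.header.to_dict().get("HD", {}).get("SO")
        if path.suffix.lower() == ".bam" and so not in (None, "coordinate"):
            raise ValueError(
                f"{path}: BAM is not coordinate-sorted (SO={so}); "
                "run `samtools sort` first"
            )
        for r in fh:
            if r.is_unmapped or r.is_secondary or r.is_supplementary:
                continue
            if r.mapping_quality < mapq_min:
                continue
            gap = any(op in (1, 2) for op, _ in (r.cigartuples or []))
            if mode == "single":
                rows.append(
                    (
                        r.reference_name,
                        r.reference_start,
                        r.reference_end,
                        "-" if r.is_reverse else "+",
                        False,
                        gap,
                    )
                )
                continue
            # paired mode: one fragment per proper pair, anchored on read 1
            if not r.is_read1:
                continue
            if not r.is_proper_pair or r.mate_is_unmapped or r.template_length == 0:
                n_skipped += 1
                continue
            tlen = r.template_length
            if r.is_reverse:
                end = r.reference_end
                start = end - abs(tlen)
                strand = "-"
            else:
                start = r.reference_start
                end = start + abs(tlen)
                strand = "+"
            if end <= start:
                n_skipped += 1
                continue
            rows.append((r.reference_name, start, end, strand, True, gap))
    df = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS + ["paired", "has_gap"])
    if not df.empty:
        df = df.astype({"start": np.int64, "end": np.int64})
    df.attrs["n_skipped"] = n_skipped
    return df


def fragments_to_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write fragments as BED6 (name = pair index, score 0)."""
    out = df[FRAGMENT_COLUMNS].copy()
    out.insert(3, "name", [f"frag{i}" for i in range(len(out))])
    out.insert(4, "score", 0)
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Hygiene filters

def dedup_and_cap(
    fragments,
    max_per_position: int = 100,
    per_strand: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Exact-duplicate removal, then the repetitive-position cap.

    Duplicates share (chrom, start, end, strand).  After deduplication, every
    fragment whose tail-end coordinate hosts *more than* ``max_per_position``
    fragment ends is removed (exactly ``max_per_position`` at one position are
    kept) — such pile-ups typically mark repetitive sequence.  ``per_strand``
    keys the cap by (chrom, position, strand) instead of (chrom, position).
    """
    df = _ensure_frame(fragments)
    n_input = len(df)
    df = df.drop_duplicates(subset=FRAGMENT_COLUMNS, keep="first")
    n_dup = n_input - len(df)

    te = tail_ends(df)
    keys = [df["chrom"].to_numpy(), te]
    if per_strand:
        keys.append(df["strand"].to_numpy())
    mi = pd.MultiIndex.from_arrays(keys)
    sizes = pd.Series(1, index=mi).groupby(level=list(range(len(keys)))).transform("size")
    over = sizes.to_numpy() > max_per_position
    capped_positions = sorted(set(mi[over]))
    kept = df.loc[~over].reset_index(drop=True)
    report = {
        "n_input": n_input,
        "n_duplicates_removed": n_dup,
        "n_capped_removed": int(over.sum()),
        "n_kept": len(kept),
        "capped_positions": capped_positions,
    }
    return kept, report


# ---------------------------------------------------------------------------
# Adjacency

class _TractIndex:
    """Per (chrom, base) sorted interval arrays for stabbing queries.

    Tracts of one base are disjoint (maximal runs / merged tolerant windows),
    so both starts and ends are sorted and a window query reduces to two
    ``searchsorted`` calls.
    """

    def __init__(self, tracts: Iterable[TractInterval]):
        by_key: dict[tuple[str, str], list[TractInterval]] = {}
        for t in tracts:
            by_key.setdefault((t.chrom, t.base), []).append(t)
        self.arrays: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for key, ts in by_key.items():
            ts.sort()
            starts = np.array([t.start for t in ts], dtype=np.int64)
            ends = np.array([t.end for t in ts], dtype=np.int64)
            lengths = ends - starts
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"tracts of base {key[1]} on {key[0]} overlap")
            self.arrays[key] = (starts, ends, lengths)

    def chroms(self) -> set[str]:
        return {c for c, _ in self.arrays}

    def query(
        self, chrom: str, base: str, ws: np.ndarray, we: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray, np.ndarray] | None]:
        """For query windows [ws, we): index ranges [lo, hi) of overlapping tracts."""
        arrs = self.arrays.get((chrom, base))
        if arrs is None:
            z = np.zeros(len(ws), dtype=np.int64)
            return z, z, None
        starts, ends, _ = arrs
        lo = np.searchsorted(ends, ws, side="right")
        hi = np.searchsorted(starts, we, side="left")
        return lo, hi, arrs


@dataclass
class AdjacencyTable:
    """Counts of fragments adjacent to tracts, by base, strand and tract length.

    ``exact[(base, strand, L)]`` counts fragments adjacent to at least one
    tract of exactly length L (a fragment adjacent to a 12-mer and a 15-mer
    contributes to both, matching per-length-subset ``bedtools window -u``
    runs).  ``by_max_len`` buckets each fragment once per base, by the length
    of the longest tract it is adjacent to, so cumulative counts never double
    count: ``count_at_least`` sums those buckets.
    """

    exact: dict[tuple[str, str, int], int] = field(default_factory=dict)
    by_max_len: dict[tuple[str, str, int], int] = field(default_factory=dict)
    n_fragments: int = 0
    n_fwd: int = 0
    n_rev: int = 0
    distance: int = 1
    end: str = "tail"

    def count_exact(self, base: str, strand: str, length: int) -> int:
        return self.exact.get((base, strand, length), 0)

    def count_at_least(self, base: str, strand: str, min_len: int) -> int:
        return sum(
            c
            for (b, s, ln), c in self.by_max_len.items()
            if b == base and s == strand and ln >= min_len
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"base": b, "strand": s, "tract_len": ln, "count": c,
             "total": self.n_fragments}
            for (b, s, ln), c in sorted(self.exact.items())
        ]
        return pd.DataFrame(rows)


def _query_windows(
    df: pd.DataFrame, distance: int, end: str
) -> tuple[np.ndarray, np.ndarray]:
    """Window [ws, we) per fragment, extended ``distance`` toward the tail side.

    ``end='tail'``: the full fragment span extended by ``distance`` on the
    tail side (bedtools window -r d / -l d semantics per strand).
    ``end='first'``: a window anchored at the first-read end and reaching
    ``distance`` bases toward the tail side — the vicinity mode used for
    single-end data, where the priming site lies downstream of read 1.
    """
    start = df["start"].to_numpy(np.int64)
    stop = df["end"].to_numpy(np.int64)
    fwd = df["strand"].to_numpy() == "+"
    if end == "tail":
        ws = np.where(fwd, start, start - distance)
        we = np.where(fwd, stop + distance, stop)
    elif end == "first":
        fe = np.where(fwd, start, stop)
        ws = np.where(fwd, fe, fe - distance)
        we = np.where(fwd, fe + distance, fe)
    else:
        raise ValueError("end must be 'tail' or 'first'")
    return ws, we


def adjacent_fragments(
    fragments,
    tracts: Sequence[TractInterval],
    distance: int = 1,
    end: Literal["tail", "first"] = "tail",
    chrom_whitelist: set[str] | None = None,
) -> AdjacencyTable:
    """Count fragments whose tail-side window overlaps homopolymer tracts.

    Tracts on chromosomes absent from the fragment frame are ignored.  Each
    fragment is counted at most once per (base, exact tract length) and once
    per base in the cumulative buckets.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    df = _ensure_frame(fragments)
    index = _TractIndex(tracts)
    table = AdjacencyTable(
        n_fragments=len(df),
        n_fwd=int((df["strand"] == "+").sum()),
        n_rev=int((df["strand"] == "-").sum()),
        distance=distance,
        end=end,
    )
    if df.empty:
        return table
    ws_all, we_all = _query_windows(df, distance, end)
    strands = df["strand"].to_numpy()
    chrom_arr = df["chrom"].to_numpy()
    for chrom in pd.unique(df["chrom"]):
        sel = chrom_arr == chrom
        ws, we, st = ws_all[sel], we_all[sel], strands[sel]
        for base in VALID_BASES:
            lo, hi, arrs = index.query(chrom, base, ws, we)
            if arrs is None:
                continue
            lengths = arrs[2]
            matched = np.flatnonzero(hi > lo)
            for i in matched:
                lens = lengths[lo[i] : hi[i]]
                s = st[i]
                for ln in np.unique(lens):
                    key = (base, s, int(ln))
                    table.exact[key] = table.exact.get(key, 0) + 1
                kmax = (base, s, int(lens.max()))
                table.by_max_len[kmax] = table.by_max_len.get(kmax, 0) + 1
    return table


def adjacency_mask(
    fragments,
    tracts: Sequence[TractInterval],
    distance: int = 1,
    end: str = "tail",
    strand_base: Mapping[str, Sequence[str]] | None = None,
) -> np.ndarray:
    """Boolean mask: fragment's tail-side window overlaps a qualifying tract.

    ``strand_base`` maps fragment strand to the tract bases that count for it
    (default: the bias-mechanism pairing ``{'+': ['T'], '-': ['A']}``).
    """
    if strand_base is None:
        strand_base = {"+": ["T"], "-": ["A"]}
    df = _ensure_frame(fragments)
    mask = np.zeros(len(df), dtype=bool)
    if df.empty:
        return mask
    index = _TractIndex(tracts)
    ws_all, we_all = _query_windows(df, distance, end)
    chrom_arr = df["chrom"].to_numpy()
    strand_arr = df["strand"].to_numpy()
    for chrom in pd.unique(df["chrom"]):
        csel = chrom_arr == chrom
        for strand, bases in strand_base.items():
            sel = csel & (strand_arr == strand)
            if not sel.any():
                continue
            idx = np.flatnonzero(sel)
            ws, we = ws_all[idx], we_all[idx]
            hit = np.zeros(len(idx), dtype=bool)
            for base in bases:
                lo, hi, arrs = index.query(chrom, base, ws, we)
                if arrs is not None:
                    hit |= hi > lo
            mask[idx] |= hit
    return mask


# ---------------------------------------------------------------------------
# Cluster and gap diagnostics

def end_position_clusters(
    fragments, min_cluster: int = 5, per_strand: bool = True
) -> tuple[float, pd.DataFrame]:
    """Fraction of fragments whose tail end coincides with >= min_cluster others.

    Pile-ups of tail ends at a single genomic coordinate are the fingerprint
    of priming at a fixed genomic tract.  Returns the fraction and a frame of
    cluster positions with their counts.
    """
    if min_cluster < 2:
        raise ValueError("min_cluster must be >= 2")
    df = _ensure_frame(fragments)
    if df.empty:
        raise ValueError("cluster fraction undefined for empty input")
    key = pd.DataFrame({"chrom": df["chrom"].to_numpy(), "pos": tail_ends(df)})
    if per_strand:
        key["strand"] = df["strand"].to_numpy()
    sizes = key.groupby(list(key.columns), sort=False).size()
    clustered = sizes[sizes >= min_cluster]
    fraction = float(clustered.sum()) / len(df)
    positions = clustered.rename("count").reset_index()
    return fraction, positions


def gapped_fraction(alignments: str | Path) -> float:
    """Fraction of primary alignments whose CIGAR contains an indel (I or D)."""
    path = Path(alignments)
    if path.suffix.lower() in (".bed", ".bedpe"):
        raise ValueError("gapped_fraction requires SAM/BAM input (CIGAR needed)")
    sam_mode = "rb" if path.suffix.lower() == ".bam" else "r"
    n = n_gap = 0
    with pysam.AlignmentFile(str(path), sam_mode, check_sq=False) as fh:
        for r in fh:
            if r.is_unmapped or r.is_secondary or r.is_supplementary:
                continue
            n += 1
            if any(op in (1, 2) for op, _ in (r.cigartuples or [])):
                n_gap += 1
    if n == 0:
        raise ValueError("no primary alignments found")
    return n_gap / n
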