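"""Fragment loading, hygiene filters, adjacency semantics, cluster diagnostics."""

import numpy as np
import pandas as pd
import pysam
import pytest

from smartbias import (
    TractInterval,
    adjacent_fragments,
    adjacency_mask,
    dedup_and_cap,
    end_position_clusters,
    gapped_fraction,
    load_fragments,
    simulate_smart_library,
    tail_ends,
    write_fragments_sam,
)

from .oracles import cluster_fraction_oracle, quadratic_adjacency_oracle


def frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


# ---------------------------------------------------------------------------
# Loading

def _write_sam(path, records, chrom="chr1", length=10_000):
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": length}]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for name, flag, pos, cigar, pnext, tlen in records:
            a = pysam.AlignedSegment()
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 42
            a.cigarstring = cigar
            a.next_reference_id = 0
            a.next_reference_start = pnext
            a.template_length = tlen
            a.query_sequence = "A" * 50
            out.write(a)


class TestLoadFragments:
    def test_forward_pair_outer_span(self, tmp_path):
        """read1 + at [100,150), read2 - at [250,300) -> fragment [100,300), +."""
        sam = tmp_path / "p.sam"
        _write_sam(sam, [
            ("p", 99, 100, "50M", 250, 200),
            ("p", 147, 250, "50M", 100, -200),
        ])
        df = load_fragments(sam)
        assert df[["start", "end", "strand"]].iloc[0].tolist() == [100, 300, "+"]
        assert tail_ends(df).tolist() == [300]

    def test_reverse_pair_mirrored(self, tmp_path):
        """read1 - at [250,300), read2 + at [100,150) -> fragment [100,300), -."""
        sam = tmp_path / "p.sam"
        _write_sam(sam, [
            ("p", 163, 100, "50M", 250, 200),
            ("p", 83, 250, "50M", 100, -200),
        ])
        df = load_fragments(sam)
        assert df[["start", "end", "strand"]].iloc[0].tolist() == [100, 300, "-"]
        assert tail_ends(df).tolist() == [100]

    def test_secondary_and_low_mapq_excluded(self, tmp_path):
        sam = tmp_path / "s.sam"
        recs = []
        for i in range(9):
            recs.append((f"r{i}", 99, 100 + i, "50M", 300 + i, 250))
            recs.append((f"r{i}", 147, 300 + i, "50M", 100 + i, -250))
        recs.append(("r0", 99 | 256, 700, "50M", 900, 250))  # secondary
        _write_sam(sam, sorted(recs, key=lambda r: r[2]))
        df = load_fragments(sam)
        assert len(df) == 9

    def test_single_mode_uses_read_span(self, tmp_path):
        sam = tmp_path / "se.sam"
        _write_sam(sam, [("r", 16, 100, "50M", -1, 0)])
        df = load_fragments(sam, mode="single")
        assert df[["start", "end", "strand"]].iloc[0].tolist() == [100, 150, "-"]

    def test_bed_requires_strand_column(self, tmp_path):
        bad = tmp_path / "x.bed"
        bad.write_text("chr1\t0\t100\n")
        with pytest.raises(ValueError, match="strand"):
            load_fragments(bad)


# ---------------------------------------------------------------------------
# Hygiene

class TestDedupAndCap:
    def test_exact_duplicates_collapsed(self):
        df = frame([("chr1", 10, 200, "+")] * 3)
        kept, report = dedup_and_cap(df)
        assert len(kept) == 1
        assert report["n_duplicates_removed"] == 2

    def test_over_cap_position_removed_entirely(self):
        """150 distinct fragments sharing a tail end are all removed (>100 rule)."""
        df = frame([("chr1", 10 + i, 500, "+") for i in range(150)])
        kept, report = dedup_and_cap(df, max_per_position=100)
        assert len(kept) == 0
        assert report["n_capped_removed"] == 150
        assert report["capped_positions"] == [("chr1", 500)]

    def test_exactly_at_cap_kept(self):
        df = frame([("chr1", 10 + i, 500, "+") for i in range(100)])
        kept, _ = dedup_and_cap(df, max_per_position=100)
        assert len(kept) == 100

    def test_identity_when_clean(self):
        df = frame([("chr1", i * 10, i * 10 + 100, "+") for i in range(20)])
        kept, report = dedup_and_cap(df)
        pd.testing.assert_frame_equal(kept, df)
        assert report["n_duplicates_removed"] == 0
        assert report["n_capped_removed"] == 0


# ---------------------------------------------------------------------------
# Adjacency

class TestAdjacency:
    @pytest.mark.parametrize(
        "tract_span,expected",
        [
            ((150, 162), 1),  # tract starts at the very next base: distance 1
            ((151, 163), 0),  # one-base gap beyond the window
            ((120, 135), 1),  # tract inside the fragment: overlap counts
        ],
    )
    def test_forward_distance_one_boundaries(self, tract_span, expected):
        df = frame([("chr1", 100, 150, "+")])
        tracts = [TractInterval("chr1", *tract_span, "T")]
        table = adjacent_fragments(df, tracts, distance=1)
        assert table.count_at_least("T", "+", 5) == expected

    def test_reverse_strand_mirrored_window(self):
        df = frame([("chr1", 100, 150, "-")])
        # tract ending exactly at the fragment start, one base upstream window
        assert adjacent_fragments(
            df, [TractInterval("chr1", 88, 100, "A")], distance=1
        ).count_at_least("A", "-", 5) == 1
        assert adjacent_fragments(
            df, [TractInterval("chr1", 87, 99, "A")], distance=1
        ).count_at_least("A", "-", 5) == 0

    def test_monotone_in_distance(self, rng):
        df = frame(
            [
                ("chr1", int(s), int(s) + 100, str(st))
                for s, st in zip(
                    rng.integers(0, 9000, 300), rng.choice(["+", "-"], 300)
                )
            ]
        )
        tracts = [
            TractInterval("chr1", int(p), int(p) + 12, "T")
            for p in sorted(rng.choice(np.arange(0, 9500, 20), 40, replace=False))
        ]
        prev = set()
        for d in (0, 1, 5, 50):
            cur = set(np.flatnonzero(adjacency_mask(
                df, tracts, distance=d, strand_base={"+": ["T"], "-": ["T"]}
            )))
            assert prev <= cur
            prev = cur

    def test_matches_quadratic_oracle(self, rng):
        frag_rows = [
            ("chr1", int(s), int(s + ln), str(st))
            for s, ln, st in zip(
                rng.integers(0, 50_000, 800),
                rng.integers(60, 400, 800),
                rng.choice(["+", "-"], 800),
            )
        ]
        # disjoint tracts per base on a grid
        tract_rows = []
        for i, p in enumerate(range(0, 50_000, 60)):
            base = "ACGT"[i % 4]
            tract_rows.append(("chr1", p, p + int(rng.integers(5, 20)), base, 0))
        df = frame(frag_rows)
        tracts = [TractInterval(c, s, e, b, m) for c, s, e, b, m in tract_rows]
        table = adjacent_fragments(df, tracts, distance=1)
        oracle = quadratic_adjacency_oracle(frag_rows, tract_rows, distance=1)
        # cross-check cumulative counts per base/strand at several thresholds
        for base in "ACGT":
            for strand in "+-":
                for L in (5, 10, 15):
                    expected = sum(
                        1
                        for fi, hits in oracle.items()
                        if frag_rows[fi][3] == strand
                        and any(b == base and ln >= L for b, ln in hits)
                    )
                    assert table.count_at_least(base, strand, L) == expected

    def test_strand_mirror_symmetry(self, rng):
        """Reverse-complementing the coordinate system preserves all counts."""
        G = 20_000
        frag_rows = [
            ("chr1", int(s), int(s + ln), str(st))
            for s, ln, st in zip(
                rng.integers(0, G - 500, 400),
                rng.integers(60, 400, 400),
                rng.choice(["+", "-"], 400),
            )
        ]
        tracts = [
            TractInterval("chr1", int(p), int(p + 12), "T")
            for p in sorted(rng.choice(np.arange(0, G - 12, 25), 60, replace=False))
        ]
        table = adjacent_fragments(frame(frag_rows), tracts, distance=1)
        flipped_frags = [
            ("chr1", G - e, G - s, "-" if st == "+" else "+")
            for c, s, e, st in frag_rows
        ]
        flipped_tracts = [
            TractInterval("chr1", G - t.end, G - t.start, "A") for t in tracts
        ]
        flipped = adjacent_fragments(frame(flipped_frags), flipped_tracts, distance=1)
        for strand, fstrand in (("+", "-"), ("-", "+")):
            for L in (5, 12):
                assert table.count_at_least("T", strand, L) == flipped.count_at_least(
                    "A", fstrand, L
                )

    def test_first_end_vicinity_window(self):
        """In first-end mode the window reaches from read 1 toward the tail side."""
        df = frame([("chr1", 1000, 1220, "+")])
        tract = [TractInterval("chr1", 1220, 1234, "T")]
        # tail end (1220) abuts the tract; first end is 1000: reachable at 250
        assert adjacent_fragments(df, tract, distance=250, end="first").count_at_least(
            "T", "+", 5
        ) == 1
        assert adjacent_fragments(df, tract, distance=100, end="first").count_at_least(
            "T", "+", 5
        ) == 0


# ---------------------------------------------------------------------------
# Clusters and gaps

class TestClusters:
    def test_all_coincident(self):
        df = frame([("chr1", 400 + i, 500, "+") for i in range(10)])
        frac, positions = end_position_clusters(df)
        assert frac == 1.0
        assert positions["count"].tolist() == [10]

    def test_all_distinct(self):
        df = frame([("chr1", 0, 500 + i, "+") for i in range(10)])
        frac, _ = end_position_clusters(df)
        assert frac == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            end_position_clusters(frame([]))

    def test_uniform_ends_match_hash_oracle(self, rng):
        n = 10_000
        ends = rng.integers(0, 10_000_000, n)
        df = frame([("chr1", int(e) - 100, int(e), "+") for e in ends])
        frac, _ = end_position_clusters(df, min_cluster=5)
        oracle = cluster_fraction_oracle(
            [("chr1", int(e), "+") for e in ends], 5
        )
        assert frac == pytest.approx(oracle)
        assert frac < 0.01


class TestGappedFraction:
    def test_matches_planted_gap_labels(self, tmp_path, genome, truth_tracts, sim_config):
        import dataclasses

        cfg = dataclasses.replace(sim_config, n_fragments=400, p_gap=0.1)
        frags, _ = simulate_smart_library(genome, truth_tracts, cfg, seed=7)
        sam = tmp_path / "lib.sam"
        write_fragments_sam(frags, genome, cfg.read_len, sam)
        # one of the two reads of a flagged fragment carries the deletion
        expected = frags["has_gap"].sum() / (2 * len(frags))
        assert gapped_fraction(sam) == pytest.approx(expected)

    def test_bed_input_unsupported(self, tmp_path):
        bed = tmp_path / "x.bed"
        bed.write_text("chr1\t0\t100\tf\t0\t+\n")
        with pytest.raises(ValueError, match="CIGAR"):
            gapped_fraction(bed)
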