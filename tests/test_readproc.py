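"""Unit and property tests for demultiplexing, dedup, trimming and crosslinks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polytrans import readproc
from polytrans.readproc import (
    DEFAULT_INTERNAL_RULE,
    DEFAULT_TERMINAL_RULES,
    CrosslinkSite,
    MappedRead,
    RawRead,
    TrimRuleTable,
    UniqueCDNA,
    assign_crosslinks,
    deduplicate,
    demultiplex,
    trim_polya,
)

# ---------------------------------------------------------------------------
# independent brute-force trimming oracle
# ---------------------------------------------------------------------------

def oracle_tract_start(seq, lo, hi, min_span, max_mm):
    """Leftmost tract start by exhaustive substring enumeration."""
    for i in range(lo, hi):
        for j in range(i + 1, hi + 1):
            sub = seq[i:j]
            if (
                sub[0] == "A"
                and sub[-1] == "A"
                and len(sub) >= min_span
                and sum(c != "A" for c in sub) <= max_mm
            ):
                return i
    return None


def oracle_trim(seq, terminal=DEFAULT_TERMINAL_RULES, internal=DEFAULT_INTERNAL_RULE):
    while True:
        out = seq
        n = len(out)
        for w, a, m in terminal:
            start = oracle_tract_start(out, n - min(w, n), n, a, m)
            if start is not None:
                out = out[:start]
                break
        start = oracle_tract_start(out, 0, len(out), *internal)
        if start is not None:
            out = out[:start]
        out = out.rstrip("A")
        if out == seq:
            return out
        seq = out


# frozen expected values computed with oracle_trim
@pytest.mark.parametrize(
    "seq,expected",
    [
        ("GATTACA" + "A" * 20, "GATTAC"),  # rule (20, 17, 2), then trailing-A strip
        ("GCGCGCGCGC", "GCGCGCGCGC"),  # no A anywhere near the end
        ("TTTTTTAA", "TTTTTT"),  # terminal tract too short for any rule
        ("", ""),
        ("A" * 30, ""),
        ("CCCC" + "A" * 3, "CCCC"),  # rule (4, 3, 0)
        ("TGAAAG" + "AAA", "TG"),  # iterated passes reach the fixed point
        # A8-G-A8 spans 17 with one mismatch: the internal rule fires
        ("C" * 10 + "A" * 8 + "G" + "A" * 8 + "C" * 5, "C" * 10),
        # one mismatch fewer A: span 16 < 17, internal rule silent
        ("C" * 10 + "A" * 8 + "G" + "A" * 7 + "C" * 5, "C" * 10 + "A" * 8 + "G" + "A" * 7 + "C" * 5),
    ],
)
def test_trim_examples(seq, expected):
    assert oracle_trim(seq) == expected  # oracle agrees with the frozen value
    assert trim_polya(seq) == expected


def test_trim_internal_tract_cuts():
    seq = "C" * 10 + "A" * 17 + "GCGCGTCGT"
    assert trim_polya(seq) == "C" * 10
    assert oracle_trim(seq) == "C" * 10


def _random_reads(n, seed, max_len=45):
    rng = np.random.default_rng(seed)
    reads = []
    for _ in range(n):
        length = int(rng.integers(0, max_len))
        # A-heavy alphabet exercises the tract rules
        reads.append("".join(rng.choice(list("AAACGT"), size=length)))
    return reads


def test_trim_matches_oracle_on_random_reads():
    for seq in _random_reads(800, seed=5):
        assert trim_polya(seq) == oracle_trim(seq), seq


@given(st.text(alphabet="ACGT", max_size=40))
@settings(max_examples=300, deadline=None)
def test_trim_idempotent_and_prefix(seq):
    out = trim_polya(seq)
    assert trim_polya(out) == out
    assert seq.startswith(out)
    assert len(out) <= len(seq)


@given(st.text(alphabet="AG", max_size=30))
@settings(max_examples=200, deadline=None)
def test_trim_oracle_equivalence_property(seq):
    assert trim_polya(seq) == oracle_trim(seq)


def test_single_pass_mode_is_weaker_or_equal():
    for seq in _random_reads(100, seed=9):
        single = trim_polya(seq, iterate=False)
        assert single.startswith(trim_polya(seq))


def test_rule_table_is_the_printed_one():
    table = TrimRuleTable.default()
    assert len(table.terminal) == 17
    assert table.terminal[0] == (20, 17, 2)
    assert table.terminal[-1] == (4, 3, 0)
    assert table.internal == (17, 2)


def test_rule_table_validation():
    with pytest.raises(ValueError):
        TrimRuleTable(terminal=((3, 5, 0),))
    with pytest.raises(ValueError):
        TrimRuleTable(internal=(0, 1))


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------

def _read(seq, barcode=None, rid="r1"):
    return RawRead(rid, seq, "I" * len(seq), barcode_read=barcode)


def test_demux_polyribo_known_plus_umi():
    read = _read("GATTACA", barcode="ACGTG" + "TTTCC")
    out = demultiplex([read], {"s1": "ACGTG"}, "polyribo")
    assert list(out) == ["s1"]
    (assigned, umi), = out["s1"]
    assert umi == "TTTCC"
    assert assigned.sequence == "GATTACA"


def test_demux_unknown_barcode_goes_to_unassigned():
    read = _read("GATTACA", barcode="CCCCC" + "TTTCC")
    out = demultiplex([read], {"s1": "ACGTG"}, "polyribo")
    assert readproc.UNASSIGNED in out and "s1" not in out


def test_demux_iclip_strips_barcode():
    read = _read("ACG" + "TTTT" + "GATTACA")
    out = demultiplex([read], {"s1": "ACG"}, "iclip")
    (assigned, umi), = out["s1"]
    assert umi == "TTTT"
    assert assigned.sequence == "GATTACA"


def test_demux_duplicate_barcode_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        demultiplex([], {"a": "ACGTG", "b": "ACGTG"}, "polyribo")


def test_demux_bad_scheme_and_length():
    with pytest.raises(ValueError, match="scheme"):
        demultiplex([], {}, "nope")
    with pytest.raises(ValueError, match="length"):
        demultiplex([], {"s": "ACG"}, "polyribo")


def test_demux_with_mismatch_tolerance():
    read = _read("GATTACA", barcode="ACGTC" + "TTTCC")
    strict = demultiplex([read], {"s1": "ACGTG"}, "polyribo")
    assert readproc.UNASSIGNED in strict
    loose = demultiplex([read], {"s1": "ACGTG"}, "polyribo", max_mismatches=1)
    assert "s1" in loose


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def test_dedup_same_tuple_collapses():
    r = MappedRead("s", "c", 100, 30, "+", "ACGT")
    unique, rejected = deduplicate([r, r])
    assert len(unique) == 1 and rejected == 0


def test_dedup_different_umi_kept():
    reads = [
        MappedRead("s", "c", 100, 30, "+", "ACGT"),
        MappedRead("s", "c", 100, 30, "+", "TTTT"),
    ]
    unique, _ = deduplicate(reads)
    assert len(unique) == 2


def test_dedup_missing_umi_rejected_with_count():
    reads = [MappedRead("s", "c", 1, 10, "+", None)]
    unique, rejected = deduplicate(reads)
    assert unique == [] and rejected == 1


def test_dedup_matches_set_oracle(rng):
    reads = [
        MappedRead(
            f"s{rng.integers(2)}",
            "c",
            int(rng.integers(5)),
            int(rng.integers(20, 23)),
            "+",
            "".join(rng.choice(list("ACGT"), 3)),
        )
        for _ in range(500)
    ]
    expected = {(r.sample, r.contig, r.start, r.length, r.strand, r.umi) for r in reads}
    unique, _ = deduplicate(reads)
    assert len(unique) == len(expected)
    # idempotence: re-deduplicating the unique set changes nothing
    again, _ = deduplicate(
        [MappedRead(c.sample, c.contig, c.start, c.length, c.strand, c.umi) for c in unique]
    )
    assert again == unique
    assert len(unique) <= len(reads)


# ---------------------------------------------------------------------------
# crosslink assignment
# ---------------------------------------------------------------------------

def _cdna(start, length=30, strand="+", umi="ACGT", sample="s"):
    return UniqueCDNA(sample, "c", start, length, strand, umi)


def test_crosslink_plus_strand_minus_one():
    sites, skipped = assign_crosslinks([_cdna(100)])
    assert skipped == 0
    assert sites == [CrosslinkSite("c", 99, "+", 1)]


def test_crosslink_at_zero_skipped():
    sites, skipped = assign_crosslinks([_cdna(0)])
    assert sites == [] and skipped == 1


def test_crosslink_minus_strand_mirrors():
    # 5' end of a minus-strand read is its rightmost base
    sites, _ = assign_crosslinks([_cdna(100, length=30, strand="-")])
    assert sites == [CrosslinkSite("c", 130, "-", 1)]


def test_crosslink_counts_shared_site():
    cdnas = [_cdna(100, length=l, umi=u) for l, u in [(30, "AAAA"), (31, "AAAA"), (32, "CCCC")]]
    sites, _ = assign_crosslinks(cdnas)
    assert sites == [CrosslinkSite("c", 99, "+", 3)]


def test_crosslink_contig_bound_skip():
    sites, skipped = assign_crosslinks([_cdna(100, strand="-")], contig_lengths={"c": 120})
    assert sites == [] and skipped == 1
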