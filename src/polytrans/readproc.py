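"""Preprocessing of 3'-end and CLIP reads.

Covers sample demultiplexing with embedded random barcodes (UMIs),
PCR-duplicate removal, rule-based removal of terminal and internal
poly(A) tracts, and extraction of crosslink sites from deduplicated
cDNAs.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "DEFAULT_TERMINAL_RULES",
    "DEFAULT_INTERNAL_RULE",
    "SCHEMES",
    "TrimRuleTable",
    "RawRead",
    "MappedRead",
    "UniqueCDNA",
    "CrosslinkSite",
    "demultiplex",
    "deduplicate",
    "trim_polya",
    "assign_crosslinks",
]

# Terminal trimming rules as (window_length, min_tract_span, allowed_mismatches),
# tried in this order; first rule whose window contains a qualifying tract wins.
DEFAULT_TERMINAL_RULES: tuple[tuple[int, int, int], ...] = (
    (20, 17, 2),
    (19, 16, 2),
    (18, 15, 2),
    (17, 14, 2),
    (16, 13, 1),
    (15, 12, 1),
    (14, 11, 1),
    (13, 10, 1),
    (12, 10, 1),
    (11, 9, 1),
    (10, 8, 1),
    (9, 8, 1),
    (8, 7, 0),
    (7, 6, 0),
    (6, 5, 0),
    (5, 3, 0),
    (4, 3, 0),
)

# Internal tract rule: (min_tract_span, allowed_mismatches).
DEFAULT_INTERNAL_RULE: tuple[int, int] = (17, 2)

# scheme -> (known barcode length, UMI length)
SCHEMES: dict[str, tuple[int, int]] = {"polyribo": (5, 5), "iclip": (3, 4)}

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class TrimRuleTable:
    """Ordered terminal tract rules plus one internal tract rule."""

    terminal: tuple[tuple[int, int, int], ...] = DEFAULT_TERMINAL_RULES
    internal: tuple[int, int] = DEFAULT_INTERNAL_RULE

    def __post_init__(self) -> None:
        for w, a, m in self.terminal:
            if not (w >= a >= 1 and m >= 0):
                raise ValueError(f"invalid terminal rule ({w}, {a}, {m})")
        a, m = self.internal
        if not (a >= 1 and m >= 0):
            raise ValueError(f"invalid internal rule ({a}, {m})")

    @classmethod
    def default(cls) -> "TrimRuleTable":
        return cls()


@dataclass
class RawRead:
    """A sequencing read; ``barcode_read`` holds the separate 10-base
    index read used by the paired 3'-end scheme."""

    id: str
    sequence: str
    qualities: str
    barcode_read: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: sequence and qualities differ in length"
            )


@dataclass(frozen=True)
class MappedRead:
    """A demultiplexed read with its (emulated) mapping coordinates."""

    sample: str
    contig: str
    start: int  # 0-based leftmost genomic coordinate
    length: int
    strand: str
    umi: Optional[str]


@dataclass(frozen=True)
class UniqueCDNA:
    sample: str
    contig: str
    start: int
    length: int
    strand: str
    umi: str


@dataclass(frozen=True)
class CrosslinkSite:
    contig: str
    position: int  # 0-based
    strand: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1 or self.position < 0:
            raise ValueError("crosslink site requires position >= 0 and count >= 1")


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[RawRead],
    known_barcodes: Mapping[str, str],
    scheme: str,
    max_mismatches: int = 0,
) -> dict[str, list[tuple[RawRead, str]]]:
    """Assign reads to samples and extract the UMI.

    ``known_barcodes`` maps sample id -> known barcode bases.  For the
    ``polyribo`` scheme the 10-base barcode read carries 5 known + 5 UMI
    bases; for ``iclip`` the first 7 bases of the read itself carry
    3 known + 4 UMI bases (stripped from the returned read sequence).

    Returns a dict sample id -> list of (read, umi); unassignable reads
    are collected under :data:`UNASSIGNED` with ``umi=""``.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {sorted(SCHEMES)}")
    known_len, umi_len = SCHEMES[scheme]
    by_code: dict[str, str] = {}
    for sample, code in known_barcodes.items():
        if len(code) != known_len:
            raise ValueError(
                f"barcode {code!r} for sample {sample!r} must have length {known_len}"
            )
        if code in by_code:
            raise ValueError(f"duplicate known barcode {code!r}")
        by_code[code] = sample

    out: dict[str, list[tuple[RawRead, str]]] = defaultdict(list)
    for read in reads:
        if scheme == "polyribo":
            tag = read.barcode_read or ""
        else:
            tag = read.sequence[: known_len + umi_len]
        if len(tag) < known_len + umi_len:
            out[UNASSIGNED].append((read, ""))
            continue
        code, umi = tag[:known_len], tag[known_len : known_len + umi_len]
        sample = by_code.get(code)
        if sample is None and max_mismatches > 0:
            hits = [s for c, s in by_code.items() if _hamming(c, code) <= max_mismatches]
            sample = hits[0] if len(hits) == 1 else None
        if sample is None:
            out[UNASSIGNED].append((read, ""))
            continue
        if scheme == "iclip":
            trimmed = RawRead(
                read.id,
                read.sequence[known_len + umi_len :],
                read.qualities[known_len + umi_len :],
            )
            out[sample].append((trimmed, umi))
        else:
            out[sample].append((read, umi))
    return dict(out)


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def deduplicate(reads: Iterable[MappedRead]) -> tuple[list[UniqueCDNA], int]:
    """Collapse PCR duplicates to unique cDNAs.

    A molecule is identified by (sample, contig, start, length, strand, UMI);
    records without a UMI are rejected and counted.  Returns the unique
    cDNAs in deterministic (sorted) order plus the rejected-record count.
    """
    seen: set[UniqueCDNA] = set()
    rejected = 0
    for r in reads:
        if not r.umi:
            rejected += 1
            continue
        seen.add(UniqueCDNA(r.sample, r.contig, r.start, r.length, r.strand, r.umi))
    ordered = sorted(
        seen, key=lambda c: (c.sample, c.contig, c.start, c.length, c.strand, c.umi)
    )
    return ordered, rejected


# ---------------------------------------------------------------------------
# poly(A) trimming
# ---------------------------------------------------------------------------

def _leftmost_tract(seq: str, lo: int, hi: int, min_span: int, max_mm: int) -> Optional[int]:
    """Leftmost start in ``seq[lo:hi]`` of an A-tract of span >= min_span.

    A tract starts and ends with ``A`` and contains at most ``max_mm``
    non-A bases anywhere inside.  Returns the absolute start index or None.
    """
    for i in range(lo, hi):
        if seq[i] != "A":
            continue
        mm = 0
        for j in range(i, hi):
            if seq[j] != "A":
                mm += 1
                if mm > max_mm:
                    break
                continue
            if j - i + 1 >= min_span:
                return i
    return None


def _pass_terminal(seq: str, rules: Sequence[tuple[int, int, int]]) -> str:
    n = len(seq)
    for w, a, m in rules:
        lo = n - min(w, n)
        start = _leftmost_tract(seq, lo, n, a, m)
        if start is not None:
            return seq[:start]
    return seq


def _pass_internal(seq: str, rule: tuple[int, int]) -> str:
    a, m = rule
    start = _leftmost_tract(seq, 0, len(seq), a, m)
    return seq[:start] if start is not None else seq


def trim_polya(sequence: str, rules: Optional[TrimRuleTable] = None, iterate: bool = True) -> str:
    """Remove poly(A) tracts from a read sequence.

    Each pass applies three stages: (1) the terminal rule table, first
    firing rule wins, trimming from the tract start to the read end;
    (2) the internal tract rule, cutting at the first qualifying tract;
    (3) stripping of any remaining trailing A bases.  With
    ``iterate=True`` (default) passes repeat until a fixed point, which
    makes trimming idempotent; ``iterate=False`` performs the single
    pass only.
    """
    if rules is None:
        rules = TrimRuleTable.default()
    cur = sequence
    while True:
        nxt = _pass_terminal(cur, rules.terminal)
        nxt = _pass_internal(nxt, rules.internal)
        nxt = nxt.rstrip("A")
        if nxt == cur or not iterate:
            return nxt
        cur = nxt


def trim_read(read: RawRead, rules: Optional[TrimRuleTable] = None, iterate: bool = True) -> RawRead:
    """Apply :func:`trim_polya` to a read, keeping qualities in sync."""
    trimmed = trim_polya(read.sequence, rules, iterate)
    return RawRead(read.id, trimmed, read.qualities[: len(trimmed)], read.barcode_read)


# ---------------------------------------------------------------------------
# crosslink assignment
# ---------------------------------------------------------------------------

def assign_crosslinks(
    cdnas: Iterable[UniqueCDNA],
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> tuple[list[CrosslinkSite], int]:
    """Derive crosslink sites from unique cDNAs.

    The site sits one nucleotide 5' of the read start in transcript
    orientation: genomic ``start - 1`` on the plus strand and genomic
    5'-end ``+ 1`` on the minus strand.  Sites falling outside the
    contig are skipped and counted.
    """
    tally: Counter[tuple[str, int, str]] = Counter()
    skipped = 0
    for c in cdnas:
        if c.strand == "+":
            site = c.start - 1
        elif c.strand == "-":
            site = (c.start + c.length - 1) + 1
        else:
            raise ValueError(f"invalid strand {c.strand!r}")
        if site < 0:
            skipped += 1
            continue
        if contig_lengths is not None and site >= contig_lengths.get(c.contig, site + 1):
            skipped += 1
            continue
        tally[(c.contig, site, c.strand)] += 1
    sites = [
        CrosslinkSite(contig, pos, strand, n)
        for (contig, pos, strand), n in sorted(tally.items())
    ]
    return sites, skipped
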