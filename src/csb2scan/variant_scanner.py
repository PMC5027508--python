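"""Exact-match search-string library and CSB 2 locus scanning.

The survey strategy: build one search string per candidate allele by wrapping
the tract (G^m X G^n or G^k) in fixed reference flanks taken from the anchor
window around the locus (rCRS 294-325), then scan every sequence for exact,
full-length occurrences of each string, on both strands.  Because the flanks
end/begin with non-G bases, no library string can occur inside another, so
each locus matches at most one string.  An anchored run-length classifier
(:func:`classify_locus`) generalises the fixed library to arbitrary tract
shapes and doubles as a brute-force cross-check of the scanner.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO

from .sequence_model import (
    GTractVariant,
    SequenceRecord,
    parse_nomenclature,
    reverse_complement,
    run_length_encode,
)
from .survey_stats import FrequencyMatrix

logger = logging.getLogger(__name__)

PACKAGED_ANCHORS = Path(__file__).parent / "data" / "anchors_rcrs.fa"


class AnchorError(ValueError):
    """Invalid flank/anchor configuration."""


class LibraryError(ValueError):
    """Search-string library violates its construction invariants."""


@dataclass(frozen=True)
class AnchorPair:
    """Fixed flanks bounding the variable G-tract, on the G-rich strand.

    ``upstream_flank`` is the sequence 5' of the tract (reverse complement of
    rCRS 316-325 for the packaged defaults) and ``downstream_flank`` the
    sequence 3' of it (reverse complement of rCRS 294-302).  The flanks must
    end/begin with a non-G base so that library strings delimit the tract
    unambiguously.  The optional extensions carry further reference context
    used to lengthen short search strings up to a minimum search size.
    """

    upstream_flank: str
    downstream_flank: str
    strand_of_definition: Literal["G-rich", "reference"] = "G-rich"
    upstream_extension: str = ""
    downstream_extension: str = ""

    def __post_init__(self) -> None:
        for label, seq in (
            ("upstream_flank", self.upstream_flank),
            ("downstream_flank", self.downstream_flank),
            ("upstream_extension", self.upstream_extension),
            ("downstream_extension", self.downstream_extension),
        ):
            if not set(seq) <= set("ACGT"):
                raise AnchorError(f"{label} must be over ACGT, got {seq!r}")
        if not self.upstream_flank or not self.downstream_flank:
            raise AnchorError("flanks must be non-empty")
        if self.upstream_flank.endswith("G"):
            raise AnchorError("upstream flank must end with a non-G base")
        if self.downstream_flank.startswith("G"):
            raise AnchorError("downstream flank must start with a non-G base")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AnchorPair":
        """Load an anchor configuration from a small FASTA-like file whose
        record ids are upstream_flank / downstream_flank / *_extension."""
        parts: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            parts[rec.id] = str(rec.seq).upper()
        try:
            return cls(
                upstream_flank=parts["upstream_flank"],
                downstream_flank=parts["downstream_flank"],
                upstream_extension=parts.get("upstream_extension", ""),
                downstream_extension=parts.get("downstream_extension", ""),
            )
        except KeyError as exc:
            raise AnchorError(f"anchor file {path} missing record {exc}") from exc

    @classmethod
    def packaged(cls) -> "AnchorPair":
        """The packaged rCRS-derived anchor configuration."""
        return cls.from_fasta(PACKAGED_ANCHORS)


@dataclass(frozen=True)
class Hit:
    """One exact full-length library-string occurrence in a record.

    Coordinates are 0-based half-open on the record's stored orientation;
    strand '+' means the G-rich string itself matched, '-' that its reverse
    complement did (i.e. the record stores the reference/C-rich strand).
    """

    record_id: str
    variant: str
    start: int
    end: int
    strand: Literal["+", "-"]

    @property
    def interval_rcrs_style(self) -> tuple[int, int]:
        """1-based inclusive interval for reports."""
        return (self.start + 1, self.end)


@dataclass
class SearchLibrary:
    """Deterministically ordered map variant name -> full search string."""

    strings: dict[str, str]
    anchors: AnchorPair
    m_range: tuple[int, int]
    n_range: tuple[int, int]
    interrupt_set: tuple[str, ...]
    continuous_range: tuple[int, int] | None
    min_length: int
    extension: tuple[int, int] = (0, 0)  # residues added (upstream, downstream)

    def __len__(self) -> int:
        return len(self.strings)

    @property
    def max_string_length(self) -> int:
        return max(len(s) for s in self.strings.values())


def _extend_flanks(
    anchors: AnchorPair, shortest_tract: int, min_length: int
) -> tuple[str, str, tuple[int, int]]:
    """Symmetrically extend flanks until the shortest string meets min_length."""
    up, down = anchors.upstream_flank, anchors.downstream_flank
    ext_up, ext_down = anchors.upstream_extension, anchors.downstream_extension
    added_up = added_down = 0
    side = 0  # alternate: 0 -> upstream, 1 -> downstream
    while len(up) + shortest_tract + len(down) < min_length:
        took = False
        for _ in range(2):
            if side == 0 and added_up < len(ext_up):
                added_up += 1
                up = ext_up[-added_up:] + anchors.upstream_flank
                took = True
            elif side == 1 and added_down < len(ext_down):
                added_down += 1
                down = anchors.downstream_flank + ext_down[:added_down]
                took = True
            side = 1 - side
            if took:
                break
        if not took:
            raise LibraryError(
                f"cannot reach min_length={min_length}: extension context exhausted"
            )
    if added_up or added_down:
        logger.info(
            "flanks extended by %d (upstream) / %d (downstream) residues to meet "
            "the %d nt minimum search-string length",
            added_up, added_down, min_length,
        )
    return up, down, (added_up, added_down)


def build_search_strings(
    anchors: AnchorPair,
    m_range: tuple[int, int] = (1, 12),
    n_range: tuple[int, int] = (1, 12),
    interrupt_set: Sequence[str] = ("A",),
    continuous_range: tuple[int, int] | None = None,
    min_length: int = 25,
) -> SearchLibrary:
    """Build the combinatorial search-string library.

    One string per (m, interrupt, n) combination plus one per continuous
    length k, ordered by (interrupt, m, n) then k.  Flanks are extended
    symmetrically from the anchor's reference context when the shortest
    string would fall below ``min_length`` (the minimum search size).
    Pairwise substring exclusivity and the length floor are verified; any
    violation fails the build loudly.
    """
    for base in interrupt_set:
        if base not in ("A", "C", "T"):
            raise LibraryError(f"interrupting base {base!r} not in {{A,C,T}}")
    tract_lengths = []
    if interrupt_set:
        if m_range[0] < 1 or n_range[0] < 1 or m_range[1] < m_range[0] or n_range[1] < n_range[0]:
            raise LibraryError(f"invalid run ranges m={m_range}, n={n_range}")
        tract_lengths.append(m_range[0] + 1 + n_range[0])
    if continuous_range is not None:
        if continuous_range[0] < 1 or continuous_range[1] < continuous_range[0]:
            raise LibraryError(f"invalid continuous range {continuous_range}")
        tract_lengths.append(continuous_range[0])
    if not tract_lengths:
        return SearchLibrary(
            strings={}, anchors=anchors, m_range=m_range, n_range=n_range,
            interrupt_set=tuple(interrupt_set), continuous_range=continuous_range,
            min_length=min_length,
        )
    up, down, extension = _extend_flanks(anchors, min(tract_lengths), min_length)

    strings: dict[str, str] = {}
    for base in interrupt_set:
        for m in range(m_range[0], m_range[1] + 1):
            for n in range(n_range[0], n_range[1] + 1):
                v = GTractVariant(m, base, n)
                strings[v.name] = up + v.tract_sequence + down
    if continuous_range is not None:
        for k in range(continuous_range[0], continuous_range[1] + 1):
            v = GTractVariant(k)
            strings[v.name] = up + v.tract_sequence + down

    names = list(strings)
    for name in names:
        if len(strings[name]) < min_length:
            raise LibraryError(
                f"string {name} has length {len(strings[name])} < min_length {min_length}"
            )
    # pairwise mutual exclusivity: no string may occur inside another
    by_len = sorted(names, key=lambda nm: len(strings[nm]))
    for i, a in enumerate(by_len):
        sa = strings[a]
        for b in by_len[i + 1:]:
            if sa in strings[b]:
                raise LibraryError(f"library string {a} is a substring of {b}")
    return SearchLibrary(
        strings=strings, anchors=anchors, m_range=m_range, n_range=n_range,
        interrupt_set=tuple(interrupt_set), continuous_range=continuous_range,
        min_length=min_length, extension=extension,
    )


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _find_all(haystack: str, needle: str, limit: int) -> Iterable[int]:
    """Start offsets of every occurrence (< limit) of needle in haystack."""
    start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx == -1 or idx >= limit:
            return
        yield idx
        start = idx + 1


def scan_record(
    record: SequenceRecord, library: SearchLibrary, both_strands: bool = True
) -> list[Hit]:
    """Exact full-length occurrences of library strings in one record.

    With ``both_strands`` (the default; deposited records may store either
    strand) the reverse complement of each string is searched too, and hits
    are reported in G-rich nomenclature regardless of strand.  For circular
    records the origin junction is scanned by appending the first
    (max string length - 1) residues.
    """
    seq = record.residues
    limit = len(seq)
    if record.circular and library.strings:
        seq = seq + record.residues[: library.max_string_length - 1]
    hits: list[Hit] = []
    for name, s in library.strings.items():
        for idx in _find_all(seq, s, limit):
            hits.append(Hit(record.id, name, idx, idx + len(s), "+"))
        if both_strands:
            rc = reverse_complement(s)
            for idx in _find_all(seq, rc, limit):
                hits.append(Hit(record.id, name, idx, idx + len(rc), "-"))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Anchored classifier (open-ended; also the scanner's brute-force oracle)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusCall:
    """Classification of one anchored locus."""

    record_id: str
    result: GTractVariant | Literal["complex"]
    start: int  # 0-based start of the tract segment, record orientation
    end: int
    strand: Literal["+", "-"]


def classify_segment(segment: str) -> GTractVariant | Literal["complex"]:
    """Run-length classification of the sequence between the two flanks.

    ``G^k`` -> continuous variant; ``G^m X G^n`` with X in {A,C,T} -> the
    interrupted variant; anything else -- including any N, two interruptions,
    or an empty segment -- is "complex" (unclassifiable, never guessed).
    """
    if not segment or "N" in segment:
        return "complex"
    runs = run_length_encode(segment)
    if len(runs) == 1 and runs[0][0] == "G":
        return GTractVariant(runs[0][1])
    if (
        len(runs) == 3
        and runs[0][0] == "G"
        and runs[2][0] == "G"
        and runs[1][0] in ("A", "C", "T")
        and runs[1][1] == 1
    ):
        return GTractVariant(runs[0][1], runs[1][0], runs[2][1])
    return "complex"


def _classify_strand(
    seq: str, record_id: str, anchors: AnchorPair, strand: str,
    max_segment: int, keep_limit: int,
) -> list[LocusCall]:
    """Classify loci on one orientation of (possibly origin-padded) seq.

    ``keep_limit`` is the record's true length; loci whose forward-mapped
    tract start falls at or beyond it are origin-pad duplicates and dropped.
    """
    up, down = anchors.upstream_flank, anchors.downstream_flank
    calls = []
    for up_start in _find_all(seq, up, len(seq)):
        seg_start = up_start + len(up)
        down_start = seq.find(down, seg_start)
        if down_start == -1 or down_start - seg_start > max_segment:
            continue
        segment = seq[seg_start:down_start]
        result = classify_segment(segment)
        if strand == "+":
            start, end = seg_start, down_start
        else:  # map back onto the record's stored orientation
            start, end = len(seq) - down_start, len(seq) - seg_start
        if start >= keep_limit:
            continue
        calls.append(LocusCall(record_id, result, start, end, strand))
    return calls


def classify_locus(
    record: SequenceRecord,
    anchors: AnchorPair,
    both_strands: bool = True,
    max_segment: int = 100,
) -> list[LocusCall]:
    """Locate anchor-flank pairs and run-length-classify each enclosed tract.

    Returns one call per locus found (an empty list means the record lacks
    the CSB 2 locus, as many partial control-region submissions do).  Multiple
    loci in one record are all classified, with a warning logged.
    """
    seq = record.residues
    if record.circular:
        pad = len(anchors.upstream_flank) + max_segment + len(anchors.downstream_flank) - 1
        seq = seq + record.residues[:pad]
    orig_len = len(record.residues)
    calls = _classify_strand(seq, record.id, anchors, "+", max_segment, orig_len)
    if both_strands:
        rc = reverse_complement(seq)
        calls += _classify_strand(rc, record.id, anchors, "-", max_segment, orig_len)
    if len(calls) > 1:
        logger.warning("record %s: %d CSB 2 loci classified", record.id, len(calls))
    return calls


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def count_hits(
    records: Iterable[SequenceRecord],
    library: SearchLibrary,
    both_strands: bool = True,
    once_per_record: bool = False,
) -> tuple[FrequencyMatrix, list[Hit]]:
    """Fold :func:`scan_record` over a record set into a frequency matrix.

    Each matched locus contributes one count; records without the locus
    contribute nothing.  ``once_per_record`` switches to strict once-per-record
    counting (first locus only) for chimeric/duplicated submissions.
    """
    matrix = FrequencyMatrix()
    all_hits: list[Hit] = []
    for record in records:
        hits = scan_record(record, library, both_strands=both_strands)
        if not hits:
            continue
        if once_per_record and len(hits) > 1:
            logger.warning(
                "record %s: %d loci, counting first only (strict mode)",
                record.id, len(hits),
            )
            hits = hits[:1]
        for h in hits:
            matrix.add(h.variant)
        all_hits.extend(hits)
    return matrix, all_hits


def hits_to_frame(hits: Sequence[Hit]) -> pd.DataFrame:
    """Per-record hit table (1-based inclusive intervals) for TSV output."""
    return pd.DataFrame(
        [
            {
                "record_id": h.record_id,
                "variant": h.variant,
                "start": h.start + 1,
                "end": h.end,
                "strand": h.strand,
            }
            for h in hits
        ],
        columns=["record_id", "variant", "start", "end", "strand"],
    )
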