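"""Domain model for the CSB 2 G-tract locus of the human mitochondrial genome.

Conserved Sequence Block 2 (CSB 2) sits in the non-coding control region of
human mtDNA.  On the G-rich strand it is, in the reference sequence, a
discontinuous guanine tract of five guanines, one adenine and seven guanines
(rCRS positions 303-315; the printed reference strand shows the reverse
complement, the well-known C7-T-C5 stretch around position 310).  Alleles are
named ``GmXGn`` -- *m* guanines, a single interrupting base *X* in {A, C, T},
then *n* guanines -- or ``Gk`` for a continuous tract of *k* guanines.

This module holds the variant nomenclature (parsing/rendering, strand
conversion), the signed *adenine position index* describing where the
interrupting base sits relative to the tract midpoint, rCRS coordinate
arithmetic for mapping transcript lengths to genomic 3' ends, and the small
table type for measured termination-product percentages (TP%).
"""
from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from itertools import groupby
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
INTERRUPT_BASES = ("A", "C", "T")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class NomenclatureError(ValueError):
    """Malformed or invalid GmXGn / Gk variant name."""


class CoordinateError(ValueError):
    """Transcript/rCRS coordinate arithmetic left the valid range."""


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Sequence records
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A single DNA sequence (complete genome or control-region fragment).

    Residues are upper-cased and restricted to {A,C,G,T,N}; any other IUPAC
    ambiguity code is mapped to N with a logged warning, mirroring the survey's
    all-or-nothing exact matching (an N in a candidate tract simply prevents
    classification rather than being guessed at).
    """

    id: str
    description: str
    residues: str
    circular: bool = False

    def __post_init__(self) -> None:
        seq = self.residues.upper()
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if not set(seq) <= VALID_BASES:
            bad = sorted(set(seq) - VALID_BASES)
            logger.warning(
                "record %s: mapping non-ACGTN codes %s to N", self.id, "".join(bad)
            )
            seq = "".join(c if c in VALID_BASES else "N" for c in seq)
        self.residues = seq

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(
            id=self.id,
            description=self.description,
            residues=reverse_complement(self.residues),
            circular=self.circular,
        )


# ---------------------------------------------------------------------------
# Variant nomenclature
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GTractVariant:
    """A CSB 2 allele in G-rich-strand nomenclature.

    ``first_run`` guanines, an optional single ``interrupt`` base, then
    ``second_run`` guanines.  A continuous tract Gk has ``interrupt=None`` and
    ``second_run=0``.
    """

    first_run: int
    interrupt: str | None = None
    second_run: int = 0

    def __post_init__(self) -> None:
        if self.first_run < 1:
            raise NomenclatureError(f"first run must be >= 1, got {self.first_run}")
        if self.interrupt is None:
            if self.second_run != 0:
                raise NomenclatureError(
                    "continuous tract must have second_run = 0, got "
                    f"{self.second_run}"
                )
        else:
            if self.interrupt not in INTERRUPT_BASES:
                raise NomenclatureError(
                    f"interrupting base must be one of A/C/T, got {self.interrupt!r}"
                )
            if self.second_run < 1:
                raise NomenclatureError(
                    f"second run must be >= 1 for interrupted tract, got "
                    f"{self.second_run}"
                )

    @property
    def is_continuous(self) -> bool:
        return self.interrupt is None

    @property
    def total_guanines(self) -> int:
        return self.first_run + self.second_run

    @property
    def tract_length(self) -> int:
        return self.total_guanines + (0 if self.is_continuous else 1)

    @property
    def name(self) -> str:
        """Canonical G-rich nomenclature, e.g. ``G5AG7`` or ``G13``."""
        if self.is_continuous:
            return f"G{self.first_run}"
        return f"G{self.first_run}{self.interrupt}G{self.second_run}"

    @property
    def tract_sequence(self) -> str:
        """The tract itself on the G-rich strand, e.g. ``GGGGGAGGGGGGG``."""
        if self.is_continuous:
            return "G" * self.first_run
        return "G" * self.first_run + self.interrupt + "G" * self.second_run

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


_INTERRUPTED_RE = re.compile(r"^G(\d+)([A-Z])G(\d+)$")
_CONTINUOUS_RE = re.compile(r"^G(\d+)$")


def parse_nomenclature(name: str) -> GTractVariant:
    """Parse a canonical variant name (``GmXGn`` or ``Gk``).

    Raises :class:`NomenclatureError` naming the offending token for malformed
    strings, zero run lengths and interrupting bases outside {A,C,T}.
    """
    name = name.strip()
    m = _INTERRUPTED_RE.match(name)
    if m:
        first, base, second = int(m.group(1)), m.group(2), int(m.group(3))
        if first < 1 or second < 1:
            raise NomenclatureError(f"{name!r}: zero-length G-run")
        if base not in INTERRUPT_BASES:
            raise NomenclatureError(
                f"{name!r}: interrupting base {base!r} not in {{A,C,T}}"
            )
        return GTractVariant(first, base, second)
    m = _CONTINUOUS_RE.match(name)
    if m:
        k = int(m.group(1))
        if k < 1:
            raise NomenclatureError(f"{name!r}: zero-length G-run")
        return GTractVariant(k)
    raise NomenclatureError(f"cannot parse variant name {name!r}")


_GENERIC_PAIR_RE = re.compile(r"^([ACGT])(\d+)([ACGT])([ACGT])(\d+)$")
_GENERIC_RUN_RE = re.compile(r"^([ACGT])(\d+)$")


def reverse_complement_name(name: str) -> str:
    """Reverse-complement a run-pair name (``G5AG7`` <-> ``C7TC5``).

    Works symmetrically on G-rich and reference-strand (C-rich) names; applying
    it twice is the identity.
    """
    name = name.strip()
    m = _GENERIC_PAIR_RE.match(name)
    if m:
        b1, r1, mid, b2, r2 = m.groups()
        if b1 != b2:
            raise NomenclatureError(f"{name!r}: run bases differ ({b1} vs {b2})")
        if int(r1) < 1 or int(r2) < 1:
            raise NomenclatureError(f"{name!r}: zero-length run")
        cb = b1.translate(_COMPLEMENT)
        cm = mid.translate(_COMPLEMENT)
        return f"{cb}{r2}{cm}{cb}{r1}"
    m = _GENERIC_RUN_RE.match(name)
    if m:
        b, r = m.groups()
        if int(r) < 1:
            raise NomenclatureError(f"{name!r}: zero-length run")
        return f"{b.translate(_COMPLEMENT)}{r}"
    raise NomenclatureError(f"cannot parse run-pair name {name!r}")


def light_strand_name(v: GTractVariant) -> str:
    """Reference-strand (C-rich) name of a variant, e.g. G5AG7 -> ``C7TC5``.

    Haplogroup studies usually quote the polyC-T-polyC spelling of the printed
    reference strand; the G-rich nomenclature used throughout this package is
    its reverse complement.
    """
    return reverse_complement_name(v.name)


# ---------------------------------------------------------------------------
# Adenine position index
# ---------------------------------------------------------------------------

def adenine_position(v: GTractVariant) -> int:
    """Signed offset of the interrupting base from the tract midpoint.

    A first run longer than the second (interrupt towards the 3' end of the
    G-rich tract) gives a positive index; a shorter first run gives a negative
    index.  Equal runs give 0, which is only possible for an even total number
    of guanines.  For odd totals the half-integer offset is labelled by the
    next integer away from zero, so e.g. G9AG6 -> +2 and G6AG7 -> -1.
    """
    if v.is_continuous:
        raise ValueError(f"{v.name}: adenine position undefined for continuous tract")
    d = v.first_run - v.second_run
    if d == 0:
        return 0
    return int(math.copysign(math.ceil(abs(d) / 2), d))


# ---------------------------------------------------------------------------
# Run-length encoding
# ---------------------------------------------------------------------------

def run_length_encode(seq: str) -> list[tuple[str, int]]:
    """Maximal-run decomposition: ``"GGGAGG" -> [("G",3),("A",1),("G",2)]``."""
    return [(base, sum(1 for _ in grp)) for base, grp in groupby(seq)]


def run_length_decode(runs: list[tuple[str, int]]) -> str:
    return "".join(base * count for base, count in runs)


# ---------------------------------------------------------------------------
# rCRS coordinates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoordinateSystem:
    """rCRS numbering for the CSB 2 window.

    User-facing positions are 1-based inclusive on the printed reference
    strand; internal intervals are 0-based half-open on whichever strand is
    being scanned.  The variable tract occupies rCRS 303-315 inside the
    294-325 anchor window used to build search strings.
    """

    tract_interval_rcrs: tuple[int, int] = (303, 315)
    anchor_region_rcrs: tuple[int, int] = (294, 325)

    def __post_init__(self) -> None:
        a0, a1 = self.anchor_region_rcrs
        t0, t1 = self.tract_interval_rcrs
        if not (a0 < t0 and t1 < a1):
            raise CoordinateError(
                f"anchor region {self.anchor_region_rcrs} must strictly contain "
                f"tract interval {self.tract_interval_rcrs}"
            )

    @staticmethod
    def rcrs_to_slice(interval: tuple[int, int]) -> slice:
        """1-based inclusive rCRS interval -> 0-based half-open slice."""
        start, end = interval
        if start < 1 or end < start:
            raise CoordinateError(f"invalid rCRS interval {interval}")
        return slice(start - 1, end)

    @staticmethod
    def slice_to_rcrs(sl: slice) -> tuple[int, int]:
        return (sl.start + 1, sl.stop)


def transcript_end_position(
    tss_rcrs: int, transcript_len: int, insertion_len: int = 0
) -> int:
    """rCRS position of a transcript 3' end for light-strand transcription.

    Transcription from the light-strand promoter proceeds towards decreasing
    rCRS numbering, so a transcript of length L starting at the TSS ends at
    ``tss - (L - 1)``.  ``insertion_len`` models a spacer inserted between the
    G-tract and the downstream terminator: the inserted bases consume
    transcript length without advancing the rCRS coordinate, so a transcript of
    fixed length ends ``insertion_len`` residues further upstream (and,
    conversely, reaching a fixed downstream residue requires a transcript
    exactly ``insertion_len`` nt longer).
    """
    if transcript_len < 1:
        raise CoordinateError(f"transcript length must be >= 1, got {transcript_len}")
    if insertion_len < 0:
        raise CoordinateError(f"insertion length must be >= 0, got {insertion_len}")
    end = tss_rcrs - (transcript_len - 1) + insertion_len
    if end < 1:
        raise CoordinateError(
            f"transcript end {end} below rCRS position 1 "
            "(circular wrap not modelled for the control-region window)"
        )
    return end


def transcript_length_for_end(
    tss_rcrs: int, end_rcrs: int, insertion_len: int = 0
) -> int:
    """Transcript length needed to reach a fixed rCRS residue (see above)."""
    if end_rcrs < 1 or end_rcrs > tss_rcrs:
        raise CoordinateError(
            f"3' end {end_rcrs} must lie in [1, TSS={tss_rcrs}] for "
            "light-strand transcription"
        )
    if insertion_len < 0:
        raise CoordinateError(f"insertion length must be >= 0, got {insertion_len}")
    return tss_rcrs - end_rcrs + 1 + insertion_len


# ---------------------------------------------------------------------------
# Termination-product (TP%) tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TPEntry:
    mean_tp: float
    sd: float | None = None
    n_reps: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_tp <= 100.0:
            raise ValueError(f"mean TP% must be in [0, 100], got {self.mean_tp}")


@dataclass
class TPTable:
    """Measured termination-product percentages keyed by variant name.

    Keys are canonical variant names plus named non-tract constructs (e.g.
    ``G>A``, ``dTP``, ``A6``, ``(UC)3``).  Shipped fixtures must carry a
    non-empty provenance string on every entry.
    """

    entries: dict[str, TPEntry] = field(default_factory=dict)

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __getitem__(self, key: str) -> TPEntry:
        return self.entries[key]

    def get(self, key: str, default: TPEntry | None = None) -> TPEntry | None:
        return self.entries.get(key, default)

    def items(self) -> Iterator[tuple[str, TPEntry]]:
        return iter(self.entries.items())

    @classmethod
    def from_tsv(cls, path: str | Path, require_provenance: bool = True) -> "TPTable":
        """Load a TSV with columns variant, mean_tp, sd, n, provenance."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"variant": str})
        entries: dict[str, TPEntry] = {}
        for row in df.itertuples(index=False):
            provenance = "" if pd.isna(row.provenance) else str(row.provenance)
            if require_provenance and not provenance:
                raise ValueError(f"TP table {path}: entry {row.variant!r} lacks provenance")
            entries[str(row.variant)] = TPEntry(
                mean_tp=float(row.mean_tp),
                sd=None if pd.isna(row.sd) else float(row.sd),
                n_reps=None if pd.isna(row.n) else int(row.n),
                provenance=provenance,
            )
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "variant": name,
                "mean_tp": e.mean_tp,
                "sd": e.sd,
                "n": e.n_reps,
                "provenance": e.provenance,
            }
            for name, e in self.entries.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float], provenance: str = "ad hoc") -> "TPTable":
        return cls({k: TPEntry(mean_tp=float(v), provenance=provenance) for k, v in mapping.items()})
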