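"""Population statistics over CSB 2 variant frequency matrices.

The survey's central object is a frequency matrix of exact-match hit counts
indexed by (first-run length m, second-run length n) for each interrupting
base, plus a count vector for continuous tracts Gk.  This module pools those
counts in the ways the survey reports them: totals by total guanine number,
sample skewness of marginal totals, quadrant occupancy around the modal
variant, the adenine-position spectrum, and the cumulative correlation of
population frequency against in vitro termination efficiency (TP%).
"""
from __future__ import annotations

import json
import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_model import (
    GTractVariant,
    TPTable,
    adenine_position,
    parse_nomenclature,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Frequency matrix
# ---------------------------------------------------------------------------

class FrequencyMatrix:
    """Hit counts per (m, n) cell for each interrupting base, plus continuous Gk.

    Sparse representation: ``interrupted[base][(m, n)]`` and ``continuous[k]``
    are plain counters, so arbitrary run lengths are representable without a
    fixed grid.
    """

    def __init__(self) -> None:
        self.interrupted: dict[str, Counter] = {}
        self.continuous: Counter = Counter()

    # -- construction -------------------------------------------------------

    def add(self, variant: GTractVariant | str, count: int = 1) -> None:
        if isinstance(variant, str):
            variant = parse_nomenclature(variant)
        if count < 0:
            raise ValueError("counts must be non-negative")
        if variant.is_continuous:
            self.continuous[variant.first_run] += count
        else:
            cells = self.interrupted.setdefault(variant.interrupt, Counter())
            cells[(variant.first_run, variant.second_run)] += count

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "FrequencyMatrix":
        fm = cls()
        for name, count in counts.items():
            fm.add(name, count)
        return fm

    # -- queries ------------------------------------------------------------

    @property
    def total_hits(self) -> int:
        return sum(self.continuous.values()) + sum(
            sum(c.values()) for c in self.interrupted.values()
        )

    def cell(self, m: int, n: int, interrupt: str = "A") -> int:
        return self.interrupted.get(interrupt, Counter()).get((m, n), 0)

    def variants(self) -> Iterator[tuple[GTractVariant, int]]:
        """Yield every occupied (variant, count) pair, interrupted then continuous."""
        for base in sorted(self.interrupted):
            for (m, n), c in sorted(self.interrupted[base].items()):
                if c:
                    yield GTractVariant(m, base, n), c
        for k, c in sorted(self.continuous.items()):
            if c:
                yield GTractVariant(k), c

    def counts_by_name(self) -> dict[str, int]:
        return {v.name: c for v, c in self.variants()}

    def modal_cell(self, interrupt: str = "A") -> tuple[int, int]:
        cells = self.interrupted.get(interrupt)
        if not cells or not any(cells.values()):
            raise ValueError(f"no hits for interrupting base {interrupt!r}")
        # deterministic tie-break: highest count, then lowest (m, n)
        return min(cells.items(), key=lambda kv: (-kv[1], kv[0]))[0]

    # -- marginals -----------------------------------------------------------

    def marginals(self, interrupt: str = "A") -> tuple[dict[int, int], dict[int, int]]:
        """Row (by m) and column (by n) totals for one interrupting base."""
        rows: Counter = Counter()
        cols: Counter = Counter()
        for (m, n), c in self.interrupted.get(interrupt, Counter()).items():
            rows[m] += c
            cols[n] += c
        return dict(rows), dict(cols)

    # -- serialization -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: interrupt, m, n, count (continuous rows use n=0)."""
        rows = []
        for v, c in self.variants():
            rows.append(
                {
                    "variant": v.name,
                    "interrupt": v.interrupt or "none",
                    "m": v.first_run,
                    "n": v.second_run,
                    "count": c,
                }
            )
        return pd.DataFrame(rows, columns=["variant", "interrupt", "m", "n", "count"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyMatrix":
        df = pd.read_csv(path, sep="\t")
        fm = cls()
        for row in df.itertuples(index=False):
            fm.add(str(row.variant), int(row.count))
        return fm

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "interrupted": {
                base: {f"{m},{n}": c for (m, n), c in sorted(cells.items()) if c}
                for base, cells in sorted(self.interrupted.items())
            },
            "continuous": {str(k): c for k, c in sorted(self.continuous.items()) if c},
            "total_hits": self.total_hits,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FrequencyMatrix":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        fm = cls()
        for base, cells in payload.get("interrupted", {}).items():
            for key, c in cells.items():
                m, n = (int(x) for x in key.split(","))
                fm.add(GTractVariant(m, base, n), int(c))
        for k, c in payload.get("continuous", {}).items():
            fm.add(GTractVariant(int(k)), int(c))
        return fm


# ---------------------------------------------------------------------------
# Pooled statistics
# ---------------------------------------------------------------------------

def totals_by_total_g(
    matrix: FrequencyMatrix,
    interrupts: Sequence[str] | None = None,
    include_continuous: bool = False,
) -> dict[int, int]:
    """Hit counts pooled by total guanine number (anti-diagonals m + n = const).

    By default pools the interrupted cells only (all interrupting bases);
    ``include_continuous`` adds the Gk vector at total = k.
    """
    totals: Counter = Counter()
    bases = interrupts if interrupts is not None else sorted(matrix.interrupted)
    for base in bases:
        for (m, n), c in matrix.interrupted.get(base, Counter()).items():
            totals[m + n] += c
    if include_continuous:
        for k, c in matrix.continuous.items():
            totals[k] += c
    return dict(sorted(totals.items()))


def sample_skewness(xs: Sequence[float], adjusted: bool = True) -> float:
    """Sample skewness of a data vector.

    The default is the adjusted Fisher-Pearson statistic
    ``N/((N-1)(N-2)) * sum(((x - mean)/s)^3)`` with *s* the (N-1) sample
    standard deviation -- the definition used by spreadsheet SKEW functions.
    ``adjusted=False`` gives the plain moment (g1) estimator.
    """
    x = np.asarray(xs, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"skewness needs at least 3 values, got {n}")
    mean = x.mean()
    if adjusted:
        s = x.std(ddof=1)
        if s == 0.0:
            raise ValueError("skewness undefined for zero sample variance")
        return float(n / ((n - 1) * (n - 2)) * np.sum(((x - mean) / s) ** 3))
    m2 = np.mean((x - mean) ** 2)
    if m2 == 0.0:
        raise ValueError("skewness undefined for zero sample variance")
    m3 = np.mean((x - mean) ** 3)
    return float(m3 / m2 ** 1.5)


@dataclass
class QuadrantCounts:
    """Occupancy of the four quadrants around a pivot cell (m0, n0).

    ``strict`` excludes the bisecting row/column (tallied as ``on_axes``);
    ``inclusive`` folds axis cells into both adjacent quadrants, which is the
    tally behind "fraction of sequences in the quadrant" style statements.
    Quadrants are named in (first-run, second-run) coordinates.
    """

    pivot: tuple[int, int]
    strict: dict[str, int]
    on_axes: int
    inclusive: dict[str, int]
    total: int

    @property
    def strict_fractions(self) -> dict[str, float]:
        return {k: v / self.total for k, v in self.strict.items()}

    @property
    def inclusive_fractions(self) -> dict[str, float]:
        return {k: v / self.total for k, v in self.inclusive.items()}


_QUADRANTS = (
    ("first_shorter_second_longer", -1, +1),
    ("first_longer_second_shorter", +1, -1),
    ("both_longer", +1, +1),
    ("both_shorter", -1, -1),
)


def quadrant_counts(
    matrix: FrequencyMatrix,
    pivot: tuple[int, int] | None = None,
    interrupt: str = "A",
) -> QuadrantCounts:
    """Partition one interrupt base's cells into quadrants around ``pivot``.

    The pivot defaults to the modal cell (G6AG7 in population data).  The
    population asymmetry -- nearly all sequences having the first run no longer
    and the second run no shorter than the modal variant -- shows up as the
    ``first_shorter_second_longer`` inclusive quadrant carrying almost all
    mass while ``both_shorter``/``first_longer_second_shorter`` are nearly
    empty.
    """
    cells = matrix.interrupted.get(interrupt, Counter())
    total = sum(cells.values())
    if total == 0:
        raise ValueError(f"no hits for interrupting base {interrupt!r}")
    if pivot is None:
        pivot = matrix.modal_cell(interrupt)
    m0, n0 = pivot
    strict = {name: 0 for name, _, _ in _QUADRANTS}
    inclusive = {name: 0 for name, _, _ in _QUADRANTS}
    on_axes = 0
    for (m, n), c in cells.items():
        dm = (m > m0) - (m < m0)
        dn = (n > n0) - (n < n0)
        if dm == 0 or dn == 0:
            on_axes += c
        for name, qm, qn in _QUADRANTS:
            if dm == qm and dn == qn:
                strict[name] += c
            if dm in (0, qm) and dn in (0, qn):
                inclusive[name] += c
    return QuadrantCounts(pivot=pivot, strict=strict, on_axes=on_axes,
                          inclusive=inclusive, total=total)


@dataclass
class PositionSpectrum:
    """Adenine-position pooling of interrupted hits."""

    counts: dict[int, int]
    fractions: dict[int, float]
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": list(self.counts),
                "count": list(self.counts.values()),
                "fraction": [self.fractions[p] for p in self.counts],
            }
        )


def position_spectrum(
    matrix: FrequencyMatrix, interrupts: Sequence[str] | None = None
) -> PositionSpectrum:
    """Pool interrupted hits by the signed position of the interrupting base."""
    bases = interrupts if interrupts is not None else sorted(matrix.interrupted)
    counts: Counter = Counter()
    for base in bases:
        for (m, n), c in matrix.interrupted.get(base, Counter()).items():
            if c:
                counts[adenine_position(GTractVariant(m, base, n))] += c
    total = sum(counts.values())
    if total == 0:
        return PositionSpectrum(counts={}, fractions={}, total=0)
    ordered = dict(sorted(counts.items()))
    return PositionSpectrum(
        counts=ordered,
        fractions={p: c / total for p, c in ordered.items()},
        total=total,
    )


# ---------------------------------------------------------------------------
# Frequency vs termination-efficiency correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurvePoint:
    variant: str
    tp_percent: float
    hits: int
    cumulative_fraction: float


@dataclass
class CumulativeCurve:
    """Occupied variants ordered by TP%, with cumulative hit fractions.

    The cumulative fraction is taken over the hits whose variant has a known
    TP% entry; variants missing from the table are listed in ``excluded``.
    """

    points: list[CurvePoint]
    excluded: list[str] = field(default_factory=list)

    @property
    def known_hits(self) -> int:
        return sum(p.hits for p in self.points)

    def fraction_within(self, lo: float, hi: float) -> float:
        """Fraction of (known-TP) hits whose variant TP% lies in [lo, hi]."""
        if not self.points:
            raise ValueError("empty curve")
        inside = sum(p.hits for p in self.points if lo <= p.tp_percent <= hi)
        return inside / self.known_hits

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([p.__dict__ for p in self.points])


def cumulative_tp_curve(matrix: FrequencyMatrix, tp_table: TPTable) -> CumulativeCurve:
    """Correlate population frequency with in vitro termination efficiency.

    Occupied variants are sorted by ascending TP% and the cumulative fraction
    of hits accumulated along the way; variants without a TP entry are
    excluded with a warning rather than imputed.
    """
    occupied = [(v.name, c) for v, c in matrix.variants()]
    known = [(name, tp_table[name].mean_tp, c) for name, c in occupied if name in tp_table]
    missing = [name for name, _ in occupied if name not in tp_table]
    if missing:
        warnings.warn(
            f"{len(missing)} occupied variant(s) absent from TP table, excluded: "
            + ", ".join(missing),
            stacklevel=2,
        )
    if not known:
        raise ValueError("no occupied variant has a TP table entry")
    known.sort(key=lambda t: (t[1], t[0]))
    total = sum(c for _, _, c in known)
    points, cum = [], 0
    for name, tp, c in known:
        cum += c
        points.append(CurvePoint(name, tp, c, cum / total))
    return CumulativeCurve(points=points, excluded=missing)


# ---------------------------------------------------------------------------
# Survey report
# ---------------------------------------------------------------------------

def survey_report(
    matrix: FrequencyMatrix,
    tp_table: TPTable | None = None,
    pivot: tuple[int, int] | None = None,
) -> dict:
    """Assemble the per-survey JSON summary (totals, skewness, quadrants,
    position spectrum and, when a TP table is supplied, the cumulative curve)."""
    report: dict = {
        "total_hits": matrix.total_hits,
        "counts": matrix.counts_by_name(),
        "totals_by_total_g": {str(k): v for k, v in totals_by_total_g(matrix).items()},
        "quadrant_coordinates": "(first_run m, second_run n); pivot = modal cell unless given",
    }
    if "A" in matrix.interrupted and any(matrix.interrupted["A"].values()):
        q = quadrant_counts(matrix, pivot=pivot, interrupt="A")
        report["quadrants"] = {
            "pivot": list(q.pivot),
            "strict": q.strict,
            "on_axes": q.on_axes,
            "inclusive": q.inclusive,
            "inclusive_fractions": q.inclusive_fractions,
        }
        rows, cols = matrix.marginals("A")
        for label, marg in (("row_totals_by_m", rows), ("col_totals_by_n", cols)):
            vals = [marg[k] for k in sorted(marg)]
            report[label] = {str(k): marg[k] for k in sorted(marg)}
            if len(vals) >= 3 and len(set(vals)) > 1:
                report[f"skewness_{label}"] = sample_skewness(vals)
    spec = position_spectrum(matrix)
    report["position_spectrum"] = {
        "counts": {str(p): c for p, c in spec.counts.items()},
        "fractions": {str(p): f for p, f in spec.fractions.items()},
    }
    if tp_table is not None:
        try:
            curve = cumulative_tp_curve(matrix, tp_table)
        except ValueError as exc:
            report["cumulative_tp_curve"] = {"error": str(exc)}
        else:
            report["cumulative_tp_curve"] = {
                "points": [p.__dict__ for p in curve.points],
                "excluded": curve.excluded,
                "fraction_tp_17_43": curve.fraction_within(17.0, 43.0),
            }
    return report
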