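"""Synthetic inputs with full ground truth for the survey and gel pipelines.

The survey generator emulates the kind of sequence set a public-database
download of human mtDNA control regions yields: a mixture of records carrying
the CSB 2 locus (tract drawn from a specified variant frequency spectrum,
embedded in the reference anchor context) and partial fragments lacking the
locus entirely; records are emitted on either strand, and optional noise
models point substitutions outside the locus and +-1 homopolymer-slippage
perturbation of run lengths (the classic failure mode when sequencing G-runs).

The gel generator renders Gaussian bands through a logarithmic migration
model (pixel = a + b*ln(length), b < 0) together with a noise-free ladder, so
densitometry routines can be validated against planted band positions and
areas.  Both generators are deterministic given their seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .densitometry import LaneProfile
from .sequence_model import (
    GTractVariant,
    SequenceRecord,
    parse_nomenclature,
    reverse_complement,
)
from .variant_scanner import AnchorPair

# Four-variant population spectrum used as the default survey condition:
# the dominant discontinuous alleles around the modal G6AG7.
DEFAULT_SPECTRUM: dict[str, float] = {
    "G6AG7": 0.40,
    "G6AG8": 0.35,
    "G5AG7": 0.15,
    "G6AG9": 0.10,
}


@dataclass
class SurveySpec:
    """Parameters of one synthetic survey (the generator's study conditions).

    ``spectrum`` gives the planted variant probabilities (must sum to 1);
    ``fraction_partial_without_csb2`` is the probability that a record is a
    partial fragment lacking the locus; ``strand_mix`` the probability a
    record is emitted as the reference (C-rich) strand; ``snp_rate`` a
    per-base substitution rate applied outside the locus footprint; and
    ``slippage_rate`` the probability that each G-run is perturbed by +-1.
    """

    spectrum: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPECTRUM))
    n_records: int = 2000
    anchors: AnchorPair | None = None  # None -> packaged rCRS anchors
    context_len: int = 150
    strand_mix: float = 0.5
    fraction_partial_without_csb2: float = 0.25
    snp_rate: float = 0.0
    slippage_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ValueError("n_records must be >= 0")
        if abs(sum(self.spectrum.values()) - 1.0) > 1e-9:
            raise ValueError("spectrum probabilities must sum to 1")
        for label, rate in (
            ("strand_mix", self.strand_mix),
            ("fraction_partial_without_csb2", self.fraction_partial_without_csb2),
            ("snp_rate", self.snp_rate),
            ("slippage_rate", self.slippage_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{label} must be in [0, 1], got {rate}")
        # fail before generation on unparseable spectrum keys
        for name in self.spectrum:
            parse_nomenclature(name)


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _apply_slippage(v: GTractVariant, rng: np.random.Generator, rate: float) -> GTractVariant:
    """Perturb each G-run by +-1 with probability ``rate`` (clamped at 1)."""
    first, second = v.first_run, v.second_run
    if rng.random() < rate:
        first = max(1, first + int(rng.choice((-1, 1))))
    if not v.is_continuous and rng.random() < rate:
        second = max(1, second + int(rng.choice((-1, 1))))
    return GTractVariant(first, v.interrupt, second if not v.is_continuous else 0)


def _apply_snps(seq: str, rng: np.random.Generator, rate: float,
                protected: tuple[int, int]) -> str:
    """Substitute bases at ``rate`` outside the protected [start, end) span."""
    if rate <= 0.0:
        return seq
    chars = list(seq)
    lo, hi = protected
    for i in range(len(chars)):
        if lo <= i < hi:
            continue
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != chars[i]]
            chars[i] = choices[int(rng.integers(3))]
    return "".join(chars)


def simulate_survey(
    spec: SurveySpec,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Generate a synthetic record set and its ground truth.

    Returns ``(records, truth)`` where ``truth`` maps record id to the planted
    variant name as present in the final sequence (slippage is applied before
    recording truth) or ``"absent"`` for partial fragments without the locus.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    anchors = spec.anchors if spec.anchors is not None else AnchorPair.packaged()
    names = sorted(spec.spectrum)
    probs = np.array([spec.spectrum[n] for n in names])
    probs = probs / probs.sum()
    variants = {n: parse_nomenclature(n) for n in names}

    # records must contain the extended search strings, so embed the full
    # extension context around the flanks
    up_full = anchors.upstream_extension + anchors.upstream_flank
    down_full = anchors.downstream_flank + anchors.downstream_extension

    records: list[SequenceRecord] = []
    truth: dict[str, str] = {}
    for i in range(spec.n_records):
        rec_id = f"syn{i:05d}"
        if rng.random() < spec.fraction_partial_without_csb2:
            residues = _random_seq(rng, 2 * spec.context_len)
            desc = "synthetic partial control-region fragment without CSB 2"
            truth[rec_id] = "absent"
        else:
            v = variants[rng.choice(names, p=probs)]
            if spec.slippage_rate > 0.0:
                v = _apply_slippage(v, rng, spec.slippage_rate)
            ctx_up = _random_seq(rng, spec.context_len)
            ctx_down = _random_seq(rng, spec.context_len)
            locus = up_full + v.tract_sequence + down_full
            residues = ctx_up + locus + ctx_down
            residues = _apply_snps(
                residues, rng, spec.snp_rate,
                protected=(len(ctx_up), len(ctx_up) + len(locus)),
            )
            desc = "synthetic control-region fragment carrying CSB 2"
            truth[rec_id] = v.name
        if rng.random() < spec.strand_mix:
            residues = reverse_complement(residues)
            desc += " (reference strand)"
        records.append(SequenceRecord(id=rec_id, description=desc, residues=residues))
    return records, truth


def truth_to_frame(truth: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"record_id": list(truth), "planted": list(truth.values())}
    )


# ---------------------------------------------------------------------------
# Gel lanes
# ---------------------------------------------------------------------------

@dataclass
class GelSpec:
    """Parameters of one synthetic gel lane.

    ``bands`` are (length nt, area, width nt) triples; the migration model is
    ``pixel = a + b * ln(length)`` with ``b < 0`` (longer fragments migrate
    less).  ``ladder_lengths`` renders a noise-free marker set through the
    same model (a 25 bp ladder by default).
    """

    bands: list[tuple[float, float, float]] = field(default_factory=list)
    migration_a: float = 1300.0
    migration_b: float = -200.0
    noise_sd: float = 0.0
    n_pixels: int = 700
    ladder_lengths: tuple[float, ...] = tuple(range(25, 325, 25))
    well_pixel: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.migration_b >= 0:
            raise ValueError("migration_b must be negative (longer fragments migrate less)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_pixels < 2:
            raise ValueError("n_pixels must be >= 2")
        for length, area, width in self.bands:
            if length <= 0 or area <= 0 or width <= 0:
                raise ValueError(f"band (length={length}, area={area}, width={width}) invalid")

    def pixel_of(self, length: float) -> float:
        return self.migration_a + self.migration_b * np.log(length)

    def sigma_pixels(self, length: float, width_nt: float) -> float:
        # |d pixel / d length| = |b| / length
        return width_nt * abs(self.migration_b) / length


def simulate_gel(
    spec: GelSpec,
) -> tuple[LaneProfile, list[tuple[float, float]], pd.DataFrame]:
    """Render a synthetic lane, its ladder and the planted band table.

    Returns ``(lane, ladder, truth)`` where ladder entries are (pixel, length)
    pairs and truth is a per-band table with the planted centre pixels.
    Bands whose centre falls outside the rendered pixel range raise an error.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.arange(spec.n_pixels, dtype=float)
    density = np.zeros(spec.n_pixels)
    rows = []
    for length, area, width in spec.bands:
        centre = spec.pixel_of(length)
        if not 0 <= centre < spec.n_pixels:
            raise ValueError(
                f"band at {length} nt maps to pixel {centre:.1f}, outside "
                f"[0, {spec.n_pixels})"
            )
        sigma = spec.sigma_pixels(length, width)
        density += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((x - centre) / sigma) ** 2
        )
        rows.append({"length_nt": length, "area": area, "width_nt": width,
                     "pixel": centre, "sigma_pixels": sigma})
    if spec.noise_sd > 0:
        density = np.clip(density + rng.normal(0.0, spec.noise_sd, spec.n_pixels), 0.0, None)
    ladder = []
    for length in spec.ladder_lengths:
        p = spec.pixel_of(length)
        if 0 <= p < spec.n_pixels:
            ladder.append((float(p), float(length)))
    lane = LaneProfile(lane_id=f"synlane-seed{spec.seed}", density=density,
                       well_pixel=spec.well_pixel)
    return lane, ladder, pd.DataFrame(rows)


def ladder_to_frame(ladder: list[tuple[float, float]]) -> pd.DataFrame:
    return pd.DataFrame({"pixel": [p for p, _ in ladder], "length": [L for _, L in ladder]})
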