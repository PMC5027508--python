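"""Gel-lane densitometry: ladder calibration, TP% quantification, peak calling.

Quantification follows the standard phosphorimager workflow for run-off
transcription assays.  A 1-D lane profile (pixel index from the well towards
the gel bottom, density per pixel) is calibrated against a DNA ladder by
piecewise-linear interpolation (a first-order Lagrange polynomial between each
pair of adjacent marker bands), giving a monotone pixel <-> fragment-length
mapping.  Termination efficiency (TP%) is the density inside the
termination-product window (92-140 nt by default) as a percentage of the total
lane density from the well down to the ~100 nt marker.  For sequencing-gel
comparisons, lanes are normalized to the maximum density inside the TP window
and local maxima are mapped back to fragment lengths and, optionally, to rCRS
3'-end coordinates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .sequence_model import transcript_end_position

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Ladder bands unusable for a monotone pixel <-> length mapping."""


class QuantificationError(ValueError):
    """Lane cannot be quantified (empty windows, zero density...)."""


@dataclass
class LaneProfile:
    """1-D densitometry trace of one gel lane (well -> bottom)."""

    lane_id: str
    density: np.ndarray
    well_pixel: int = 0

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.ndim != 1 or self.density.size < 2:
            raise ValueError("lane profile needs at least 2 pixels")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")
        if not 0 <= self.well_pixel < self.density.size:
            raise ValueError(
                f"well_pixel {self.well_pixel} outside profile of "
                f"{self.density.size} pixels"
            )

    @classmethod
    def from_tsv(cls, path: str | Path, lane_id: str | None = None, well_pixel: int = 0) -> "LaneProfile":
        """Load a (pixel, density) TSV; pixels must be a contiguous 0..P-1 grid."""
        df = pd.read_csv(path, sep="\t")
        df = df.sort_values("pixel")
        pixels = df["pixel"].to_numpy()
        if not np.array_equal(pixels, np.arange(pixels.size)):
            raise ValueError(f"{path}: pixel column must be contiguous from 0")
        return cls(
            lane_id=lane_id or Path(path).stem,
            density=df["density"].to_numpy(dtype=float),
            well_pixel=well_pixel,
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"pixel": np.arange(self.density.size), "density": self.density}).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class LadderCalibration:
    """Monotone pixel <-> length mapping through the ladder knots.

    Interpolation is piecewise linear between adjacent knots; beyond the knot
    hull the edge segments are extended linearly and the extrapolation is
    flagged with a logged warning.
    """

    pixels: np.ndarray   # strictly increasing
    lengths: np.ndarray  # strictly decreasing (longer fragments migrate less)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.pixels.size < 2 or self.pixels.size != self.lengths.size:
            raise CalibrationError("need >= 2 (pixel, length) knots")
        if np.any(np.diff(self.pixels) <= 0) or np.any(np.diff(self.lengths) >= 0):
            raise CalibrationError(
                "ladder must be strictly monotone: increasing pixel, decreasing length"
            )

    @property
    def pixel_hull(self) -> tuple[float, float]:
        return float(self.pixels[0]), float(self.pixels[-1])

    @property
    def length_hull(self) -> tuple[float, float]:
        return float(self.lengths[-1]), float(self.lengths[0])

    def in_hull_pixels(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return (p >= self.pixels[0]) & (p <= self.pixels[-1])

    def pixel_to_length(self, p, warn: bool = True) -> np.ndarray | float:
        p = np.asarray(p, dtype=float)
        out = self._interp(p, self.pixels, self.lengths)
        if warn and np.any(~self.in_hull_pixels(p)):
            logger.warning("pixel -> length extrapolation beyond ladder hull")
        return float(out) if out.ndim == 0 else out

    def length_to_pixel(self, length) -> np.ndarray | float:
        # invert: lengths decrease with pixel, so flip for ascending interp
        length = np.asarray(length, dtype=float)
        out = self._interp(length, self.lengths[::-1], self.pixels[::-1])
        lo, hi = self.length_hull
        if np.any((length < lo) | (length > hi)):
            logger.warning("length -> pixel extrapolation beyond ladder hull")
        return float(out) if out.ndim == 0 else out

    @staticmethod
    def _interp(x, xp, fp) -> np.ndarray:
        """np.interp with linear extrapolation from the edge segments."""
        x = np.asarray(x, dtype=float)
        shape = x.shape
        x = np.atleast_1d(x)
        y = np.interp(x, xp, fp)
        lo_slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        hi_slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y = np.where(x < xp[0], fp[0] + (x - xp[0]) * lo_slope, y)
        y = np.where(x > xp[-1], fp[-1] + (x - xp[-1]) * hi_slope, y)
        return y.reshape(shape)


def fit_ladder(bands: Sequence[tuple[float, float]]) -> LadderCalibration:
    """Fit the pixel <-> length calibration through ladder bands.

    ``bands`` is a sequence of (pixel, length) pairs in any order; they must
    be jointly monotone (length strictly decreasing with migration distance).
    """
    if len(bands) < 2:
        raise CalibrationError("need at least 2 ladder bands")
    arr = sorted((float(p), float(L)) for p, L in bands)
    pixels = np.array([p for p, _ in arr])
    lengths = np.array([L for _, L in arr])
    return LadderCalibration(pixels=pixels, lengths=lengths)


def fit_ladder_global_line(bands: Sequence[tuple[float, float]]) -> LadderCalibration:
    """Sensitivity-check alternative: a single least-squares line pixel ~ length.

    Returns a two-knot calibration spanning the band hull so downstream code is
    unchanged.  The piecewise interpolant (:func:`fit_ladder`) is the default.
    """
    if len(bands) < 2:
        raise CalibrationError("need at least 2 ladder bands")
    p = np.array([b[0] for b in bands], dtype=float)
    L = np.array([b[1] for b in bands], dtype=float)
    slope, intercept = np.polyfit(L, p, 1)
    if slope >= 0:
        raise CalibrationError("fitted line must have longer fragments migrating less")
    L0, L1 = L.max(), L.min()
    return LadderCalibration(
        pixels=np.array([intercept + slope * L0, intercept + slope * L1]),
        lengths=np.array([L0, L1]),
    )


def read_ladder_tsv(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path, sep="\t")
    return [(float(r.pixel), float(r.length)) for r in df.itertuples(index=False)]


@dataclass(frozen=True)
class QuantRegions:
    """Quantification windows.

    ``tp_window_nt``: termination-product region in nt (default 92-140, the
    window covering TP1-TP3).  ``lower_cutoff_nt``: total lane density is
    integrated from the well down to the ~100 nt marker.  Because the TP
    window's lower edge (92 nt) lies just below that marker, the effective
    total-window cutoff is min(lower_cutoff, TP lower edge), so the TP region
    is always a subset of the total.  ``include_cutoff``/``include_well``
    toggle whether the marker pixel itself and the well material count towards
    the total (defaults: both included).
    """

    tp_window_nt: tuple[float, float] = (92.0, 140.0)
    lower_cutoff_nt: float = 100.0
    include_cutoff: bool = True
    include_well: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.tp_window_nt
        if not lo < hi:
            raise ValueError(f"invalid TP window {self.tp_window_nt}")

    @property
    def effective_cutoff_nt(self) -> float:
        return min(self.lower_cutoff_nt, self.tp_window_nt[0])


def quantify_tp_fraction(
    profile: LaneProfile,
    calibration: LadderCalibration,
    regions: QuantRegions = QuantRegions(),
) -> float:
    """Termination efficiency: TP-window density as % of total lane density.

    Total = density from the well down to the (~100 nt) cutoff pixel; TP =
    density over pixels whose calibrated length falls in the TP window.
    Invariant to uniform rescaling of the lane.
    """
    lo_nt, hi_nt = regions.tp_window_nt
    hull_lo, hull_hi = calibration.length_hull
    if lo_nt < hull_lo or hi_nt > hull_hi:
        raise QuantificationError(
            f"TP window {regions.tp_window_nt} nt outside calibration hull "
            f"({hull_lo:g}-{hull_hi:g} nt)"
        )
    n = profile.density.size
    pixels = np.arange(n)
    lengths = np.asarray(calibration.pixel_to_length(pixels, warn=False))

    cutoff_pixel = float(calibration.length_to_pixel(regions.effective_cutoff_nt))
    start = profile.well_pixel if regions.include_well else profile.well_pixel + 1
    if regions.include_cutoff:
        total_mask = (pixels >= start) & (pixels <= cutoff_pixel)
    else:
        total_mask = (pixels >= start) & (pixels < cutoff_pixel)
    tp_mask = (lengths >= lo_nt) & (lengths <= hi_nt) & total_mask

    total = profile.density[total_mask].sum()
    if total <= 0:
        raise QuantificationError(f"lane {profile.lane_id}: zero total density in window")
    return 100.0 * profile.density[tp_mask].sum() / total


def normalize_profile(
    profile: LaneProfile,
    calibration: LadderCalibration,
    window_nt: tuple[float, float] = (92.0, 140.0),
) -> LaneProfile:
    """Divide the lane by its maximum density inside the given length window."""
    lengths = np.asarray(calibration.pixel_to_length(np.arange(profile.density.size), warn=False))
    mask = (lengths >= window_nt[0]) & (lengths <= window_nt[1])
    if not mask.any():
        raise QuantificationError(f"window {window_nt} nt maps outside the profile")
    peak = profile.density[mask].max()
    if peak <= 0:
        raise QuantificationError(f"lane {profile.lane_id}: zero maximum in window")
    return LaneProfile(
        lane_id=profile.lane_id,
        density=profile.density / peak,
        well_pixel=profile.well_pixel,
    )


@dataclass(frozen=True)
class Peak:
    length_nt: float
    height: float          # relative to the lane maximum
    pixel: float
    rcrs_end: int | None = None


def call_peaks(
    profile: LaneProfile,
    calibration: LadderCalibration,
    min_prominence: float = 0.05,
    tss_rcrs: int | None = None,
) -> list[Peak]:
    """Local maxima of the lane, mapped to fragment lengths.

    ``min_prominence`` is a fraction of the lane maximum.  Peak pixel
    positions are refined to sub-pixel accuracy by a three-point parabolic
    fit.  When ``tss_rcrs`` is given, each peak length is also mapped to the
    rCRS position of the corresponding transcript 3' end (light-strand
    transcription from the configured start site).
    """
    d = profile.density
    top = d.max()
    if top <= 0:
        return []
    idx, _ = find_peaks(d, prominence=min_prominence * top)
    peaks = []
    for i in idx:
        p = float(i)
        if 0 < i < d.size - 1:
            denom = d[i - 1] - 2 * d[i] + d[i + 1]
            if denom < 0:
                p += 0.5 * (d[i - 1] - d[i + 1]) / denom
        length = float(calibration.pixel_to_length(p))
        rcrs = None
        if tss_rcrs is not None:
            rcrs = transcript_end_position(tss_rcrs, int(round(length)))
        peaks.append(Peak(length_nt=length, height=float(d[i] / top), pixel=p, rcrs_end=rcrs))
    peaks.sort(key=lambda pk: pk.length_nt)
    return peaks


def peaks_to_frame(peaks: Sequence[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [p.__dict__ for p in peaks],
        columns=["length_nt", "height", "pixel", "rcrs_end"],
    )
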