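"""Sub-pixel FWHM edge localization on vessel density profiles.

The measurement model: a line drawn across a retinal vessel on an OCT
B-scan yields a grayscale density profile on which the two vessel walls
appear as two prominent extrema (valleys for dark walls) flanking the lumen.
Each wall has two flanks — one facing the surrounding tissue (outer) and one
facing the lumen (inner) — and the wall *edge* on a flank is placed where the
intensity crosses the midpoint between that flank's extreme values
(full-width-at-half-maximum convention).  Concretely, per flank:

1. extreme levels are read off a 3-point moving average of the profile
   (suppressing single-sample noise in the peak/trough values);
2. the half level is the arithmetic midpoint of the flank's smoothed
   maximum and minimum;
3. a straight line (chord) is drawn through the pair of *consecutive raw
   samples* with the largest absolute intensity difference inside the flank;
4. the edge is the intersection of that chord with the half level,
   giving a sub-pixel position in µm.

Four edges assemble into an :class:`EdgeSet` ordered along the profile:
outer-upper, inner-upper, inner-lower, outer-lower.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    BandDetectionError,
    DegenerateFlankError,
    EdgeLocalizationError,
    EdgeOrderingError,
    InvalidSpecError,
)
from .image import DensityProfile

__all__ = [
    "DEFAULT_PROMINENCE",
    "WallBand",
    "Chord",
    "EdgeEstimate",
    "EdgeSet",
    "smooth3",
    "locate_bands",
    "flank_half_level",
    "steepest_chord",
    "edge_position",
    "detect_edges",
]

#: default prominence (grayscale units) a smoothed extremum must have to
#: count as a wall or shoulder; suppresses speckle-induced micro-extrema.
DEFAULT_PROMINENCE = 5.0

Polarity = Literal["dark_walls", "bright_walls"]


def smooth3(values: np.ndarray) -> np.ndarray:
    """Centred moving average of window 3; end samples keep raw values.

    The window is never truncated: the two boundary samples are copied
    through unchanged, which is safe because wall edges never sit at the
    profile termini.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise InvalidSpecError("smooth3 needs a 1-D array of at least 3 samples")
    out = v.copy()
    out[1:-1] = (v[:-2] + v[1:-1] + v[2:]) / 3.0
    return out


@dataclass(frozen=True)
class WallBand:
    """One wall extremum with its two flank index ranges (inclusive)."""

    wall: Literal["upper", "lower"]
    extremum_index: int
    outer_flank: tuple[int, int]
    inner_flank: tuple[int, int]

    def __post_init__(self) -> None:
        for lo, hi in (self.outer_flank, self.inner_flank):
            if not 0 <= lo < hi:
                raise InvalidSpecError("flank ranges must be non-empty index intervals")


@dataclass(frozen=True)
class Chord:
    """The line through two consecutive profile samples."""

    i0: int
    i1: int
    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def slope(self) -> float:
        return (self.y1 - self.y0) / (self.x1 - self.x0)

    def solve(self, level: float) -> float:
        """x such that the chord line equals ``level``."""
        return self.x0 + (level - self.y0) / self.slope


@dataclass(frozen=True)
class EdgeEstimate:
    """One sub-pixel wall-edge location."""

    wall: Literal["upper", "lower"]
    side: Literal["outer", "inner"]
    position: float
    half_level: float
    chord_slope: float
    chord_indices: tuple[int, int]


@dataclass(frozen=True)
class EdgeSet:
    """The four wall edges of one vessel cross-section, in profile order."""

    outer_upper: EdgeEstimate
    inner_upper: EdgeEstimate
    inner_lower: EdgeEstimate
    outer_lower: EdgeEstimate

    def __post_init__(self) -> None:
        p = self.positions
        if not (p[0] < p[1] < p[2] < p[3]):
            raise EdgeOrderingError(f"edge positions not strictly increasing: {p}")

    @property
    def positions(self) -> tuple[float, float, float, float]:
        return (
            self.outer_upper.position,
            self.inner_upper.position,
            self.inner_lower.position,
            self.outer_lower.position,
        )


def _wall_signal(smoothed: np.ndarray, polarity: Polarity) -> np.ndarray:
    """Signal in which wall extrema appear as peaks."""
    if polarity == "dark_walls":
        return -smoothed
    if polarity == "bright_walls":
        return smoothed
    raise InvalidSpecError(f"unknown polarity {polarity!r}")


def _last_argmax(a: np.ndarray) -> int:
    """Index of the last occurrence of the maximum (ties break toward the end)."""
    return len(a) - 1 - int(np.argmax(a[::-1]))


def locate_bands(
    profile: DensityProfile,
    polarity: Polarity = "dark_walls",
    prominence: float = DEFAULT_PROMINENCE,
) -> tuple[WallBand, WallBand]:
    """Find the upper and lower wall bands on a smoothed profile.

    The two most prominent wall-polarity extrema are taken as the wall
    centres; a lumen extremum of opposite polarity must lie between them.
    Each wall's inner flank runs from the wall extremum to the lumen
    extremum; its outer flank runs outward to the nearest qualifying
    opposite-polarity extremum (the background shoulder) or, when the
    outward segment is monotone or flat, to its most extreme sample.

    Raises
    ------
    BandDetectionError
        If fewer than two qualifying wall extrema exist, or no lumen
        extremum separates them.  Such profiles are rejected, mirroring the
        manual rule of only measuring images that clearly show the wall.
    """
    s = smooth3(profile.values)
    wsig = _wall_signal(s, polarity)
    wall_peaks, wall_props = find_peaks(wsig, prominence=prominence)
    if len(wall_peaks) < 2:
        raise BandDetectionError(
            f"found {len(wall_peaks)} wall extremum(a); need 2 (prominence >= {prominence})"
        )
    order = np.argsort(wall_props["prominences"])[::-1]
    top2 = np.sort(wall_peaks[order[:2]])
    i_up, i_lo = int(top2[0]), int(top2[1])

    shoulder_peaks, shoulder_props = find_peaks(-wsig, prominence=prominence)
    between = shoulder_peaks[(shoulder_peaks > i_up) & (shoulder_peaks < i_lo)]
    if len(between) == 0:
        raise BandDetectionError("no lumen extremum between the two wall extrema")
    # Inward flank targets: each wall's *adjacent* qualifying
    # opposite-polarity extremum.  On a clean profile both are the single
    # lumen extremum; under speckle the nearest qualifying bump bounds the
    # flank tightly so plateau noise cannot masquerade as the edge.
    i_lum_up = int(between.min())
    i_lum_lo = int(between.max())

    # Outward shoulders: nearest qualifying opposite extremum, else the most
    # extreme sample of the outward segment (last/first occurrence so the
    # flank stays as tight as possible around the wall).
    left_candidates = shoulder_peaks[shoulder_peaks < i_up]
    if len(left_candidates) > 0:
        j_left = int(left_candidates.max())
    else:
        j_left = _last_argmax(-wsig[: i_up + 1])
    right_candidates = shoulder_peaks[shoulder_peaks > i_lo]
    if len(right_candidates) > 0:
        j_right = int(right_candidates.min())
    else:
        j_right = i_lo + int(np.argmax(-wsig[i_lo:]))
    if j_left >= i_up or j_right <= i_lo:
        raise BandDetectionError("wall extremum has no outward flank")

    upper = WallBand("upper", i_up, outer_flank=(j_left, i_up), inner_flank=(i_up, i_lum_up))
    lower = WallBand("lower", i_lo, outer_flank=(i_lo, j_right), inner_flank=(i_lum_lo, i_lo))
    return upper, lower


def flank_half_level(smoothed: np.ndarray, flank: tuple[int, int]) -> float:
    """Midpoint of the smoothed maximum and minimum within a flank.

    This is the "half maximum" level of the method: the edge is placed where
    intensity crosses halfway between the flank's peak and trough, both read
    on the 3-point-averaged curve.
    """
    lo, hi = flank
    seg = np.asarray(smoothed, dtype=float)[lo : hi + 1]
    if len(seg) < 2:
        raise InvalidSpecError("flank must span at least two samples")
    mx, mn = float(seg.max()), float(seg.min())
    if mx == mn:
        raise DegenerateFlankError("flat flank: maximum equals minimum")
    return (mx + mn) / 2.0


def steepest_chord(
    values: np.ndarray,
    flank: tuple[int, int],
    positions: np.ndarray,
    wall_index: int | None = None,
) -> Chord:
    """Line through the consecutive sample pair of largest |difference|.

    Evaluated on the values passed in (raw by default in
    :func:`detect_edges`); ties are broken toward the pair nearest the wall
    extremum so the fitted edge stays adjacent to the wall.
    """
    lo, hi = flank
    v = np.asarray(values, dtype=float)
    x = np.asarray(positions, dtype=float)
    if hi - lo < 1:
        raise InvalidSpecError("flank must span at least two samples")
    diffs = np.abs(np.diff(v[lo : hi + 1]))
    best = float(diffs.max())
    if best == 0:
        raise DegenerateFlankError("no intensity change anywhere in flank")
    candidates = lo + np.flatnonzero(diffs == best)
    if wall_index is not None and len(candidates) > 1:
        dist = np.minimum(
            np.abs(candidates - wall_index), np.abs(candidates + 1 - wall_index)
        )
        candidates = candidates[dist == dist.min()]
    i0 = int(candidates[0])
    i1 = i0 + 1
    return Chord(i0, i1, float(x[i0]), float(v[i0]), float(x[i1]), float(v[i1]))


def edge_position(
    chord: Chord,
    half_level: float,
    flank_bounds: tuple[float, float] | None = None,
) -> float:
    """Intersection of the chord with the half level, in µm.

    The crossing must fall inside the flank being analysed (bounds
    inclusive); a crossing outside it means the chord does not straddle the
    half level and the edge cannot be trusted.
    """
    if chord.y1 == chord.y0:
        raise DegenerateFlankError("chord slope is zero")
    x = chord.solve(half_level)
    if flank_bounds is not None:
        lo, hi = flank_bounds
        tol = 1e-9 * max(1.0, abs(hi - lo))
        if not (lo - tol <= x <= hi + tol):
            raise EdgeLocalizationError(
                f"half-level crossing {x:.3f} µm outside flank [{lo:.3f}, {hi:.3f}]"
            )
    return float(x)


def _flank_edge(
    raw: np.ndarray,
    smoothed: np.ndarray,
    positions: np.ndarray,
    band: WallBand,
    side: Literal["outer", "inner"],
    chord_on: Literal["raw", "smoothed"],
) -> EdgeEstimate:
    flank = band.outer_flank if side == "outer" else band.inner_flank
    level = flank_half_level(smoothed, flank)
    chord_values = raw if chord_on == "raw" else smoothed
    chord = steepest_chord(chord_values, flank, positions, band.extremum_index)
    bounds = (float(positions[flank[0]]), float(positions[flank[1]]))
    pos = edge_position(chord, level, bounds)
    return EdgeEstimate(band.wall, side, pos, level, chord.slope, (chord.i0, chord.i1))


def detect_edges(
    profile: DensityProfile,
    polarity: Polarity = "dark_walls",
    prominence: float = DEFAULT_PROMINENCE,
    chord_on: Literal["raw", "smoothed"] = "raw",
) -> EdgeSet:
    """Locate all four vessel-wall edges on a density profile.

    Runs band detection, then per flank the half-level/steepest-chord
    crossing.  ``chord_on`` selects whether the steepest chord is evaluated
    on the raw profile (default) or on the 3-point-averaged one; the
    smoothed curve is always used for the extreme levels.

    Returns
    -------
    EdgeSet
        With positions strictly increasing along the profile; violations
        raise :class:`~octvessel.errors.EdgeOrderingError`.
    """
    if chord_on not in ("raw", "smoothed"):
        raise InvalidSpecError(f"chord_on must be 'raw' or 'smoothed', got {chord_on!r}")
    upper, lower = locate_bands(profile, polarity, prominence)
    raw = profile.values
    smoothed = smooth3(raw)
    pos = profile.positions
    return EdgeSet(
        outer_upper=_flank_edge(raw, smoothed, pos, upper, "outer", chord_on),
        inner_upper=_flank_edge(raw, smoothed, pos, upper, "inner", chord_on),
        inner_lower=_flank_edge(raw, smoothed, pos, lower, "inner", chord_on),
        outer_lower=_flank_edge(raw, smoothed, pos, lower, "outer", chord_on),
    )
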