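"""Raster OCT images, measurement-line profiles, and the zone B annulus.

Coordinate convention: continuous positions are in micrometres (µm), with
the origin at the centre of the top-left pixel.  ``x`` runs along image
columns (transverse axis), ``y`` along rows (axial axis).  A pixel index
``(row, col)`` therefore sits at ``(x, y) = (col * transverse_pitch,
row * axial_pitch)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize

from .errors import InvalidSpecError, ProfileBoundsError

__all__ = [
    "OCTImage",
    "DensityProfile",
    "ZoneBAnnulus",
    "aspect_normalize",
    "extract_profile",
    "zone_b_annulus",
    "read_image",
    "write_image",
]

#: minimum number of profile samples: two 3-point-averaged extrema plus a gap
MIN_PROFILE_SAMPLES = 7


@dataclass(frozen=True)
class OCTImage:
    """A 2-D grayscale B-scan raster with a physical pixel pitch per axis.

    Parameters
    ----------
    pixels
        2-D float array of grayscale values, nominally in [0, 255].
    axial_pitch
        µm per pixel along rows (depth axis).
    transverse_pitch
        µm per pixel along columns (lateral axis).
    """

    pixels: np.ndarray
    axial_pitch: float
    transverse_pitch: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise InvalidSpecError("image raster must be a non-empty 2-D array")
        if not (self.axial_pitch > 0 and self.transverse_pitch > 0):
            raise InvalidSpecError("pixel pitches must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def is_isotropic(self) -> bool:
        return np.isclose(self.axial_pitch, self.transverse_pitch)

    @property
    def height_um(self) -> float:
        """Physical span between the first and last row centres."""
        return (self.shape[0] - 1) * self.axial_pitch

    @property
    def width_um(self) -> float:
        return (self.shape[1] - 1) * self.transverse_pitch


@dataclass(frozen=True)
class DensityProfile:
    """Grayscale samples along a measurement line, uniformly spaced in µm."""

    values: np.ndarray
    step: float
    start: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise InvalidSpecError("profile values must be 1-D")
        if len(v) < MIN_PROFILE_SAMPLES:
            raise InvalidSpecError(
                f"profile needs at least {MIN_PROFILE_SAMPLES} samples, got {len(v)}"
            )
        if not self.step > 0:
            raise InvalidSpecError("profile step must be positive")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def positions(self) -> np.ndarray:
        """Sample positions in µm measured from the profile start."""
        return self.start + self.step * np.arange(len(self.values))

    @property
    def length_um(self) -> float:
        return self.step * (len(self.values) - 1)

    def reversed(self) -> "DensityProfile":
        """The same physical profile traversed from the other end."""
        return DensityProfile(self.values[::-1].copy(), self.step, self.start)


def aspect_normalize(img: OCTImage) -> OCTImage:
    """Resample an image to an isotropic 1:1 µm pixel grid.

    OCT devices record with different axial and transverse resolutions, so
    the raw raster is anisotropic; distances measured across pixels are only
    meaningful after resampling to a common pitch.  The target pitch is the
    finer (smaller) of the two input pitches, so no information is discarded.
    Resampling is bilinear.  An already-isotropic image is returned unchanged.
    """
    if img.is_isotropic:
        return img
    target = min(img.axial_pitch, img.transverse_pitch)
    rows, cols = img.shape
    new_rows = int(round(rows * img.axial_pitch / target))
    new_cols = int(round(cols * img.transverse_pitch / target))
    out = resize(
        img.pixels,
        (new_rows, new_cols),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return OCTImage(out, target, target)


def extract_profile(
    img: OCTImage,
    p0: tuple[float, float],
    p1: tuple[float, float],
    step: float | None = None,
) -> DensityProfile:
    """Sample a density profile along the segment ``p0 -> p1`` (µm).

    This is the "line tool" of the measurement protocol: a straight line is
    drawn through a vessel and grayscale values are read off at uniform
    spacing by bilinear interpolation.  Positions are measured from ``p0``.

    Parameters
    ----------
    p0, p1
        Segment end points as ``(x, y)`` in µm.
    step
        Sample spacing in µm; defaults to the finer pixel pitch of ``img``.

    Raises
    ------
    ProfileBoundsError
        If either end point (hence part of the segment) lies outside the
        raster.
    """
    if step is None:
        step = min(img.axial_pitch, img.transverse_pitch)
    if not step > 0:
        raise InvalidSpecError("profile step must be positive")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    if length == 0:
        raise InvalidSpecError("profile end points coincide")
    n = int(np.floor(length / step + 1e-9)) + 1
    t = step * np.arange(n)
    pts = p0[None, :] + (p1 - p0)[None, :] / length * t[:, None]
    cols = pts[:, 0] / img.transverse_pitch
    rows = pts[:, 1] / img.axial_pitch
    eps = 1e-9
    nrows, ncols = img.shape
    if (
        rows.min() < -eps
        or cols.min() < -eps
        or rows.max() > nrows - 1 + eps
        or cols.max() > ncols - 1 + eps
    ):
        raise ProfileBoundsError("measurement line leaves the image raster")
    values = ndimage.map_coordinates(
        img.pixels,
        np.vstack([np.clip(rows, 0, nrows - 1), np.clip(cols, 0, ncols - 1)]),
        order=1,
        mode="nearest",
    )
    return DensityProfile(values, step)


@dataclass(frozen=True)
class ZoneBAnnulus:
    """The annular measurement region around the optic disc."""

    center: tuple[float, float]
    inner_radius: float
    outer_radius: float
    mode: str

    def contains(self, point: tuple[float, float]) -> bool:
        r = float(np.hypot(point[0] - self.center[0], point[1] - self.center[1]))
        return self.inner_radius <= r <= self.outer_radius


def zone_b_annulus(
    disc_center: tuple[float, float],
    disc_diameter: float,
    mode: Literal["ring", "standard"] = "ring",
) -> ZoneBAnnulus:
    """Build the zone B annulus for point-in-zone queries.

    Two conventions are supported, because the positioning-ring protocol and
    the conventional fundus-photography definition of zone B disagree:

    ``ring``
        Concentric circles of 1.0 and 1.5 disc diameters centred on the disc,
        i.e. radii ``(0.5 D, 0.75 D)`` — the region delimited by the drawn
        positioning ring.
    ``standard``
        The conventional zone B: 0.5 to 1.0 disc diameters from the disc
        *margin*, i.e. radii ``(0.75 D, 1.0 D)``.
    """
    if not disc_diameter > 0:
        raise InvalidSpecError("disc diameter must be positive")
    d = float(disc_diameter)
    if mode == "ring":
        radii = (0.5 * d, 0.75 * d)
    elif mode == "standard":
        radii = (0.75 * d, 1.0 * d)
    else:
        raise InvalidSpecError(f"unknown zone mode {mode!r}")
    return ZoneBAnnulus(tuple(map(float, disc_center)), radii[0], radii[1], mode)


def read_image(
    path: str | Path, axial_pitch: float, transverse_pitch: float
) -> OCTImage:
    """Read an 8-bit grayscale BMP/PNG/TIFF as an :class:`OCTImage`."""
    with Image.open(path) as im:
        px = np.asarray(im.convert("L"), dtype=float)
    return OCTImage(px, axial_pitch, transverse_pitch)


def write_image(img: OCTImage, path: str | Path) -> None:
    """Write the raster as an 8-bit grayscale image (format from suffix)."""
    px = np.clip(np.round(img.pixels), 0, 255).astype(np.uint8)
    Image.fromarray(px, mode="L").save(path)
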