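"""Synthetic OCT vessel phantoms and cohort simulation.

No raw per-patient data exist for the measurement protocol this package
implements, so every downstream stage is exercised against synthetic inputs
with known ground truth:

* :func:`render_profile` — a 1-D density profile across an idealized vessel
  (background | wall | lumen | wall | background), Gaussian-blurred to
  emulate the system PSF and optionally degraded with multiplicative
  gamma speckle, the standard surrogate for coherent-imaging noise.
* :func:`render_bscan` — a 2-D pseudo-B-scan of the same vessel as a
  concentric disk/annulus model.
* :func:`simulate_cohort` / :func:`simulate_study` — per-eye parameter
  tables drawn from normal summaries, with the derived columns (wall
  thicknesses, arteriovenous ratio) recomputed row-wise from the drawn
  diameters so the defining identities hold exactly in every record.

Ground-truth wall-edge positions are the template's discontinuities; a
symmetric blur crosses the half level exactly at a step, so for isolated
edges the truth is also the ideal FWHM answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, special

from . import reference
from .errors import InvalidSpecError
from .image import DensityProfile, OCTImage
from .metrics import arteriovenous_ratio, wall_thickness

__all__ = [
    "SyntheticVesselSpec",
    "GroundTruth",
    "CohortSpec",
    "render_profile",
    "render_bscan",
    "simulate_cohort",
    "simulate_study",
]


@dataclass(frozen=True)
class SyntheticVesselSpec:
    """Geometry, contrast and noise of one synthetic vessel cross-section.

    Defaults describe a typical retinal arteriole as measured by this
    protocol (outer diameter 147 µm, lumen 114 µm) imaged at 5 µm pitch
    with a 5 µm PSF sigma, dark walls on mid-gray tissue with a bright
    lumen, and no speckle.

    Parameters
    ----------
    speckle_shape
        Shape of the unit-mean gamma multiplicative noise (variance =
        1/shape).  ``None`` or ``inf`` means noiseless.
    """

    outer_diameter: float = 147.0
    lumen_diameter: float = 114.0
    wall_intensity: float = 60.0
    lumen_intensity: float = 200.0
    background_intensity: float = 140.0
    psf_sigma: float = 5.0
    speckle_shape: float | None = None
    pixel_pitch: float = 5.0
    polarity: Literal["dark_walls", "bright_walls"] = "dark_walls"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.outer_diameter > self.lumen_diameter > 0:
            raise InvalidSpecError("need outer_diameter > lumen_diameter > 0")
        if self.psf_sigma < 0:
            raise InvalidSpecError("psf_sigma must be >= 0")
        if not self.pixel_pitch > 0:
            raise InvalidSpecError("pixel_pitch must be positive")
        for name in ("wall_intensity", "lumen_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise InvalidSpecError(f"{name} must lie in [0, 255]")
        if self.speckle_shape is not None and not self.speckle_shape > 0:
            raise InvalidSpecError("speckle_shape must be positive (or None)")
        if self.polarity == "dark_walls":
            if not self.wall_intensity < min(self.lumen_intensity, self.background_intensity):
                raise InvalidSpecError("dark_walls requires wall darker than lumen and background")
        elif self.polarity == "bright_walls":
            if not self.wall_intensity > max(self.lumen_intensity, self.background_intensity):
                raise InvalidSpecError("bright_walls requires wall brighter than lumen and background")
        else:
            raise InvalidSpecError(f"unknown polarity {self.polarity!r}")

    @property
    def wall_thickness(self) -> float:
        return (self.outer_diameter - self.lumen_diameter) / 2.0

    @property
    def noiseless(self) -> bool:
        return self.speckle_shape is None or math.isinf(self.speckle_shape)


@dataclass(frozen=True)
class GroundTruth:
    """True wall-edge positions (µm) along the profile axis."""

    outer_upper: float
    inner_upper: float
    inner_lower: float
    outer_lower: float

    def __post_init__(self) -> None:
        if not (self.outer_upper < self.inner_upper < self.inner_lower < self.outer_lower):
            raise InvalidSpecError("ground-truth edges must be strictly increasing")

    @property
    def edges(self) -> tuple[float, float, float, float]:
        return (self.outer_upper, self.inner_upper, self.inner_lower, self.outer_lower)

    @property
    def outer_diameter(self) -> float:
        return self.outer_lower - self.outer_upper

    @property
    def lumen_diameter(self) -> float:
        return self.inner_lower - self.inner_upper

    def mirrored(self, about: float) -> "GroundTruth":
        """The truth of the same profile traversed from the other end."""
        e = [2 * about - x for x in self.edges]
        return GroundTruth(e[3], e[2], e[1], e[0])


def _default_length(spec: SyntheticVesselSpec) -> float:
    # outer diameter plus 6 sigma of blur plus a 30 µm background shoulder
    # on each side, so the shoulders reach their plateau.
    return spec.outer_diameter + 6.0 * spec.psf_sigma + 60.0


def _template_1d(x: np.ndarray, spec: SyntheticVesselSpec, center: float) -> np.ndarray:
    r = np.abs(x - center)
    out = np.full_like(x, spec.background_intensity, dtype=float)
    out[r <= spec.outer_diameter / 2.0] = spec.wall_intensity
    out[r <= spec.lumen_diameter / 2.0] = spec.lumen_intensity
    return out


def _blurred_1d(x: np.ndarray, spec: SyntheticVesselSpec, center: float) -> np.ndarray:
    """Analytic Gaussian blur of the piecewise-constant template.

    Convolving a step with a Gaussian gives the normal CDF, so the blurred
    template is a sum of four scaled CDF terms — exact, with no discrete
    convolution error.
    """
    if spec.psf_sigma < 1e-6:  # physically zero; avoids overflow in x/sigma
        return _template_1d(x, spec, center)
    s = spec.psf_sigma
    e1 = center - spec.outer_diameter / 2.0
    e2 = center - spec.lumen_diameter / 2.0
    e3 = center + spec.lumen_diameter / 2.0
    e4 = center + spec.outer_diameter / 2.0
    phi = special.ndtr
    bg, wall, lum = (
        spec.background_intensity,
        spec.wall_intensity,
        spec.lumen_intensity,
    )
    return (
        bg
        + (wall - bg) * (phi((x - e1) / s) - phi((x - e4) / s))
        + (lum - wall) * (phi((x - e2) / s) - phi((x - e3) / s))
    )


def _speckle(spec: SyntheticVesselSpec, shape: tuple[int, ...]) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    k = float(spec.speckle_shape)  # type: ignore[arg-type]
    return rng.gamma(k, 1.0 / k, size=shape)


def render_profile(
    spec: SyntheticVesselSpec, length: float | None = None
) -> tuple[DensityProfile, GroundTruth]:
    """Render a 1-D density profile with known edge positions.

    The vessel is centred on the profile; samples sit at multiples of the
    pixel pitch.  ``length`` (µm) must exceed ``outer_diameter +
    6 * psf_sigma`` so that both background shoulders are present.
    """
    if length is None:
        length = _default_length(spec)
    if not length > 0:
        raise InvalidSpecError("profile length must be positive")
    if not length > spec.outer_diameter + 6.0 * spec.psf_sigma:
        raise InvalidSpecError(
            "profile length must exceed outer_diameter + 6*psf_sigma"
        )
    n = int(round(length / spec.pixel_pitch)) + 1
    x = spec.pixel_pitch * np.arange(n)
    center = x[-1] / 2.0
    values = _blurred_1d(x, spec, center)
    if not spec.noiseless:
        values = values * _speckle(spec, values.shape)
    truth = GroundTruth(
        center - spec.outer_diameter / 2.0,
        center - spec.lumen_diameter / 2.0,
        center + spec.lumen_diameter / 2.0,
        center + spec.outer_diameter / 2.0,
    )
    return DensityProfile(values, spec.pixel_pitch), truth


def render_bscan(
    spec: SyntheticVesselSpec,
    height: int | None = None,
    width: int | None = None,
) -> tuple[OCTImage, GroundTruth]:
    """Render a pseudo-B-scan: a lumen disk inside a wall annulus.

    The vessel centre sits at the exact raster centre ``((h-1)/2, (w-1)/2)``
    in pixels.  Ground truth is given for the vertical measurement line
    through the vessel centre, with positions measured from the top row.
    Blur is a discrete 2-D Gaussian; speckle, when enabled, is i.i.d. per
    pixel.
    """
    if height is None:
        height = int(math.ceil(_default_length(spec) / spec.pixel_pitch)) + 1
    if width is None:
        width = height
    if height < 2 or width < 2:
        raise InvalidSpecError("bscan canvas must be at least 2x2 pixels")
    span = (min(height, width) - 1) * spec.pixel_pitch
    if not span > spec.outer_diameter + 6.0 * spec.psf_sigma:
        raise InvalidSpecError("bscan canvas too small for the vessel annulus plus blur margin")
    yy, xx = np.meshgrid(
        spec.pixel_pitch * np.arange(height),
        spec.pixel_pitch * np.arange(width),
        indexing="ij",
    )
    cy = spec.pixel_pitch * (height - 1) / 2.0
    cx = spec.pixel_pitch * (width - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    img = np.full_like(r, spec.background_intensity, dtype=float)
    img[r <= spec.outer_diameter / 2.0] = spec.wall_intensity
    img[r <= spec.lumen_diameter / 2.0] = spec.lumen_intensity
    if spec.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.psf_sigma / spec.pixel_pitch, mode="nearest")
    if not spec.noiseless:
        img = img * _speckle(spec, img.shape)
    truth = GroundTruth(
        cy - spec.outer_diameter / 2.0,
        cy - spec.lumen_diameter / 2.0,
        cy + spec.lumen_diameter / 2.0,
        cy + spec.outer_diameter / 2.0,
    )
    return OCTImage(img, spec.pixel_pitch, spec.pixel_pitch), truth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

#: the four directly drawn diameters; AWT, VWT, AVR are derived row-wise
DRAWN = ("RALD", "RAOD", "RVLD", "RVOD")

ArmSummary = Mapping[str, tuple[float, float]]


@dataclass(frozen=True)
class CohortSpec:
    """Two arms of per-eye vessel parameters drawn from normal summaries.

    ``arm_a``/``arm_b`` map parameter names to (mean, SD); the four
    diameters RALD, RAOD, RVLD, RVOD are drawn, and AWT, VWT, AVR are
    recomputed from the drawn diameters so the defining identities hold in
    every record (summaries supplied for derived parameters are ignored).

    ``lumen_outer_corr`` correlates each vessel's lumen and outer diameter
    within an eye — anatomically the two track each other closely, and the
    published wall-thickness SDs are far smaller than the diameter SDs,
    implying a correlation near 0.9.  ``within_subject_corr`` applies
    between the two arms when ``paired`` (same subject measured twice).
    """

    arm_a: ArmSummary
    arm_b: ArmSummary
    n_a: int
    n_b: int
    paired: bool = False
    within_subject_corr: float = 0.9
    lumen_outer_corr: float = 0.9
    labels_a: tuple[int, str, str] = (0, "right", "single")
    labels_b: tuple[int, str, str] = (1, "ipsilateral", "pre_cas")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_a < 2 or self.n_b < 2:
            raise InvalidSpecError("arm sizes must be at least 2")
        if self.paired and self.n_a != self.n_b:
            raise InvalidSpecError("paired arms must have equal sizes")
        for corr in (self.within_subject_corr, self.lumen_outer_corr):
            if not 0 <= corr < 1:
                raise InvalidSpecError("correlations must lie in [0, 1)")
        for arm in (self.arm_a, self.arm_b):
            for p in DRAWN:
                if p not in arm:
                    raise InvalidSpecError(f"arm summary missing parameter {p}")
                if arm[p][1] < 0:
                    raise InvalidSpecError("SDs must be non-negative")


def _equicorr(k: int, rho: float) -> np.ndarray:
    c = np.full((k, k), rho)
    np.fill_diagonal(c, 1.0)
    return c


def _draw_correlated(
    rng: np.random.Generator,
    means: np.ndarray,
    sds: np.ndarray,
    corr: np.ndarray,
    n: int,
) -> np.ndarray:
    """n draws from N(means, diag(sds) @ corr @ diag(sds))."""
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by spec bounds
        raise InvalidSpecError("degenerate covariance structure") from exc
    z = rng.standard_normal((n, len(means)))
    return means + (z @ chol.T) * sds


def _vessel_block(
    rng: np.random.Generator,
    summaries: Sequence[ArmSummary],
    lumen_key: str,
    outer_key: str,
    n: int,
    cond_corr: np.ndarray,
    lumen_outer_corr: float,
) -> np.ndarray:
    """Draw (n, n_cond, 2) lumen/outer diameters across correlated conditions."""
    k = len(summaries)
    means, sds = [], []
    for s in summaries:
        means += [s[lumen_key][0], s[outer_key][0]]
        sds += [s[lumen_key][1], s[outer_key][1]]
    corr = np.kron(cond_corr, _equicorr(2, lumen_outer_corr))
    draws = _draw_correlated(rng, np.array(means), np.array(sds), corr, n)
    return draws.reshape(n, k, 2)


def _records_frame(
    subject_ids: Sequence[str],
    labels: Sequence[tuple[int, str, str]],
    artery: np.ndarray,
    vein: np.ndarray,
) -> pd.DataFrame:
    """Assemble rows for every (subject, condition), deriving AWT/VWT/AVR."""
    rows = []
    for i, sid in enumerate(subject_ids):
        for c, (group, eye, timepoint) in enumerate(labels):
            rald, raod = artery[i, c]
            rvld, rvod = vein[i, c]
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "eye": eye,
                    "timepoint": timepoint,
                    "RALD": rald,
                    "RAOD": raod,
                    "AWT": wall_thickness(raod, rald),
                    "RVLD": rvld,
                    "RVOD": rvod,
                    "VWT": wall_thickness(rvod, rvld),
                    "AVR": arteriovenous_ratio(raod, rvod),
                }
            )
    return pd.DataFrame(rows)


def _draw_arm_set(
    rng: np.random.Generator,
    summaries: Sequence[ArmSummary],
    labels: Sequence[tuple[int, str, str]],
    n: int,
    cond_corr: np.ndarray,
    lumen_outer_corr: float,
    id_prefix: str,
) -> pd.DataFrame:
    artery = _vessel_block(rng, summaries, "RALD", "RAOD", n, cond_corr, lumen_outer_corr)
    vein = _vessel_block(rng, summaries, "RVLD", "RVOD", n, cond_corr, lumen_outer_corr)
    ids = [f"{id_prefix}{i + 1:04d}" for i in range(n)]
    return _records_frame(ids, labels, artery, vein)


def simulate_cohort(cs: CohortSpec) -> pd.DataFrame:
    """Simulate a two-arm cohort of per-eye records.

    Returns a table with one row per eye record and columns ``subject_id,
    group, eye, timepoint, RALD, RAOD, AWT, RVLD, RVOD, VWT, AVR``.  When
    ``paired``, the two arms are drawn jointly per subject at the
    within-subject correlation and share subject ids.
    """
    rng = np.random.default_rng(cs.seed)
    if cs.paired:
        cond_corr = _equicorr(2, cs.within_subject_corr)
        return _draw_arm_set(
            rng,
            [cs.arm_a, cs.arm_b],
            [cs.labels_a, cs.labels_b],
            cs.n_a,
            cond_corr,
            cs.lumen_outer_corr,
            "S",
        )
    one = np.eye(1)
    frame_a = _draw_arm_set(
        rng, [cs.arm_a], [cs.labels_a], cs.n_a, one, cs.lumen_outer_corr, "A"
    )
    frame_b = _draw_arm_set(
        rng, [cs.arm_b], [cs.labels_b], cs.n_b, one, cs.lumen_outer_corr, "B"
    )
    return pd.concat([frame_a, frame_b], ignore_index=True)


def simulate_study(
    n0: int | None = None,
    n1: int | None = None,
    within_subject_corr: float = 0.9,
    lumen_outer_corr: float = 0.9,
    seed: int = 0,
    summaries: Mapping[tuple[int, str, str], ArmSummary] | None = None,
) -> pd.DataFrame:
    """Simulate the full two-group study layout.

    Group 0 subjects contribute left and right eyes (one timepoint); group 1
    subjects contribute ipsilateral and contralateral eyes both before and
    after stenting (four correlated conditions per subject).  Defaults for
    arm sizes and parameter summaries come from the published study tables
    (:mod:`octvessel.reference`); repeated conditions within a subject are
    equicorrelated at ``within_subject_corr``.
    """
    if summaries is None:
        summaries = reference.ARM_SUMMARIES
    if n0 is None:
        n0 = reference.GROUP_SIZES[0]
    if n1 is None:
        n1 = reference.GROUP_SIZES[1]
    if n0 < 2 or n1 < 2:
        raise InvalidSpecError("group sizes must be at least 2")
    rng = np.random.default_rng(seed)
    g0_labels = [(0, "left", "single"), (0, "right", "single")]
    g1_labels = [
        (1, "ipsilateral", "pre_cas"),
        (1, "ipsilateral", "post_cas"),
        (1, "contralateral", "pre_cas"),
        (1, "contralateral", "post_cas"),
    ]
    g0 = _draw_arm_set(
        rng,
        [summaries[k] for k in g0_labels],
        g0_labels,
        n0,
        _equicorr(2, within_subject_corr),
        lumen_outer_corr,
        "G0-",
    )
    g1 = _draw_arm_set(
        rng,
        [summaries[k] for k in g1_labels],
        g1_labels,
        n1,
        _equicorr(4, within_subject_corr),
        lumen_outer_corr,
        "G1-",
    )
    return pd.concat([g0, g1], ignore_index=True)
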