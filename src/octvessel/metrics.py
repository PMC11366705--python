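"""Vessel parameters derived from edge sets.

Seven parameters describe one eye: the arteriolar and venular lumen and
outer diameters (RALD, RAOD, RVLD, RVOD, in µm), the wall thicknesses

    AWT = (RAOD - RALD) / 2        VWT = (RVOD - RVLD) / 2

and the arteriovenous ratio AVR = RAOD / RVOD.  Each vessel is measured in
triplicate and the replicate diameters averaged before the derived
parameters are computed (so AVR is a ratio of mean diameters; see
``ratio_of_means`` on :func:`derive_record` for the alternative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidSpecError, SchemaError
from .fwhm import EdgeSet

__all__ = [
    "PARAMETERS",
    "VesselMeasurement",
    "EyeRecord",
    "wall_thickness",
    "arteriovenous_ratio",
    "diameters_from_edges",
    "average_replicates",
    "derive_record",
    "records_to_frame",
    "validate_cohort_frame",
]

logger = logging.getLogger(__name__)

PARAMETERS = ("RALD", "RAOD", "AWT", "RVLD", "RVOD", "VWT", "AVR")

#: columns every cohort table must carry
COHORT_COLUMNS = ("subject_id", "group", "eye", "timepoint") + PARAMETERS

EXPECTED_REPLICATES = 3


def wall_thickness(outer: float, lumen: float) -> float:
    """Wall thickness from outer and lumen diameter: ``(outer - lumen) / 2``."""
    return (outer - lumen) / 2.0


def arteriovenous_ratio(raod: float, rvod: float) -> float:
    """Arteriovenous ratio: arteriolar over venular outer diameter."""
    if rvod == 0:
        raise InvalidSpecError("venular outer diameter must be nonzero for AVR")
    return raod / rvod


def diameters_from_edges(es: EdgeSet) -> tuple[float, float]:
    """(lumen, outer) diameters in µm from one edge set.

    Outer diameter spans the two outer edges, lumen diameter the two inner
    edges; both are invariant to where the vessel sits on the profile.
    """
    lumen = es.inner_lower.position - es.inner_upper.position
    outer = es.outer_lower.position - es.outer_upper.position
    return float(lumen), float(outer)


@dataclass(frozen=True)
class VesselMeasurement:
    """Replicate diameter measurements of one vessel, with their means."""

    vessel: Literal["artery", "vein"]
    lumen_replicates: tuple[float, ...]
    outer_replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.lumen_replicates) != len(self.outer_replicates):
            raise InvalidSpecError("replicate lists must have equal length")
        if len(self.lumen_replicates) == 0:
            raise InvalidSpecError("at least one replicate required")
        for lum, out in zip(self.lumen_replicates, self.outer_replicates):
            if out < lum:
                raise InvalidSpecError(
                    f"replicate outer diameter {out} smaller than lumen {lum}"
                )

    @property
    def lumen_diameter(self) -> float:
        return float(np.mean(self.lumen_replicates))

    @property
    def outer_diameter(self) -> float:
        return float(np.mean(self.outer_replicates))


def average_replicates(
    replicates: Sequence[tuple[float, float]],
    vessel: Literal["artery", "vein"] = "artery",
) -> VesselMeasurement:
    """Average replicate (lumen, outer) diameter pairs for one vessel.

    The protocol measures each vessel three times and uses the arithmetic
    mean; a deviating replicate count is accepted but logged.
    """
    if len(replicates) == 0:
        raise InvalidSpecError("no replicates to average")
    if len(replicates) != EXPECTED_REPLICATES:
        logger.warning(
            "%s measured %d time(s); protocol expects %d",
            vessel,
            len(replicates),
            EXPECTED_REPLICATES,
        )
    lumen = tuple(float(r[0]) for r in replicates)
    outer = tuple(float(r[1]) for r in replicates)
    return VesselMeasurement(vessel, lumen, outer)


@dataclass(frozen=True)
class EyeRecord:
    """One eye at one timepoint with all seven vessel parameters."""

    subject_id: str
    group: int
    eye: Literal["left", "right", "ipsilateral", "contralateral"]
    timepoint: Literal["pre_cas", "post_cas", "single"]
    RALD: float
    RAOD: float
    AWT: float
    RVLD: float
    RVOD: float
    VWT: float
    AVR: float

    def __post_init__(self) -> None:
        if not (self.RAOD >= self.RALD >= 0 and self.RVOD >= self.RVLD >= 0):
            raise InvalidSpecError("diameters must satisfy outer >= lumen >= 0")
        if not np.isclose(self.AWT, wall_thickness(self.RAOD, self.RALD)):
            raise InvalidSpecError("AWT inconsistent with (RAOD - RALD)/2")
        if not np.isclose(self.VWT, wall_thickness(self.RVOD, self.RVLD)):
            raise InvalidSpecError("VWT inconsistent with (RVOD - RVLD)/2")
        if not np.isclose(self.AVR, self.RAOD / self.RVOD) or self.AVR <= 0:
            raise InvalidSpecError("AVR inconsistent with RAOD/RVOD")

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "eye": self.eye,
            "timepoint": self.timepoint,
            **{p: getattr(self, p) for p in PARAMETERS},
        }


def derive_record(
    artery: VesselMeasurement,
    vein: VesselMeasurement,
    subject_id: str = "anon",
    group: int = 0,
    eye: str = "right",
    timepoint: str = "single",
) -> EyeRecord:
    """Build an :class:`EyeRecord` from averaged artery and vein measurements.

    All derived parameters come from the averaged diameters, so AVR is a
    ratio of means; :func:`mean_replicate_avr` provides the alternative
    (mean of per-replicate ratios), which cannot live inside an
    :class:`EyeRecord` because the record enforces ``AVR = RAOD / RVOD``
    exactly.
    """
    rald, raod = artery.lumen_diameter, artery.outer_diameter
    rvld, rvod = vein.lumen_diameter, vein.outer_diameter
    avr = arteriovenous_ratio(raod, rvod)
    return EyeRecord(
        subject_id,
        int(group),
        eye,
        timepoint,
        rald,
        raod,
        wall_thickness(raod, rald),
        rvld,
        rvod,
        wall_thickness(rvod, rvld),
        avr,
    )


def mean_replicate_avr(artery: VesselMeasurement, vein: VesselMeasurement) -> float:
    """Mean of per-replicate AVRs (the alternative to the ratio of means)."""
    if len(artery.outer_replicates) != len(vein.outer_replicates):
        raise InvalidSpecError("per-replicate AVR needs equal replicate counts")
    return float(
        np.mean(
            [
                arteriovenous_ratio(a, v)
                for a, v in zip(artery.outer_replicates, vein.outer_replicates)
            ]
        )
    )


def records_to_frame(records: Iterable[EyeRecord]) -> pd.DataFrame:
    """Collect eye records into a cohort table."""
    frame = pd.DataFrame([r.as_dict() for r in records])
    if frame.empty:
        raise InvalidSpecError("no records to collect")
    return frame


def validate_cohort_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Check a cohort table's schema; returns the frame for chaining."""
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns: {missing}")
    bad = frame.index[~frame["group"].isin([0, 1])].tolist()
    if bad:
        raise SchemaError(f"rows with group not in {{0, 1}}: {bad[:10]}")
    bad = frame.index[
        ~frame["eye"].isin(["left", "right", "ipsilateral", "contralateral"])
    ].tolist()
    if bad:
        raise SchemaError(f"rows with unknown eye label: {bad[:10]}")
    bad = frame.index[
        ~frame["timepoint"].isin(["pre_cas", "post_cas", "single"])
    ].tolist()
    if bad:
        raise SchemaError(f"rows with unknown timepoint label: {bad[:10]}")
    return frame
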