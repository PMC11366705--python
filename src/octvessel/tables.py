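"""Assemble the study's comparison tables from a cohort of eye records.

Eight comparisons make up the battery:

========================  =============================  ========
name                      contrast                       pairing
========================  =============================  ========
g0_left_vs_right          group 0 left vs right eye      paired
g1pre_vs_g0_right         stenosis ipsi pre vs ctrl R    independent
g1pre_vs_g0_left          stenosis ipsi pre vs ctrl L    independent
g1post_vs_g0_right        stenosis ipsi post vs ctrl R   independent
g1post_vs_g0_left         stenosis ipsi post vs ctrl L   independent
g1_ipsi_vs_contra_pre     ipsi vs contra, before CAS     paired
g1_ipsi_vs_contra_post    ipsi vs contra, after CAS      paired
g1_pre_vs_post            ipsi before vs after CAS       paired
========================  =============================  ========

Paired contrasts compare the same subjects and are joined on
``subject_id``; independent contrasts compare the stenosis group against
the control group.  Per parameter, a Shapiro-Wilk gate (optional, on by
default) routes to t-tests or rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InfiniteStatisticError, InvalidSpecError
from .metrics import PARAMETERS, validate_cohort_frame
from .stats import (
    ALPHA,
    StatResult,
    independent_t,
    paired_t,
    rank_test,
    shapiro_wilk_gate,
)

__all__ = ["COMPARISONS", "StudyBattery", "build_tables"]

ArmKey = tuple[int, str, str]

#: name -> (arm_a key, arm_b key, paired)
COMPARISONS: dict[str, tuple[ArmKey, ArmKey, bool]] = {
    "g0_left_vs_right": ((0, "left", "single"), (0, "right", "single"), True),
    "g1pre_vs_g0_right": ((1, "ipsilateral", "pre_cas"), (0, "right", "single"), False),
    "g1pre_vs_g0_left": ((1, "ipsilateral", "pre_cas"), (0, "left", "single"), False),
    "g1post_vs_g0_right": ((1, "ipsilateral", "post_cas"), (0, "right", "single"), False),
    "g1post_vs_g0_left": ((1, "ipsilateral", "post_cas"), (0, "left", "single"), False),
    "g1_ipsi_vs_contra_pre": (
        (1, "ipsilateral", "pre_cas"),
        (1, "contralateral", "pre_cas"),
        True,
    ),
    "g1_ipsi_vs_contra_post": (
        (1, "ipsilateral", "post_cas"),
        (1, "contralateral", "post_cas"),
        True,
    ),
    "g1_pre_vs_post": (
        (1, "ipsilateral", "pre_cas"),
        (1, "ipsilateral", "post_cas"),
        True,
    ),
}


@dataclass
class StudyBattery:
    """All comparison tables plus a report of anything skipped."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    def to_csv_dir(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name, frame in self.tables.items():
            frame.to_csv(d / f"{name}.csv", index=False)
        if self.skipped:
            pd.Series(self.skipped, name="reason").rename_axis("table").to_csv(
                d / "skipped.csv"
            )


def _select_arm(frame: pd.DataFrame, key: ArmKey) -> pd.DataFrame:
    group, eye, timepoint = key
    return frame[
        (frame["group"] == group)
        & (frame["eye"] == eye)
        & (frame["timepoint"] == timepoint)
    ]


def _row_result(
    a: np.ndarray, b: np.ndarray, paired: bool, gate: bool, alpha: float
) -> StatResult:
    route = "normal"
    if gate:
        try:
            if paired:
                route = shapiro_wilk_gate(a - b, alpha)
            else:
                routes = {shapiro_wilk_gate(a, alpha), shapiro_wilk_gate(b, alpha)}
                route = "skewed" if "skewed" in routes else "normal"
        except InvalidSpecError:
            route = "normal"
    try:
        if route == "skewed":
            return rank_test(a, b, paired=paired)
        return paired_t(a, b) if paired else independent_t(a, b)
    except InfiniteStatisticError:
        return StatResult("degenerate", float("nan"), None, float("nan"))


def build_tables(
    cohort: pd.DataFrame,
    use_normality_gate: bool = True,
    alpha: float = ALPHA,
) -> StudyBattery:
    """Run the full comparison battery on a cohort table.

    Each table row carries both arms' mean and SD, the test used, its
    statistic, degrees of freedom and p-value for one of the seven vessel
    parameters.  Contrasts whose arms are missing from the cohort (for
    example no post-stenting records) are skipped with a reason rather
    than failing the whole battery.
    """
    cohort = validate_cohort_frame(cohort)
    battery = StudyBattery()
    for name, (key_a, key_b, paired) in COMPARISONS.items():
        arm_a = _select_arm(cohort, key_a)
        arm_b = _select_arm(cohort, key_b)
        if len(arm_a) < 2 or len(arm_b) < 2:
            battery.skipped[name] = (
                f"arm sizes {len(arm_a)} vs {len(arm_b)}; need at least 2 each"
            )
            continue
        if paired:
            merged = arm_a.merge(arm_b, on="subject_id", suffixes=("_a", "_b"))
            if len(merged) < 2:
                battery.skipped[name] = (
                    f"only {len(merged)} subject(s) present in both paired arms"
                )
                continue
        rows = []
        for p in PARAMETERS:
            if paired:
                va = merged[f"{p}_a"].to_numpy(float)
                vb = merged[f"{p}_b"].to_numpy(float)
            else:
                va = arm_a[p].to_numpy(float)
                vb = arm_b[p].to_numpy(float)
            res = _row_result(va, vb, paired, use_normality_gate, alpha)
            rows.append(
                {
                    "parameter": p,
                    "mean_a": va.mean(),
                    "sd_a": va.std(ddof=1),
                    "n_a": len(va),
                    "mean_b": vb.mean(),
                    "sd_b": vb.std(ddof=1),
                    "n_b": len(vb),
                    "test": res.test,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p": res.p,
                }
            )
        battery.tables[name] = pd.DataFrame(rows)
    return battery
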