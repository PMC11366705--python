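"""Published summary statistics used as simulation defaults and test inputs.

These are the per-arm summary rows (mean, SD) of the seven vessel
parameters, the arm sizes, and the 2x2 contingency counts of a two-group
carotid-artery-stenosis cohort study measured with this FWHM protocol
(group 0: no stenosis, both eyes; group 1: unilateral stenosis, ipsilateral
and contralateral eyes before and after carotid artery stenting).  The raw
per-eye data were never deposited, so these printed summaries are the only
quantitative anchor available: the cohort simulator uses them as its default
generating parameters and the statistics battery can recompute test
statistics directly from them.
"""

from __future__ import annotations

PARAMETERS = ("RALD", "RAOD", "AWT", "RVLD", "RVOD", "VWT", "AVR")

#: arm sizes: 59 subjects without stenosis (group 0), 50 with (group 1)
GROUP_SIZES = {0: 59, 1: 50}

#: (group, eye, timepoint) -> parameter -> (mean, SD); µm except AVR
ARM_SUMMARIES: dict[tuple[int, str, str], dict[str, tuple[float, float]]] = {
    (0, "left", "single"): {
        "RALD": (114.46, 9.79),
        "RAOD": (147.33, 10.81),
        "AWT": (16.44, 2.21),
        "RVLD": (150.21, 16.52),
        "RVOD": (178.01, 16.6),
        "VWT": (13.9, 3.37),
        "AVR": (0.83, 0.07),
    },
    (0, "right", "single"): {
        "RALD": (114.67, 11.86),
        "RAOD": (146.91, 12.36),
        "AWT": (16.12, 2.63),
        "RVLD": (149.91, 17.33),
        "RVOD": (177.49, 18.35),
        "VWT": (13.79, 3.16),
        "AVR": (0.83, 0.07),
    },
    (1, "ipsilateral", "pre_cas"): {
        "RALD": (103.96, 11.56),
        "RAOD": (135.42, 12.17),
        "AWT": (15.73, 2.46),
        "RVLD": (155.25, 16.51),
        "RVOD": (186.84, 18.65),
        "VWT": (15.79, 3.65),
        "AVR": (0.73, 0.09),
    },
    (1, "ipsilateral", "post_cas"): {
        "RALD": (108.02, 11.48),
        "RAOD": (139.56, 12.26),
        "AWT": (15.77, 2.38),
        "RVLD": (150.82, 15.68),
        "RVOD": (182.23, 17.87),
        "VWT": (15.71, 4.12),
        "AVR": (0.77, 0.09),
    },
    (1, "contralateral", "pre_cas"): {
        "RALD": (111.18, 10.23),
        "RAOD": (143.4, 9.03),
        "AWT": (16.11, 2.6),
        "RVLD": (152.67, 17.92),
        "RVOD": (183.45, 18.41),
        "VWT": (15.39, 3.14),
        "AVR": (0.79, 0.09),
    },
    (1, "contralateral", "post_cas"): {
        "RALD": (110.47, 10.69),
        "RAOD": (143.6, 9.09),
        "AWT": (16.56, 2.82),
        "RVLD": (147.34, 18.65),
        "RVOD": (179.48, 18.17),
        "VWT": (16.07, 4.00),
        "AVR": (0.81, 0.09),
    },
}

#: baseline 2x2 contingency counts as (group0_yes, group1_yes, group0_no,
#: group1_no); for "sex", "yes" means male.
CONTINGENCY_2X2: dict[str, tuple[int, int, int, int]] = {
    "sex_male": (23, 14, 36, 36),
    "diabetes": (23, 13, 36, 37),
    "smoking": (16, 16, 43, 34),
    "hypertension": (33, 37, 26, 13),
    "dyslipidemia": (14, 16, 45, 34),
}

#: baseline quantitative covariates: (mean0, sd0, n0, mean1, sd1, n1)
AGE_SUMMARY = (62.31, 8.11, 59, 65.66, 9.53, 50)
BMI_SUMMARY = (23.31, 3.69, 59, 23.81, 2.9, 50)
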