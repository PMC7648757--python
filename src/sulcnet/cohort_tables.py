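"""Published demographic and clinical summary statistics of the study cohorts.

The raw participant data behind these summaries are not publicly deposited,
but the printed per-group means, SDs, ns and contingency counts are
sufficient inputs to reconstruct the reported one-way ANOVA F and Pearson
chi-square statistics exactly (up to rounding of the printed values). Group
order throughout: UK H+, UK H-, Shanghai H+, Shanghai H-, (Shanghai HC where
applicable).
"""

from __future__ import annotations

GROUP_NS = {"uk_hplus": 79, "uk_hminus": 43, "sh_hplus": 22, "sh_hminus": 37, "sh_hc": 63}

#: PANSS P3 hallucination item, mean (SD) per patient group at scan.
PANSS_P3 = {
    "means": (3.96, 1.21, 4.18, 1.03),
    "sds": (0.97, 0.47, 1.01, 0.16),
    "ns": (79, 43, 22, 37),
    "reported_f": 211.1,
    "reported_df": (3, 177),
}

#: PANSS P1 delusion item, same four patient groups.
PANSS_P1 = {
    "means": (3.57, 2.35, 3.18, 2.24),
    "sds": (1.45, 1.43, 1.62, 1.48),
    "ns": (79, 43, 22, 37),
    "reported_f": 10.09,
    "reported_df": (3, 177),
}

#: PANSS P3 averaged over the follow-up year (UK sample only).
PANSS_P3_YEAR_AVERAGE = {
    "means": (3.45, 1.23),
    "sds": (0.98, 0.34),
    "ns": (79, 43),
    "reported_f": 205.1,
    "reported_df": (1, 120),
}

#: Male/Female counts for the five groups (incl. Shanghai healthy controls).
GENDER_COUNTS = {
    "table": ((54, 25), (30, 13), (15, 7), (21, 16), (36, 27)),
    "reported_chi2": 3.56,
    "reported_df": 4,
}

#: Fraction of patients experiencing hallucinations, per sample.
HALLUCINATION_PROPORTIONS = {
    "uk": {"h_plus": 79, "patients": 122, "reported_pct": 65},
    "shanghai": {"h_plus": 22, "patients": 59, "reported_pct": 37},
}

#: Semi-automated vs manual sulcal length agreement (left hemisphere).
REPORTED_ICC_LEFT = {"icc": 0.933, "ci": (0.922, 0.941)}
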