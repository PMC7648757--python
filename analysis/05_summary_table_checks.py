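#!/usr/bin/env python
"""Reconstruct the published demographic test statistics from printed summaries.

The study's raw participant data are not deposited, but its demographic
table prints per-group means, SDs, ns and contingency counts — sufficient to
recompute the reported one-way ANOVA F values and the gender chi-square, and
the per-sample hallucination proportions. Writes results/table_checks.json.
"""

import json
from pathlib import Path

import numpy as np

from sulcnet.cohort_tables import (
    GENDER_COUNTS,
    HALLUCINATION_PROPORTIONS,
    PANSS_P1,
    PANSS_P3,
    PANSS_P3_YEAR_AVERAGE,
)
from sulcnet.sulcal import anova_from_summary, chisq_from_table

OUT = Path("results/table_checks.json")


def main() -> None:
    report = {}
    for name, table in (("panss_p3", PANSS_P3), ("panss_p1_delusion", PANSS_P1),
                        ("panss_p3_year_average", PANSS_P3_YEAR_AVERAGE)):
        res = anova_from_summary(table["means"], table["sds"], table["ns"])
        report[name] = {"f": round(res.value, 3), "df": list(res.df),
                        "reported_f": table["reported_f"]}
        print(f"{name}: F{tuple(int(d) for d in res.df)} = {res.value:.1f} "
              f"(reported {table['reported_f']})")

    chi = chisq_from_table(GENDER_COUNTS["table"])
    report["gender"] = {"chi2": round(chi.value, 3), "df": chi.df[0],
                        "reported_chi2": GENDER_COUNTS["reported_chi2"]}
    print(f"gender: chi2({int(chi.df[0])}) = {chi.value:.2f} "
          f"(reported {GENDER_COUNTS['reported_chi2']})")

    for sample, row in HALLUCINATION_PROPORTIONS.items():
        pct = 100.0 * row["h_plus"] / row["patients"]
        report[f"pct_hallucinating_{sample}"] = {
            "pct": round(pct, 2), "reported_pct": row["reported_pct"],
        }
        print(f"{sample}: {row['h_plus']}/{row['patients']} = {pct:.1f}% hallucinating "
              f"(reported {row['reported_pct']}%)")

    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(report, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
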