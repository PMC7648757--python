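#!/usr/bin/env python
"""Sulcal asymmetry and group-contrast analysis.

Reads results/cohort/, computes asymmetry indices (AI = 2(R-L)/(R+L)) with
one-sample and between-group tests, and the covariate-adjusted group
contrasts on PCS/STS length and depth. Writes results/sulcal/ and prints the
planned left-PCS contrasts.
"""

from pathlib import Path

from sulcnet.data import AnalysisConfig, read_cohort
from sulcnet.pipeline import setup_logging, stage_sulcal_stats

COHORT = Path("results/cohort")
OUT = Path("results/sulcal")


def main() -> None:
    setup_logging()
    cohort = read_cohort(COHORT / "subjects.tsv", COHORT / "lgi.tsv",
                         COHORT / "sulci.tsv", COHORT / "atlas.json")
    OUT.mkdir(parents=True, exist_ok=True)
    bundle = stage_sulcal_stats(cohort, AnalysisConfig(rng_seed=7), OUT)

    reg = bundle["regression_results"]
    planned = reg[reg["family"] == "planned"]
    print("planned left-PCS length contrasts (adjusted for age/sex/site/TIV):")
    for _, row in planned.iterrows():
        print(f"  {row['metric']} {row['contrast']}: t({row['df']}) = {row['t']:.3f}, "
              f"p = {row['p']:.4g}, beta = {row['beta']:.3f}")

    ai = bundle["ai_results"]
    pcs_len = ai[(ai.sulcus == "PCS") & (ai.measure == "length") &
                 (ai.test == "anova")]
    print(f"PCS length AI 3-group ANOVA: F = {pcs_len['stat'].iloc[0]:.3f}, "
          f"p = {pcs_len['p'].iloc[0]:.4g}")


if __name__ == "__main__":
    main()
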