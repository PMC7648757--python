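"""End-to-end pipeline: simulate -> sulcal stats -> covariance networks ->
permutation inference, with structured logging and a run manifest.

Each stage is a function taking (cohort/config, out_dir) so the numbered
analysis drivers, the CLI and the tests all share one implementation. All
randomness flows from the config seed through per-stage child seeds.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import covnet, permutation, sulcal
from .data import (
    AnalysisConfig,
    Cohort,
    Group,
    ValidationError,
    child_seed,
    read_cohort,
    write_cohort,
    write_results,
)
from .simulate import CohortSpec, generate_cohort

log = logging.getLogger("sulcnet")

#: Planned contrasts on left PCS length, evaluated uncorrected at alpha.
PLANNED_CONTRASTS = (("H+", "H-"), ("H+", "HC"))


def setup_logging(out_dir: Path | None = None) -> None:
    """Human-readable log to stderr plus JSON-lines log next to the outputs."""
    log.setLevel(logging.INFO)
    log.handlers.clear()
    stream = logging.StreamHandler(sys.stderr)
    stream.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(stream)
    if out_dir is not None:
        jsonl = logging.FileHandler(Path(out_dir) / "run_log.jsonl")

        class _JsonFormatter(logging.Formatter):
            def format(self, record):
                return json.dumps(
                    {"t": record.created, "level": record.levelname, "msg": record.getMessage()}
                )

        jsonl.setFormatter(_JsonFormatter())
        log.addHandler(jsonl)


def stage_simulate(spec: CohortSpec, out_dir: Path) -> Cohort:
    cohort, manifest = generate_cohort(spec)
    paths = write_cohort(cohort, out_dir)
    with open(Path(out_dir) / "ground_truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("simulate: wrote %d subjects x %d parcels to %s",
             len(cohort.subjects), cohort.lgi.shape[1], out_dir)
    return cohort


def stage_sulcal_stats(cohort: Cohort, config: AnalysisConfig, out_dir: Path) -> dict:
    """Asymmetry indices, per-group/one-way AI tests, and adjusted contrasts."""
    ai = sulcal.ai_table(cohort.sulci)
    ai = ai.merge(cohort.subjects[["group"]], left_on="subject_id", right_index=True)

    ai_tests = []
    for (sulcus, measure), sub in ai.groupby(["sulcus", "measure"]):
        by_group = {g: sub.loc[sub["group"] == g, "ai"].to_numpy()
                    for g in sorted(sub["group"].unique())}
        res = sulcal.ai_group_tests(by_group)
        for gname, sr in res["per_group"].items():
            ai_tests.append({"sulcus": sulcus, "measure": measure, "test": f"one_sample_{gname}",
                             "stat": sr.value, "df": sr.df[0], "p": sr.p})
        an = res["anova"]
        ai_tests.append({"sulcus": sulcus, "measure": measure, "test": "anova",
                         "stat": an.value, "df": an.df[1], "p": an.p})
        for _, row in res["tukey"].iterrows():
            ai_tests.append({"sulcus": sulcus, "measure": measure,
                             "test": f"tukey_{row['group1']}_vs_{row['group2']}",
                             "stat": row["meandiff"], "df": np.nan, "p": row["p_adj"]})
    ai_tests = pd.DataFrame(ai_tests)

    # covariate-adjusted contrasts per sulcus x hemisphere x measure
    wide = cohort.sulci.pivot_table(
        index="subject_id", columns=["sulcus", "hemisphere"],
        values=["length_mm", "depth_mm"],
    )
    regressions = []
    for (value, sulcus, hemi) in wide.columns:
        metric = wide[(value, sulcus, hemi)].loc[cohort.subjects.index]
        for contrast in PLANNED_CONTRASTS:
            if not all((cohort.subjects["group"] == g).any() for g in contrast):
                continue
            rr = sulcal.sulcal_regression(metric, cohort.subjects, contrast)
            planned = value == "length_mm" and sulcus == "PCS" and hemi == "L"
            regressions.append(
                {"metric": f"{sulcus}_{hemi}_{value[:-3]}", "contrast": rr.contrast,
                 "estimate": rr.estimate, "beta": rr.standardized_beta, "t": rr.t,
                 "df": rr.df, "p": rr.p, "family": "planned" if planned else "exploratory"}
            )
    regressions = pd.DataFrame(regressions)
    # exploratory metrics form one BH family; planned contrasts stay uncorrected
    expl = regressions["family"] == "exploratory"
    regressions["q"] = np.nan
    if expl.any():
        regressions.loc[expl, "q"] = permutation.fdr_adjust(
            regressions.loc[expl, "p"].to_numpy()
        )

    bundle = {"ai_results": ai_tests, "regression_results": regressions,
              "ai_values": ai.reset_index(drop=True)}
    write_results(bundle, out_dir)
    log.info("sulcal-stats: %d AI tests, %d regression contrasts", len(ai_tests), len(regressions))
    return bundle


def stage_covnet(cohort: Cohort, config: AnalysisConfig, out_dir: Path) -> dict:
    """Residualize, build per-group correlation matrices, block summaries and
    threshold curves with bootstrap CIs."""
    residuals = covnet.residualize(cohort.lgi, cohort.subjects)
    parcels = list(cohort.lgi.columns)
    out = {"residuals": residuals, "matrices": {}, "net8": {}, "hemi16": {}, "curves": []}
    for group in sorted(cohort.subjects["group"].unique()):
        mask = cohort.group_mask(group)
        corr = covnet.build_group_covariance(residuals, mask)
        out["matrices"][group] = corr
        for level in ("net8", "hemi16"):
            out[level][group] = covnet.block_summarize(
                corr, cohort.atlas, parcels, level=level, group=group
            )
        for block in config.block_tests:
            ci = covnet.bootstrap_block_ci(
                residuals, mask, cohort.atlas, block, config.threshold_grid,
                config.n_bootstrap,
                seed=child_seed(config.rng_seed, f"bootstrap-{group}-{block[0]}-{block[1]}"),
            )
            ci.insert(0, "group", group)
            ci.insert(1, "block", f"{block[0]}|{block[1]}")
            out["curves"].append(ci)

    bundle = {}
    for level in ("net8", "hemi16"):
        frames = []
        for group, summary in out[level].items():
            m = summary.block_matrix.copy()
            m.insert(0, "group", group)
            frames.append(m)
        bundle[f"block_summary_{level}"] = pd.concat(frames)
    bundle["threshold_curves"] = pd.concat(out["curves"], ignore_index=True)
    write_results(bundle, out_dir)
    log.info("covnet: %d groups, %d parcels", len(out["matrices"]), len(parcels))
    return out


def stage_permtest(
    cohort: Cohort, config: AnalysisConfig, out_dir: Path,
    residuals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Group-label permutation tests for each configured block, H+ vs H-."""
    if residuals is None:
        residuals = covnet.residualize(cohort.lgi, cohort.subjects)
    results = permutation.permutation_test(
        residuals,
        cohort.subjects["group"],
        cohort.atlas,
        config.block_tests,
        contrast=("H+", "H-"),
        n_permutations=config.n_permutations,
        seed=child_seed(config.rng_seed, "permtest"),
    )
    frame = permutation.results_frame(results)
    write_results({"permutation_results": frame}, out_dir)
    log.info("permtest: B=%d, min q=%.4g", config.n_permutations, frame["q"].min())
    return frame


def run_all(
    config: AnalysisConfig,
    out_dir: str | Path,
    spec: CohortSpec | None = None,
    cohort_dir: str | Path | None = None,
) -> dict:
    """Run every stage in order; returns the run manifest.

    Either a cohort spec (simulate first) or a directory of existing cohort
    files must be supplied. Fails fast on stage errors, leaving a
    ``<stage>.failed`` marker next to any partial outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    setup_logging(out)
    manifest = {"seed": config.rng_seed, "stages": [], "version": _version()}
    t0 = time.time()

    def run_stage(name, fn):
        stage_dir = out / name
        stage_dir.mkdir(exist_ok=True)
        start = time.time()
        try:
            result = fn(stage_dir)
        except Exception:
            (stage_dir / f"{name}.failed").touch()
            raise
        files = sorted(p.name for p in stage_dir.iterdir() if p.is_file())
        manifest["stages"].append(
            {"stage": name, "elapsed_s": round(time.time() - start, 3), "files": files}
        )
        log.info("stage %s done (%.1fs)", name, time.time() - start)
        return result

    if spec is not None:
        cohort = run_stage("simulate", lambda d: stage_simulate(spec, d))
    elif cohort_dir is not None:
        cd = Path(cohort_dir)
        cohort = read_cohort(cd / "subjects.tsv", cd / "lgi.tsv", cd / "sulci.tsv",
                             cd / "atlas.json")
    else:
        raise ValidationError("run_all needs either a cohort spec or a cohort directory")

    run_stage("sulcal_stats", lambda d: stage_sulcal_stats(cohort, config, d))
    cov = run_stage("covnet", lambda d: stage_covnet(cohort, config, d))
    run_stage("permtest", lambda d: stage_permtest(cohort, config, d, cov["residuals"]))

    manifest["elapsed_s"] = round(time.time() - t0, 3)
    # checksums of every written file, for end-to-end determinism checks
    from .data import _sha256

    manifest["checksums"] = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name not in ("run_manifest.json", "run_log.jsonl")
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("sulcnet")
    except Exception:
        return "unknown"
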