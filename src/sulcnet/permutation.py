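"""Group-label permutation inference for block-mean covariance differences.

Each permutation reassigns every participant to one of three new groups of
the original sizes — LGI values and covariates travel with the participant,
only the group label is shuffled — and recomputes both contrast groups'
block means on the permuted labels. Two-tailed p-values use the add-one
Monte-Carlo estimator p = (1 + #{|null| >= |observed|}) / (B + 1), and the
tested family is corrected by Benjamini-Hochberg FDR.

Residualization is not recomputed inside permutations by default (the
covariate adjustment is a fixed property of each participant); pass
re-residualized tables explicitly for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .covnet import BlockIndex
from .data import AtlasMap, ValidationError


@dataclass
class PermutationResult:
    """Observed block-mean difference with its permutation null."""

    contrast: tuple[str, str]
    block: tuple[str, str]
    observed_diff: float
    null_diffs: np.ndarray
    p: float
    q: float | None = None
    n_permutations: int = 0
    seed: int | None = None


def permute_group_labels(labels: np.ndarray, group_sizes: dict[str, int],
                         rng: np.random.Generator) -> np.ndarray:
    """Uniform random relabelling preserving the original group sizes."""
    labels = np.asarray(labels)
    total = sum(group_sizes.values())
    if total != labels.size:
        raise ValidationError(
            f"group sizes sum to {total} but there are {labels.size} subjects"
        )
    pool = np.concatenate([np.repeat(g, n) for g, n in sorted(group_sizes.items())])
    return pool[rng.permutation(labels.size)]


def _group_block_means(
    data: np.ndarray,
    rows: np.ndarray,
    pair_rows: np.ndarray,
    pair_cols: np.ndarray,
) -> float:
    """Mean block correlation for one set of subject rows (NaN-safe)."""
    sub = data[rows]
    sd = sub.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub, rowvar=False)
    vals = np.asarray(corr, dtype=float)[pair_rows, pair_cols]
    bad = sd == 0
    if bad.any():
        keep = ~(bad[pair_rows] | bad[pair_cols])
        vals = vals[keep]
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def permutation_test(
    residuals: pd.DataFrame,
    groups: pd.Series,
    atlas: AtlasMap,
    blocks,
    contrast: tuple[str, str],
    n_permutations: int,
    seed: int,
    level: str = "net8",
    group_sizes: dict[str, int] | None = None,
) -> list[PermutationResult]:
    """Permutation test of M_a - M_b for each block in ``blocks``.

    ``groups`` is subject-indexed (aligned with ``residuals``); permutations
    shuffle all labels into three groups of the original sizes even when a
    single pairwise contrast is tested, and the contrast is evaluated on the
    two relevant permuted groups. All blocks share the same permutation
    sequence, which preserves their dependence under the null.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    # canonical subject order: results must not depend on input row order
    residuals = residuals.sort_index()
    labels = groups.loc[residuals.index].to_numpy()
    sizes = group_sizes or {g: int((labels == g).sum()) for g in np.unique(labels)}
    for g in contrast:
        if sizes.get(g, 0) < 4:
            raise ValidationError(f"contrast group {g} needs >= 4 subjects")

    data = residuals.to_numpy(dtype=float)
    index = BlockIndex(atlas, list(residuals.columns), level)
    pair_idx = [index.pairs[index.key(*b)] for b in blocks]

    def diffs(lab: np.ndarray) -> np.ndarray:
        rows_a = np.where(lab == contrast[0])[0]
        rows_b = np.where(lab == contrast[1])[0]
        out = np.empty(len(blocks))
        for k, (pr, pc) in enumerate(pair_idx):
            out[k] = _group_block_means(data, rows_a, pr, pc) - _group_block_means(
                data, rows_b, pr, pc
            )
        return out

    observed = diffs(labels)
    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, len(blocks)))
    for b in range(n_permutations):
        null[b] = diffs(permute_group_labels(labels, sizes, rng))

    results = []
    for k, block in enumerate(blocks):
        exceed = int(np.sum(np.abs(null[:, k]) >= abs(observed[k])))
        p = (1 + exceed) / (n_permutations + 1)
        results.append(
            PermutationResult(
                contrast=tuple(contrast),
                block=tuple(block),
                observed_diff=float(observed[k]),
                null_diffs=null[:, k].copy(),
                p=float(p),
                n_permutations=n_permutations,
                seed=seed,
            )
        )
    qs = fdr_adjust(np.array([r.p for r in results]))
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p_values must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def results_frame(results: list[PermutationResult]) -> pd.DataFrame:
    """Flatten permutation results to one row per block x contrast."""
    return pd.DataFrame(
        [
            {
                "contrast": f"{r.contrast[0]} vs {r.contrast[1]}",
                "block": f"{r.block[0]}|{r.block[1]}",
                "observed_diff": r.observed_diff,
                "p": r.p,
                "q": r.q,
                "n_permutations": r.n_permutations,
                "seed": r.seed,
            }
            for r in results
        ]
    )
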