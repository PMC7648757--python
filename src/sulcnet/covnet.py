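"""Gyrification-based structural covariance networks.

Per-group inter-regional Pearson correlation matrices of covariate-adjusted
local gyrification index (LGI), summarized into resting-state-network blocks
(8x8 networks or 16x16 network-by-hemisphere), with threshold-sweep curves
and subject-resampling bootstrap confidence intervals.

Adjustment is ordinary-least-squares residualization on
[intercept, age, sex, site dummies, TIV] fitted over the pooled sample (all
groups together) by default, so the adjustment is held fixed under
group-label permutation; per-group fitting is available via ``per_group=``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AtlasMap, ValidationError
from .sulcal import covariate_design


@dataclass
class BlockSummary:
    """Network-level mean covariance for one group.

    ``block_matrix``: block x block mean correlations (within-block means
    exclude the unit diagonal); ``pair_counts``: number of parcel pairs
    entering each mean (NaN entries excluded and counted separately).
    """

    group: str
    level: str  # "net8" | "hemi16"
    block_matrix: pd.DataFrame
    pair_counts: pd.DataFrame


def residualize(
    lgi: pd.DataFrame,
    subjects: pd.DataFrame,
    per_group: bool = False,
) -> pd.DataFrame:
    """Replace each parcel column by OLS residuals on the covariate design.

    Residual columns are exactly orthogonal to every covariate column. With
    ``per_group=True`` the model is fitted separately within each group.
    """
    if per_group:
        parts = []
        for g in sorted(subjects["group"].unique()):
            mask = subjects["group"] == g
            parts.append(residualize(lgi.loc[mask], subjects.loc[mask], per_group=False))
        return pd.concat(parts).loc[lgi.index]
    X, names = covariate_design(subjects.loc[lgi.index])
    if len(lgi) <= X.shape[1] + 2:
        raise ValidationError("too few subjects to residualize on the covariate design")
    Y = lgi.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid, index=lgi.index, columns=lgi.columns)


def build_group_covariance(residuals: pd.DataFrame, mask: np.ndarray) -> np.ndarray:
    """Pearson correlation across one group's subjects for every parcel pair.

    Zero-variance parcels (within the group) yield NaN rows/columns, which
    downstream block means exclude. Diagonal is exactly 1 where defined.
    """
    sub = residuals.to_numpy(dtype=float)[np.asarray(mask, dtype=bool)]
    if sub.shape[0] < 4:
        raise ValidationError("need >= 4 subjects in the group")
    sd = sub.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    idx = np.where(~degenerate)[0]
    corr[idx, idx] = 1.0
    return corr


class BlockIndex:
    """Precomputed parcel-pair index arrays for every block of an atlas level.

    Lets block means be recomputed in O(pairs) inside permutation and
    bootstrap loops without touching the atlas again.
    """

    def __init__(self, atlas: AtlasMap, parcel_ids: list[str], level: str = "net8"):
        labels = atlas.labels(level).loc[parcel_ids].to_numpy()
        self.level = level
        self.blocks = sorted(set(labels))
        self.pairs: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        pos = {b: np.where(labels == b)[0] for b in self.blocks}
        for i, a in enumerate(self.blocks):
            ia = pos[a]
            # within-block: unordered off-diagonal pairs (upper triangle)
            r, c = np.triu_indices(len(ia), k=1)
            self.pairs[(a, a)] = (ia[r], ia[c])
            for b in self.blocks[i + 1:]:
                ib = pos[b]
                rr = np.repeat(ia, len(ib))
                cc = np.tile(ib, len(ia))
                self.pairs[(a, b)] = (rr, cc)

    def key(self, a: str, b: str) -> tuple[str, str]:
        return (a, b) if (a, b) in self.pairs else (b, a)

    def block_values(self, corr: np.ndarray, a: str, b: str) -> np.ndarray:
        r, c = self.pairs[self.key(a, b)]
        return corr[r, c]

    def block_mean(self, corr: np.ndarray, a: str, b: str) -> float:
        vals = self.block_values(corr, a, b)
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else float("nan")


def block_summarize(
    corr: np.ndarray, atlas: AtlasMap, parcel_ids: list[str], level: str = "net8",
    group: str = "",
) -> BlockSummary:
    """Average a parcel-level correlation matrix into network blocks.

    Within-block means average the off-diagonal upper triangle; between-block
    means average all cross pairs; blocks with <2 parcels (within) or an empty
    cross set are NaN with pair count 0.
    """
    index = BlockIndex(atlas, parcel_ids, level)
    blocks = index.blocks
    mat = pd.DataFrame(np.nan, index=blocks, columns=blocks)
    counts = pd.DataFrame(0, index=blocks, columns=blocks)
    for i, a in enumerate(blocks):
        for b in blocks[i:]:
            vals = index.block_values(corr, a, b)
            vals = vals[~np.isnan(vals)]
            if vals.size:
                mat.loc[a, b] = mat.loc[b, a] = float(vals.mean())
            counts.loc[a, b] = counts.loc[b, a] = int(vals.size)
    return BlockSummary(group=group, level=level, block_matrix=mat, pair_counts=counts)


def net8_from_hemi16(hemi: BlockSummary) -> BlockSummary:
    """Collapse a 16x16 hemisphere-resolved summary to 8x8 network blocks.

    Exact identity with direct 8x8 summarization: each network block mean is
    the pair-count-weighted average of its hemisphere sub-block means.
    """
    nets = sorted({b.rsplit("_", 1)[0] for b in hemi.block_matrix.index})
    mat = pd.DataFrame(np.nan, index=nets, columns=nets)
    counts = pd.DataFrame(0, index=nets, columns=nets)
    members = {n: [b for b in hemi.block_matrix.index if b.rsplit("_", 1)[0] == n] for n in nets}
    for i, a in enumerate(nets):
        for b in nets[i:]:
            total, weight = 0.0, 0
            seen = set()
            for sa in members[a]:
                for sb in members[b]:
                    key = tuple(sorted((sa, sb)))
                    if key in seen:
                        continue
                    seen.add(key)
                    cnt = int(hemi.pair_counts.loc[sa, sb])
                    val = hemi.block_matrix.loc[sa, sb]
                    if cnt and not np.isnan(val):
                        total += val * cnt
                        weight += cnt
            if weight:
                mat.loc[a, b] = mat.loc[b, a] = total / weight
            counts.loc[a, b] = counts.loc[b, a] = weight
    return BlockSummary(group=hemi.group, level="net8", block_matrix=mat, pair_counts=counts)


def threshold_sweep(
    corr: np.ndarray,
    atlas: AtlasMap,
    parcel_ids: list[str],
    block: tuple[str, str],
    threshold_grid,
    level: str = "net8",
) -> pd.DataFrame:
    """Mean surviving block correlation per threshold.

    At threshold tau, entries <= tau are discarded (not zeroed) and the mean
    is taken over survivors; an empty surviving set yields NaN. At tau = -1
    this equals the unthresholded block mean exactly.
    """
    grid = np.asarray(threshold_grid, dtype=float)
    if grid.size and (grid.min() < -1 or grid.max() > 1):
        raise ValidationError("threshold grid must lie within [-1, 1]")
    index = BlockIndex(atlas, parcel_ids, level)
    vals = index.block_values(corr, *block)
    vals = vals[~np.isnan(vals)]
    rows = []
    for tau in grid:
        surviving = vals[vals > tau]
        rows.append(
            {
                "threshold": float(tau),
                "mean_corr": float(surviving.mean()) if surviving.size else np.nan,
                "n_surviving": int(surviving.size),
            }
        )
    return pd.DataFrame(rows)


def bootstrap_block_ci(
    residuals: pd.DataFrame,
    mask: np.ndarray,
    atlas: AtlasMap,
    block: tuple[str, str],
    threshold_grid,
    n_bootstrap: int,
    seed: int,
    level: str = "net8",
) -> pd.DataFrame:
    """Percentile 95% bootstrap CI of the thresholded block mean.

    Subjects are resampled with replacement within the group; the correlation
    matrix and thresholded block means are recomputed per resample. Returns
    one row per threshold with point estimate and CI bounds.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 4:
        raise ValidationError("need >= 4 subjects in the group")
    grid = np.asarray(threshold_grid, dtype=float)
    data = residuals.to_numpy(dtype=float)[mask]
    n = data.shape[0]
    index = BlockIndex(atlas, list(residuals.columns), level)
    r_idx, c_idx = index.pairs[index.key(*block)]

    def sweep(values: np.ndarray) -> np.ndarray:
        vals = values[~np.isnan(values)]
        out = np.full(grid.size, np.nan)
        for k, tau in enumerate(grid):
            surv = vals[vals > tau]
            if surv.size:
                out[k] = surv.mean()
        return out

    def block_entries(sub: np.ndarray) -> np.ndarray:
        sd = sub.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        corr = np.asarray(corr, dtype=float)
        bad = sd == 0
        if bad.any():
            corr[bad, :] = np.nan
            corr[:, bad] = np.nan
        return corr[r_idx, c_idx]

    point = sweep(block_entries(data))
    rng = np.random.default_rng(seed)
    draws = np.empty((n_bootstrap, grid.size))
    for b in range(n_bootstrap):
        take = rng.integers(0, n, n)
        draws[b] = sweep(block_entries(data[take]))
    # thresholds above every resample's maximum give all-NaN columns by design
    import warnings

    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanpercentile(draws, 2.5, axis=0)
        hi = np.nanpercentile(draws, 97.5, axis=0)
    return pd.DataFrame(
        {
            "threshold": grid,
            "mean_corr": point,
            "ci_low": lo,
            "ci_high": hi,
        }
    )
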