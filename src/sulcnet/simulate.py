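"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes, for a
hallucination-stratified schizophrenia cohort (patients with hallucinations
H+, patients without H-, healthy controls HC):

* group sizes 101 / 80 / 63 by default;
* per-parcel local gyrification index (LGI) values with block-structured
  inter-subject correlations generated from a factor model — a group-shared
  global factor, one factor per resting-state network (correlated across
  network pairs where a specific between-network coupling is planted), and
  unique noise — so the expected correlation of two parcels is available in
  closed form: ``rho_global + rho_network`` within a network, ``rho_global``
  (plus any planted between-term) across networks;
* sulcal length/depth draws (truncated normal at 0) planting a shorter left
  paracingulate sulcus (PCS) in H+, leftward PCS length/depth asymmetry in HC
  and H- but not H+, and rightward superior temporal sulcus (STS) depth
  asymmetry in all groups;
* linear covariate confounds (age, sex, site, TIV) added to every
  morphometric value, centred at reference covariate values so planted group
  means are unchanged in expectation.

Every generated cohort is accompanied by a ground-truth manifest recording
the exact planted parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import AtlasMap, Cohort, Group, child_seed

#: Eight canonical large-scale resting-state networks.
NETWORKS = (
    "auditory",
    "default_mode",
    "dorsal_attention",
    "frontoparietal",
    "limbic",
    "salience",
    "somatomotor",
    "visual",
)

DEFAULT_GROUP_SIZES = {Group.H_PLUS: 101, Group.H_MINUS: 80, Group.HC: 63}

#: Planted true block correlations of covariate-adjusted LGI. The salience
#: and auditory entries reproduce the elevated within- and between-network
#: gyrification synchrony in hallucinating patients; every other network gets
#: a common within-network level on top of the global baseline.
DEFAULT_BLOCK_CORR = {
    Group.H_PLUS: {
        "global": 0.20,
        "within": {"salience": 0.493, "auditory": 0.631},
        "between": {("auditory", "salience"): 0.501},
    },
    Group.H_MINUS: {
        "global": 0.20,
        "within": {"salience": 0.371, "auditory": 0.532},
        "between": {("auditory", "salience"): 0.355},
    },
    Group.HC: {
        "global": 0.20,
        "within": {"salience": 0.375, "auditory": 0.523},
        "between": {("auditory", "salience"): 0.375},
    },
}

#: Within-network correlation for networks not listed explicitly above.
DEFAULT_WITHIN_OTHER = 0.35

#: Per-group (sulcus, hemisphere) -> (length mean, length sd, depth mean,
#: depth sd), all mm. Sign structure: left PCS shortened by ~0.5 SD in H+;
#: leftward PCS length/depth asymmetry in HC and H- but not H+; leftward STS
#: length and rightward STS depth asymmetry in all groups; right STS depth
#: slightly reduced in H+.
DEFAULT_SULCAL_PARAMS = {
    Group.H_PLUS: {
        ("PCS", "L"): (39.0, 22.0, 10.2, 2.5),
        ("PCS", "R"): (40.0, 22.0, 10.0, 2.5),
        ("STS", "L"): (95.0, 12.0, 20.0, 2.5),
        ("STS", "R"): (88.0, 12.0, 21.4, 2.5),
    },
    Group.H_MINUS: {
        ("PCS", "L"): (50.0, 22.0, 11.0, 2.5),
        ("PCS", "R"): (40.0, 22.0, 10.0, 2.5),
        ("STS", "L"): (95.0, 12.0, 20.0, 2.5),
        ("STS", "R"): (88.0, 12.0, 21.8, 2.5),
    },
    Group.HC: {
        ("PCS", "L"): (52.0, 22.0, 11.0, 2.5),
        ("PCS", "R"): (40.0, 22.0, 10.0, 2.5),
        ("STS", "L"): (95.0, 12.0, 20.0, 2.5),
        ("STS", "R"): (88.0, 12.0, 22.0, 2.5),
    },
}

#: Linear covariate effects. Continuous covariates are centred at the
#: reference values below before the betas apply, so planted group means are
#: preserved. Units: LGI per year / per category / per mm^3; sulcal mm alike.
DEFAULT_COVARIATE_BETAS = {
    "lgi": {"age": -0.004, "sex_f": -0.02, "site": {"site2": 0.02, "site3": -0.02}, "tiv": 5e-8},
    "sulcal_length": {"age": -0.05, "sex_f": -1.0, "site": {"site2": 0.5, "site3": -0.5}, "tiv": 1e-5},
    "sulcal_depth": {"age": -0.01, "sex_f": -0.2, "site": {"site2": 0.1, "site3": -0.1}, "tiv": 2e-6},
}

COVARIATE_REFERENCE = {"age": 25.0, "tiv": 1.48e6}

#: Covariate sampling distributions per group, matched to the demographic
#: summaries of the pooled two-site study samples.
DEFAULT_COVARIATE_DISTS = {
    Group.H_PLUS: {"age": (24.9, 5.5), "p_female": 0.317, "tiv": (1.4546e6, 2.0e5)},
    Group.H_MINUS: {"age": (25.2, 5.7), "p_female": 0.363, "tiv": (1.4790e6, 2.0e5)},
    Group.HC: {"age": (24.7, 7.35), "p_female": 0.429, "tiv": (1.5441e6, 1.6e5)},
}

SITE_NAMES = ("site1", "site2", "site3")
SITE_PROBS = (0.5, 0.3, 0.2)

#: PANSS P3 score distributions (H+ over 3..7, H- over 1..2) giving group
#: means near the study's ~4.0 and ~1.15.
P3_SCORES_HPLUS = ((3, 4, 5, 6, 7), (0.35, 0.35, 0.20, 0.07, 0.03))
P3_SCORES_HMINUS = ((1, 2), (0.85, 0.15))


class SpecError(ValueError):
    """Raised when a cohort specification is internally inconsistent."""


@dataclass
class CohortSpec:
    """Full specification of a synthetic cohort.

    Defaults reproduce the study conditions: group sizes 101/80/63, 360
    parcels (180 per hemisphere) balanced over 8 networks, planted block
    correlations matching the reported gyrification synchrony, and realistic
    sulcal and covariate scales. Tests typically shrink ``n_parcels``.
    """

    group_sizes: Mapping[Group, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_parcels: int = 360
    block_corr: Mapping = field(default_factory=lambda: _deep_copy(DEFAULT_BLOCK_CORR))
    within_other: float = DEFAULT_WITHIN_OTHER
    sulcal_params: Mapping = field(default_factory=lambda: _deep_copy(DEFAULT_SULCAL_PARAMS))
    covariate_betas: Mapping = field(default_factory=lambda: _deep_copy(DEFAULT_COVARIATE_BETAS))
    covariate_dists: Mapping = field(default_factory=lambda: _deep_copy(DEFAULT_COVARIATE_DISTS))
    lgi_mean: float = 2.5
    lgi_scale: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parcels % 2 != 0 or self.n_parcels < 16:
            raise SpecError("n_parcels must be even and >= 16 (>=1 parcel per network+hemisphere)")
        for g, n in self.group_sizes.items():
            if n < 3:
                raise SpecError(f"group size for {g} must be >= 3")
        for g in self.group_sizes:
            self.loadings(g)  # validates the variance decomposition

    def within(self, group: Group, network: str) -> float:
        bc = self.block_corr[group]
        return float(bc["within"].get(network, self.within_other))

    def loadings(self, group: Group) -> tuple[float, dict[str, float], np.ndarray]:
        """Variance shares: (global, per-network, network-factor correlation).

        Raises :class:`SpecError` when the implied per-parcel decomposition
        exceeds total variance 1 or a planted between-block correlation is
        unattainable given the network loadings.
        """
        bc = self.block_corr[group]
        a_g = float(bc["global"])
        if not (0 <= a_g < 1):
            raise SpecError(f"global correlation must lie in [0, 1), got {a_g}")
        a_net = {}
        for net in NETWORKS:
            a = self.within(group, net) - a_g
            if a < 0:
                raise SpecError(f"within-network correlation for {net} below global level")
            if a_g + a >= 1:
                raise SpecError(f"variance decomposition exceeds 1 for network {net}")
            a_net[net] = a
        corr = np.eye(len(NETWORKS))
        for (na, nb), rho in bc.get("between", {}).items():
            i, j = NETWORKS.index(na), NETWORKS.index(nb)
            denom = np.sqrt(a_net[na] * a_net[nb])
            if denom == 0:
                raise SpecError(f"between-block correlation planted on zero-loading pair {na},{nb}")
            c = (float(rho) - a_g) / denom
            if not (-1 <= c <= 1):
                raise SpecError(f"between-block correlation {rho} unattainable for {na},{nb}")
            corr[i, j] = corr[j, i] = c
        # factor correlation matrix must be PSD to be sampleable
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise SpecError("network-factor correlation matrix is not positive semidefinite")
        return a_g, a_net, corr

    def expected_block_corr(self, group: Group, net_a: str, net_b: str) -> float:
        """Closed-form expected correlation of covariate-adjusted LGI for a
        parcel pair in networks ``net_a`` and ``net_b``."""
        a_g, a_net, corr = self.loadings(group)
        if net_a == net_b:
            return a_g + a_net[net_a]
        c = corr[NETWORKS.index(net_a), NETWORKS.index(net_b)]
        return a_g + c * np.sqrt(a_net[net_a] * a_net[net_b])


def _deep_copy(obj):
    if isinstance(obj, dict):
        return {k: _deep_copy(v) for k, v in obj.items()}
    return obj


def balanced_atlas(n_parcels: int) -> AtlasMap:
    """Balanced assignment of ``n_parcels`` to 8 networks × 2 hemispheres.

    Parcels are named ``L_0001`` ... and assigned cyclically within each
    hemisphere so every (network, hemisphere) cell has ~n/16 parcels.
    """
    rows = []
    per_hemi = n_parcels // 2
    for hemi in ("L", "R"):
        for k in range(per_hemi):
            rows.append(
                {
                    "parcel_id": f"{hemi}_{k + 1:04d}",
                    "network": NETWORKS[k % len(NETWORKS)],
                    "hemisphere": hemi,
                }
            )
    table = pd.DataFrame(rows).set_index("parcel_id")
    return AtlasMap(table)


def _covariate_shift(betas: Mapping, covariates: pd.DataFrame) -> np.ndarray:
    """Linear predictor of the planted covariate confound for each subject."""
    shift = betas["age"] * (covariates["age"].to_numpy() - COVARIATE_REFERENCE["age"])
    shift = shift + betas["sex_f"] * (covariates["sex"] == "F").to_numpy(dtype=float)
    shift = shift + betas["tiv"] * (covariates["tiv"].to_numpy() - COVARIATE_REFERENCE["tiv"])
    for site_name, b in betas.get("site", {}).items():
        shift = shift + b * (covariates["site"] == site_name).to_numpy(dtype=float)
    return shift


def generate_parcel_lgi(
    spec: CohortSpec,
    group: Group,
    covariates: pd.DataFrame,
    atlas: AtlasMap,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw the subjects × parcels LGI block for one group.

    Factor-model construction: each subject gets one global factor draw and
    one (correlated) draw per network factor; a parcel in network ``k`` is
    ``mu_p + covariate shift + scale * (sqrt(a_g) G + sqrt(a_k) F_k + sqrt(u) eps)``
    with unique variance ``u = 1 - a_g - a_k``, so inter-subject parcel
    correlations equal the planted block values in expectation.
    """
    n = len(covariates)
    a_g, a_net, fcorr = spec.loadings(group)
    parcels = atlas.parcel_ids
    nets = atlas.table["network"].to_numpy()

    chol = np.linalg.cholesky(fcorr + 1e-12 * np.eye(len(NETWORKS)))
    g_factor = rng.standard_normal(n)
    f_net = rng.standard_normal((n, len(NETWORKS))) @ chol.T
    eps = rng.standard_normal((n, len(parcels)))

    net_idx = np.array([NETWORKS.index(net) for net in nets])
    a_vec = np.array([a_net[net] for net in nets])
    u_vec = 1.0 - a_g - a_vec

    latent = (
        np.sqrt(a_g) * g_factor[:, None]
        + np.sqrt(a_vec)[None, :] * f_net[:, net_idx]
        + np.sqrt(u_vec)[None, :] * eps
    )
    # stable per-parcel baseline, independent of group or cohort size
    mu_rng = np.random.default_rng(child_seed(spec.seed, "parcel-means"))
    mu = spec.lgi_mean + 0.1 * mu_rng.standard_normal(len(parcels))

    shift = _covariate_shift(spec.covariate_betas["lgi"], covariates)
    values = mu[None, :] + spec.lgi_scale * latent + shift[:, None]
    return pd.DataFrame(values, index=covariates.index, columns=parcels)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws resampled until non-negative (physical lengths/depths)."""
    if sd < 0:
        raise SpecError(f"negative SD {sd}")
    out = rng.normal(mean, sd, size)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < 0
    return out


def generate_sulcal_measures(
    spec: CohortSpec,
    group: Group,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw PCS/STS length and depth per hemisphere for one group's subjects."""
    params = spec.sulcal_params[group]
    n = len(covariates)
    len_shift = _covariate_shift(spec.covariate_betas["sulcal_length"], covariates)
    dep_shift = _covariate_shift(spec.covariate_betas["sulcal_depth"], covariates)
    rows = []
    for (sulcus, hemi), (lmean, lsd, dmean, dsd) in sorted(params.items()):
        lengths = np.maximum(_truncated_normal(rng, lmean, lsd, n) + len_shift, 0.0)
        depths = np.maximum(_truncated_normal(rng, dmean, dsd, n) + dep_shift, 0.0)
        for sid, length, depth in zip(covariates.index, lengths, depths):
            rows.append(
                {
                    "subject_id": sid,
                    "sulcus": sulcus,
                    "hemisphere": hemi,
                    "length_mm": float(length),
                    "depth_mm": float(depth),
                }
            )
    return pd.DataFrame(rows)


def _draw_covariates(
    spec: CohortSpec, group: Group, ids: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    dist = spec.covariate_dists[group]
    n = len(ids)
    age = rng.normal(*dist["age"], n)
    sex = np.where(rng.random(n) < dist["p_female"], "F", "M")
    site = rng.choice(SITE_NAMES, size=n, p=SITE_PROBS)
    tiv = np.maximum(_truncated_normal(rng, *dist["tiv"], n), 1.0)
    if group is Group.H_PLUS:
        scores, probs = P3_SCORES_HPLUS
        p3 = rng.choice(scores, size=n, p=probs).astype(float)
    elif group is Group.H_MINUS:
        scores, probs = P3_SCORES_HMINUS
        p3 = rng.choice(scores, size=n, p=probs).astype(float)
    else:
        p3 = np.full(n, np.nan)
    return pd.DataFrame(
        {
            "group": group.value,
            "panss_p3": p3,
            "age": age,
            "sex": sex,
            "site": site,
            "tiv": tiv,
        },
        index=pd.Index(ids, name="subject_id"),
    )


def generate_cohort(spec: CohortSpec) -> tuple[Cohort, dict]:
    """Generate a full synthetic cohort plus its ground-truth manifest.

    Subject-level factors are redrawn independently per group, so planted
    between-group covariance differences are exact, not inherited.
    """
    atlas = balanced_atlas(spec.n_parcels)
    subj_frames, lgi_frames, sulcal_frames = [], [], []
    counter = 0
    for group in (Group.H_PLUS, Group.H_MINUS, Group.HC):
        n = int(spec.group_sizes.get(group, 0))
        if n == 0:
            continue
        ids = [f"S{counter + k + 1:04d}" for k in range(n)]
        counter += n
        rng = np.random.default_rng(child_seed(spec.seed, f"group-{group.value}"))
        cov = _draw_covariates(spec, group, ids, rng)
        subj_frames.append(cov)
        lgi_frames.append(generate_parcel_lgi(spec, group, cov, atlas, rng))
        sulcal_frames.append(generate_sulcal_measures(spec, group, cov, rng))

    subjects = pd.concat(subj_frames).sort_index()
    lgi = pd.concat(lgi_frames).loc[subjects.index]
    sulci = (
        pd.concat(sulcal_frames, ignore_index=True)
        .sort_values(["subject_id", "sulcus", "hemisphere"])
        .reset_index(drop=True)
    )
    cohort = Cohort(subjects=subjects, lgi=lgi, sulci=sulci, atlas=atlas)
    manifest = ground_truth_manifest(spec)
    return cohort, manifest


def ground_truth_manifest(spec: CohortSpec) -> dict:
    """Exact planted parameters, serialized alongside every generated cohort."""
    return {
        "seed": spec.seed,
        "group_sizes": {g.value: int(n) for g, n in spec.group_sizes.items()},
        "n_parcels": spec.n_parcels,
        "block_corr": {
            g.value: {
                "global": bc["global"],
                "within": dict(bc["within"]),
                "between": {f"{a}|{b}": rho for (a, b), rho in bc.get("between", {}).items()},
            }
            for g, bc in spec.block_corr.items()
        },
        "within_other": spec.within_other,
        "sulcal_params": {
            g.value: {f"{s}_{h}": list(map(float, v)) for (s, h), v in params.items()}
            for g, params in spec.sulcal_params.items()
        },
        "covariate_betas": spec.covariate_betas,
        "covariate_reference": COVARIATE_REFERENCE,
        "lgi_mean": spec.lgi_mean,
        "lgi_scale": spec.lgi_scale,
        "distributions": "age/tiv normal per group, sex Bernoulli, 3 categorical sites; "
        "sulcal metrics truncated normal at 0; LGI factor-model normal",
    }
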