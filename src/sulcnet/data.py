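"""Data model, file I/O, configuration and seed handling shared by all pipeline stages.

The on-disk cohort is four plain-text files:

* ``subjects.tsv`` — one row per participant: group label (``H+``/``H-``/``HC``),
  PANSS P3 hallucination score (1–7, optional for controls), age (years), sex
  (``M``/``F``), scanning site, and total intracranial volume (TIV, mm^3).
* ``lgi.tsv`` — subjects × parcels matrix of local gyrification index values.
* ``sulci.tsv`` — long table of sulcal length/depth (mm) per sulcus per hemisphere.
* ``atlas.json`` — parcel → {network, hemisphere} mapping.

All matrices downstream are indexed by the sorted subject-id order of the
metadata table so results do not depend on file row order.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml


class Group(str, enum.Enum):
    """Hallucination-status group."""

    H_PLUS = "H+"
    H_MINUS = "H-"
    HC = "HC"


class Hemisphere(str, enum.Enum):
    L = "L"
    R = "R"


class Sulcus(str, enum.Enum):
    PCS = "PCS"
    STS = "STS"


#: Order used for group-wise outputs everywhere.
GROUP_ORDER = (Group.H_PLUS, Group.H_MINUS, Group.HC)

SUBJECT_COLUMNS = ["group", "panss_p3", "age", "sex", "site", "tiv"]
SULCAL_COLUMNS = ["subject_id", "sulcus", "hemisphere", "length_mm", "depth_mm"]


class ValidationError(ValueError):
    """Raised when an input table violates the cohort contract."""


def classify_group(panss_p3: int) -> Group:
    """Assign hallucination status from the PANSS P3 hallucinatory-behaviour score.

    A score strictly greater than 2 defines the hallucinating group (H+);
    scores of 1 or 2 define patients without hallucinations (H-). Healthy
    controls are a cohort designation and are never assigned from a score.
    """
    score = int(panss_p3)
    if score != panss_p3 or not (1 <= score <= 7):
        raise ValidationError(f"PANSS P3 score must be an integer in [1, 7], got {panss_p3!r}")
    return Group.H_PLUS if score > 2 else Group.H_MINUS


def child_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific child seed from the run seed.

    SHA-256 of ``"{seed}:{stage}"``, truncated to 31 bits, so every pipeline
    stage gets an independent, reproducible stream from a single config seed.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class AtlasMap:
    """Parcel → (resting-state network, hemisphere) mapping.

    ``table`` is indexed by parcel id with columns ``network`` and
    ``hemisphere`` (``"L"``/``"R"``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"network", "hemisphere"} - set(self.table.columns)
        if missing:
            raise ValidationError(f"atlas table missing columns: {sorted(missing)}")
        bad = set(self.table["hemisphere"]) - {"L", "R"}
        if bad:
            raise ValidationError(f"atlas hemisphere labels must be L/R, got {sorted(bad)}")

    @property
    def parcel_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def networks(self) -> list[str]:
        return sorted(self.table["network"].unique())

    def labels(self, level: str) -> pd.Series:
        """Per-parcel block label: network name (``net8``) or
        ``network_hemisphere`` (``hemi16``)."""
        if level == "net8":
            return self.table["network"].copy()
        if level == "hemi16":
            return self.table["network"] + "_" + self.table["hemisphere"]
        raise ValueError(f"unknown level {level!r}; expected 'net8' or 'hemi16'")

    @classmethod
    def from_json(cls, path: str | Path) -> "AtlasMap":
        with open(path) as fh:
            raw = json.load(fh)
        table = pd.DataFrame.from_dict(raw, orient="index")
        table.index.name = "parcel_id"
        return cls(table[["network", "hemisphere"]])

    def to_json(self, path: str | Path) -> None:
        payload = {
            str(pid): {"network": row["network"], "hemisphere": row["hemisphere"]}
            for pid, row in self.table.iterrows()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class Cohort:
    """Validated in-memory cohort.

    ``subjects`` is indexed by subject id (sorted); ``lgi`` shares that exact
    index; ``sulci`` is a long table keyed by subject id.
    """

    subjects: pd.DataFrame
    lgi: pd.DataFrame
    sulci: pd.DataFrame
    atlas: AtlasMap

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects.index)

    def group_mask(self, group: Group | str) -> np.ndarray:
        return (self.subjects["group"] == str(getattr(group, "value", group))).to_numpy()


# Default blocks tested for group differences: within-salience, within-auditory
# and the salience–auditory intersection.
DEFAULT_BLOCK_TESTS = (
    ("salience", "salience"),
    ("auditory", "auditory"),
    ("salience", "auditory"),
)


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters.

    ``n_permutations`` and ``n_bootstrap`` default to 5000; the threshold grid
    spans -0.2 to 1.0 in steps of 0.05; planned contrasts are evaluated at
    ``alpha_planned`` and exploratory families corrected at ``fdr_level``.
    """

    n_permutations: int = 5000
    n_bootstrap: int = 5000
    threshold_grid: tuple[float, ...] = tuple(np.round(np.arange(-0.2, 1.0 + 1e-9, 0.05), 2))
    fdr_level: float = 0.05
    alpha_planned: float = 0.05
    rng_seed: int = 0
    block_tests: tuple[tuple[str, str], ...] = DEFAULT_BLOCK_TESTS

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.n_bootstrap < 1:
            raise ValidationError("n_bootstrap must be >= 1")
        grid = np.asarray(self.threshold_grid, dtype=float)
        if grid.size and (np.any(np.diff(grid) <= 0) or grid.min() < -1 or grid.max() > 1):
            raise ValidationError("threshold_grid must be strictly increasing within [-1, 1]")
        if not (0 < self.fdr_level < 1):
            raise ValidationError("fdr_level must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "threshold_grid" in raw:
            raw["threshold_grid"] = tuple(float(x) for x in raw["threshold_grid"])
        if "block_tests" in raw:
            raw["block_tests"] = tuple(tuple(pair) for pair in raw["block_tests"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["threshold_grid"] = [float(x) for x in self.threshold_grid]
        payload["block_tests"] = [list(pair) for pair in self.block_tests]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def _require_columns(df: pd.DataFrame, columns: Iterable[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{name} is missing columns {missing}")


def read_subjects(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "site": str, "sex": str})
    _require_columns(df, ["subject_id"] + SUBJECT_COLUMNS, "subjects table")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"duplicate subject ids: {dupes}")
    df = df.set_index("subject_id").sort_index()

    # Fill group from PANSS P3 where blank; cross-check where both present.
    for sid, row in df.iterrows():
        has_score = pd.notna(row["panss_p3"])
        if has_score:
            score = row["panss_p3"]
            derived = classify_group(score)
            if pd.isna(row["group"]) or row["group"] == "":
                df.loc[sid, "group"] = derived.value
            elif row["group"] != Group.HC.value and row["group"] != derived.value:
                raise ValidationError(
                    f"subject {sid}: group {row['group']!r} inconsistent with PANSS P3 {score}"
                )
        elif pd.isna(row["group"]) or row["group"] == "":
            raise ValidationError(f"subject {sid}: neither group nor PANSS P3 given")
    bad_groups = set(df["group"]) - {g.value for g in Group}
    if bad_groups:
        raise ValidationError(f"unknown group labels: {sorted(bad_groups)}")

    for col in ("age", "tiv"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.index[vals.isna()].tolist()
            raise ValidationError(f"non-numeric or missing {col} for subjects {bad}")
        df[col] = vals
    if (df["tiv"] <= 0).any():
        raise ValidationError("tiv must be positive")
    bad_sex = set(df["sex"]) - {"M", "F"}
    if bad_sex:
        raise ValidationError(f"sex must be M/F, got {sorted(bad_sex)}")
    if df["site"].isna().any():
        raise ValidationError("missing site labels")
    return df


def read_parcel_table(path: str | Path, subject_ids: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise ValidationError("lgi table must have a subject_id first column")
    df = df.set_index("subject_id")
    extra = set(df.index) - set(subject_ids)
    missing = set(subject_ids) - set(df.index)
    if extra or missing:
        raise ValidationError(
            f"lgi subjects do not match metadata: extra={sorted(extra)} missing={sorted(missing)}"
        )
    df = df.loc[subject_ids]
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise ValidationError(f"non-numeric LGI at row {row!r}, column {col!r}")
        df[col] = vals.astype(float)
    return df


def read_sulci(path: str | Path, subject_ids: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    _require_columns(df, SULCAL_COLUMNS, "sulcal table")
    unknown = set(df["subject_id"]) - set(subject_ids)
    if unknown:
        raise ValidationError(f"sulcal table has subjects absent from metadata: {sorted(unknown)}")
    bad_sulci = set(df["sulcus"]) - {s.value for s in Sulcus}
    if bad_sulci:
        raise ValidationError(f"unknown sulci: {sorted(bad_sulci)}")
    bad_hemi = set(df["hemisphere"]) - {"L", "R"}
    if bad_hemi:
        raise ValidationError(f"hemisphere must be L/R, got {sorted(bad_hemi)}")
    for col in ("length_mm", "depth_mm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0])
            raise ValidationError(f"non-numeric {col} at row {row}")
        if (vals < 0).any():
            raise ValidationError(f"negative {col}; lengths/depths are non-negative (0 = absent)")
        df[col] = vals.astype(float)
    return df.sort_values(["subject_id", "sulcus", "hemisphere"]).reset_index(drop=True)


def read_cohort(
    subject_path: str | Path,
    parcel_path: str | Path,
    sulcal_path: str | Path,
    atlas_path: str | Path,
) -> Cohort:
    """Read and cross-validate the four cohort files into one in-memory model."""
    subjects = read_subjects(subject_path)
    ids = list(subjects.index)
    lgi = read_parcel_table(parcel_path, ids)
    sulci = read_sulci(sulcal_path, ids)
    atlas = AtlasMap.from_json(atlas_path)
    uncovered = set(lgi.columns) - set(atlas.parcel_ids)
    if uncovered:
        raise ValidationError(f"atlas does not cover parcels: {sorted(uncovered)}")
    unknown = set(atlas.parcel_ids) - set(lgi.columns)
    if unknown:
        raise ValidationError(f"atlas maps parcels absent from the LGI table: {sorted(unknown)}")
    return Cohort(subjects=subjects, lgi=lgi, sulci=sulci, atlas=atlas)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the four cohort files; inverse of :func:`read_cohort`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "subjects": out / "subjects.tsv",
        "lgi": out / "lgi.tsv",
        "sulci": out / "sulci.tsv",
        "atlas": out / "atlas.json",
    }
    cohort.subjects.to_csv(paths["subjects"], sep="\t", float_format="%.12g")
    cohort.lgi.to_csv(paths["lgi"], sep="\t", float_format="%.12g")
    cohort.sulci.to_csv(paths["sulci"], sep="\t", index=False, float_format="%.12g")
    cohort.atlas.to_json(paths["atlas"])
    return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(bundle: Mapping[str, object], out_dir: str | Path) -> pd.DataFrame:
    """Write a results bundle deterministically and return a checksum manifest.

    DataFrames are written as ``<name>.csv`` at full precision; dicts/lists as
    ``<name>.json`` with sorted keys. The manifest lists every file with its
    SHA-256 content checksum.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise OSError(f"not a writable directory: {out}")
    rows = []
    for name in sorted(bundle):
        obj = bundle[name]
        if isinstance(obj, pd.DataFrame):
            path = out / f"{name}.csv"
            obj.to_csv(path, float_format="%.17g")
        else:
            path = out / f"{name}.json"
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        rows.append({"name": name, "file": path.name, "sha256": _sha256(path)})
    manifest = pd.DataFrame(rows, columns=["name", "file", "sha256"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, enum.Enum):
        return obj.value
    raise TypeError(f"not JSON serializable: {type(obj)}")
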