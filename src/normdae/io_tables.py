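"""Morphometry tables: the 104-feature schema, readers, normalization, label coding.

The feature space is the standard FreeSurfer regional summary of a T1 scan:
mean cortical thickness of the 68 Desikan--Killiany parcels (34 per
hemisphere) plus the volume of 36 segmented subcortical/midline structures,
for a fixed, ordered vector of 104 features per subject.

The canonical on-disk format is a tidy CSV with one row per subject
(``subject_id,age,sex,group,dataset,<104 feature columns>``). A reader for
the tab-separated exports of FreeSurfer's ``aparcstats2table`` /
``asegstats2table`` is provided as a convenience dialect.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("normdae")

SD_FLOOR = 1e-8  #: floor for per-feature SD; guards degenerate (constant) features

COVARIATE_COLUMNS = ("subject_id", "age", "sex", "group", "dataset")

#: Desikan--Killiany cortical parcels, FreeSurfer aparc order (34 per hemisphere).
DESIKAN_KILLIANY_PARCELS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
)

#: Bilateral segmentation structures (aseg naming, without the Left-/Right- prefix).
ASEG_BILATERAL = (
    "Lateral-Ventricle", "Inf-Lat-Vent", "Cerebellum-White-Matter",
    "Cerebellum-Cortex", "Thalamus-Proper", "Caudate", "Putamen", "Pallidum",
    "Hippocampus", "Amygdala", "Accumbens-area", "VentralDC", "vessel",
    "choroid-plexus",
)

#: Midline / unpaired segmentation structures.
ASEG_MIDLINE = (
    "3rd-Ventricle", "4th-Ventricle", "Brain-Stem", "CSF",
    "WM-hypointensities", "Optic-Chiasm", "CC_Anterior", "CC_Posterior",
)


class SchemaError(ValueError):
    """A table does not conform to the expected feature schema."""


class TableValidationError(ValueError):
    """A table fails a content-level validation rule."""


@dataclass(frozen=True)
class Feature:
    """One regional feature: a named measure with kind, side and atlas."""

    name: str
    kind: str  # "thickness" | "volume"
    hemisphere: str  # "left" | "right" | "midline"
    atlas: str  # "desikan_killiany" | "aseg"


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature definition shared by every matrix in a run."""

    features: tuple[Feature, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise SchemaError("feature names must be unique")
        for f in self.features:
            if f.kind not in ("thickness", "volume"):
                raise SchemaError(f"unknown feature kind {f.kind!r}")
            if f.hemisphere not in ("left", "right", "midline"):
                raise SchemaError(f"unknown hemisphere {f.hemisphere!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def count(self, kind: str) -> int:
        return sum(1 for f in self.features if f.kind == kind)

    def to_json(self, path: str | Path) -> None:
        payload = [f.__dict__ for f in self.features]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSchema":
        payload = json.loads(Path(path).read_text())
        return cls(tuple(Feature(**entry) for entry in payload))


def default_schema() -> FeatureSchema:
    """The canonical 104-feature schema: 68 thickness + 36 volume entries.

    The thickness block lists left-hemisphere parcels then right-hemisphere
    parcels, in FreeSurfer aparc order, using ``aparcstats2table`` column
    names (``lh_<parcel>_thickness``). The volume block lists the 28
    bilateral aseg structures (left then right, interleaved per structure)
    followed by 8 midline structures. The segmentation-structure choice is
    this package's documented default (aseg exports vary across FreeSurfer
    versions); pass a schema JSON to override it.
    """
    features: list[Feature] = []
    for hemi, prefix in (("left", "lh"), ("right", "rh")):
        for parcel in DESIKAN_KILLIANY_PARCELS:
            features.append(
                Feature(f"{prefix}_{parcel}_thickness", "thickness", hemi,
                        "desikan_killiany")
            )
    for structure in ASEG_BILATERAL:
        features.append(Feature(f"Left-{structure}", "volume", "left", "aseg"))
        features.append(Feature(f"Right-{structure}", "volume", "right", "aseg"))
    for structure in ASEG_MIDLINE:
        features.append(Feature(structure, "volume", "midline", "aseg"))
    return FeatureSchema(tuple(features))


@dataclass
class MorphometryTable:
    """Per-subject covariates plus the ordered regional feature matrix.

    ``data`` holds one row per subject with the covariate columns
    ``subject_id, age, sex, group, dataset`` followed by the schema's 104
    feature columns, in schema order.
    """

    data: pd.DataFrame
    schema: FeatureSchema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        missing = [c for c in COVARIATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing covariate column(s): {missing}")
        missing_feats = [n for n in self.schema.names if n not in self.data.columns]
        if missing_feats:
            raise SchemaError(
                f"missing feature column(s): {missing_feats[:5]}"
                + ("..." if len(missing_feats) > 5 else "")
            )
        # enforce schema column order regardless of input order
        self.data = self.data[list(COVARIATE_COLUMNS) + list(self.schema.names)]
        self.data = self.data.reset_index(drop=True)
        if self.data["subject_id"].duplicated().any():
            dupes = self.data.loc[self.data["subject_id"].duplicated(), "subject_id"]
            raise TableValidationError(f"duplicate subject_id(s): {sorted(set(dupes))}")
        feats = self.data[list(self.schema.names)]
        if feats.isna().any().any():
            bad = feats.columns[feats.isna().any()].tolist()
            raise TableValidationError(f"missing feature values in: {bad[:5]}")
        bad_sex = set(self.data["sex"]) - {"M", "F"}
        if bad_sex:
            raise TableValidationError(f"sex must be 'M' or 'F', got {bad_sex}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def x(self) -> np.ndarray:
        """Feature matrix, subjects x n_features, float64, schema order."""
        return self.data[list(self.schema.names)].to_numpy(dtype=float)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.data["subject_id"].to_numpy()

    @property
    def ages(self) -> np.ndarray:
        return self.data["age"].to_numpy(dtype=int)

    @property
    def sexes(self) -> np.ndarray:
        return self.data["sex"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.data["group"].to_numpy()

    @property
    def datasets(self) -> np.ndarray:
        return self.data["dataset"].to_numpy()

    def subset(self, mask: np.ndarray) -> "MorphometryTable":
        return MorphometryTable(self.data.loc[np.asarray(mask)].copy(), self.schema)

    def subset_rows(self, indices) -> "MorphometryTable":
        """Subset by integer row positions (order preserved as given)."""
        return MorphometryTable(self.data.iloc[np.asarray(indices)].copy(), self.schema)

    def select_group(self, group: str) -> "MorphometryTable":
        return self.subset(self.groups == group)

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def _validate_ages(df: pd.DataFrame, age_range: tuple[int, int]) -> pd.DataFrame:
    lo, hi = age_range
    ages = pd.to_numeric(df["age"], errors="coerce")
    if ages.isna().any():
        bad = df.loc[ages.isna(), "subject_id"].tolist()
        raise TableValidationError(f"non-numeric age for subject(s): {bad[:5]}")
    keep = (ages >= lo) & (ages <= hi)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "excluded %d subject(s) outside age range [%d, %d]", n_dropped, lo, hi
        )
    out = df.loc[keep].copy()
    out["age"] = ages[keep].astype(int)
    return out


def _coerce_features(df: pd.DataFrame, names: Sequence[str]) -> pd.DataFrame:
    for name in names:
        col = pd.to_numeric(df[name], errors="coerce")
        if col.isna().any() and not df[name].isna().any():
            bad = df.loc[col.isna() & df[name].notna(), "subject_id"].tolist()
            raise TableValidationError(
                f"non-numeric value in feature {name!r} for subject(s): {bad[:5]}"
            )
        df[name] = col.astype(float)
    return df


def read_morphometry_table(
    path: str | Path,
    schema: FeatureSchema | None = None,
    dialect: str = "tidy_csv",
    age_range: tuple[int, int] = (22, 37),
) -> MorphometryTable:
    """Read and validate a morphometry table.

    Parameters
    ----------
    path
        Tidy CSV file (``dialect="tidy_csv"``) or a directory containing
        FreeSurfer table exports (``dialect="freesurfer_tsv"``): files
        ``lh_thickness.tsv``, ``rh_thickness.tsv``, ``aseg_volumes.tsv``
        (tab-separated, first column = subject id, as written by
        ``aparcstats2table`` / ``asegstats2table``) plus a ``covariates.csv``
        with the five covariate columns.
    schema
        Feature schema; defaults to :func:`default_schema`.
    age_range
        Inclusive inclusion range; rows outside it are dropped with a logged
        count (default 22--37 years, the reference cohort's age span).
    """
    schema = schema or default_schema()
    path = Path(path)
    if dialect == "tidy_csv":
        if not path.exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path, dtype={"subject_id": str})
    elif dialect == "freesurfer_tsv":
        df = _read_freesurfer_dir(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing covariate column(s): {missing}")
    missing_feats = [n for n in schema.names if n not in df.columns]
    if missing_feats:
        raise SchemaError(f"missing feature column(s): {missing_feats[:5]}")
    df = _validate_ages(df, age_range)
    df = _coerce_features(df, schema.names)
    return MorphometryTable(df, schema)


def _read_fs_table(path: Path) -> pd.DataFrame:
    """One FreeSurfer table export: first column subject id, rest measures."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={df.columns[0]: "subject_id"})
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def _read_freesurfer_dir(path: Path) -> pd.DataFrame:
    path = Path(path)
    required = ["lh_thickness.tsv", "rh_thickness.tsv", "aseg_volumes.tsv",
                "covariates.csv"]
    for name in required:
        if not (path / name).exists():
            raise FileNotFoundError(path / name)
    cov = pd.read_csv(path / "covariates.csv", dtype={"subject_id": str})
    merged = cov
    for name in required[:3]:
        part = _read_fs_table(path / name)
        merged = merged.merge(part, on="subject_id", how="inner", validate="1:1")
    return merged


# ---------------------------------------------------------------------------
# Reference normalization (z-scoring against the healthy cohort)
# ---------------------------------------------------------------------------

@dataclass
class NormalizationParams:
    """Frozen per-feature mean/SD of the reference cohort.

    Test cohorts are always scaled with these reference parameters — never
    re-fit on test data — so a deviation is measured against the healthy
    population's location and spread.
    """

    mean: np.ndarray
    sd: np.ndarray
    feature_names: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise ValueError("mean and sd must be 1-D vectors of equal length")
        if np.any(self.sd <= 0):
            raise ValueError("sd must be strictly positive (after flooring)")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "source": self.source,
            "features": {
                name: {"mean": float(m), "sd": float(s)}
                for name, m, s in zip(self.feature_names, self.mean, self.sd)
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationParams":
        payload = json.loads(Path(path).read_text())
        names = tuple(payload["features"])
        mean = np.array([payload["features"][n]["mean"] for n in names])
        sd = np.array([payload["features"][n]["sd"] for n in names])
        return cls(mean, sd, names, payload.get("source", ""))


def fit_normalization(table: MorphometryTable, source: str = "") -> NormalizationParams:
    """Per-feature mean and population SD (divide by n) of a reference table.

    Zero-variance features get the floor SD ``1e-8`` and a warning; they
    would otherwise make the z-score undefined.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 subjects to fit normalization")
    x = table.x
    mean = x.mean(axis=0)
    sd = x.std(axis=0)  # population SD
    degenerate = sd < SD_FLOOR
    if degenerate.any():
        names = [table.schema.names[i] for i in np.flatnonzero(degenerate)]
        logger.warning("zero-variance feature(s) floored at sd=%g: %s", SD_FLOOR, names[:5])
        sd = np.where(degenerate, SD_FLOOR, sd)
    return NormalizationParams(mean, sd, table.schema.names, source)


def apply_normalization(table: MorphometryTable, params: NormalizationParams) -> np.ndarray:
    """z = (x - mean) / sd with the reference parameters. Subjects x features."""
    if tuple(params.feature_names) != tuple(table.schema.names):
        raise ValueError("normalization feature order does not match table schema")
    return (table.x - params.mean) / params.sd


def invert_normalization(z: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Map z-scored features back to original units."""
    return np.asarray(z, dtype=float) * params.sd + params.mean


# ---------------------------------------------------------------------------
# Covariate one-hot coding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelCoding:
    """One-hot classes for the supervised heads: 16 integer ages and 2 sexes."""

    age_classes: tuple[int, ...] = tuple(range(22, 38))
    sex_classes: tuple[str, ...] = ("M", "F")

    def __post_init__(self) -> None:
        ages = self.age_classes
        if tuple(ages) != tuple(range(ages[0], ages[-1] + 1)):
            raise ValueError("age_classes must be contiguous integers")
        if tuple(self.sex_classes) != ("M", "F"):
            raise ValueError("sex class order is fixed as (M, F)")

    @property
    def n_age_classes(self) -> int:
        return len(self.age_classes)


def encode_labels(
    table: MorphometryTable, coding: LabelCoding | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One-hot age (subjects x 16) and sex (subjects x 2) matrices."""
    coding = coding or LabelCoding()
    ages = table.ages
    out_of_range = ~np.isin(ages, coding.age_classes)
    if out_of_range.any():
        bad = ages[out_of_range]
        raise ValueError(f"age(s) outside coding classes: {sorted(set(bad))}")
    age_idx = ages - coding.age_classes[0]
    y_age = np.zeros((len(table), coding.n_age_classes))
    y_age[np.arange(len(table)), age_idx] = 1.0
    sex_idx = (table.sexes == "F").astype(int)  # M -> 0, F -> 1
    y_sex = np.zeros((len(table), 2))
    y_sex[np.arange(len(table)), sex_idx] = 1.0
    return y_age, y_sex
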