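"""Synthetic reference and clinical cohorts with realistic covariance structure.

The generator emulates the statistical structure the normative model assumes
in real regional morphometry: continuous features on heterogeneous scales
(mm for thickness, mm^3 for volumes), linear age and sex effects, and
inter-regional correlation induced by shared latent factors. The healthy
generative model for subject ``n`` with integer age ``a_n`` and sex ``s_n`` is

    x_n = baseline_mean
          + age_slopes * (a_n - midrange)
          + sex_offsets * 1[s_n = M]
          + loadings @ f_n + eps_n

with ``f_n ~ N(0, I_K)`` latent factors and ``eps_n ~ N(0, noise_sd^2)``
independent regional noise. Patients additionally receive a mean shift of
``shift_sizes[r]`` *marginal SDs* in each affected region ``r`` and/or a
substituted loading matrix (a pure covariance perturbation that changes
inter-regional correlations while preserving marginal variances when the
substitution preserves row norms, e.g. a sign flip).

Shifts are expressed in marginal-SD units so experiments are scale-free
across the mixed mm / mm^3 feature space.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_tables import FeatureSchema, MorphometryTable, default_schema


@dataclass
class CohortSpec:
    """Full description of one synthetic study (reference + clinical cohorts)."""

    n_reference: int = 1000
    n_controls: int = 100
    n_patients: int = 100
    baseline_mean: np.ndarray = None  # (n_features,)
    age_slopes: np.ndarray = None  # feature units per year
    sex_offsets: np.ndarray = None  # feature units, added for males
    loadings: np.ndarray = None  # (n_features, n_factors)
    noise_sd: np.ndarray | float = 1.0  # scalar or per-feature
    age_range: tuple[int, int] = (22, 37)
    male_fraction: float = 0.5
    affected_regions: tuple[int, ...] = ()
    shift_sizes: tuple[float, ...] = ()  # in marginal-SD units, one per region
    loading_perturbation: np.ndarray | None = None  # patients' loadings, if set
    seed: int = 0

    @property
    def n_features(self) -> int:
        return len(self.baseline_mean)

    @property
    def n_factors(self) -> int:
        return 0 if self.loadings is None or self.loadings.size == 0 else self.loadings.shape[1]

    def validate(self) -> None:
        for name in ("n_reference", "n_controls", "n_patients"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        p = self.n_features
        for name in ("age_slopes", "sex_offsets"):
            if len(getattr(self, name)) != p:
                raise ValueError(f"{name} must have length {p}")
        if self.loadings is not None and self.loadings.shape[0] != p:
            raise ValueError("loadings must have one row per feature")
        if self.loadings is not None and not np.all(np.isfinite(self.loadings)):
            raise ValueError("loadings must be finite")
        if np.any(np.asarray(self.noise_sd) <= 0):
            raise ValueError("noise_sd must be positive")
        if len(self.shift_sizes) != len(self.affected_regions):
            raise ValueError("shift_sizes must match affected_regions in length")
        if self.affected_regions and (
            min(self.affected_regions) < 0 or max(self.affected_regions) >= p
        ):
            raise ValueError("affected_regions out of range")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        if self.age_range[1] < self.age_range[0]:
            raise ValueError("empty age_range")
        if self.loading_perturbation is not None and (
            self.loading_perturbation.shape != self.loadings.shape
        ):
            raise ValueError("loading_perturbation must match loadings shape")

    def to_json(self, path: str | Path) -> None:
        payload = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, np.ndarray):
                value = value.tolist()
            elif isinstance(value, tuple):
                value = list(value)
            payload[f.name] = value
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        payload = json.loads(Path(path).read_text())
        arrays = ("baseline_mean", "age_slopes", "sex_offsets", "loadings",
                  "loading_perturbation")
        kwargs = {}
        for key, value in payload.items():
            if key in arrays and value is not None:
                value = np.asarray(value, dtype=float)
            elif key in ("age_range", "affected_regions", "shift_sizes"):
                value = tuple(value)
            elif key == "noise_sd" and isinstance(value, list):
                value = np.asarray(value, dtype=float)
            kwargs[key] = value
        return cls(**kwargs)


def _age_variance(age_range: tuple[int, int]) -> float:
    m = age_range[1] - age_range[0] + 1
    return (m * m - 1) / 12.0


def marginal_sd(spec: CohortSpec) -> np.ndarray:
    """Closed-form per-feature SD of the healthy generative model.

    Var(x_i) = slope_i^2 Var(age) + offset_i^2 p(1-p) + sum_k L_ik^2 + noise_i^2
    with age uniform on the integer range and sex Bernoulli(male_fraction).
    Used to calibrate patient mean shifts in scale-free units.
    """
    spec.validate()
    p_male = spec.male_fraction
    var = (
        np.asarray(spec.age_slopes, dtype=float) ** 2 * _age_variance(spec.age_range)
        + np.asarray(spec.sex_offsets, dtype=float) ** 2 * p_male * (1 - p_male)
        + np.broadcast_to(np.asarray(spec.noise_sd, dtype=float) ** 2, (spec.n_features,))
    )
    if spec.n_factors:
        var = var + (spec.loadings ** 2).sum(axis=1)
    return np.sqrt(var)


def _simulate_block(
    spec: CohortSpec,
    n: int,
    rng: np.random.Generator,
    patient: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw covariates and features for one group; returns (age, sex, x)."""
    lo, hi = spec.age_range
    ages = rng.integers(lo, hi + 1, size=n)
    male = rng.random(n) < spec.male_fraction
    midrange = (lo + hi) / 2.0
    baseline = np.asarray(spec.baseline_mean, dtype=float)
    x = (
        baseline
        + np.outer(ages - midrange, np.asarray(spec.age_slopes, dtype=float))
        + np.outer(male, np.asarray(spec.sex_offsets, dtype=float))
    )
    loadings = spec.loadings
    if patient and spec.loading_perturbation is not None:
        loadings = spec.loading_perturbation
    if loadings is not None and loadings.size:
        factors = rng.standard_normal((n, loadings.shape[1]))
        x = x + factors @ loadings.T
    x = x + rng.standard_normal((n, spec.n_features)) * np.asarray(spec.noise_sd)
    if patient and spec.affected_regions:
        msd = marginal_sd(spec)
        for region, shift in zip(spec.affected_regions, spec.shift_sizes):
            x[:, region] += shift * msd[region]
    sexes = np.where(male, "M", "F")
    return ages, sexes, x


def _to_table(
    ages: np.ndarray,
    sexes: np.ndarray,
    x: np.ndarray,
    schema: FeatureSchema,
    prefix: str,
    group: str,
    dataset: str,
) -> pd.DataFrame:
    df = pd.DataFrame(x, columns=list(schema.names))
    df.insert(0, "subject_id", [f"{prefix}{i:05d}" for i in range(len(ages))])
    df.insert(1, "age", ages)
    df.insert(2, "sex", sexes)
    df.insert(3, "group", group)
    df.insert(4, "dataset", dataset)
    return df


def generate_cohort(
    spec: CohortSpec, schema: FeatureSchema | None = None
) -> tuple[MorphometryTable, MorphometryTable]:
    """Generate (reference, clinical) tables. Deterministic given ``spec.seed``.

    The reference table holds ``n_reference`` healthy subjects (dataset
    ``"REFERENCE"``). The clinical table holds ``n_controls`` healthy controls
    (group ``"HC"``) and ``n_patients`` patients (group ``"PAT"``), both with
    dataset ``"CLINICAL"`` so downstream group comparisons see a single site.
    """
    spec.validate()
    schema = schema or default_schema()
    if schema.n_features != spec.n_features:
        raise ValueError(
            f"spec has {spec.n_features} features but schema has {schema.n_features}"
        )
    rng = np.random.default_rng(spec.seed)
    ref_age, ref_sex, ref_x = _simulate_block(spec, spec.n_reference, rng, patient=False)
    hc_age, hc_sex, hc_x = _simulate_block(spec, spec.n_controls, rng, patient=False)
    pat_age, pat_sex, pat_x = _simulate_block(spec, spec.n_patients, rng, patient=True)
    reference = MorphometryTable(
        _to_table(ref_age, ref_sex, ref_x, schema, "REF", "HC", "REFERENCE"), schema
    )
    clinical_df = pd.concat(
        [
            _to_table(hc_age, hc_sex, hc_x, schema, "HC", "HC", "CLINICAL"),
            _to_table(pat_age, pat_sex, pat_x, schema, "PAT", "PAT", "CLINICAL"),
        ],
        ignore_index=True,
    )
    clinical = MorphometryTable(clinical_df, schema)
    return reference, clinical


def sign_flip_loadings(loadings: np.ndarray, regions) -> np.ndarray:
    """Covariance-only perturbation: negate the loading rows of ``regions``.

    Marginal variances are unchanged (row norms are preserved) but every
    correlation between a flipped region and the rest of the brain reverses
    sign — the "altered connectivity without altered volume" mechanism.
    """
    perturbed = np.array(loadings, dtype=float, copy=True)
    perturbed[list(regions), :] *= -1.0
    return perturbed


#: Default affected regions: 8 of 104, spanning thickness (indices < 68) and
#: volume (indices >= 68) blocks.
DEFAULT_AFFECTED_REGIONS = (5, 17, 30, 47, 60, 70, 85, 100)


def default_cohort_spec(
    seed: int = 0,
    n_reference: int = 1000,
    n_controls: int = 100,
    n_patients: int = 100,
    n_factors: int = 10,
    affected_regions: tuple[int, ...] = DEFAULT_AFFECTED_REGIONS,
    shift_size: float = 0.8,
    schema: FeatureSchema | None = None,
) -> CohortSpec:
    """A realistic default study: mixed-scale features, shared-factor
    correlation, moderate age/sex effects, and patients with 0.8-SD shifts
    in 8 regions.

    Per-feature variance decomposes (in marginal-SD units) as roughly
    45% shared factors, 35% regional noise, 15% age, 5% sex. Scales and
    baselines differ by feature kind: thickness ~2.5 mm with ~0.15 mm SD,
    volumes ~5000 mm^3 with ~750 mm^3 SD, so normalization is genuinely
    exercised. Structural constants (loading directions, effect signs) are
    drawn once from a fixed generator so the *study design* does not change
    with ``seed``; ``seed`` drives only subject sampling.
    """
    schema = schema or default_schema()
    p = schema.n_features
    kinds = np.array([f.kind for f in schema.features])
    scale = np.where(kinds == "thickness", 0.15, 750.0)
    baseline = np.where(kinds == "thickness", 2.5, 5000.0)

    design_rng = np.random.default_rng(104)  # fixed: design, not sampling
    # variance shares on the standardized scale
    age_share, sex_share, factor_share = 0.15, 0.05, 0.45
    noise_share = 1.0 - age_share - sex_share - factor_share
    age_sign = design_rng.choice([-1.0, 1.0], size=p)
    slopes_std = age_sign * np.sqrt(age_share / _age_variance((22, 37)))
    sex_sign = design_rng.choice([-1.0, 1.0], size=p)
    offsets_std = sex_sign * np.sqrt(sex_share / 0.25)
    raw = design_rng.standard_normal((p, n_factors))
    raw /= np.linalg.norm(raw, axis=1, keepdims=True)
    loadings_std = raw * np.sqrt(factor_share)

    return CohortSpec(
        n_reference=n_reference,
        n_controls=n_controls,
        n_patients=n_patients,
        baseline_mean=baseline,
        age_slopes=slopes_std * scale,
        sex_offsets=offsets_std * scale,
        loadings=loadings_std * scale[:, None],
        noise_sd=np.sqrt(noise_share) * scale,
        age_range=(22, 37),
        male_fraction=0.5,
        affected_regions=tuple(affected_regions),
        shift_sizes=tuple(shift_size for _ in affected_regions),
        seed=seed,
    )
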