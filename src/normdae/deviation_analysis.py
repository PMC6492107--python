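"""Deviation metrics, regional deviation maps, and nonparametric group statistics.

A subject's *deviation metric* is the mean squared reconstruction error over
all regional features (computed on z-scored features, so mm and mm^3 regions
contribute comparably):

    D = (1 / n_regions) * sum_i (x_i - x_hat_i)^2

Group differences in the total metric, and region-wise differences in the
squared errors (the *deviation map*), are tested with the two-tailed
Mann--Whitney U test and sized with Cliff's delta. Because regional tests in
adjacent/homotopic regions are correlated, no family-wise correction is
applied; instead a conservative fixed threshold (default p < .01) controls
the expected false-positive rate at 1% per region.

Group comparisons refuse mixed dataset labels: site/scanner/population
differences would otherwise confound the contrast, so patients are only
compared with controls from the same dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import MorphometryTable, NormalizationParams, apply_normalization
from .normative_autoencoder import TrainedNormativeModel, reconstruct

#: largest n_a * n_b for which the exact Mann-Whitney null is enumerated
EXACT_MW_LIMIT = 400


def deviation_metric(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean squared residual over regions for one subject."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return float(np.mean((x - x_hat) ** 2))


@dataclass
class DeviationResult:
    """Per-subject deviation metrics and regional squared errors for one table."""

    subject_ids: np.ndarray
    deviation_metrics: np.ndarray  # (n_subjects,)
    regional_sq_errors: np.ndarray  # (n_subjects, n_regions)
    region_names: tuple[str, ...]
    groups: np.ndarray
    datasets: np.ndarray

    def __post_init__(self) -> None:
        # tolerance only for summation-order effects on re-read tables
        if not np.allclose(
            self.deviation_metrics, self.regional_sq_errors.mean(axis=1),
            rtol=1e-9, atol=1e-12
        ):
            raise ValueError("deviation metric must equal the mean regional error")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.regional_sq_errors, columns=list(self.region_names))
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "group", self.groups)
        df.insert(2, "dataset", self.datasets)
        df.insert(3, "deviation_metric", self.deviation_metrics)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DeviationResult":
        meta = ("subject_id", "group", "dataset", "deviation_metric")
        regions = tuple(c for c in df.columns if c not in meta)
        return cls(
            subject_ids=df["subject_id"].to_numpy(),
            deviation_metrics=df["deviation_metric"].to_numpy(dtype=float),
            regional_sq_errors=df[list(regions)].to_numpy(dtype=float),
            region_names=regions,
            groups=df["group"].to_numpy(),
            datasets=df["dataset"].to_numpy(),
        )

    def select_group(self, group: str) -> "DeviationResult":
        mask = self.groups == group
        return DeviationResult(
            self.subject_ids[mask], self.deviation_metrics[mask],
            self.regional_sq_errors[mask], self.region_names,
            self.groups[mask], self.datasets[mask],
        )


def compute_deviations(
    model: TrainedNormativeModel,
    table: MorphometryTable,
    normalization: NormalizationParams | None = None,
) -> DeviationResult:
    """Score every subject in ``table`` against the normative model."""
    norm = normalization or model.normalization
    x = apply_normalization(table, norm)
    x_hat, _, _, _ = reconstruct(model, table, normalization=norm)
    sq = (x - x_hat) ** 2
    return DeviationResult(
        subject_ids=table.subject_ids,
        deviation_metrics=sq.mean(axis=1),
        regional_sq_errors=sq,
        region_names=table.schema.names,
        groups=table.groups,
        datasets=table.datasets,
    )


# ---------------------------------------------------------------------------
# Nonparametric two-sample machinery
# ---------------------------------------------------------------------------

def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-tailed Mann--Whitney U test; returns (U_a, two-sided p).

    U_a counts pairs where a > b, with half credit for ties. The exact null
    distribution is enumerated when ``n_a * n_b <= 400`` and there are no
    ties; otherwise the normal approximation with tie and continuity
    corrections is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact = (a.size * b.size <= EXACT_MW_LIMIT) and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def cliffs_delta(sample_a, sample_b) -> float:
    """Cliff's delta: (#{a > b} - #{a < b}) / (n_a * n_b), in [-1, 1]."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    diff = a[:, None] - b[None, :]
    return float((np.sign(diff)).sum() / (a.size * b.size))


@dataclass
class GroupComparison:
    """Group-level contrast of the total deviation metric."""

    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    median_a: float
    median_b: float
    u_statistic: float
    p_value: float
    cliffs_delta: float

    @property
    def abs_cliffs_delta(self) -> float:
        return abs(self.cliffs_delta)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["abs_cliffs_delta"] = self.abs_cliffs_delta
        return d


def _check_same_dataset(results_a: DeviationResult, results_b: DeviationResult) -> None:
    labels = set(results_a.datasets) | set(results_b.datasets)
    if len(labels) > 1:
        raise ValueError(
            f"refusing to compare groups across datasets {sorted(labels)}: "
            "site/scanner/population differences would confound the contrast"
        )


def compare_groups(
    results_a: DeviationResult, results_b: DeviationResult
) -> GroupComparison:
    """Contrast total deviation metrics of two groups from the same dataset.

    Convention: group *a* is the patient (or test) group, so a positive
    Cliff's delta means higher deviation in *a*.
    """
    _check_same_dataset(results_a, results_b)
    da, db = results_a.deviation_metrics, results_b.deviation_metrics
    u, p = mann_whitney_u(da, db)
    return GroupComparison(
        n_a=da.size, n_b=db.size,
        mean_a=float(da.mean()), sd_a=float(da.std()),
        mean_b=float(db.mean()), sd_b=float(db.std()),
        median_a=float(np.median(da)), median_b=float(np.median(db)),
        u_statistic=u, p_value=p, cliffs_delta=cliffs_delta(da, db),
    )


def _regional_table(
    values_a: np.ndarray,
    values_b: np.ndarray,
    region_names,
    threshold: float,
) -> pd.DataFrame:
    rows = []
    for j, name in enumerate(region_names):
        u, p = mann_whitney_u(values_a[:, j], values_b[:, j])
        delta = cliffs_delta(values_a[:, j], values_b[:, j])
        rows.append({
            "region": name, "u_statistic": u, "p_value": p,
            "abs_cliffs_delta": abs(delta), "significant": bool(p < threshold),
        })
    df = pd.DataFrame(rows)
    return df.sort_values(
        "abs_cliffs_delta", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def regional_comparison(
    results_a: DeviationResult,
    results_b: DeviationResult,
    threshold: float = 0.01,
) -> pd.DataFrame:
    """Region-wise contrast of reconstruction errors, sorted by |Cliff's delta|.

    Columns: region, u_statistic, p_value, abs_cliffs_delta, significant
    (p < ``threshold``).
    """
    _check_same_dataset(results_a, results_b)
    if results_a.region_names != results_b.region_names:
        raise ValueError("region name mismatch between the two results")
    return _regional_table(
        results_a.regional_sq_errors, results_b.regional_sq_errors,
        results_a.region_names, threshold,
    )


def mass_univariate(
    table_a: MorphometryTable,
    table_b: MorphometryTable,
    threshold: float = 0.01,
) -> pd.DataFrame:
    """The classical per-region contrast on raw (unreconstructed) features.

    Applies the identical Mann--Whitney / Cliff's-delta machinery to the
    original thickness/volume values, for contrasting multivariate deviation
    findings with what a mass-univariate analysis would detect.
    """
    if table_a.schema.names != table_b.schema.names:
        raise ValueError("tables must share a feature schema")
    datasets = set(table_a.datasets) | set(table_b.datasets)
    if len(datasets) > 1:
        raise ValueError(f"refusing to compare across datasets {sorted(datasets)}")
    return _regional_table(table_a.x, table_b.x, table_a.schema.names, threshold)
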