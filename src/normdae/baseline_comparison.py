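"""Bootstrap AUC comparison: normative deviation score vs a linear SVM.

Both methods are evaluated by percentile bootstrap:

* **SVM** — per replicate, a bootstrap training set of ``floor(0.7 n)``
  draws with replacement from the clinical table; all subjects never drawn
  form the out-of-bag test set. The soft-margin C is chosen on the bootstrap
  training set by stratified k-fold cross-validation maximizing mean
  balanced accuracy over a power-of-two grid; the model is refit on the full
  bootstrap training set and scored on the out-of-bag subjects by AUC-ROC.
  Features are z-scored with the *reference* cohort's parameters so both
  methods see identical inputs.

* **Normative** — per replicate, the healthy reference table is resampled
  with replacement (same size) and the autoencoder retrained on it; every
  clinical subject is then scored by the deviation metric, normalizing with
  the ORIGINAL reference parameters (not the resample's), and AUC-ROC is
  computed against the true labels.

Each distribution is summarized by its median and a percentile confidence
interval. The default C grid is {2^e : e odd, -15 <= e <= 15} (16 values).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import balanced_accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io_tables import (
    MorphometryTable,
    NormalizationParams,
    apply_normalization,
    fit_normalization,
)
from .normative_autoencoder import ModelConfig, build_model, train
from .deviation_analysis import compute_deviations

logger = logging.getLogger("normdae")

DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-15, 16, 2))  # 16 odd exponents


@dataclass
class BootstrapSpec:
    """Bootstrap protocol parameters."""

    n_reps: int = 1000
    train_fraction: float = 0.7
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    cv_folds: int = 10
    ci_level: float = 95.0
    seed: int = 0
    svm_score: str = "probability"  # or "margin"
    class_weight: str | None = None  # e.g. "balanced"

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if not self.c_grid:
            raise ValueError("c_grid must be nonempty")
        if self.n_reps <= 0 or self.cv_folds < 2:
            raise ValueError("n_reps must be positive and cv_folds >= 2")


@dataclass
class PerformanceDistribution:
    """Bootstrap AUC sample with median and percentile CI."""

    auc_samples: np.ndarray
    method: str  # "svm" | "normative"
    ci_level: float = 95.0
    chosen_c: np.ndarray | None = None  # per-rep selected C (svm only)

    def __post_init__(self) -> None:
        self.auc_samples = np.asarray(self.auc_samples, dtype=float)
        if np.any((self.auc_samples < 0) | (self.auc_samples > 1)):
            raise ValueError("AUC samples must lie in [0, 1]")

    @property
    def median(self) -> float:
        return float(np.median(self.auc_samples))

    @property
    def ci(self) -> tuple[float, float]:
        tail = (100.0 - self.ci_level) / 2.0
        lo, hi = np.percentile(self.auc_samples, [tail, 100.0 - tail])
        return float(lo), float(hi)

    def to_dict(self) -> dict:
        lo, hi = self.ci
        return {"method": self.method, "median": self.median,
                "ci_low": lo, "ci_high": hi, "ci_level": self.ci_level,
                "n_reps": int(self.auc_samples.size)}


def auc_from_scores(scores, labels) -> float:
    """AUC-ROC: P(random positive outscores random negative), half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels.astype(int), scores))


def _patient_labels(table: MorphometryTable, control_label: str = "HC") -> np.ndarray:
    labels = table.groups != control_label
    if labels.all() or not labels.any():
        raise ValueError("clinical table must contain both controls and patients")
    return labels


def _select_c(
    x: np.ndarray,
    y: np.ndarray,
    spec: BootstrapSpec,
    rng_seed: int,
) -> float:
    """Grid-search C by stratified k-fold CV mean balanced accuracy.

    Ties break toward smaller C (stronger regularization). Fold count is
    capped by the smallest class so stratification stays valid on small
    bootstrap samples.
    """
    n_folds = min(spec.cv_folds, int(np.bincount(y.astype(int)).min()))
    n_folds = max(n_folds, 2)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
    best_c, best_score = None, -np.inf
    for c in sorted(spec.c_grid):
        scores = []
        for tr, va in skf.split(x, y):
            clf = SVC(kernel="linear", C=c, class_weight=spec.class_weight)
            clf.fit(x[tr], y[tr])
            scores.append(balanced_accuracy_score(y[va], clf.predict(x[va])))
        mean_score = float(np.mean(scores))
        if mean_score > best_score:  # strict: first (smallest) C wins ties
            best_score, best_c = mean_score, c
    return best_c


def bootstrap_svm_auc(
    clinical: MorphometryTable,
    reference_norm: NormalizationParams,
    spec: BootstrapSpec,
    control_label: str = "HC",
) -> PerformanceDistribution:
    """Bootstrap the linear-SVM AUC on a clinical table.

    Replicates whose bootstrap training set or out-of-bag test set lacks a
    class are discarded, logged and redrawn.
    """
    spec.validate()
    x = apply_normalization(clinical, reference_norm)
    y = _patient_labels(clinical, control_label)
    n = len(clinical)
    n_train = int(np.floor(spec.train_fraction * n))
    ss = np.random.SeedSequence(spec.seed)
    aucs, chosen = [], []
    n_discarded = 0
    rep = 0
    while len(aucs) < spec.n_reps:
        child = ss.spawn(1)[0]
        rng = np.random.default_rng(child)
        rep += 1
        in_bag = rng.integers(0, n, size=n_train)
        oob = np.setdiff1d(np.arange(n), in_bag)
        if len(np.unique(y[in_bag])) < 2 or len(np.unique(y[oob])) < 2:
            n_discarded += 1
            continue
        cv_seed = int(child.generate_state(1)[0] % (2 ** 31))
        c = _select_c(x[in_bag], y[in_bag], spec, cv_seed)
        if spec.svm_score == "probability":
            clf = CalibratedClassifierCV(
                SVC(kernel="linear", C=c, class_weight=spec.class_weight),
                method="sigmoid", cv=5, ensemble=False,
            )
            clf.fit(x[in_bag], y[in_bag])
            pos = list(clf.classes_).index(True)
            scores = clf.predict_proba(x[oob])[:, pos]
        else:
            clf = SVC(kernel="linear", C=c, class_weight=spec.class_weight)
            clf.fit(x[in_bag], y[in_bag])
            scores = clf.decision_function(x[oob])
            if clf.classes_[1] != True:  # noqa: E712 - sklearn class order
                scores = -scores
        aucs.append(auc_from_scores(scores, y[oob]))
        chosen.append(c)
    if n_discarded:
        logger.info("discarded and redrew %d single-class bootstrap replicate(s)",
                    n_discarded)
    return PerformanceDistribution(np.array(aucs), "svm", spec.ci_level,
                                   chosen_c=np.array(chosen))


def bootstrap_normative_auc(
    reference: MorphometryTable,
    clinical: MorphometryTable,
    model_config: ModelConfig,
    spec: BootstrapSpec,
    control_label: str = "HC",
    resample_clinical: bool = False,
) -> PerformanceDistribution:
    """Bootstrap the normative deviation-score AUC.

    Each replicate retrains the autoencoder on a with-replacement resample
    of the reference cohort, then scores the clinical table with the
    deviation metric, normalizing with the original reference parameters.

    By default the clinical table is fixed, so the distribution captures
    training variability only (its CI is tight around the clinical sample's
    AUC). With ``resample_clinical=True`` each replicate also bootstraps the
    clinical subjects, so the CI additionally reflects test-sample
    variability — required for the CI to cover 0.5 under a null
    (non-discriminating) score.
    """
    spec.validate()
    original_norm = fit_normalization(reference, source="reference")
    y = _patient_labels(clinical, control_label)
    n = len(reference)
    n_clin = len(clinical)
    ss = np.random.SeedSequence(spec.seed)
    aucs = []
    while len(aucs) < spec.n_reps:
        child = ss.spawn(1)[0]
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n)
        if resample_clinical:
            clin_idx = rng.integers(0, n_clin, size=n_clin)
            if len(np.unique(y[clin_idx])) < 2:
                continue
        else:
            clin_idx = np.arange(n_clin)
        boot_df = reference.data.iloc[idx].copy()
        boot_df["subject_id"] = [f"BOOT{i:05d}" for i in range(n)]
        boot = MorphometryTable(boot_df, reference.schema)
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        cfg = dataclasses.replace(model_config, seed=seed)
        trained = train(build_model(cfg), boot)
        dev = compute_deviations(trained, clinical, normalization=original_norm)
        aucs.append(auc_from_scores(dev.deviation_metrics[clin_idx],
                                    y[clin_idx]))
    return PerformanceDistribution(np.array(aucs), "normative", spec.ci_level)
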