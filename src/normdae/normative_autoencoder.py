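"""The semi-supervised denoising deep autoencoder (NumPy implementation).

Architecture (default 104 -> 100 -> 75 -> 100 -> 104):

    encoder   x ->(SELU) h1 ->(SELU) z
    heads     h1 ->(softmax) p_age (16-way), h1 ->(softmax) p_sex (2-way)
    decoder   concat(z, p_age, p_sex) ->(SELU) h2 ->(linear) x_hat

Training minimizes, per mini-batch of corrupted inputs,

    Loss = MSE(x, x_hat) + CE(y_age, p_age) + CE(y_sex, p_sex) + XCov(z, p)

(term weights configurable) plus an L2 penalty on weight matrices. The
input is corrupted with fresh additive Gaussian noise each step (denoising
scheme); the target is always the clean, z-scored input. The XCov term is
the summed squared batch cross-covariance between latent units and the
concatenated head outputs — it pushes age/sex information out of ``z`` and
into the supervised heads, so the latent code is disentangled from the
covariates that the decoder receives explicitly.

All forward/backward passes, the Adam optimizer and the exponential
learning-rate decay are implemented here in NumPy; gradients are analytic
(verified against finite differences in the test suite).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import KFold

from .io_tables import (
    LabelCoding,
    MorphometryTable,
    NormalizationParams,
    apply_normalization,
    encode_labels,
    fit_normalization,
)

SELU_ALPHA = 1.6732632423543772
SELU_SCALE = 1.0507009873554805
_LOG_EPS = 1e-12

WEIGHT_KEYS = ("W1", "Wz", "Wa", "Ws", "W2", "Wo")
BIAS_KEYS = ("b1", "bz", "ba", "bs", "b2", "bo")


def selu(a: np.ndarray) -> np.ndarray:
    return SELU_SCALE * np.where(a > 0, a, SELU_ALPHA * (np.exp(np.minimum(a, 0.0)) - 1.0))


def selu_grad(a: np.ndarray) -> np.ndarray:
    return SELU_SCALE * np.where(a > 0, 1.0, SELU_ALPHA * np.exp(np.minimum(a, 0.0)))


def softmax(a: np.ndarray) -> np.ndarray:
    shifted = a - a.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class ModelConfig:
    """Hyperparameters of the normative autoencoder."""

    input_dim: int = 104
    h1_units: int = 100
    z_units: int = 75
    h2_units: int = 100
    n_age_classes: int = 16
    n_sex_classes: int = 2
    l2_coefficient: float = 1e-3
    corruption_sd: float = 0.1
    epochs: int = 2000
    batch_size: int = 64
    lr_initial: float = 0.05
    lr_final: float = 0.0005
    loss_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        for name in ("input_dim", "h1_units", "z_units", "h2_units",
                     "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.z_units >= self.h1_units:
            raise ValueError("z_units must be smaller than h1_units (bottleneck)")
        if self.lr_final >= self.lr_initial:
            raise ValueError("lr_final must be smaller than lr_initial")
        if len(self.loss_weights) != 4:
            raise ValueError("loss_weights must have 4 entries (recon, age, sex, xcov)")

    def learning_rates(self) -> np.ndarray:
        """Per-epoch LR: exponential decay hitting lr_final at the last epoch."""
        if self.epochs == 1:
            return np.array([self.lr_initial])
        gamma = (self.lr_final / self.lr_initial) ** (1.0 / (self.epochs - 1))
        return self.lr_initial * gamma ** np.arange(self.epochs)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["loss_weights"] = list(self.loss_weights)
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelConfig":
        payload = json.loads(Path(path).read_text())
        payload["loss_weights"] = tuple(payload["loss_weights"])
        return cls(**payload)


def _init_params(config: ModelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """LeCun-normal init for SELU layers; Glorot-uniform for softmax/linear outputs."""
    d, h1, z, h2 = config.input_dim, config.h1_units, config.z_units, config.h2_units
    na, ns = config.n_age_classes, config.n_sex_classes
    d_dec = z + na + ns

    def lecun(fan_in: int, fan_out: int) -> np.ndarray:
        return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, fan_out))

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    return {
        "W1": lecun(d, h1), "b1": np.zeros(h1),
        "Wz": lecun(h1, z), "bz": np.zeros(z),
        "Wa": glorot(h1, na), "ba": np.zeros(na),
        "Ws": glorot(h1, ns), "bs": np.zeros(ns),
        "W2": lecun(d_dec, h2), "b2": np.zeros(h2),
        "Wo": glorot(h2, d), "bo": np.zeros(d),
    }


class NormativeAutoencoder:
    """Untrained model: parameters + config + the run's random generator."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.params = _init_params(config, self.rng)

    # -- forward ------------------------------------------------------------

    def forward(self, x: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        a1 = x @ p["W1"] + p["b1"]
        h1 = selu(a1)
        az = h1 @ p["Wz"] + p["bz"]
        z = selu(az)
        aa = h1 @ p["Wa"] + p["ba"]
        pa = softmax(aa)
        as_ = h1 @ p["Ws"] + p["bs"]
        ps = softmax(as_)
        d_in = np.concatenate([z, pa, ps], axis=1)
        a2 = d_in @ p["W2"] + p["b2"]
        h2 = selu(a2)
        xhat = h2 @ p["Wo"] + p["bo"]
        return {"x": x, "a1": a1, "h1": h1, "az": az, "z": z, "aa": aa, "pa": pa,
                "as": as_, "ps": ps, "d_in": d_in, "a2": a2, "h2": h2, "xhat": xhat}

    # -- loss and gradients --------------------------------------------------

    def loss_terms(
        self,
        cache: dict[str, np.ndarray],
        x_clean: np.ndarray,
        y_age: np.ndarray,
        y_sex: np.ndarray,
    ) -> dict[str, float]:
        n = x_clean.shape[0]
        w = self.config.loss_weights
        recon = float(np.mean((cache["xhat"] - x_clean) ** 2))
        ce_age = float(-np.mean(np.sum(y_age * np.log(cache["pa"] + _LOG_EPS), axis=1)))
        ce_sex = float(-np.mean(np.sum(y_sex * np.log(cache["ps"] + _LOG_EPS), axis=1)))
        xcov = xcov_cost(cache["z"], np.concatenate([cache["pa"], cache["ps"]], axis=1))
        l2_pen = self.config.l2_coefficient * sum(
            float(np.sum(self.params[k] ** 2)) for k in WEIGHT_KEYS
        )
        total = w[0] * recon + w[1] * ce_age + w[2] * ce_sex + w[3] * xcov
        return {"total": total, "recon": recon, "ce_age": ce_age,
                "ce_sex": ce_sex, "xcov": float(xcov), "l2_penalty": l2_pen}

    def gradients(
        self,
        cache: dict[str, np.ndarray],
        x_clean: np.ndarray,
        y_age: np.ndarray,
        y_sex: np.ndarray,
    ) -> dict[str, np.ndarray]:
        p = self.params
        cfg = self.config
        w_r, w_a, w_s, w_x = cfg.loss_weights
        l2 = cfg.l2_coefficient
        n, d = x_clean.shape
        z, pa, ps = cache["z"], cache["pa"], cache["ps"]
        nz = z.shape[1]

        # reconstruction path
        g_xhat = w_r * 2.0 * (cache["xhat"] - x_clean) / (n * d)
        gWo = cache["h2"].T @ g_xhat + 2.0 * l2 * p["Wo"]
        gbo = g_xhat.sum(axis=0)
        g_h2 = g_xhat @ p["Wo"].T
        g_a2 = g_h2 * selu_grad(cache["a2"])
        gW2 = cache["d_in"].T @ g_a2 + 2.0 * l2 * p["W2"]
        gb2 = g_a2.sum(axis=0)
        g_d = g_a2 @ p["W2"].T
        g_z_dec = g_d[:, :nz]
        g_pa_dec = g_d[:, nz:nz + pa.shape[1]]
        g_ps_dec = g_d[:, nz + pa.shape[1]:]

        # XCov: C = zc.T @ yc / n, cost = 0.5 * sum(C^2)
        y = np.concatenate([pa, ps], axis=1)
        zc = z - z.mean(axis=0)
        yc = y - y.mean(axis=0)
        C = zc.T @ yc / n
        g_z_x = w_x * (yc @ C.T) / n  # centering term vanishes: yc columns sum to 0
        g_y_x = w_x * (zc @ C) / n
        g_pa_x = g_y_x[:, :pa.shape[1]]
        g_ps_x = g_y_x[:, pa.shape[1]:]

        # latent path
        g_z = g_z_dec + g_z_x
        g_az = g_z * selu_grad(cache["az"])
        gWz = cache["h1"].T @ g_az + 2.0 * l2 * p["Wz"]
        gbz = g_az.sum(axis=0)

        # heads: cross-entropy at logits + p-space gradients through softmax
        def head_logit_grad(pk, yk, g_pk, weight):
            g_ce = weight * (pk - yk) / n
            inner = (g_pk * pk).sum(axis=1, keepdims=True)
            g_from_p = pk * (g_pk - inner)
            return g_ce + g_from_p

        g_aa = head_logit_grad(pa, y_age, g_pa_dec + g_pa_x, w_a)
        g_as = head_logit_grad(ps, y_sex, g_ps_dec + g_ps_x, w_s)
        gWa = cache["h1"].T @ g_aa + 2.0 * l2 * p["Wa"]
        gba = g_aa.sum(axis=0)
        gWs = cache["h1"].T @ g_as + 2.0 * l2 * p["Ws"]
        gbs = g_as.sum(axis=0)

        # shared first layer
        g_h1 = g_az @ p["Wz"].T + g_aa @ p["Wa"].T + g_as @ p["Ws"].T
        g_a1 = g_h1 * selu_grad(cache["a1"])
        gW1 = cache["x"].T @ g_a1 + 2.0 * l2 * p["W1"]
        gb1 = g_a1.sum(axis=0)

        return {"W1": gW1, "b1": gb1, "Wz": gWz, "bz": gbz, "Wa": gWa, "ba": gba,
                "Ws": gWs, "bs": gbs, "W2": gW2, "b2": gb2, "Wo": gWo, "bo": gbo}


def xcov_cost(z_batch: np.ndarray, yhat_batch: np.ndarray) -> float:
    """Cross-covariance disentanglement cost: 0.5 * sum_ij C_ij^2 with
    C_ij = (1/n) sum_n (z_ni - mean_i)(y_nj - mean_j)."""
    z_batch = np.asarray(z_batch, dtype=float)
    yhat_batch = np.asarray(yhat_batch, dtype=float)
    n = z_batch.shape[0]
    if n < 2 or yhat_batch.shape[0] != n:
        raise ValueError("need matching batches with n >= 2")
    zc = z_batch - z_batch.mean(axis=0)
    yc = yhat_batch - yhat_batch.mean(axis=0)
    C = zc.T @ yc / n
    return float(0.5 * np.sum(C ** 2))


class _Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: dict[str, np.ndarray]):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class TrainedNormativeModel:
    """Trained weights + frozen reference normalization + label coding."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    normalization: NormalizationParams
    coding: LabelCoding
    history: pd.DataFrame

    def _net(self) -> NormativeAutoencoder:
        net = NormativeAutoencoder.__new__(NormativeAutoencoder)
        net.config = self.config
        net.params = self.params
        net.rng = None
        return net

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.config.to_json(out_dir / "config.json")
        self.normalization.to_json(out_dir / "normalization.json")
        np.savez(out_dir / "weights.npz", **self.params)
        self.history.to_csv(out_dir / "history.csv", index=False)

    @classmethod
    def load(cls, out_dir: str | Path) -> "TrainedNormativeModel":
        out_dir = Path(out_dir)
        config = ModelConfig.from_json(out_dir / "config.json")
        normalization = NormalizationParams.from_json(out_dir / "normalization.json")
        with np.load(out_dir / "weights.npz") as npz:
            params = {k: npz[k] for k in npz.files}
        history = pd.read_csv(out_dir / "history.csv")
        coding = LabelCoding(
            age_classes=tuple(range(22, 22 + config.n_age_classes))
        )
        return cls(config, params, normalization, coding, history)


def build_model(config: ModelConfig) -> NormativeAutoencoder:
    """Instantiate an untrained model; same seed -> identical initial weights."""
    return NormativeAutoencoder(config)


def train(
    model: NormativeAutoencoder,
    reference_table: MorphometryTable,
    holdout: MorphometryTable | None = None,
    coding: LabelCoding | None = None,
) -> TrainedNormativeModel:
    """Train on the healthy reference cohort.

    Normalization is fit on ``reference_table`` and frozen into the returned
    model. Each step corrupts the z-scored batch with fresh additive
    Gaussian noise (SD ``corruption_sd``); the loss targets the clean batch.
    Data are reshuffled every epoch; the final short batch is kept. The
    recorded per-epoch terms are batch-size-weighted means, so the history's
    ``total_loss`` equals the weighted sum of its four terms at every epoch.
    """
    cfg = model.config
    coding = coding or LabelCoding(
        age_classes=tuple(range(22, 22 + cfg.n_age_classes))
    )
    if len(reference_table) < cfg.batch_size:
        raise ValueError("reference table smaller than one batch")
    norm = fit_normalization(reference_table, source="reference")
    x_all = apply_normalization(reference_table, norm)
    y_age_all, y_sex_all = encode_labels(reference_table, coding)
    if holdout is not None:
        x_hold = apply_normalization(holdout, norm)

    n = x_all.shape[0]
    lrs = cfg.learning_rates()
    adam = _Adam(model.params)
    rng = model.rng
    records = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        sums = {"total": 0.0, "recon": 0.0, "ce_age": 0.0, "ce_sex": 0.0,
                "xcov": 0.0, "l2_penalty": 0.0}
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = x_all[idx]
            if cfg.corruption_sd > 0:
                xc = xb + rng.normal(0.0, cfg.corruption_sd, size=xb.shape)
            else:
                xc = xb
            cache = model.forward(xc)
            terms = model.loss_terms(cache, xb, y_age_all[idx], y_sex_all[idx])
            if not np.isfinite(terms["total"]):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {terms}"
                )
            grads = model.gradients(cache, xb, y_age_all[idx], y_sex_all[idx])
            adam.step(model.params, grads, lrs[epoch])
            for k in sums:
                sums[k] += terms[k] * len(idx)
        rec = {k: v / n for k, v in sums.items()}
        rec["epoch"] = epoch
        rec["lr"] = lrs[epoch]
        if holdout is not None:
            xhat_hold = model.forward(x_hold)["xhat"]
            rec["val_recon"] = float(np.mean((xhat_hold - x_hold) ** 2))
        records.append(rec)
    history = pd.DataFrame(records).rename(columns={"total": "total_loss",
                                                    "recon": "recon_mse"})
    cols = ["epoch", "total_loss", "recon_mse", "ce_age", "ce_sex", "xcov",
            "l2_penalty", "lr"] + (["val_recon"] if holdout is not None else [])
    return TrainedNormativeModel(cfg, model.params, norm, coding, history[cols])


def reconstruct(
    model: TrainedNormativeModel,
    table: MorphometryTable,
    normalization: NormalizationParams | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Clean-input inference: returns (x_hat, p_age, p_sex, z), z-scored space.

    ``normalization`` overrides the model's frozen parameters (used by the
    bootstrap protocol, which scores with the original reference scaling).
    """
    norm = normalization or model.normalization
    x = apply_normalization(table, norm)
    cache = model._net().forward(x)
    return cache["xhat"], cache["pa"], cache["ps"], cache["z"]


def covariate_performance(
    model: TrainedNormativeModel, table: MorphometryTable
) -> tuple[float, float]:
    """(age MAE in years, sex balanced accuracy in [0, 1]) on a labelled table."""
    _, pa, ps, _ = reconstruct(model, table)
    ages = np.asarray(model.coding.age_classes)
    pred_age = ages[pa.argmax(axis=1)]
    mae = float(np.mean(np.abs(pred_age - table.ages)))
    pred_sex = np.asarray(model.coding.sex_classes)[ps.argmax(axis=1)]
    bacc = float(balanced_accuracy_score(table.sexes, pred_sex))
    return mae, bacc


def candidate_grid(unit_grid) -> list[tuple[int, int]]:
    """All (h1, z) pairs with z < h1; h2 mirrors h1 (symmetric configs)."""
    grid = sorted(set(unit_grid))
    return [(h1, z) for h1 in grid for z in grid if z < h1]


def select_architecture(
    reference_table: MorphometryTable,
    unit_grid=(10, 25, 50, 75, 100),
    k_folds: int = 10,
    base_config: ModelConfig | None = None,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Grid search over symmetric layer sizes by k-fold CV reconstruction error.

    Every candidate sets h1 = h2 from the grid and z from the grid with
    z < h1. Each fold fits normalization on its training split, trains, and
    scores clean-input reconstruction MSE on the validation split. Returns
    the argmin-mean-validation-error config and the full CV table.
    """
    base = base_config or ModelConfig()
    candidates = candidate_grid(unit_grid)
    if not candidates:
        raise ValueError("no candidate satisfies z < h1 on this grid")
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=base.seed)
    rows = []
    for h1, z in candidates:
        fold_errors = []
        for fold, (tr, va) in enumerate(kf.split(np.arange(len(reference_table)))):
            cfg = dataclasses.replace(base, h1_units=h1, z_units=z, h2_units=h1)
            trained = train(build_model(cfg), reference_table.subset_rows(tr))
            x_va = apply_normalization(reference_table.subset_rows(va),
                                       trained.normalization)
            xhat = trained._net().forward(x_va)["xhat"]
            fold_errors.append(float(np.mean((xhat - x_va) ** 2)))
        rows.append({"h1_units": h1, "z_units": z, "h2_units": h1,
                     "mean_val_recon": float(np.mean(fold_errors)),
                     "sd_val_recon": float(np.std(fold_errors))})
    cv_table = pd.DataFrame(rows)
    best = cv_table.loc[cv_table["mean_val_recon"].idxmin()]
    best_config = dataclasses.replace(
        base, h1_units=int(best["h1_units"]), z_units=int(best["z_units"]),
        h2_units=int(best["h2_units"])
    )
    return best_config, cv_table
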