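"""Single-hidden-layer feed-forward regressor: fingerprint + dielectric -> nm.

The network has one hidden layer of ReLU units (250 by default) and a
single linear output, trained by mini-batch stochastic gradient descent
for at most ``max_iterations`` epochs on a random 90/10 train/test split.
Fitting delegates to scikit-learn's ``MLPRegressor``; the learned weights
are extracted into :class:`TrainedSpectralModel`, whose forward pass is an
explicit NumPy computation that tests verify against an independent
brute-force oracle.

Because SGD training is stochastic, headline metrics are reported as
medians over several seeds (see :func:`train_model_multiseed`).
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from malphot.dataset_io import PhotophysicsRecord, SubstitutionClass
from malphot.featurize import fingerprint_smiles

TARGETS = ("emission", "absorption")


@dataclass
class ModelConfig:
    """Hyperparameters of the wavelength regressor.

    ``eps_transform``: "raw" appends the dielectric constant unchanged;
    "zscore" standardizes it with statistics fitted on the training split.
    Targets are always trained in centered/scaled form internally and
    reported back in nm.
    """

    n_bits: int = 1024
    radius: int = 5
    hidden_units: int = 250
    activation: str = "relu"
    max_iterations: int = 2000
    train_fraction: float = 0.9
    target: str = "emission"  # or "absorption"
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 32
    l2_alpha: float = 1e-4
    eps_transform: str = "raw"  # or "zscore"
    center_targets: bool = True
    validation_fraction: float = 0.0  # >0 enables early stopping on a held-out split

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.hidden_units < 1 or self.max_iterations < 1:
            raise ValueError("hidden_units and max_iterations must be >= 1")
        if self.target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}")
        if self.eps_transform not in ("raw", "zscore"):
            raise ValueError("eps_transform must be 'raw' or 'zscore'")


@dataclass
class TrainedSpectralModel:
    """Weights and scaling constants of a fitted wavelength regressor.

    Prediction is ``y = w2 . relu(W1^T x_scaled + b1) + b2`` rescaled back
    to nm, where ``x_scaled = (x - x_mean) / x_scale``.
    """

    w1: np.ndarray  # (n_features, hidden_units)
    b1: np.ndarray  # (hidden_units,)
    w2: np.ndarray  # (hidden_units,)
    b2: float
    x_mean: np.ndarray  # (n_features,)
    x_scale: np.ndarray  # (n_features,)
    y_mean: float
    y_scale: float
    config: ModelConfig
    loss_curve: list[float] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.w1.shape[0]

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        """Forward pass on raw feature rows (fingerprint bits + dielectric)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        Z = (X - self.x_mean) / self.x_scale
        H = np.maximum(Z @ self.w1 + self.b1, 0.0)
        y = H @ self.w2 + self.b2
        return y * self.y_scale + self.y_mean

    def predict(self, smiles: str, dielectric: float) -> float:
        return predict_wavelength(self, smiles, dielectric)

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "format": "malphot-spectral-model-v1",
            "config": dataclasses.asdict(self.config),
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
            "loss_curve": list(self.loss_curve),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TrainedSpectralModel":
        text = (
            Path(source).read_text()
            if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and source.endswith(".json"))
            else source
        )
        payload = json.loads(text)
        if payload.get("format") != "malphot-spectral-model-v1":
            raise ValueError("not a malphot spectral model file")
        return cls(
            w1=np.array(payload["w1"], dtype=np.float64),
            b1=np.array(payload["b1"], dtype=np.float64),
            w2=np.array(payload["w2"], dtype=np.float64),
            b2=float(payload["b2"]),
            x_mean=np.array(payload["x_mean"], dtype=np.float64),
            x_scale=np.array(payload["x_scale"], dtype=np.float64),
            y_mean=float(payload["y_mean"]),
            y_scale=float(payload["y_scale"]),
            config=ModelConfig(**payload["config"]),
            loss_curve=[float(v) for v in payload["loss_curve"]],
        )


@dataclass
class FitMetrics:
    """Train/test coefficients of determination and residual summaries (nm)."""

    r2_train: float
    r2_test: float
    mae_train: float
    mae_test: float
    residuals_train: np.ndarray
    residuals_test: np.ndarray
    per_class_mae: dict[SubstitutionClass, float]
    dataset_mean: float  # mean observed wavelength, for mean-relative reporting

    def to_dict(self) -> dict:
        return {
            "r2_train": self.r2_train,
            "r2_test": self.r2_test,
            "mae_train": self.mae_train,
            "mae_test": self.mae_test,
            "per_class_mae": {k.value: v for k, v in self.per_class_mae.items()},
            "dataset_mean": self.dataset_mean,
        }


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot.

    Zero-variance observations give 0 by convention.  Always <= 1.
    """
    obs = np.asarray(observed, dtype=np.float64)
    pred = np.asarray(predicted, dtype=np.float64)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("observed and predicted must be equal, nonzero length")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def split_dataset(
    records: list, train_fraction: float, seed: int
) -> tuple[list, list]:
    """Random disjoint, exhaustive train/test partition.

    Train size is ``floor(train_fraction * n)``; reproducible for a fixed
    seed.  Both partitions must be nonempty.
    """
    n = len(records)
    n_train = math.floor(train_fraction * n)
    if n_train < 1 or n - n_train < 1:
        raise ValueError(
            f"cannot split {n} records at fraction {train_fraction}: "
            "both partitions must be nonempty"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = [records[i] for i in perm[:n_train]]
    test = [records[i] for i in perm[n_train:]]
    return train, test


def _target_value(record: PhotophysicsRecord, target: str) -> float | None:
    return record.lambda_em if target == "emission" else record.lambda_abs


def build_design_matrix(
    records: list[PhotophysicsRecord], config: ModelConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (n, n_bits+1) and target vector (nm) for records."""
    fps = {}
    X = np.zeros((len(records), config.n_bits + 1), dtype=np.float64)
    y = np.zeros(len(records), dtype=np.float64)
    for i, rec in enumerate(records):
        if rec.smiles not in fps:
            fps[rec.smiles] = fingerprint_smiles(
                rec.smiles, radius=config.radius, n_bits=config.n_bits
            ).bits
        X[i, : config.n_bits] = fps[rec.smiles]
        X[i, config.n_bits] = rec.dielectric
        t = _target_value(rec, config.target)
        y[i] = np.nan if t is None else t
    return X, y


def train_model(
    records: list[PhotophysicsRecord], config: ModelConfig
) -> tuple[TrainedSpectralModel, FitMetrics]:
    """Fit the regressor on records carrying the configured target.

    Records missing the target wavelength are excluded before splitting.
    Returns the trained model and metrics on both partitions.
    """
    usable = [r for r in records if _target_value(r, config.target) is not None]
    if not usable:
        raise ValueError(f"no records carry a {config.target} wavelength")
    train, test = split_dataset(usable, config.train_fraction, config.seed)

    X_tr, y_tr = build_design_matrix(train, config)
    X_te, y_te = build_design_matrix(test, config)

    # input scaling: bits stay 0/1; the dielectric column is standardized
    # when requested so its scale does not dominate SGD updates
    x_mean = np.zeros(X_tr.shape[1])
    x_scale = np.ones(X_tr.shape[1])
    if config.eps_transform == "zscore":
        eps = X_tr[:, -1]
        x_mean[-1] = eps.mean()
        sd = eps.std()
        x_scale[-1] = sd if sd > 0 else 1.0
    y_mean = float(y_tr.mean()) if config.center_targets else 0.0
    y_sd = float(y_tr.std()) if config.center_targets else 1.0
    y_scale = y_sd if y_sd > 0 else 1.0

    Z_tr = (X_tr - x_mean) / x_scale
    t_tr = (y_tr - y_mean) / y_scale

    reg = MLPRegressor(
        hidden_layer_sizes=(config.hidden_units,),
        activation=config.activation,
        solver="sgd",
        learning_rate="constant",
        learning_rate_init=config.learning_rate,
        batch_size=min(config.batch_size, len(train)),
        alpha=config.l2_alpha,
        max_iter=config.max_iterations,
        random_state=config.seed,
        momentum=0.9,
        nesterovs_momentum=True,
        tol=1e-7,
        n_iter_no_change=50,
        early_stopping=config.validation_fraction > 0,
        validation_fraction=config.validation_fraction or 0.1,
        shuffle=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        reg.fit(Z_tr, t_tr)
    if not np.isfinite(reg.loss_):
        raise RuntimeError(
            f"training diverged (non-finite loss) at iteration {reg.n_iter_}"
        )

    model = TrainedSpectralModel(
        w1=np.asarray(reg.coefs_[0], dtype=np.float64),
        b1=np.asarray(reg.intercepts_[0], dtype=np.float64),
        w2=np.asarray(reg.coefs_[1], dtype=np.float64).ravel(),
        b2=float(np.ravel(reg.intercepts_[1])[0]),
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        config=config,
        loss_curve=[float(v) for v in reg.loss_curve_],
    )

    pred_tr = model.predict_features(X_tr)
    pred_te = model.predict_features(X_te)
    res_tr = pred_tr - y_tr
    res_te = pred_te - y_te
    per_class: dict[SubstitutionClass, list[float]] = {}
    for rec, r in zip(train + test, np.concatenate([res_tr, res_te])):
        per_class.setdefault(rec.substitution_class, []).append(abs(float(r)))
    metrics = FitMetrics(
        r2_train=r_squared(y_tr, pred_tr),
        r2_test=r_squared(y_te, pred_te),
        mae_train=float(np.abs(res_tr).mean()),
        mae_test=float(np.abs(res_te).mean()),
        residuals_train=res_tr,
        residuals_test=res_te,
        per_class_mae={k: float(np.mean(v)) for k, v in per_class.items()},
        dataset_mean=float(np.concatenate([y_tr, y_te]).mean()),
    )
    return model, metrics


def train_model_multiseed(
    records: list[PhotophysicsRecord],
    config: ModelConfig,
    n_seeds: int = 10,
) -> dict:
    """Median train/test R2 and MAE over ``n_seeds`` reseeded runs.

    Seeds are ``config.seed, config.seed + 1, ...``; each reseeds both the
    split and the weight initialization.  This is the reported headline
    because single SGD runs fluctuate.
    """
    r2_tr, r2_te, mae_te = [], [], []
    for k in range(n_seeds):
        cfg = dataclasses.replace(config, seed=config.seed + k)
        _, m = train_model(records, cfg)
        r2_tr.append(m.r2_train)
        r2_te.append(m.r2_test)
        mae_te.append(m.mae_test)
    return {
        "r2_train_median": float(np.median(r2_tr)),
        "r2_test_median": float(np.median(r2_te)),
        "mae_test_median": float(np.median(mae_te)),
        "r2_train_all": r2_tr,
        "r2_test_all": r2_te,
        "n_seeds": n_seeds,
    }


def predict_wavelength(
    model: TrainedSpectralModel, smiles: str, dielectric: float
) -> float:
    """Predicted wavelength (nm) for one molecule in one solvent."""
    if dielectric < 1.0:
        raise ValueError(f"dielectric {dielectric} < 1")
    cfg = model.config
    fp = fingerprint_smiles(smiles, radius=cfg.radius, n_bits=cfg.n_bits)
    x = np.empty(cfg.n_bits + 1, dtype=np.float64)
    x[: cfg.n_bits] = fp.bits
    x[cfg.n_bits] = dielectric
    return float(model.predict_features(x)[0])


@dataclass
class SweepResult:
    points: list[tuple[float, float]]  # (dielectric, predicted nm)
    delta_lambda: float  # lambda(eps_max) - lambda(eps_min)


def solvatochromic_sweep(
    model: TrainedSpectralModel, smiles: str, eps_grid
) -> SweepResult:
    """Predictions across an ascending dielectric grid, with the net shift."""
    grid = list(eps_grid)
    if not grid:
        raise ValueError("empty dielectric grid")
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("dielectric grid must be sorted ascending")
    lams = [predict_wavelength(model, smiles, e) for e in grid]
    return SweepResult(
        points=list(zip(grid, lams)), delta_lambda=lams[-1] - lams[0]
    )
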