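"""Random-forest regression of LAI from 5-band reflectance.

Features (the five band reflectances) and the target (LAI) are both
z-score standardised on the training block; predictions are produced by
averaging tree outputs in standardised space and de-standardising back to
m^2 m^-2.  The forest follows the study configuration: bootstrap sampling,
squared-error splitting, ``max_features = floor(log2(5)) = 2``, 200 trees
and ``min_samples_leaf = 1`` by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .bands import BAND_NAMES, N_BANDS
from .dataset import SyntheticDataset

__all__ = [
    "NormalizationStats",
    "RFRModel",
    "split_dataset",
    "train_rfr",
    "tune_hyperparameters",
    "predict_lai",
]

MAX_FEATURES = int(np.floor(np.log2(N_BANDS)))  # = 2

DEFAULT_TUNING_GRID = {
    "n_estimators": (5, 50, 100, 200, 300, 400, 500, 1000),
    "min_samples_leaf": (1, 5, 10, 15),
}


@dataclass(frozen=True)
class NormalizationStats:
    """Per-feature and target z-score statistics fitted on the training set."""

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float

    def __post_init__(self) -> None:
        if np.any(self.x_scale <= 0) or self.y_scale <= 0:
            raise ValueError("normalization scales must be > 0")

    def standardize_x(self, x: np.ndarray) -> np.ndarray:
        return (x - self.x_mean) / self.x_scale

    def standardize_y(self, y: np.ndarray) -> np.ndarray:
        return (y - self.y_mean) / self.y_scale

    def destandardize_y(self, z: np.ndarray) -> np.ndarray:
        return z * self.y_scale + self.y_mean


@dataclass
class RFRModel:
    """A trained forest plus its normalisation contract and provenance."""

    forest: RandomForestRegressor
    norm: NormalizationStats
    band_order: tuple[str, ...] = BAND_NAMES
    hyperparameters: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def predict(self, x) -> np.ndarray:
        return predict_lai(self, x)

    def save(self, path: str | Path) -> None:
        """Persist as a directory: serialized forest + JSON sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.forest, path / "forest.joblib")
        sidecar = {
            "band_order": list(self.band_order),
            "hyperparameters": self.hyperparameters,
            "provenance": self.provenance,
            "norm": {
                "x_mean": self.norm.x_mean.tolist(),
                "x_scale": self.norm.x_scale.tolist(),
                "y_mean": self.norm.y_mean,
                "y_scale": self.norm.y_scale,
            },
        }
        (path / "model.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RFRModel":
        path = Path(path)
        forest = joblib.load(path / "forest.joblib")
        sidecar = json.loads((path / "model.json").read_text())
        norm = NormalizationStats(
            x_mean=np.asarray(sidecar["norm"]["x_mean"], dtype=float),
            x_scale=np.asarray(sidecar["norm"]["x_scale"], dtype=float),
            y_mean=float(sidecar["norm"]["y_mean"]),
            y_scale=float(sidecar["norm"]["y_scale"]),
        )
        return cls(
            forest=forest,
            norm=norm,
            band_order=tuple(sidecar["band_order"]),
            hyperparameters=sidecar["hyperparameters"],
            provenance=sidecar["provenance"],
        )


def split_dataset(
    ds: SyntheticDataset, train_fraction: float = 0.75, seed: int = 0
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Disjoint random train/test split with sizes floor(n f) / n - floor(n f)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(ds)
    n_train = int(np.floor(n * train_fraction))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return ds.take(perm[:n_train]), ds.take(perm[n_train:])


def _fit_norm(x: np.ndarray, y: np.ndarray) -> NormalizationStats:
    x_scale = x.std(axis=0, ddof=0)
    y_scale = float(y.std(ddof=0))
    if np.any(x_scale <= 0) or y_scale <= 0:
        raise ValueError("training data has a constant feature or target")
    return NormalizationStats(
        x_mean=x.mean(axis=0), x_scale=x_scale, y_mean=float(y.mean()), y_scale=y_scale
    )


def train_rfr(
    train: SyntheticDataset,
    n_estimators: int = 200,
    min_samples_leaf: int = 1,
    seed: int = 0,
    bootstrap: bool = True,
    n_jobs: int = 1,
) -> RFRModel:
    """Standardise on the training block and fit the forest.

    Raises on an empty training set.  The split rule uses squared error with
    at most ``floor(log2(5)) = 2`` candidate features per split.
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    x = train.reflectance
    y = train.lai
    norm = _fit_norm(x, y)
    forest = RandomForestRegressor(
        n_estimators=n_estimators,
        min_samples_leaf=min_samples_leaf,
        max_features=MAX_FEATURES,
        criterion="squared_error",
        bootstrap=bootstrap,
        random_state=seed,
        n_jobs=n_jobs,
    )
    forest.fit(norm.standardize_x(x), norm.standardize_y(y))
    return RFRModel(
        forest=forest,
        norm=norm,
        hyperparameters={
            "n_estimators": n_estimators,
            "min_samples_leaf": min_samples_leaf,
            "max_features": MAX_FEATURES,
            "bootstrap": bootstrap,
        },
        provenance={
            "training_dataset": train.provenance.get("dataset"),
            "training_seed": int(seed),
            "n_train": len(train),
        },
    )


def tune_hyperparameters(
    train: SyntheticDataset,
    grid: dict | None = None,
    folds: int = 3,
    seed: int = 0,
    n_jobs: int = 1,
) -> tuple[int, int]:
    """K-fold cross-validated grid search over forest hyperparameters.

    Returns the ``(n_estimators, min_samples_leaf)`` pair with the lowest
    mean cross-validated MSE (on standardised targets); ties break towards
    the smaller ``n_estimators``, then the smaller ``min_samples_leaf``.
    """
    grid = grid or DEFAULT_TUNING_GRID
    combos = sorted(product(grid["n_estimators"], grid["min_samples_leaf"]))
    if not combos:
        raise ValueError("empty tuning grid")
    x = train.reflectance
    y = train.lai
    norm = _fit_norm(x, y)
    xs = norm.standardize_x(x)
    ys = norm.standardize_y(y)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(xs))

    best = None
    best_score = np.inf
    for n_est, leaf in combos:
        fold_mse = []
        for tr_idx, va_idx in splits:
            forest = RandomForestRegressor(
                n_estimators=n_est,
                min_samples_leaf=leaf,
                max_features=MAX_FEATURES,
                criterion="squared_error",
                bootstrap=True,
                random_state=seed,
                n_jobs=n_jobs,
            )
            forest.fit(xs[tr_idx], ys[tr_idx])
            err = forest.predict(xs[va_idx]) - ys[va_idx]
            fold_mse.append(float(np.mean(err ** 2)))
        score = float(np.mean(fold_mse))
        if score < best_score - 1e-15:
            best_score = score
            best = (n_est, leaf)
    return best


def predict_lai(model: RFRModel, x) -> np.ndarray | float:
    """Predict LAI (m^2 m^-2) from band reflectance in the model band order.

    ``x`` may be a single 5-vector or an ``(n, 5)`` batch.  No clipping is
    applied; forest means are naturally bounded by the training LAI range.
    """
    arr = np.asarray(x, dtype=float)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != len(model.band_order):
        raise ValueError(
            f"expected band vectors of length {len(model.band_order)}, got shape {np.shape(x)}"
        )
    z = model.forest.predict(model.norm.standardize_x(arr))
    y = model.norm.destandardize_y(z)
    return float(y[0]) if single else y
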