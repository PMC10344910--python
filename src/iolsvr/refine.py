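"""SVR refinement of SRK/T predicted refractions.

An epsilon-insensitive support vector regressor with an RBF kernel maps the
six features (SRK/T predicted refraction, AXL, CR, ACD, LT, WTW) to the
achieved postoperative MRSE.  Features are standardized on the training set
before the kernel; hyperparameters (C, gamma) are chosen by inner k-fold
grid search on the training set only, minimizing mean squared error.

Fitting goes through scikit-learn, but the trained model is stored as the
explicit kernel expansion (support vectors, dual coefficients, intercept),
so prediction is a plain RBF sum and persistence is exact JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from . import srkt
from .exceptions import InvalidConfigError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "RefinerConfig",
    "RefinerModel",
    "build_features",
    "train_refiner",
    "refine",
    "save_model",
    "load_model",
]

FEATURE_NAMES = ["srkt_pred", "axl", "cr", "acd", "lt", "wtw"]

_FEATURE_COLUMNS = {
    "srkt_pred": "srkt_pred_d",
    "axl": "axl_mm",
    "cr": "cr_mm",
    "acd": "acd_mm",
    "lt": "lt_mm",
    "wtw": "wtw_mm",
}

MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RefinerConfig:
    """Grid-search configuration for the refiner.

    The default grids span the informative regimes for cohorts of tens to
    thousands of eyes; ``fast()`` returns a reduced configuration suitable
    for repeated large-cohort cross-validation, and ``fixed(c, gamma)`` pins
    the hyperparameters (singleton grids skip the inner search entirely).
    ``target`` selects whether the regressor predicts the MRSE directly or
    the SRK/T residual (mrse − srkt_pred); the refined refraction is the
    same quantity either way.
    """

    c_grid: tuple = (0.1, 1.0, 10.0, 100.0, 1000.0)
    gamma_grid: tuple = (0.001, 0.01, 0.1, 1.0)
    epsilon: float = 0.1
    inner_folds: int = 5
    seed: int = 0
    target: str = "mrse"

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise InvalidConfigError("hyperparameter grids must be non-empty")
        if self.epsilon < 0:
            raise InvalidConfigError("epsilon must be >= 0")
        if self.inner_folds < 2:
            raise InvalidConfigError("inner_folds must be >= 2")
        if self.target not in ("mrse", "residual"):
            raise InvalidConfigError("target must be 'mrse' or 'residual'")

    @classmethod
    def fast(cls, seed: int = 0, target: str = "mrse") -> "RefinerConfig":
        return cls(
            c_grid=(1.0, 10.0),
            gamma_grid=(0.01, 0.1),
            inner_folds=3,
            seed=seed,
            target=target,
        )

    @classmethod
    def fixed(
        cls, c: float = 10.0, gamma: float = 0.1, seed: int = 0,
        target: str = "mrse",
    ) -> "RefinerConfig":
        return cls(
            c_grid=(c,), gamma_grid=(gamma,), inner_folds=2, seed=seed,
            target=target,
        )


@dataclass
class RefinerModel:
    """A trained refiner: scaler, hyperparameters, kernel expansion."""

    feature_names: list
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    chosen_c: float
    chosen_gamma: float
    epsilon: float
    support_vectors: np.ndarray  # standardized
    dual_coef: np.ndarray
    intercept: float
    target: str
    provenance: dict = field(default_factory=dict)

    def predict_standardized(self, xs: np.ndarray) -> np.ndarray:
        d2 = (
            np.sum(xs**2, axis=1)[:, None]
            + np.sum(self.support_vectors**2, axis=1)[None, :]
            - 2.0 * xs @ self.support_vectors.T
        )
        k = np.exp(-self.chosen_gamma * np.maximum(d2, 0.0))
        return k @ self.dual_coef + self.intercept


def build_features(
    records: pd.DataFrame, srkt_preds: Optional[Sequence[float]] = None
):
    """Assemble the n x 6 feature matrix (fixed order) and the MRSE target.

    ``records`` is a cohort table; the SRK/T prediction is taken from
    ``srkt_preds`` if given, else from a ``srkt_pred_d`` column, else
    computed from the biometry.
    """
    df = records
    if srkt_preds is not None:
        if len(srkt_preds) != len(df):
            raise InvalidInputError("srkt_preds length mismatch")
        pred = np.asarray(srkt_preds, dtype=float)
    elif "srkt_pred_d" in df.columns:
        pred = df["srkt_pred_d"].to_numpy(dtype=float)
    else:
        pred = srkt.predicted_refraction(
            df["axl_mm"].to_numpy(),
            df["cr_mm"].to_numpy(),
            df["a_constant"].to_numpy(),
            df["iol_power_d"].to_numpy(),
        )
    cols = [pred] + [
        df[_FEATURE_COLUMNS[name]].to_numpy(dtype=float)
        for name in FEATURE_NAMES[1:]
    ]
    X = np.column_stack(cols)
    bad = ~np.all(np.isfinite(X), axis=1)
    if np.any(bad):
        ids = df.loc[bad, "eye_id"].tolist() if "eye_id" in df.columns else \
            list(np.flatnonzero(bad))
        raise InvalidInputError(f"missing/non-finite biometry for eyes: {ids}")
    y = df["mrse_d"].to_numpy(dtype=float) if "mrse_d" in df.columns else None
    return X, y


def _standardize_fit(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    degenerate = scale <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if np.any(degenerate):
        logger.warning(
            "zero-variance feature(s) %s; scale fixed to 1",
            [FEATURE_NAMES[i] for i in np.flatnonzero(degenerate)],
        )
        scale = np.where(degenerate, 1.0, scale)
    return mean, scale


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def train_refiner(
    records: pd.DataFrame, config: RefinerConfig = RefinerConfig()
) -> RefinerModel:
    """Standardize, grid-search (C, gamma) by inner k-fold MSE, refit on all
    training rows.  Deterministic for a given seed and data."""
    X, y = build_features(records)
    if y is None or np.any(~np.isfinite(y)):
        raise InvalidInputError("training records need finite mrse_d targets")
    n = len(X)
    if n < 12:
        raise InvalidInputError(f"need at least 12 training eyes, got {n}")

    if config.target == "residual":
        y_fit = y - X[:, 0]
    else:
        y_fit = y

    mean, scale = _standardize_fit(X)
    Xs = (X - mean) / scale

    grid = [(c, g) for c in config.c_grid for g in config.gamma_grid]
    if len(grid) == 1:
        chosen_c, chosen_gamma = grid[0]
        cv_mse = {}
    else:
        kf = KFold(
            n_splits=config.inner_folds, shuffle=True, random_state=config.seed
        )
        splits = list(kf.split(Xs))
        cv_mse = {}
        for c, g in grid:
            errs = []
            for tr, va in splits:
                m = SVR(kernel="rbf", C=c, gamma=g, epsilon=config.epsilon,
                        cache_size=500)
                m.fit(Xs[tr], y_fit[tr])
                resid = m.predict(Xs[va]) - y_fit[va]
                errs.append(float(np.mean(resid**2)))
            cv_mse[(c, g)] = float(np.mean(errs))
        # deterministic tie-break: grid order (C ascending, gamma ascending)
        chosen_c, chosen_gamma = min(grid, key=lambda cg: (cv_mse[cg], grid.index(cg)))

    final = SVR(
        kernel="rbf", C=chosen_c, gamma=chosen_gamma, epsilon=config.epsilon,
        cache_size=500,
    )
    final.fit(Xs, y_fit)

    return RefinerModel(
        feature_names=list(FEATURE_NAMES),
        scaler_mean=mean,
        scaler_scale=scale,
        chosen_c=float(chosen_c),
        chosen_gamma=float(chosen_gamma),
        epsilon=float(config.epsilon),
        support_vectors=final.support_vectors_.copy(),
        dual_coef=final.dual_coef_.ravel().copy(),
        intercept=float(final.intercept_[0]),
        target=config.target,
        provenance={
            "seed": config.seed,
            "c_grid": list(config.c_grid),
            "gamma_grid": list(config.gamma_grid),
            "inner_folds": config.inner_folds,
            "n_train": n,
            "fingerprint": _fingerprint(X, y),
            "cv_mse": {f"{c}:{g}": v for (c, g), v in cv_mse.items()},
        },
    )


def refine(model: RefinerModel, records: pd.DataFrame) -> np.ndarray:
    """Refined predicted refraction (D) per record; never mutates the model."""
    if len(records) == 0:
        return np.zeros(0)
    X, _ = build_features(records)
    xs = (X - model.scaler_mean) / model.scaler_scale
    out_of_range = np.abs(xs) > 10.0
    if np.any(out_of_range):
        logger.warning(
            "%d record(s) have features beyond 10 training SDs; "
            "predictions are extrapolations",
            int(np.count_nonzero(np.any(out_of_range, axis=1))),
        )
    pred = model.predict_standardized(xs)
    if model.target == "residual":
        pred = pred + X[:, 0]
    return pred


def save_model(model: RefinerModel, path) -> None:
    """Persist a refiner to a self-describing JSON file (exact doubles)."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "feature_names": model.feature_names,
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_scale": model.scaler_scale.tolist(),
        "chosen_c": model.chosen_c,
        "chosen_gamma": model.chosen_gamma,
        "epsilon": model.epsilon,
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "intercept": model.intercept,
        "target": model.target,
        "provenance": model.provenance,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path) -> RefinerModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise InvalidConfigError(
            f"unsupported model schema {payload.get('schema_version')}"
        )
    return RefinerModel(
        feature_names=payload["feature_names"],
        scaler_mean=np.array(payload["scaler_mean"]),
        scaler_scale=np.array(payload["scaler_scale"]),
        chosen_c=payload["chosen_c"],
        chosen_gamma=payload["chosen_gamma"],
        epsilon=payload["epsilon"],
        support_vectors=np.array(payload["support_vectors"]),
        dual_coef=np.array(payload["dual_coef"]),
        intercept=payload["intercept"],
        target=payload["target"],
        provenance=payload.get("provenance", {}),
    )
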