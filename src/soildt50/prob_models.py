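"""Probabilistic regressors from molecular features to Gaussian predictive
distributions over log10 half-life.

Two backends:

* Gaussian-process regression with a per-sample heteroscedastic noise
  term ``alpha_i = mu_std_i**2`` added to the kernel diagonal, so targets
  with uncertain Bayesian means are down-weighted during fitting. A white
  noise term is fitted ON TOP of the fixed alphas and acts as a noise
  floor in the predictive variance.
* A random-forest baseline whose predictive SD is the spread of the
  per-tree predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    ConstantKernel,
    Matern,
    WhiteKernel,
)

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

KERNEL_KINDS = ("rbf", "matern15", "matern25")


@dataclass(frozen=True)
class KernelSpec:
    """Configuration of the GP covariance function.

    The kernel is ``constant * base(length_scale) + white``, with *base*
    one of RBF / Matern(1.5) / Matern(2.5) (isotropic). Set
    ``optimize=False`` to freeze hyperparameters at their initial values,
    e.g. for oracle comparisons.
    """

    kind: str = "matern25"
    length_scale: float = 1.0
    constant: float = 1.0
    noise: float = 1e-5
    optimize: bool = True
    n_restarts: int = 5

    def __post_init__(self):
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"kernel kind must be one of {KERNEL_KINDS}")

    def build(self):
        bounds = (1e-3, 1e4) if self.optimize else "fixed"
        noise_bounds = (1e-8, 1e2) if self.optimize else "fixed"
        if self.kind == "rbf":
            base = RBF(length_scale=self.length_scale, length_scale_bounds=bounds)
        else:
            nu = 1.5 if self.kind == "matern15" else 2.5
            base = Matern(length_scale=self.length_scale, nu=nu, length_scale_bounds=bounds)
        return (
            ConstantKernel(self.constant, constant_value_bounds=bounds) * base
            + WhiteKernel(self.noise, noise_level_bounds=noise_bounds)
        )


@dataclass
class TrainingSet:
    """Aligned features, targets, and per-compound target noise.

    ``noise`` carries alpha_i = mu_std_i**2 (variance of the Bayesian
    mean-half-life estimate) per training compound.
    """

    X: FeatureMatrix
    y: np.ndarray
    noise: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.noise = np.asarray(self.noise, dtype=float)
        n = self.X.shape[0]
        if self.y.shape != (n,) or self.noise.shape != (n,):
            raise ValueError("X, y and noise must be row-aligned")
        if (self.noise <= 0).any():
            raise ValueError("all noise entries (alpha) must be > 0")


@dataclass(frozen=True)
class PredictiveDistribution:
    """Gaussian predictive distribution over log10 half-life (days)."""

    pred_mean: float
    pred_std: float

    def __post_init__(self):
        if not (self.pred_std > 0):
            raise ValueError("pred_std must be > 0")


@dataclass
class GPModelState:
    """A fitted GP: the sklearn regressor plus the target-centering shift."""

    gp: GaussianProcessRegressor
    y_center: float
    kernel_spec: KernelSpec
    feature_names: list[str]

    @property
    def fitted_kernel(self):
        return self.gp.kernel_


def fit_gpr(train: TrainingSet, kernel_spec: Optional[KernelSpec] = None,
            seed: int = 0) -> GPModelState:
    """Fit a GP regressor with heteroscedastic per-sample noise.

    Targets are centered by their training mean before fitting (and
    un-centered on prediction), keeping predictive SDs in log10-day units.
    Kernel hyperparameters maximize the log marginal likelihood with
    ``kernel_spec.n_restarts`` restarts seeded from *seed*.
    """
    if train.X.shape[0] < 1:
        raise ValueError("need at least one training row")
    spec = kernel_spec or KernelSpec()
    y_center = float(train.y.mean())
    gp = GaussianProcessRegressor(
        kernel=spec.build(),
        alpha=train.noise,
        optimizer="fmin_l_bfgs_b" if spec.optimize else None,
        n_restarts_optimizer=spec.n_restarts if spec.optimize else 0,
        normalize_y=False,
        random_state=seed,
    )
    gp.fit(train.X.values, train.y - y_center)
    if spec.optimize:
        logger.info(
            "GPR fitted: kernel=%s restarts=%d seed=%d lml=%.3f",
            gp.kernel_, spec.n_restarts, seed,
            gp.log_marginal_likelihood_value_,
        )
    return GPModelState(
        gp=gp,
        y_center=y_center,
        kernel_spec=spec,
        feature_names=list(train.X.feature_names),
    )


def predict_gpr(model: GPModelState, X_query: np.ndarray | FeatureMatrix
                ) -> list[PredictiveDistribution]:
    """Predictive mean and SD per query row.

    The predictive variance is the usual GP conditional
    ``k(x,x) - k*^T (K + diag(alpha))^{-1} k*``; because the white-noise
    term is part of the kernel it also appears in ``k(x,x)`` and acts as
    a fitted noise floor.
    """
    values = X_query.values if isinstance(X_query, FeatureMatrix) else np.asarray(X_query)
    if values.ndim != 2 or values.shape[1] != len(model.feature_names):
        raise ValueError(
            f"query has {values.shape[-1] if values.ndim == 2 else 'bad'} features, "
            f"model expects {len(model.feature_names)}"
        )
    mean, std = model.gp.predict(values, return_std=True)
    std = np.maximum(std, 1e-10)  # jitter floor keeps pred_std > 0
    return [
        PredictiveDistribution(pred_mean=float(m) + model.y_center, pred_std=float(s))
        for m, s in zip(mean, std)
    ]


@dataclass
class RFModelState:
    """A fitted random forest plus the SD floor for degenerate spreads."""

    forest: RandomForestRegressor
    std_floor: float
    feature_names: list[str]


def fit_rf(train: TrainingSet, n_trees: int = 500, seed: int = 0,
           std_floor: float = 1e-3) -> RFModelState:
    """Fit the random-forest baseline (bootstrap, unlimited depth)."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    forest = RandomForestRegressor(
        n_estimators=n_trees, bootstrap=True, random_state=seed, n_jobs=1
    )
    forest.fit(train.X.values, train.y)
    return RFModelState(
        forest=forest, std_floor=std_floor,
        feature_names=list(train.X.feature_names),
    )


def predict_rf(state: RFModelState, X_query: np.ndarray | FeatureMatrix
               ) -> list[PredictiveDistribution]:
    """Ensemble mean and population SD across trees, floored at
    ``std_floor`` so the pred_std > 0 invariant holds."""
    values = X_query.values if isinstance(X_query, FeatureMatrix) else np.asarray(X_query)
    per_tree = np.stack([t.predict(values) for t in state.forest.estimators_])
    mean = per_tree.mean(axis=0)
    std = np.maximum(per_tree.std(axis=0, ddof=0), state.std_floor)
    return [
        PredictiveDistribution(pred_mean=float(m), pred_std=float(s))
        for m, s in zip(mean, std)
    ]


class SchemaVersionError(RuntimeError):
    """Raised when a model archive was written by an incompatible version."""


def save_model_archive(
    path: str | Path,
    model: GPModelState | RFModelState,
    scaler_state: np.ndarray,
    selected_features: Sequence[str],
    all_feature_names: Sequence[str],
    feature_spec_names: Sequence[str],
    extra: Optional[dict] = None,
) -> None:
    """Persist everything needed to score new SMILES: feature-set choice,
    fitted scaler, selected feature list, and the fitted model."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "model": model,
        "scaler_state": np.asarray(scaler_state),
        "selected_features": list(selected_features),
        "all_feature_names": list(all_feature_names),
        "feature_spec_names": list(feature_spec_names),
        "extra": extra or {},
    }
    joblib.dump(payload, path)


def load_model_archive(path: str | Path) -> dict:
    payload = joblib.load(path)
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"archive schema version {version} != supported {SCHEMA_VERSION}"
        )
    return payload
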