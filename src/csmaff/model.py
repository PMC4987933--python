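"""Gaussian-process regression from structural signatures to pAffinity.

The regressor maps the concatenated cutoff-scan + descriptor vector to
-log10(Kd|Ki).  Features are standardized on the training data; the GP
kernel defaults to RBF plus a white-noise term with hyperparameters set
by marginal-likelihood maximization.  A trained model is persisted
together with its feature schema, scaling parameters and signature
configuration so that prediction-time features can be validated against
training-time layout.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import datetime, timezone

import joblib
import numpy as np
import sklearn
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, Matern, WhiteKernel
from sklearn.preprocessing import StandardScaler

from . import __version__ as _pkg_version
from .dataset import make_folds
from .evaluation import EvaluationReport, evaluate
from .pharmacophore import TYPING_TABLE_VERSION
from .signatures import SignatureVector

__all__ = [
    "GPConfig",
    "GaussianProcessAffinityRegressor",
    "TrainedModel",
    "train",
    "predict",
    "save_model",
    "load_model",
    "cross_validate",
]

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class GPConfig:
    """Hyperparameter initializations and options for the GP."""

    kernel: str = "rbf_plus_white"  # rbf | rbf_plus_white | matern52
    length_scale_init: float | None = None  # None: sqrt(n_features) at fit
    noise_init: float = 0.1
    normalize_target: bool = False
    feature_standardize: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.length_scale_init is not None and self.length_scale_init <= 0:
            raise ValueError("hyperparameter initializations must be positive")
        if self.noise_init <= 0:
            raise ValueError("hyperparameter initializations must be positive")
        if self.kernel not in ("rbf", "rbf_plus_white", "matern52"):
            raise ValueError(f"unknown kernel: {self.kernel}")


class GaussianProcessAffinityRegressor(RegressorMixin, BaseEstimator):
    """sklearn estimator: standardize features, fit an exact GP.

    Parameters
    ----------
    kernel : {"rbf", "rbf_plus_white", "matern52"}
        "rbf" is noise-free interpolation; the default adds a learned
        white-noise term; "matern52" is a rougher alternative, also with
        white noise.
    length_scale_init, noise_init : float
        Initializations for marginal-likelihood optimization.
    normalize_target : bool
        Standardize y inside the GP (pK labels are already well scaled,
        so off by default).
    feature_standardize : bool
        Zero-mean/unit-variance feature scaling fit on the training data.
    random_state : int
        Seeds the GP optimizer; fits are deterministic given data + seed.
    """

    def __init__(
        self,
        kernel: str = "rbf_plus_white",
        length_scale_init: float | None = None,
        noise_init: float = 0.1,
        normalize_target: bool = False,
        feature_standardize: bool = True,
        random_state: int = 0,
    ):
        self.kernel = kernel
        self.length_scale_init = length_scale_init
        self.noise_init = noise_init
        self.normalize_target = normalize_target
        self.feature_standardize = feature_standardize
        self.random_state = random_state

    def _make_kernel(self, n_features: int):
        ls = self.length_scale_init
        if ls is None:
            # median-distance heuristic for standardized features
            ls = float(np.sqrt(n_features))
        base = ConstantKernel(1.0, (1e-3, 1e4))
        if self.kernel == "matern52":
            k = base * Matern(
                length_scale=ls,
                length_scale_bounds=(1e-2, 1e6),
                nu=2.5,
            )
        else:
            k = base * RBF(length_scale=ls, length_scale_bounds=(1e-2, 1e6))
        if self.kernel in ("rbf_plus_white", "matern52"):
            k = k + WhiteKernel(
                noise_level=self.noise_init**2, noise_level_bounds=(1e-12, 1e2)
            )
        return k

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        if len(y) < 5:
            raise ValueError("need at least 5 training complexes")
        if np.ptp(y) == 0:
            raise ValueError("degenerate constant training target")
        if self.feature_standardize:
            self.scaler_ = StandardScaler().fit(X)
            Xs = self.scaler_.transform(X)
        else:
            self.scaler_ = None
            Xs = X
        self.gp_ = GaussianProcessRegressor(
            kernel=self._make_kernel(X.shape[1]),
            alpha=1e-10,
            normalize_y=self.normalize_target,
            n_restarts_optimizer=0,
            random_state=self.random_state,
        )
        self.gp_.fit(Xs, y)
        self.n_features_in_ = X.shape[1]
        return self

    def _transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature count mismatch: {X.shape[1]} vs {self.n_features_in_}"
            )
        return self.scaler_.transform(X) if self.scaler_ is not None else X

    def predict(self, X, return_std: bool = False):
        return self.gp_.predict(self._transform(X), return_std=return_std)


@dataclass
class TrainedModel:
    """A fitted regressor bound to its feature schema and provenance."""

    regressor: GaussianProcessAffinityRegressor
    schema: tuple[str, ...]
    config_hash: str
    gp_config: GPConfig
    metadata: dict = field(default_factory=dict)

    def schema_hash(self) -> str:
        return hashlib.sha256("\n".join(self.schema).encode()).hexdigest()[:16]


def _stack(X: list[SignatureVector]) -> tuple[np.ndarray, tuple[str, ...], str]:
    if not X:
        raise ValueError("empty training set")
    schema = X[0].schema
    chash = X[0].config_hash
    for s in X[1:]:
        if s.schema != schema or s.config_hash != chash:
            raise ValueError("signature schema mismatch among training vectors")
    return np.vstack([s.values for s in X]), schema, chash


def train(
    X: list[SignatureVector], y, cfg: GPConfig | None = None
) -> TrainedModel:
    """Fit the GP on signature vectors with uniform schema."""
    cfg = cfg or GPConfig()
    mat, schema, chash = _stack(X)
    y = np.asarray(y, dtype=np.float64)
    if len(y) != len(mat):
        raise ValueError("label count does not match signature count")
    reg = GaussianProcessAffinityRegressor(
        kernel=cfg.kernel,
        length_scale_init=cfg.length_scale_init,
        noise_init=cfg.noise_init,
        normalize_target=cfg.normalize_target,
        feature_standardize=cfg.feature_standardize,
        random_state=cfg.seed,
    ).fit(mat, y)
    metadata = {
        "n_train": len(y),
        "created": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "package_version": _pkg_version,
        "sklearn_version": sklearn.__version__,
        "numpy_version": np.__version__,
        "typing_table_version": TYPING_TABLE_VERSION,
    }
    return TrainedModel(
        regressor=reg,
        schema=schema,
        config_hash=chash,
        gp_config=cfg,
        metadata=metadata,
    )


def predict(model: TrainedModel, x: SignatureVector) -> tuple[float, float]:
    """Posterior mean (-log10 Kd|Ki) and predictive SD for one complex."""
    if x.config_hash != model.config_hash or x.schema != model.schema:
        diffs = [
            i
            for i, (a, b) in enumerate(zip(x.schema, model.schema))
            if a != b
        ][:5]
        raise ValueError(
            "signature schema does not match the trained model "
            f"(first differing positions: {diffs}, lengths {len(x.schema)} vs "
            f"{len(model.schema)})"
        )
    mean, std = model.regressor.predict(x.values[None, :], return_std=True)
    return float(mean[0]), float(std[0])


def save_model(model: TrainedModel, path) -> None:
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "schema_hash": model.schema_hash(),
        "model": model,
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedModel:
    """Load a persisted model, refusing on any provenance mismatch."""
    payload = joblib.load(path)
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {payload.get('format_version')} != "
            f"{_MODEL_FORMAT_VERSION}"
        )
    model: TrainedModel = payload["model"]
    if payload.get("schema_hash") != model.schema_hash():
        raise ValueError("schema hash mismatch: model file appears altered")
    saved_ttv = model.metadata.get("typing_table_version")
    if saved_ttv != TYPING_TABLE_VERSION:
        raise ValueError(
            f"typing table version mismatch: model was trained with "
            f"{saved_ttv!r}, package provides {TYPING_TABLE_VERSION!r}"
        )
    return model


def cross_validate(
    X: list[SignatureVector],
    y,
    k: int = 10,
    cfg: GPConfig | None = None,
    seed: int = 0,
    ids: list[str] | None = None,
) -> tuple[EvaluationReport, np.ndarray]:
    """k-fold CV: out-of-fold predictions assembled over all folds.

    Returns the evaluation report on the pooled out-of-fold predictions
    and the out-of-fold prediction vector aligned with ``y``.
    """
    cfg = cfg or GPConfig(seed=seed)
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if ids is None:
        ids = [str(i) for i in range(n)]
    fold_ids = make_folds(ids, k, seed)
    pos = {i: p for p, i in enumerate(ids)}
    oof = np.full(n, np.nan)
    for fold in fold_ids:
        test_idx = np.array([pos[i] for i in fold])
        if len(test_idx) == 0 or n - len(test_idx) < 5:
            raise ValueError(
                "fold leaves too few training complexes (need >= 5 per fit)"
            )
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        model = train([X[i] for i in np.flatnonzero(mask)], y[mask], cfg)
        mat = np.vstack([X[i].values for i in test_idx])
        oof[test_idx] = model.regressor.predict(mat)
    assert not np.isnan(oof).any()  # folds partition the training set
    if np.ptp(oof) == 0:
        # a no-skill GP can collapse to a constant prediction (e.g. on
        # permuted labels); report zero association rather than refusing
        report = EvaluationReport(
            n=n,
            pearson_r=0.0,
            spearman_rho=0.0,
            residual_sd=float(np.std(y, ddof=1)),
        )
        return report, oof
    return evaluate(y, oof), oof
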