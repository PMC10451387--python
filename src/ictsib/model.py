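"""Stability-index regression: training tables, Bayesian hyperparameter
optimization, and the four per-condition model families.

The SI estimation pipeline mirrors common practice for small clinical
cohorts: features are standardized on training statistics; hyperparameters
of each model family (L2-regularized linear regression, RBF support-vector
regression, penalized-spline GAM, regression tree) are chosen by Bayesian
optimization - a Gaussian-process surrogate with the probability-of-
improvement acquisition, 30 optimization iterations after a 10-point Latin
hypercube initial design - minimizing 5-fold cross-validated RMSE; the
selected model is refitted on the full training split. Linear models expose
their coefficients folded back to the raw feature scale so the fitted
formula ``SI = bias + sum_i beta_i * feature_i`` is directly usable outside
the package.

Train/test splitting is by *subject* (all conditions of a subject fall on
the same side) to avoid leakage between a subject's conditions.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.stats import qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .errors import (
    ConfigurationError,
    DomainError,
    InsufficientDataError,
    UndefinedCorrelationError,
)
from .types import FEATURE_NAMES, Condition, SwayFeatures

MODEL_TYPES = ("linear", "svm", "gam", "tree")
EXPORT_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# training data


@dataclass(frozen=True)
class TrainingRow:
    subject_id: str
    condition: Condition
    features: SwayFeatures
    si_reference: float


@dataclass
class TrainingTable:
    """Per-(subject, condition) sway features with reference SI values."""

    rows: list[TrainingRow]
    source: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for row in self.rows:
            key = (row.subject_id, row.condition)
            if key in seen:
                raise ValueError(f"duplicated (subject, condition) pair: {key}")
            seen.add(key)
            if not (row.si_reference >= 0):
                raise ValueError(f"si_reference must be >= 0, got {row.si_reference} for {key}")
            if not row.features.is_complete():
                raise ValueError(f"missing feature values in training row {key}")

    def subjects(self) -> list[str]:
        out: list[str] = []
        for row in self.rows:
            if row.subject_id not in out:
                out.append(row.subject_id)
        return out

    def for_condition(self, condition: Condition) -> "TrainingTable":
        return TrainingTable(
            [r for r in self.rows if r.condition == condition], source=self.source
        )

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        X = np.vstack([r.features.to_array() for r in self.rows])
        y = np.array([r.si_reference for r in self.rows])
        return X, y

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        records = [
            {
                "subject_id": r.subject_id,
                "condition": r.condition.value,
                **r.features.to_dict(),
                "si_reference": r.si_reference,
            }
            for r in self.rows
        ]
        cols = ["subject_id", "condition", *FEATURE_NAMES, "si_reference"]
        pd.DataFrame.from_records(records, columns=cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, source: str = "") -> "TrainingTable":
        import pandas as pd

        df = pd.read_csv(path)
        rows = [
            TrainingRow(
                str(row["subject_id"]),
                Condition(row["condition"]),
                SwayFeatures.from_dict({n: row[n] for n in FEATURE_NAMES}),
                float(row["si_reference"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(rows, source=source or str(path))


def split_dataset(
    table: TrainingTable, train_fraction: float = 0.7, seed: int = 0
) -> tuple[TrainingTable, TrainingTable]:
    """Split by subject into train/test; train size = floor(fraction * n_subjects)."""
    if not (0 < train_fraction < 1):
        raise DomainError(f"train_fraction must be in (0, 1), got {train_fraction}")
    subjects = sorted(table.subjects())
    if len(subjects) < 2:
        raise InsufficientDataError("splitting needs at least 2 distinct subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    n_train = math.floor(train_fraction * len(subjects))
    train_set = {subjects[i] for i in order[:n_train]}
    train_rows = [r for r in table.rows if r.subject_id in train_set]
    test_rows = [r for r in table.rows if r.subject_id not in train_set]
    return (
        TrainingTable(train_rows, source=table.source),
        TrainingTable(test_rows, source=table.source),
    )


# ---------------------------------------------------------------------------
# Bayesian optimization (GP surrogate + probability of improvement)


@dataclass(frozen=True)
class Param:
    """One hyperparameter dimension of a search space."""

    name: str
    kind: str  # "uniform" | "log_uniform" | "integer"
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "log_uniform", "integer"):
            raise DomainError(f"unknown parameter kind {self.kind!r}")
        if self.high < self.low or (self.kind == "log_uniform" and self.low <= 0):
            raise DomainError(f"invalid range for {self.name}: [{self.low}, {self.high}]")

    def from_unit(self, u: float) -> float | int:
        if self.kind == "log_uniform":
            return float(np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low))))
        value = self.low + u * (self.high - self.low)
        return int(round(value)) if self.kind == "integer" else float(value)


SearchSpace = tuple[Param, ...]


@dataclass(frozen=True)
class BOConfig:
    """Bayesian-optimization settings: 30 POI iterations after a 10-point
    Latin-hypercube initial design, by default."""

    n_iterations: int = 30
    acquisition: str = "POI"
    n_initial: int = 10
    xi: float = 0.01  # POI improvement margin, as a fraction of the loss range
    n_candidates: int = 512
    seed: int = 0
    search_space: dict[str, SearchSpace] | None = None  # per-model override

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise DomainError("n_iterations must be >= 1")
        if self.acquisition != "POI":
            raise DomainError(f"unsupported acquisition {self.acquisition!r}")


@dataclass
class BOResult:
    best_params: dict[str, float | int]
    best_loss: float
    trace: list[tuple[dict[str, float | int], float]]


def _to_params(space: SearchSpace, u: np.ndarray) -> dict[str, float | int]:
    return {p.name: p.from_unit(float(ui)) for p, ui in zip(space, u)}


def bayesian_optimize(objective, space: SearchSpace, config: BOConfig | None = None) -> BOResult:
    """Minimize ``objective(params)`` over a bounded search space.

    A Gaussian-process surrogate (Matern 5/2 + white noise) is fitted to the
    evaluated points in the unit cube; each iteration evaluates the random
    candidate maximizing the probability of improving on the incumbent best
    by a small margin. Already-evaluated points are never re-evaluated, so a
    degenerate (single-point) space costs exactly one evaluation. The result
    is the argmin over all evaluations and is reproducible given the seed.
    """
    config = config or BOConfig()
    rng = np.random.default_rng(config.seed)
    d = len(space)
    if d == 0:
        raise DomainError("search space is empty")

    evaluated: dict[tuple, float] = {}
    trace: list[tuple[dict, float]] = []
    U: list[np.ndarray] = []
    losses: list[float] = []

    def key_of(u: np.ndarray) -> tuple:
        # integers collapse to their rounded value; floats to 12 significant digits
        return tuple(
            p.from_unit(float(ui)) if p.kind == "integer" else round(float(ui), 12)
            for p, ui in zip(space, u)
        )

    def evaluate(u: np.ndarray) -> None:
        k = key_of(u)
        if k in evaluated:
            return
        params = _to_params(space, u)
        loss = float(objective(params))
        evaluated[k] = loss
        U.append(u)
        losses.append(loss)
        trace.append((params, loss))

    degenerate = all(p.low == p.high for p in space)
    if degenerate:
        evaluate(np.zeros(d))
    else:
        sampler = qmc.LatinHypercube(d=d, seed=rng)
        for u in sampler.random(config.n_initial):
            evaluate(np.asarray(u))
        for _ in range(config.n_iterations):
            X = np.vstack(U)
            y = np.asarray(losses)
            y_span = float(y.max() - y.min()) or 1.0
            kernel = ConstantKernel(1.0) * Matern(
                length_scale=np.full(d, 0.3), nu=2.5, length_scale_bounds=(1e-2, 1e2)
            ) + WhiteKernel(1e-6, noise_level_bounds=(1e-10, 1e-1))
            gp = GaussianProcessRegressor(
                kernel=kernel,
                normalize_y=True,
                n_restarts_optimizer=1,
                random_state=int(rng.integers(2**31)),
            )
            cand = rng.random((config.n_candidates, d))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gp.fit(X, y)
                    mu, sd = gp.predict(cand, return_std=True)
                sd = np.maximum(sd, 1e-12)
                threshold = y.min() - config.xi * y_span
                poi = stats.norm.cdf((threshold - mu) / sd)
                order = np.argsort(-poi)
            except Exception:  # GP failure: fall back to random exploration
                order = rng.permutation(config.n_candidates)
            for idx in order:
                if key_of(cand[idx]) not in evaluated:
                    evaluate(cand[idx])
                    break

    best = int(np.argmin(losses))
    return BOResult(_to_params(space, U[best]), losses[best], trace)


# ---------------------------------------------------------------------------
# model families

DEFAULT_SEARCH_SPACES: dict[str, SearchSpace] = {
    "linear": (Param("alpha", "log_uniform", 1e-6, 1e3),),
    "svm": (
        Param("C", "log_uniform", 1e-2, 1e3),
        Param("gamma", "log_uniform", 1e-4, 1e1),
        Param("epsilon", "uniform", 0.01, 1.0),
    ),
    "gam": tuple(
        Param(f"alpha_{i}", "log_uniform", 1e-3, 1e4) for i in range(len(FEATURE_NAMES))
    )
    + (Param("n_splines", "integer", 5, 20),),
    "tree": (
        Param("max_depth", "integer", 2, 12),
        Param("min_samples_leaf", "integer", 2, 20),
    ),
}


class _GamRegressor:
    """Penalized B-spline additive model (statsmodels GLMGam backend).

    Constant feature columns carry no spline information and are dropped
    from the smoother.
    """

    def __init__(self, alphas: list[float], n_splines: int):
        self.alphas = alphas
        self.n_splines = int(n_splines)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_GamRegressor":
        from statsmodels.gam.api import BSplines, GLMGam

        self.keep_ = np.std(X, axis=0) > 1e-12
        Xk = X[:, self.keep_]
        alphas = [a for a, k in zip(self.alphas, self.keep_) if k]
        df = [self.n_splines] * Xk.shape[1]
        self.smoother_ = BSplines(Xk, df=df, degree=[3] * Xk.shape[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.result_ = GLMGam(y, smoother=self.smoother_, alpha=alphas).fit()
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(
            self.result_.predict(exog_smooth=X[:, self.keep_])
        )


def _build_estimator(model_type: str, params: dict):
    if model_type == "linear":
        return Ridge(alpha=float(params["alpha"]))
    if model_type == "svm":
        return SVR(
            kernel="rbf",
            C=float(params["C"]),
            gamma=float(params["gamma"]),
            epsilon=float(params["epsilon"]),
        )
    if model_type == "gam":
        alphas = [float(params[f"alpha_{i}"]) for i in range(len(FEATURE_NAMES))]
        return _GamRegressor(alphas, params["n_splines"])
    if model_type == "tree":
        return DecisionTreeRegressor(
            max_depth=int(params["max_depth"]),
            min_samples_leaf=int(params["min_samples_leaf"]),
            random_state=0,
        )
    raise DomainError(f"unknown model type {model_type!r}; expected one of {MODEL_TYPES}")


@dataclass
class ConditionModel:
    """A fitted SI regressor for one CTSIB condition.

    ``beta``/``bias`` (linear models only) are on the *raw* feature scale,
    so ``predict = bias + beta . features`` without standardization.
    """

    condition: Condition
    model_type: str
    hyperparams: dict[str, float | int]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    beta: np.ndarray | None = None
    bias: float | None = None
    estimator: object | None = field(default=None, repr=False)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_mean) / self.feature_sd

    def predict_array(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(FEATURE_NAMES):
            raise DomainError(
                f"feature matrix must have {len(FEATURE_NAMES)} columns, got {X.shape[1]}"
            )
        if not np.isfinite(X).all():
            raise DomainError("feature vector contains missing (non-finite) values")
        if self.model_type == "linear":
            return self.bias + X @ self.beta
        return np.asarray(self.estimator.predict(self.standardize(X)), dtype=float)


def predict_si(model: ConditionModel, features: SwayFeatures) -> float:
    """Predict the stability index for one feature vector."""
    return float(model.predict_array(features.to_array()[None, :])[0])


def _cv_rmse(model_type: str, params: dict, X: np.ndarray, y: np.ndarray, seed: int) -> float:
    kf = KFold(n_splits=5, shuffle=True, random_state=seed)
    errors = []
    for train_idx, val_idx in kf.split(X):
        est = _build_estimator(model_type, params)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X[train_idx], y[train_idx])
                pred = est.predict(X[val_idx])
        except Exception:
            return 1e6  # numerically infeasible hyperparameters
        if not np.all(np.isfinite(pred)):
            return 1e6
        errors.append(np.mean((pred - y[val_idx]) ** 2))
    return float(np.sqrt(np.mean(errors)))


def fit_condition_model(
    train: TrainingTable,
    model_type: str = "linear",
    bo: BOConfig | None = None,
    condition: Condition | None = None,
) -> ConditionModel:
    """Fit one condition's SI model with Bayesian hyperparameter optimization.

    ``train`` must contain rows of a single condition (or ``condition`` must
    select one). Features are standardized on training statistics; the
    optimizer minimizes 5-fold cross-validated RMSE; the chosen model is
    refitted on all training rows.
    """
    if model_type not in MODEL_TYPES:
        raise DomainError(f"unknown model type {model_type!r}; expected one of {MODEL_TYPES}")
    bo = bo or BOConfig()
    if condition is not None:
        train = train.for_condition(condition)
    conditions = {r.condition for r in train.rows}
    if len(conditions) != 1:
        raise ConfigurationError(
            f"training table must hold exactly one condition, found {sorted(c.value for c in conditions)}"
        )
    cond = conditions.pop()
    if len(train.rows) < 10:
        raise InsufficientDataError(
            f"need >= 10 training rows for {cond.value}, got {len(train.rows)}"
        )
    X_raw, y = train.to_arrays()
    mean = X_raw.mean(axis=0)
    sd = X_raw.std(axis=0, ddof=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    X = (X_raw - mean) / sd

    if float(np.std(y)) < 1e-12:
        warnings.warn(
            f"constant SI target for {cond.value}; returning intercept-only model",
            stacklevel=2,
        )
        return ConditionModel(
            condition=cond,
            model_type="linear",
            hyperparams={},
            feature_mean=mean,
            feature_sd=sd,
            beta=np.zeros(len(FEATURE_NAMES)),
            bias=float(y.mean()),
        )

    space = (bo.search_space or DEFAULT_SEARCH_SPACES).get(model_type) or DEFAULT_SEARCH_SPACES[
        model_type
    ]
    result = bayesian_optimize(
        lambda params: _cv_rmse(model_type, params, X, y, bo.seed), space, bo
    )
    est = _build_estimator(model_type, result.best_params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)

    model = ConditionModel(
        condition=cond,
        model_type=model_type,
        hyperparams=dict(result.best_params),
        feature_mean=mean,
        feature_sd=sd,
        estimator=est,
    )
    if model_type == "linear":
        beta_std = np.asarray(est.coef_, dtype=float)
        bias_std = float(est.intercept_)
        model.beta = beta_std / sd
        model.bias = bias_std - float((beta_std * mean / sd).sum())
    return model


@dataclass
class EvaluationResult:
    r: float
    rmse: float
    n: int


def evaluate_model(model: ConditionModel, test: TrainingTable) -> EvaluationResult:
    """Pearson correlation (and RMSE) between reference and predicted SI."""
    if len(test.rows) < 3:
        raise InsufficientDataError(f"evaluation needs >= 3 test rows, got {len(test.rows)}")
    X, y = test.to_arrays()
    pred = model.predict_array(X)
    if float(np.std(y)) < 1e-15 or float(np.std(pred)) < 1e-15:
        raise UndefinedCorrelationError("zero variance in references or predictions")
    r, _ = stats.pearsonr(y, pred)
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    return EvaluationResult(r=float(r), rmse=rmse, n=len(y))


# ---------------------------------------------------------------------------
# linear-formula export


def export_linear_formula(models: dict[Condition, ConditionModel], path: str | Path) -> None:
    """Write per-condition beta/bias of linear models as JSON.

    Loading the file with :func:`load_linear_formula` reconstitutes models
    whose predictions match the originals exactly.
    """
    for cond, model in models.items():
        if model.model_type != "linear" or model.beta is None:
            raise TypeError(f"model for {cond.value} is not linear; cannot export formula")
    doc = {
        "schema_version": EXPORT_SCHEMA_VERSION,
        "conditions": {
            cond.value: {
                "beta": {name: float(b) for name, b in zip(FEATURE_NAMES, model.beta)},
                "bias": float(model.bias),
            }
            for cond, model in models.items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_linear_formula(path: str | Path) -> dict[Condition, ConditionModel]:
    """Reconstitute linear condition models from an exported formula file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    models: dict[Condition, ConditionModel] = {}
    for label, entry in doc["conditions"].items():
        cond = Condition(label)
        beta = np.array([float(entry["beta"][name]) for name in FEATURE_NAMES])
        models[cond] = ConditionModel(
            condition=cond,
            model_type="linear",
            hyperparams={},
            feature_mean=np.zeros(len(FEATURE_NAMES)),
            feature_sd=np.ones(len(FEATURE_NAMES)),
            beta=beta,
            bias=float(entry["bias"]),
        )
    return models
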