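"""Regression models, the 70/15/15 split, grid search and evaluation metrics.

Seven model kinds run through one fit/predict contract: partial least
squares (plsr), random forest (rf), k-nearest-neighbour (knnr), support
vector (svr) regression, and three recurrent kinds (lstm, bilstm,
bilstm_gs) that read the feature vector as an ordered sequence of scalar
steps.  "Calibration" metrics (Rc2, RMSEc) are computed on the training
split and "prediction" metrics (Rp2, RMSEp) on the held-out test split;
the validation split is used only for tuning and early stopping.

The statsmodels-style entry point is :class:`YieldModel` — built from a
labelled :class:`~hypyield.containers.SampleTable` or plain arrays, its
``fit()`` returns a :class:`YieldResults` carrying the metrics and a
``summary()`` table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from hypyield.containers import SampleTable
from hypyield.errors import ConfigurationError, DataError, DimensionError
from hypyield.nn import LSTMRegressor

MODEL_KINDS = ("plsr", "rf", "knnr", "svr", "lstm", "bilstm", "bilstm_gs")

# Winning hyperparameters of the grid searches, used as defaults
DEFAULT_HYPERPARAMETERS = {
    "plsr": {"n_components": 10},
    "rf": {"n_estimators": 200},
    "knnr": {"n_neighbors": 10},
    "svr": {"C": 10.0},
    "lstm": {"learning_rate": 0.01},
    "bilstm": {"learning_rate": 0.01},
    "bilstm_gs": {"learning_rate": 0.01, "hidden_layer_size": 50},
}

# Search grids for grid_search; only the winners above are data-backed
DEFAULT_GRIDS = {
    "plsr": {"n_components": list(range(1, 16))},
    "rf": {"n_estimators": [50, 100, 200, 400]},
    "knnr": {"n_neighbors": [1, 3, 5, 10, 15]},
    "svr": {"C": [0.1, 1.0, 10.0, 100.0]},
    "lstm": {"learning_rate": [1e-4, 1e-3, 1e-2, 1e-1]},
    "bilstm": {"learning_rate": [1e-4, 1e-3, 1e-2, 1e-1]},
    "bilstm_gs": {
        "learning_rate": [1e-4, 1e-3, 1e-2, 1e-1],
        "hidden_layer_size": [10, 25, 50, 100],
    },
}


# ---------------------------------------------------------------------------
# Metrics


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise DimensionError("y and y_hat must have equal length")
    if y.size < 2:
        raise ConfigurationError("R^2 needs at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DataError("R^2 undefined for constant y")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root mean square error."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise DimensionError("y and y_hat must have equal length")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


# ---------------------------------------------------------------------------
# Dataset split


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigurationError("split fractions must sum to 1")


def split_sizes(n: int, fractions=(0.70, 0.15, 0.15)) -> tuple[int, int, int]:
    """Floor each fraction; the remainder goes to the training split."""
    floors = [int(np.floor(n * f)) for f in fractions]
    floors[0] += n - sum(floors)
    return tuple(floors)


def split_dataset(table: SampleTable, spec: SplitSpec | None = None, seed: int | None = None) -> SampleTable:
    """Assign train/val/test labels by seeded shuffle + contiguous blocks."""
    if spec is None:
        spec = SplitSpec(seed=0 if seed is None else seed)
    n = table.n_samples
    n_train, n_val, n_test = split_sizes(n, spec.fractions)
    if min(n_train, n_val, n_test) < 1 or n < 10:
        raise ConfigurationError(f"n={n} too small for non-empty 70/15/15 splits")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    labels[order[:n_train]] = "train"
    labels[order[n_train : n_train + n_val]] = "val"
    labels[order[n_train + n_val :]] = "test"
    out = table.with_spectra(table.spectra.copy())
    out.split = labels
    return out


# ---------------------------------------------------------------------------
# Model construction


@dataclass
class ModelSpec:
    """One model kind with its hyperparameters and training seed."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    training_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ConfigurationError(f"unknown model kind {self.kind!r}")
        allowed = set(DEFAULT_HYPERPARAMETERS[self.kind])
        unknown = set(self.hyperparameters) - allowed
        if unknown:
            raise ConfigurationError(
                f"hyperparameters {sorted(unknown)} not valid for kind {self.kind!r}"
            )
        merged = dict(DEFAULT_HYPERPARAMETERS[self.kind])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged


class FittedModel:
    """Uniform predict wrapper over sklearn estimators and the LSTM kinds."""

    def __init__(self, spec: ModelSpec, estimator, n_features: int):
        self.spec = spec
        self._est = estimator
        self.n_features = n_features

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            X = np.atleast_2d(X)
        if X.shape[0] == 0:
            return np.empty(0)
        if X.shape[1] != self.n_features:
            raise DimensionError(
                f"model was trained on {self.n_features} features, got {X.shape[1]}"
            )
        pred = self._est.predict(X)
        return np.asarray(pred, dtype=float).ravel()


def _build_estimator(spec: ModelSpec, nn_options: dict | None = None):
    hp = spec.hyperparameters
    seed = spec.training_seed
    if spec.kind == "plsr":
        return PLSRegression(n_components=hp["n_components"], scale=True)
    if spec.kind == "rf":
        return RandomForestRegressor(n_estimators=hp["n_estimators"], random_state=seed)
    if spec.kind == "knnr":
        return make_pipeline(StandardScaler(), KNeighborsRegressor(n_neighbors=hp["n_neighbors"]))
    if spec.kind == "svr":
        # standardised features and targets keep the epsilon tube on a
        # comparable scale across datasets
        from sklearn.compose import TransformedTargetRegressor

        return TransformedTargetRegressor(
            regressor=make_pipeline(StandardScaler(), SVR(C=hp["C"])),
            transformer=StandardScaler(),
        )
    opts = dict(nn_options or {})
    hidden = hp.get("hidden_layer_size", opts.pop("hidden_size", 50))
    return LSTMRegressor(
        hidden_size=hidden,
        bidirectional=spec.kind in ("bilstm", "bilstm_gs"),
        learning_rate=hp["learning_rate"],
        seed=seed,
        **opts,
    )


def fit(
    spec: ModelSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    nn_options: dict | None = None,
) -> FittedModel:
    """Fit one model kind; recurrent kinds use the validation set for early stopping.

    ``nn_options`` tunes the recurrent training schedule (``max_epochs``,
    ``batch_size``, ``patience``, ``hidden_size``) without touching the
    searched hyperparameters.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    y_train = np.asarray(y_train, dtype=float).ravel()
    if not (np.all(np.isfinite(X_train)) and np.all(np.isfinite(y_train))):
        raise DataError("non-finite values in training data")
    est = _build_estimator(spec, nn_options)
    if isinstance(est, LSTMRegressor):
        est.fit(X_train, y_train, X_val, y_val)
    elif spec.kind == "plsr":
        n_comp = min(
            spec.hyperparameters["n_components"],
            X_train.shape[1],
            X_train.shape[0] - 1,
        )
        est.set_params(n_components=max(1, n_comp))
        est.fit(X_train, y_train)
    elif spec.kind == "knnr":
        k = min(spec.hyperparameters["n_neighbors"], X_train.shape[0])
        est.set_params(kneighborsregressor__n_neighbors=k)
        est.fit(X_train, y_train)
    else:
        est.fit(X_train, y_train)
    return FittedModel(spec, est, X_train.shape[1])


def predict(model: FittedModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


# ---------------------------------------------------------------------------
# Grid search


def grid_search(
    kind: str,
    grid: dict | None,
    X_train: np.ndarray,
    y_train: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    nn_options: dict | None = None,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Exhaustive seeded k-fold CV over every grid point; argmin CV RMSE wins.

    Ties break toward the earlier grid point in iteration order.  Returns
    the winning :class:`ModelSpec` and the full score surface (one row per
    grid point with its mean CV RMSE), which feeds the hyperparameter
    heatmap.
    """
    if grid is None:
        grid = DEFAULT_GRIDS[kind]
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ConfigurationError("grid must be non-empty")
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    y_train = np.asarray(y_train, dtype=float).ravel()
    names = list(grid)
    rows = []
    best_rmse = np.inf
    best_point = None
    n_splits = min(folds, X_train.shape[0])
    cv = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    split_idx = list(cv.split(X_train))
    for values in itertools.product(*(grid[n] for n in names)):
        point = dict(zip(names, values))
        fold_rmse = []
        for tr, te in split_idx:
            spec = ModelSpec(kind=kind, hyperparameters=point, training_seed=seed)
            m = fit(spec, X_train[tr], y_train[tr], nn_options=nn_options)
            fold_rmse.append(rmse(y_train[te], m.predict(X_train[te])))
        score = float(np.mean(fold_rmse))
        rows.append({**point, "cv_rmse": score})
        if score < best_rmse:
            best_rmse = score
            best_point = point
    surface = pd.DataFrame(rows)
    best = ModelSpec(kind=kind, hyperparameters=best_point, training_seed=seed)
    return best, surface


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class EvaluationReport:
    """Calibration/prediction metrics for one input-set x model combination."""

    Rc2: float
    RMSEc: float
    Rp2: float
    RMSEp: float
    input_code: str = ""
    kind: str = ""
    hyperparameters: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "input_code": self.input_code,
            "model": self.kind,
            "Rc2": self.Rc2,
            "RMSEc": self.RMSEc,
            "Rp2": self.Rp2,
            "RMSEp": self.RMSEp,
            "hyperparameters": str(self.hyperparameters),
        }


def evaluate(
    model: FittedModel,
    X: np.ndarray,
    y: np.ndarray,
    split: np.ndarray,
    input_code: str = "",
) -> EvaluationReport:
    """Score a fitted model on the training (calibration) and test (prediction) splits."""
    split = np.asarray(split, dtype=object)
    for label in ("train", "test"):
        if not np.any(split == label):
            raise ConfigurationError(f"empty {label!r} split")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    tr = split == "train"
    te = split == "test"
    y_tr_hat = model.predict(X[tr])
    y_te_hat = model.predict(X[te])
    return EvaluationReport(
        Rc2=r_squared(y[tr], y_tr_hat),
        RMSEc=rmse(y[tr], y_tr_hat),
        Rp2=r_squared(y[te], y_te_hat),
        RMSEp=rmse(y[te], y_te_hat),
        input_code=input_code,
        kind=model.spec.kind,
        hyperparameters=dict(model.spec.hyperparameters),
    )


# ---------------------------------------------------------------------------
# Model/Results front end


class YieldModel:
    """A yield regression problem: features, targets and split labels.

    Construct from arrays plus a split-label vector, or with
    :meth:`from_table` / :meth:`from_dataframe`.  ``fit()`` trains the
    requested model kind (optionally grid-searched first) and returns a
    :class:`YieldResults`.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        split: np.ndarray,
        kind: str = "plsr",
        hyperparameters: dict | None = None,
        input_code: str = "",
        training_seed: int = 0,
        nn_options: dict | None = None,
    ):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float).ravel()
        self.split = np.asarray(split, dtype=object)
        if self.X.shape[0] != self.y.size or self.y.size != self.split.size:
            raise DimensionError("X, y and split must agree in length")
        self.spec = ModelSpec(
            kind=kind,
            hyperparameters=hyperparameters or {},
            training_seed=training_seed,
        )
        self.input_code = input_code
        self.nn_options = nn_options

    @classmethod
    def from_table(cls, table: SampleTable, **kwargs) -> "YieldModel":
        if table.split is None:
            raise DataError("table has no split labels; run split_dataset first")
        return cls(table.spectra, table.y, table.split, **kwargs)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, feature_columns: list, target: str = "yield",
        split_column: str = "split", **kwargs,
    ) -> "YieldModel":
        return cls(
            df[feature_columns].to_numpy(dtype=float),
            df[target].to_numpy(dtype=float),
            df[split_column].to_numpy(),
            **kwargs,
        )

    def fit(self, tune: bool = False, grid: dict | None = None, folds: int = 5) -> "YieldResults":
        tr = self.split == "train"
        va = self.split == "val"
        surface = None
        spec = self.spec
        if tune:
            spec, surface = grid_search(
                spec.kind, grid, self.X[tr], self.y[tr],
                folds=folds, seed=spec.training_seed, nn_options=self.nn_options,
            )
        fitted = fit(
            spec,
            self.X[tr],
            self.y[tr],
            self.X[va] if va.any() else None,
            self.y[va] if va.any() else None,
            nn_options=self.nn_options,
        )
        report = evaluate(fitted, self.X, self.y, self.split, self.input_code)
        return YieldResults(model=self, fitted=fitted, report=report, surface=surface)


@dataclass
class YieldResults:
    """Fit outcome: the fitted model, its metrics, and any tuning surface."""

    model: YieldModel
    fitted: FittedModel
    report: EvaluationReport
    surface: pd.DataFrame | None = None

    @property
    def Rc2(self) -> float:
        return self.report.Rc2

    @property
    def RMSEc(self) -> float:
        return self.report.RMSEc

    @property
    def Rp2(self) -> float:
        return self.report.Rp2

    @property
    def RMSEp(self) -> float:
        return self.report.RMSEp

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.fitted.predict(X)

    def summary(self) -> str:
        r = self.report
        lines = [
            "Yield regression results",
            "=" * 48,
            f"model kind        : {r.kind}",
            f"input code        : {r.input_code or '-'}",
            f"hyperparameters   : {r.hyperparameters}",
            f"n train/val/test  : "
            f"{int(np.sum(self.model.split == 'train'))}/"
            f"{int(np.sum(self.model.split == 'val'))}/"
            f"{int(np.sum(self.model.split == 'test'))}",
            "-" * 48,
            f"calibration  Rc2  : {r.Rc2:8.4f}   RMSEc : {r.RMSEc:8.4f}",
            f"prediction   Rp2  : {r.Rp2:8.4f}   RMSEp : {r.RMSEp:8.4f}",
            "=" * 48,
        ]
        return "\n".join(lines)
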