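"""QSPR regression harness: descriptors -> physicochemical properties.

Quantitative structure-property relationship (QSPR) modelling regresses a
physicochemical property (boiling point, flash point, molar refractivity,
...) on molecular descriptors. Five model families are supported: ordinary
least squares (``ols``), ridge (``ridge``), lasso (``lasso``), elastic net
(``enet``) and epsilon-insensitive support-vector regression (``svr``).

The module follows the Model/Results idiom: ``QSPRModel`` holds the aligned
data and method configuration, ``QSPRModel.fit()`` returns a ``QSPRResults``
with coefficients on the original descriptor scale, in-sample metrics
(Pearson r, R^2, MSE), a ``summary()`` table and an ``equation()`` renderer.
Thin functional wrappers (`fit`, `evaluate`, `compare_models`,
`equation_text`) mirror the same operations.

Conventions, stated because they matter for interpreting the numbers:

* Metrics are in-sample on all rows, with no train/test split.
* Penalized fits (ridge/lasso/enet) and SVR standardize predictors to zero
  mean, unit variance internally; reported coefficients are transformed back
  to the original scale. OLS is fit unstandardized.
* With fewer samples than descriptors, OLS returns the minimum-norm least
  squares solution and emits `RankDeficiencyWarning`.
* Penalty strengths follow scikit-learn's conventions: lasso/enet minimize
  (1/2n)||y - Xb||^2 + penalty, so the full-shrinkage threshold is
  lambda_max = max |X_std^T (y - ybar)| / n (see `lasso_lambda_max`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, Lasso, Ridge
from sklearn.svm import SVR

from .errors import AlignmentError, EquationUnavailableError, RegressionError

__all__ = [
    "METHODS",
    "DEFAULT_HYPERPARAMETERS",
    "FitMetrics",
    "QSPRModel",
    "QSPRResults",
    "load_qspr_tables",
    "fit",
    "evaluate",
    "compare_models",
    "equation_text",
    "lasso_lambda_max",
    "loocv_grid_search",
    "RankDeficiencyWarning",
    "ConstantPredictionWarning",
    "ZeroVarianceDescriptorWarning",
]

METHODS = ("ols", "ridge", "lasso", "enet", "svr")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "ols": {},
    "ridge": {"lam": 1.0},
    "lasso": {"lam": 0.1},
    "enet": {"lam": 0.1, "mix": 0.5},
    "svr": {"kernel": "rbf", "C": 100.0, "epsilon": 0.1, "gamma": "auto"},
}

_COORD_DESCENT_TOL = 1e-7


class RankDeficiencyWarning(UserWarning):
    """OLS design matrix is rank deficient; minimum-norm solution returned."""


class ConstantPredictionWarning(UserWarning):
    """Predictions have zero variance; Pearson r reported as 0."""


class ZeroVarianceDescriptorWarning(UserWarning):
    """A descriptor is constant and was dropped before standardization."""


def load_qspr_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The packaged 13-drug descriptor and property tables.

    Returns (descriptors, properties), both indexed by drug name. Descriptor
    columns: AZI, M1, M2, mM2, H, ReZG3, SDD, I, F. Property columns: BP,
    EoV, FP, MR, MV, P, MW, MM, PSA, HAC, C.
    """
    data = resources.files("revent.data")
    with resources.as_file(data / "drug_descriptors.csv") as p:
        X = pd.read_csv(p, comment="#", index_col=0)
    with resources.as_file(data / "drug_properties.csv") as p:
        Y = pd.read_csv(p, comment="#", index_col=0)
    return X, Y


@dataclass(frozen=True)
class FitMetrics:
    """In-sample goodness-of-fit triple."""

    pearson_r: float
    r_squared: float
    mse: float


def _align(X: pd.DataFrame, y: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    if len(X) < 2:
        raise RegressionError("need at least 2 rows to fit or evaluate")
    if set(X.index) != set(y.index):
        missing = set(X.index) ^ set(y.index)
        raise AlignmentError(
            f"descriptor and property rows do not match; mismatched labels: "
            f"{sorted(missing)[:5]}"
        )
    if X.columns.duplicated().any():
        raise RegressionError("duplicate descriptor names")
    if X.isna().any().any() or y.isna().any():
        raise RegressionError("missing cells are not allowed")
    return X, y.loc[X.index]


class QSPRModel:
    """A regression model specification bound to aligned data.

    Parameters
    ----------
    X : DataFrame of descriptors, rows labelled by compound.
    y : Series of one property, labels matching X.
    method : one of ``ols``, ``ridge``, ``lasso``, ``enet``, ``svr``.
    hyperparameters : ridge/lasso/enet ``lam`` (>= 0), enet ``mix`` in [0,1],
        svr ``kernel``/``C``/``epsilon``/``gamma``.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: pd.Series,
        method: str = "ols",
        **hyperparameters,
    ):
        if method not in METHODS:
            raise RegressionError(
                f"unknown method {method!r}; choose from {METHODS}"
            )
        X = pd.DataFrame(X).astype(float)
        y = pd.Series(y).astype(float)
        self.X, self.y = _align(X, y)
        self.method = method
        hp = dict(DEFAULT_HYPERPARAMETERS[method])
        unknown = set(hyperparameters) - set(hp)
        if unknown:
            raise RegressionError(
                f"invalid hyperparameters for {method}: {sorted(unknown)}"
            )
        hp.update(hyperparameters)
        self._validate_hyper(method, hp)
        self.hyperparameters = hp

    @staticmethod
    def _validate_hyper(method: str, hp: Mapping) -> None:
        if "lam" in hp and hp["lam"] < 0:
            raise RegressionError("penalty lam must be >= 0")
        if method == "enet" and not 0 <= hp["mix"] <= 1:
            raise RegressionError("enet mix must lie in [0, 1]")
        if method == "svr":
            if hp["C"] <= 0:
                raise RegressionError("svr C must be > 0")
            if hp["epsilon"] < 0:
                raise RegressionError("svr epsilon must be >= 0")

    @classmethod
    def from_tables(
        cls,
        descriptors: pd.DataFrame,
        properties: pd.DataFrame,
        target: str,
        method: str = "ols",
        **hyperparameters,
    ) -> "QSPRModel":
        """Join a descriptor table with one property column by row label."""
        if target not in properties.columns:
            raise RegressionError(
                f"property {target!r} not in table; available: "
                f"{list(properties.columns)}"
            )
        y = properties[target]
        return cls(descriptors.loc[sorted(descriptors.index)],
                   y.loc[sorted(y.index)], method=method, **hyperparameters)

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int | None = None) -> "QSPRResults":
        X, y = self.X, self.y
        names = list(X.columns)
        Xv = X.to_numpy()
        yv = y.to_numpy()
        hp = self.hyperparameters

        if self.method == "ols":
            design = np.column_stack([np.ones(len(Xv)), Xv])
            beta, _, rank, _ = np.linalg.lstsq(design, yv, rcond=None)
            if rank < design.shape[1]:
                warnings.warn(
                    f"design matrix rank {rank} < {design.shape[1]}; "
                    "minimum-norm OLS solution returned",
                    RankDeficiencyWarning,
                    stacklevel=2,
                )
            return QSPRResults(
                model=self,
                coefficients=pd.Series(beta[1:], index=names),
                intercept=float(beta[0]),
                kept_columns=names,
                standardization=None,
                _predictor=None,
            )

        # standardized fits
        mu = Xv.mean(axis=0)
        sd = Xv.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            dropped = [n for n, k in zip(names, keep) if not k]
            warnings.warn(
                f"zero-variance descriptors dropped: {dropped}",
                ZeroVarianceDescriptorWarning,
                stacklevel=2,
            )
        kept_names = [n for n, k in zip(names, keep) if k]
        if not kept_names:
            raise RegressionError("all descriptors have zero variance")
        Xs = (Xv[:, keep] - mu[keep]) / sd[keep]

        if self.method == "ridge":
            est = Ridge(alpha=hp["lam"], fit_intercept=True)
        elif self.method == "lasso":
            est = Lasso(alpha=hp["lam"], fit_intercept=True,
                        tol=_COORD_DESCENT_TOL, max_iter=200_000)
        elif self.method == "enet":
            est = ElasticNet(alpha=hp["lam"], l1_ratio=hp["mix"],
                             fit_intercept=True, tol=_COORD_DESCENT_TOL,
                             max_iter=200_000)
        else:  # svr
            est = SVR(kernel=hp["kernel"], C=hp["C"], epsilon=hp["epsilon"],
                      gamma=hp["gamma"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sklearn convergence chatter
            est.fit(Xs, yv)

        std = {"mean": dict(zip(kept_names, mu[keep])),
               "scale": dict(zip(kept_names, sd[keep]))}

        if self.method == "svr" and hp["kernel"] != "linear":
            return QSPRResults(
                model=self,
                coefficients=None,
                intercept=None,
                kept_columns=kept_names,
                standardization=std,
                _predictor=est,
            )
        if self.method == "svr":
            beta_std = est.coef_.ravel()
            b0 = float(est.intercept_.ravel()[0])
        else:
            beta_std = est.coef_.ravel()
            b0 = float(est.intercept_)
        # back to original scale: y = b0 + sum b_j (x_j - mu_j)/sd_j
        coef = beta_std / sd[keep]
        intercept = b0 - float(np.dot(beta_std, mu[keep] / sd[keep]))
        return QSPRResults(
            model=self,
            coefficients=pd.Series(coef, index=kept_names),
            intercept=intercept,
            kept_columns=kept_names,
            standardization=std,
            _predictor=est,
        )


@dataclass
class QSPRResults:
    """A fitted QSPR model.

    ``coefficients``/``intercept`` are on the original descriptor scale (None
    for nonlinear-kernel SVR, which has no linear form); predictions from
    them agree with the internal standardized fit to numerical precision.
    """

    model: QSPRModel
    coefficients: pd.Series | None
    intercept: float | None
    kept_columns: list[str]
    standardization: dict | None
    _predictor: object | None = field(repr=False, default=None)

    @property
    def method(self) -> str:
        return self.model.method

    @property
    def hyperparameters(self) -> dict:
        return dict(self.model.hyperparameters)

    def predict(self, X: pd.DataFrame | None = None) -> pd.Series:
        if X is None:
            X = self.model.X
        X = pd.DataFrame(X).astype(float)
        missing = [c for c in self.kept_columns if c not in X.columns]
        if missing:
            raise RegressionError(f"prediction input lacks descriptors {missing}")
        if self._predictor is not None and (
            self.coefficients is None or self.method == "svr"
        ):
            mu = np.array([self.standardization["mean"][c] for c in self.kept_columns])
            sd = np.array([self.standardization["scale"][c] for c in self.kept_columns])
            Xs = (X[self.kept_columns].to_numpy() - mu) / sd
            return pd.Series(self._predictor.predict(Xs), index=X.index)
        vals = self.intercept + X[self.kept_columns].to_numpy() @ self.coefficients.to_numpy()
        return pd.Series(vals, index=X.index)

    def metrics(self, X: pd.DataFrame | None = None, y: pd.Series | None = None) -> FitMetrics:
        if X is None and y is None:
            X, y = self.model.X, self.model.y
        X, y = _align(pd.DataFrame(X).astype(float), pd.Series(y).astype(float))
        pred = self.predict(X)
        return _metrics_from(y.to_numpy(), pred.to_numpy())

    def equation(self, precision: int = 4) -> str:
        """Render ``PROP = intercept + (coef) NAME + ...``; zero coefficients
        are omitted, matching sparse lasso equations."""
        if self.coefficients is None:
            raise EquationUnavailableError(
                "nonlinear-kernel SVR has no linear equation form"
            )
        target = self.model.y.name or "y"
        parts = [f"{self.intercept:.{precision}f}"]
        for name, c in self.coefficients.items():
            if c == 0.0:
                continue
            parts.append(f"({c:.{precision}f}) {name}")
        return f"{target} = " + " + ".join(parts)

    def summary(self) -> str:
        m = self.metrics()
        hp = ", ".join(f"{k}={v}" for k, v in self.hyperparameters.items()) or "-"
        lines = [
            "QSPR regression results",
            "=" * 54,
            f"method:        {self.method}",
            f"target:        {self.model.y.name}",
            f"observations:  {len(self.model.y)}",
            f"descriptors:   {len(self.kept_columns)}",
            f"hyperparams:   {hp}",
            f"Pearson r:     {m.pearson_r: .4f}",
            f"R-squared:     {m.r_squared: .4f}",
            f"MSE:           {m.mse: .4f}",
            "-" * 54,
        ]
        if self.coefficients is None:
            lines.append("(nonlinear kernel: no linear coefficients)")
        else:
            lines.append(f"{'term':<16s}{'coefficient':>16s}")
            lines.append(f"{'intercept':<16s}{self.intercept:>16.4f}")
            for name, c in self.coefficients.items():
                lines.append(f"{name:<16s}{c:>16.4f}")
        lines.append("=" * 54)
        return "\n".join(lines)


def _metrics_from(obs: np.ndarray, pred: np.ndarray) -> FitMetrics:
    resid = obs - pred
    mse = float(np.mean(resid**2))
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sstot if sstot > 0 else float("nan")
    if np.std(pred) == 0 or np.std(obs) == 0:
        warnings.warn(
            "constant predictions or observations; Pearson r reported as 0",
            ConstantPredictionWarning,
            stacklevel=3,
        )
        r = 0.0
    else:
        r = float(np.corrcoef(pred, obs)[0, 1])
    return FitMetrics(pearson_r=r, r_squared=r2, mse=mse)


# ---------------------------------------------------------------------------
# functional wrappers


def fit(
    X: pd.DataFrame,
    y: pd.Series,
    method: str = "ols",
    hyperparameters: Mapping | None = None,
    seed: int | None = None,
) -> QSPRResults:
    return QSPRModel(X, y, method=method, **(dict(hyperparameters or {}))).fit(seed=seed)


def evaluate(results: QSPRResults, X: pd.DataFrame, y: pd.Series) -> FitMetrics:
    return results.metrics(X, y)


def compare_models(
    X: pd.DataFrame,
    y: pd.Series,
    methods: Sequence[str] = METHODS,
    hyperparameters: Mapping[str, Mapping] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """One row of in-sample metrics per method, deterministic given seed."""
    hyper = hyperparameters or {}
    rows = []
    for method in methods:
        res = fit(X, y, method=method,
                  hyperparameters=hyper.get(method, {}), seed=seed)
        m = res.metrics()
        rows.append({"model": method, "pearson_r": m.pearson_r,
                     "r_squared": m.r_squared, "mse": m.mse})
    return pd.DataFrame(rows, columns=["model", "pearson_r", "r_squared", "mse"])


def equation_text(results: QSPRResults, precision: int = 4) -> str:
    return results.equation(precision=precision)


def lasso_lambda_max(X: pd.DataFrame, y: pd.Series) -> float:
    """Smallest penalty that shrinks every lasso coefficient to zero
    (standardized predictors, scikit-learn's 1/2n objective scaling)."""
    X, y = _align(pd.DataFrame(X).astype(float), pd.Series(y).astype(float))
    Xv = X.to_numpy()
    sd = Xv.std(axis=0, ddof=0)
    keep = sd > 0
    Xs = (Xv[:, keep] - Xv[:, keep].mean(axis=0)) / sd[keep]
    yc = y.to_numpy() - y.to_numpy().mean()
    return float(np.max(np.abs(Xs.T @ yc)) / len(yc))


def loocv_grid_search(
    X: pd.DataFrame,
    y: pd.Series,
    method: str,
    grid: Sequence[Mapping],
    seed: int | None = None,
) -> tuple[dict, float]:
    """Leave-one-out hyperparameter search; returns (best_params, best_mse)."""
    X, y = _align(pd.DataFrame(X).astype(float), pd.Series(y).astype(float))
    best: tuple[dict, float] | None = None
    for params in grid:
        sq_errors = []
        for left_out in X.index:
            train = X.index != left_out
            res = fit(X.loc[train], y.loc[train], method=method,
                      hyperparameters=params, seed=seed)
            pred = res.predict(X.loc[[left_out]]).iloc[0]
            sq_errors.append((y.loc[left_out] - pred) ** 2)
        mse = float(np.mean(sq_errors))
        if best is None or mse < best[1]:
            best = (dict(params), mse)
    if best is None:
        raise RegressionError("empty hyperparameter grid")
    return best
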