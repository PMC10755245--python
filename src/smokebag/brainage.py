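"""Brain-age prediction from residualized regional gray-matter volumes.

The estimator is a gradient-boosted tree ensemble (XGBoost) trained under
nested five-fold cross-validation: the outer loop yields one out-of-fold
prediction per training subject, the inner loop selects hyperparameters on
training subjects only (minimum mean MAE). The brain-age gap (BAG) is
predicted minus chronological age. Because regression-to-the-mean makes raw
BAG anti-correlate with age, a bias model (BAG regressed on age in the
training population) is subtracted from BAG wherever the ensemble is
applied — including cohorts the model never saw, using the *training*
coefficients unchanged.

``BrainAgeModel(features, age).fit()`` returns a :class:`BrainAgeResults`
carrying out-of-fold predictions, the fitted bias model, fit metrics and a
``summary()`` table; ``results.predict(new_features)`` averages the
per-fold models on a new cohort. Thin functional wrappers (``residualize``,
``fit_brainage``, ``predict_new``, ``fit_bias``, ``apply_bias``,
``fit_metrics``) expose the individual steps.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold
from xgboost import XGBRegressor

from ._utils import design_matrix, residualize_on

DEFAULT_PARAM_GRID = {
    "max_depth": [2, 4, 6],
    "learning_rate": [0.05, 0.1],
    "n_estimators": [100, 300],
}


def residualize(features, covariates) -> pd.DataFrame:
    """Replace each feature column by its least-squares residual on
    [intercept | covariates]. Residuals are exactly orthogonal to every
    covariate column."""
    feats = pd.DataFrame(features).astype(float)
    if feats.isna().any().any():
        raise ValueError("features contain missing values")
    X, _ = design_matrix(len(feats), covariates)
    resid = residualize_on(feats.to_numpy(), X)
    return pd.DataFrame(resid, index=feats.index, columns=feats.columns)


@dataclass
class BiasModel:
    """Linear trend of training-set BAG on chronological age."""

    slope: float
    intercept: float

    def predicted_bias(self, age) -> np.ndarray:
        return self.slope * np.asarray(age, dtype=float) + self.intercept


@dataclass
class FitMetrics:
    pearson_r: float
    r_ci_low: float
    r_ci_high: float
    rmse: float
    mae: float
    n: int


def fit_metrics(predicted, age) -> FitMetrics:
    """Pearson r with Fisher-z 95% CI (SE = 1/sqrt(n-3)), RMSE and MAE."""
    pred = np.asarray(predicted, dtype=float)
    age = np.asarray(age, dtype=float)
    if pred.size < 4:
        raise ValueError("need at least 4 observations")
    if pred.std() == 0 or age.std() == 0:
        raise ValueError("zero variance in predictions or age")
    r = float(np.corrcoef(pred, age)[0, 1])
    z = np.arctanh(min(max(r, -0.9999999999), 0.9999999999))
    half = stats.norm.ppf(0.975) / np.sqrt(pred.size - 3)
    err = pred - age
    return FitMetrics(
        pearson_r=r,
        r_ci_low=float(np.tanh(z - half)),
        r_ci_high=float(np.tanh(z + half)),
        rmse=float(np.sqrt(np.mean(err**2))),
        mae=float(np.mean(np.abs(err))),
        n=pred.size,
    )


def fit_bias(oof_predictions, age) -> BiasModel:
    """Regress out-of-fold BAG on age (training population only)."""
    age = np.asarray(age, dtype=float)
    if age.std() == 0:
        raise ValueError("constant age vector: bias slope undefined")
    bag = np.asarray(oof_predictions, dtype=float) - age
    slope, intercept = np.polyfit(age, bag, deg=1)
    return BiasModel(slope=float(slope), intercept=float(intercept))


def apply_bias(bias: BiasModel, predictions, age) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the training-age trend: corrected BAG = BAG - (slope*age + b).

    Returns (corrected predicted age, corrected BAG); corrected predicted
    age is chronological age plus the corrected BAG.
    """
    age = np.asarray(age, dtype=float)
    bag = np.asarray(predictions, dtype=float) - age
    cbag = bag - bias.predicted_bias(age)
    return age + cbag, cbag


def _param_combos(grid: dict) -> list[dict]:
    keys = sorted(grid)
    return [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]


def _regressor(params: dict, seed: int) -> XGBRegressor:
    return XGBRegressor(
        objective="reg:squarederror",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
        **params,
    )


class BrainAgeModel:
    """Nested-CV gradient-boosted brain-age model.

    Parameters
    ----------
    features : DataFrame
        Residualized region volumes (subjects x regions), no missing values.
    age : array-like
        Chronological age in years.
    n_outer_folds, n_inner_folds : int
        Outer folds yield out-of-fold predictions; inner folds drive
        hyperparameter selection by minimum mean MAE.
    param_grid : dict
        Lists of candidate values per XGBoost parameter; an empty or None
        grid falls back to :data:`DEFAULT_PARAM_GRID`.
    """

    def __init__(
        self,
        features,
        age,
        n_outer_folds: int = 5,
        n_inner_folds: int = 5,
        param_grid: dict | None = None,
    ):
        self.features = pd.DataFrame(features).astype(float)
        self.age = np.asarray(age, dtype=float)
        if len(self.features) != self.age.size:
            raise ValueError("features and age length mismatch")
        if self.age.size < n_outer_folds:
            raise ValueError("fewer subjects than outer folds")
        self.n_outer_folds = n_outer_folds
        self.n_inner_folds = n_inner_folds
        self.param_grid = param_grid or DEFAULT_PARAM_GRID

    @classmethod
    def from_cohort(cls, cohort, covariate_columns, **kwargs) -> "BrainAgeModel":
        """Build from a CohortTable: region volumes residualized on the
        given covariate columns, age taken from the ``age`` column."""
        feats = residualize(cohort.regions(), cohort.table[list(covariate_columns)])
        return cls(feats, cohort.table["age"].to_numpy(), **kwargs)

    # stratify the outer split by age decile so fold age distributions match
    def _outer_folds(self, seed: int):
        decile = pd.qcut(self.age, q=10, labels=False, duplicates="drop")
        skf = StratifiedKFold(
            n_splits=self.n_outer_folds, shuffle=True, random_state=seed
        )
        return skf.split(self.features, decile)

    def _select_params(self, X, y, combos, seed: int) -> dict:
        if len(combos) == 1:
            return combos[0]
        kf = KFold(n_splits=self.n_inner_folds, shuffle=True, random_state=seed)
        splits = list(kf.split(X))
        best, best_mae = combos[0], np.inf
        for params in combos:
            maes = []
            for tr, va in splits:
                reg = _regressor(params, seed)
                reg.fit(X[tr], y[tr])
                maes.append(np.mean(np.abs(reg.predict(X[va]) - y[va])))
            mean_mae = float(np.mean(maes))
            if mean_mae < best_mae:
                best, best_mae = params, mean_mae
        return best

    def fit(self, seed: int = 0) -> "BrainAgeResults":
        X = self.features.to_numpy()
        y = self.age
        combos = _param_combos(self.param_grid)
        oof = np.full(y.size, np.nan)
        fold_id = np.full(y.size, -1, dtype=int)
        ensemble, chosen = [], []
        for k, (tr, te) in enumerate(self._outer_folds(seed)):
            if len(te) < 2 or len(tr) < 2:
                raise ValueError("fold with fewer than 2 subjects")
            params = self._select_params(X[tr], y[tr], combos, seed + k)
            reg = _regressor(params, seed)
            reg.fit(X[tr], y[tr])
            oof[te] = reg.predict(X[te])
            fold_id[te] = k
            ensemble.append(reg)
            chosen.append(params)
        bias = fit_bias(oof, y)
        cpred, cbag = apply_bias(bias, oof, y)
        return BrainAgeResults(
            model=self,
            ensemble=ensemble,
            chosen_params=chosen,
            age=y,
            predicted=oof,
            corrected_predicted=cpred,
            fold_id=fold_id,
            bias=bias,
            feature_columns=list(self.features.columns),
            seed=seed,
        )


class BrainAgeResults:
    """Fitted brain-age ensemble with out-of-fold predictions and bias model.

    Attributes mirror the per-subject quantities: ``predicted`` (raw
    out-of-fold predicted age), ``bag``, ``corrected_predicted`` and
    ``corrected_bag`` (after subtracting the training age-trend), plus the
    fold assignment and the per-fold chosen hyperparameters.
    """

    def __init__(
        self,
        model,
        ensemble,
        chosen_params,
        age,
        predicted,
        corrected_predicted,
        fold_id,
        bias,
        feature_columns,
        seed,
    ):
        self.model = model
        self.ensemble = ensemble
        self.chosen_params = chosen_params
        self.age = age
        self.predicted = predicted
        self.corrected_predicted = corrected_predicted
        self.fold_id = fold_id
        self.bias = bias
        self.feature_columns = feature_columns
        self.seed = seed

    @property
    def bag(self) -> np.ndarray:
        return self.predicted - self.age

    @property
    def corrected_bag(self) -> np.ndarray:
        return self.corrected_predicted - self.age

    @property
    def metrics(self) -> FitMetrics:
        return fit_metrics(self.predicted, self.age)

    @property
    def corrected_metrics(self) -> FitMetrics:
        return fit_metrics(self.corrected_predicted, self.age)

    def predict(self, features) -> np.ndarray:
        """Mean of the per-fold model predictions on a new cohort."""
        feats = pd.DataFrame(features)
        missing = [c for c in self.feature_columns if c not in feats.columns]
        extra = [c for c in feats.columns if c not in self.feature_columns]
        if missing or extra:
            raise ValueError(
                f"feature schema mismatch; missing={missing[:5]} extra={extra[:5]}"
            )
        X = feats[self.feature_columns].to_numpy(dtype=float)
        if X.shape[0] == 0:
            return np.empty(0)
        return np.mean([m.predict(X) for m in self.ensemble], axis=0)

    def predict_corrected(self, features, age) -> tuple[np.ndarray, np.ndarray]:
        """Predict a new cohort and apply the training bias model unchanged.
        Returns (corrected predicted age, corrected BAG)."""
        return apply_bias(self.bias, self.predict(features), age)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.age,
                "predicted_age": self.predicted,
                "corrected_predicted_age": self.corrected_predicted,
                "bag": self.bag,
                "corrected_bag": self.corrected_bag,
                "fold": self.fold_id,
            }
        )

    def summary(self) -> str:
        m, c = self.metrics, self.corrected_metrics
        lines = [
            "Brain-age model (gradient-boosted trees, nested CV)",
            f"  n = {self.age.size}, outer folds = {len(self.ensemble)}, seed = {self.seed}",
            f"  raw:       r = {m.pearson_r:.3f} [{m.r_ci_low:.3f}, {m.r_ci_high:.3f}], "
            f"RMSE = {m.rmse:.3f}, MAE = {m.mae:.3f}",
            f"  corrected: r = {c.pearson_r:.3f} [{c.r_ci_low:.3f}, {c.r_ci_high:.3f}], "
            f"RMSE = {c.rmse:.3f}, MAE = {c.mae:.3f}",
            f"  bias model: BAG = {self.bias.slope:.4f} * age + {self.bias.intercept:.4f}",
            f"  corr(corrected BAG, age) = "
            f"{np.corrcoef(self.corrected_bag, self.age)[0, 1]:.2e}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Predicted vs chronological age scatter with the identity line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(self.age, self.predicted, s=6, alpha=0.4, label="raw")
        ax.scatter(
            self.age, self.corrected_predicted, s=6, alpha=0.4, label="corrected"
        )
        lims = [self.age.min(), self.age.max()]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel("chronological age (years)")
        ax.set_ylabel("predicted age (years)")
        ax.legend()
        return ax


def fit_brainage(
    features,
    age,
    n_outer_folds: int = 5,
    n_inner_folds: int = 5,
    param_grid: dict | None = None,
    seed: int = 0,
) -> tuple[BrainAgeResults, np.ndarray]:
    """Functional wrapper: returns (results object, out-of-fold predictions)."""
    res = BrainAgeModel(
        features, age, n_outer_folds, n_inner_folds, param_grid
    ).fit(seed=seed)
    return res, res.predicted


def predict_new(results: BrainAgeResults, features) -> np.ndarray:
    return results.predict(features)
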