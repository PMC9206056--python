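"""VIF-filtered, cross-validated linear models of sleep outcomes.

The variable-importance stage regresses a per-athlete sleep outcome (total
sleep time or sleep efficiency) on the athlete's aggregate sleep behaviour:
SRI, onset/offset/midpoint/bedtime medians, onset and offset MADs, absolute
onset and offset night-to-night variation, and the complementary outcome.

Procedure: seeded 80/20 train-test split; iterative removal of predictors
with variance inflation factor >= 10; tenfold cross-validation with 5
repeats on the training set; ordinary least squares for the final fit;
held-out R-squared and range-normalised RMSE (%) on the test set; variable
importance as |t| statistics min-max scaled to [0, 100].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import RepeatedKFold

logger = logging.getLogger("somnoreg")

#: Default predictor columns per outcome (complementary outcome included).
DEFAULT_PREDICTORS: dict[str, tuple[str, ...]] = {
    "total_sleep_time": (
        "sri",
        "med_onset_min",
        "med_offset_min",
        "med_midpoint_min",
        "mad_onset_min",
        "mad_offset_min",
        "var_onset_min",
        "var_offset_min",
        "med_bedtime_min",
        "med_eff_pct",
    ),
    "sleep_efficiency": (
        "sri",
        "med_onset_min",
        "med_offset_min",
        "med_midpoint_min",
        "mad_onset_min",
        "mad_offset_min",
        "var_onset_min",
        "var_offset_min",
        "med_bedtime_min",
        "med_tst_h",
    ),
}

OUTCOME_COLUMNS = {
    "total_sleep_time": "med_tst_h",
    "sleep_efficiency": "med_eff_pct",
}


@dataclass
class ModelSpec:
    """Configuration of one importance model."""

    outcome: str
    predictors: tuple[str, ...] | None = None
    split_fraction: float = 0.8
    cv_folds: int = 10
    cv_repeats: int = 5
    vif_threshold: float = 10.0
    seed: int = 0
    nrmse_norm: str = "range"  # or "mean"

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_COLUMNS:
            raise ValueError(
                f"outcome must be one of {sorted(OUTCOME_COLUMNS)}, "
                f"got {self.outcome!r}"
            )
        if self.predictors is None:
            self.predictors = DEFAULT_PREDICTORS[self.outcome]
        self.predictors = tuple(self.predictors)
        if OUTCOME_COLUMNS[self.outcome] in self.predictors:
            raise ValueError("outcome column may not appear among predictors")


def split_train_test(
    profiles: pd.DataFrame, fraction: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded shuffle split into disjoint, exhaustive train/test sets."""
    n = len(profiles)
    if n < 10:
        raise ValueError(f"need at least 10 athletes to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fraction * n))
    train = profiles.iloc[order[:n_train]].reset_index(drop=True)
    test = profiles.iloc[order[n_train:]].reset_index(drop=True)
    return train, test


def _aux_r2(X: np.ndarray, y: np.ndarray) -> float:
    """R-squared of y regressed on X plus an intercept."""
    design = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 1.0
    return 1.0 - float((resid**2).sum()) / tss


def vif_filter(
    design: pd.DataFrame, threshold: float = 10.0
) -> tuple[list[str], dict[str, float], dict[str, float]]:
    """Iteratively drop the highest-VIF predictor while any VIF >= threshold.

    VIF_k = 1 / (1 - R2_k) with R2_k from regressing predictor k on the
    remaining predictors (with intercept).  Perfectly collinear columns get
    infinite VIF.  Ties at the maximum are broken by column name so the
    result does not depend on column order.

    Returns ``(retained_names, final_vifs, removed_vifs)``.
    """
    if design.shape[1] < 2:
        raise ValueError("VIF filtering needs at least 2 predictors")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("VIF filtering needs more rows than predictors")
    cols = sorted(design.columns)
    removed: dict[str, float] = {}
    while len(cols) >= 2:
        vifs: dict[str, float] = {}
        for c in cols:
            others = [o for o in cols if o != c]
            r2 = _aux_r2(
                design[others].to_numpy(float), design[c].to_numpy(float)
            )
            vifs[c] = float("inf") if r2 >= 1.0 - 1e-8 else 1.0 / (1.0 - r2)
        top = max(vifs.values())
        worst = min(c for c in cols if vifs[c] == top)  # tie -> first by name
        if vifs[worst] < threshold:
            return cols, vifs, removed
        logger.info("VIF filter removing %s (VIF = %.1f)", worst, vifs[worst])
        removed[worst] = vifs[worst]
        cols = [c for c in cols if c != worst]
    final = {cols[0]: 1.0}
    return cols, final, removed


@dataclass
class FittedModel:
    """A final OLS fit plus its cross-validation metrics."""

    outcome_col: str
    predictors: list[str]
    results: sm.regression.linear_model.RegressionResultsWrapper
    cv_r2: float
    cv_rmse: float
    r2_train: float
    rmse_train: float

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(
            frame[self.predictors].to_numpy(float), has_constant="add"
        )
        return np.asarray(self.results.predict(X))


def cv_linear_fit(
    train: pd.DataFrame,
    outcome_col: str,
    predictors: Sequence[str],
    cv_folds: int = 10,
    cv_repeats: int = 5,
    seed: int = 0,
) -> FittedModel:
    """Repeated k-fold CV of an OLS fit, then a final fit on all of train.

    CV R-squared and RMSE are means over the ``cv_folds * cv_repeats``
    held-out folds.  The final coefficients (and the t statistics behind
    variable importance) come from an OLS fit on the full training set.
    """
    predictors = list(predictors)
    X = train[predictors].to_numpy(float)
    y = train[outcome_col].to_numpy(float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in the post-filter design")
    cv = RepeatedKFold(n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed)
    r2s, rmses = [], []
    for tr, te in cv.split(X):
        fit = LinearRegression().fit(X[tr], y[tr])
        pred = fit.predict(X[te])
        resid = y[te] - pred
        rmses.append(float(np.sqrt(np.mean(resid**2))))
        tss = float(((y[te] - y[te].mean()) ** 2).sum())
        r2s.append(1.0 - float((resid**2).sum()) / tss if tss > 0 else 0.0)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular design after VIF filtering")
    results = sm.OLS(y, design).fit()
    pred_train = np.asarray(results.predict(design))
    return FittedModel(
        outcome_col=outcome_col,
        predictors=predictors,
        results=results,
        cv_r2=float(np.mean(r2s)),
        cv_rmse=float(np.mean(rmses)),
        r2_train=float(results.rsquared),
        rmse_train=float(np.sqrt(np.mean((y - pred_train) ** 2))),
    )


def evaluate_test(
    model: FittedModel, test: pd.DataFrame, nrmse_norm: str = "range"
) -> tuple[float, float]:
    """Held-out R-squared and normalised RMSE (%) on the test set.

    NRMSE is RMSE divided by the observed range of the outcome on the test
    set (or by its mean under ``nrmse_norm='mean'``), times 100.
    """
    if test.empty:
        raise ValueError("empty test set")
    y = test[model.outcome_col].to_numpy(float)
    pred = model.predict(test)
    resid = y - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("constant observed outcome on the test set")
    r2 = 1.0 - float((resid**2).sum()) / tss
    if nrmse_norm == "range":
        denom = float(y.max() - y.min())
    elif nrmse_norm == "mean":
        denom = float(np.abs(y.mean()))
    else:
        raise ValueError(f"nrmse_norm must be 'range' or 'mean', got {nrmse_norm!r}")
    if denom == 0:
        raise ValueError("NRMSE normaliser is zero")
    return r2, 100.0 * rmse / denom


def variable_importance(model: FittedModel) -> dict[str, float]:
    """|t| of each coefficient, min-max scaled to [0, 100].

    With a single retained predictor the score is 100; with several, the
    largest |t| maps to 100 and the smallest to 0.
    """
    tvals = np.abs(np.asarray(model.results.tvalues)[1:])  # drop intercept
    if tvals.size == 1:
        return {model.predictors[0]: 100.0}
    lo, hi = tvals.min(), tvals.max()
    if hi == lo:
        scaled = np.full(tvals.shape, 100.0)
    else:
        scaled = 100.0 * (tvals - lo) / (hi - lo)
    return {p: float(s) for p, s in zip(model.predictors, scaled)}


@dataclass
class ModelReport:
    """Everything the importance stage reports for one outcome."""

    outcome: str
    outcome_col: str
    predictors_used: list[str]
    removed_predictors: dict[str, float]
    vif: dict[str, float]
    coefficients: dict[str, float]
    cv_r2: float
    cv_rmse: float
    r2_train: float
    rmse_train: float
    r2_test: float
    nrmse_test_percent: float
    importance: dict[str, float]
    n_train: int
    n_test: int
    seed: int
    model: FittedModel = field(repr=False, compare=False, default=None)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "outcome",
                "outcome_col",
                "predictors_used",
                "removed_predictors",
                "vif",
                "coefficients",
                "cv_r2",
                "cv_rmse",
                "r2_train",
                "rmse_train",
                "r2_test",
                "nrmse_test_percent",
                "importance",
                "n_train",
                "n_test",
                "seed",
            )
        }
        d["vif"] = {k: (None if np.isinf(v) else v) for k, v in d["vif"].items()}
        d["removed_predictors"] = {
            k: (None if np.isinf(v) else v)
            for k, v in d["removed_predictors"].items()
        }
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def fit_importance_model(
    profiles: pd.DataFrame, spec: ModelSpec
) -> ModelReport:
    """Run the full importance pipeline for one outcome.

    Split, VIF-filter on the training design, cross-validate, final OLS
    fit, held-out evaluation, scaled-|t| importance.  Athletes with any
    missing value among outcome or predictors are dropped first.
    """
    outcome_col = OUTCOME_COLUMNS[spec.outcome]
    cols = [outcome_col, *spec.predictors]
    data = profiles.dropna(subset=cols).reset_index(drop=True)
    dropped = len(profiles) - len(data)
    if dropped:
        logger.info("dropping %d athletes with incomplete profiles", dropped)
    train, test = split_train_test(data, spec.split_fraction, spec.seed)
    retained, vifs, removed = vif_filter(
        train[list(spec.predictors)], spec.vif_threshold
    )
    fitted = cv_linear_fit(
        train,
        outcome_col,
        retained,
        cv_folds=spec.cv_folds,
        cv_repeats=spec.cv_repeats,
        seed=spec.seed,
    )
    r2_test, nrmse = evaluate_test(fitted, test, nrmse_norm=spec.nrmse_norm)
    coef = {"intercept": float(fitted.results.params[0])}
    coef.update(
        {p: float(c) for p, c in zip(retained, fitted.results.params[1:])}
    )
    return ModelReport(
        outcome=spec.outcome,
        outcome_col=outcome_col,
        predictors_used=list(retained),
        removed_predictors=removed,
        vif=vifs,
        coefficients=coef,
        cv_r2=fitted.cv_r2,
        cv_rmse=fitted.cv_rmse,
        r2_train=fitted.r2_train,
        rmse_train=fitted.rmse_train,
        r2_test=r2_test,
        nrmse_test_percent=nrmse,
        importance=variable_importance(fitted),
        n_train=len(train),
        n_test=len(test),
        seed=spec.seed,
        model=fitted,
    )


def residual_density(
    model: FittedModel, train: pd.DataFrame, path: str | None = None
):
    """Residual-normality diagnostic: a density plot of final-fit residuals."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = train[model.outcome_col].to_numpy(float)
    resid = y - model.predict(train)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    from scipy import stats as sps

    grid = np.linspace(resid.min() - resid.std(), resid.max() + resid.std(), 200)
    kde = sps.gaussian_kde(resid)
    ax.plot(grid, kde(grid))
    ax.set_xlabel("residual")
    ax.set_ylabel("density")
    ax.set_title(f"Residual density ({model.outcome_col})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
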