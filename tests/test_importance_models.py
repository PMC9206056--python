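"""Train/test splitting, VIF filtering, CV linear fits, importance scores."""

import numpy as np
import pandas as pd
import pytest

import somnoreg as sr
from somnoreg.importance_models import (
    DEFAULT_PREDICTORS,
    ModelSpec,
    cv_linear_fit,
    evaluate_test,
    fit_importance_model,
    variable_importance,
)


def make_frame(n=100, seed=0, noise=0.5):
    """Profiles-shaped frame where TST is driven by offset minus onset."""
    rng = np.random.default_rng(seed)
    onset = rng.normal(680, 40, n)
    offset = rng.normal(1240, 45, n)
    df = pd.DataFrame(
        {
            "sri": rng.normal(85, 5, n),
            "med_onset_min": onset,
            "med_offset_min": offset,
            "med_midpoint_min": (onset + offset) / 2,
            "mad_onset_min": rng.gamma(2, 10, n),
            "mad_offset_min": rng.gamma(2, 10, n),
            "var_onset_min": rng.gamma(2, 15, n),
            "var_offset_min": rng.gamma(2, 15, n),
            "med_bedtime_min": onset - rng.exponential(6, n),
            "med_eff_pct": rng.normal(86, 4, n),
        }
    )
    df["med_tst_h"] = (offset - onset) / 60.0 + rng.normal(0, noise, n)
    return df


@pytest.mark.parametrize("n, n_train", [(100, 80), (10, 8), (47, 38)])
def test_split_sizes(n, n_train):
    df = make_frame(n)
    train, test = sr.split_train_test(df, 0.8, seed=0)
    assert len(train) == n_train and len(test) == n - n_train


def test_split_is_disjoint_exhaustive_and_deterministic():
    df = make_frame(60).reset_index().rename(columns={"index": "rid"})
    t1, s1 = sr.split_train_test(df, 0.8, seed=3)
    t2, s2 = sr.split_train_test(df, 0.8, seed=3)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(s1, s2)
    assert set(t1["rid"]).isdisjoint(s1["rid"])
    assert set(t1["rid"]) | set(s1["rid"]) == set(df["rid"])


def test_split_needs_ten_athletes():
    with pytest.raises(ValueError, match="10"):
        sr.split_train_test(make_frame(9), 0.8, seed=0)


def test_orthogonal_predictors_all_survive():
    rng = np.random.default_rng(1)
    raw = rng.normal(size=(50, 3))
    q, _ = np.linalg.qr(raw - raw.mean(0))
    design = pd.DataFrame(q, columns=["a", "b", "c"])
    retained, vifs, removed = sr.vif_filter(design, threshold=10)
    assert retained == ["a", "b", "c"] and not removed
    assert all(v == pytest.approx(1.0, abs=1e-6) for v in vifs.values())


def test_duplicated_column_removed_with_infinite_vif():
    rng = np.random.default_rng(2)
    x = rng.normal(size=40)
    design = pd.DataFrame(
        {"a": x, "a_copy": x, "b": rng.normal(size=40)}
    )
    retained, _, removed = sr.vif_filter(design, threshold=10)
    assert "b" in retained and len(retained) == 2
    assert len(removed) == 1 and np.isinf(list(removed.values())[0])


def test_vif_values_match_statsmodels_oracle():
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    rng = np.random.default_rng(3)
    z = rng.normal(size=60)
    design = pd.DataFrame(
        {
            "a": z + rng.normal(0, 0.8, 60),
            "b": z + rng.normal(0, 0.8, 60),
            "c": rng.normal(size=60),
        }
    )
    retained, vifs, removed = sr.vif_filter(design, threshold=10)
    assert not removed  # correlated but below threshold
    X = np.column_stack([np.ones(60), design[retained].to_numpy()])
    for k, name in enumerate(retained):
        assert vifs[name] == pytest.approx(
            variance_inflation_factor(X, k + 1), rel=1e-8
        )


def test_vif_filter_independent_of_column_order():
    df = make_frame(80, seed=4)
    cols = list(DEFAULT_PREDICTORS["total_sleep_time"])
    a = sr.vif_filter(df[cols], 10)
    b = sr.vif_filter(df[cols[::-1]], 10)
    assert a[0] == b[0] and a[2] == b[2]


def test_vif_contract_errors():
    df = make_frame(20)
    with pytest.raises(ValueError, match="2 predictors"):
        sr.vif_filter(df[["sri"]])
    with pytest.raises(ValueError, match="rows"):
        sr.vif_filter(df[:5][["sri", "med_onset_min", "med_offset_min",
                              "med_midpoint_min", "mad_onset_min",
                              "mad_offset_min"]])


def test_noiseless_linear_outcome_gives_perfect_cv():
    df = make_frame(60, noise=0.0)
    df["y"] = 2.0 * df["sri"] + 1.0
    fitted = cv_linear_fit(df, "y", ["sri"], seed=0)
    assert fitted.cv_r2 == pytest.approx(1.0)
    assert fitted.cv_rmse == pytest.approx(0.0, abs=1e-8)


def test_independent_outcome_gives_near_zero_cv_r2():
    rng = np.random.default_rng(5)
    df = make_frame(200, seed=5)
    df["y"] = rng.normal(size=200)  # unrelated to every predictor
    fitted = cv_linear_fit(df, "y", ["sri", "mad_onset_min"], seed=0)
    assert abs(fitted.cv_r2) <= 0.1


def test_final_coefficients_match_normal_equations():
    X = np.array(
        [[1.0, 2.0, 0.5], [0.0, 1.0, 1.5], [3.0, 0.0, 2.0],
         [1.5, 1.0, 0.0], [2.0, 2.5, 1.0]]
    )
    y = np.array([1.0, 0.5, 2.5, 1.2, 2.2])
    df = pd.DataFrame(X, columns=["a", "b", "c"])
    df["y"] = y
    fitted = cv_linear_fit(df, "y", ["a", "b", "c"], cv_folds=2, cv_repeats=1)
    D = np.column_stack([np.ones(5), X])
    beta = np.linalg.solve(D.T @ D, D.T @ y)
    np.testing.assert_allclose(np.asarray(fitted.results.params), beta, rtol=1e-8)


def test_perfect_and_mean_prediction_metrics():
    df = make_frame(50, noise=0.0)
    df["y"] = 3.0 + 0.1 * df["med_offset_min"]
    fitted = cv_linear_fit(df, "y", ["med_offset_min"], cv_folds=5, cv_repeats=1)
    r2, nrmse = evaluate_test(fitted, df)
    assert r2 == pytest.approx(1.0) and nrmse == pytest.approx(0.0, abs=1e-6)

    class MeanModel:
        outcome_col = "y"

        def predict(self, frame):
            return np.full(len(frame), df["y"].mean())

    r2_mean, _ = evaluate_test(MeanModel(), df)
    assert r2_mean == pytest.approx(0.0, abs=1e-12)


def test_nrmse_normalisers():
    df = make_frame(30, seed=6)
    df["y"] = df["sri"] + np.random.default_rng(6).normal(0, 2, 30)
    fitted = cv_linear_fit(df, "y", ["sri"], cv_folds=3, cv_repeats=1)
    y = df["y"].to_numpy()
    resid = y - fitted.predict(df)
    rmse = np.sqrt(np.mean(resid**2))
    _, by_range = evaluate_test(fitted, df, nrmse_norm="range")
    _, by_mean = evaluate_test(fitted, df, nrmse_norm="mean")
    assert by_range == pytest.approx(100 * rmse / (y.max() - y.min()))
    assert by_mean == pytest.approx(100 * rmse / abs(y.mean()))


def test_constant_test_outcome_rejected():
    df = make_frame(20)
    df["y"] = df["sri"]
    fitted = cv_linear_fit(df, "y", ["sri"], cv_folds=2, cv_repeats=1)
    flat = df.copy()
    flat["y"] = 5.0
    with pytest.raises(ValueError, match="constant"):
        evaluate_test(fitted, flat)


def test_importance_scaling():
    df = make_frame(100, seed=7)
    rng = np.random.default_rng(7)
    df["y"] = df["med_offset_min"] * 0.05 + rng.normal(0, 0.3, 100)
    single = cv_linear_fit(df, "y", ["med_offset_min"], cv_folds=3, cv_repeats=1)
    assert variable_importance(single) == {"med_offset_min": 100.0}
    multi = cv_linear_fit(
        df, "y", ["med_offset_min", "sri", "mad_onset_min"],
        cv_folds=3, cv_repeats=1,
    )
    imp = variable_importance(multi)
    assert max(imp.values()) == 100.0 and min(imp.values()) == 0.0
    assert imp["med_offset_min"] == 100.0  # signal dwarfs the noise terms


def test_pipeline_report_is_deterministic(small_profiles):
    spec = ModelSpec(outcome="total_sleep_time", seed=9, cv_repeats=2)
    r1 = fit_importance_model(small_profiles, spec)
    r2 = fit_importance_model(small_profiles, spec)
    assert r1.to_dict() == r2.to_dict()


def test_outcome_cannot_be_a_predictor():
    with pytest.raises(ValueError, match="outcome"):
        ModelSpec(outcome="total_sleep_time",
                  predictors=("sri", "med_tst_h"))
    with pytest.raises(ValueError, match="outcome"):
        ModelSpec(outcome="nonsense")
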