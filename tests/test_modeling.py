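import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats
from sklearn.metrics import mean_absolute_error, r2_score

from predba.modeling import (
    StackParams,
    fit_stack,
    greedy_select,
    load_model,
    loocv_evaluate,
    mae,
    pearson_r,
    r2,
    rank_features,
    ridge_loo_pearson,
    save_model,
)
from predba.synthetic import SyntheticTableSpec, make_synthetic_table

FAST = StackParams(
    gbrt_n_estimators=30, ada_n_estimators=15, bag_n_estimators=15,
    meta_n_estimators=30,
)


# --- metrics -----------------------------------------------------------------

def test_pearson_examples():
    assert pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
    assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)


def test_pearson_flags_degenerate_input():
    with pytest.raises(ValueError):
        pearson_r([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        pearson_r([1, 2], [1, 2])


def test_mae_and_r2_examples():
    assert mae([0, 2], [1, 1]) == pytest.approx(1.0)
    assert mae([1, 2, 3], [1, 2, 3]) == 0.0
    assert r2([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    actual = np.array([1.0, 2.0, 3.0, 6.0])
    assert r2(actual, np.full(4, actual.mean())) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        mae([1, 2], [1, 2, 3])


def test_metrics_match_independent_implementations():
    rng = np.random.default_rng(42)
    for _ in range(50):
        a = rng.normal(size=25)
        b = a + rng.normal(scale=0.5, size=25)
        assert pearson_r(a, b) == pytest.approx(scipy_stats.pearsonr(a, b)[0], abs=1e-12)
        assert mae(a, b) == pytest.approx(mean_absolute_error(a, b), abs=1e-12)
        assert r2(a, b) == pytest.approx(r2_score(a, b), abs=1e-12)


# --- ranking -----------------------------------------------------------------

def _table(n=30, p=12, seed=0):
    spec = SyntheticTableSpec(n_rows=n, n_features=p, noise_sd=0.1, seed=seed)
    return make_synthetic_table(spec)


def test_exact_copy_feature_ranks_first():
    table, y, _ = _table()
    table = table.copy()
    table["xix_count"] = y  # perfect-copy column
    ranked = rank_features(table, y)
    assert ranked[0][0] == "xix_count"
    assert ranked[0][1] == pytest.approx(1.0)


def test_constant_and_missing_features_excluded():
    table, y, _ = _table()
    table = table.copy()
    table["xix_count"] = 3.14
    table["xx_count"] = np.where(np.arange(len(table)) == 0, np.nan, 1.0)
    names = [n for n, _ in rank_features(table, y, top=len(table.columns))]
    assert "xix_count" not in names
    assert "xx_count" not in names


def test_planted_correlation_ordering():
    rng = np.random.default_rng(3)
    n = 400
    y = rng.normal(size=n)
    cols = {}
    planted = [("f_strong", 0.9), ("f_mid", 0.5), ("f_weak", 0.1)]
    for name, rho in planted:
        cols[name] = rho * y + np.sqrt(1 - rho**2) * rng.normal(size=n)
    for k in range(9):
        cols[f"noise{k}"] = rng.normal(size=n)
    table = pd.DataFrame(cols)
    ranked = [n for n, _ in rank_features(table, y, top=3)]
    assert ranked == ["f_strong", "f_mid", "f_weak"]
    # scores agree with a direct correlation evaluation
    for name, score in rank_features(table, y, top=3):
        assert score == pytest.approx(abs(pearson_r(table[name], y)), abs=1e-12)


def test_rank_needs_three_rows():
    table, y, _ = _table()
    with pytest.raises(ValueError):
        rank_features(table.iloc[:2], y[:2])


# --- greedy selection ---------------------------------------------------------

def test_greedy_recovers_single_planted_feature():
    spec = SyntheticTableSpec(
        n_rows=40, n_features=10, informative_weights=(1.0,), noise_sd=1e-9, seed=1
    )
    table, y, truth = make_synthetic_table(spec)
    result = greedy_select(table, y)
    assert result.selected == list(truth.informative)


def test_greedy_recovers_two_planted_features_first():
    spec = SyntheticTableSpec(
        n_rows=50, n_features=10, informative_weights=(1.0, 1.0), noise_sd=0.05, seed=2
    )
    table, y, truth = make_synthetic_table(spec)
    result = greedy_select(table, y)
    assert set(result.selected[:2]) == set(truth.informative)


def test_pure_noise_selects_at_most_one():
    rng = np.random.default_rng(9)
    table = pd.DataFrame(
        rng.normal(size=(40, 8)), columns=[f"noise{k}" for k in range(8)]
    )
    y = rng.normal(size=40)
    result = greedy_select(table, y, epsilon=0.5)
    assert len(result.selected) <= 1


def test_objective_trace_strictly_increasing():
    table, y, _ = _table(seed=5)
    result = greedy_select(table, y)
    trace = result.objective_trace
    assert all(b > a for a, b in zip(trace, trace[1:]))
    assert len(result.selected) <= 5
    assert set(result.selected) <= {n for n, _ in result.ranked}


def test_ridge_loo_rejects_constant_feature():
    y = np.arange(10.0)
    with pytest.raises(ValueError):
        ridge_loo_pearson(np.ones((10, 1)), y)


# --- stacking ----------------------------------------------------------------

def test_constant_target_reproduced():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(12, 3))
    y = np.full(12, 4.25)
    model = fit_stack(X, y, seed=0, params=FAST)
    assert np.allclose(model.predict(X), 4.25, atol=1e-6)


def test_same_seed_identical_predictions():
    table, y, _ = _table(n=25, seed=8)
    sel = ["protein_mass", "hbond_count"]
    m1 = fit_stack(table, y, selected=sel, seed=11, params=FAST)
    m2 = fit_stack(table, y, selected=sel, seed=11, params=FAST)
    assert np.array_equal(m1.predict(table), m2.predict(table))


def test_small_n_rejected():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="at least 5"):
        fit_stack(rng.normal(size=(4, 2)), rng.normal(size=4))


def test_missing_selected_column_named():
    table, y, _ = _table(n=20)
    model = fit_stack(table, y, selected=["protein_mass"], seed=0, params=FAST)
    with pytest.raises(KeyError, match="protein_mass"):
        model.predict(table.drop(columns=["protein_mass"]))


def test_model_save_load_roundtrip(tmp_path):
    table, y, _ = _table(n=20)
    model = fit_stack(table, y, selected=["protein_mass"], seed=0, params=FAST)
    path = tmp_path / "model.joblib"
    save_model(model, path)
    loaded = load_model(path)
    assert loaded.selected_features == ["protein_mass"]
    assert np.array_equal(loaded.predict(table), model.predict(table))


def test_oof_stack_not_much_worse_than_worst_base():
    # regression guard on the synthetic recovery data
    from sklearn.model_selection import KFold

    table, y, _ = _table(n=30, seed=12)
    sel = ["protein_mass", "hbond_count"]
    X = table[sel].to_numpy()

    def oof_r(fit_predict):
        preds = np.empty(len(y))
        for train, test in KFold(5, shuffle=True, random_state=0).split(X):
            preds[test] = fit_predict(X[train], y[train], X[test])
        return pearson_r(y, preds)

    def stack_fp(Xtr, ytr, Xte):
        return fit_stack(Xtr, ytr, seed=3, params=FAST).predict(Xte)

    from predba.modeling import _make_base_models

    base_rs = []
    for name in ("GBRT", "AdaR", "BagR"):
        def base_fp(Xtr, ytr, Xte, _name=name):
            m = _make_base_models(FAST, 3)[_name]
            m.fit(Xtr, ytr)
            return m.predict(Xte)
        base_rs.append(oof_r(base_fp))
    assert oof_r(stack_fp) >= min(base_rs) - 0.05


# --- LOOCV -------------------------------------------------------------------

def test_honest_loocv_recovers_planted_signal():
    spec = SyntheticTableSpec(
        n_rows=25, n_features=12, informative_weights=(2.0, 1.0, 0.5),
        noise_sd=0.1, seed=4,
    )
    table, y, _ = make_synthetic_table(spec)
    report = loocv_evaluate(table, y, mode="honest", seed=4, params=FAST)
    assert report.r >= 0.8
    assert report.n == 25
    assert len(report.pairs) == 25


def test_paper_mode_equals_naive_double_loop():
    spec = SyntheticTableSpec(n_rows=8, n_features=6, noise_sd=0.2, seed=6)
    table, y, _ = make_synthetic_table(spec)
    sel = list(table.columns[:2])
    report = loocv_evaluate(
        table, y, mode="paper", selected=sel, seed=6, params=FAST
    )
    # independent naive LOO loop
    preds = np.empty(8)
    for i in range(8):
        rest = [k for k in range(8) if k != i]
        model = fit_stack(
            table.iloc[rest], y[np.array(rest)], selected=sel, seed=6, params=FAST
        )
        preds[i] = model.predict(table.iloc[[i]])[0]
    got = np.array([p[2] for p in report.pairs])
    assert np.array_equal(got, preds)
    assert [p[0] for p in report.pairs] == list(table.index)


def test_loocv_needs_six_rows():
    table, y, _ = _table(n=5)
    with pytest.raises(ValueError, match="at least 6"):
        loocv_evaluate(table.iloc[:5], y[:5])


def test_loocv_report_json_deterministic():
    spec = SyntheticTableSpec(n_rows=10, n_features=6, noise_sd=0.2, seed=13)
    table, y, _ = make_synthetic_table(spec)
    r1 = loocv_evaluate(table, y, mode="paper", selected=list(table.columns[:2]),
                        seed=13, params=FAST)
    r2_ = loocv_evaluate(table, y, mode="paper", selected=list(table.columns[:2]),
                         seed=13, params=FAST)
    assert r1.to_json() == r2_.to_json()


def test_paper_mode_uses_class_preset():
    from predba.catalogue import PAPER_FEATURE_SETS

    spec = SyntheticTableSpec(n_rows=10, n_features=52, noise_sd=0.2, seed=14)
    table, y, _ = make_synthetic_table(spec)
    report = loocv_evaluate(table, y, mode="paper", class_label="SS", seed=0, params=FAST)
    assert report.selections[0] == PAPER_FEATURE_SETS["SS"]
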