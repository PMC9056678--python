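"""Model objects: spec serialization, fitting, grid search, baselines and
external evaluation."""

import numpy as np
import pandas as pd
import pytest

from econfqspr.models import (
    FeaturizedSplit,
    ModelSpec,
    NeuralQSPR,
    evaluate_external,
    grid_search_cv,
    train_baseline,
)


def test_model_spec_round_trips_through_json():
    spec = ModelSpec(
        hidden=((97, True), (24, True)),
        activation="relu",
        optimizer="rmsprop",
        l2_lambda=0.001,
        dropout=0.03,
        epochs=500,
    )
    assert ModelSpec.from_json(spec.to_json()) == spec
    assert "97, bN" in spec.label()


@pytest.mark.parametrize(
    "kwargs",
    [
        {"hidden": ()},
        {"hidden": ((0, True),)},
        {"hidden": ((8, True),), "activation": "gelu"},
        {"hidden": ((8, True),), "optimizer": "sgd"},
        {"hidden": ((8, True),), "dropout": 1.0},
        {"hidden": ((8, True),), "l2_lambda": -1.0},
        {"hidden": ((8, True),), "epochs": 0},
    ],
)
def test_model_spec_validation(kwargs):
    with pytest.raises(ValueError):
        ModelSpec(**kwargs)


def test_single_layer_tanh_rmsprop_trains_without_error(small_featurized):
    """The melting-point-style configuration (wide bN layer, tanh, RMSprop,
    strong weight decay, light dropout) must train cleanly."""
    f = small_featurized
    spec = ModelSpec(
        hidden=((len(f.kept_columns), True),),
        activation="tanh",
        optimizer="rmsprop",
        l2_lambda=0.1,
        dropout=0.01,
        epochs=60,
    )
    res = NeuralQSPR(f.y_train, f.X_train, spec).fit(seed=0)
    assert np.isfinite(res.predict(f.X_test)).all()
    assert "Neural QSPR" in res.summary()


def test_fit_is_reproducible_and_inference_deterministic(small_featurized):
    f = small_featurized
    spec = ModelSpec(hidden=((12, True),), epochs=30)
    r1 = NeuralQSPR(f.y_train, f.X_train, spec).fit(seed=9)
    r2 = NeuralQSPR(f.y_train, f.X_train, spec).fit(seed=9)
    np.testing.assert_array_equal(r1.predict(f.X_test), r2.predict(f.X_test))
    np.testing.assert_array_equal(r1.predict(f.X_test), r1.predict(f.X_test))


def test_predict_aligns_and_rejects_mismatched_columns(small_featurized):
    f = small_featurized
    res = NeuralQSPR(
        f.y_train, f.X_train, ModelSpec(hidden=((8, True),), epochs=10)
    ).fit(seed=0)
    shuffled = f.X_test[list(reversed(f.X_test.columns))]
    np.testing.assert_allclose(res.predict(shuffled), res.predict(f.X_test))
    with pytest.raises(ValueError):
        res.predict(f.X_test.iloc[:, :-2])


def test_from_dataframe_builds_and_fits(small_table):
    table, _ = small_table
    spec = ModelSpec(hidden=((16, True),), epochs=20)
    model = NeuralQSPR.from_dataframe(table, spec)
    res = model.fit(seed=0)
    assert len(res.fittedvalues) == len(table)


def test_grid_search_identity_and_partition_reuse(small_featurized):
    f = small_featurized
    lone = ModelSpec(hidden=((8, True),), epochs=500)
    out = grid_search_cv([lone], f.X_train, f.y_train, folds=3, seed=0, cv_epochs=20)
    assert len(out) == 1 and out[0].spec == lone
    assert len(out[0].fold_reports) == 3
    # fold partitions do not depend on the order of the space
    a = ModelSpec(hidden=((8, True),), epochs=500)
    b = ModelSpec(hidden=((4, False),), activation="sigmoid", epochs=500)
    r_ab = grid_search_cv([a, b], f.X_train, f.y_train, folds=3, seed=0, cv_epochs=20)
    r_ba = grid_search_cv([b, a], f.X_train, f.y_train, folds=3, seed=0, cv_epochs=20)
    means_ab = {r.spec: r.mae_mean for r in r_ab}
    means_ba = {r.spec: r.mae_mean for r in r_ba}
    assert means_ab == means_ba


def test_grid_search_ranks_dominating_spec_first(small_featurized):
    f = small_featurized
    strong = ModelSpec(hidden=((len(f.kept_columns), True),), activation="relu",
                       epochs=500)
    crippled = ModelSpec(hidden=((1, False),), activation="sigmoid",
                         l2_lambda=10.0, dropout=0.5, epochs=500)
    out = grid_search_cv(
        [crippled, strong], f.X_train, f.y_train, folds=3, seed=0, cv_epochs=120
    )
    assert out[0].spec == strong
    assert out[0].mae_mean < out[1].mae_mean


def test_grid_search_validation(small_featurized):
    f = small_featurized
    with pytest.raises(ValueError):
        grid_search_cv([], f.X_train, f.y_train)
    with pytest.raises(ValueError):
        grid_search_cv(
            [ModelSpec(hidden=((4, True),))], f.X_train, f.y_train, folds=10_000
        )


def test_baselines_contract(small_featurized):
    f = small_featurized
    rfr1 = train_baseline("RFR", {"tree": 30}, f.X_train, f.y_train, seed=0)
    rfr2 = train_baseline("RFR", {"tree": 30}, f.X_train, f.y_train, seed=0)
    np.testing.assert_array_equal(rfr1.predict(f.X_test), rfr2.predict(f.X_test))

    # an epsilon tube wider than the response range fits nothing
    y = f.y_train - f.y_train.mean()
    svm = train_baseline(
        "SVM", {"gamma": "auto", "C": 10.0, "epsilon": 2 * np.abs(y).max()},
        f.X_train, y,
    )
    assert np.ptp(svm.predict(f.X_test)) < 1e-6

    with pytest.raises(ValueError):
        train_baseline("GBM", {}, f.X_train, f.y_train)


def test_evaluate_external_reports_per_partition_ranges(small_featurized):
    f = small_featurized

    class Oracle:  # predicts perfectly on both partitions
        def predict(self, X):
            key = tuple(np.asarray(X).shape)
            return {
                tuple(np.asarray(f.X_train).shape): f.y_train,
                tuple(np.asarray(f.X_test).shape): f.y_test,
            }[key]

    rep = evaluate_external(Oracle(), f)
    assert rep["test"].r_squared == pytest.approx(1.0)
    assert rep["test"].mae == 0.0
    assert rep["test"].spearman == pytest.approx(1.0)
    assert rep["train_range"] == (float(f.y_train.min()), float(f.y_train.max()))
    assert rep["test_range"] == (float(f.y_test.min()), float(f.y_test.max()))

    empty = FeaturizedSplit(
        X_train=f.X_train, y_train=f.y_train,
        X_test=f.X_test.iloc[:0], y_test=f.y_test[:0],
        kept_columns=f.kept_columns,
    )
    with pytest.raises(ValueError):
        evaluate_external(Oracle(), empty)


def test_prune_on_train_only_aligns_test_columns(small_table):
    from econfqspr.data import split_dataset

    table, _ = small_table
    split = split_dataset(table, ratio=0.2, seed=1)
    f_all = FeaturizedSplit.from_split(split, prune_on="all")
    f_tr = FeaturizedSplit.from_split(split, prune_on="train")
    assert list(f_tr.X_test.columns) == f_tr.kept_columns
    # a bit varying within train varies within train+test a fortiori
    assert set(f_tr.kept_columns) <= set(f_all.kept_columns)
    with pytest.raises(ValueError):
        FeaturizedSplit.from_split(split, prune_on="both")
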