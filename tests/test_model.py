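"""Grid search, two-level training, prediction flow, and persistence."""

import numpy as np
import pytest

from nrpred.encoding import PhysChemEncoder
from nrpred.exceptions import BatchTooLarge, ModelMismatch, NrpredError, TooFewSamples
from nrpred.model import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    GridSearchResult,
    ModelConfig,
    TwoLevelNRClassifier,
    grid_search,
    load_model,
    predict,
    save_model,
    train,
)
from nrpred.seqio import SUBFAMILIES

SMALL_CFG = ModelConfig(C_grid=(8.0,), gamma_grid=(2.0**-9,), rng_seed=0)


@pytest.fixture(scope="module")
def encoded(small_labeled_dataset):
    enc = PhysChemEncoder().fit()
    X = enc.transform(small_labeled_dataset.sequences)
    y = np.asarray(small_labeled_dataset.labels, dtype=object)
    return X, y


def test_default_grids_are_the_standard_powers_of_two():
    assert DEFAULT_C_GRID[0] == 2.0**-5 and DEFAULT_C_GRID[-1] == 2.0**15
    assert DEFAULT_GAMMA_GRID[0] == 2.0**-15 and DEFAULT_GAMMA_GRID[-1] == 2.0**3
    assert len(DEFAULT_C_GRID) == 11 and len(DEFAULT_GAMMA_GRID) == 10


def test_grid_search_single_point_returns_it(encoded):
    X, y = encoded
    res = grid_search(X, (y != "nonNR").astype(int), SMALL_CFG)
    assert (res.C, res.gamma) == (8.0, 2.0**-9)
    assert 0.0 <= res.cv_accuracy <= 1.0


def test_grid_search_deterministic(encoded):
    X, y = encoded
    cfg = ModelConfig(C_grid=(1.0, 8.0), gamma_grid=(2.0**-9, 2.0**-7), rng_seed=5)
    a = grid_search(X, (y != "nonNR").astype(int), cfg)
    b = grid_search(X, (y != "nonNR").astype(int), cfg)
    assert a == b


def test_grid_search_tie_breaks_to_smaller_c_then_gamma():
    # a linearly separable toy problem where every cell scores 1.0
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(-5, 0.1, (10, 4)), rng.normal(5, 0.1, (10, 4))])
    y = np.array([0] * 10 + [1] * 10)
    cfg = ModelConfig(C_grid=(4.0, 1.0, 16.0), gamma_grid=(0.5, 0.125), rng_seed=0)
    res = grid_search(X, y, cfg)
    assert res.cv_accuracy == 1.0
    assert (res.C, res.gamma) == (1.0, 0.125)


def test_grid_search_reduces_folds_for_small_classes(encoded):
    X, y = encoded
    y1 = (y != "nonNR").astype(int)
    cfg = ModelConfig(C_grid=(8.0,), gamma_grid=(2.0**-9,), cv_folds=12, rng_seed=0)
    with pytest.warns(UserWarning, match="reducing CV folds"):
        res = grid_search(X, y1, cfg)
    assert res.n_folds == 10  # NR side has 10 members


def test_grid_search_rejects_singleton_class(encoded):
    X, y = encoded
    y_bad = y.copy()
    y_bad[:] = "NR1"
    y_bad[0] = "nonNR"
    with pytest.raises(TooFewSamples):
        grid_search(X, y_bad, SMALL_CFG)


def test_classifier_fit_contract(encoded):
    X, y = encoded
    clf = TwoLevelNRClassifier(C_grid=(8.0,), gamma_grid=(2.0**-9,), random_state=0)
    clf.fit(X, y)
    assert clf.level1_search_.C in clf.C_grid
    assert clf.level2_search_.gamma in clf.gamma_grid
    assert clf.subfamilies_ == ("NR1", "NR2")
    preds = clf.predict(X)
    assert set(preds) <= {"nonNR", *SUBFAMILIES}
    labels = clf.predict_labels(X)
    for lab in labels:
        if lab.level1 == "non-NR":
            assert lab.level2 is None
        else:
            assert lab.level2 in SUBFAMILIES


def test_classifier_rejects_degenerate_datasets(encoded):
    X, y = encoded
    clf = TwoLevelNRClassifier(C_grid=(8.0,), gamma_grid=(2.0**-9,))
    with pytest.raises(NrpredError):
        clf.fit(X, np.array(["NR1"] * len(y), dtype=object))  # no non-NR
    with pytest.raises(NrpredError):
        clf.fit(X, np.array(["nonNR"] * len(y), dtype=object))  # no NR
    y_one_sub = y.copy()
    y_one_sub[y_one_sub == "NR2"] = "NR1"
    with pytest.raises(NrpredError):
        clf.fit(X, y_one_sub)  # only one subfamily


def test_level2_ignores_non_nr_rows(encoded):
    """Perturbing non-NR feature rows must not change the level-2 machine."""
    X, y = encoded
    fixed = {
        1: GridSearchResult(8.0, 2.0**-9, 1.0, 5),
        2: GridSearchResult(8.0, 2.0**-9, 1.0, 5),
    }
    nr_mask = y != "nonNR"
    clf_a = TwoLevelNRClassifier().fit(X, y, search=fixed)
    X_perturbed = X.copy()
    X_perturbed[~nr_mask] += 100.0
    clf_b = TwoLevelNRClassifier().fit(X_perturbed, y, search=fixed)
    assert np.array_equal(clf_a.level2_.predict(X[nr_mask]), clf_b.level2_.predict(X[nr_mask]))


def test_retrain_same_seed_is_bit_identical(small_labeled_dataset, encoded):
    X, _ = encoded
    cfg = ModelConfig(C_grid=(1.0, 8.0), gamma_grid=(2.0**-9,), rng_seed=3)
    m1 = train(small_labeled_dataset, cfg)
    m2 = train(small_labeled_dataset, cfg)
    assert m1.level1_params == m2.level1_params
    assert m1.level2_params == m2.level2_params
    assert np.array_equal(m1.classifier.predict(X), m2.classifier.predict(X))


def test_predict_batch_cap_and_per_record_errors(small_labeled_dataset):
    model = train(small_labeled_dataset, SMALL_CFG)
    ok = ["ACDEFGHIKLMNPQRSTVWY"] * 3 + ["ACDE"]  # last one too short
    records = predict(model, ok)
    assert len(records) == 4
    assert records[-1].error is not None and records[-1].label is None
    assert all(r.error is None and r.label is not None for r in records[:3])

    with pytest.raises(BatchTooLarge):
        predict(model, ["ACDEFGHIKLMNPQRSTVWY"] * 501)


def test_model_persistence_round_trip(small_labeled_dataset, tmp_path):
    model = train(small_labeled_dataset, SMALL_CFG)
    path = tmp_path / "model.joblib"
    save_model(model, path)
    back = load_model(path)
    probe = ["ACDEFGHIKLMNPQRSTVWY" * 3]
    assert [str(r.label) for r in predict(back, probe)] == [
        str(r.label) for r in predict(model, probe)
    ]


def test_model_load_refuses_encoder_mismatch(small_labeled_dataset, tmp_path):
    from nrpred.encoding import EncoderConfig

    model = train(small_labeled_dataset, SMALL_CFG)
    path = tmp_path / "model.joblib"
    save_model(model, path)
    with pytest.raises(ModelMismatch):
        load_model(path, encoder_config=EncoderConfig(max_lag=5))
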