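"""SMOTE, the three classifier families, and the repeated-CV protocol."""

import numpy as np
import pytest

from qmerloc import (CNNSpec, MLPSpec, RFSpec, compute_metrics, featurize,
                     grouped_split, repeated_cv, smote_oversample, train_model)
from qmerloc.models import build_cnn


@pytest.fixture(scope="module")
def imbalanced(rng):
    X = rng.normal(size=(100, 6))
    y = np.array([0] * 90 + [1] * 10)
    X[y == 1] += 1.5
    return X, y


class TestSmote:
    def test_balances_and_preserves_originals(self, imbalanced):
        X, y = imbalanced
        X2, y2 = smote_oversample(X, y, seed=0)
        assert np.bincount(y2).tolist() == [90, 90]
        assert np.array_equal(X2[:100], X)

    def test_synthetic_rows_inside_minority_envelope(self, imbalanced):
        X, y = imbalanced
        X2, y2 = smote_oversample(X, y, seed=0)
        synth = X2[100:]
        lo, hi = X[y == 1].min(axis=0), X[y == 1].max(axis=0)
        assert (synth >= lo - 1e-12).all() and (synth <= hi + 1e-12).all()

    def test_deterministic_under_seed(self, imbalanced):
        X, y = imbalanced
        a = smote_oversample(X, y, seed=3)[0]
        b = smote_oversample(X, y, seed=3)[0]
        assert np.array_equal(a, b)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            smote_oversample(X, np.zeros(10, dtype=int))

    def test_tiny_minority_reduces_k_with_warning(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([0] * 17 + [1] * 3)
        with pytest.warns(UserWarning, match="reducing k"):
            X2, y2 = smote_oversample(X, y, seed=0)
        assert np.bincount(y2).tolist() == [17, 17]


@pytest.fixture(scope="module")
def tiny_separable(rng):
    X = rng.random((20, 64))
    y = np.array([0, 1] * 10)
    X[y == 1, 7] += 2.0
    return X, y


@pytest.mark.parametrize("kind", ["rf", "mlp", "cnn1d"])
def test_capacity_on_tiny_separable_fixture(kind, tiny_separable):
    """Each model family can drive training accuracy to 1.0 on 20 rows."""
    X, y = tiny_separable
    model = train_model(kind, X, y, seed=0, epochs=80)
    assert (model.predict(X) == y).mean() == 1.0
    scores = model.scores(X)
    assert ((scores >= 0) & (scores <= 1)).all()
    assert not np.isnan(scores).any()


def test_single_class_training_rejected(rng):
    X = rng.random((10, 4))
    with pytest.raises(ValueError):
        train_model("rf", X, np.ones(10, dtype=int))


def test_rf_uses_100_trees(tiny_separable):
    X, y = tiny_separable
    model = train_model("rf", X, y, seed=0)
    assert len(model.forest.estimators_) == RFSpec().n_trees == 100


def test_cnn_layer_arithmetic_512():
    """512 -> conv3 -> 510 -> pool3 -> 170 -> conv3 -> 168 -> pool3 -> 56."""
    net = build_cnn(512, CNNSpec(), seed=0)
    x = np.random.default_rng(0).random((2, 512))
    shapes = []
    h = x
    for layer in net.layers:
        h = layer.forward(h, training=False)
        shapes.append(h.shape)
    assert (2, 510, 128) in shapes
    assert (2, 170, 128) in shapes
    assert (2, 168, 256) in shapes
    assert (2, 56, 256) in shapes
    assert shapes[-1] == (2, 1)
    out = net.forward(x)
    assert ((out > 0) & (out < 1)).all()


def test_repeated_cv_counts_and_stratification(rng):
    X = rng.normal(size=(200, 8))
    y = np.array([0, 1] * 100)
    X[y == 1, 0] += 1.0
    result = repeated_cv("rf", X, y, seed=0)
    assert len(result.reports) == 10
    assert result.folds == 5 and result.repeats == 2
    for rep in result.reports:
        # stratified folds: class proportions within one sample of global
        assert abs((rep.tp + rep.fn) - (rep.tn + rep.fp)) <= 1
    assert result.std("oa") >= 0


def test_repeated_cv_null_signal():
    """Label-permuted data yields chance-level AUC."""
    rng = np.random.default_rng(55)
    X = rng.normal(size=(200, 8))
    y = rng.permutation(np.array([0, 1] * 100))
    result = repeated_cv("rf", X, y, seed=1)
    assert 0.4 <= result.mean("auc") <= 0.6


def test_repeated_cv_errors_on_sparse_class(rng):
    X = rng.normal(size=(20, 4))
    y = np.array([0] * 17 + [1] * 3)
    with pytest.raises(ValueError):
        repeated_cv("rf", X, y, folds=5)


def test_smote_never_touches_evaluation_fold(rng, monkeypatch):
    """Rows oversampled in a fold never coincide with that fold's test rows."""
    import qmerloc.models as models_mod

    X = rng.normal(size=(60, 4))
    y = np.array([0] * 40 + [1] * 20)
    seen = []
    original = models_mod.smote_oversample

    def spy(Xf, yf, *a, **kw):
        seen.append(np.asarray(Xf))
        return original(Xf, yf, *a, **kw)

    monkeypatch.setattr(models_mod, "smote_oversample", spy)
    models_mod.repeated_cv("rf", X, y, folds=5, repeats=1, seed=0)
    assert len(seen) == 5
    # each SMOTE input has exactly the training-fold size (48 of 60 rows)
    for Xf in seen:
        assert Xf.shape[0] == 48


def test_class_weight_alternative(imbalanced):
    X, y = imbalanced
    result = repeated_cv("rf", X, y, imbalance="class-weight", seed=0,
                         repeats=1)
    assert len(result.reports) == 5
    with pytest.raises(ValueError):
        repeated_cv("rf", X, y, imbalance="bogus")


def test_all_models_beat_majority_baseline():
    """On the planted-motif fixture every family clears 90% held-out accuracy."""
    from qmerloc import (FixtureConfig, generate_annotations,
                         generate_sequences, select_gene_transcripts)

    config = FixtureConfig(seed=3)  # 400 genes, default planted signal
    records, _ = generate_sequences(config)
    genes = select_gene_transcripts(records, generate_annotations(config))
    train, test = grouped_split(genes, 0.2, seed=3)
    fm_tr = featurize(train, "CL1", 3, 1)
    fm_te = featurize(test, "CL1", 3, 1)
    majority = max(np.bincount(fm_te.y)) / len(fm_te.y)
    for kind in ("rf", "mlp", "cnn1d"):
        model = train_model(kind, fm_tr.X, fm_tr.y, seed=3, epochs=60)
        oa = compute_metrics(fm_te.y, model.predict(fm_te.X)).oa
        assert oa >= 0.9
        assert oa > majority
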