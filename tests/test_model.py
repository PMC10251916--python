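import numpy as np
import pytest

from herdsense import model, nn


def test_reference_stack():
    spec = model.reference_model()
    assert len(spec.layers) == 8
    kinds = [ls.kind for ls in spec.layers]
    assert kinds == ["conv1d"] * 3 + ["dropout", "maxpool1d", "flatten",
                                      "dense", "dense"]
    assert spec.layers[0].filters == 128
    assert [ls.filters for ls in spec.layers[:3]] == [128, 64, 32]
    assert all(ls.kernel_size == 3 and ls.padding == "valid"
               and ls.stride == 1 for ls in spec.layers[:3])
    assert spec.layers[3].rate == pytest.approx(0.3)
    assert spec.layers[-1].activation == "softmax"
    assert spec.layers[-1].units == 5


def test_audit_shapes_and_parameter_counts():
    aud = model.audit(model.reference_model())
    assert aud.output_shapes == [(38, 128), (36, 64), (34, 32), (34, 32),
                                 (17, 32), (544,), (100,), (5,)]
    assert aud.param_counts == [5888, 24640, 6176, 0, 0, 0, 54500, 505]
    assert aud.total_params == 91709


def test_audit_agrees_with_built_network_per_layer():
    """The analytic audit and the instantiated weight arrays are two
    independent computations of the same totals."""
    spec = model.reference_model()
    aud = model.audit(spec)
    rng = np.random.default_rng(0)
    net = model.build_network(spec, rng, rng)
    assert [ly.n_params() for ly in net.layers] == aud.param_counts
    assert net.n_params() == aud.total_params
    # output shapes agree too
    x = np.zeros((2, 40, 15), dtype=np.float32)
    for layer, expected in zip(net.layers, aud.output_shapes):
        x = layer.forward(x, train=False)
        assert x.shape[1:] == expected


def test_impossible_architecture_is_rejected():
    bad = model.ModelSpec(layers=(
        model.LayerSpec("conv1d", filters=8, kernel_size=41,
                        activation="relu", name="huge"),
        model.LayerSpec("flatten"),
        model.LayerSpec("dense", units=5, activation="softmax"),
    ))
    with pytest.raises(model.ArchitectureError, match="huge"):
        model.audit(bad)


def test_wrong_output_width_is_rejected(small_split):
    bad = model.ModelSpec(layers=(
        model.LayerSpec("flatten"),
        model.LayerSpec("dense", units=4, activation="softmax"),
    ))
    with pytest.raises(model.ArchitectureError, match="final layer"):
        model.BehaviourCNN(small_split, bad)


def test_zero_epochs_predicts_from_initialization(small_split):
    clf = model.BehaviourCNN(small_split)
    res = clf.fit(model.TrainConfig(epochs=0, seed=0))
    assert len(res.learning_curve) == 0
    probs = res.predict_proba(small_split.X_test[:8])
    assert probs.shape == (8, 5)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_training_is_deterministic_under_seed(small_split):
    clf = model.BehaviourCNN(small_split)
    a = clf.fit(model.TrainConfig(epochs=2, seed=11))
    b = clf.fit(model.TrainConfig(epochs=2, seed=11))
    assert a.learning_curve.equals(b.learning_curve)
    for pa, pb in zip(a.network.parameters(), b.network.parameters()):
        np.testing.assert_array_equal(pa, pb)


def test_separable_data_is_learned(fitted):
    assert fitted.learning_curve.train_acc.iloc[-1] > 0.95


def test_predictions_beat_majority_class(fitted):
    data = fitted.model.data
    majority = max(np.bincount(data.y_test)) / len(data.y_test)
    pred = fitted.predict_proba(data.X_test).argmax(axis=1)
    assert (pred == data.y_test).mean() > majority


def test_probability_contract(fitted):
    X = fitted.model.data.X_test[:5]
    dup = np.concatenate([X, X])
    probs = fitted.predict_proba(dup)
    assert np.all(probs >= 0)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    np.testing.assert_array_equal(probs[:5], probs[5:])


def test_predict_rejects_bad_shape(fitted):
    with pytest.raises(ValueError, match="expected"):
        fitted.predict_proba(np.zeros((3, 39, 15)))


def test_summary_mentions_key_settings(fitted):
    text = fitted.summary()
    assert "91,709" in text
    assert "adam" in text
    assert "categorical_crossentropy" in text


def test_save_round_trip(tmp_path, fitted):
    fitted.save(tmp_path / "weights")
    import json
    sidecar = json.loads((tmp_path / "weights.json").read_text())
    assert sidecar["total_params"] == 91709
    with np.load(tmp_path / "weights.npz") as z:
        total = sum(z[k].size for k in z.files)
    assert total == 91709
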