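import numpy as np
import pytest

from dbrmeta import (
    FeatureConfig,
    Label,
    ModelConfig,
    TrackSimConfig,
    SimConfig,
    ablate,
    auc,
    binary_labels,
    build_model,
    build_profiles,
    calibrate,
    compute_roc,
    fit_meta_predictor,
    generate_dataset,
    load_model,
    predict,
    save_model,
    simulate_tracks,
    train,
)
from dbrmeta import nn


def small_labeled_dataset(seed=0, oracle_shift=6.0):
    """Tiny dataset whose first track is nearly the label itself."""
    ds = generate_dataset(SimConfig(
        n_dna_proteins=10, n_other_proteins=5, length_median=60,
        length_sigma=0.2, dbr_fraction=0.08, structure_fraction=0.5, seed=seed,
    ))
    simulate_tracks(ds, [
        TrackSimConfig("diso_a", d_struct=oracle_shift, d_dis=oracle_shift),
        TrackSimConfig("struct_a", d_struct=0.5, d_dis=0.5),
        TrackSimConfig("struct_b", d_struct=0.5, d_dis=0.5),
    ], seed=seed + 1)
    ids = sorted(ds.proteins)
    split = {"train": ids[0::3] + ids[2::3], "val": ids[1::3]}
    return ds, split


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------


def test_build_deterministic_from_seed():
    cfg = ModelConfig(seed=3)
    w1 = build_model(cfg, 170).get_weights()
    w2 = build_model(cfg, 170).get_weights()
    for a, b in zip(w1, w2):
        np.testing.assert_array_equal(a, b)


def test_parameter_count_closed_form():
    cfg = ModelConfig()
    net = build_model(cfg, 170)
    d, h, f = cfg.d_model, cfg.n_heads, cfg.ff_hidden
    proj = 170 * d + d
    per_block = 4 * (d * d + d) + (d * f + f) + (f * d + d) + 2 * d
    head = sum(
        i * o + o for i, o in zip(cfg.head_dims[:-1], cfg.head_dims[1:])
    )
    assert net.n_parameters() == proj + cfg.n_blocks * per_block + head


def test_no_transformer_reduces_to_projection_and_head():
    net = build_model(ModelConfig(n_blocks=0), 30)
    assert len(net.blocks) == 0
    x = np.random.default_rng(0).random((1, 8, 30))
    out = net.forward(x, np.ones((1, 8), bool))
    assert out.shape == (1, 8)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        ModelConfig(n_heads=3)  # 20 not divisible by 3
    with pytest.raises(ValueError):
        ModelConfig(head_dims=(16, 8, 1))
    with pytest.raises(ValueError):
        ModelConfig(loss="hinge")


def test_gradients_match_finite_differences(monkeypatch):
    monkeypatch.setattr(nn, "DTYPE", np.float64)
    rng = np.random.default_rng(0)
    net = nn.Network(n_features=6, d_model=4, n_blocks=1, n_heads=2,
                     ff_hidden=8, head_dims=(4, 2, 1), seed=1)
    x = rng.random((2, 5, 6))
    y = (rng.random((2, 5)) < 0.5).astype(float)
    mask = np.ones((2, 5), bool)
    mask[1, 3:] = False  # include padding in the check

    def loss_value():
        return nn.masked_loss_and_grad(net.forward(x, mask), y, mask)[0]

    _, dlogits = nn.masked_loss_and_grad(net.forward(x, mask), y, mask)
    net.backward(dlogits)
    eps = 1e-6
    for layer in (net.proj, net.blocks[0].attn, net.blocks[0].norm,
                  net.head[0]):
        for name, p in layer.params.items():
            flat = p.ravel()
            idx = rng.integers(0, flat.size, size=min(4, flat.size))
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                up = loss_value()
                flat[i] = orig - eps
                down = loss_value()
                flat[i] = orig
                numeric = (up - down) / (2 * eps)
                analytic = layer.grads[name].ravel()[i]
                assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-9)


def test_initial_bce_near_chance_on_balanced_data():
    net = build_model(ModelConfig(), 170)
    rng = np.random.default_rng(0)
    x = rng.random((2, 40, 170))
    y = np.tile([0.0, 1.0], 40).reshape(2, 40)
    mask = np.ones((2, 40), bool)
    loss, _ = nn.masked_loss_and_grad(net.forward(x, mask), y, mask)
    assert loss == pytest.approx(np.log(2), abs=0.1)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _quick_config(**kw):
    base = dict(batch_size=8, max_epochs=15, patience=15, seed=0)
    base.update(kw)
    return ModelConfig(**base)


def test_training_reproducible_and_loss_decreases():
    ds, split = small_labeled_dataset()
    logs = []
    for _ in range(2):
        trained, _ = fit_meta_predictor(ds, split, _quick_config())
        logs.append(trained.training_log)
    assert logs[0] == logs[1]
    losses = [e["train_loss"] for e in logs[0]]
    assert losses[-1] < losses[0]


def test_learns_oracle_track_quickly():
    """With a near-label input track, held-out AUC should exceed 0.95."""
    ds, split = small_labeled_dataset()
    trained, profiles = fit_meta_predictor(
        ds, split, _quick_config(batch_size=2, max_epochs=40, patience=40)
    )
    val = {p: profiles[p] for p in split["val"]}
    preds = predict(trained, val)
    scores = np.concatenate([preds[p].propensities for p in sorted(val)])
    labels = ds.pooled_labels(sorted(val))
    assert auc(compute_roc(labels, scores)) > 0.95


def test_train_rejects_single_class_and_overlap():
    ds, split = small_labeled_dataset()
    profiles = build_profiles(ds)
    labels = {pid: np.zeros(len(ds.proteins[pid])) for pid in ds.proteins}
    pick = lambda part: {p: profiles[p] for p in split[part]}
    net = build_model(_quick_config(), 170)
    with pytest.raises(ValueError, match="one class"):
        train(net, pick("train"), labels, pick("val"), labels, _quick_config())
    with pytest.raises(ValueError, match="both train and val"):
        train(net, pick("train"), labels, pick("train"), labels, _quick_config())


# ---------------------------------------------------------------------------
# inference and calibration
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def trained_small():
    ds, split = small_labeled_dataset()
    trained, profiles = fit_meta_predictor(
        ds, split, ModelConfig(batch_size=8, max_epochs=10, patience=10, seed=1)
    )
    return ds, split, trained, profiles


def test_predictions_are_probabilities(trained_small):
    ds, split, trained, profiles = trained_small
    preds = predict(trained, profiles)
    for pid, track in preds.items():
        assert len(track) == len(ds.proteins[pid])
        assert ((track.propensities >= 0) & (track.propensities <= 1)).all()
        assert track.calls is not None  # fit_meta_predictor calibrates


def test_chunking_invisible_for_short_proteins(trained_small):
    ds, split, trained, profiles = trained_small
    pid = min(ds.proteins, key=lambda p: len(ds.proteins[p]))
    assert len(ds.proteins[pid]) < 128
    import dataclasses
    t128 = dataclasses.replace(
        trained, config=dataclasses.replace(trained.config, chunk_len=128)
    )
    a = predict(trained, {pid: profiles[pid]})[pid].propensities
    b = predict(t128, {pid: profiles[pid]})[pid].propensities
    np.testing.assert_array_equal(a, b)


def test_manifest_mismatch_rejected(trained_small):
    ds, split, trained, _ = trained_small
    other = build_profiles(ds, FeatureConfig(window=1))
    with pytest.raises(ValueError, match="manifest"):
        predict(trained, other)


def test_calibration_targets_fpr(trained_small):
    ds, split, trained, profiles = trained_small
    labels = binary_labels(ds, ds.proteins)
    val = {p: profiles[p] for p in split["val"]}
    thr = calibrate(trained, val, labels, target_fpr=0.1)
    assert 0 < thr < 1
    preds = predict(trained, val)
    y = ds.pooled_labels(sorted(val)) == Label.DNA
    calls = np.concatenate([preds[p].calls for p in sorted(val)])
    fpr = (calls & ~y).sum() / (~y).sum()
    assert fpr <= 0.15  # near the target on finite validation data
    thr_loose = calibrate(trained, val, labels, target_fpr=0.99)
    assert thr_loose < thr


def test_checkpoint_roundtrip(tmp_path, trained_small):
    ds, split, trained, profiles = trained_small
    path = tmp_path / "model.json"
    save_model(trained, path)
    loaded = load_model(path)
    pid = split["val"][0]
    np.testing.assert_allclose(
        predict(loaded, {pid: profiles[pid]})[pid].propensities,
        predict(trained, {pid: profiles[pid]})[pid].propensities,
        atol=1e-6,
    )
    assert loaded.calibrated_threshold == trained.calibrated_threshold


# ---------------------------------------------------------------------------
# ablation switches
# ---------------------------------------------------------------------------


def test_ablation_switches_reshape_features():
    mc, fc = ModelConfig(), FeatureConfig()
    _, fc2 = ablate(mc, fc, "no_group3")
    assert fc2.n_columns == 150
    _, fc3 = ablate(mc, fc, "no_window")
    assert fc3.n_columns == 30
    mc4, _ = ablate(mc, fc, "no_transformer")
    assert mc4.n_blocks == 0
    mc5, _ = ablate(mc, fc, "l1_loss")
    assert mc5.loss == "l1"
    _, fc6 = ablate(mc, fc, "drop_predictor:diso_a")
    assert fc6.n_columns == 15 * 9 + 20


def test_ablation_idempotent_and_unknown_switch():
    mc, fc = ModelConfig(), FeatureConfig()
    once = ablate(mc, fc, "no_window")
    twice = ablate(*once, "no_window")
    assert once == twice
    with pytest.raises(ValueError):
        ablate(mc, fc, "bogus")
    with pytest.raises(KeyError):
        ablate(mc, fc, "drop_predictor:nope")
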