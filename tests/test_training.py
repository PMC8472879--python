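"""Training protocol semantics: early stopping, determinism, fine-tuning."""

import numpy as np
import pytest

from ppgbp import datasets as ds
from ppgbp import training as tr
from ppgbp.models import ModelSpec, build_model


def _toy_split(rng, n_subjects=4, per_subject=30, length=64, mode="mixed"):
    X, y, sid, off = [], [], [], []
    for i in range(n_subjects):
        base = rng.uniform(95, 145)
        t = np.arange(length) / length
        for j in range(per_subject):
            sbp = base + rng.normal(0, 2)
            X.append(np.sin(2 * np.pi * t * (1 + sbp / 200))[:, None]
                     + rng.normal(0, 0.05, (length, 1)))
            y.append([sbp, sbp / 2])
            sid.append(f"s{i}")
            off.append(j * length)
    pool = ds.WindowSet(X=np.stack(X), y=np.array(y), subject=np.array(sid),
                        offset=np.array(off), hr=np.full(len(sid), 70.0),
                        snr=np.zeros(len(sid)))
    if mode == "mixed":
        return ds.split_mixed(pool, seed=0)
    return ds.split_non_mixed(pool, n_subjects - 2, 1, 1, seed=0)


class TestEarlyStopping:
    def test_patience_semantics_scripted_metrics(self, monkeypatch):
        """Metric {10,9,9,...}: stop at epoch 12, restore the epoch-2 best."""
        scripted = [10.0, 9.0] + [9.0] * 20
        calls = {"n": 0}
        snapshots = {}

        def fake_metrics(model, X, y, batch_size):
            calls["n"] += 1
            value = scripted[calls["n"] - 1]
            snapshots[calls["n"]] = model.state_dict()
            return value, value

        monkeypatch.setattr(tr, "_epoch_metrics", fake_metrics)
        rng = np.random.default_rng(0)
        split = _toy_split(rng)
        model = build_model(ModelSpec("cnn_small", 64, 1), seed=0)
        cfg = tr.TrainingConfig(max_epochs=100, patience=10, batch_size=16,
                                seed=0)
        history = tr.train(model, split, cfg)
        assert history.stopped_epoch == 12
        assert history.best_epoch == 2
        restored = model.state_dict()
        best = snapshots[2]
        assert all(np.array_equal(restored[k], best[k]) for k in best)

    def test_runs_to_max_epochs_when_always_improving(self, monkeypatch):
        values = iter(np.linspace(10, 1, 200))

        def fake_metrics(model, X, y, batch_size):
            v = float(next(values))
            return v, v

        monkeypatch.setattr(tr, "_epoch_metrics", fake_metrics)
        split = _toy_split(np.random.default_rng(1))
        model = build_model(ModelSpec("cnn_small", 64, 1), seed=0)
        cfg = tr.TrainingConfig(max_epochs=15, patience=10, batch_size=16)
        history = tr.train(model, split, cfg)
        assert history.stopped_epoch == 15
        assert history.best_epoch == 15


def test_training_deterministic_under_seed():
    split = _toy_split(np.random.default_rng(2))
    cfg = tr.TrainingConfig(max_epochs=3, patience=2, batch_size=16, seed=4)
    fps = []
    for _ in range(2):
        model = build_model(ModelSpec("cnn_small", 64, 1), seed=4)
        tr.train(model, split, cfg)
        fps.append(model.fingerprint(include_head=True))
    assert fps[0] == fps[1]


def test_training_reduces_validation_error():
    split = _toy_split(np.random.default_rng(3))
    model = build_model(ModelSpec("cnn_small", 64, 1), seed=1)
    history = tr.train(model, split, tr.TrainingConfig(
        max_epochs=20, patience=10, batch_size=16, seed=1))
    assert min(history.val_mae) < history.val_mae[0]


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        tr.TrainingConfig(patience=10, max_epochs=10)
    with pytest.raises(ValueError):
        tr.TrainingConfig(learning_rate=-1.0)
    with pytest.raises(ValueError):
        tr.TransferConfig(trainable_scope="half")


class TestPersonalize:
    def _pretrained(self):
        split = _toy_split(np.random.default_rng(5), mode="non_mixed")
        model = build_model(ModelSpec("cnn_small", 64, 1), seed=2)
        tr.train(model, split, tr.TrainingConfig(
            max_epochs=10, patience=5, batch_size=16, seed=2))
        return model, split

    def test_zero_calibration_leaves_model_unchanged(self):
        model, split = self._pretrained()
        sid = sorted(set(split.test.subject))[0]
        ws = split.test.by_subject(sid)
        part = ds.make_personalization_partition(ws, "first_20", seed=0)
        empty = ds.PersonalizationPartition(
            subject_id=part.subject_id, strategy="first_20",
            calibration=part.calibration.subset(np.arange(0)),
            test=part.test, spare_pool=part.spare_pool)
        out = tr.personalize(model, empty)
        assert out.fingerprint(True) == model.fingerprint(True)

    def test_personalization_never_touches_test_windows(self):
        model, split = self._pretrained()
        sid = sorted(set(split.test.subject))[0]
        part = ds.make_personalization_partition(
            split.test.by_subject(sid), "random_20", seed=1)
        assert not (part.calibration.window_ids() & part.test.window_ids())
        tr.personalize(model, part, tr.TrainingConfig(
            max_epochs=5, patience=2, batch_size=8, seed=1))


class TestTransfer:
    def test_final_layer_freeze_is_exact(self):
        split = _toy_split(np.random.default_rng(6), n_subjects=5,
                           mode="non_mixed")
        model = build_model(ModelSpec("cnn_small", 64, 1), seed=3)
        tr.train(model, split, tr.TrainingConfig(
            max_epochs=5, patience=2, batch_size=16, seed=3))
        pool = ds.WindowSet.concat([split.train, split.val, split.test])
        rppg_sets = {sid: pool.by_subject(sid) for sid in pool.subjects()}
        res = tr.transfer_to_rppg(
            model, rppg_sets, tr.TransferConfig(),
            tr.TrainingConfig(max_epochs=3, patience=2, batch_size=8, seed=3))
        assert res.fingerprint_unchanged.all()
        assert len(res) == len(rppg_sets)      # every subject tested once
        assert set(res.test_subject) == set(rppg_sets)

    def test_too_few_subjects_rejected(self):
        model = build_model(ModelSpec("cnn_small", 64, 1), seed=0)
        with pytest.raises(ValueError):
            tr.transfer_to_rppg(model, {"a": None, "b": None})


def test_window_study_emits_full_grid():
    rng = np.random.default_rng(7)
    pools = {("const_time", 2): _toy_pool(rng), ("const_beats", 2): _toy_pool(rng)}
    table = tr.run_window_study(
        pools, architectures=("cnn_small",), n_rep=2,
        sizes=(60, 20, 20),
        cfg=tr.TrainingConfig(max_epochs=3, patience=2, batch_size=16, seed=0))
    assert len(table) == 2 * 2        # strategies x reps
    assert set(table.strategy) == {"const_time", "const_beats"}
    assert table.mae_sbp.notna().all()


def _toy_pool(rng, n=120, length=64):
    X = rng.normal(size=(n, length, 1))
    sbp = rng.uniform(90, 150, n)
    return ds.WindowSet(X=X, y=np.column_stack([sbp, sbp / 2]),
                        subject=np.array([f"s{i % 6}" for i in range(n)]),
                        offset=np.arange(n) * length,
                        hr=np.full(n, 70.0), snr=np.zeros(n))
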