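"""Training, personalization and transfer-learning protocols.

* :func:`train` — Adam, mean-squared-error loss on the (SBP, DBP) pair,
  early stopping (default patience 10, max 200 epochs) that always restores
  the checkpoint minimizing the monitored validation metric;
* :func:`personalize` — continued optimization on a held-out subject's 20%
  calibration windows (all layers trainable), evaluated only on that
  subject's reserved test half;
* :func:`transfer_to_rppg` — fine-tuning a contact-PPG pre-trained network
  on camera-derived pulse windows with everything but the final layer
  frozen (enforced by a byte-exact fingerprint), rotated over subjects so
  that each is tested exactly once with its cyclic neighbour as validation
  (15/1/1 at the 17-subject study size);
* :func:`run_window_study` — repeated trainings across cropping strategies
  and window lengths, emitting the tidy table consumed by the paired
  comparison of the evaluation module.

Every test window is audited to never enter an optimization step.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ppgbp import nn
from ppgbp.datasets import (DatasetSplit, PersonalizationPartition, WindowSet,
                            make_personalization_partition)
from ppgbp.models import ModelSpec, NeuralModel, build_model

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig", "TransferConfig", "TrainingHistory",
    "train", "personalize", "transfer_to_rppg", "run_window_study",
    "evaluate_windows",
]


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3     # Adam alpha
    max_epochs: int = 200
    patience: int = 10
    batch_size: int = 128
    monitor: str = "val_mae"        # or val_loss
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be below max_epochs")
        if self.monitor not in ("val_loss", "val_mae"):
            raise ValueError("monitor must be val_loss or val_mae")


@dataclass
class TransferConfig:
    trainable_scope: str = "final_layer_only"   # or "all"
    personalization: str = "none"               # none | first_20 | random_20
    n_beats: int = 7

    def __post_init__(self) -> None:
        if self.trainable_scope not in ("final_layer_only", "all"):
            raise ValueError("unknown trainable_scope")
        if self.personalization not in ("none", "first_20", "random_20"):
            raise ValueError("unknown personalization strategy")


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_mae: list = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(1, len(self.train_loss) + 1),
                             "train_loss": self.train_loss,
                             "val_loss": self.val_loss,
                             "val_mae": self.val_mae})


def _epoch_metrics(model: NeuralModel, X: np.ndarray, y: np.ndarray,
                   batch_size: int) -> tuple[float, float]:
    """(MSE loss in standardized units, MAE in mmHg) over a dataset."""
    losses, maes, weights = [], [], []
    y_std = model.standardize(y)
    for i in range(0, len(X), batch_size):
        pred = model.forward(X[i:i + batch_size], train=False)
        loss, _ = nn.mse_loss_and_grad(pred, y_std[i:i + batch_size])
        pred_mmhg = pred * model.y_std + model.y_mean
        maes.append(float(np.abs(pred_mmhg - y[i:i + batch_size]).mean()))
        losses.append(loss)
        weights.append(len(pred))
    w = np.array(weights, dtype=float)
    return (float(np.average(losses, weights=w)),
            float(np.average(maes, weights=w)))


def train(model: NeuralModel, split: DatasetSplit,
          cfg: TrainingConfig | None = None,
          scope: str = "all") -> TrainingHistory:
    """Fit a model on a split with early stopping; returns the history.

    The model is modified in place and left holding the weights of the
    epoch with the best monitored validation metric (never the last).
    """
    cfg = cfg or TrainingConfig()
    if len(split.train) == 0 or len(split.val) == 0:
        raise ValueError("train and val partitions must be nonempty")
    if split.train.window_ids() & split.test.window_ids():
        raise AssertionError("test windows leaked into training")
    rng = np.random.default_rng(cfg.seed)
    if model.y_mean is None:
        model.set_target_scaler(split.train.y)
    X, y = split.train.X, split.train.y
    y_std = model.standardize(y)
    params = model.parameters(scope)
    opt = nn.Adam(params, lr=cfg.learning_rate)
    history = TrainingHistory()
    best_metric = np.inf
    best_state = None
    wait = 0
    for epoch in range(1, cfg.max_epochs + 1):
        perm = rng.permutation(len(X))
        epoch_losses = []
        for i in range(0, len(perm), cfg.batch_size):
            idx = perm[i:i + cfg.batch_size]
            pred = model.forward(X[idx], train=True)
            loss, grad = nn.mse_loss_and_grad(pred, y_std[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss={loss})")
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_losses.append(loss)
        val_loss, val_mae = _epoch_metrics(model, split.val.X, split.val.y,
                                           cfg.batch_size)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.val_mae.append(val_mae)
        metric = val_loss if cfg.monitor == "val_loss" else val_mae
        if metric < best_metric:
            best_metric = metric
            best_state = model.state_dict()
            history.best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break
    history.stopped_epoch = len(history.train_loss)
    if best_state is not None:
        model.load_state_dict(best_state)
    logger.info("training stopped at epoch %d, best epoch %d (%s=%.4f)",
                history.stopped_epoch, history.best_epoch, cfg.monitor,
                best_metric)
    return history


def evaluate_windows(model, windows: WindowSet) -> tuple[float, float]:
    """(SBP MAE, DBP MAE) in mmHg of a model on a window set."""
    pred = model.predict(windows.X)
    err = np.abs(pred - windows.y)
    return float(err[:, 0].mean()), float(err[:, 1].mean())


def _calibration_split(calibration: WindowSet, seed: int,
                       cap_val_frac: float = 0.1) -> DatasetSplit:
    """Internal train/val split of a calibration set (temporal 10% tail)."""
    n = len(calibration)
    n_val = max(1, int(round(cap_val_frac * n)))
    order = np.argsort(calibration.offset, kind="stable")
    ws = calibration.subset(order)
    return DatasetSplit(mode="mixed",
                        train=ws.subset(np.arange(0, n - n_val)),
                        val=ws.subset(np.arange(n - n_val, n)),
                        test=ws.subset(np.arange(0)), seed=seed)


def personalize(model: NeuralModel, partition: PersonalizationPartition,
                cfg: TrainingConfig | None = None) -> NeuralModel:
    """Fine-tune a pre-trained model on a subject's calibration windows.

    All layers are trainable.  The calibration set's temporal 10% tail is
    used as the early-stopping validation split.  Returns a new model; the
    input model is untouched.  Evaluation must use ``partition.test`` only.
    """
    cfg = cfg or TrainingConfig(max_epochs=50, patience=5)
    if partition.calibration.window_ids() & partition.test.window_ids():
        raise AssertionError("calibration and test overlap")
    personalized = model.clone()
    if len(partition.calibration) == 0:
        return personalized
    inner = _calibration_split(partition.calibration, cfg.seed)
    train(personalized, inner, cfg, scope="all")
    return personalized


def transfer_to_rppg(model: NeuralModel, rppg_sets: dict[str, WindowSet],
                     cfg: TransferConfig | None = None,
                     train_cfg: TrainingConfig | None = None) -> pd.DataFrame:
    """Leave-two-out transfer of a PPG-trained network to rPPG windows.

    Subjects are ordered deterministically; fold ``k`` tests subject ``k``
    with subject ``k+1`` (cyclic) as validation and the rest as fine-tuning
    data, so each subject is tested exactly once.  Under
    ``final_layer_only`` the body fingerprint must be byte-identical before
    and after fine-tuning (hard error otherwise).  Optional personalization
    adds the test subject's calibration windows to the fine-tuning set and
    evaluates on the complementary reserved half.
    """
    cfg = cfg or TransferConfig()
    train_cfg = train_cfg or TrainingConfig(max_epochs=50, patience=5)
    subjects = sorted(rppg_sets)
    if len(subjects) < 3:
        raise ValueError("need at least 3 rPPG subjects")
    rows = []
    for k, test_sid in enumerate(subjects):
        val_sid = subjects[(k + 1) % len(subjects)]
        train_sids = [s for s in subjects if s not in (test_sid, val_sid)]
        train_ws = WindowSet.concat([rppg_sets[s] for s in train_sids])
        test_ws = rppg_sets[test_sid]
        if cfg.personalization != "none":
            partition = make_personalization_partition(
                test_ws, strategy=cfg.personalization, seed=train_cfg.seed)
            train_ws = WindowSet.concat([train_ws, partition.calibration])
            test_ws = partition.test
        fold_split = DatasetSplit(mode="non_mixed", train=train_ws,
                                  val=rppg_sets[val_sid],
                                  test=test_ws, seed=train_cfg.seed) \
            if cfg.personalization == "none" else \
            DatasetSplit(mode="mixed", train=train_ws,
                         val=rppg_sets[val_sid], test=test_ws,
                         seed=train_cfg.seed)
        mae_before = evaluate_windows(model, test_ws)
        tuned = model.clone()
        fp_before = tuned.fingerprint(include_head=False)
        train(tuned, fold_split, train_cfg, scope=cfg.trainable_scope)
        fp_after = tuned.fingerprint(include_head=False)
        if cfg.trainable_scope == "final_layer_only" and fp_before != fp_after:
            raise RuntimeError("frozen weights changed during transfer "
                               f"fine-tuning of fold {k} ({test_sid})")
        mae_after = evaluate_windows(tuned, test_ws)
        rows.append({
            "fold": k, "test_subject": test_sid, "val_subject": val_sid,
            "n_test": len(test_ws),
            "mae_sbp_before": mae_before[0], "mae_dbp_before": mae_before[1],
            "mae_sbp_after": mae_after[0], "mae_dbp_after": mae_after[1],
            "fingerprint_unchanged": fp_before == fp_after,
        })
    return pd.DataFrame(rows)


def run_window_study(pools: dict[tuple[str, int], WindowSet],
                     architectures: tuple[str, ...] = ("alexnet1d", "resnet1d"),
                     n_rep: int = 3,
                     sizes: tuple[int, int, int] = (100_000, 25_000, 25_000),
                     cfg: TrainingConfig | None = None,
                     samples_per_beat: int = 125) -> pd.DataFrame:
    """Repeated trainings over (architecture, strategy, length) cells.

    ``pools`` maps (strategy, length) to a window pool.  Each repetition
    draws ``sizes`` samples at random (scaled down when the pool is
    smaller) and records test MAE, producing the paired table for the
    cropping-strategy comparison.
    """
    cfg = cfg or TrainingConfig(max_epochs=50, patience=10)
    rows = []
    for (strategy, length), pool in sorted(pools.items()):
        for arch in architectures:
            for rep in range(n_rep):
                cell = f"{cfg.seed}:{strategy}:{length}:{arch}:{rep}"
                rng = np.random.default_rng(
                    int.from_bytes(hashlib.sha256(cell.encode()).digest()[:4],
                                   "little"))
                n = len(pool)
                n_train = min(sizes[0], int(0.7 * n))
                n_val = min(sizes[1], int(0.15 * n))
                n_test = min(sizes[2], n - n_train - n_val)
                perm = rng.permutation(n)
                split = DatasetSplit(
                    mode="mixed",
                    train=pool.subset(perm[:n_train]),
                    val=pool.subset(perm[n_train:n_train + n_val]),
                    test=pool.subset(perm[n_train + n_val:
                                          n_train + n_val + n_test]),
                    seed=cfg.seed)
                length_samples = pool.X.shape[1]
                spec = ModelSpec(architecture=arch,
                                 input_length=length_samples,
                                 input_channels=pool.X.shape[2])
                model = build_model(spec, seed=cfg.seed + rep)
                train(model, split, replace(cfg, seed=cfg.seed + rep))
                mae_sbp, mae_dbp = evaluate_windows(model, split.test)
                rows.append({"architecture": arch, "strategy": strategy,
                             "length": length, "rep": rep,
                             "mae_sbp": mae_sbp, "mae_dbp": mae_dbp})
    return pd.DataFrame(rows)
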