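"""Training loop: Adam on cross-entropy + L2, per-epoch history logging,
run-to-run reproducibility bands, and the learning-curve experiment.

Each epoch reshuffles the training subset, consumes it in batches of 64,
and updates the parameters by Adam on the mean cross-entropy plus the L2
weight penalty.  The epoch's training metrics are the running average over
its batches (predictions collected as the batches are consumed); the
validation set is evaluated once, in eval mode, at the epoch's end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .network import (Network, cross_entropy, l2_gradients, l2_penalty,
                      one_hot, softmax)
from .prep import DatasetSplits, iterate_batches

__all__ = [
    "OptimizerConfig",
    "EpochRecord",
    "TrainingHistory",
    "TrainingDivergedError",
    "Adam",
    "fit",
    "evaluate_split",
    "repeat_runs",
    "learning_curve",
]


class TrainingDivergedError(RuntimeError):
    """The loss became non-finite during optimization."""


@dataclass(frozen=True)
class OptimizerConfig:
    learning_rate: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    n_epochs: int = 100
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.learning_rate >= 0:
            raise ValueError("learning_rate must be non-negative")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class Adam:
    """Standard Adam with bias-corrected first/second moment estimates."""

    def __init__(self, opt: OptimizerConfig):
        self.opt = opt
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self, params: dict, grads: dict) -> None:
        o = self.opt
        self.t += 1
        for key, g in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = o.adam_beta1 * self.m[key] + (1 - o.adam_beta1) * g
            self.v[key] = o.adam_beta2 * self.v[key] + (1 - o.adam_beta2) * g ** 2
            mhat = self.m[key] / (1 - o.adam_beta1 ** self.t)
            vhat = self.v[key] / (1 - o.adam_beta2 ** self.t)
            params[key] -= o.learning_rate * mhat / (np.sqrt(vhat) + o.adam_epsilon)


@dataclass
class EpochRecord:
    epoch: int
    train_cross_entropy: float
    val_cross_entropy: float
    train_report: _metrics.MetricsReport
    val_report: _metrics.MetricsReport

    def to_row(self) -> dict:
        row = {"epoch": self.epoch,
               "train_cross_entropy": self.train_cross_entropy,
               "val_cross_entropy": self.val_cross_entropy}
        for prefix, rep in (("train", self.train_report),
                            ("val", self.val_report)):
            for c, name in enumerate(("sw480", "otii", "blank")):
                row[f"{prefix}_f1_{name}"] = float(rep.f1[c])
            row[f"{prefix}_f1_micro"] = rep.micro[2]
            row[f"{prefix}_f1_macro"] = rep.macro[2]
            row[f"{prefix}_f1_weighted"] = rep.weighted[2]
            row[f"{prefix}_bacc"] = rep.balanced_accuracy
        return row


@dataclass
class TrainingHistory:
    records: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.records])

    def __len__(self) -> int:
        return len(self.records)


def _epoch_seed(seed: int, epoch: int, salt: int = 0) -> int:
    return int(np.random.SeedSequence([seed, epoch, salt]).generate_state(1)[0]
               % (2 ** 31))


def _train_step(network: Network, Xb, yb, adam: Adam, l2_multiplier: float,
                rng: np.random.Generator):
    logits = network.forward(Xb, train=True, rng=rng)
    probs = softmax(logits)
    yb1 = one_hot(yb, network.config.n_classes)
    data_ce = cross_entropy(probs, yb1)
    loss = data_ce + l2_penalty(network, l2_multiplier)
    if not np.isfinite(loss):
        raise TrainingDivergedError(
            f"non-finite loss {loss!r}; reduce the learning rate")
    network.backward((probs - yb1) / len(yb))
    grads = network.gradients()
    for key, g in l2_gradients(network, l2_multiplier).items():
        grads[key] = grads[key] + g
    adam.step(network.parameters(), grads)
    return data_ce, logits.argmax(axis=1)


def fit(network: Network, X: np.ndarray, y: np.ndarray, splits: DatasetSplits,
        opt: OptimizerConfig | None = None,
        l2_multiplier: float | None = None,
        keep_prob: float | None = None) -> TrainingHistory:
    """Train in place; returns one EpochRecord per epoch.

    ``l2_multiplier`` / ``keep_prob`` override the values stored in the
    network's configuration (used by the regularization search).
    """
    opt = opt or OptimizerConfig()
    if len(splits.train) == 0 or len(splits.validation) == 0:
        raise ValueError("train and validation subsets must be non-empty")
    if l2_multiplier is None:
        l2_multiplier = network.config.l2_multiplier
    if keep_prob is not None:
        network.set_dropout_keep_prob(keep_prob)

    Xtr, ytr = X[splits.train], y[splits.train]
    Xva, yva = X[splits.validation], y[splits.validation]
    adam = Adam(opt)
    history = TrainingHistory()
    for epoch in range(opt.n_epochs):
        rng = np.random.default_rng(_epoch_seed(opt.seed, epoch, salt=1))
        ce_sum = 0.0
        n_seen = 0
        preds, trues = [], []
        for Xb, yb in iterate_batches(Xtr, ytr, opt.batch_size,
                                      _epoch_seed(opt.seed, epoch)):
            batch_ce, pred = _train_step(network, Xb, yb, adam, l2_multiplier,
                                         rng)
            ce_sum += batch_ce * len(yb)
            n_seen += len(yb)
            preds.append(pred)
            trues.append(yb)
        train_ce = ce_sum / n_seen
        train_report = _metrics.full_report(np.concatenate(trues),
                                            np.concatenate(preds))
        val_probs, val_report = evaluate_split(network, Xva, yva)
        val_ce = cross_entropy(val_probs, one_hot(yva, network.config.n_classes))
        history.records.append(EpochRecord(
            epoch=epoch, train_cross_entropy=float(train_ce),
            val_cross_entropy=float(val_ce),
            train_report=train_report, val_report=val_report))
    return history


def evaluate_split(network: Network, X: np.ndarray, y: np.ndarray,
                   batch_size: int = 256):
    """Eval-mode forward over a whole subset; returns (probabilities,
    MetricsReport from the argmax predictions)."""
    if len(X) == 0:
        raise ValueError("empty subset")
    chunks = [softmax(network.forward(X[i:i + batch_size]))
              for i in range(0, len(X), batch_size)]
    probs = np.concatenate(chunks)
    report = _metrics.full_report(y, probs.argmax(axis=1))
    return probs, report


def repeat_runs(make_network, X, y, splits, opt: OptimizerConfig,
                n_runs: int = 5, seeds=None):
    """Repeat training from fresh random initializations.

    ``make_network(seed)`` must build an identically configured network.
    Returns (histories, bands) where bands is a DataFrame of the per-epoch
    across-run mean and standard deviation of every logged metric.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if seeds is None:
        seeds = [opt.seed + i for i in range(n_runs)]
    if len(seeds) != n_runs:
        raise ValueError("need one seed per run")
    histories = []
    for run_seed in seeds:
        net = make_network(run_seed)
        run_opt = OptimizerConfig(
            learning_rate=opt.learning_rate, adam_beta1=opt.adam_beta1,
            adam_beta2=opt.adam_beta2, adam_epsilon=opt.adam_epsilon,
            n_epochs=opt.n_epochs, batch_size=opt.batch_size, seed=run_seed)
        histories.append(fit(net, X, y, splits, run_opt))
    frames = [h.to_frame() for h in histories]
    stacked = pd.concat(frames, keys=range(n_runs))
    grouped = stacked.groupby("epoch")
    mean = grouped.mean().add_suffix("_mean")
    sd = grouped.std(ddof=1).add_suffix("_sd")
    bands = pd.concat([mean, sd], axis=1).reset_index()
    return histories, bands


def learning_curve(make_network, X, y, splits: DatasetSplits,
                   opt: OptimizerConfig, train_sizes, seed: int = 0):
    """Train once per training-set size (validation set fixed) and record the
    final-epoch train and validation cross-entropies."""
    import warnings
    rows = []
    for size in train_sizes:
        size = int(size)
        if size > len(splits.train):
            raise ValueError(f"train size {size} exceeds available "
                             f"{len(splits.train)} examples")
        if size < opt.batch_size:
            warnings.warn(f"train size {size} below one batch; the batch "
                          "shrinks accordingly", RuntimeWarning)
        sub = DatasetSplits(
            train=splits.train[:size], validation=splits.validation,
            test=splits.test, fractions=splits.fractions,
            split_seed=splits.split_seed)
        net = make_network(seed)
        history = fit(net, X, y, sub, opt)
        last = history.records[-1]
        rows.append({"train_size": size,
                     "train_cross_entropy": last.train_cross_entropy,
                     "val_cross_entropy": last.val_cross_entropy})
    return pd.DataFrame(rows)
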