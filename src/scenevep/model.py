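"""Compact convolutional classifier for averaged visual evoked potentials.

The architecture treats an averaged VEP as a 17-channel x 500-sample image
and stacks three convolutional blocks that operate on the time axis only:

* ConvBlock1 — 8 temporal filters of length 64 with 32-sample replicate
  padding per side, then batch norm (time 500 -> 501);
* ConvBlock2 — 16 pointwise (1, 1) filters, batch norm, ELU, average pool
  over 4 samples, dropout 0.5 (501 -> 125);
* ConvBlock3 — 16 temporal filters of length 16 with 8-sample replicate
  padding per side, a second pointwise (1, 1) stage, batch norm, ELU,
  average pool over 8, dropout 0.5 (125 -> 15);
* a fully connected layer from the flattened 16 x 17 x 15 = 4,080 features
  to the class scores, with softmax probabilities.

Pooling uses floor division and no padding; the replicate paddings are per
side.  Those two conventions are pinned by the 4,080-feature flatten size
and are checked against an independent integer-arithmetic oracle in the
test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import _nn
from .montage import CHANNELS_17

logger = logging.getLogger(__name__)

N_MODEL_CHANNELS = len(CHANNELS_17)  # 17
N_TIMEPOINTS = 500


@dataclass
class ArchitectureSpec:
    """Hyperparameters of the classifier; defaults are the fixed design."""

    n_channels: int = N_MODEL_CHANNELS
    n_times: int = N_TIMEPOINTS
    conv1_filters: int = 8
    conv1_kernel: int = 64
    conv1_pad: int = 32
    conv2_filters: int = 16
    pool2: int = 4
    conv3_kernel: int = 16
    conv3_pad: int = 8
    pool3: int = 8
    dropout: float = 0.5

    def time_lengths(self) -> dict[str, int]:
        """Time-axis length after each block, by integer arithmetic only."""
        t1 = self.n_times + 2 * self.conv1_pad - self.conv1_kernel + 1
        t2 = t1 // self.pool2
        t3 = (t2 + 2 * self.conv3_pad - self.conv3_kernel + 1) // self.pool3
        return {"conv1": t1, "block2": t2, "block3": t3}

    def flatten_features(self) -> int:
        return self.conv2_filters * self.n_channels * self.time_lengths()["block3"]

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


class EEGNetVariant:
    """The classifier: a :class:`~scenevep._nn.Sequential` stack plus
    bookkeeping for the Grad-CAM feature-map taps."""

    def __init__(self, n_classes: int, spec: ArchitectureSpec | None = None,
                 seed: int = 0):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.spec = spec or ArchitectureSpec()
        self.n_classes = n_classes
        self.seed = seed
        rng = np.random.default_rng(seed)
        s = self.spec
        layers = [
            _nn.ReplicatePad(s.conv1_pad),
            _nn.ConvTime(1, s.conv1_filters, s.conv1_kernel, rng),
            _nn.BatchNorm(s.conv1_filters),
            _nn.ConvTime(s.conv1_filters, s.conv2_filters, 1, rng),   # tap "conv"
            _nn.BatchNorm(s.conv2_filters),
            _nn.ELU(),
            _nn.AvgPoolTime(s.pool2),                                  # tap "pooled"
            _nn.Dropout(s.dropout),
            _nn.ReplicatePad(s.conv3_pad),
            _nn.ConvTime(s.conv2_filters, s.conv2_filters, s.conv3_kernel, rng),
            _nn.ConvTime(s.conv2_filters, s.conv2_filters, 1, rng),
            _nn.BatchNorm(s.conv2_filters),
            _nn.ELU(),
            _nn.AvgPoolTime(s.pool3),
            _nn.Dropout(s.dropout),
            _nn.Flatten(),
            _nn.Linear(self.spec.flatten_features(), n_classes, rng),
        ]
        self.net = _nn.Sequential(layers)
        self.tap_index = {"conv": 3, "pooled": 6}
        self._dropout_rng = np.random.default_rng(seed + 1)

    # -- forward -----------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        s = self.spec
        if x.shape[1:] != (1, s.n_channels, s.n_times):
            raise ValueError(
                f"input must be (n, {s.n_channels}, {s.n_times}); got {x.shape}")
        return x

    def logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = self._check_input(x)
        return self.net.forward(x, training=training, rng=self._dropout_rng)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _nn.softmax(self.logits(x, training=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def feature_map_and_gradient(self, x: np.ndarray, target_class: int,
                                 tap: str = "conv"):
        """Feature map A at the tap layer and the gradient dscore/dA of the
        target-class score (pre-softmax logit), both in eval mode."""
        if not 0 <= target_class < self.n_classes:
            raise ValueError(f"target class {target_class} out of range")
        idx = self.tap_index[tap]
        x = self._check_input(x)
        logits, fmap = self.net.forward(x, training=False, capture=idx)
        gy = np.zeros_like(logits)
        gy[:, target_class] = 1.0
        _, grad = self.net.backward(gy, capture=idx, stop_at=idx)
        return fmap, grad

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        for i, layer in enumerate(self.net.layers):
            for name, p in layer.params.items():
                arrays[f"layer{i}.{name}"] = p
            if isinstance(layer, _nn.BatchNorm):
                arrays[f"layer{i}.running_mean"] = layer.running_mean
                arrays[f"layer{i}.running_var"] = layer.running_var
        header = json.dumps({"n_classes": self.n_classes, "seed": self.seed,
                             "spec": self.spec.__dict__})
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "EEGNetVariant":
        with np.load(path) as z:
            header = json.loads(bytes(z["__header__"]).decode())
            model = cls(header["n_classes"], ArchitectureSpec(**header["spec"]),
                        seed=header["seed"])
            for i, layer in enumerate(model.net.layers):
                for name in layer.params:
                    layer.params[name][...] = z[f"layer{i}.{name}"]
                if isinstance(layer, _nn.BatchNorm):
                    layer.running_mean[...] = z[f"layer{i}.running_mean"]
                    layer.running_var[...] = z[f"layer{i}.running_var"]
        return model


def build_model(n_classes: int, seed: int = 0,
                spec: ArchitectureSpec | None = None) -> EEGNetVariant:
    return EEGNetVariant(n_classes, spec=spec, seed=seed)


def randomize_final_layer(model: EEGNetVariant, seed: int = 0) -> EEGNetVariant:
    """Copy of the model with a freshly re-initialized fully connected head
    (used by the attribution sanity check: a randomized readout should
    destroy any class-specific localization)."""
    import copy

    out = copy.deepcopy(model)
    rng = np.random.default_rng(seed)
    lin = out.net.layers[-1]
    lin.params["W"] = (rng.standard_normal(lin.params["W"].shape)
                       * np.sqrt(2.0 / lin.params["W"].shape[0])).astype(np.float32)
    lin.params["b"] = np.zeros_like(lin.params["b"])
    return out


# -- training ---------------------------------------------------------------

#: training epoch counts per classification target (selected from the
#: validation-trace procedure; see docs/methods.md)
DEFAULT_EPOCHS = {"category": 361, "naturalness": 221, "openness": 341,
                  "roughness": 301}


@dataclass
class TrainConfig:
    n_epochs: int = 361
    batch_size: int = 64
    lr: float = 1e-3
    weight_decay: float = 0.0
    seed: int = 0
    eval_every: int = 1  # epochs between test-accuracy evaluations (0 = never)

    def __post_init__(self):
        if self.n_epochs <= 0 or self.batch_size <= 0 or self.lr <= 0:
            raise ValueError("n_epochs, batch_size and lr must be positive")


@dataclass
class TrainTrace:
    epochs: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    test_accuracy: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        acc = self.test_accuracy or [np.nan] * len(self.epochs)
        return pd.DataFrame({"epoch": self.epochs, "train_loss": self.train_loss,
                             "test_accuracy": acc})


def _stack_samples(samples) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.data for s in samples]).astype(np.float32)
    y = np.asarray([s.label for s in samples], dtype=np.int64)
    return X, y


def train(model: EEGNetVariant, samples, cfg: TrainConfig,
          test_samples=None) -> TrainTrace:
    """Train with Adam on categorical cross-entropy; deterministic for a
    given config seed (data order, dropout and init all derive from seeds).

    ``samples`` is a list of AveragedSample (or any objects with ``.data``
    shaped (17, 500) and an integer ``.label``); returns the per-epoch
    loss / test-accuracy trace used for epoch-count selection.
    """
    X, y = _stack_samples(samples)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    Xt = yt = None
    if test_samples:
        Xt, yt = _stack_samples(test_samples)
    rng = np.random.default_rng(cfg.seed)
    model._dropout_rng = np.random.default_rng(cfg.seed + 1)
    opt = _nn.Adam(model.net, lr=cfg.lr, weight_decay=cfg.weight_decay)
    trace = TrainTrace()
    n = len(X)
    for epoch in range(cfg.n_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model.logits(X[idx], training=True)
            loss, dlogits = _nn.cross_entropy(logits, y[idx])
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
        trace.epochs.append(epoch)
        trace.train_loss.append(float(np.mean(losses)))
        if Xt is not None and cfg.eval_every and (epoch % cfg.eval_every == 0
                                                  or epoch == cfg.n_epochs - 1):
            acc = float((model.predict(Xt) == yt).mean())
            trace.test_accuracy.append(acc)
        elif Xt is not None:
            trace.test_accuracy.append(np.nan)
    return trace


# -- metrics ----------------------------------------------------------------

def top_n_accuracy(probs: np.ndarray, labels: np.ndarray, n: int) -> float:
    """Fraction of samples whose true class is among the n highest-scoring
    classes.  Ties are broken by a stable sort, i.e. the lower class index
    wins, so the result is deterministic."""
    probs = np.atleast_2d(probs)
    if not 1 <= n <= probs.shape[1]:
        raise ValueError(f"n must be in [1, {probs.shape[1]}]")
    order = np.argsort(-probs, axis=1, kind="stable")
    hits = (order[:, :n] == np.asarray(labels)[:, None]).any(axis=1)
    return float(hits.mean())


def balanced_accuracy(tp: int, fn: int, fp: int, tn: int) -> float:
    """Mean of sensitivity and specificity: (tp/(tp+fn) + tn/(tn+fp)) / 2."""
    if min(tp, fn, fp, tn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    if tp + fn == 0:
        raise ValueError("no positive-class samples (tp + fn = 0)")
    if tn + fp == 0:
        raise ValueError("no negative-class samples (tn + fp = 0)")
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def binary_confusion(pred: np.ndarray, truth: np.ndarray) -> dict[str, int]:
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    return {
        "tp": int(((pred == 1) & (truth == 1)).sum()),
        "fn": int(((pred == 0) & (truth == 1)).sum()),
        "fp": int(((pred == 1) & (truth == 0)).sum()),
        "tn": int(((pred == 0) & (truth == 0)).sum()),
    }


@dataclass
class EvalResult:
    """Group-level evaluation: per-participant metrics, their means, and
    one-sample t-tests against the computed chance levels with BH-FDR
    adjustment across the reported metric family."""

    label_kind: str
    per_participant: pd.DataFrame
    metrics: dict
    confusion: np.ndarray | dict


def evaluate(model: EEGNetVariant, test_samples, label_kind: str,
             top_n: int = 2) -> EvalResult:
    """Evaluate grouped by participant.

    For multi-class targets the reported family is (accuracy, top-n
    accuracy); for binary targets it is the balanced accuracy.  Chance
    levels are computed (1/K, n/K, 1/2), never hard-coded.  The group test
    is a two-tailed one-sample t-test across participants against chance,
    BH-FDR adjusted over the family.
    """
    by_pid: dict = {}
    for s in test_samples:
        by_pid.setdefault(s.participant_id, []).append(s)
    if not by_pid:
        raise ValueError("no test samples")
    K = model.n_classes
    binary = label_kind != "category" and K == 2
    rows = []
    total_conf = (np.zeros((K, K), dtype=int) if not binary
                  else {"tp": 0, "fn": 0, "fp": 0, "tn": 0})
    for pid, group in sorted(by_pid.items()):
        X, yv = _stack_samples(group)
        probs = model.predict_proba(X)
        pred = probs.argmax(axis=1)
        row = {"participant_id": pid, "n": len(yv),
               "accuracy": float((pred == yv).mean())}
        if binary:
            conf = binary_confusion(pred, yv)
            for k, v in conf.items():
                total_conf[k] += v
            try:
                row["balanced_accuracy"] = balanced_accuracy(**conf)
            except ValueError:
                logger.warning("participant %s has a one-class test set; "
                               "balanced accuracy undefined, using accuracy", pid)
                row["balanced_accuracy"] = row["accuracy"]
        else:
            row[f"top{top_n}_accuracy"] = top_n_accuracy(probs, yv, top_n)
            for t, p in zip(yv, pred):
                total_conf[t, p] += 1
        rows.append(row)
    per = pd.DataFrame(rows)
    if len(per) < 2:
        raise ValueError("group statistics need at least 2 participants")

    if binary:
        family = {"balanced_accuracy": 0.5}
    else:
        family = {"accuracy": 1.0 / K, f"top{top_n}_accuracy": top_n / K}
    metrics = {}
    pvals = []
    for name, chance in family.items():
        vals = per[name].to_numpy()
        t, p = stats.ttest_1samp(vals, popmean=chance)
        metrics[name] = {"mean": float(vals.mean()), "sem": float(stats.sem(vals)),
                         "chance": chance, "t": float(t), "p": float(p)}
        pvals.append(p)
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    for name, padj in zip(family, p_adj):
        metrics[name]["p_fdr"] = float(padj)
    return EvalResult(label_kind=label_kind, per_participant=per,
                      metrics=metrics, confusion=total_conf)
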