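"""The three-branch classifier and its imbalance-aware training loop.

Each protein is described by three aligned blocks — an expression tensor,
a localization row and a network embedding vector — processed by dedicated
branches that each emit a 16-dimensional feature (equal widths so no block
dominates by size).  The concatenated features pass through a small dense
head to a sigmoid essentiality probability.

Essential proteins are a minority (roughly 19% in yeast), so training
supports three regimes:

* ``sampling`` — per epoch, all E training positives plus E freshly drawn
  negatives (1:1 balanced undersampling).  The probability that a given
  negative is never seen across n epochs is ``(1 - E/NE)^n``.
* ``class_weight`` — the full training split with the positive-class loss
  term up-weighted.
* ``raw`` — per epoch, 2E examples drawn uniformly from the training split
  regardless of class (same set size as ``sampling``); a given example is
  never seen with probability ``(1 - 2E/(E+NE))^n``.

Optimization is binary cross-entropy with RMSprop (learning rate 0.001,
batch size 64, 20 epochs by default), fully reproducible under a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import evaluation
from .expression_features import ExpressionTensorSet
from .localization_features import LocalizationMatrix
from .nn import BatchNorm, Conv1D, Dense, GlobalMaxPool, MaxPool1D, RMSprop, sigmoid

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "FeatureBundle",
    "ThreeBranchModel",
    "split_dataset",
    "balanced_epoch_sample",
    "non_selection_probability",
    "build_model",
    "train_model",
    "predict",
    "build_feature_bundle",
]

BRANCHES = ("expression", "localization", "embedding")


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 0.001
    optimizer: str = "rmsprop"
    conv_filters: int = 64
    conv_kernel_size: int = 3
    imbalance_mode: str = "sampling"
    class_weight_positive: float = 8.0
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.imbalance_mode not in {"sampling", "class_weight", "raw"}:
            raise ValueError(f"unknown imbalance_mode {self.imbalance_mode!r}")
        if not 1 <= self.class_weight_positive <= 10:
            raise ValueError("class_weight_positive must be in [1, 10]")
        if self.optimizer != "rmsprop":
            raise ValueError("only the rmsprop optimizer is supported")

    @classmethod
    def from_dict(cls, data: Mapping) -> "TrainingConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "split_fractions" in data:
            data["split_fractions"] = tuple(data["split_fractions"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "TrainingConfig":
        with open(path, encoding="utf-8") as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})


@dataclass
class FeatureBundle:
    """Per-protein inputs aligned on one protein ordering."""

    proteins: list[str]
    expression: np.ndarray  # (N, n_cond, n_rep, T)
    localization: np.ndarray  # (N, K)
    embedding: np.ndarray  # (N, d)
    labels: np.ndarray  # (N,), 0/1

    def __post_init__(self) -> None:
        n = len(self.proteins)
        for name in ("expression", "localization", "embedding", "labels"):
            block = getattr(self, name)
            if block.shape[0] != n:
                raise ValueError(f"{name} block not aligned: {block.shape[0]} rows for {n} proteins")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.proteins)

    def subset(self, idx: np.ndarray) -> "FeatureBundle":
        return FeatureBundle(
            proteins=[self.proteins[i] for i in idx],
            expression=self.expression[idx],
            localization=self.localization[idx],
            embedding=self.embedding[idx],
            labels=self.labels[idx],
        )


def build_feature_bundle(
    proteins: Sequence[str],
    tensors: ExpressionTensorSet,
    loc_matrix: LocalizationMatrix,
    embedding: Mapping[str, np.ndarray],
    labels: Mapping[str, int],
) -> FeatureBundle:
    """Align the three feature blocks and labels on one protein ordering."""
    if list(tensors.proteins) != list(proteins) or list(loc_matrix.proteins) != list(proteins):
        raise ValueError("expression/localization blocks not aligned with the protein ordering")
    dim = len(next(iter(embedding.values())))
    emb = np.stack([np.asarray(embedding.get(p, np.zeros(dim)), dtype=float) for p in proteins])
    y = np.array([labels[p] for p in proteins], dtype=int)
    return FeatureBundle(
        proteins=list(proteins),
        expression=tensors.values,
        localization=loc_matrix.values,
        embedding=emb,
        labels=y,
    )


# ---------------------------------------------------------------------------
# Splitting and sampling
# ---------------------------------------------------------------------------

def split_dataset(
    bundle: FeatureBundle,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[FeatureBundle, FeatureBundle, FeatureBundle]:
    """Shuffle under ``seed`` and partition contiguously into train/val/test."""
    if any(f <= 0 for f in fractions):
        raise ValueError("all split fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n = len(bundle)
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(fractions[0] * n)
    n_val = int(fractions[1] * n)
    return (
        bundle.subset(perm[:n_train]),
        bundle.subset(perm[n_train : n_train + n_val]),
        bundle.subset(perm[n_train + n_val :]),
    )


def balanced_epoch_sample(
    train_labels: np.ndarray, seed: int, epoch_index: int
) -> np.ndarray:
    """All positives plus an equal number of freshly drawn negatives.

    Negatives are sampled uniformly without replacement; the epoch index is
    folded into the random stream so every epoch sees a different subset.
    """
    y = np.asarray(train_labels)
    pos = np.nonzero(y == 1)[0]
    neg = np.nonzero(y == 0)[0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("training split must contain both classes")
    if pos.size > neg.size:
        raise ValueError(
            f"cannot draw {pos.size} negatives without replacement from {neg.size}"
        )
    rng = np.random.default_rng([seed, epoch_index])
    chosen = rng.choice(neg, size=pos.size, replace=False)
    return np.concatenate([pos, chosen])


def non_selection_probability(E: int, NE: int, n: int, mode: str = "balanced") -> float:
    """Closed-form probability of never being drawn across ``n`` iterations.

    ``balanced``: a given negative under 1:1 undersampling, ``(1 - E/NE)^n``.
    ``raw``: a given example under uniform 2E-subsampling,
    ``(1 - 2E/(E+NE))^n``.
    """
    if E < 0 or NE <= 0 or n < 0:
        raise ValueError("require E >= 0, NE > 0, n >= 0")
    if mode == "balanced":
        if E > NE:
            raise ValueError("balanced mode requires E <= NE")
        return float((1.0 - E / NE) ** n)
    if mode == "raw":
        frac = 2.0 * E / (E + NE)
        if frac > 1:
            raise ValueError("2E exceeds the dataset size")
        return float((1.0 - frac) ** n)
    raise ValueError(f"mode must be 'balanced' or 'raw', got {mode!r}")


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class _ExpressionBranchNet:
    """conv/BN/max-pool per condition, concat, pointwise conv, GMP, dense 16."""

    def __init__(self, n_cond: int, n_rep: int, filters: int, kernel: int, rng):
        self.n_cond = n_cond
        self.convs = [Conv1D(n_rep, filters, kernel, rng) for _ in range(n_cond)]
        self.bns = [BatchNorm(filters) for _ in range(n_cond)]
        self.pools = [MaxPool1D(2) for _ in range(n_cond)]
        self.pointwise = Conv1D(n_cond * filters, filters, 1, rng)
        self.gmp = GlobalMaxPool()
        self.dense = Dense(filters, 16, "relu", rng)
        self.filters = filters

    @property
    def layers(self):
        return [*self.convs, *self.bns, self.pointwise, self.dense]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        streams = []
        for c in range(self.n_cond):
            s = x[:, c].transpose(0, 2, 1)  # (B, T, n_rep)
            s = self.convs[c].forward(s, train)
            s = self.bns[c].forward(s, train)
            s = self.pools[c].forward(s, train)
            streams.append(s)
        h = np.concatenate(streams, axis=2)
        h = self.pointwise.forward(h, train)
        h = self.gmp.forward(h, train)
        return self.dense.forward(h, train)

    def backward(self, dout: np.ndarray) -> None:
        d = self.dense.backward(dout)
        d = self.gmp.backward(d)
        d = self.pointwise.backward(d)
        for c in range(self.n_cond):
            dc = d[:, :, c * self.filters : (c + 1) * self.filters]
            dc = self.pools[c].backward(dc)
            dc = self.bns[c].backward(dc)
            self.convs[c].backward(dc)


class _DenseBranchNet:
    """A stack of dense layers with an optional batch norm before the last."""

    def __init__(self, widths: list[int], rng, batch_norm_before_last: bool = False):
        self.layers_seq: list = []
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            if batch_norm_before_last and i == len(widths) - 2:
                self.layers_seq.append(BatchNorm(a))
            self.layers_seq.append(Dense(a, b, "relu", rng))

    @property
    def layers(self):
        return [l for l in self.layers_seq if l.params]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers_seq:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers_seq):
            dout = layer.backward(dout)


class ThreeBranchModel:
    """Expression + localization + embedding branches, dense head, sigmoid.

    Any subset of branches can be enabled (ablations); each enabled branch
    contributes a 16-wide feature to the concatenated head input.
    """

    def __init__(
        self,
        expression_shape: tuple[int, int, int],
        localization_dim: int,
        embedding_dim: int,
        config: TrainingConfig | None = None,
        branches: Sequence[str] = BRANCHES,
    ):
        config = config or TrainingConfig()
        self.branches = tuple(b for b in BRANCHES if b in branches)
        if not self.branches:
            raise ValueError("at least one branch must be enabled")
        unknown = set(branches) - set(BRANCHES)
        if unknown:
            raise ValueError(f"unknown branches: {sorted(unknown)}")
        rng = np.random.default_rng(config.seed)
        n_cond, n_rep, _ = expression_shape
        self.expr = _ExpressionBranchNet(n_cond, n_rep, config.conv_filters, config.conv_kernel_size, rng)
        self.loc = _DenseBranchNet([localization_dim, 64, 64, 16], rng, batch_norm_before_last=True)
        self.emb = _DenseBranchNet([embedding_dim, 64, 16], rng)
        self.head_hidden = Dense(16 * len(self.branches), 16, "relu", rng)
        self.head_out = Dense(16, 1, None, rng)
        self.config = config
        self._shapes = (tuple(expression_shape), localization_dim, embedding_dim)

    # -- plumbing ----------------------------------------------------------
    def _branch_nets(self):
        nets = {"expression": self.expr, "localization": self.loc, "embedding": self.emb}
        return [(name, nets[name]) for name in self.branches]

    @property
    def layers(self):
        out = []
        for _, net in self._branch_nets():
            out.extend(net.layers)
        out.extend([self.head_hidden, self.head_out])
        return out

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params))

    # -- forward / backward ------------------------------------------------
    def forward(self, xe: np.ndarray, xl: np.ndarray, xn: np.ndarray, train: bool = False) -> np.ndarray:
        feats = []
        for name, net in self._branch_nets():
            x = {"expression": xe, "localization": xl, "embedding": xn}[name]
            feats.append(net.forward(x, train))
        h = np.concatenate(feats, axis=1)
        h = self.head_hidden.forward(h, train)
        z = self.head_out.forward(h, train)[:, 0]
        self._prob = sigmoid(z)
        return self._prob

    def backward(self, y: np.ndarray, sample_weight: np.ndarray) -> None:
        """Gradient of weighted binary cross-entropy through the whole net."""
        w = sample_weight / sample_weight.sum()
        dz = (w * (self._prob - y))[:, None]
        d = self.head_out.backward(dz)
        d = self.head_hidden.backward(d)
        for i, (_, net) in enumerate(self._branch_nets()):
            net.backward(d[:, 16 * i : 16 * (i + 1)])


    # -- persistence -------------------------------------------------------
    def _state_arrays(self) -> list[np.ndarray]:
        arrays = list(self.params)
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                arrays.extend([layer.running_mean, layer.running_var])
        return arrays

    def save(self, path) -> None:
        import json

        meta = {
            "expression_shape": list(self._shapes[0]),
            "localization_dim": self._shapes[1],
            "embedding_dim": self._shapes[2],
            "branches": list(self.branches),
            "config": {
                f.name: (list(v) if isinstance(v := getattr(self.config, f.name), tuple) else v)
                for f in fields(TrainingConfig)
            },
        }
        arrays = {f"arr_{i}": a for i, a in enumerate(self._state_arrays())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "ThreeBranchModel":
        import json

        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            config = TrainingConfig.from_dict(
                {**meta["config"], "split_fractions": tuple(meta["config"]["split_fractions"])}
            )
            model = cls(
                tuple(meta["expression_shape"]),
                meta["localization_dim"],
                meta["embedding_dim"],
                config,
                meta["branches"],
            )
            for target, key in zip(model._state_arrays(), (f"arr_{i}" for i in range(len(data) - 1))):
                target[...] = data[key]
        return model


def build_model(
    config: TrainingConfig,
    expression_shape: tuple[int, int, int],
    localization_dim: int,
    embedding_dim: int,
    branches: Sequence[str] = BRANCHES,
) -> ThreeBranchModel:
    return ThreeBranchModel(expression_shape, localization_dim, embedding_dim, config, branches)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _bce_loss(prob: np.ndarray, y: np.ndarray, weight: np.ndarray) -> float:
    p = np.clip(prob, 1e-12, 1 - 1e-12)
    losses = -(y * np.log(p) + (1 - y) * np.log(1 - p))
    return float((weight * losses).sum() / weight.sum())


def _epoch_indices(y: np.ndarray, mode: str, seed: int, epoch: int) -> np.ndarray:
    if mode in ("sampling",):
        return balanced_epoch_sample(y, seed, epoch)
    if mode == "raw":
        n_pos = int((y == 1).sum())
        rng = np.random.default_rng([seed, epoch, 1])
        size = min(2 * n_pos, y.size)
        return rng.choice(y.size, size=size, replace=False)
    return np.arange(y.size)  # class_weight: full raw training split


def train_model(
    model: ThreeBranchModel,
    bundle: FeatureBundle,
    config: TrainingConfig | None = None,
) -> tuple[ThreeBranchModel, list[dict]]:
    """Split, then run the per-epoch loop of the configured imbalance mode.

    Returns the trained model and a per-epoch history with training loss and
    validation loss/AUC/AP.  The test split is carved out but never touched;
    recover it with :func:`split_dataset` under the same seed.
    """
    config = config or model.config
    train_b, val_b, _ = split_dataset(bundle, config.split_fractions, config.seed)
    y_train = train_b.labels
    if len(np.unique(y_train)) < 2:
        raise ValueError("training split contains a single class")
    opt = RMSprop(lr=config.learning_rate)
    rng = np.random.default_rng([config.seed, 7])
    history: list[dict] = []
    for epoch in range(config.epochs):
        idx = _epoch_indices(y_train, config.imbalance_mode, config.seed, epoch)
        idx = idx[rng.permutation(idx.size)]
        epoch_loss, n_batches = 0.0, 0
        for s in range(0, idx.size, config.batch_size):
            batch = idx[s : s + config.batch_size]
            if batch.size < 2:  # batch norm needs >= 2 in train mode
                continue
            yb = y_train[batch]
            wb = np.ones(batch.size)
            if config.imbalance_mode == "class_weight":
                wb[yb == 1] = config.class_weight_positive
            prob = model.forward(
                train_b.expression[batch],
                train_b.localization[batch],
                train_b.embedding[batch],
                train=True,
            )
            epoch_loss += _bce_loss(prob, yb, wb)
            n_batches += 1
            model.backward(yb, wb)
            opt.step(model.params, model.grads)
        record: dict = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
        val_prob = model.forward(val_b.expression, val_b.localization, val_b.embedding, train=False)
        record["val_loss"] = _bce_loss(val_prob, val_b.labels, np.ones(len(val_b)))
        if len(np.unique(val_b.labels)) == 2:
            record["val_auc"] = evaluation.roc_auc(val_b.labels, val_prob)
            record["val_ap"] = evaluation.pr_ap(val_b.labels, val_prob)
        history.append(record)
        logger.info(
            "epoch %d: train_loss=%.4f val_loss=%.4f val_auc=%s",
            epoch,
            record["train_loss"],
            record["val_loss"],
            f"{record.get('val_auc', float('nan')):.4f}",
        )
    return model, history


def predict(
    model: ThreeBranchModel,
    bundle: FeatureBundle,
    threshold: float | None = None,
    batch_size: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-protein probabilities and hard labels (``prob >= threshold``)."""
    threshold = model.config.decision_threshold if threshold is None else threshold
    probs = []
    for s in range(0, len(bundle), batch_size):
        probs.append(
            model.forward(
                bundle.expression[s : s + batch_size],
                bundle.localization[s : s + batch_size],
                bundle.embedding[s : s + batch_size],
                train=False,
            )
        )
    prob = np.concatenate(probs) if probs else np.empty(0)
    return prob, (prob >= threshold).astype(int)
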