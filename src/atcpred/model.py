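"""The convolution-transformer pair classifier and its training loop.

One encoder per drug-similarity channel turns that channel's 2 x (n + m_k)
aggregated feature into an embedding:

1. a 1-D convolution (the 2 rows are input channels) tokenises the column
   axis into L = floor((n + m_k - kernel)/stride) + 1 tokens of dimension
   ``model_width``;
2. sinusoidal positional encodings are added (optional);
3. ``n_blocks`` transformer encoder blocks — multi-head scaled dot-product
   self-attention plus a two-layer ReLU feed-forward network, post-norm
   residuals, dropout — mix the tokens;
4. average pooling over tokens yields the embedding.

The channel embeddings are concatenated and a single fully connected layer
followed by a sigmoid produces the association probability.  Training
minimises binary cross-entropy with the Adam optimizer on the balanced pair
set; all randomness (weight init, shuffling, dropout) is seeded.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .dataset import AssociationTable, FoldSplit, LabeledPair, inject_label_noise
from .drug_similarity import SimilarityMatrix
from .errors import TrainingDivergedError, ValidationError
from .features import AggregatedFeature, batch_features, feature_array
from .nn import (
    Adam,
    Conv1dTokenizer,
    Linear,
    Tensor,
    TransformerBlock,
    bce_with_logits,
    concat,
    n_tokens,
    sinusoidal_positions,
)

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "FoldResult",
    "scaled_dot_attention",
    "CTEncoder",
    "PairClassifier",
    "train",
    "predict_pair",
]

_POS_ENCODINGS = ("sinusoidal", "none")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults for the attention stack (dropout 0.1, 16 heads, feed-forward
    hidden size 128, 3 blocks) are the configuration found optimal in the
    underlying study; the convolution geometry (kernel 16, stride 8, width
    128) is this package's choice, sized to reduce a few-thousand-column
    feature to a transformer-friendly token count.
    """

    conv_kernel: int = 16
    conv_stride: int = 8
    model_width: int = 128
    n_heads: int = 16
    ffn_hidden: int = 128
    n_blocks: int = 3
    dropout: float = 0.1
    share_encoders: bool = False
    positional_encoding: str = "sinusoidal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_width % self.n_heads:
            raise ValidationError(
                f"model_width {self.model_width} must be divisible by n_heads {self.n_heads}"
            )
        if not (0.0 <= self.dropout < 1.0):
            raise ValidationError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.n_blocks < 0:
            raise ValidationError("n_blocks must be >= 0")
        if self.conv_kernel < 1 or self.conv_stride < 1:
            raise ValidationError("conv kernel and stride must be >= 1")
        if self.positional_encoding not in _POS_ENCODINGS:
            raise ValidationError(
                f"positional_encoding must be one of {_POS_ENCODINGS}"
            )

    @property
    def d_k(self) -> int:
        return self.model_width // self.n_heads


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (binary cross-entropy + Adam)."""

    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValidationError("epochs, batch_size and learning_rate must be positive")


def scaled_dot_attention(
    q: np.ndarray, k: np.ndarray, v: np.ndarray, d_k: int
) -> np.ndarray:
    """softmax(QK^T / sqrt(d_k)) V on plain arrays.

    Reference form of the attention kernel; the trainable layers use the
    autodiff equivalent.  Rows of the output are convex combinations of the
    rows of V.
    """
    q, k, v = (np.asarray(x, dtype=float) for x in (q, k, v))
    if d_k <= 0:
        raise ValidationError(f"d_k must be positive, got {d_k}")
    if q.shape[-1] != k.shape[-1] or k.shape[-2] != v.shape[-2]:
        raise ValidationError(
            f"non-conformable attention shapes Q{q.shape} K{k.shape} V{v.shape}"
        )
    scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(d_k)
    scores -= scores.max(axis=-1, keepdims=True)
    weights = np.exp(scores)
    weights /= weights.sum(axis=-1, keepdims=True)
    return weights @ v


class CTEncoder:
    """Convolution tokeniser + transformer blocks + average pooling."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.conv = Conv1dTokenizer(
            rng, config.conv_kernel, config.conv_stride, config.model_width
        )
        self.blocks = [
            TransformerBlock(
                rng, config.model_width, config.n_heads, config.ffn_hidden, config.dropout
            )
            for _ in range(config.n_blocks)
        ]
        self._pos_cache: dict[int, np.ndarray] = {}

    def _positions(self, length: int) -> np.ndarray | None:
        if self.config.positional_encoding == "none":
            return None
        if length not in self._pos_cache:
            self._pos_cache[length] = sinusoidal_positions(length, self.config.model_width)
        return self._pos_cache[length]

    def __call__(self, x: np.ndarray, rng: np.random.Generator | None = None) -> Tensor:
        """Encode a (batch, 2, n + m_k) array; ``rng`` enables dropout (training)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[1] != 2:
            raise ValidationError(f"expected (batch, 2, length) input, got {x.shape}")
        if x.shape[2] < self.config.conv_kernel:
            raise ValidationError(
                f"feature length {x.shape[2]} shorter than conv kernel "
                f"{self.config.conv_kernel}"
            )
        tokens = self.conv(x)  # (B, L, width)
        pos = self._positions(tokens.shape[1])
        if pos is not None:
            tokens = tokens + Tensor(pos)
        if rng is not None and self.config.dropout > 0:
            tokens = tokens.dropout(self.config.dropout, rng)
        for block in self.blocks:
            tokens = block(tokens, rng)
        return tokens.mean(axis=1)  # average pooling over tokens

    def parameters(self) -> list[Tensor]:
        return self.conv.parameters() + [p for b in self.blocks for p in b.parameters()]


class PairClassifier:
    """Per-channel CT encoders plus the concatenate / fully-connected / sigmoid head.

    The head is channel-position-aware: embeddings are concatenated in the
    fixed ``channels`` order, so permuting channel inputs changes the output
    unless ``share_encoders`` is set and the head weights happen to coincide.
    """

    def __init__(self, config: ModelConfig, channels: Sequence[str] = ("CS", "DDI", "SE")):
        if not channels:
            raise ValidationError("at least one channel is required")
        self.config = config
        self.channels = tuple(channels)
        rng = np.random.default_rng(config.seed)
        if config.share_encoders:
            shared = CTEncoder(config, rng)
            self.encoders = {ch: shared for ch in self.channels}
        else:
            self.encoders = {ch: CTEncoder(config, rng) for ch in self.channels}
        self.head = Linear(rng, config.model_width * len(self.channels), 1)

    def logits(
        self,
        features: Mapping[str, np.ndarray],
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        missing = [ch for ch in self.channels if ch not in features]
        if missing:
            raise ValidationError(f"missing channel features: {missing}")
        embeddings = [self.encoders[ch](features[ch], rng) for ch in self.channels]
        joint = concat(embeddings, axis=-1) if len(embeddings) > 1 else embeddings[0]
        return self.head(joint).reshape(-1)

    def predict_proba(self, features: Mapping[str, np.ndarray]) -> np.ndarray:
        """Association probabilities in (0, 1), evaluation mode (no dropout)."""
        return self.logits(features, rng=None).sigmoid().data

    def parameters(self) -> list[Tensor]:
        seen: dict[int, Tensor] = {}
        for enc in self.encoders.values():
            for p in enc.parameters():
                seen.setdefault(id(p), p)
        for p in self.head.parameters():
            seen.setdefault(id(p), p)
        return list(seen.values())

    # -- persistence ---------------------------------------------------------
    def save(self, path: "str | Path") -> None:
        path = Path(path)
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        meta = {"config": asdict(self.config), "channels": list(self.channels)}
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: "str | Path") -> "PairClassifier":
        with np.load(Path(path), allow_pickle=False) as archive:
            meta = json.loads(str(archive["__meta__"]))
            model = cls(ModelConfig(**meta["config"]), meta["channels"])
            for i, p in enumerate(model.parameters()):
                p.data[...] = archive[f"param_{i}"]
        return model


def predict_pair(features: Sequence[AggregatedFeature], model: PairClassifier) -> float:
    """Probability for one pair from its per-channel aggregated features."""
    by_channel = {f.channel: f for f in features}
    if len(by_channel) != len(features) or set(by_channel) != set(model.channels):
        raise ValidationError(
            f"need exactly one feature per channel {model.channels}, "
            f"got {[f.channel for f in features]}"
        )
    targets = {(f.drug_index, f.code_index) for f in features}
    if len(targets) != 1:
        raise ValidationError(f"features refer to different pairs: {sorted(targets)}")
    batch = {ch: by_channel[ch].matrix[None, :, :] for ch in model.channels}
    return float(model.predict_proba(batch)[0])


@dataclass
class FoldResult:
    """Outcome of training/evaluating one cross-validation fold."""

    fold_id: int
    model: PairClassifier
    test_pairs: list[LabeledPair]
    test_scores: np.ndarray
    train_losses: list[float] = field(default_factory=list)


def _channel_arrays(
    pairs: Sequence[LabeledPair],
    drug_sims: Mapping[str, SimilarityMatrix],
    atc_sim: np.ndarray,
    table: AssociationTable,
    test_pairs: Sequence[LabeledPair],
    channels: Sequence[str],
) -> dict[str, np.ndarray]:
    return {
        ch: feature_array(
            batch_features(pairs, drug_sims[ch], atc_sim, table, test_pairs)
        )
        for ch in channels
    }


def fit_classifier(
    model: PairClassifier,
    features: Mapping[str, np.ndarray],
    labels: np.ndarray,
    train_cfg: TrainConfig,
) -> list[float]:
    """Minibatch Adam/BCE training; returns the mean loss per epoch."""
    labels = np.asarray(labels, dtype=float)
    n = labels.shape[0]
    optimizer = Adam(model.parameters(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed)
    epoch_losses: list[float] = []
    for _ in range(train_cfg.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            batch = {ch: arr[idx] for ch, arr in features.items()}
            optimizer.zero_grad()
            loss = bce_with_logits(model.logits(batch, rng), labels[idx])
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"loss became {loss.data} at step {optimizer.t}; "
                    "lower the learning rate"
                )
            loss.backward()
            optimizer.step()
            total += float(loss.data) * len(idx)
        epoch_losses.append(total / n)
    return epoch_losses


def train(
    folds: Sequence[FoldSplit],
    table: AssociationTable,
    drug_sims: Mapping[str, SimilarityMatrix],
    atc_sim: np.ndarray,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    channels: Sequence[str] | None = None,
    perturbation: tuple[float, str] | None = None,
) -> list[FoldResult]:
    """Train and score every fold.

    For each fold the association features are assembled from a table whose
    test-pair cells are masked; each sample additionally has its own target
    cell zeroed.  ``perturbation=(fraction, mode)`` applies label noise to
    the training pairs of every fold (labels only; evaluation pairs are
    untouched), for robustness experiments.
    """
    if channels is None:
        channels = tuple(drug_sims)
    results: list[FoldResult] = []
    for fold in folds:
        train_pairs = list(fold.train_pairs)
        if perturbation is not None:
            fraction, mode = perturbation
            train_pairs = inject_label_noise(
                train_pairs, fraction, mode, table,
                seed=(train_cfg.seed * 1009 + fold.fold_id) % 2**31,
            )
        x_train = _channel_arrays(
            train_pairs, drug_sims, atc_sim, table, fold.test_pairs, channels
        )
        y_train = np.array([p.label for p in train_pairs], dtype=float)
        fold_model_cfg = ModelConfig(
            **{**asdict(model_cfg), "seed": (model_cfg.seed * 1013 + fold.fold_id) % 2**31}
        )
        model = PairClassifier(fold_model_cfg, channels)
        fold_train_cfg = TrainConfig(
            epochs=train_cfg.epochs,
            batch_size=train_cfg.batch_size,
            learning_rate=train_cfg.learning_rate,
            seed=(train_cfg.seed * 1019 + fold.fold_id) % 2**31,
        )
        losses = fit_classifier(model, x_train, y_train, fold_train_cfg)
        x_test = _channel_arrays(
            fold.test_pairs, drug_sims, atc_sim, table, fold.test_pairs, channels
        )
        scores = model.predict_proba(x_test)
        results.append(
            FoldResult(fold.fold_id, model, list(fold.test_pairs), scores, losses)
        )
    return results
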