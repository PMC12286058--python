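"""Autoencoder latent encoding of q-mer profiles.

The 4^q-dimensional normalized profile is compressed through a dense
encoder (256 -> 128 units, ReLU + batch normalization, 30% dropout)
into a latent code (512 features by default); the decoder mirrors the
encoder (128 -> 256) and reconstructs the input through a sigmoid
output, so reconstruction is trained with binary cross-entropy on
[0, 1]-scaled profiles.  The encoder half is what downstream
classifiers consume.

The autoencoder is fitted on training-partition features only and then
applied to held-out features, to keep the test partition unseen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn


@dataclass(frozen=True)
class AutoencoderSpec:
    input_dim: int = 4096
    encoder_widths: tuple[int, ...] = (256, 128)
    latent_dim: int = 512
    dropout: float = 0.3

    def __post_init__(self):
        if self.input_dim < 1 or self.latent_dim < 1 or any(
                w < 1 for w in self.encoder_widths):
            raise ValueError("all layer widths must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0,1), got {self.dropout}")

    @property
    def decoder_widths(self) -> tuple[int, ...]:
        return tuple(reversed(self.encoder_widths))


@dataclass
class TrainedEncoder:
    """A fitted autoencoder: full network plus the encoder-only prefix."""

    spec: AutoencoderSpec
    network: nn.Network
    n_encoder_layers: int
    loss_history: list[float] = field(default_factory=list)

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Map (rows, input_dim) profiles to (rows, latent_dim) codes."""
        X = _check_inputs(np.asarray(X, dtype=float), self.spec)
        for layer in self.network.layers[:self.n_encoder_layers]:
            X = layer.forward(X, training=False)
        return X

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        X = _check_inputs(np.asarray(X, dtype=float), self.spec)
        return self.network.forward(X, training=False)


def _check_inputs(X: np.ndarray, spec: AutoencoderSpec) -> np.ndarray:
    if X.ndim != 2 or X.shape[1] != spec.input_dim:
        raise ValueError(
            f"expected (rows, {spec.input_dim}) input, got {X.shape}")
    return X


def _scale_unit(X: np.ndarray) -> np.ndarray:
    """Clip to [0, 1]; normalized profiles already lie there per sequence,
    so this is defensive (mismatch profiles can exceed 1 when the ball is
    large relative to the window count)."""
    top = X.max()
    if top > 1.0:
        X = X / top
    return np.clip(X, 0.0, 1.0)


def _build(spec: AutoencoderSpec, rng: np.random.Generator
           ) -> tuple[nn.Network, int]:
    layers: list[nn.Layer] = []
    prev = spec.input_dim
    for width in spec.encoder_widths:
        layers += [nn.Dense(prev, width, rng), nn.BatchNorm(width), nn.ReLU()]
        prev = width
    layers.append(nn.Dropout(spec.dropout, rng))
    layers.append(nn.Dense(prev, spec.latent_dim, rng))
    n_encoder = len(layers)
    prev = spec.latent_dim
    for width in spec.decoder_widths:
        layers += [nn.Dense(prev, width, rng), nn.ReLU()]
        prev = width
    layers += [nn.Dense(prev, spec.input_dim, rng), nn.Sigmoid()]
    return nn.Network(layers), n_encoder


def fit_autoencoder(train_X: np.ndarray, spec: AutoencoderSpec | None = None,
                    *, epochs: int = 100, batch_size: int = 32,
                    lr: float = 1e-3, seed: int = 0,
                    validation_fraction: float = 0.1,
                    patience: int = 10) -> TrainedEncoder:
    """Fit the reconstruction autoencoder on training-partition profiles."""
    train_X = np.asarray(train_X, dtype=float)
    if spec is None:
        spec = AutoencoderSpec(input_dim=train_X.shape[1])
    _check_inputs(train_X, spec)
    X = _scale_unit(train_X)
    rng = np.random.default_rng(seed)
    network, n_encoder = _build(spec, rng)
    history = network.fit(X, X, epochs=epochs, batch_size=batch_size, lr=lr,
                          seed=seed, validation_fraction=validation_fraction,
                          patience=patience)
    return TrainedEncoder(spec=spec, network=network,
                          n_encoder_layers=n_encoder, loss_history=history)


def encode(model: TrainedEncoder, X: np.ndarray) -> np.ndarray:
    """Latent codes for ``X``; inference is deterministic (dropout off)."""
    return model.encode(_scale_unit(np.asarray(X, dtype=float)))
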