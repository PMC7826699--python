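"""The odor labeling convolutional encoder-decoder (OLCE).

The model is a convolutional autoencoder whose bottleneck is constrained
to odor class labels: the encoder F maps a zero-centered S x T sensor
response to a softmax probability vector over the K odor classes, and a
mirrored decoder G reconstructs the response from that vector.  Training
jointly minimizes cross-entropy at the bottleneck plus a weighted
mean-squared reconstruction error, so the label layer doubles as the
classifier output and the decoder reveals which input features drive it.

Default architecture (10 sensors x 120 time points, 7 classes):

    encoder  10x120 -conv(7,k5)-> 7x116 -pool2-> 7x58 -conv(12,k3)-> 12x56
             -pool2-> 12x28 -flatten-> 336 -FC-> 7 -softmax
    decoder  7 -FC-> 336 -> 12x28 -unpool-> 12x56 -tconv(7,k3)-> 7x58
             -unpool-> 7x116 -tconv(10,k5)-> 10x120

Unpooling re-uses the paired encoder max-pool indices; the final decoder
layer is linear because zero-centered targets are signed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .data import OdorDataset


class ArchitectureError(ValueError):
    """The layer-length arithmetic of a requested architecture is inexact."""


class NotTrainedError(RuntimeError):
    pass


@dataclass
class OlceArchitecture:
    """Structural parameters of the encoder-decoder stack."""

    in_channels: int = 10
    in_length: int = 120
    conv1_channels: int = 7
    conv1_kernel: int = 5
    conv2_channels: int = 12
    conv2_kernel: int = 3
    pool: int = 2
    n_classes: int = 7

    def length_trace(self) -> list[int]:
        """Per-stage temporal lengths [L, L1, L1/2, L2, L2/2]; raises if the
        pooling arithmetic is inexact anywhere."""
        l1 = self.in_length - (self.conv1_kernel - 1)
        if l1 < self.pool or l1 % self.pool:
            raise ArchitectureError(
                f"conv1 output length {l1} not divisible by pool {self.pool}"
            )
        p1 = l1 // self.pool
        l2 = p1 - (self.conv2_kernel - 1)
        if l2 < self.pool or l2 % self.pool:
            raise ArchitectureError(
                f"conv2 output length {l2} not divisible by pool {self.pool}"
            )
        p2 = l2 // self.pool
        return [self.in_length, l1, p1, l2, p2]

    @property
    def flatten_dim(self) -> int:
        return self.conv2_channels * self.length_trace()[-1]

    def encoder_trace(self) -> list:
        """Shapes after each encoder stage, ending at the K-way bottleneck."""
        l, l1, p1, l2, p2 = self.length_trace()
        return [
            (self.in_channels, l),
            (self.conv1_channels, l1),
            (self.conv1_channels, p1),
            (self.conv2_channels, l2),
            (self.conv2_channels, p2),
            self.flatten_dim,
            self.n_classes,
        ]

    def decoder_trace(self) -> list:
        return self.encoder_trace()[::-1]


@dataclass
class TrainConfig:
    """Optimization settings; 200 epochs of mini-batch Adam by default."""

    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    recon_weight: float = 1.0   # lambda on the reconstruction MSE
    teacher_forcing: bool = False  # decoder sees one-hot labels instead of softmax
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.recon_weight < 0:
            raise ValueError("recon_weight must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def olce_loss(
    probabilities: np.ndarray,
    true_labels: np.ndarray,
    x_hat: np.ndarray,
    x: np.ndarray,
    recon_weight: float,
) -> tuple[float, float, float]:
    """Joint objective: returns (total, classification, reconstruction).

    total = CrossEntropy(probabilities, labels) + lambda * MSE(x_hat, x).
    """
    if recon_weight < 0:
        raise ValueError("recon_weight must be >= 0")
    ce = nn.cross_entropy(np.atleast_2d(probabilities), np.atleast_1d(true_labels))
    mse = float(np.mean((x_hat - x) ** 2))
    return ce + recon_weight * mse, ce, mse


class OlceModel:
    """Encoder F and decoder G sharing max-pool indices.

    Build with :func:`build_model`; the public surface is ``encode``,
    ``decode``, ``reconstruct``, ``predict``, ``fit``, ``save``/``load``.
    """

    def __init__(self, architecture: OlceArchitecture, seed: int = 0) -> None:
        architecture.length_trace()  # validate before allocating anything
        self.architecture = architecture
        self.seed = seed
        self.trained = False
        self.history: list[dict] = []
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2**20]))
        a = architecture
        self.pool1 = nn.MaxPool1d()
        self.pool2 = nn.MaxPool1d()
        self.enc_layers: list[nn.Layer] = [
            nn.Conv1d(a.in_channels, a.conv1_channels, a.conv1_kernel, rng),
            nn.ReLU(),
            self.pool1,
            nn.Conv1d(a.conv1_channels, a.conv2_channels, a.conv2_kernel, rng),
            nn.ReLU(),
            self.pool2,
            nn.Flatten(),
            nn.Linear(a.flatten_dim, a.n_classes, rng),
        ]
        p2 = a.length_trace()[-1]
        self.dec_layers: list[nn.Layer] = [
            nn.Linear(a.n_classes, a.flatten_dim, rng),
            nn.ReLU(),
            nn.Unflatten(a.conv2_channels, p2),
            nn.MaxUnpool1d(self.pool2),
            nn.ConvTranspose1d(a.conv2_channels, a.conv1_channels, a.conv2_kernel, rng),
            nn.ReLU(),
            nn.MaxUnpool1d(self.pool1),
            nn.ConvTranspose1d(a.conv1_channels, a.in_channels, a.conv1_kernel, rng),
        ]

    # -- forward passes ----------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 2
        if single:
            x = x[None]
        a = self.architecture
        if x.shape[1:] != (a.in_channels, a.in_length):
            raise ValueError(
                f"input shape {x.shape[1:]} != ({a.in_channels}, {a.in_length})"
            )
        return x

    def _encode_batch(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = x
        for layer in self.enc_layers:
            h = layer.forward(h)
        return nn.softmax(h), h  # probabilities, logits

    def _decode_batch(self, y: np.ndarray) -> np.ndarray:
        h = y
        for layer in self.dec_layers:
            h = layer.forward(h)
        return h

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Class-probability vector(s); pooling indices are retained on the
        model for the paired :meth:`decode` call."""
        xb = self._check_input(x)
        p, _ = self._encode_batch(xb)
        return p[0] if np.asarray(x).ndim == 2 else p

    def decode(self, y: np.ndarray) -> np.ndarray:
        """Reconstruction from a bottleneck vector, using the pooling indices
        of the immediately preceding encode call."""
        y = np.asarray(y, dtype=float)
        single = y.ndim == 1
        yb = y[None] if single else y
        if yb.shape[1] != self.architecture.n_classes:
            raise ValueError(
                f"bottleneck length {yb.shape[1]} != K={self.architecture.n_classes}"
            )
        if not hasattr(self.pool1, "indices"):
            raise RuntimeError("decode requires pooling indices from a paired encode")
        out = self._decode_batch(yb)
        return out[0] if single else out

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        """decode(encode(x)) with shared pooling indices; same shape as x."""
        xb = self._check_input(x)
        p, _ = self._encode_batch(xb)
        out = self._decode_batch(p)
        return out[0] if np.asarray(x).ndim == 2 else out

    def predict(self, x: np.ndarray) -> int | np.ndarray:
        """Argmax class index; ties resolve to the lowest index.

        Predicting from an untrained model is permitted (useful for smoke
        tests) but flagged with a warning.
        """
        if not self.trained:
            warnings.warn("predicting from an untrained model", stacklevel=2)
        p = self.encode(x)
        return int(np.argmax(p)) if p.ndim == 1 else np.argmax(p, axis=1)

    # -- training ----------------------------------------------------------

    def fit(self, train: OdorDataset, config: TrainConfig) -> "OlceModel":
        """Mini-batch joint optimization of the classification +
        reconstruction objective; records per-epoch mean losses and
        training accuracy in ``self.history``."""
        if len(train) == 0:
            raise ValueError("empty training set")
        x_all = train.values_array()
        y_all = train.labels()
        k = self.architecture.n_classes
        if y_all.max() >= k:
            raise ValueError(f"label {y_all.max()} out of range for K={k}")
        n = len(train)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**21]))
        opt = nn.Adam(self.enc_layers + self.dec_layers, lr=config.learning_rate)
        lam = config.recon_weight
        onehot = np.eye(k)
        self.history = []
        for epoch in range(config.epochs):
            order = rng.permutation(n)
            tot_sum = ce_sum = mse_sum = 0.0
            correct = 0
            for start in range(0, n, config.batch_size):
                idx = order[start:start + config.batch_size]
                xb, yb = x_all[idx], y_all[idx]
                m = len(idx)
                p, logits = self._encode_batch(xb)
                dec_in = onehot[yb] if config.teacher_forcing else p
                x_hat = self._decode_batch(dec_in)
                total, ce, mse = olce_loss(p, yb, x_hat, xb, lam)
                tot_sum += total * m
                ce_sum += ce * m
                mse_sum += mse * m
                correct += int((p.argmax(axis=1) == yb).sum())
                # backward: reconstruction path
                dxhat = lam * 2.0 * (x_hat - xb) / x_hat.size
                g = dxhat
                for layer in reversed(self.dec_layers):
                    g = layer.backward(g)
                # bottleneck gradient: CE w.r.t. logits, plus the decoder's
                # gradient pulled through the softmax unless teacher-forced
                dlogits = (p - onehot[yb]) / m
                if not config.teacher_forcing:
                    dlogits = dlogits + nn.softmax_vjp(p, g)
                g = dlogits
                for layer in reversed(self.enc_layers):
                    g = layer.backward(g)
                opt.step()
            self.history.append(
                {
                    "epoch": epoch,
                    "loss": tot_sum / n,
                    "classification_loss": ce_sum / n,
                    "reconstruction_loss": mse_sum / n,
                    "train_accuracy": correct / n,
                }
            )
        self.trained = True
        return self

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        """Single-file checkpoint: architecture + parameters + history."""
        arrays: dict[str, np.ndarray] = {}
        for tag, layers in (("enc", self.enc_layers), ("dec", self.dec_layers)):
            for i, layer in enumerate(layers):
                for j, p in enumerate(layer.params):
                    arrays[f"{tag}_{i}_{j}"] = p
        meta = {
            "architecture": asdict(self.architecture),
            "seed": self.seed,
            "trained": self.trained,
            "history": self.history,
        }
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "OlceModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            model = cls(OlceArchitecture(**meta["architecture"]), seed=meta["seed"])
            model.trained = meta["trained"]
            model.history = meta["history"]
            for tag, layers in (("enc", model.enc_layers), ("dec", model.dec_layers)):
                for i, layer in enumerate(layers):
                    for j in range(len(layer.params)):
                        layer.params[j][...] = data[f"{tag}_{i}_{j}"]
        return model


def build_model(arch: OlceArchitecture | None = None, seed: int = 0) -> OlceModel:
    """Construct an untrained model, validating the layer-length arithmetic."""
    return OlceModel(arch or OlceArchitecture(), seed=seed)


class OlceClassifier:
    """Dataset-level fit/predict adapter so the encoder-decoder plugs into
    the same comparison harness as the baseline classifiers."""

    def __init__(self, architecture: OlceArchitecture | None = None,
                 train_config: TrainConfig | None = None, seed: int = 0) -> None:
        self.architecture = architecture
        base = train_config or TrainConfig()
        self.train_config = replace_seed(base, seed)
        self.seed = seed
        self.model: OlceModel | None = None

    def fit(self, dataset: OdorDataset) -> "OlceClassifier":
        arch = self.architecture
        if arch is None:
            arch = OlceArchitecture(
                in_channels=dataset.n_sensors,
                in_length=dataset.n_timepoints,
                n_classes=len(dataset.class_names),
            )
        self.model = build_model(arch, seed=self.seed)
        self.model.fit(dataset, self.train_config)
        return self

    def predict(self, dataset: OdorDataset) -> np.ndarray:
        if self.model is None:
            raise NotTrainedError("fit before predict")
        return np.asarray(self.model.predict(dataset.values_array()))


def replace_seed(config: TrainConfig, seed: int) -> TrainConfig:
    from dataclasses import replace

    return replace(config, seed=seed)
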