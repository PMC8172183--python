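"""Fully connected autoencoder, trained from scratch by minibatch SGD on an
RMSE reconstruction loss.

The network compresses a feature vector X through an encoder Z = f(X) and
reconstructs it with a mirrored decoder X' = g(Z); the code Z (50 units by
default) is the latent representation handed to the classifiers.  The loss is

    L = sqrt( (1/N) * sum_i (x_i - x'_i)^2 )

with N the total number of scalar entries in the batch.  Hidden layers use
ReLU, the output layer is linear (standard for real-valued reconstruction
under a squared-error-type loss); both are configurable, and `tanh` /
`identity` are available for gradient checking and linear-limit analyses.

Inputs are z-scored per feature column with statistics from the training
data only; the statistics are stored on the model so encoding applies the
same transform at inference time.

Everything here is plain numpy: weights, forward pass, backpropagation and
the SGD loop are explicit, and `gradient_check` validates the analytic
gradients against central finite differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import WindowedFeatures

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
}


@dataclass(frozen=True)
class AEArchitecture:
    """Layer plan: input -> encoder_widths (last entry is the latent code)
    -> mirrored decoder -> input-sized linear output."""

    input_dim: int
    encoder_widths: tuple[int, ...] = (50, 50, 50)
    hidden_activation: str = "relu"
    output_activation: str = "identity"

    def __post_init__(self) -> None:
        if self.input_dim < 1 or any(w < 1 for w in self.encoder_widths):
            raise ValueError("all layer widths must be >= 1")
        for act in (self.hidden_activation, self.output_activation):
            if act not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {act!r}")

    @property
    def latent_dim(self) -> int:
        return self.encoder_widths[-1]

    @property
    def decoder_widths(self) -> tuple[int, ...]:
        return tuple(reversed(self.encoder_widths[:-1])) + (self.input_dim,)

    @property
    def layer_widths(self) -> tuple[int, ...]:
        """Widths of every layer including input and output."""
        return (self.input_dim,) + self.encoder_widths + self.decoder_widths

    @property
    def n_encoder_layers(self) -> int:
        return len(self.encoder_widths)


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.01
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0


@dataclass
class AutoencoderModel:
    arch: AEArchitecture
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    mean: np.ndarray  # per-feature standardization, learned from training data
    scale: np.ndarray
    training_trace: list[float] = field(default_factory=list)
    seed: int | None = None

    def forward(self, X: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Return (pre-activations per layer, post-activations per layer incl. input)."""
        h_act, _ = _ACTIVATIONS[self.arch.hidden_activation]
        o_act, _ = _ACTIVATIONS[self.arch.output_activation]
        zs, hs = [], [X]
        h = X
        n_layers = len(self.weights)
        for li, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            zs.append(z)
            h = o_act(z) if li == n_layers - 1 else h_act(z)
            hs.append(h)
        return zs, hs

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[1][-1]

    def encode_matrix(self, X: np.ndarray) -> np.ndarray:
        """Latent codes for already-standardized rows."""
        return self.forward(X)[1][self.arch.n_encoder_layers]

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


def rmse_loss(x: np.ndarray, x_prime: np.ndarray) -> float:
    """Root-mean-square reconstruction error over all scalar entries."""
    x = np.asarray(x, dtype=float)
    x_prime = np.asarray(x_prime, dtype=float)
    if x.shape != x_prime.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_prime.shape}")
    return float(np.sqrt(np.mean((x - x_prime) ** 2)))


def _init_params(arch: AEArchitecture, rng: np.random.Generator):
    """Glorot-uniform weights, zero biases."""
    widths = arch.layer_widths
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _backprop(model: AutoencoderModel, X: np.ndarray):
    """Analytic gradients of the RMSE loss w.r.t. every weight and bias.

    The RMSE gradient is (x' - x) / (N * L); at zero residual (L == 0) the
    derivative is singular and the gradient is defined as zero.
    """
    _, h_deriv = _ACTIVATIONS[model.arch.hidden_activation]
    _, o_deriv = _ACTIVATIONS[model.arch.output_activation]
    zs, hs = model.forward(X)
    resid = hs[-1] - X
    n_total = resid.size
    loss = float(np.sqrt(np.mean(resid**2)))
    gW = [np.zeros_like(W) for W in model.weights]
    gb = [np.zeros_like(b) for b in model.biases]
    if loss == 0.0:
        return loss, gW, gb
    delta = resid / (n_total * loss) * o_deriv(zs[-1])
    for li in range(len(model.weights) - 1, -1, -1):
        gW[li] = hs[li].T @ delta
        gb[li] = delta.sum(axis=0)
        if li > 0:
            delta = (delta @ model.weights[li].T) * h_deriv(zs[li - 1])
    return loss, gW, gb


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, WindowedFeatures):
        return features.matrix
    return np.atleast_2d(np.asarray(features, dtype=float))


def fit_standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale < 1e-12, 1.0, scale)  # constant columns pass through
    return mean, scale


def train(
    features,
    arch: AEArchitecture | None = None,
    hyper: TrainConfig = TrainConfig(),
) -> AutoencoderModel:
    """Train an autoencoder on the feature rows; deterministic given hyper.seed.

    The trace records the full-dataset RMSE before training (epoch 0) and
    after every epoch; the returned model carries the best-epoch weights,
    so the final trace entry of the *returned* parameters never exceeds any
    earlier entry.  Training stops at max_epochs or after `patience` epochs
    without improvement.
    """
    X_raw = _as_matrix(features)
    if arch is None:
        arch = AEArchitecture(input_dim=X_raw.shape[1])
    if arch.input_dim != X_raw.shape[1]:
        raise ValueError(f"arch.input_dim={arch.input_dim} but features have {X_raw.shape[1]} columns")

    mean, scale = fit_standardizer(X_raw)
    X = (X_raw - mean) / scale
    rng = np.random.default_rng(hyper.seed)
    weights, biases = _init_params(arch, rng)
    model = AutoencoderModel(arch=arch, weights=weights, biases=biases,
                             mean=mean, scale=scale, seed=hyper.seed)

    n = X.shape[0]
    trace = [rmse_loss(X, model.reconstruct(X))]
    best_loss = trace[0]
    best_params = ([W.copy() for W in weights], [b.copy() for b in biases])
    stall = 0
    for epoch in range(1, hyper.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, hyper.batch_size):
            batch = X[order[start : start + hyper.batch_size]]
            loss, gW, gb = _backprop(model, batch)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}, lr={hyper.lr}"
                )
            for W, b, dW, db in zip(model.weights, model.biases, gW, gb):
                W -= hyper.lr * dW
                b -= hyper.lr * db
        epoch_loss = rmse_loss(X, model.reconstruct(X))
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(f"training diverged at epoch {epoch}, lr={hyper.lr}")
        trace.append(epoch_loss)
        if epoch_loss < best_loss - 1e-12:
            best_loss = epoch_loss
            best_params = ([W.copy() for W in model.weights], [b.copy() for b in model.biases])
            stall = 0
        else:
            stall += 1
            if stall >= hyper.patience:
                break
    model.weights, model.biases = best_params
    model.training_trace = trace
    return model


def encode(model: AutoencoderModel, features: WindowedFeatures, restandardize: bool = True) -> WindowedFeatures:
    """Latent representation of every row; labels and provenance carried through.

    If `restandardize`, latent columns are z-scored with their own statistics
    (computed on these rows) before being handed to a classifier.
    """
    if features.matrix.shape[1] != model.arch.input_dim:
        raise ValueError(
            f"model expects {model.arch.input_dim} input features, got {features.matrix.shape[1]}"
        )
    Z = model.encode_matrix(model.standardize(features.matrix))
    if restandardize:
        mu, sd = fit_standardizer(Z)
        Z = (Z - mu) / sd
    return WindowedFeatures(
        feature_set=features.feature_set + "_latent",
        matrix=Z,
        labels=features.labels,
        subject_ids=features.subject_ids,
        groups=features.groups,
        window_indices=features.window_indices,
        column_names=tuple(f"z{i}" for i in range(Z.shape[1])),
    )


def encode_matrix(model: AutoencoderModel, X: np.ndarray) -> np.ndarray:
    """Latent codes for a raw (unstandardized) matrix."""
    return model.encode_matrix(model.standardize(np.atleast_2d(np.asarray(X, dtype=float))))


def gradient_check(
    arch: AEArchitecture | None = None, seed: int = 0, n_points: int = 10, eps: float = 1e-6
) -> float:
    """Max relative error between backprop and central finite differences.

    Runs on a tiny network with tanh hidden units (smooth, so the finite
    difference is well posed) and random data.
    """
    if arch is None:
        arch = AEArchitecture(input_dim=3, encoder_widths=(4, 2), hidden_activation="tanh")
    rng = np.random.default_rng(seed)
    weights, biases = _init_params(arch, rng)
    model = AutoencoderModel(arch=arch, weights=weights, biases=biases,
                             mean=np.zeros(arch.input_dim), scale=np.ones(arch.input_dim))
    X = rng.standard_normal((n_points, arch.input_dim))
    _, gW, gb = _backprop(model, X)

    max_rel = 0.0
    for params, grads in ((model.weights, gW), (model.biases, gb)):
        for arr, grad in zip(params, grads):
            flat, gflat = arr.ravel(), grad.ravel()
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + eps
                lp = rmse_loss(X, model.reconstruct(X))
                flat[i] = orig - eps
                lm = rmse_loss(X, model.reconstruct(X))
                flat[i] = orig
                fd = (lp - lm) / (2 * eps)
                denom = max(abs(fd), abs(gflat[i]), 1e-8)
                max_rel = max(max_rel, abs(fd - gflat[i]) / denom)
    return max_rel


def save_model(model: AutoencoderModel, path: str | Path) -> None:
    """JSON header (architecture, seed, standardization) + text weight arrays."""
    path = Path(path)
    payload = {
        "arch": {
            "input_dim": model.arch.input_dim,
            "encoder_widths": list(model.arch.encoder_widths),
            "hidden_activation": model.arch.hidden_activation,
            "output_activation": model.arch.output_activation,
        },
        "seed": model.seed,
        "mean": model.mean.tolist(),
        "scale": model.scale.tolist(),
        "training_trace": model.training_trace,
        "weights": [W.tolist() for W in model.weights],
        "biases": [b.tolist() for b in model.biases],
    }
    path.write_text(json.dumps(payload))


def load_model(path: str | Path) -> AutoencoderModel:
    payload = json.loads(Path(path).read_text())
    arch = AEArchitecture(
        input_dim=payload["arch"]["input_dim"],
        encoder_widths=tuple(payload["arch"]["encoder_widths"]),
        hidden_activation=payload["arch"]["hidden_activation"],
        output_activation=payload["arch"]["output_activation"],
    )
    return AutoencoderModel(
        arch=arch,
        weights=[np.asarray(W, dtype=float) for W in payload["weights"]],
        biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
        mean=np.asarray(payload["mean"], dtype=float),
        scale=np.asarray(payload["scale"], dtype=float),
        training_trace=list(payload["training_trace"]),
        seed=payload["seed"],
    )
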