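"""End-to-end demonstration: a tiny dropout-enabled classifier on
procedurally generated two-class texture images.

The two classes mimic, very loosely, the textural distinction between
glandular and keratinised tumour morphology: class 0 tiles contain
soft random blobs, class 1 tiles contain an oriented stripe grating.
An ``ambiguity`` level in [0, 1] blends the two motifs (1 = equal
blend), creating decision-boundary tiles.

The classifier is a deliberately small multilayer perceptron (two
hidden layers, ReLU, sigmoid output) written directly in numpy, with
inverted dropout after each hidden layer kept active at inference so
that repeated forward passes yield a Monte Carlo dropout ensemble.
It demonstrates the mechanism end-to-end on a CPU in seconds; it makes
no performance claims.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .ensembles import TileEnsemble
from .errors import ConfigError, DomainError

# ---------------------------------------------------------------------------
# procedural images


@dataclass(frozen=True)
class ProceduralImageSpec:
    """Parameters of the two-class texture generator."""

    image_size: int = 64
    blob_count: int = 8          # class-0 motif: number of Gaussian blobs
    blob_sigma: float = 5.0      # blob radius, pixels
    stripe_frequency: float = 6.0  # class-1 motif: grating cycles per image
    noise_sd: float = 0.05       # additive pixel noise
    ambiguous_fraction: float = 0.2  # fraction of tiles given ambiguity_level
    ambiguity_level: float = 1.0     # blend applied to ambiguous tiles
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 8:
            raise ConfigError("image_size must be >= 8")
        if self.blob_count < 1:
            raise ConfigError("blob_count must be >= 1")
        if self.stripe_frequency <= 0:
            raise ConfigError("stripe_frequency must be > 0")
        if not (0.0 <= self.ambiguous_fraction <= 1.0):
            raise ConfigError("ambiguous_fraction must lie in [0, 1]")
        if not (0.0 <= self.ambiguity_level <= 1.0):
            raise ConfigError("ambiguity_level must lie in [0, 1]")


def _blob_motif(spec: ProceduralImageSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.image_size
    yy, xx = np.mgrid[0:n, 0:n]
    img = np.zeros((n, n))
    for _ in range(spec.blob_count):
        cy, cx = rng.uniform(0, n, size=2)
        img += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * spec.blob_sigma**2))
    img /= img.max() if img.max() > 0 else 1.0
    return img


def _stripe_motif(spec: ProceduralImageSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.image_size
    yy, xx = np.mgrid[0:n, 0:n]
    angle = rng.uniform(0, np.pi)
    phase = rng.uniform(0, 2 * np.pi)
    coord = np.cos(angle) * xx + np.sin(angle) * yy
    img = 0.5 + 0.5 * np.sin(2 * np.pi * spec.stripe_frequency * coord / n + phase)
    return img


def _render_tile(
    spec: ProceduralImageSpec, label: int, ambiguity: float, rng: np.random.Generator
) -> np.ndarray:
    own = _blob_motif(spec, rng) if label == 0 else _stripe_motif(spec, rng)
    other = _stripe_motif(spec, rng) if label == 0 else _blob_motif(spec, rng)
    w = 0.5 * ambiguity  # 0 -> pure motif, 1 -> equal blend
    img = (1 - w) * own + w * other
    img = img + spec.noise_sd * rng.standard_normal(img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_procedural_tiles(
    spec: ProceduralImageSpec, n_slides: int, tiles_per_slide: int
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Generate images and a manifest for ``n_slides`` slides per class.

    Returns ``(images, manifest)`` where ``images`` has shape
    ``(n_tiles, size, size)`` in [0, 1] and the manifest carries
    ``tile_id, slide_id, patient_id, label, ambiguity``.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xD3770]))
    images, rows = [], []
    for label in (0, 1):
        for s in range(n_slides):
            slide_id = f"D{label}_{s:03d}"
            for t in range(tiles_per_slide):
                ambiguous = rng.random() < spec.ambiguous_fraction
                amb = spec.ambiguity_level if ambiguous else 0.0
                images.append(_render_tile(spec, label, amb, rng))
                rows.append(
                    {
                        "tile_id": f"{slide_id}_t{t:04d}",
                        "slide_id": slide_id,
                        "patient_id": f"P_{slide_id}",
                        "label": label,
                        "ambiguity": amb,
                    }
                )
    return np.stack(images), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dropout MLP


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class DropoutMLP:
    """Two-hidden-layer perceptron with inverted dropout after each
    hidden layer, trained by Adam on binary cross-entropy.

    Dropout stays active at inference, so each call to
    :meth:`forward` with ``train=True`` masks a fresh random subset of
    hidden units — exactly the stochasticity Monte Carlo dropout
    ensembles rely on.
    """

    def __init__(self, n_features: int, hidden_width: int = 64,
                 dropout_p: float = 0.1, seed: int = 0):
        if not (0.0 <= dropout_p < 1.0):
            raise ConfigError("dropout_p must lie in [0, 1)")
        self.dropout_p = dropout_p
        self.rng = np.random.default_rng(np.random.SeedSequence([seed, 0x111D]))
        scale1 = np.sqrt(2.0 / n_features)
        scale2 = np.sqrt(2.0 / hidden_width)
        self.W1 = self.rng.standard_normal((n_features, hidden_width)) * scale1
        self.b1 = np.zeros(hidden_width)
        self.W2 = self.rng.standard_normal((hidden_width, hidden_width)) * scale2
        self.b2 = np.zeros(hidden_width)
        self.W3 = self.rng.standard_normal((hidden_width, 1)) * scale2
        self.b3 = np.zeros(1)

    def _masks(self, shape: tuple, active: bool) -> np.ndarray:
        if not active or self.dropout_p == 0.0:
            return np.ones(shape)
        keep = 1.0 - self.dropout_p
        return (self.rng.random(shape) < keep) / keep

    def forward(self, X: np.ndarray, dropout: bool):
        h1 = np.maximum(X @ self.W1 + self.b1, 0.0)
        m1 = self._masks(h1.shape, dropout)
        h1d = h1 * m1
        h2 = np.maximum(h1d @ self.W2 + self.b2, 0.0)
        m2 = self._masks(h2.shape, dropout)
        h2d = h2 * m2
        p = _sigmoid(h2d @ self.W3 + self.b3).ravel()
        return p, (X, h1, m1, h1d, h2, m2, h2d)

    def _step(self, X: np.ndarray, y: np.ndarray, lr: float, adam_state: dict) -> None:
        p, (X_, h1, m1, h1d, h2, m2, h2d) = self.forward(X, dropout=True)
        n = len(y)
        dz3 = (p - y)[:, None] / n  # BCE + sigmoid
        grads = {}
        grads["W3"] = h2d.T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dh2d = dz3 @ self.W3.T
        dz2 = dh2d * m2 * (h2 > 0)
        grads["W2"] = h1d.T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        dh1d = dz2 @ self.W2.T
        dz1 = dh1d * m1 * (h1 > 0)
        grads["W1"] = X_.T @ dz1
        grads["b1"] = dz1.sum(axis=0)

        adam_state["t"] += 1
        t = adam_state["t"]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            m = adam_state["m"][k] = beta1 * adam_state["m"][k] + (1 - beta1) * g
            v = adam_state["v"][k] = beta2 * adam_state["v"][k] + (1 - beta2) * g**2
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            setattr(self, k, getattr(self, k) - lr * mhat / (np.sqrt(vhat) + eps))

    def train(self, X: np.ndarray, y: np.ndarray, epochs: int = 15,
              batch_size: int = 64, lr: float = 1e-3) -> None:
        params = ("W1", "b1", "W2", "b2", "W3", "b3")
        adam = {
            "t": 0,
            "m": {k: np.zeros_like(getattr(self, k)) for k in params},
            "v": {k: np.zeros_like(getattr(self, k)) for k in params},
        }
        n = len(y)
        for _ in range(epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                self._step(X[idx], y[idx], lr, adam)

    def mc_passes(self, X: np.ndarray, passes: int) -> np.ndarray:
        """``passes`` stochastic forward passes; shape (n, passes)."""
        if passes < 2:
            raise DomainError("an ensemble needs >= 2 forward passes")
        return np.column_stack(
            [self.forward(X, dropout=True)[0] for _ in range(passes)]
        )


class DemoClassifier:
    """Trained demo model plus the feature pipeline, exposing the
    predictor-style ensemble interface over images."""

    def __init__(self, mlp: DropoutMLP, mean: np.ndarray, std: np.ndarray):
        self.mlp = mlp
        self._mean = mean
        self._std = std

    def _features(self, images: np.ndarray) -> np.ndarray:
        X = images.reshape(len(images), -1)
        return (X - self._mean) / self._std

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Deterministic single pass with dropout disabled."""
        p, _ = self.mlp.forward(self._features(images), dropout=False)
        return p

    def predict_ensemble(
        self,
        images: np.ndarray,
        manifest: pd.DataFrame,
        passes: int = 30,
    ) -> list[TileEnsemble]:
        values = self.mlp.mc_passes(self._features(images), passes)
        return [
            TileEnsemble(
                tile_id=str(row["tile_id"]),
                slide_id=str(row["slide_id"]),
                patient_id=str(row["patient_id"]),
                label=int(row["label"]),
                pass_values=tuple(values[i]),
            )
            for i, (_, row) in enumerate(manifest.iterrows())
        ]


def train_demo_classifier(
    images: np.ndarray,
    labels: Sequence[int],
    dropout_p: float = 0.1,
    hidden_width: int = 64,
    seed: int = 0,
    epochs: int = 15,
) -> DemoClassifier:
    """Train the dropout MLP on flattened, standardised pixels."""
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise DomainError("training set must contain both classes")
    X = images.reshape(len(images), -1)
    mean = X.mean(axis=0)
    std = X.std(axis=0) + 1e-8
    Xn = (X - mean) / std
    mlp = DropoutMLP(Xn.shape[1], hidden_width=hidden_width,
                     dropout_p=dropout_p, seed=seed)
    mlp.train(Xn, y, epochs=epochs)
    return DemoClassifier(mlp, mean, std)
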