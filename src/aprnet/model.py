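"""Hexapeptide networks and the five-member ensemble predictor.

A single network maps an encoded hexapeptide window (6 x 36 descriptors) to an
aggregation-propensity score in [0, 1]. The published architecture is eight
layers: a time-distributed input projection (36 -> 64 per residue), two
bidirectional LSTMs (per-step width 64, then a 96-wide concatenation of the
two final states), two 32-unit dense layers each followed by dropout, and a
single sigmoid output. The deployed predictor is an ensemble of five such
networks — one per cross-validation fold — whose scores are combined by
arithmetic mean.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import N_FEATURES, EncodedWindow
from . import nn

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1
ENSEMBLE_SIZE = 5

#: How the declared layer widths are wired; recorded in every model manifest.
WIRING = (
    "input: time-distributed dense (tanh), one projection per residue; "
    "bidirectional LSTM layers concatenate forward/backward hidden states "
    "(per-step width = 2 x hidden); all but the last return sequences, the "
    "last returns the concatenated final states of both directions; dense "
    "block uses ReLU with inverted dropout after each hidden dense layer; "
    "output: linear dense to one unit + logistic squashing"
)

DROPOUT_GRID = (0.0, 0.2, 0.4, 0.6, 0.8)
LEARNING_RATE_GRID = (1e-4, 1e-3, 1e-2, 1e-1)
BATCH_SIZE_GRID = (16, 32)

__all__ = [
    "ModelConfig",
    "NetworkModel",
    "EnsembleModel",
    "PUBLISHED_CONFIG",
    "build_network",
    "predict_window",
    "predict_ensemble",
    "save_model",
    "load_model",
    "ENSEMBLE_SIZE",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization hyperparameters.

    ``neurons_per_layer`` lists declared output widths in network order: the
    input projection, each bidirectional layer (total width, both directions),
    and each hidden dense layer. The final one-unit output layer is implicit
    and counts toward ``n_dense_layers``, matching the published layer
    numbering (with two bidirectional and three dense layers the network has
    eight layers).
    """

    n_bidirectional_layers: int = 2
    n_dense_layers: int = 3
    dropout: float = 0.2
    neurons_per_layer: tuple[int, ...] = (64, 64, 96, 32, 32)
    batch_size: int = 32
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_bidirectional_layers not in (1, 2):
            raise ValueError(
                f"n_bidirectional_layers must be 1 or 2, got {self.n_bidirectional_layers}"
            )
        if self.n_dense_layers not in (1, 2, 3):
            raise ValueError(
                f"n_dense_layers must be in {{1,2,3}}, got {self.n_dense_layers}"
            )
        if not any(abs(self.dropout - d) < 1e-9 for d in DROPOUT_GRID):
            raise ValueError(
                f"dropout must be on the grid {DROPOUT_GRID}, got {self.dropout}"
            )
        expected = 1 + self.n_bidirectional_layers + (self.n_dense_layers - 1)
        npl = tuple(int(n) for n in self.neurons_per_layer)
        if len(npl) != expected:
            raise ValueError(
                f"neurons_per_layer must list {expected} widths "
                f"(input projection + {self.n_bidirectional_layers} bidirectional "
                f"+ {self.n_dense_layers - 1} hidden dense), got {len(npl)}"
            )
        for w in npl:
            if not 8 <= w <= 512:
                raise ValueError(f"layer width {w} outside the allowed range [8, 512]")
        for w in npl[1:1 + self.n_bidirectional_layers]:
            if w % 2:
                raise ValueError(
                    f"bidirectional layer width {w} must be even "
                    "(it concatenates two directions)"
                )
        if self.batch_size not in BATCH_SIZE_GRID:
            raise ValueError(
                f"batch_size must be one of {BATCH_SIZE_GRID}, got {self.batch_size}"
            )
        if not any(abs(self.learning_rate - lr) / lr < 1e-9 for lr in LEARNING_RATE_GRID):
            raise ValueError(
                f"learning_rate must be one of {LEARNING_RATE_GRID}, "
                f"got {self.learning_rate}"
            )
        object.__setattr__(self, "neurons_per_layer", npl)

    @property
    def n_layers(self) -> int:
        """Layer count in the published numbering (dropout shares its dense row)."""
        return 1 + self.n_bidirectional_layers + 2 * (self.n_dense_layers - 1) + 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["neurons_per_layer"] = list(self.neurons_per_layer)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            n_bidirectional_layers=int(d["n_bidirectional_layers"]),
            n_dense_layers=int(d["n_dense_layers"]),
            dropout=float(d["dropout"]),
            neurons_per_layer=tuple(int(x) for x in d["neurons_per_layer"]),
            batch_size=int(d["batch_size"]),
            learning_rate=float(d["learning_rate"]),
        )


#: The top-performing architecture from the hyperparameter search.
PUBLISHED_CONFIG = ModelConfig()


@dataclass
class NetworkModel:
    """One trained (or freshly initialized) hexapeptide network."""

    config: ModelConfig
    net: nn.Network
    seed: int
    n_features: int = N_FEATURES
    stopping_epoch: int | None = None
    training_history: dict[str, list[float]] = field(default_factory=dict)

    @property
    def n_layers(self) -> int:
        return self.config.n_layers

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None, :, :]
        if X.ndim != 3 or X.shape[1:] != (6, self.n_features):
            raise ValueError(
                f"expected windows of shape (n, 6, {self.n_features}), got {X.shape}"
            )
        return self.net.predict_proba(X)


def build_network(config: ModelConfig, seed: int, n_features: int = N_FEATURES) -> NetworkModel:
    """Assemble an untrained network with deterministic initialization."""
    rng = np.random.default_rng(seed)
    widths = config.neurons_per_layer
    layers: list[nn.Layer] = []
    layers.append(nn.TimeDistributedDense(n_features, widths[0], rng))
    prev = widths[0]
    n_bi = config.n_bidirectional_layers
    for i in range(n_bi):
        out_width = widths[1 + i]
        layers.append(
            nn.BiLSTM(prev, out_width // 2, rng, return_sequences=(i < n_bi - 1))
        )
        prev = out_width
    for j in range(config.n_dense_layers - 1):
        w = widths[1 + n_bi + j]
        layers.append(nn.Dense(prev, w, rng, activation="relu"))
        layers.append(nn.Dropout(config.dropout))
        prev = w
    layers.append(nn.Dense(prev, 1, rng, activation=None))
    return NetworkModel(config=config, net=nn.Network(layers), seed=seed,
                        n_features=n_features)


def predict_window(model: NetworkModel, window: EncodedWindow | np.ndarray) -> float:
    """Score a single encoded hexapeptide window; dropout is inactive."""
    mat = window.matrix if isinstance(window, EncodedWindow) else np.asarray(window)
    return float(model.predict_batch(mat)[0])


@dataclass
class EnsembleModel:
    """Five fold-specific networks combined by arithmetic-mean consensus."""

    members: list[NetworkModel]
    feature_table_id: str = ""
    threshold: float | None = None  # Youden-J default classification cut-off
    allow_any_size: bool = False

    def __post_init__(self) -> None:
        if len(self.members) != ENSEMBLE_SIZE:
            if not self.allow_any_size:
                raise ValueError(
                    f"ensemble must have exactly {ENSEMBLE_SIZE} members, "
                    f"got {len(self.members)} (pass allow_any_size=True to override)"
                )
            logger.warning(
                "ensemble built with %d members instead of %d",
                len(self.members), ENSEMBLE_SIZE,
            )

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        scores = np.stack([m.predict_batch(X) for m in self.members])
        return scores.mean(axis=0)


def predict_ensemble(ensemble: EnsembleModel, window: EncodedWindow | np.ndarray) -> float:
    """Consensus score: the mean of the member scores."""
    mat = window.matrix if isinstance(window, EncodedWindow) else np.asarray(window)
    return float(ensemble.predict_batch(mat)[0])


# ---------------------------------------------------------------------------
# persistence: a directory with manifest.json plus one .npz per network
# ---------------------------------------------------------------------------

def _save_network_weights(model: NetworkModel, path: Path) -> None:
    np.savez(path, **model.net.get_weights())


def _network_manifest(model: NetworkModel) -> dict:
    return {
        "config": model.config.to_dict(),
        "seed": model.seed,
        "n_features": model.n_features,
        "stopping_epoch": model.stopping_epoch,
        "training_history": model.training_history,
    }


def _load_network(manifest: dict, weights_path: Path) -> NetworkModel:
    model = build_network(
        ModelConfig.from_dict(manifest["config"]),
        seed=int(manifest["seed"]),
        n_features=int(manifest.get("n_features", N_FEATURES)),
    )
    try:
        with np.load(weights_path) as npz:
            model.net.set_weights({k: npz[k] for k in npz.files})
    except Exception as exc:
        raise ValueError(f"corrupted or unreadable weight file {weights_path}: {exc}") from exc
    model.stopping_epoch = manifest.get("stopping_epoch")
    model.training_history = manifest.get("training_history", {})
    return model


def save_model(model: NetworkModel | EnsembleModel, path: str | Path) -> Path:
    """Persist a network or ensemble to a directory (manifest + weights)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if isinstance(model, NetworkModel):
        manifest = {
            "format_version": FORMAT_VERSION,
            "kind": "network",
            "wiring": WIRING,
            "network": _network_manifest(model),
        }
        _save_network_weights(model, path / "weights.npz")
    elif isinstance(model, EnsembleModel):
        manifest = {
            "format_version": FORMAT_VERSION,
            "kind": "ensemble",
            "wiring": WIRING,
            "feature_table_id": model.feature_table_id,
            "threshold": model.threshold,
            "n_members": len(model.members),
            "members": [_network_manifest(m) for m in model.members],
        }
        for i, m in enumerate(model.members):
            _save_network_weights(m, path / f"member_{i}.npz")
    else:
        raise TypeError(f"cannot save object of type {type(model).__name__}")
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return path


def load_model(path: str | Path) -> NetworkModel | EnsembleModel:
    """Load a model directory written by :func:`save_model`."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.is_file():
        raise FileNotFoundError(f"no manifest.json in {path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupted manifest in {path}: {exc}") from exc
    version = manifest.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"model format version {version!r} not supported "
            f"(expected {FORMAT_VERSION})"
        )
    if manifest["kind"] == "network":
        return _load_network(manifest["network"], path / "weights.npz")
    if manifest["kind"] == "ensemble":
        members = [
            _load_network(m, path / f"member_{i}.npz")
            for i, m in enumerate(manifest["members"])
        ]
        return EnsembleModel(
            members=members,
            feature_table_id=manifest.get("feature_table_id", ""),
            threshold=manifest.get("threshold"),
            allow_any_size=True,
        )
    raise ValueError(f"unknown model kind {manifest['kind']!r} in {path}")
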