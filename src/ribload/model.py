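"""CNN regression of mean ribosome load (MRL) from 50-nt 5'UTR sequence.

Architecture: three 1-D convolutional layers (120 filters each, kernel 8,
length-preserving padding, ReLU) over a one-hot encoded sequence, flattened
into a 40-unit dense layer with dropout, and a linear scalar output.
Targets are standardized on the training split before fitting and
predictions are inverse-transformed back to the MRL scale; performance is
always reported as r² on the untransformed scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from . import _nn
from .simdata import ReporterLibrary

BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}


@dataclass(frozen=True)
class ModelSpec:
    input_length: int = 50
    n_conv_layers: int = 3
    filters_per_layer: int = 120
    kernel_size: int = 8
    dense_units: int = 40
    dropout_rate: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 3

    def __post_init__(self):
        for name in ("input_length", "n_conv_layers", "filters_per_layer",
                     "kernel_size", "dense_units", "batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class EvaluationResult:
    r_squared: float
    n: int
    library_id: str = ""


def one_hot(sequence: str) -> np.ndarray:
    """L×4 one-hot matrix, column order A, C, G, T.

    Ambiguity codes (including N) are rejected: both reporter designs are
    unambiguous at 50 nt, so an N indicates an upstream processing error.
    """
    mat = np.zeros((len(sequence), 4), dtype=np.float32)
    for i, base in enumerate(sequence):
        j = _BASE_INDEX.get(base)
        if j is None:
            raise ValueError(f"invalid base {base!r} at position {i}")
        mat[i, j] = 1.0
    return mat


def decode_one_hot(matrix: np.ndarray) -> str:
    return "".join(BASE_ORDER[j] for j in np.asarray(matrix).argmax(axis=1))


def encode_sequences(sequences: Iterable[str], length: int = 50) -> np.ndarray:
    seqs = list(sequences)
    out = np.zeros((len(seqs), length, 4), dtype=np.float32)
    for i, s in enumerate(seqs):
        if len(s) != length:
            raise ValueError(f"sequence {i} has length {len(s)}, expected {length}")
        out[i] = one_hot(s)
    return out


def build_model(spec: ModelSpec, seed: int) -> _nn.Network:
    """Seeded, untrained network for the given architecture spec."""
    rng = np.random.default_rng(seed)
    layers: list = []
    cin = 4
    for _ in range(spec.n_conv_layers):
        layers.append(_nn.Conv1DSame(cin, spec.filters_per_layer, spec.kernel_size,
                                     relu=True, rng=rng))
        cin = spec.filters_per_layer
    layers.append(_nn.Flatten())
    layers.append(_nn.Dense(spec.input_length * spec.filters_per_layer,
                            spec.dense_units, relu=True, rng=rng))
    layers.append(_nn.Dropout(spec.dropout_rate))
    layers.append(_nn.Dense(spec.dense_units, 1, relu=False, rng=rng))
    return _nn.Network(layers)


@dataclass
class TrainedModel:
    """Trained network plus its target scaler and training history."""

    net: _nn.Network
    spec: ModelSpec
    scaler: tuple[float, float]  # (mean, sd) of training targets
    history: list[dict] = field(default_factory=list)
    seed: int = 0
    model_id: str = "mrl_cnn"

    # -- prediction ------------------------------------------------------
    def predict_scaled(self, x: np.ndarray) -> np.ndarray:
        """Raw network output (standardized-target scale)."""
        return self.net.predict(np.ascontiguousarray(x, dtype=np.float32))

    def input_gradients(self, x: np.ndarray) -> np.ndarray:
        return self.net.input_gradients(np.ascontiguousarray(x, dtype=np.float32))

    def predict_mrl(self, sequences: Union[Sequence[str], np.ndarray]) -> np.ndarray:
        """Predict MRL on the original scale for sequences or encoded input."""
        x = (np.ascontiguousarray(sequences, dtype=np.float32)
             if isinstance(sequences, np.ndarray) and sequences.ndim == 3
             else encode_sequences(sequences, self.spec.input_length))
        mean, sd = self.scaler
        return self.predict_scaled(x).astype(np.float64) * sd + mean

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        meta = {"spec": asdict(self.spec), "scaler": list(self.scaler),
                "history": self.history, "seed": self.seed, "model_id": self.model_id}
        arrays = {f"param_{i}": p for i, p in enumerate(self.net.params)}
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            spec = ModelSpec(**meta["spec"])
            net = build_model(spec, seed=meta["seed"])
            params = [data[f"param_{i}"] for i in range(len(net.params))]
            net.set_params(params)
        return cls(net=net, spec=spec, scaler=tuple(meta["scaler"]),
                   history=meta["history"], seed=meta["seed"], model_id=meta["model_id"])


def _train_arrays(library: ReporterLibrary, spec: ModelSpec):
    split = library.frame["split"]
    if split.notna().any() and (split == "train").any():
        train_lib = library.subset_split("train")
    else:
        train_lib = library
    mrl = train_lib.mrl
    if np.isnan(mrl).any():
        raise ValueError("training reporters missing MRL values")
    if len(train_lib) == 0:
        raise ValueError("empty training split")
    x = encode_sequences(train_lib.sequences, spec.input_length)
    return x, mrl


def train(
    net: _nn.Network,
    library: ReporterLibrary,
    epochs: Optional[int] = None,
    validation_fraction: float = 0.05,
    seed: int = 0,
    spec: Optional[ModelSpec] = None,
    epoch_callback=None,
) -> TrainedModel:
    """Fit the network on the library's train split.

    Targets are standardized with the training split's own mean/sd; the
    last ``validation_fraction`` of the split (by stored order) is held out
    for per-epoch validation-loss monitoring.
    """
    spec = spec or ModelSpec()
    epochs = epochs if epochs is not None else spec.epochs
    x, y = _train_arrays(library, spec)
    mean, sd = float(np.mean(y)), float(np.std(y))
    if sd == 0:
        raise ValueError("training targets have zero variance; cannot standardize")
    ys = ((y - mean) / sd).astype(np.float32)
    n_val = int(round(validation_fraction * len(x)))
    if n_val > 0:
        x_tr, y_tr = x[:-n_val], ys[:-n_val]
        x_val, y_val = x[-n_val:], ys[-n_val:]
    else:
        x_tr, y_tr, x_val, y_val = x, ys, None, None
    rng = np.random.default_rng(seed)
    history = _nn.fit(net, x_tr, y_tr, epochs=epochs, batch_size=spec.batch_size,
                      lr=spec.learning_rate, rng=rng, x_val=x_val, y_val=y_val,
                      epoch_callback=epoch_callback)
    return TrainedModel(net=net, spec=spec, scaler=(mean, sd), history=history, seed=seed)


def evaluate_r2(trained: TrainedModel, library: ReporterLibrary,
                split: Optional[str] = None) -> EvaluationResult:
    """Coefficient of determination on the untransformed MRL scale."""
    lib = library.subset_split(split) if split else library
    y = lib.mrl
    if len(y) < 2:
        raise ValueError("need at least 2 reporters to compute r²")
    if np.isnan(y).any():
        raise ValueError("MRL values missing")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero target variance")
    pred = trained.predict_mrl(list(lib.sequences))
    ss_res = float(np.sum((y - pred) ** 2))
    return EvaluationResult(r_squared=1.0 - ss_res / ss_tot, n=len(y),
                            library_id=lib.kind)


def fine_tune(
    pretrained: TrainedModel,
    library: ReporterLibrary,
    epoch_grid: Iterable[int] = range(1, 16),
    selection_split: str = "test",
    seed: int = 0,
) -> TrainedModel:
    """Epoch-grid transfer learning: continue training on a second library.

    For each epoch count ``e`` in the grid, the pretrained weights are
    continued on the library's train split for ``e`` epochs (targets
    re-standardized on that split, fresh optimizer state) and the candidate
    with the highest r² on ``selection_split`` wins; ties go to the
    smallest ``e``.  Implemented as one seeded run of ``max(grid)`` epochs
    with per-epoch weight snapshots, which is step-for-step identical to
    the independent runs because training is sequential.
    """
    grid = sorted(set(int(e) for e in epoch_grid))
    if not grid:
        raise ValueError("empty epoch grid")
    if grid[0] < 1:
        raise ValueError("epoch counts must be >= 1")
    sel = library.subset_split(selection_split)
    if len(sel) == 0:
        raise ValueError(f"selection split {selection_split!r} is empty")
    net = pretrained.net.copy()
    snapshots: dict[int, list[np.ndarray]] = {}

    def snap(epoch, running_net):
        if epoch in grid:
            snapshots[epoch] = [p.copy() for p in running_net.params]

    tuned = train(net, library, epochs=grid[-1], seed=seed, spec=pretrained.spec,
                  epoch_callback=snap)
    best_e, best_r2 = None, -np.inf
    scores = {}
    for e in grid:
        tuned.net.set_params(snapshots[e])
        r2 = evaluate_r2(tuned, sel).r_squared
        scores[e] = r2
        if r2 > best_r2:  # strict: ties keep the earlier (smaller) epoch
            best_e, best_r2 = e, r2
    tuned.net.set_params(snapshots[best_e])
    tuned.history = tuned.history[:best_e] + [
        {"epoch_search": scores, "selected_epochs": best_e}
    ]
    return tuned


def count_params(spec: ModelSpec) -> int:
    """Closed-form trainable parameter count for the architecture."""
    k, f, d, L = spec.kernel_size, spec.filters_per_layer, spec.dense_units, spec.input_length
    total = 4 * k * f + f
    total += (spec.n_conv_layers - 1) * (f * k * f + f)
    total += (L * f) * d + d
    total += d + 1
    return total


def with_spec(spec: ModelSpec, **overrides) -> ModelSpec:
    return replace(spec, **overrides)
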