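"""Sparse autoencoders whose latent units develop place-field-like responses.

A stack of linear maps with rectified-linear hidden units; hidden layers may
additionally be sparsified either per sample (keep the top-k activations of
each row) or per unit across a batch (lifetime sparsity: each unit keeps only
its top fraction of samples).  The output layer is linear.  The objective is
half the squared Frobenius reconstruction error, optionally restricted to the
input components belonging to the unmasked viewing sectors of each row.

Training is plain mini-batch gradient descent with a step-size adaptive
update (Adagrad by default, Adam available); gradients flow only through the
entries retained by the sparsifiers (straight-through on the support), the
standard estimator for winner-take-all autoencoders.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

DEAD_UNIT_THRESHOLD = 1e-8


# ---------------------------------------------------------------------------
# sparsity specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpatialSparsity:
    """Keep the k largest activations within each sample; zero the rest."""

    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("spatial sparsity needs k >= 1")

    def label(self) -> str:
        return f"SP{self.k}"


@dataclass(frozen=True)
class LifetimeSparsity:
    """Keep, per unit, the top p percent of activations across a batch."""

    p: float

    def __post_init__(self) -> None:
        if not (0 < self.p <= 100):
            raise ValueError("lifetime sparsity needs p in (0, 100]")

    def label(self) -> str:
        return f"LT{self.p:g}%"


Sparsity = Union[SpatialSparsity, LifetimeSparsity, None]


def spatial_sparsify(H: np.ndarray, k: int) -> np.ndarray:
    """Row-wise top-k projection; ties keep the lowest index.

    ``k`` at or above the row length is the identity.
    """
    H = np.atleast_2d(H)
    if k >= H.shape[1]:
        return H.copy()
    # stable sort of -H: equal values keep ascending column order
    order = np.argsort(-H, axis=1, kind="stable")
    out = np.zeros_like(H)
    keep = order[:, :k]
    rows = np.arange(H.shape[0])[:, None]
    out[rows, keep] = H[rows, keep]
    return out


def lifetime_sparsify(H: np.ndarray, p: float) -> np.ndarray:
    """Column-wise winner-take-all across the batch.

    Each column keeps its ``ceil(p * B / 100)`` largest entries (ties to the
    lowest row index) and zeroes the rest; rows may come out entirely zero.
    """
    H = np.atleast_2d(H)
    B = H.shape[0]
    if B == 0:
        return H.copy()
    keep_n = int(np.ceil(p * B / 100.0))
    if keep_n >= B:
        return H.copy()
    order = np.argsort(-H, axis=0, kind="stable")
    out = np.zeros_like(H)
    cols = np.arange(H.shape[1])[None, :]
    out[order[:keep_n], cols] = H[order[:keep_n], cols]
    return out


def _sparsify(H: np.ndarray, spec: Sparsity, train_mode: bool) -> np.ndarray:
    if spec is None:
        return H
    if isinstance(spec, SpatialSparsity):
        return spatial_sparsify(H, spec.k)
    if isinstance(spec, LifetimeSparsity):
        # lifetime competition needs a population of samples; at inference
        # on arbitrary single inputs it is replaced by the identity
        return lifetime_sparsify(H, spec.p) if train_mode else H
    raise TypeError(f"unknown sparsity spec {spec!r}")


# ---------------------------------------------------------------------------
# configuration and weights
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AEConfig:
    """Architecture and training hyper-parameters.

    ``layer_dims`` runs input -> hidden... -> output with equal first and
    last entries; ``sparsity`` gives one spec per hidden layer (the output
    layer is never sparsified).
    """

    layer_dims: tuple[int, ...]
    sparsity: tuple[Sparsity, ...]
    masked_loss: bool = False
    normalize: bool = True
    epochs: int = 100
    batch_size: int = 1000
    learning_rate: float = 0.015
    #: any step-size adaptive first-order method
    optimizer: str = "adagrad"
    #: "constant" or "warmup<N>" (linear ramp over the first N epochs)
    lr_schedule: str = "constant"
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.layer_dims) < 3:
            raise ValueError("need at least input, one hidden, and output layer")
        if self.layer_dims[0] != self.layer_dims[-1]:
            raise ValueError("autoencoder input and output dims must match")
        if len(self.sparsity) != len(self.layer_dims) - 2:
            raise ValueError(
                f"need one sparsity spec per hidden layer "
                f"({len(self.layer_dims) - 2}), got {len(self.sparsity)}"
            )
        if self.optimizer not in ("adagrad", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.lr_schedule != "constant" and not self.lr_schedule.startswith("warmup"):
            raise ValueError(f"unknown lr schedule {self.lr_schedule!r}")

    @property
    def latent_dim(self) -> int:
        return self.layer_dims[len(self.layer_dims) // 2]

    @property
    def latent_layer(self) -> int:
        """Index (1-based over weight layers) of the bottleneck layer."""
        return len(self.layer_dims) // 2

    def to_json(self) -> str:
        spec = []
        for s in self.sparsity:
            if s is None:
                spec.append(None)
            elif isinstance(s, SpatialSparsity):
                spec.append({"kind": "spatial", "k": s.k})
            else:
                spec.append({"kind": "lifetime", "p": s.p})
        payload = {
            "layer_dims": list(self.layer_dims),
            "sparsity": spec,
            "masked_loss": self.masked_loss,
            "normalize": self.normalize,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "optimizer": self.optimizer,
            "lr_schedule": self.lr_schedule,
            "seed": self.seed,
            "label": self.label,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AEConfig":
        payload = json.loads(text)
        spec: list[Sparsity] = []
        for s in payload["sparsity"]:
            if s is None:
                spec.append(None)
            elif s["kind"] == "spatial":
                spec.append(SpatialSparsity(s["k"]))
            else:
                spec.append(LifetimeSparsity(s["p"]))
        return cls(
            layer_dims=tuple(payload["layer_dims"]),
            sparsity=tuple(spec),
            masked_loss=payload["masked_loss"],
            normalize=payload.get("normalize", True),
            epochs=payload["epochs"],
            batch_size=payload["batch_size"],
            learning_rate=payload["learning_rate"],
            optimizer=payload.get("optimizer", "adagrad"),
            lr_schedule=payload.get("lr_schedule", "constant"),
            seed=payload["seed"],
            label=payload.get("label", ""),
        )


def hidden_dims(input_dim: int, latent_dim: int, n_layers: int) -> tuple[int, ...]:
    """Symmetric layer sizes between input and latent dim.

    Intermediate encoder layer i (from the input side) has size
    ``(input_dim - latent_dim) / 2^i``, i.e. the 5-layer default shrinks
    2700 -> 1335 -> 30.  ``n_layers`` counts all layers including input and
    output (odd, >= 3).
    """
    if n_layers < 3 or n_layers % 2 == 0:
        raise ValueError("n_layers must be odd and >= 3")
    half = (n_layers - 1) // 2
    span = input_dim - latent_dim
    enc = [input_dim] + [
        int(round(span / 2**i)) for i in range(1, half)
    ] + [latent_dim]
    return tuple(enc + enc[-2::-1])


@dataclass
class AEWeights:
    """Per-layer weight matrices and bias vectors."""

    W: list[np.ndarray]
    b: list[np.ndarray]

    @property
    def layer_dims(self) -> tuple[int, ...]:
        return tuple([self.W[0].shape[0]] + [w.shape[1] for w in self.W])

    def validate(self) -> None:
        for n, (w, bias) in enumerate(zip(self.W, self.b)):
            if not (np.isfinite(w).all() and np.isfinite(bias).all()):
                raise FloatingPointError(f"non-finite parameters in layer {n + 1}")
            if n > 0 and self.W[n - 1].shape[1] != w.shape[0]:
                raise ValueError(f"layer {n + 1} input dim does not chain")

    def save(self, out_dir: str | Path, config: AEConfig | None = None) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for n, (w, bias) in enumerate(zip(self.W, self.b)):
            arrays[f"W{n}"] = w
            arrays[f"b{n}"] = bias
        np.savez_compressed(out / "weights.npz", **arrays)
        if config is not None:
            (out / "config.json").write_text(config.to_json())

    @classmethod
    def load(cls, in_dir: str | Path) -> "AEWeights":
        data = np.load(Path(in_dir) / "weights.npz")
        n_layers = len(data.files) // 2
        return cls(
            W=[data[f"W{n}"] for n in range(n_layers)],
            b=[data[f"b{n}"] for n in range(n_layers)],
        )


def init_weights(config: AEConfig) -> AEWeights:
    """Small uniform init scaled by fan-in; zero biases."""
    rng = np.random.default_rng([zlib.crc32(b"ae-init"), config.seed])
    W, b = [], []
    for fan_in, fan_out in zip(config.layer_dims[:-1], config.layer_dims[1:]):
        scale = 1.0 / np.sqrt(fan_in)
        W.append(rng.uniform(-scale, scale, size=(fan_in, fan_out)))
        b.append(np.zeros(fan_out))
    return AEWeights(W=W, b=b)


# ---------------------------------------------------------------------------
# forward / loss
# ---------------------------------------------------------------------------


def forward(
    X: np.ndarray,
    weights: AEWeights,
    sparsity: Sequence[Sparsity],
    train_mode: bool = False,
    return_all: bool = False,
):
    """Run the network; hidden layers are ReLU + sparsifier, output is linear.

    Returns ``(H, X_hat)`` where ``H`` is the bottleneck feature map, or the
    full list of post-activation layer outputs when ``return_all`` is set.
    """
    X = np.atleast_2d(X)
    if X.shape[1] != weights.W[0].shape[0]:
        raise ValueError(
            f"input dim {X.shape[1]} does not match layer 1 ({weights.W[0].shape[0]})"
        )
    n_layers = len(weights.W)
    latent_layer = n_layers // 2  # 0-based index into outputs
    outputs = []
    A = X
    for n, (w, bias) in enumerate(zip(weights.W, weights.b)):
        Z = A @ w + bias
        if n < n_layers - 1:
            A = np.maximum(Z, 0.0)
            A = _sparsify(A, sparsity[n], train_mode)
        else:
            A = Z
        outputs.append(A)
    if return_all:
        return outputs
    return outputs[latent_layer - 1], outputs[-1]


def encode_linear(
    X: np.ndarray, weights: AEWeights, sparsity: Sequence[Sparsity] | None = None
) -> np.ndarray:
    """Latent response without bottleneck competition.

    Earlier hidden layers keep their inference-time sparsifiers (lifetime
    specs are identity at inference anyway) but the bottleneck layer applies
    only the rectifier, giving the dense "linear response" used for response
    maps.
    """
    X = np.atleast_2d(X)
    n_layers = len(weights.W)
    latent = n_layers // 2
    if sparsity is None:
        sparsity = [None] * (n_layers - 1)
    A = X
    for n in range(latent):
        Z = A @ weights.W[n] + weights.b[n]
        A = np.maximum(Z, 0.0)
        if n < latent - 1:
            A = _sparsify(A, sparsity[n], train_mode=False)
    return A


def reconstruction_loss(
    X: np.ndarray, X_hat: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Half the squared Frobenius error, optionally over unmasked entries."""
    if X.shape != X_hat.shape:
        raise ValueError("input and reconstruction shapes differ")
    diff = X - X_hat
    if mask is not None:
        diff = diff * mask
    return 0.5 * float(np.sum(diff * diff))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _sparsity_mask(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    """Gradient gate: pass only where the sparsifier retained the activation."""
    return (post > 0.0) | ((post == pre) & (pre > 0.0))


def train(
    X: np.ndarray,
    config: AEConfig,
    loss_mask: np.ndarray | None = None,
    callback=None,
) -> tuple[AEWeights, list[float]]:
    """Mini-batch Adam on the (optionally masked) reconstruction objective.

    ``loss_mask`` is a boolean matrix aligned with ``X`` flagging the entries
    that contribute to the error (the visible sector blocks).  Returns the
    trained weights and the per-epoch loss history.  Deterministic for a
    fixed config seed.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    if X.shape[0] == 0:
        raise ValueError("training set is empty")
    if config.masked_loss and loss_mask is None:
        raise ValueError("masked_loss requires a loss_mask")
    weights = init_weights(config)
    n_layers = len(weights.W)
    mW = [np.zeros_like(w) for w in weights.W]
    vW = [np.zeros_like(w) for w in weights.W]
    mb = [np.zeros_like(b) for b in weights.b]
    vb = [np.zeros_like(b) for b in weights.b]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    warmup = (
        int(config.lr_schedule.removeprefix("warmup") or 5)
        if config.lr_schedule.startswith("warmup")
        else 0
    )
    step = 0
    rng = np.random.default_rng([zlib.crc32(b"ae-batches"), config.seed])
    history: list[float] = []
    use_mask = config.masked_loss and loss_mask is not None
    for epoch in range(config.epochs):
        lr = config.learning_rate
        if warmup:
            lr *= min(1.0, (epoch + 1) / warmup)
        order = rng.permutation(X.shape[0])
        epoch_loss = 0.0
        for start in range(0, X.shape[0], config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = X[idx]
            mask = loss_mask[idx] if use_mask else None
            # forward, keeping pre-sparsification activations for the gate
            acts = [xb]
            pre_sparse = []
            A = xb
            for n in range(n_layers):
                Z = A @ weights.W[n] + weights.b[n]
                if n < n_layers - 1:
                    R = np.maximum(Z, 0.0)
                    pre_sparse.append(R)
                    A = _sparsify(R, config.sparsity[n], train_mode=True)
                else:
                    pre_sparse.append(Z)
                    A = Z
                acts.append(A)
            diff = acts[-1] - xb
            if mask is not None:
                diff = diff * mask
            with np.errstate(over="ignore"):
                batch_loss = 0.5 * float(np.sum(diff * diff))
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch + 1}: loss is not finite"
                )
            epoch_loss += batch_loss
            # backward
            G = diff
            for n in range(n_layers - 1, -1, -1):
                if n < n_layers - 1:
                    G = G * _sparsity_mask(pre_sparse[n], acts[n + 1])
                gW = acts[n].T @ G
                gb = G.sum(axis=0)
                if n > 0:
                    G = G @ weights.W[n].T
                if config.optimizer == "adagrad":
                    vW[n] += gW * gW
                    vb[n] += gb * gb
                    weights.W[n] -= lr * gW / (np.sqrt(vW[n]) + eps)
                    weights.b[n] -= lr * gb / (np.sqrt(vb[n]) + eps)
                else:  # adam
                    step_t = step + 1
                    mW[n] = beta1 * mW[n] + (1 - beta1) * gW
                    vW[n] = beta2 * vW[n] + (1 - beta2) * gW * gW
                    mb[n] = beta1 * mb[n] + (1 - beta1) * gb
                    vb[n] = beta2 * vb[n] + (1 - beta2) * gb * gb
                    corr1 = 1 - beta1**step_t
                    corr2 = 1 - beta2**step_t
                    weights.W[n] -= lr * (mW[n] / corr1) / (np.sqrt(vW[n] / corr2) + eps)
                    weights.b[n] -= lr * (mb[n] / corr1) / (np.sqrt(vb[n] / corr2) + eps)
            step += 1
        history.append(epoch_loss)
        logger.info("epoch %d/%d loss %.6g", epoch + 1, config.epochs, epoch_loss)
        if callback is not None:
            callback(epoch, epoch_loss, weights)
    weights.validate()
    return weights, history


def count_dead_units_from_responses(H: np.ndarray, threshold: float = DEAD_UNIT_THRESHOLD) -> int:
    """Units whose maximum linear response over all rows is below threshold."""
    return int(np.sum(H.max(axis=0) <= threshold))
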