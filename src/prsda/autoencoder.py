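"""Stacked denoising autoencoder with tied weights.

Each layer holds a single weight matrix ``W`` plus an encoding bias ``b`` and
a reconstruction bias ``b'``; decoding always uses ``W.T`` (tied weights), so
a layer has exactly three trainable arrays.  Encoding is sigmoid, decoding is
affine with no output nonlinearity (an optional clamp to [0, 1] is a
post-processing flag, off by default).

Training happens in two phases: greedy layer-wise denoising pretraining
(each layer reconstructs its clean input from a zero-masked copy under a
squared-error objective) followed by end-to-end fine-tuning of the mirrored
encode/decode stack under a coordinate-RMSD objective against the template
native coordinates.  All gradients are analytic backpropagation; the test
suite checks them against central finite differences.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import NormalizationScale

__all__ = [
    "SDALayer",
    "SDAModel",
    "sigmoid",
    "encode_layer",
    "decode_layer",
    "forward",
    "rmsd_loss",
    "loss_and_gradients",
    "pretrain_layerwise",
    "finetune",
    "save_checkpoint",
    "load_checkpoint",
    "DEFAULT_RATIOS",
]

DEFAULT_RATIOS = (0.9, 0.8, 0.7)
_CHECKPOINT_MAGIC = b"PRSDA-CKPT-1"
_EPS = 1e-12


def sigmoid(x):
    """Logistic function 1 / (1 + exp(-x)), elementwise, saturation-safe."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class SDALayer:
    """One tied-weight layer: W (n_in x n_out), b (n_out), b' (n_in)."""

    W: np.ndarray
    b: np.ndarray
    b_prime: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.b_prime = np.asarray(self.b_prime, dtype=float)
        n_in, n_out = self.W.shape
        if self.b.shape != (n_out,) or self.b_prime.shape != (n_in,):
            raise ValueError("bias shapes inconsistent with W")
        for arr in (self.W, self.b, self.b_prime):
            if not np.all(np.isfinite(arr)):
                raise ValueError("layer parameters must be finite")

    @property
    def n_in(self) -> int:
        return self.W.shape[0]

    @property
    def n_out(self) -> int:
        return self.W.shape[1]

    @classmethod
    def initialize(cls, n_in: int, n_out: int, rng: np.random.Generator) -> "SDALayer":
        # symmetric uniform fan-in/fan-out initialization
        bound = np.sqrt(6.0 / (n_in + n_out))
        return cls(
            W=rng.uniform(-bound, bound, size=(n_in, n_out)),
            b=np.zeros(n_out),
            b_prime=np.zeros(n_in),
        )


def encode_layer(x: np.ndarray, layer: SDALayer) -> np.ndarray:
    """y = sigmoid(x W + b); accepts a vector or a (batch, n_in) matrix."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != layer.n_in:
        raise ValueError(f"input width {x.shape[-1]} != layer n_in {layer.n_in}")
    return sigmoid(x @ layer.W + layer.b)


def decode_layer(y: np.ndarray, layer: SDALayer, clamp: bool = False) -> np.ndarray:
    """z = y W' + b' with W' = W.T; affine (no output nonlinearity).

    ``clamp`` optionally clips the result into [0, 1] as post-processing.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != layer.n_out:
        raise ValueError(f"input width {y.shape[-1]} != layer n_out {layer.n_out}")
    z = y @ layer.W.T + layer.b_prime
    if clamp:
        z = np.clip(z, 0.0, 1.0)
    return z


@dataclass
class SDAModel:
    """Mirrored encode/decode stack of tied-weight layers.

    ``scale`` is the normalization frozen at training time; ``centroid`` is
    the Angstrom centroid of the training-set reference frame, used to place
    test-time input chains.  ``training_log`` accumulates per-epoch losses.
    """

    layers: list
    scale: NormalizationScale | None = None
    seed: int = 0
    centroid: np.ndarray | None = None
    clamp_output: bool = False
    training_log: dict = field(default_factory=lambda: {"pretrain": [], "finetune": []})

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("model needs at least one layer")
        for prev, cur in zip(self.layers, self.layers[1:]):
            if cur.n_in != prev.n_out:
                raise ValueError("adjacent layer widths do not chain")
        if any(layer.n_out < 1 for layer in self.layers):
            raise ValueError("zero-width layer")

    @property
    def input_dim(self) -> int:
        return self.layers[0].n_in

    @property
    def hidden_widths(self) -> tuple[int, ...]:
        return tuple(layer.n_out for layer in self.layers)

    @classmethod
    def create(
        cls,
        input_dim: int,
        ratios: tuple[float, ...] = DEFAULT_RATIOS,
        seed: int = 0,
        scale: NormalizationScale | None = None,
    ) -> "SDAModel":
        """Build a fresh model with widths floor(ratio_k * previous width)."""
        if any(not 0 < r < 1 for r in ratios):
            raise ValueError("decrease ratios must lie in (0, 1)")
        rng = np.random.default_rng(seed)
        widths = [input_dim]
        for r in ratios:
            widths.append(int(np.floor(r * widths[-1])))
        if min(widths) < 1:
            raise ValueError("zero-width layer: input too small for the ratios")
        layers = [
            SDALayer.initialize(n_in, n_out, rng)
            for n_in, n_out in zip(widths, widths[1:])
        ]
        return cls(layers=layers, scale=scale, seed=seed)

    def parameters(self):
        for layer in self.layers:
            yield from (layer.W, layer.b, layer.b_prime)


def forward(model: SDAModel, x: np.ndarray) -> np.ndarray:
    """Encode through all layers, then decode back through them mirrored.

    Accepts a single feature vector or a (batch, input_dim) matrix; output
    has the same shape as the input.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    a = x[None, :] if single else x
    if a.shape[1] != model.input_dim:
        raise ValueError(f"input width {a.shape[1]} != model input_dim {model.input_dim}")
    for layer in model.layers:
        a = encode_layer(a, layer)
    for layer in reversed(model.layers):
        a = decode_layer(a, layer)
    if model.clamp_output:
        a = np.clip(a, 0.0, 1.0)
    return a[0] if single else a


def _coord_channel_mask(dim: int, included_residues=None) -> np.ndarray:
    """Boolean mask over feature channels selecting coordinate entries of
    included residues (residue-type channels are always excluded)."""
    if dim % 13 != 0:
        raise ValueError("feature dimension is not a multiple of 13")
    L = dim // 13
    mask = np.zeros((L, 13), dtype=bool)
    if included_residues is None:
        mask[:, :12] = True
    else:
        inc = np.asarray(included_residues)
        if inc.dtype == bool:
            mask[inc, :12] = True
        else:
            mask[inc.astype(int), :12] = True
    return mask.reshape(-1)


def rmsd_loss(pred: np.ndarray, label: np.ndarray, included_residues=None) -> float:
    """Coordinate RMSD between two feature vectors, in normalized units.

    Only the 12 coordinate channels of included residues enter the sum;
    residue-type channels (and zero-filled vacant positions, when an
    inclusion mask is given) are excluded.  ``n`` counts atoms, so the value
    matches the geometric RMSD of the de-interleaved point sets.
    """
    pred = np.asarray(pred, dtype=float)
    label = np.asarray(label, dtype=float)
    if pred.shape != label.shape:
        raise ValueError("prediction and label lengths differ")
    mask = _coord_channel_mask(pred.shape[-1], included_residues)
    n_atoms = int(mask.sum()) // 3
    if n_atoms == 0:
        raise ValueError("empty inclusion set")
    d = (pred[..., mask] - label[..., mask]) ** 2
    return float(np.sqrt(d.sum(axis=-1) / n_atoms).mean())


def loss_and_gradients(model: SDAModel, inputs: np.ndarray, labels: np.ndarray,
                       included_residues=None):
    """Mean per-sample RMSD loss on a batch plus analytic parameter gradients.

    Returns ``(loss, grads)`` where ``grads`` mirrors the layer structure as
    a list of (dW, db, db_prime) triples.
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    T = np.atleast_2d(np.asarray(labels, dtype=float))
    if X.shape != T.shape:
        raise ValueError("inputs and labels differ in shape")
    B = X.shape[0]
    mask = _coord_channel_mask(X.shape[1], included_residues)
    n_atoms = int(mask.sum()) // 3
    if n_atoms == 0:
        raise ValueError("empty inclusion set")

    # forward pass, keeping activations
    acts = [X]
    for layer in model.layers:
        acts.append(encode_layer(acts[-1], layer))
    decs = [acts[-1]]
    for layer in reversed(model.layers):
        decs.append(decode_layer(decs[-1], layer))
    Z = decs[-1]

    diff = np.where(mask, Z - T, 0.0)
    per_sample = np.sqrt((diff**2).sum(axis=1) / n_atoms)
    loss = float(per_sample.mean())
    if not np.isfinite(loss):
        raise FloatingPointError("training loss is not finite")

    # d(mean RMSD)/dZ; samples already at zero loss contribute no gradient
    denom = np.where(per_sample > _EPS, per_sample, np.inf)
    G = diff / (B * n_atoms * denom[:, None])

    K = len(model.layers)
    grads = [
        (np.zeros_like(l.W), np.zeros_like(l.b), np.zeros_like(l.b_prime))
        for l in model.layers
    ]
    # decode steps in forward order were layers reversed: layer K-1 first.
    # decs: [a_K, d_{K-1}, ..., d_0]; step m (0-based) used layer K-1-m,
    # mapping decs[m] -> decs[m+1].  Walk them backwards.
    for m in reversed(range(K)):
        layer = model.layers[K - 1 - m]
        dW, db, dbp = grads[K - 1 - m]
        dbp += G.sum(axis=0)
        dW += G.T @ decs[m]
        G = G @ layer.W  # gradient w.r.t. decs[m]

    # back through the encode chain
    for k in reversed(range(K)):
        layer = model.layers[k]
        a = acts[k + 1]
        delta = G * a * (1.0 - a)
        dW, db, dbp = grads[k]
        dW += acts[k].T @ delta
        db += delta.sum(axis=0)
        G = delta @ layer.W.T
    return loss, grads


def _mask_noise(h: np.ndarray, fraction: float, rng: np.random.Generator,
                protect_aa: bool) -> np.ndarray:
    """Zero entries independently with the given probability.

    At the visible layer the residue-type channels are protected, matching
    the corruption applied to raw feature vectors.
    """
    if fraction <= 0:
        return h
    out = h.copy()
    if protect_aa and h.shape[1] % 13 == 0:
        cols = _coord_channel_mask(h.shape[1])
        drop = rng.random((h.shape[0], int(cols.sum()))) < fraction
        sub = out[:, cols]
        sub[drop] = 0.0
        out[:, cols] = sub
    else:
        drop = rng.random(h.shape) < fraction
        out[drop] = 0.0
    return out


def pretrain_layerwise(
    model: SDAModel,
    data: np.ndarray,
    epochs: int = 100,
    learning_rate: float = 0.05,
    mask_fraction: float = 0.3,
    batch_size: int = 20,
    seed: int = 0,
) -> SDAModel:
    """Greedy denoising pretraining of each layer in place.

    Layer k is trained to reconstruct its clean input from a zero-masked copy
    under mean squared error; deeper layers consume the previous layers'
    clean encodings.  Deterministic for a given seed.  Returns the model.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[1] != model.input_dim:
        raise ValueError("data width does not match model input_dim")
    if data.shape[0] < 2:
        import logging
        logging.getLogger(__name__).warning(
            "pretraining on %d sample(s); layers will memorize", data.shape[0]
        )
    rng = np.random.default_rng(seed)
    h = data
    for k, layer in enumerate(model.layers):
        losses = []
        for _ in range(epochs):
            order = rng.permutation(h.shape[0])
            epoch_losses = []
            for start in range(0, len(order), batch_size):
                idx = order[start : start + batch_size]
                clean = h[idx]
                noisy = _mask_noise(clean, mask_fraction, rng, protect_aa=(k == 0))
                y = encode_layer(noisy, layer)
                r = decode_layer(y, layer)
                diff = r - clean
                bsz, width = clean.shape
                loss = float((diff**2).mean())
                if not np.isfinite(loss):
                    raise FloatingPointError("pretraining loss is not finite")
                epoch_losses.append(loss)
                g_r = 2.0 * diff / (bsz * width)
                d_bp = g_r.sum(axis=0)
                d_W = g_r.T @ y  # decode path
                g_y = g_r @ layer.W
                delta = g_y * y * (1.0 - y)
                d_W += noisy.T @ delta  # encode path
                d_b = delta.sum(axis=0)
                layer.W -= learning_rate * d_W
                layer.b -= learning_rate * d_b
                layer.b_prime -= learning_rate * d_bp
            losses.append(float(np.mean(epoch_losses)))
        model.training_log["pretrain"].append(losses)
        h = encode_layer(h, layer)  # clean encoding feeds the next layer
    return model


def finetune(
    model: SDAModel,
    inputs: np.ndarray,
    labels: np.ndarray,
    epochs: int = 300,
    learning_rate: float = 0.01,
    batch_size: int = 20,
    seed: int = 0,
    included_residues=None,
    corrupt_fraction: float = 0.0,
) -> SDAModel:
    """End-to-end mini-batch SGD on the coordinate-RMSD objective, in place.

    Labels are the template-native feature vectors.  Mini-batch order is
    shuffled deterministically per seed; per-epoch mean loss is appended to
    the training log.  ``corrupt_fraction`` optionally masks inputs during
    fine-tuning (off by default; denoising noise normally lives in
    pretraining only).
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    T = np.atleast_2d(np.asarray(labels, dtype=float))
    if X.shape != T.shape:
        raise ValueError("inputs and labels differ in shape")
    if X.shape[1] != model.input_dim:
        raise ValueError("data width does not match model input_dim")
    rng = np.random.default_rng(seed)
    for _ in range(epochs):
        order = rng.permutation(X.shape[0])
        epoch_losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            xb = X[idx]
            if corrupt_fraction > 0:
                xb = _mask_noise(xb, corrupt_fraction, rng, protect_aa=True)
            loss, grads = loss_and_gradients(model, xb, T[idx], included_residues)
            epoch_losses.append(loss)
            for layer, (dW, db, dbp) in zip(model.layers, grads):
                layer.W -= learning_rate * dW
                layer.b -= learning_rate * db
                layer.b_prime -= learning_rate * dbp
        model.training_log["finetune"].append(float(np.mean(epoch_losses)))
    return model


def save_checkpoint(model: SDAModel, path) -> None:
    """Serialize a model to a small versioned binary container.

    Layout: magic, 8-byte little-endian JSON header length, JSON header
    (shapes, scale, seed, centroid, training log), then the parameter arrays
    as raw little-endian float64 in layer order (W, b, b').  Byte-identical
    for identical models.
    """
    header = {
        "shapes": [list(l.W.shape) for l in model.layers],
        "scale": None if model.scale is None
        else {"xmin": model.scale.xmin, "xmax": model.scale.xmax},
        "seed": model.seed,
        "centroid": None if model.centroid is None else list(map(float, model.centroid)),
        "clamp_output": model.clamp_output,
        "training_log": model.training_log,
    }
    blob = json.dumps(header, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(_CHECKPOINT_MAGIC)
        fh.write(struct.pack("<Q", len(blob)))
        fh.write(blob)
        for arr in model.parameters():
            fh.write(np.ascontiguousarray(arr, dtype="<f8").tobytes())


def load_checkpoint(path) -> SDAModel:
    """Load a checkpoint, rejecting unknown versions or short/odd files."""
    raw = Path(path).read_bytes()
    if not raw.startswith(_CHECKPOINT_MAGIC):
        raise ValueError("not a recognized model checkpoint (bad magic/version)")
    off = len(_CHECKPOINT_MAGIC)
    (hlen,) = struct.unpack_from("<Q", raw, off)
    off += 8
    header = json.loads(raw[off : off + hlen].decode())
    off += hlen
    layers = []
    for n_in, n_out in header["shapes"]:
        arrays = []
        for shape in ((n_in, n_out), (n_out,), (n_in,)):
            count = int(np.prod(shape))
            end = off + count * 8
            if end > len(raw):
                raise ValueError("checkpoint truncated or shape-inconsistent")
            arrays.append(np.frombuffer(raw[off:end], dtype="<f8").reshape(shape).copy())
            off = end
        layers.append(SDALayer(W=arrays[0], b=arrays[1], b_prime=arrays[2]))
    if off != len(raw):
        raise ValueError("checkpoint has trailing bytes; shape-inconsistent file")
    scale = None
    if header["scale"] is not None:
        scale = NormalizationScale(header["scale"]["xmin"], header["scale"]["xmax"])
    centroid = None if header["centroid"] is None else np.array(header["centroid"])
    return SDAModel(
        layers=layers,
        scale=scale,
        seed=header["seed"],
        centroid=centroid,
        clamp_output=header.get("clamp_output", False),
        training_log=header.get("training_log", {"pretrain": [], "finetune": []}),
    )
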