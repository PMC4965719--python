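"""Stacked sparse autoencoder for learning hidden waveform features.

The encoder maps a per-channel fragment vector x in [0,1]^d through one or
two sigmoid hidden layers, h = sigma(W x + b_h); the decoder mirrors it,
x_tilde = sigma(W' h + b_x).  Training minimises the cross-entropy
reconstruction cost plus a KL sparsity penalty that pushes the mean
activation rho_hat_j of every top-layer unit toward a small target rho:

    J_SAE = sum_x L(x, g(f(x))) + beta * sum_j KL(rho || rho_hat_j)

with L the elementwise cross-entropy and KL the Bernoulli divergence.
Training is greedy layerwise pretraining followed by joint fine-tuning of
the full stack, plain mini-batch SGD throughout, deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .segmentation import FragmentPool

_EPS = 1e-10  # clamp for logs; sigmoid outputs cannot reach 0/1 in float64
              # for the weight magnitudes used here, so gradients stay exact


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class SAEConfig:
    input_dim: int
    hidden_dims: list[int] = field(default_factory=lambda: [400, 250])
    rho: float = 0.05
    beta: float = 3.0
    learning_rate: float = 0.1
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")
        if not 1 <= len(self.hidden_dims) <= 2:
            raise ValueError("hidden_dims must have one or two entries")
        for h in self.hidden_dims:
            if not 1 <= h <= self.input_dim:
                raise ValueError(
                    f"hidden dim {h} must be in [1, input_dim={self.input_dim}]"
                )
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    @property
    def n_words(self) -> int:
        """Dictionary size M = width of the top hidden layer."""
        return self.hidden_dims[-1]


def sigmoid(z):
    """Numerically stable logistic function 1 / (1 + exp(-z))."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


def reconstruction_loss(x, x_tilde) -> float:
    """Summed elementwise cross-entropy between target and reconstruction."""
    x = np.asarray(x, dtype=float)
    xt = np.clip(np.asarray(x_tilde, dtype=float), _EPS, 1.0 - _EPS)
    if x.shape != xt.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {xt.shape}")
    return float(-np.sum(x * np.log(xt) + (1.0 - x) * np.log(1.0 - xt)))


def kl_sparsity(rho: float, rho_hat) -> float:
    """Sum over units of the Bernoulli KL divergence KL(rho || rho_hat_j).

    Nonnegative; zero iff every rho_hat_j equals rho.  Mean activations at
    exactly 0 or 1 are clamped away from the boundary.
    """
    rho_hat = np.clip(np.asarray(rho_hat, dtype=float), _EPS, 1.0 - _EPS)
    return float(
        np.sum(
            rho * np.log(rho / rho_hat)
            + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rho_hat))
        )
    )


@dataclass
class SAEModel:
    """Encoder/decoder weight stacks.

    encoder[i] = (W, b) with W of shape (out, in); decoder mirrors the
    encoder in reverse so decoder[-1] maps back to input_dim.
    """

    encoder: list[tuple[np.ndarray, np.ndarray]]
    decoder: list[tuple[np.ndarray, np.ndarray]]
    config: SAEConfig

    def _check_input(self, x, dim, what):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != dim:
            raise ValueError(f"{what} has dimension {x.shape[1]}, expected {dim}")
        return x

    def encode_layers(self, x) -> list[np.ndarray]:
        """Activations of every hidden layer, bottom to top."""
        a = self._check_input(x, self.config.input_dim, "input")
        acts = []
        for W, b in self.encoder:
            a = sigmoid(a @ W.T + b)
            acts.append(a)
        return acts

    def encode(self, x) -> np.ndarray:
        """Top-layer hidden activation, length M (batch: N x M)."""
        top = self.encode_layers(x)[-1]
        return top[0] if np.asarray(x).ndim == 1 else top

    def decode(self, h) -> np.ndarray:
        a = self._check_input(h, self.config.n_words, "hidden code")
        for W, b in self.decoder:
            a = sigmoid(a @ W.T + b)
        return a[0] if np.asarray(h).ndim == 1 else a

    def reconstruct(self, x) -> np.ndarray:
        return self.decode(self.encode(x))

    # -- persistence: one JSON header line with shapes, then the flat
    #    little-endian float64 parameter arrays in header order.

    def save(self, path) -> None:
        arrays, shapes = [], []
        for side, stack in (("encoder", self.encoder), ("decoder", self.decoder)):
            for i, (W, b) in enumerate(stack):
                arrays += [W, b]
                shapes += [[f"{side}{i}.W", list(W.shape)], [f"{side}{i}.b", list(b.shape)]]
        header = {"kind": "sae", "config": asdict(self.config), "arrays": shapes}
        with open(path, "wb") as fh:
            fh.write((json.dumps(header, sort_keys=True) + "\n").encode())
            for a in arrays:
                fh.write(np.ascontiguousarray(a, dtype="<f8").tobytes())

    @classmethod
    def load(cls, path) -> "SAEModel":
        with open(path, "rb") as fh:
            header = json.loads(fh.readline().decode())
            if header.get("kind") != "sae":
                raise ValueError(f"{path} is not a serialized autoencoder")
            cfg = SAEConfig(**header["config"])
            flat: dict[str, np.ndarray] = {}
            for name, shape in header["arrays"]:
                n = int(np.prod(shape))
                flat[name] = np.frombuffer(fh.read(n * 8), dtype="<f8").reshape(shape).copy()
        n_enc = len(cfg.hidden_dims)
        enc = [(flat[f"encoder{i}.W"], flat[f"encoder{i}.b"]) for i in range(n_enc)]
        dec = [(flat[f"decoder{i}.W"], flat[f"decoder{i}.b"]) for i in range(n_enc)]
        return cls(encoder=enc, decoder=dec, config=cfg)


@dataclass
class TrainStats:
    """Per-epoch log of the cost decomposition on the full training set."""

    records: list[dict] = field(default_factory=list)

    def log(self, phase: str, epoch: int, j_sae: float, j_ae: float,
            penalty: float, rho_hat: np.ndarray) -> None:
        self.records.append(
            {"phase": phase, "epoch": epoch, "J_SAE": j_sae, "J_AE": j_ae,
             "penalty": penalty, "mean_rho_hat": float(np.mean(rho_hat))}
        )

    def of_phase(self, phase: str) -> list[dict]:
        return [r for r in self.records if r["phase"] == phase]


def _init_layer(rng, n_out: int, n_in: int):
    lim = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-lim, lim, size=(n_out, n_in)), np.zeros(n_out)


def _forward(layers, X):
    acts = [X]
    for W, b in layers:
        acts.append(sigmoid(acts[-1] @ W.T + b))
    return acts


def sae_cost(model: SAEModel, X, rho: float | None = None, beta: float | None = None):
    """(J_SAE, J_AE, rho_hat) on a batch; rho_hat from the top hidden layer."""
    X = model._check_input(X, model.config.input_dim, "batch")
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    rho = model.config.rho if rho is None else rho
    beta = model.config.beta if beta is None else beta
    acts = _forward(model.encoder + model.decoder, X)
    top = acts[len(model.encoder)]
    rho_hat = top.mean(axis=0)
    j_ae = reconstruction_loss(X, acts[-1])
    j_sae = j_ae + beta * kl_sparsity(rho, rho_hat)
    return j_sae, j_ae, rho_hat


def sae_gradient(model: SAEModel, X, rho: float | None = None, beta: float | None = None):
    """Backpropagation gradients of J_SAE w.r.t. every (W, b).

    Returns (enc_grads, dec_grads) mirroring the model's stacks.  The
    sparsity penalty enters through the top hidden layer: since rho_hat_j
    is the batch mean of activations, each sample receives the extra
    activation gradient (beta/N) * (-rho/rho_hat_j + (1-rho)/(1-rho_hat_j)).
    """
    X = model._check_input(X, model.config.input_dim, "batch")
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    rho = model.config.rho if rho is None else rho
    beta = model.config.beta if beta is None else beta
    layers = model.encoder + model.decoder
    acts = _forward(layers, X)
    n = X.shape[0]
    top_idx = len(model.encoder)
    rho_hat = acts[top_idx].mean(axis=0)

    grads = [None] * len(layers)
    # cross-entropy through sigmoid: dJ/dz at the output is (x_tilde - x)
    delta = acts[-1] - X
    for l in range(len(layers) - 1, -1, -1):
        W, _ = layers[l]
        grads[l] = (delta.T @ acts[l], delta.sum(axis=0))
        if l > 0:
            da = delta @ W
            if l == top_idx:  # inject the sparsity term at the dictionary layer
                da = da + (beta / n) * (
                    -rho / np.clip(rho_hat, _EPS, None)
                    + (1.0 - rho) / np.clip(1.0 - rho_hat, _EPS, None)
                )
            a = acts[l]
            delta = da * a * (1.0 - a)
    n_enc = len(model.encoder)
    return grads[:n_enc], grads[n_enc:]


def pool_matrix(pool: FragmentPool) -> np.ndarray:
    """Stack every channel of every normalized fragment as a training row."""
    rows = []
    for frag in pool:
        if not frag.normalized:
            raise ValueError("fragments must be normalized before training")
        rows.append(frag.values)
    if not rows:
        raise ValueError("empty fragment pool")
    return np.vstack(rows)


def fragment_features(model: SAEModel, pool: FragmentPool) -> np.ndarray:
    """Per-fragment hidden feature: channel-mean of top-layer activations.

    A fragment has one length-d vector per channel; each is encoded
    separately and the M-dimensional codes are averaged, giving one
    feature vector per fragment (n_fragments x M).
    """
    feats = np.empty((len(pool), model.config.n_words))
    for i, frag in enumerate(pool):
        feats[i] = model.encode(frag.values).mean(axis=0)
    return feats


def _sgd(model: SAEModel, X, epochs, lr, batch_size, rng, stats, phase):
    n = X.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n)
        for s in range(0, n, batch_size):
            batch = X[order[s : s + batch_size]]
            enc_g, dec_g = sae_gradient(model, batch)
            scale = lr / batch.shape[0]
            for (W, b), (gW, gb) in zip(model.encoder, enc_g):
                W -= scale * gW
                b -= scale * gb
            for (W, b), (gW, gb) in zip(model.decoder, dec_g):
                W -= scale * gW
                b -= scale * gb
        j_sae, j_ae, rho_hat = sae_cost(model, X)
        if not np.isfinite(j_sae):
            raise DivergenceError(f"{phase}: non-finite loss at epoch {epoch}")
        stats.log(phase, epoch, j_sae, j_ae, j_sae - j_ae, rho_hat)


def train_sae(data, config: SAEConfig) -> tuple[SAEModel, TrainStats]:
    """Train the stacked sparse autoencoder.

    `data` is a FragmentPool (each channel of each fragment becomes one
    training vector) or an (N, input_dim) matrix of values in [0, 1].
    Layers are pretrained greedily — each hidden layer as a one-hidden-
    layer sparse autoencoder on the codes of the layer below — and the
    full stack is then fine-tuned jointly with the sparsity penalty on
    the top (dictionary) layer.  Deterministic given config.seed.
    """
    X = pool_matrix(data) if isinstance(data, FragmentPool) else np.atleast_2d(
        np.asarray(data, dtype=float)
    )
    if X.shape[1] != config.input_dim:
        raise ValueError(f"data dimension {X.shape[1]} != input_dim {config.input_dim}")
    if X.shape[0] < config.batch_size:
        raise ValueError(
            f"need at least batch_size={config.batch_size} vectors, got {X.shape[0]}"
        )
    rng = np.random.default_rng(config.seed)
    stats = TrainStats()

    # greedy layerwise pretraining
    sub_models = []
    layer_input = X
    in_dim = config.input_dim
    for li, h in enumerate(config.hidden_dims):
        sub_cfg = SAEConfig(
            input_dim=in_dim, hidden_dims=[h], rho=config.rho, beta=config.beta,
            learning_rate=config.learning_rate, epochs=config.epochs,
            batch_size=config.batch_size, seed=config.seed,
        )
        sub = SAEModel(
            encoder=[_init_layer(rng, h, in_dim)],
            decoder=[_init_layer(rng, in_dim, h)],
            config=sub_cfg,
        )
        _sgd(sub, layer_input, config.epochs, config.learning_rate,
             config.batch_size, rng, stats, f"pretrain{li+1}")
        sub_models.append(sub)
        layer_input = sub.encode(layer_input)
        in_dim = h

    model = SAEModel(
        encoder=[sub.encoder[0] for sub in sub_models],
        decoder=[sub.decoder[0] for sub in reversed(sub_models)],
        config=config,
    )
    _sgd(model, X, config.epochs, config.learning_rate, config.batch_size,
         rng, stats, "finetune")
    return model, stats
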