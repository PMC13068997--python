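"""Client-side model and local optimization.

The federated object of study here is the classifier that sits on top of a
frozen feature-embedding pathway, so the client model is a compact
multilayer perceptron over feature vectors: one or more hidden linear
layers with ReLU activations (optionally followed by per-sample
normalization layers with learnable gain/shift), and a final 2-class linear
"head".  Parameters live in a flat :class:`~fedhetero.params.ParamVector`
with segments ``backbone`` (hidden linears), ``norm`` (normalization
gain/shift, present only when enabled) and ``head`` (final linear, weight
matrix row-major followed by bias) — the head segment is what the
representation-drift term of the aggregation rule compares across clients.

Training is mini-batch adaptive-moment gradient descent (AdamW-style:
bias-corrected first/second moments with decoupled weight decay) on
unweighted cross-entropy; everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParamVector

__all__ = [
    "ModelSpec",
    "OptState",
    "init_model",
    "train_local",
    "predict_scores",
    "loss_and_grad",
]

_EPS = 1e-5  # normalization-layer variance floor


@dataclass(frozen=True)
class ModelSpec:
    """Architecture of the client classifier.

    The default (input -> 16 -> 2) is a desk-scale analogue of the
    512-256-2 perceptron head used on frozen CT-embedding features.
    """

    input_dim: int
    hidden_dims: tuple[int, ...] = (16,)
    n_classes: int = 2
    use_norm_layers: bool = False
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if self.n_classes != 2:
            raise ValueError("only binary classification is supported")
        if not self.hidden_dims:
            raise ValueError("at least one hidden layer is required")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def _dims(self) -> list[int]:
        return [self.input_dim, *self.hidden_dims]

    def segment_sizes(self) -> dict[str, int]:
        dims = self._dims
        backbone = sum(dims[i + 1] * dims[i] + dims[i + 1] for i in range(len(dims) - 1))
        norm = 2 * sum(self.hidden_dims) if self.use_norm_layers else 0
        head = self.n_classes * dims[-1] + self.n_classes
        return {"backbone": backbone, "norm": norm, "head": head}

    def segment_map(self) -> dict[str, tuple[int, int]]:
        out: dict[str, tuple[int, int]] = {}
        offset = 0
        for name, size in self.segment_sizes().items():
            if size == 0:
                continue
            out[name] = (offset, offset + size)
            offset += size
        return out

    @property
    def n_params(self) -> int:
        return sum(self.segment_sizes().values())


def _unflatten(spec: ModelSpec, values: np.ndarray):
    """Split a flat vector into (hidden (W, b) pairs, norm (g, s) pairs, head (W, b))."""
    dims = spec._dims
    i = 0
    hidden = []
    for li in range(len(dims) - 1):
        fan_out, fan_in = dims[li + 1], dims[li]
        W = values[i : i + fan_out * fan_in].reshape(fan_out, fan_in)
        i += fan_out * fan_in
        b = values[i : i + fan_out]
        i += fan_out
        hidden.append((W, b))
    norms = []
    if spec.use_norm_layers:
        for h in spec.hidden_dims:
            g = values[i : i + h]
            i += h
            s = values[i : i + h]
            i += h
            norms.append((g, s))
    fan_out, fan_in = spec.n_classes, dims[-1]
    Wh = values[i : i + fan_out * fan_in].reshape(fan_out, fan_in)
    i += fan_out * fan_in
    bh = values[i : i + fan_out]
    return hidden, norms, (Wh, bh)


def init_model(spec: ModelSpec, seed: int) -> ParamVector:
    """He-initialized parameter vector; deterministic given the seed.

    Normalization gains start at 1 and shifts at 0; biases start at 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1417]))
    dims = spec._dims
    parts: list[np.ndarray] = []
    for li in range(len(dims) - 1):
        fan_out, fan_in = dims[li + 1], dims[li]
        parts.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=fan_out * fan_in))
        parts.append(np.zeros(fan_out))
    if spec.use_norm_layers:
        for h in spec.hidden_dims:
            parts.append(np.ones(h))
            parts.append(np.zeros(h))
    parts.append(rng.normal(0.0, np.sqrt(1.0 / dims[-1]), size=spec.n_classes * dims[-1]))
    parts.append(np.zeros(spec.n_classes))
    return ParamVector(np.concatenate(parts), spec.segment_map())


def _forward(spec: ModelSpec, values: np.ndarray, X: np.ndarray, cache: bool = False):
    hidden, norms, (Wh, bh) = _unflatten(spec, values)
    a = X
    caches = []
    for li, (W, b) in enumerate(hidden):
        z = a @ W.T + b
        if spec.use_norm_layers:
            mu = z.mean(axis=1, keepdims=True)
            var = z.var(axis=1, keepdims=True)
            sd = np.sqrt(var + _EPS)
            zhat = (z - mu) / sd
            g, s = norms[li]
            y = g * zhat + s
        else:
            zhat, sd, y = None, None, z
        a_new = np.maximum(0.0, y)
        if cache:
            caches.append((a, z, zhat, sd, y, a_new))
        a = a_new
    logits = a @ Wh.T + bh
    if cache:
        return logits, (hidden, norms, (Wh, bh), caches, a)
    return logits


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def loss_and_grad(
    spec: ModelSpec, values: np.ndarray, X: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient with respect to the flat vector."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    logits, (hidden, norms, (Wh, bh), caches, a_last) = _forward(spec, values, X, cache=True)
    probs = _softmax(logits)
    loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-300)))

    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n

    gWh = dlogits.T @ a_last
    gbh = dlogits.sum(axis=0)
    da = dlogits @ Wh

    g_hidden = [None] * len(hidden)
    g_norms = [None] * len(hidden)
    for li in range(len(hidden) - 1, -1, -1):
        a_in, z, zhat, sd, y_pre, _ = caches[li]
        dy = da * (y_pre > 0)
        if spec.use_norm_layers:
            g, _s = norms[li]
            g_norms[li] = (np.sum(dy * zhat, axis=0), dy.sum(axis=0))
            dzhat = dy * g
            m1 = dzhat.mean(axis=1, keepdims=True)
            m2 = (dzhat * zhat).mean(axis=1, keepdims=True)
            dz = (dzhat - m1 - zhat * m2) / sd
        else:
            dz = dy
        W, _b = hidden[li]
        g_hidden[li] = (dz.T @ a_in, dz.sum(axis=0))
        da = dz @ W

    parts = []
    for gW, gb in g_hidden:
        parts.append(gW.ravel())
        parts.append(gb)
    if spec.use_norm_layers:
        for gg, gs in g_norms:
            parts.append(gg)
            parts.append(gs)
    parts.append(gWh.ravel())
    parts.append(gbh)
    return loss, np.concatenate(parts)


@dataclass
class OptState:
    """Adaptive-moment optimizer state (first/second moments, step count).

    Local to one client's training pass; pass the same object to chained
    :func:`train_local` calls to continue optimization seamlessly.
    """

    m: np.ndarray
    v: np.ndarray
    t: int = 0

    @classmethod
    def fresh(cls, n_params: int) -> "OptState":
        return cls(np.zeros(n_params), np.zeros(n_params))


def train_local(
    spec: ModelSpec,
    params: ParamVector,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int,
    lr: float,
    weight_decay: float = 0.0,
    seed: int = 0,
    batch_size: int = 4,
    epoch_offset: int = 0,
    opt_state: OptState | None = None,
    betas: tuple[float, float] = (0.9, 0.999),
) -> tuple[ParamVector, float]:
    """Mini-batch AdamW-style updates: bias-corrected adaptive moments with
    decoupled weight decay.

    The batch schedule of epoch ``e`` is drawn from a stream keyed by
    ``(seed, epoch_offset + e)``, so ``epochs=2`` is identical to two
    chained ``epochs=1`` calls with offsets 0 and 1 sharing one
    ``opt_state``.  Returns the updated vector and the mean training loss
    over all steps.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if X.shape[0] == 0:
        raise ValueError("empty training split")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if X.shape[1] != spec.input_dim:
        raise ValueError(f"expected {spec.input_dim} features, got {X.shape[1]}")

    values = params.values.copy()
    if opt_state is None:
        opt_state = OptState.fresh(values.size)
    b1, b2 = betas
    eps = 1e-8
    loss_sum = 0.0
    n_seen = 0
    for e in range(epochs):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), int(epoch_offset + e), 0x5EED])
        )
        order = rng.permutation(X.shape[0])
        for start in range(0, X.shape[0], batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X[idx], y[idx]
            if spec.dropout > 0.0:
                # inverted dropout on the features entering the classifier
                mask = rng.random(xb.shape) >= spec.dropout
                xb = xb * mask / (1.0 - spec.dropout)
            loss, grad = loss_and_grad(spec, values, xb, yb)
            opt_state.t += 1
            opt_state.m = b1 * opt_state.m + (1 - b1) * grad
            opt_state.v = b2 * opt_state.v + (1 - b2) * grad**2
            mhat = opt_state.m / (1 - b1**opt_state.t)
            vhat = opt_state.v / (1 - b2**opt_state.t)
            values -= lr * mhat / (np.sqrt(vhat) + eps)
            if weight_decay:
                values -= lr * weight_decay * values
            loss_sum += loss * len(idx)
            n_seen += len(idx)
    return ParamVector(values, params.segments), loss_sum / n_seen


def predict_scores(spec: ModelSpec, params: ParamVector, X: np.ndarray) -> np.ndarray:
    """Positive-class probabilities via softmax over the two logits."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != spec.input_dim:
        raise ValueError(f"expected (n, {spec.input_dim}) features, got {X.shape}")
    logits = _forward(spec, params.values, X)
    return _softmax(logits)[:, 1]
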