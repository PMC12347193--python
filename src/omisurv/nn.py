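"""Self-normalizing feedforward network in NumPy.

The backbone is a stack of seven ``linear -> SELU -> Alpha-Dropout`` blocks
followed by a final linear layer producing a 48-dimensional patient
embedding. SELU's fixed constants (lambda = 1.05071, alpha = 1.6733) drive
activations toward zero mean and unit variance through depth when weights are
initialized zero-mean normal with variance 1/fan-in (LeCun initialization),
and Alpha-Dropout preserves that property during training by dropping units
to the SELU negative-saturation value ``-lambda*alpha`` and applying the
affine correction that restores the pre-dropout mean and variance.

Task heads are single linear layers on the embedding: a scalar hazard score
(higher = higher risk), ``n_classes`` logits (33 by default, one per cancer
type), or a scalar regression output (e.g. the TLS ratio). Forward, backward,
and the Adam optimizer are implemented here directly; everything is
deterministic given the configuration seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .matrix import InvalidInputError

__all__ = [
    "SELU_LAMBDA",
    "SELU_ALPHA",
    "SNNConfig",
    "Backbone",
    "Model",
    "Adam",
    "selu",
    "selu_grad",
    "alpha_dropout",
    "build_backbone",
    "attach_head",
    "default_hidden_widths",
]

#: SELU scale factor (the fixed point of the self-normalizing map).
SELU_LAMBDA = 1.05071
#: SELU negative scale factor.
SELU_ALPHA = 1.6733


def selu(
    x: np.ndarray | float,
    lam: float = SELU_LAMBDA,
    alpha: float = SELU_ALPHA,
) -> np.ndarray | float:
    """Scaled exponential linear unit: ``lam*x`` for x > 0, else
    ``lam*alpha*(exp(x) - 1)``. Elementwise; total on all reals."""
    x = np.asarray(x, dtype=np.float64)
    out = np.where(x > 0, lam * x, lam * alpha * np.expm1(np.minimum(x, 0.0)))
    return out if out.ndim else float(out)


def selu_grad(
    x: np.ndarray, lam: float = SELU_LAMBDA, alpha: float = SELU_ALPHA
) -> np.ndarray:
    """Derivative of SELU with respect to its input."""
    x = np.asarray(x, dtype=np.float64)
    return np.where(x > 0, lam, lam * alpha * np.exp(np.minimum(x, 0.0)))


def _alpha_dropout_coeffs(
    rate: float, lam: float = SELU_LAMBDA, alpha: float = SELU_ALPHA
) -> tuple[float, float, float]:
    """Saturation value and affine correction (a, b) for a given drop rate.

    With drop probability ``p``, units are set to ``ap = -lam*alpha`` and the
    output is ``a * (kept-or-saturated) + b`` where ``a = (q + ap^2 p q)^-1/2``
    and ``b = -a * ap * p`` (q = 1 - p). For zero-mean unit-variance input
    this restores mean 0 and variance 1 exactly.
    """
    ap = -lam * alpha
    q = 1.0 - rate
    a = (q + ap * ap * rate * q) ** -0.5
    b = -a * ap * rate
    return ap, a, b


def alpha_dropout(
    x: np.ndarray,
    rate: float,
    mode: Literal["train", "eval"] = "train",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Alpha-Dropout: identity in eval mode or at rate 0; in train mode drops
    entries to the SELU saturation value with probability ``rate`` and applies
    the mean/variance-preserving affine correction."""
    if not 0.0 <= rate < 1.0:
        raise InvalidInputError(f"dropout rate must be in [0, 1), got {rate}")
    x = np.asarray(x, dtype=np.float64)
    if mode == "eval" or rate == 0.0:
        return x
    if rng is None:
        rng = np.random.default_rng()
    keep = rng.random(x.shape) >= rate
    ap, a, b = _alpha_dropout_coeffs(rate)
    return a * np.where(keep, x, ap) + b


def default_hidden_widths(
    input_dim: int, embedding_dim: int = 48, n_hidden: int = 7
) -> list[int]:
    """Geometric taper from the input width toward the embedding width.

    The published architecture fixes depth (7 hidden layers) and the embedding
    size (48) but not the hidden widths; a geometric interpolation scales the
    same shape to any input dimension.
    """
    if input_dim < 1:
        raise InvalidInputError("input_dim must be positive")
    widths = []
    for k in range(1, n_hidden + 1):
        t = k / (n_hidden + 1)
        w = round(math.exp((1 - t) * math.log(input_dim) + t * math.log(embedding_dim)))
        widths.append(max(int(w), embedding_dim))
    return widths


@dataclass
class SNNConfig:
    """Architecture and regularization configuration of the backbone."""

    input_dim: int
    hidden_widths: Sequence[int] | None = None
    embedding_dim: int = 48
    dropout_rate: float = 0.25
    selu_lambda: float = SELU_LAMBDA
    selu_alpha: float = SELU_ALPHA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise InvalidInputError("input_dim must be positive")
        if self.hidden_widths is None:
            self.hidden_widths = default_hidden_widths(
                self.input_dim, self.embedding_dim
            )
        self.hidden_widths = [int(w) for w in self.hidden_widths]
        if any(w <= 0 for w in self.hidden_widths):
            raise InvalidInputError("hidden widths must be positive")
        if self.embedding_dim < 1:
            raise InvalidInputError("embedding_dim must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise InvalidInputError("dropout_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "input_dim": self.input_dim,
            "hidden_widths": list(self.hidden_widths),
            "embedding_dim": self.embedding_dim,
            "dropout_rate": self.dropout_rate,
            "selu_lambda": self.selu_lambda,
            "selu_alpha": self.selu_alpha,
            "seed": self.seed,
        }


class Backbone:
    """Seven-block self-normalizing encoder producing patient embeddings.

    Weights are LeCun-normal (variance 1/fan-in), fully determined by the
    config seed. ``mode`` is ``'train'`` or ``'eval'``; eval-mode forward is
    deterministic, train-mode forward draws dropout masks from the backbone's
    seeded generator.
    """

    def __init__(self, config: SNNConfig):
        self.config = config
        self.mode: Literal["train", "eval"] = "eval"
        rng = np.random.default_rng(config.seed)
        dims = [config.input_dim, *config.hidden_widths, config.embedding_dim]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            self.weights.append(rng.normal(0.0, fan_in**-0.5, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(1)[0]
        )

    @property
    def n_hidden_blocks(self) -> int:
        return len(self.weights) - 1  # final linear layer is the embedding layer

    def train(self) -> "Backbone":
        self.mode = "train"
        return self

    def eval(self) -> "Backbone":
        self.mode = "eval"
        return self

    def parameters(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases]

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.config.input_dim:
            raise InvalidInputError(
                f"expected input of shape (n, {self.config.input_dim}), "
                f"got {x.shape}"
            )
        return x

    def forward(
        self, x: np.ndarray, return_hidden: bool = False
    ) -> np.ndarray | tuple[np.ndarray, list[np.ndarray]]:
        """Map ``(n, input_dim)`` inputs to ``(n, embedding_dim)`` embeddings.

        With ``return_hidden=True`` also returns the post-activation (after
        SELU, before dropout) output of each hidden block — used to verify the
        self-normalization property.
        """
        x = self._check_input(x)
        cfg = self.config
        h = x
        hidden: list[np.ndarray] = []
        for k in range(self.n_hidden_blocks):
            z = h @ self.weights[k] + self.biases[k]
            a = selu(z, cfg.selu_lambda, cfg.selu_alpha)
            if return_hidden:
                hidden.append(a)
            if self.mode == "train" and cfg.dropout_rate > 0:
                a = alpha_dropout(a, cfg.dropout_rate, "train", self._dropout_rng)
            h = a
        emb = h @ self.weights[-1] + self.biases[-1]
        return (emb, hidden) if return_hidden else emb

    __call__ = forward

    def forward_cached(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        """Forward pass retaining the intermediates needed for backprop."""
        x = self._check_input(x)
        cfg = self.config
        h = x
        inputs, preacts, keeps = [], [], []
        train = self.mode == "train" and cfg.dropout_rate > 0
        for k in range(self.n_hidden_blocks):
            inputs.append(h)
            z = h @ self.weights[k] + self.biases[k]
            preacts.append(z)
            a = selu(z, cfg.selu_lambda, cfg.selu_alpha)
            if train:
                keep = self._dropout_rng.random(a.shape) >= cfg.dropout_rate
                ap, sa, sb = _alpha_dropout_coeffs(
                    cfg.dropout_rate, cfg.selu_lambda, cfg.selu_alpha
                )
                a = sa * np.where(keep, a, ap) + sb
                keeps.append((keep, sa))
            else:
                keeps.append(None)
            h = a
        inputs.append(h)
        emb = h @ self.weights[-1] + self.biases[-1]
        return emb, {"inputs": inputs, "preacts": preacts, "keeps": keeps}

    def backward(
        self, grad_emb: np.ndarray, cache: dict
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Gradients of the loss w.r.t. all weights and biases, given the
        gradient at the embedding output."""
        cfg = self.config
        gW = [np.empty(0)] * len(self.weights)
        gb = [np.empty(0)] * len(self.biases)
        inputs, preacts, keeps = cache["inputs"], cache["preacts"], cache["keeps"]
        g = grad_emb
        gW[-1] = inputs[-1].T @ g
        gb[-1] = g.sum(axis=0)
        g = g @ self.weights[-1].T
        for k in range(self.n_hidden_blocks - 1, -1, -1):
            if keeps[k] is not None:
                keep, sa = keeps[k]
                g = g * sa * keep
            g = g * selu_grad(preacts[k], cfg.selu_lambda, cfg.selu_alpha)
            gW[k] = inputs[k].T @ g
            gb[k] = g.sum(axis=0)
            if k > 0:
                g = g @ self.weights[k].T
        return gW, gb


HEAD_KINDS = ("hazard", "classify", "regress")


class Model:
    """A backbone with one linear task head.

    The head maps the 48-d embedding to a scalar hazard score (higher means
    higher risk, i.e. shorter expected survival), class logits, or a scalar
    regression estimate. The backbone object is shared — swapping heads never
    touches encoder parameters.
    """

    def __init__(self, backbone: Backbone, kind: str, n_classes: int = 33):
        if kind not in HEAD_KINDS:
            raise InvalidInputError(
                f"unknown head kind {kind!r}; expected one of {HEAD_KINDS}"
            )
        self.backbone = backbone
        self.kind = kind
        self.output_dim = n_classes if kind == "classify" else 1
        rng = np.random.default_rng(
            np.random.SeedSequence(backbone.config.seed).spawn(2)[1]
        )
        d = backbone.config.embedding_dim
        self.head_w = rng.normal(0.0, d**-0.5, size=(d, self.output_dim))
        self.head_b = np.zeros(self.output_dim)

    def train(self) -> "Model":
        self.backbone.train()
        return self

    def eval(self) -> "Model":
        self.backbone.eval()
        return self

    def parameters(self) -> list[np.ndarray]:
        return [*self.backbone.parameters(), self.head_w, self.head_b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.backbone.forward(x) @ self.head_w + self.head_b
        return out[:, 0] if self.output_dim == 1 else out

    __call__ = forward

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Deterministic eval-mode prediction: hazard scores, class
        probabilities (softmax), or regression estimates."""
        mode = self.backbone.mode
        self.backbone.eval()
        try:
            out = self.forward(x)
        finally:
            self.backbone.mode = mode
        if self.kind == "classify":
            e = np.exp(out - out.max(axis=1, keepdims=True))
            return e / e.sum(axis=1, keepdims=True)
        return out

    def forward_cached(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        emb, cache = self.backbone.forward_cached(x)
        cache["emb"] = emb
        out = emb @ self.head_w + self.head_b
        return (out[:, 0] if self.output_dim == 1 else out), cache

    def backward(self, grad_out: np.ndarray, cache: dict) -> list[np.ndarray]:
        if grad_out.ndim == 1:
            grad_out = grad_out[:, None]
        g_head_w = cache["emb"].T @ grad_out
        g_head_b = grad_out.sum(axis=0)
        gW, gb = self.backbone.backward(grad_out @ self.head_w.T, cache)
        return [*gW, *gb, g_head_w, g_head_b]

    def state_dict(self) -> dict:
        return {
            "config": self.backbone.config.to_dict(),
            "kind": self.kind,
            "n_classes": self.output_dim if self.kind == "classify" else 33,
            "params": [p.copy() for p in self.parameters()],
        }

    def load_params(self, params: Sequence[np.ndarray]) -> None:
        own = self.parameters()
        if len(own) != len(params):
            raise InvalidInputError("parameter count mismatch")
        for p, q in zip(own, params):
            if p.shape != q.shape:
                raise InvalidInputError(
                    f"parameter shape mismatch: {p.shape} vs {q.shape}"
                )
            p[...] = q

    def copy(self) -> "Model":
        clone = Model(
            Backbone(replace(self.backbone.config)),
            self.kind,
            self.output_dim if self.kind == "classify" else 33,
        )
        clone.load_params(self.parameters())
        return clone

    def with_dropout(self, rate: float) -> "Model":
        """Same parameters, different dropout rate (used by fine-tuning)."""
        cfg = replace(self.backbone.config, dropout_rate=rate)
        clone = Model(
            Backbone(cfg), self.kind, self.output_dim if self.kind == "classify" else 33
        )
        clone.load_params(self.parameters())
        return clone


def build_backbone(config: SNNConfig) -> Backbone:
    """Construct the seven-block self-normalizing encoder from its config."""
    return Backbone(config)


def attach_head(backbone: Backbone, kind: str, n_classes: int = 33) -> Model:
    """Attach a linear task head to a (shared) backbone."""
    return Model(backbone, kind, n_classes)


class Adam:
    """Adam optimizer over a model's parameter list.

    ``weight_decay`` is an L2 penalty added to the gradient (applied to
    weight matrices only, not biases).
    """

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(self.params, grads)):
            if self.weight_decay and p.ndim > 1:
                g = g + self.weight_decay * p
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
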