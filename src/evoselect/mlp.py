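"""Multilayer perceptron trained with Levenberg-Marquardt backpropagation.

The classifier is a fully-connected net with hidden layers of 20, 10 and 5
units (tanh) and a single sigmoid output, trained to minimize the sum of
squared errors F(x) = e(x)^T e(x) over the flat parameter vector x of all
weights and biases.  Each update solves

    x_{k+1} = x_k - (J^T J + mu I)^(-1) J^T e

where J is the Jacobian of the error vector e = t - a with respect to x,
assembled from layer sensitivities propagated backward through the network.
The damping mu is adapted by the usual accept/reject schedule: an accepted
step (F decreased) divides mu, a rejected one multiplies it.

When the parameter count exceeds the number of error components the step is
computed through the algebraically identical dual system
J^T (J J^T + mu I)^(-1) e, which keeps the linear solve at the size of the
training set rather than the size of x.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "MLP",
    "TrainConfig",
    "TrainHistory",
    "init_network",
    "forward",
    "compute_jacobian",
    "lm_step",
    "train_lmbp",
]

HIDDEN_LAYERS = (20, 10, 5)


def _tanh(n: np.ndarray) -> np.ndarray:
    return np.tanh(n)


def _dtanh(a: np.ndarray, n: np.ndarray) -> np.ndarray:
    return 1.0 - a * a


def _sigmoid(n: np.ndarray) -> np.ndarray:
    out = np.empty_like(n)
    pos = n >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-n[pos]))
    en = np.exp(n[~pos])
    out[~pos] = en / (1.0 + en)
    return out


def _dsigmoid(a: np.ndarray, n: np.ndarray) -> np.ndarray:
    return a * (1.0 - a)


def _linear(n: np.ndarray) -> np.ndarray:
    return n


def _dlinear(a: np.ndarray, n: np.ndarray) -> np.ndarray:
    return np.ones_like(n)


ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "tanh": (_tanh, _dtanh),
    "sigmoid": (_sigmoid, _dsigmoid),
    "linear": (_linear, _dlinear),
}


def param_count(layer_sizes: Sequence[int]) -> int:
    return int(sum((layer_sizes[m - 1] + 1) * layer_sizes[m] for m in range(1, len(layer_sizes))))


@dataclass
class MLP:
    """A feed-forward net: layer sizes, per-layer activations, flat parameters x."""

    layer_sizes: tuple[int, ...]
    activations: tuple[str, ...]
    x: np.ndarray

    def __post_init__(self) -> None:
        self.layer_sizes = tuple(int(s) for s in self.layer_sizes)
        self.activations = tuple(self.activations)
        self.x = np.asarray(self.x, dtype=float)
        if len(self.activations) != len(self.layer_sizes) - 1:
            raise ValueError("need one activation per non-input layer")
        for name in self.activations:
            if name not in ACTIVATIONS:
                raise ValueError(f"unknown activation {name!r}")
        if self.x.shape != (param_count(self.layer_sizes),):
            raise ValueError(
                f"x has length {self.x.size}, topology needs {param_count(self.layer_sizes)}"
            )
        if not np.all(np.isfinite(self.x)):
            raise ValueError("parameters must be finite")

    @property
    def n_params(self) -> int:
        return self.x.size

    def weights(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Views (W_m of shape out x in, b_m) into the flat vector x."""
        out = []
        offset = 0
        for m in range(1, len(self.layer_sizes)):
            n_in, n_out = self.layer_sizes[m - 1], self.layer_sizes[m]
            w = self.x[offset : offset + n_in * n_out].reshape(n_out, n_in)
            offset += n_in * n_out
            b = self.x[offset : offset + n_out]
            offset += n_out
            out.append((w, b))
        return out

    def with_x(self, x: np.ndarray) -> "MLP":
        return MLP(self.layer_sizes, self.activations, x)


def init_network(
    input_dim: int,
    seed: int,
    hidden: tuple[int, ...] = HIDDEN_LAYERS,
    output_dim: int = 1,
    init_scale: float = 0.05,
) -> MLP:
    """Standard topology (input, 20, 10, 5, 1): tanh hidden layers, sigmoid output.

    Weights and biases are drawn uniformly in +-init_scale/sqrt(fan_in),
    seeded for reproducibility.  The small default scale starts training in
    the near-linear regime, which empirically avoids most of the poor local
    minima the damped Gauss-Newton steps otherwise settle into.
    """
    if input_dim < 1:
        raise ValueError(f"input_dim must be >= 1, got {input_dim}")
    layer_sizes = (input_dim, *hidden, output_dim)
    activations = ("tanh",) * len(hidden) + ("sigmoid",)
    rng = np.random.default_rng(seed)
    chunks = []
    for m in range(1, len(layer_sizes)):
        n_in, n_out = layer_sizes[m - 1], layer_sizes[m]
        bound = init_scale / np.sqrt(n_in)
        chunks.append(rng.uniform(-bound, bound, size=n_in * n_out + n_out))
    return MLP(layer_sizes, activations, np.concatenate(chunks))


@dataclass
class ForwardCache:
    """Per-layer activations a_m and net inputs n_m from one forward pass."""

    a: list[np.ndarray]  # a[0] = inputs, a[M] = outputs; each (n_cases, size_m)
    n: list[np.ndarray]  # net inputs per non-input layer; n[m] pairs with a[m+1]


def forward(mlp: MLP, inputs: np.ndarray) -> tuple[np.ndarray, ForwardCache]:
    """Propagate inputs (n_cases x input_dim) forward; cache a_m, n_m."""
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if X.shape[1] != mlp.layer_sizes[0]:
        raise ValueError(
            f"input width {X.shape[1]} does not match topology input {mlp.layer_sizes[0]}"
        )
    a_list = [X]
    n_list = []
    a = X
    for (w, b), act in zip(mlp.weights(), mlp.activations):
        n = a @ w.T + b
        a = ACTIVATIONS[act][0](n)
        n_list.append(n)
        a_list.append(a)
    return a, ForwardCache(a=a_list, n=n_list)


def compute_jacobian(mlp: MLP, cache: ForwardCache) -> np.ndarray:
    """Jacobian of the error vector e = t - a w.r.t. x.

    Row order: case-major, then output component.  Columns follow the flat
    layout of x.  Built from the sensitivity recursion
    S^m = F'^m(n^m) * (W^{m+1})^T S^{m+1}, seeded at the output layer with
    S^M = -F'^M(n^M) (the derivative of e, hence the sign).
    """
    n_layers = len(mlp.layer_sizes) - 1
    n_cases = cache.a[0].shape[0]
    n_out = mlp.layer_sizes[-1]
    params = mlp.weights()

    # S[m] has shape (n_cases, layer_size_m, n_out)
    sens: list[np.ndarray | None] = [None] * n_layers
    d_last = ACTIVATIONS[mlp.activations[-1]][1](cache.a[-1], cache.n[-1])
    s = np.zeros((n_cases, n_out, n_out))
    diag = np.arange(n_out)
    s[:, diag, diag] = -d_last
    sens[n_layers - 1] = s
    for m in range(n_layers - 2, -1, -1):
        w_next = params[m + 1][0]  # (size_{m+1}, size_m)
        back = np.einsum("ji,njo->nio", w_next, sens[m + 1])
        d_m = ACTIVATIONS[mlp.activations[m]][1](cache.a[m + 1], cache.n[m])
        sens[m] = d_m[:, :, np.newaxis] * back

    J = np.empty((n_cases * n_out, mlp.n_params))
    col = 0
    for m in range(n_layers):
        a_prev = cache.a[m]  # (n_cases, size_{m-1})
        s_m = sens[m]  # (n_cases, size_m, n_out)
        n_in = mlp.layer_sizes[m]
        n_units = mlp.layer_sizes[m + 1]
        # weight block: d e_{c,o} / d W[i, j] = S[c, i, o] * a_prev[c, j]
        wblock = np.einsum("cio,cj->coij", s_m, a_prev).reshape(
            n_cases * n_out, n_units * n_in
        )
        J[:, col : col + n_units * n_in] = wblock
        col += n_units * n_in
        bblock = np.transpose(s_m, (0, 2, 1)).reshape(n_cases * n_out, n_units)
        J[:, col : col + n_units] = bblock
        col += n_units
    return J


def errors_and_loss(mlp: MLP, X: np.ndarray, T: np.ndarray) -> tuple[np.ndarray, float, ForwardCache]:
    out, cache = forward(mlp, X)
    T = np.atleast_2d(np.asarray(T, dtype=float))
    e = (T - out).reshape(-1)
    return e, float(e @ e), cache


def lm_step(x: np.ndarray, J: np.ndarray, e: np.ndarray, mu: float) -> np.ndarray:
    """One damped Gauss-Newton candidate: x - (J^T J + mu I)^(-1) J^T e.

    Solved without forming an explicit inverse; when rows(J) < cols(J) the
    dual form x - J^T (J J^T + mu I)^(-1) e is used (identical result).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if not (np.all(np.isfinite(J)) and np.all(np.isfinite(e))):
        raise FloatingPointError("non-finite Jacobian or error vector")
    n_rows, n_cols = J.shape
    if n_rows < n_cols:
        A = J @ J.T
        A[np.diag_indices_from(A)] += mu
        delta = J.T @ np.linalg.solve(A, e)
    else:
        A = J.T @ J
        A[np.diag_indices_from(A)] += mu
        delta = np.linalg.solve(A, J.T @ e)
    return x - delta


@dataclass(frozen=True)
class TrainConfig:
    """LM damping schedule and stopping rules."""

    max_iterations: int = 100
    mu_init: float = 1e-3
    mu_increase_factor: float = 10.0
    mu_decrease_factor: float = 10.0
    mu_max: float = 1e10
    goal_mse: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_init <= 0:
            raise ValueError("mu_init must be positive")
        if self.mu_increase_factor <= 1 or self.mu_decrease_factor <= 1:
            raise ValueError("mu factors must exceed 1")


@dataclass
class TrainHistory:
    """Per-iteration log: loss F, MSE, damping mu, and whether the step was accepted."""

    iteration: list[int] = field(default_factory=list)
    F: list[float] = field(default_factory=list)
    mse: list[float] = field(default_factory=list)
    mu: list[float] = field(default_factory=list)
    accepted: list[bool] = field(default_factory=list)

    def record(self, it: int, F: float, mse: float, mu: float, accepted: bool) -> None:
        self.iteration.append(it)
        self.F.append(F)
        self.mse.append(mse)
        self.mu.append(mu)
        self.accepted.append(accepted)

    def accepted_F(self) -> list[float]:
        return [f for f, ok in zip(self.F, self.accepted) if ok]


def train_lmbp(
    mlp: MLP, X: np.ndarray, T: np.ndarray, cfg: TrainConfig
) -> tuple[MLP, TrainHistory]:
    """Train by LM accept/reject iterations until goal MSE, max iterations or mu_max.

    Each outer iteration computes the Jacobian once, then proposes steps with
    increasing mu until one lowers F (accept: mu shrinks) or mu exceeds
    mu_max (terminate).  The accepted-step F sequence is strictly decreasing
    by construction.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("need at least one training case")
    history = TrainHistory()
    e, F, cache = errors_and_loss(mlp, X, T)
    n_err = e.size
    mu = cfg.mu_init
    for it in range(cfg.max_iterations):
        if F / n_err <= cfg.goal_mse:
            break
        J = compute_jacobian(mlp, cache)
        improved = False
        while mu <= cfg.mu_max:
            x_new = lm_step(mlp.x, J, e, mu)
            cand = mlp.with_x(x_new)
            e_new, F_new, cache_new = errors_and_loss(cand, X, T)
            if not np.isfinite(F_new):
                raise FloatingPointError(
                    f"non-finite loss at iteration {it} (mu={mu:g}); aborting"
                )
            if F_new < F:
                mlp, e, F, cache = cand, e_new, F_new, cache_new
                mu = mu / cfg.mu_decrease_factor
                history.record(it, F, F / n_err, mu, True)
                improved = True
                break
            mu = mu * cfg.mu_increase_factor
            history.record(it, F_new, F_new / n_err, mu, False)
        if not improved:
            break
    return mlp, history
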