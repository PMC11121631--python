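"""Deep N-to-1 convolutional neural network: forward pass and exact gradients.

The model maps a variable-length sequence of per-position feature vectors
(width D) to a single 8-class probability vector:

    input kernel  -> hidden kernels (x k) -> average pooling -> fully connected

Every convolutional kernel is itself a small two-layer feed-forward network
applied at each sequence position with shared weights: a proper kernel
reading a window of ``2*semi_context + 1`` positions, a sigmoid, a kernel of
size 1, and another sigmoid.  The input kernel uses semi-context ``c``, the
``k`` hidden-to-hidden kernels use semi-context ``gamma``.  The outputs of
the last kernel are averaged element-wise over all N positions into one
state vector, from which a fully connected network (one sigmoid hidden
layer, softmax output) predicts the class.

Windows extending past either end of the sequence are padded with zero
vectors, so every one of the N true positions contributes to the pooling
mean.  With no hidden-to-hidden kernel the architecture has 3 hidden layers
(two in the input kernel plus the fully connected hidden layer); each
hidden-to-hidden kernel adds 2, giving ``3 + 2k`` in total.

Everything is plain float64 numpy; gradients are analytic (verified against
central finite differences in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .records import N_CLASSES, LocalizationClass

__all__ = [
    "N1NNConfig",
    "N1NNParams",
    "ForwardTrace",
    "init_params",
    "forward",
    "loss",
    "backward",
    "apply_gradients",
]

#: Probability floor used when computing -log p[target].
_LOSS_FLOOR = 1e-12


@dataclass(frozen=True)
class N1NNConfig:
    """Hyperparameters of one N-to-1 network.

    Parameters
    ----------
    c
        Input semi-context: the input kernel reads ``2c + 1`` positions.
    gamma
        Hidden semi-context: each hidden kernel reads ``2*gamma + 1``
        intermediate state vectors.
    n_hidden_kernels
        Number k of hidden-to-hidden kernels stacked after the input kernel
        (k = 0 is the minimal architecture).
    input_width
        Per-position encoding width D (21 one-hot, 22 profile).
    kernel_hidden_units
        Width H of the first layer inside each kernel.
    state_units
        Width S of the intermediate state vectors emitted by each kernel,
        and hence of the pooled vector.
    fc_hidden_units
        Width F of the fully connected hidden layer.
    n_classes
        Number of output classes (8).
    """

    c: int = 5
    gamma: int = 8
    n_hidden_kernels: int = 1
    input_width: int = 22
    kernel_hidden_units: int = 8
    state_units: int = 8
    fc_hidden_units: int = 8
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        if self.c < 0 or self.gamma < 0:
            raise ValueError("semi-contexts c and gamma must be >= 0")
        if self.n_hidden_kernels < 0:
            raise ValueError("n_hidden_kernels must be >= 0")
        for name in ("input_width", "kernel_hidden_units", "state_units",
                     "fc_hidden_units", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def input_window(self) -> int:
        return 2 * self.c + 1

    @property
    def hidden_window(self) -> int:
        return 2 * self.gamma + 1

    @property
    def n_hidden_layers(self) -> int:
        """Hidden-layer count: 3 for the minimal architecture, +2 per hidden kernel."""
        return 3 + 2 * self.n_hidden_kernels


@dataclass
class KernelParams:
    """Weights of one two-layer convolutional kernel (window -> H -> S)."""

    w1: np.ndarray  # (window * in_width, H)
    b1: np.ndarray  # (H,)
    w2: np.ndarray  # (H, S)
    b2: np.ndarray  # (S,)

    def arrays(self):
        return [self.w1, self.b1, self.w2, self.b2]


@dataclass
class N1NNParams:
    """All weight and bias arrays of one network, plus a mutation counter.

    ``version`` is bumped by :func:`apply_gradients`; forward traces record
    it so that :func:`backward` can detect a stale trace.
    """

    input_kernel: KernelParams
    hidden_kernels: List[KernelParams]
    fc_w1: np.ndarray  # (S, F)
    fc_b1: np.ndarray  # (F,)
    fc_w2: np.ndarray  # (F, n_classes)
    fc_b2: np.ndarray  # (n_classes,)
    version: int = 0

    def arrays(self) -> List[np.ndarray]:
        """All parameter arrays in a fixed, documented order."""
        out = self.input_kernel.arrays()
        for k in self.hidden_kernels:
            out.extend(k.arrays())
        out.extend([self.fc_w1, self.fc_b1, self.fc_w2, self.fc_b2])
        return out

    def copy(self) -> "N1NNParams":
        return N1NNParams(
            input_kernel=KernelParams(*[a.copy() for a in self.input_kernel.arrays()]),
            hidden_kernels=[
                KernelParams(*[a.copy() for a in k.arrays()])
                for k in self.hidden_kernels
            ],
            fc_w1=self.fc_w1.copy(),
            fc_b1=self.fc_b1.copy(),
            fc_w2=self.fc_w2.copy(),
            fc_b2=self.fc_b2.copy(),
            version=self.version,
        )


@dataclass
class ForwardTrace:
    """Per-stage activations kept for backpropagation."""

    config: N1NNConfig
    n_positions: int
    input_windows: np.ndarray          # (N, (2c+1)*D)
    kernel_hidden: List[np.ndarray]    # per kernel: (N, H) post-sigmoid
    kernel_states: List[np.ndarray]    # per kernel: (N, S) post-sigmoid
    kernel_windows: List[np.ndarray]   # per hidden kernel: (N, (2g+1)*S)
    pooled: np.ndarray                 # (S,)
    fc_hidden: np.ndarray              # (F,) post-sigmoid
    probabilities: np.ndarray          # (n_classes,)
    params_id: int = 0
    params_version: int = 0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    r = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-r, r, size=(fan_in, fan_out))


def _init_kernel(rng: np.random.Generator, in_width: int, window: int,
                 hidden: int, state: int) -> KernelParams:
    fan_in = window * in_width
    return KernelParams(
        w1=_glorot(rng, fan_in, hidden),
        b1=np.zeros(hidden),
        w2=_glorot(rng, hidden, state),
        b2=np.zeros(state),
    )


def init_params(config: N1NNConfig, seed: int) -> N1NNParams:
    """Initialize weights uniform in [-r, r], r = sqrt(6/(fan_in+fan_out)); zero biases.

    Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    input_kernel = _init_kernel(rng, config.input_width, config.input_window,
                                config.kernel_hidden_units, config.state_units)
    hidden = [
        _init_kernel(rng, config.state_units, config.hidden_window,
                     config.kernel_hidden_units, config.state_units)
        for _ in range(config.n_hidden_kernels)
    ]
    return N1NNParams(
        input_kernel=input_kernel,
        hidden_kernels=hidden,
        fc_w1=_glorot(rng, config.state_units, config.fc_hidden_units),
        fc_b1=np.zeros(config.fc_hidden_units),
        fc_w2=_glorot(rng, config.fc_hidden_units, config.n_classes),
        fc_b2=np.zeros(config.n_classes),
    )


def _windowize(x: np.ndarray, semi: int) -> np.ndarray:
    """Stack, for each of the N positions, the flattened window of 2*semi+1 rows.

    Rows beyond either end are zero vectors.
    """
    n, d = x.shape
    if semi == 0:
        return x
    pad = np.zeros((semi, d), dtype=x.dtype)
    xp = np.concatenate([pad, x, pad], axis=0)
    window = 2 * semi + 1
    view = np.lib.stride_tricks.sliding_window_view(xp, (window, d))
    return view[:, 0].reshape(n, window * d)


def _unwindowize(dwin: np.ndarray, n: int, d: int, semi: int) -> np.ndarray:
    """Adjoint of :func:`_windowize`: scatter window gradients back to positions."""
    if semi == 0:
        return dwin
    window = 2 * semi + 1
    dxp = np.zeros((n + 2 * semi, d), dtype=dwin.dtype)
    dw = dwin.reshape(n, window, d)
    for o in range(window):
        dxp[o:o + n] += dw[:, o]
    return dxp[semi:semi + n]


def forward(params: N1NNParams, x: np.ndarray, config: N1NNConfig) -> ForwardTrace:
    """Run the network on an N x D feature matrix and keep all activations."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != config.input_width:
        raise ValueError(
            f"input width {x.shape[1] if x.ndim == 2 else None} does not match "
            f"config.input_width={config.input_width}"
        )
    n = x.shape[0]
    if n < 1:
        raise ValueError("input must have at least one position")

    win0 = _windowize(x, config.c)
    k_hidden, k_states, k_windows = [], [], []

    a1 = _sigmoid(win0 @ params.input_kernel.w1 + params.input_kernel.b1)
    state = _sigmoid(a1 @ params.input_kernel.w2 + params.input_kernel.b2)
    k_hidden.append(a1)
    k_states.append(state)

    for kp in params.hidden_kernels:
        win = _windowize(state, config.gamma)
        k_windows.append(win)
        a1 = _sigmoid(win @ kp.w1 + kp.b1)
        state = _sigmoid(a1 @ kp.w2 + kp.b2)
        k_hidden.append(a1)
        k_states.append(state)

    pooled = state.mean(axis=0)
    fc_h = _sigmoid(pooled @ params.fc_w1 + params.fc_b1)
    logits = fc_h @ params.fc_w2 + params.fc_b2
    z = logits - logits.max()
    ez = np.exp(z)
    probs = ez / ez.sum()

    return ForwardTrace(
        config=config,
        n_positions=n,
        input_windows=win0,
        kernel_hidden=k_hidden,
        kernel_states=k_states,
        kernel_windows=k_windows,
        pooled=pooled,
        fc_hidden=fc_h,
        probabilities=probs,
        params_id=id(params),
        params_version=params.version,
    )


def loss(trace: ForwardTrace, target: LocalizationClass) -> float:
    """Cross-entropy -log p[target] (relative entropy to a one-hot target)."""
    p = float(trace.probabilities[int(target)])
    return -float(np.log(max(p, _LOSS_FLOOR)))


def backward(params: N1NNParams, trace: ForwardTrace,
             target: LocalizationClass) -> N1NNParams:
    """Exact gradient of :func:`loss` w.r.t. every parameter.

    Returns a structure congruent to ``params`` holding gradients.  Raises
    if the trace was not produced by this exact parameter state.
    """
    if trace.params_id != id(params) or trace.params_version != params.version:
        raise ValueError("stale trace: forward() must be re-run after a parameter update")
    cfg = trace.config
    n = trace.n_positions

    # softmax + cross-entropy
    dlogits = trace.probabilities.copy()
    dlogits[int(target)] -= 1.0

    g_fc_w2 = np.outer(trace.fc_hidden, dlogits)
    g_fc_b2 = dlogits
    dfc_h = params.fc_w2 @ dlogits
    dfc_pre = dfc_h * trace.fc_hidden * (1.0 - trace.fc_hidden)
    g_fc_w1 = np.outer(trace.pooled, dfc_pre)
    g_fc_b1 = dfc_pre
    dpooled = params.fc_w1 @ dfc_pre

    # pooling mean distributes 1/N to every position
    dstate = np.tile(dpooled / n, (n, 1))

    g_hidden: List[KernelParams] = []
    for idx in range(len(params.hidden_kernels) - 1, -1, -1):
        kp = params.hidden_kernels[idx]
        state = trace.kernel_states[idx + 1]
        a1 = trace.kernel_hidden[idx + 1]
        win = trace.kernel_windows[idx]
        d2 = dstate * state * (1.0 - state)
        g_w2 = a1.T @ d2
        g_b2 = d2.sum(axis=0)
        da1 = d2 @ kp.w2.T
        d1 = da1 * a1 * (1.0 - a1)
        g_w1 = win.T @ d1
        g_b1 = d1.sum(axis=0)
        g_hidden.append(KernelParams(g_w1, g_b1, g_w2, g_b2))
        dwin = d1 @ kp.w1.T
        dstate = _unwindowize(dwin, n, cfg.state_units, cfg.gamma)
    g_hidden.reverse()

    kp = params.input_kernel
    state = trace.kernel_states[0]
    a1 = trace.kernel_hidden[0]
    d2 = dstate * state * (1.0 - state)
    g_w2 = a1.T @ d2
    g_b2 = d2.sum(axis=0)
    da1 = d2 @ kp.w2.T
    d1 = da1 * a1 * (1.0 - a1)
    g_w1 = trace.input_windows.T @ d1
    g_b1 = d1.sum(axis=0)
    g_input = KernelParams(g_w1, g_b1, g_w2, g_b2)

    return N1NNParams(
        input_kernel=g_input,
        hidden_kernels=g_hidden,
        fc_w1=g_fc_w1,
        fc_b1=g_fc_b1,
        fc_w2=g_fc_w2,
        fc_b2=g_fc_b2,
    )


def apply_gradients(params: N1NNParams, grads: N1NNParams,
                    learning_rate: float, weight_decay: float = 0.0) -> None:
    """In-place SGD step ``w -= lr * (g + wd * w)``; bumps the version counter."""
    for w, g in zip(params.arrays(), grads.arrays()):
        if weight_decay:
            w -= learning_rate * (g + weight_decay * w)
        else:
            w -= learning_rate * g
    params.version += 1
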