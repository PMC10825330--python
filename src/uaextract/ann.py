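"""Feed-forward surrogate network with Levenberg-Marquardt training.

The surrogate is a single-hidden-layer perceptron with log-sigmoid
activation on both the hidden and the output layer.  For the four-factor
extraction study the selected architecture is 4-12-4: four process factors
in, twelve hidden units, four responses out, giving
4*12 + 12 + 4*12 + 4 = 112 free parameters.

Because the output units are sigmoidal, targets are affinely scaled into
[0.05, 0.95]; the 0.05 margin keeps the extreme targets away from the
saturated tails where the gradient vanishes.  Training minimises the sum of
squared scaled residuals with a damped Gauss-Newton (Levenberg-Marquardt)
iteration using the exact analytic Jacobian.

Variable-importance analysis follows the connection-weights idea: the
signed influence of input i on output o is the sum over hidden units of the
product of the input-to-hidden and hidden-to-output weights along each
path.  Garson's nonnegative, per-output-normalised variant is available as
an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignTable

__all__ = [
    "NetworkParams",
    "ScalingSpec",
    "TrainingConfig",
    "TrainedNetwork",
    "InfluenceTable",
    "forward",
    "forward_scaled",
    "train_lm",
    "select_hidden_neurons",
    "relative_influence",
]


def logsig(z: np.ndarray) -> np.ndarray:
    """Numerically safe log-sigmoid 1/(1+exp(-z))."""
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class NetworkParams:
    """Weights and biases of the two-layer network.

    ``u``: hidden-by-input weights; ``th``: hidden biases; ``w``:
    output-by-hidden weights; ``to``: output biases.
    """

    u: np.ndarray
    th: np.ndarray
    w: np.ndarray
    to: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.atleast_2d(np.asarray(self.u, float))
        self.th = np.asarray(self.th, float).ravel()
        self.w = np.atleast_2d(np.asarray(self.w, float))
        self.to = np.asarray(self.to, float).ravel()
        h, i = self.u.shape
        o, h2 = self.w.shape
        if h2 != h or self.th.shape != (h,) or self.to.shape != (o,):
            raise ValueError("inconsistent network parameter shapes")
        if not all(np.all(np.isfinite(a)) for a in (self.u, self.th, self.w, self.to)):
            raise ValueError("network parameters must be finite")

    @property
    def n_inputs(self) -> int:
        return self.u.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.u.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.w.shape[0]

    @property
    def n_params(self) -> int:
        return self.u.size + self.th.size + self.w.size + self.to.size

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.u.ravel(), self.th, self.w.ravel(), self.to])

    @classmethod
    def from_vector(cls, vec: np.ndarray, n_inputs: int, n_hidden: int, n_outputs: int):
        vec = np.asarray(vec, float)
        nu = n_hidden * n_inputs
        nw = n_outputs * n_hidden
        if vec.size != nu + n_hidden + nw + n_outputs:
            raise ValueError("parameter vector has wrong length")
        u = vec[:nu].reshape(n_hidden, n_inputs)
        th = vec[nu : nu + n_hidden]
        w = vec[nu + n_hidden : nu + n_hidden + nw].reshape(n_outputs, n_hidden)
        to = vec[nu + n_hidden + nw :]
        return cls(u, th, w, to)

    def to_dict(self) -> dict:
        return {
            "u": self.u.tolist(),
            "th": self.th.tolist(),
            "w": self.w.tolist(),
            "to": self.to.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        return cls(np.array(d["u"]), np.array(d["th"]), np.array(d["w"]), np.array(d["to"]))


@dataclass
class ScalingSpec:
    """Affine maps between natural units and the sigmoid-friendly box.

    Inputs map from their natural ranges onto [lo, hi] (default
    [0.05, 0.95]); targets map the same way, and predictions are unscaled
    through the inverse output map.
    """

    in_min: np.ndarray
    in_max: np.ndarray
    out_min: np.ndarray
    out_max: np.ndarray
    lo: float = 0.05
    hi: float = 0.95

    def __post_init__(self) -> None:
        for a in ("in_min", "in_max", "out_min", "out_max"):
            setattr(self, a, np.asarray(getattr(self, a), float).ravel())
        if np.any(self.in_max <= self.in_min) or np.any(self.out_max <= self.out_min):
            raise ValueError("scaling ranges must be non-degenerate")

    @classmethod
    def from_data(cls, X: np.ndarray, Y: np.ndarray, lo: float = 0.05, hi: float = 0.95):
        X = np.atleast_2d(X)
        Y = np.atleast_2d(Y)
        return cls(X.min(0), X.max(0), Y.min(0), Y.max(0), lo, hi)

    def scale_in(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        return self.lo + (self.hi - self.lo) * (X - self.in_min) / (self.in_max - self.in_min)

    def scale_out(self, Y: np.ndarray) -> np.ndarray:
        Y = np.asarray(Y, float)
        return self.lo + (self.hi - self.lo) * (Y - self.out_min) / (self.out_max - self.out_min)

    def unscale_out(self, Ys: np.ndarray) -> np.ndarray:
        Ys = np.asarray(Ys, float)
        return self.out_min + (Ys - self.lo) * (self.out_max - self.out_min) / (self.hi - self.lo)

    def to_dict(self) -> dict:
        return {
            "in_min": self.in_min.tolist(),
            "in_max": self.in_max.tolist(),
            "out_min": self.out_min.tolist(),
            "out_max": self.out_max.tolist(),
            "lo": self.lo,
            "hi": self.hi,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingSpec":
        return cls(
            np.array(d["in_min"]),
            np.array(d["in_max"]),
            np.array(d["out_min"]),
            np.array(d["out_max"]),
            d.get("lo", 0.05),
            d.get("hi", 0.95),
        )


@dataclass
class TrainingConfig:
    """Levenberg-Marquardt training hyperparameters.

    ``split`` is the train/validation/test fraction triple applied by a
    seeded shuffle of the run indices.  ``mu0`` is the initial damping,
    multiplied by ``mu_inc`` on a rejected step and ``mu_dec`` on an
    accepted one; training stops at ``max_cycles`` accepted cycles, when
    the damping exceeds ``mu_max``, or when the relative SSE improvement
    falls below ``ftol``.
    """

    max_cycles: int = 5000
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    mu0: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10
    ftol: float = 1e-14
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def forward_scaled(params: NetworkParams, Xs: np.ndarray):
    """Forward pass in scaled space; returns (hidden, output) activations."""
    Xs = np.atleast_2d(np.asarray(Xs, float))
    if Xs.shape[1] != params.n_inputs:
        raise ValueError(
            f"expected {params.n_inputs} inputs, got {Xs.shape[1]}"
        )
    H = logsig(Xs @ params.u.T + params.th)
    Ys = logsig(H @ params.w.T + params.to)
    return H, Ys


def forward(params: NetworkParams, scaling: ScalingSpec, X: np.ndarray) -> np.ndarray:
    """Predict natural-unit responses for natural-unit inputs."""
    X = np.asarray(X, float)
    single = X.ndim == 1
    _, Ys = forward_scaled(params, scaling.scale_in(np.atleast_2d(X)))
    Y = scaling.unscale_out(Ys)
    return Y[0] if single else Y


def _jacobian(params: NetworkParams, Xs: np.ndarray):
    """Residual Jacobian d y_scaled / d theta, rows ordered (pattern, output).

    Parameter order matches :meth:`NetworkParams.to_vector`:
    u (row-major), th, w (row-major), to.
    """
    H, Ys = forward_scaled(params, Xs)
    n, h = H.shape
    o = params.n_outputs
    i = params.n_inputs
    dY = Ys * (1.0 - Ys)                      # (n, o)
    dH = H * (1.0 - H)                        # (n, h)

    J = np.zeros((n * o, params.n_params))
    # d/d to: block-diagonal in the output index
    J_to = np.zeros((n, o, o))
    idx = np.arange(o)
    J_to[:, idx, idx] = dY
    # d/d w[o',h]: nonzero only for the output's own weight row (o' == o)
    J_w = np.zeros((n, o, o, h))
    J_w[:, idx, idx, :] = dY[:, :, None] * H[:, None, :]
    # back-propagated hidden sensitivity: dY * w * dH
    S = dY[:, :, None] * params.w[None, :, :] * dH[:, None, :]  # (n, o, h)
    # d/d th = S ; d/d u[h,i] = S * x_i
    J_u = S[:, :, :, None] * Xs[:, None, None, :]               # (n, o, h, i)

    nu = h * i
    J[:, :nu] = J_u.reshape(n * o, nu)
    J[:, nu : nu + h] = S.reshape(n * o, h)
    J[:, nu + h : nu + h + o * h] = J_w.reshape(n * o, o * h)
    J[:, nu + h + o * h :] = J_to.reshape(n * o, o)
    return J, Ys


def _lm_step(A: np.ndarray, g: np.ndarray, mu: float) -> np.ndarray:
    """Damped Gauss-Newton step: solve (J'J + mu*I) dp = -g with A = J'J."""
    return np.linalg.solve(A + mu * np.eye(len(g)), -g)


def split_indices(n: int, split: tuple[float, float, float], seed: int):
    """Seeded shuffle split of run indices into train/val/test."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    n_train = max(2, min(n_train, n))
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


@dataclass
class TrainedNetwork:
    params: NetworkParams
    scaling: ScalingSpec
    history: dict = field(default_factory=dict)
    split: dict = field(default_factory=dict)
    r2: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return forward(self.params, self.scaling, X)


def _init_params(n_inputs: int, n_hidden: int, n_outputs: int, rng) -> NetworkParams:
    # small uniform init keeps the sigmoids in their responsive region
    u = rng.uniform(-0.5, 0.5, (n_hidden, n_inputs))
    th = rng.uniform(-0.5, 0.5, n_hidden)
    w = rng.uniform(-0.5, 0.5, (n_outputs, n_hidden))
    to = rng.uniform(-0.5, 0.5, n_outputs)
    return NetworkParams(u, th, w, to)


def _mse(params: NetworkParams, Xs, Ts) -> float:
    if len(Xs) == 0:
        return float("nan")
    _, Ys = forward_scaled(params, Xs)
    return float(np.mean((Ys - Ts) ** 2))


def train_lm(
    design: DesignTable | None = None,
    config: TrainingConfig | None = None,
    hidden_n: int = 12,
    *,
    X: np.ndarray | None = None,
    Y: np.ndarray | None = None,
    init_params: NetworkParams | None = None,
    scaling: ScalingSpec | None = None,
) -> TrainedNetwork:
    """Train the surrogate by Levenberg-Marquardt on a response design.

    Either a :class:`DesignTable` carrying responses or raw ``X``/``Y``
    arrays (natural units) may be given.  The step solves
    ``(J'J + mu*I) dp = -J'r`` and is accepted only if it lowers the
    training SSE, so the accepted-cycle SSE sequence is non-increasing.

    ``init_params`` fixes the starting point (its hidden size overrides
    ``hidden_n``); ``scaling`` fixes the natural-to-sigmoid maps instead of
    deriving them from the training split.
    """
    config = config or TrainingConfig()
    if design is not None:
        X = design.natural
        Y = design.responses
    if X is None or Y is None:
        raise ValueError("provide a design with responses or X and Y arrays")
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 training rows")

    tr, va, te = split_indices(n, config.split, config.seed)
    if scaling is None:
        scaling = ScalingSpec.from_data(X[tr], Y[tr])
    Xs, Ts = scaling.scale_in(X), scaling.scale_out(Y)

    rng = np.random.default_rng(config.seed)
    if init_params is not None:
        params = init_params
        hidden_n = params.n_hidden
    else:
        params = _init_params(X.shape[1], hidden_n, Y.shape[1], rng)
    vec = params.to_vector()
    shape = (X.shape[1], hidden_n, Y.shape[1])

    def unpack(v):
        return NetworkParams.from_vector(v, *shape)

    Xtr, Ttr = Xs[tr], Ts[tr]
    mu = config.mu0
    J, Ys = _jacobian(params, Xtr)
    r = (Ys - Ttr).ravel()
    sse = float(r @ r)
    history = {"train_mse": [], "val_mse": [], "test_mse": [], "mu": []}

    for _ in range(config.max_cycles):
        g = J.T @ r
        A = J.T @ J
        accepted = False
        while mu <= config.mu_max:
            try:
                dp = _lm_step(A, g, mu)
            except np.linalg.LinAlgError:
                mu *= config.mu_inc
                continue
            cand_vec = vec + dp
            cand = unpack(cand_vec)
            _, Ys_new = forward_scaled(cand, Xtr)
            r_new = (Ys_new - Ttr).ravel()
            sse_new = float(r_new @ r_new)
            if sse_new < sse:
                accepted = True
                break
            mu *= config.mu_inc
        if not accepted:
            if mu > config.mu_max and sse > 1e-20 and np.linalg.norm(g, np.inf) > 1e-6:
                warnings.warn(
                    "Levenberg-Marquardt stalled at the damping ceiling; "
                    "returning the best parameters found",
                    RuntimeWarning,
                )
            break
        improvement = (sse - sse_new) / max(sse, 1e-300)
        vec, params, sse = cand_vec, cand, sse_new
        mu = max(mu * config.mu_dec, 1e-20)
        J, Ys = _jacobian(params, Xtr)
        r = (Ys - Ttr).ravel()
        history["train_mse"].append(sse / r.size)
        history["val_mse"].append(_mse(params, Xs[va], Ts[va]))
        history["test_mse"].append(_mse(params, Xs[te], Ts[te]))
        history["mu"].append(mu)
        if improvement < config.ftol or sse < 1e-24:
            break

    def r2_of(idx):
        if len(idx) == 0:
            return float("nan")
        pred = forward(params, scaling, X[idx])
        obs = Y[idx]
        sse_ = float(np.sum((pred - obs) ** 2))
        sst = float(np.sum((obs - obs.mean(0)) ** 2))
        return 1.0 - sse_ / sst if sst > 0 else float("nan")

    return TrainedNetwork(
        params,
        scaling,
        history,
        split={"train": tr.tolist(), "val": va.tolist(), "test": te.tolist()},
        r2={"train": r2_of(tr), "val": r2_of(va), "test": r2_of(te)},
    )


def select_hidden_neurons(
    design: DesignTable,
    config: TrainingConfig | None = None,
    candidates=range(3, 16),
) -> int:
    """Pick the hidden-layer size with the lowest validation MSE.

    Every candidate is trained from the same seed; ties go to the smaller
    network.  Candidates with an empty validation split fall back to the
    training MSE.
    """
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ValueError("empty candidate list")
    config = config or TrainingConfig()
    best_h, best_err = None, np.inf
    for h in candidates:
        net = train_lm(design, config, hidden_n=h)
        val = net.history["val_mse"]
        err = val[-1] if val and np.isfinite(val[-1]) else net.history["train_mse"][-1]
        if err < best_err:
            best_h, best_err = h, err
    return best_h


@dataclass
class InfluenceTable:
    """Signed (or Garson-normalised) input-to-output influence values."""

    values: pd.DataFrame  # index: inputs, columns: outputs
    method: str


def relative_influence(
    params: NetworkParams,
    method: str = "connection-weights",
    input_names=None,
    output_names=None,
) -> InfluenceTable:
    """Per-(input, output) variable importance from the trained weights.

    ``connection-weights`` (Olden): RI(i, o) = sum_h u[h,i] * w[o,h] — the
    sign says whether raising the input raises the output.  ``garson``:
    nonnegative |u|*|w| shares, normalised to sum to one per output.
    """
    if input_names is None:
        input_names = [f"x{i + 1}" for i in range(params.n_inputs)]
    if output_names is None:
        output_names = [f"y{o + 1}" for o in range(params.n_outputs)]
    if method in ("connection-weights", "olden"):
        ri = (params.w @ params.u).T  # (inputs, outputs)
        tag = "connection-weights"
    elif method == "garson":
        absu = np.abs(params.u)  # (h, i)
        absw = np.abs(params.w)  # (o, h)
        # share of each input within each hidden unit, weighted by |w|
        shares = absu / absu.sum(axis=1, keepdims=True)  # (h, i)
        contrib = absw @ shares  # (o, i)
        ri = (contrib / contrib.sum(axis=1, keepdims=True)).T
        tag = "garson"
    else:
        raise ValueError(f"unknown influence method {method!r}")
    return InfluenceTable(pd.DataFrame(ri, index=input_names, columns=output_names), tag)
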