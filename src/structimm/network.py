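"""Feed-forward classifier trained by scaled conjugate gradients.

A single-hidden-layer network (tanh hidden units, logistic output, bias at
both layers) maps a standardized feature vector to a score in (0, 1), read
as confidence that the peptide is immunogenic.  Training minimizes
cross-entropy with Moller's scaled-conjugate-gradient algorithm (conjugate
directions, Hessian-free curvature estimates via finite differencing of the
gradient, Levenberg-Marquardt-style adjustment of the scaling parameter)
and validation-based early stopping: training halts after ``patience``
consecutive epochs without a validation-loss improvement and the
best-validation snapshot is returned.

Input standardization statistics are estimated from the training fold only
and stored with the model, so validation/test data never leak into them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

_SCG_SIGMA0 = 5e-5   # finite-difference step scale (Moller)
_SCG_LAMBDA0 = 5e-7  # initial scaling (trust-region) parameter


@dataclass
class NetworkSpec:
    n_inputs: int
    n_hidden: int = 5
    hidden_activation: str = "tanh"
    output_activation: str = "logistic"

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ConfigError("n_inputs must be >= 1")
        if not (1 <= self.n_hidden <= 64):
            raise ConfigError("n_hidden out of range")


@dataclass
class NetworkModel:
    spec: NetworkSpec
    w1: np.ndarray           # (n_hidden, n_inputs + 1), last column = bias
    w2: np.ndarray           # (1, n_hidden + 1), last entry = bias
    mu: np.ndarray           # per-feature location (training folds)
    sigma: np.ndarray        # per-feature scale (training folds, > 0)

    @classmethod
    def initialize(cls, spec: NetworkSpec, seed: int = 0) -> "NetworkModel":
        rng = np.random.default_rng(seed)
        lim1 = 1.0 / np.sqrt(spec.n_inputs + 1)
        lim2 = 1.0 / np.sqrt(spec.n_hidden + 1)
        return cls(
            spec=spec,
            w1=rng.uniform(-lim1, lim1, size=(spec.n_hidden, spec.n_inputs + 1)),
            w2=rng.uniform(-lim2, lim2, size=(1, spec.n_hidden + 1)),
            mu=np.zeros(spec.n_inputs),
            sigma=np.ones(spec.n_inputs),
        )

    def set_standardization(self, x_train: np.ndarray) -> None:
        self.mu = x_train.mean(axis=0)
        sd = x_train.std(axis=0)
        self.sigma = np.where(sd > 0, sd, 1.0)

    # -- parameter vector helpers -----------------------------------------
    def get_params(self) -> np.ndarray:
        return np.concatenate([self.w1.ravel(), self.w2.ravel()])

    def set_params(self, w: np.ndarray) -> None:
        n1 = self.w1.size
        self.w1 = w[:n1].reshape(self.w1.shape).copy()
        self.w2 = w[n1:].reshape(self.w2.shape).copy()

    # -- serialization (bit-exact round trip via JSON repr floats) --------
    def to_json(self) -> str:
        return json.dumps({
            "spec": {"n_inputs": self.spec.n_inputs,
                     "n_hidden": self.spec.n_hidden,
                     "hidden_activation": self.spec.hidden_activation,
                     "output_activation": self.spec.output_activation},
            "w1": self.w1.tolist(),
            "w2": self.w2.tolist(),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "NetworkModel":
        d = json.loads(text)
        return cls(spec=NetworkSpec(**d["spec"]),
                   w1=np.array(d["w1"]), w2=np.array(d["w2"]),
                   mu=np.array(d["mu"]), sigma=np.array(d["sigma"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "NetworkModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _forward_raw(model: NetworkModel, x: np.ndarray):
    """x: (n, d) standardized. Returns (scores, hidden activations)."""
    xb = np.hstack([x, np.ones((x.shape[0], 1))])
    h = np.tanh(xb @ model.w1.T)
    hb = np.hstack([h, np.ones((h.shape[0], 1))])
    z = hb @ model.w2.T
    score = 1.0 / (1.0 + np.exp(-z))
    return score.ravel(), h


def forward(model: NetworkModel, x: np.ndarray) -> np.ndarray | float:
    """Score(s) in (0, 1) for one vector or a batch of rows."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != model.spec.n_inputs:
        raise ConfigError(f"expected {model.spec.n_inputs} inputs, "
                          f"got {x.shape[1]}")
    xs = (x - model.mu) / model.sigma
    scores, _ = _forward_raw(model, xs)
    return float(scores[0]) if single else scores


def loss(model: NetworkModel, x: np.ndarray, y: np.ndarray) -> float:
    """Mean cross-entropy on standardized inputs (x already standardized)."""
    p, _ = _forward_raw(model, x)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def gradient(model: NetworkModel, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact backpropagation gradient of mean cross-entropy, flattened.

    *x* must already be standardized.  With a logistic output and
    cross-entropy loss the output delta is simply (p - y)/n.
    """
    if len(x) == 0:
        raise ConfigError("empty batch")
    if not np.all(np.isfinite(x)):
        raise ValueError("NaN/inf in inputs")
    n = x.shape[0]
    xb = np.hstack([x, np.ones((n, 1))])
    h = np.tanh(xb @ model.w1.T)
    hb = np.hstack([h, np.ones((n, 1))])
    p = 1.0 / (1.0 + np.exp(-(hb @ model.w2.T)))
    delta_out = (p - y.reshape(-1, 1)) / n           # (n, 1)
    g2 = delta_out.T @ hb                            # (1, n_hidden+1)
    delta_h = (delta_out @ model.w2[:, :-1]) * (1.0 - h ** 2)
    g1 = delta_h.T @ xb                              # (n_hidden, n_inputs+1)
    return np.concatenate([g1.ravel(), g2.ravel()])


@dataclass
class TrainState:
    epoch: int = 0
    val_failures: int = 0
    best_val_loss: float = np.inf
    best_params: np.ndarray | None = None
    history: list[tuple[float, float]] = field(default_factory=list)


def scg_train(model: NetworkModel, x_train: np.ndarray, y_train: np.ndarray,
              x_val: np.ndarray, y_val: np.ndarray,
              patience: int = 6, max_epochs: int = 1000,
              seed: int = 0, standardize: bool = True) -> NetworkModel:
    """Scaled-conjugate-gradient training with early stopping.

    Standardization statistics come from *x_train* only; validation data are
    transformed with them.  Deterministic given *seed* (which controls only
    the weight initialization already stored in *model* if you pass a fresh
    one; the SCG iteration itself is deterministic).
    """
    x_train = np.asarray(x_train, dtype=float)
    x_val = np.asarray(x_val, dtype=float)
    if len(x_train) == 0 or len(x_val) == 0:
        raise ConfigError("empty training or validation split")
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    if standardize:
        model.set_standardization(x_train)
    xt = (x_train - model.mu) / model.sigma
    xv = (x_val - model.mu) / model.sigma

    def f(w: np.ndarray) -> float:
        model.set_params(w)
        return loss(model, xt, y_train)

    def fprime(w: np.ndarray) -> np.ndarray:
        model.set_params(w)
        return gradient(model, xt, y_train)

    w = model.get_params()
    state = TrainState()
    lam = _SCG_LAMBDA0
    lam_bar = 0.0
    r = -fprime(w)
    p = r.copy()
    success = True
    n_params = len(w)
    fw = f(w)
    delta = 1.0
    mu_pr = 0.0

    model.set_params(w)
    state.best_params = w.copy()
    state.best_val_loss = loss(model, xv, y_val)

    for epoch in range(1, max_epochs + 1):
        state.epoch = epoch
        p_norm2 = float(p @ p)
        if p_norm2 < 1e-24:
            break
        if success:
            sigma = _SCG_SIGMA0 / np.sqrt(p_norm2)
            s = (fprime(w + sigma * p) - fprime(w)) / sigma
            delta = float(p @ s)
        delta += (lam - lam_bar) * p_norm2
        if delta <= 0:  # make the Hessian estimate positive definite
            lam_bar = 2.0 * (lam - delta / p_norm2)
            delta = -delta + lam * p_norm2
            lam = lam_bar
        mu_pr = float(p @ r)
        alpha = mu_pr / delta
        fw_new = f(w + alpha * p)
        comparison = 2.0 * delta * (fw - fw_new) / (mu_pr ** 2)
        if comparison >= 0:
            w = w + alpha * p
            fw = fw_new
            r_new = -fprime(w)
            lam_bar = 0.0
            success = True
            if epoch % n_params == 0:
                p = r_new.copy()  # restart
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu_pr
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam = max(lam * 0.25, 1e-15)
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam = lam + delta * (1.0 - comparison) / p_norm2

        model.set_params(w)
        val_loss = loss(model, xv, y_val)
        state.history.append((fw, val_loss))
        if val_loss < state.best_val_loss - 1e-12:
            state.best_val_loss = val_loss
            state.best_params = w.copy()
            state.val_failures = 0
        else:
            state.val_failures += 1
            if state.val_failures >= patience:
                break

    model.set_params(state.best_params)
    return model
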