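"""Wake-Sleep training: local, alpha-gated delta-rule parameter updates.

Both pathways learn from a compartmental prediction error between a unit's
actual activity and the drive of the compartment being trained:

* recognition (basal) parameters: ``d_theta = alpha * eta * (r - h)/sigma_b^2
  * dh/d_theta`` — nonzero only during Sleep (alpha=1), when activity is a
  sample from the generative model and the basal pathway learns to invert it;
* generative (apical) parameters: ``d_theta = (1-alpha) * eta * (r - mu)/
  sigma_p^2 * dmu/d_theta`` — nonzero only during Wake.

The derivatives ``dh/d_theta`` are computed analytically per parameter type
(soma-nonlinearity derivative x branch conductance x branch-nonlinearity
derivative x presynaptic rate), with normalization statistics treated as
constants within a step, so each update only uses quantities local to the
synapse, its branch, and its soma.  The top layer's mean path uses the
learned variance ``h2`` in place of ``sigma_b^2``, and ``h2`` itself is
updated from the same Gaussian log-likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wakesleep.model import (
    ActivityState,
    CompartmentParams,
    DriveCache,
    NetworkParams,
    compartment_forward,
    freeze_norms,
    sample_sleep,
    sample_wake,
)

__all__ = [
    "TrainConfig",
    "UpdateVector",
    "compartment_param_grads",
    "recognition_update",
    "generative_update",
    "apply_update",
    "AdamState",
    "train",
    "iter_params",
]

_PARAM_NAMES = ("W", "c", "rho", "b", "gamma", "beta")
_AFFINE_NAMES = ("sg", "sb")


def _param_names(p: CompartmentParams) -> tuple[str, ...]:
    if p.soma == "norm_affine":
        return _PARAM_NAMES + _AFFINE_NAMES
    return _PARAM_NAMES


@dataclass(frozen=True)
class TrainConfig:
    """Wake-Sleep loop hyperparameters."""

    batch_size: int = 512
    n_epochs: int = 100
    learning_rate: float = 1e-3
    optimizer: str = "adam"  # "adam" | "plain"
    seed: int = 0
    # optional plateau stopping on the reconstruction proxy: stop once the
    # proxy has not improved by a fraction stop_tol for stop_patience epochs
    stop_patience: int | None = None
    stop_tol: float = 0.02

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (normalization needs a batch)")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.optimizer not in ("adam", "plain"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class UpdateVector:
    """Flat collection of parameter increments, partitioned apical/basal."""

    entries: dict[str, np.ndarray] = field(default_factory=dict)
    group: dict[str, str] = field(default_factory=dict)

    def add(self, key: str, value: np.ndarray, group: str) -> None:
        self.entries[key] = value
        self.group[key] = group

    def iadd(self, other: "UpdateVector", scale: float = 1.0) -> "UpdateVector":
        for key, value in other.entries.items():
            if key in self.entries:
                self.entries[key] += scale * value
            else:
                self.add(key, scale * value, other.group[key])
        return self

    def flat(self, group: str | None = None) -> np.ndarray:
        """Concatenate entries (optionally one group) into one vector."""
        keys = sorted(
            k for k in self.entries if group is None or self.group[k] == group
        )
        if not keys:
            return np.zeros(0)
        return np.concatenate([self.entries[k].ravel() for k in keys])

    def check_finite(self) -> None:
        for key, value in self.entries.items():
            if not np.all(np.isfinite(value)):
                raise FloatingPointError(f"non-finite update for parameter {key}")


def iter_params(net: NetworkParams):
    """Yield (identifier, array, group) over every learnable parameter.

    Recognition parameters (including the variance head) form the basal
    group; generative parameters form the apical group.
    """
    for name, p in net.compartments():
        group = "apical" if name.startswith("gen") else "basal"
        for pname in _param_names(p):
            yield f"{name}/{pname}", getattr(p, pname), group


def compartment_param_grads(
    params: CompartmentParams,
    cache: DriveCache,
    g: np.ndarray,
    error: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Batch-averaged gradients w.r.t. each parameter given dL/d(soma input).

    ``g`` has shape [batch, width].  Per-parameter forms: the soma bias sees
    ``g`` directly; a branch conductance sees ``g`` times the branch output;
    a dendritic synapse sees ``g`` weighted by its branch's conductance and
    branch-nonlinearity derivative times the presynaptic rate.  Conductance
    gradients are chained through softplus onto the stored pre-parameter.
    For an affine soma, ``error`` (dL/d drive output) supplies the gradients
    of the soma scale/shift.
    """
    B = g.shape[0]
    w = params.conductance
    # k: dL/d(branch pre-activation v_in)  [batch, width, nb]
    k = g[:, :, None] * w * params.gamma * cache.branch_inv_std * (
        1.0 - cache.tanh_v**2
    )
    sig = 1.0 / (1.0 + np.exp(-params.rho))  # d softplus / d rho
    grads = {
        "b": g.mean(axis=0),
        "rho": (g[:, :, None] * cache.u).mean(axis=0) * sig,
        "gamma": (g[:, :, None] * w * cache.branch_that).mean(axis=0),
        "beta": g.mean(axis=0)[:, None] * w,
        "W": np.einsum("bin,bj->inj", k, cache.x) / B,
        "c": k.mean(axis=0),
    }
    if params.soma == "norm_affine":
        if error is None:
            raise ValueError("affine soma gradients need the output error")
        grads["sg"] = (error * cache.soma_that).mean(axis=0)
        grads["sb"] = error.mean(axis=0)
    return grads


def _soma_grad_norm(
    params: CompartmentParams, cache: DriveCache, error: np.ndarray
) -> np.ndarray:
    """dL/d(soma input) for a tanh+norm soma, error = dL/d(drive output)."""
    g = error * (1.0 - cache.tanh_vt**2) * cache.soma_inv_std
    if params.soma == "norm_affine":
        g = g * params.sg
    return g


def recognition_update(
    net: NetworkParams,
    activity: ActivityState,
    alpha: float,
    eta: float,
    training: bool | None = False,
) -> UpdateVector:
    """Alpha-gated delta-rule increments for all basal (recognition) parameters.

    Drives are recomputed from ``activity``; errors are
    ``(r^l - h(r^{l-1}))/sigma_b^2`` (top layer: divided by the learned
    variance ``h2`` instead).  Every entry is multiplied by ``alpha * eta``,
    so the Wake phase (alpha=0) produces exact zeros.
    """
    cfg = net.config
    L = cfg.n_layers
    out = UpdateVector()
    gate = alpha * eta
    for l in range(1, L + 1):
        p = net.recognition[l - 1]
        cache = compartment_forward(p, activity.r[l - 1], training)
        if l < L:
            err = (activity.r[l] - cache.out) / cfg.sigma_b**2
            g = _soma_grad_norm(p, cache, err)
            grads = compartment_param_grads(p, cache, g, err)
            for pname, grad in grads.items():
                out.add(f"rec/{l}/{pname}", gate * grad, "basal")
        else:
            h2cache = compartment_forward(net.h2, activity.r[L - 1], training)
            var = h2cache.out
            err = (activity.r[L] - cache.out) / var
            g = _soma_grad_norm(p, cache, err)
            for pname, grad in compartment_param_grads(p, cache, g, err).items():
                out.add(f"rec/{L}/{pname}", gate * grad, "basal")
            # variance head: d logN / d(soma input) with h2 = exp(soma input)
            g2 = 0.5 * ((activity.r[L] - cache.out) ** 2 / var - 1.0)
            for pname, grad in compartment_param_grads(net.h2, h2cache, g2).items():
                out.add(f"h2/{pname}", gate * grad, "basal")
    return out


def generative_update(
    net: NetworkParams,
    activity: ActivityState,
    alpha: float,
    eta: float,
    training: bool | None = False,
) -> UpdateVector:
    """(1-alpha)-gated increments for all apical (generative) parameters.

    Mirror of :func:`recognition_update` with error
    ``(r^l - mu(r^{l+1}))/sigma_p^2``; the Sleep phase (alpha=1) produces
    exact zeros.
    """
    cfg = net.config
    L = cfg.n_layers
    out = UpdateVector()
    gate = (1.0 - alpha) * eta
    for l in range(L):
        p = net.generative[l]
        cache = compartment_forward(p, activity.r[l + 1], training)
        err = (activity.r[l] - cache.out) / cfg.sigma_p**2
        g = _soma_grad_norm(p, cache, err)
        for pname, grad in compartment_param_grads(p, cache, g, err).items():
            out.add(f"gen/{l}/{pname}", gate * grad, "apical")
    return out


def apply_update(net: NetworkParams, update: UpdateVector) -> None:
    """Add increments in place to the named parameters."""
    params = {key: arr for key, arr, _ in iter_params(net)}
    for key, inc in update.entries.items():
        params[key] += inc


@dataclass
class AdamState:
    """Adaptive-moment estimation applied to averaged update directions."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: dict[str, np.ndarray] = field(default_factory=dict)
    v: dict[str, np.ndarray] = field(default_factory=dict)

    def step(self, net: NetworkParams, update: UpdateVector) -> None:
        self.t += 1
        params = {key: arr for key, arr, _ in iter_params(net)}
        for key, g in update.entries.items():
            m = self.m.setdefault(key, np.zeros_like(g))
            v = self.v.setdefault(key, np.zeros_like(g))
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g**2 - v)
            mhat = m / (1.0 - self.beta1**self.t)
            vhat = v / (1.0 - self.beta2**self.t)
            params[key] += self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _reconstruction_proxy(net: NetworkParams, stimuli: np.ndarray, rng) -> float:
    """MSE between the stimulus and its generative reconstruction mu(r^1)."""
    act = sample_wake(net, stimuli, rng, training=False)
    recon = compartment_forward(net.generative[0], act.r[1], training=False).out
    return float(np.mean((stimuli - recon) ** 2))


def train(
    net: NetworkParams,
    dataset: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator | None = None,
) -> tuple[NetworkParams, pd.DataFrame]:
    """Alternating Wake/Sleep training loop; freezes norms when done.

    Each step draws a stimulus batch, runs a Wake sample (alpha=0) and
    applies the generative update, then a Sleep sample (alpha=1) and the
    recognition update.  Returns the trained network and a per-epoch log
    (reconstruction proxy and mean update norms per phase).  With
    ``n_epochs=0`` the network is returned unchanged (untrained control).
    """
    if len(dataset) == 0:
        raise ValueError("dataset must be nonempty")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = len(dataset)
    batch = min(cfg.batch_size, n)
    opt = AdamState(lr=cfg.learning_rate) if cfg.optimizer == "adam" else None
    eval_idx = rng.choice(n, size=min(n, 256), replace=False)
    rows = []
    best = math.inf
    since_improvement = 0
    for epoch in range(cfg.n_epochs):
        order = rng.permutation(n)
        wake_norms, sleep_norms = [], []
        for start in range(0, n - batch + 1, batch):
            stim = dataset[order[start : start + batch]]
            # Wake: bottom-up sampling trains apical (generative) synapses
            act = sample_wake(net, stim, rng, training=True)
            upd = generative_update(net, act, alpha=0.0, eta=1.0)
            upd.check_finite()
            wake_norms.append(float(np.linalg.norm(upd.flat())))
            _step(net, upd, opt, cfg)
            # Sleep: top-down sampling trains basal (recognition) synapses
            act = sample_sleep(net, batch, rng, training=True)
            upd = recognition_update(net, act, alpha=1.0, eta=1.0)
            upd.check_finite()
            sleep_norms.append(float(np.linalg.norm(upd.flat())))
            _step(net, upd, opt, cfg)
        recon = _reconstruction_proxy(net, dataset[eval_idx], rng)
        rows.append(
            {
                "epoch": epoch,
                "recon_mse": recon,
                "wake_update_norm": float(np.mean(wake_norms)) if wake_norms else math.nan,
                "sleep_update_norm": float(np.mean(sleep_norms)) if sleep_norms else math.nan,
            }
        )
        if cfg.stop_patience is not None:
            if recon < best * (1.0 - cfg.stop_tol):
                best = recon
                since_improvement = 0
            else:
                since_improvement += 1
                if since_improvement >= cfg.stop_patience:
                    break
    if cfg.n_epochs > 0:
        freeze_norms(net)
    return net, pd.DataFrame(rows)


def _step(net: NetworkParams, upd: UpdateVector, opt: AdamState | None, cfg: TrainConfig) -> None:
    if opt is not None:
        opt.step(net, upd)
    else:
        for key in upd.entries:
            upd.entries[key] *= cfg.learning_rate
        apply_update(net, upd)
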