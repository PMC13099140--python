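"""Core layered generative/recognition network with multicompartment units.

Each unit pools ``n_branches`` dendritic branches.  Branch ``n`` of unit
``i`` computes ``phi_d(W[i, n] @ x + c[i, n])`` where ``phi_d`` is tanh
followed by batch normalization with a learnable affine; the soma combines
branches through strictly positive conductances ``w[i, n]`` and applies
``phi`` = tanh followed by batch normalization constrained to zero mean and
unit variance across the batch (no affine, preventing scale indeterminacy
between the apical and basal pathways).  The recognition pathway ``h`` maps
layer l-1 to layer l; the generative pathway ``mu`` maps layer l+1 to
layer l; the top layer carries an extra variance head ``h2`` whose soma
nonlinearity is an exponential (positivity).

Branch conductances are stored as unconstrained pre-parameters and mapped
through softplus, so positivity survives arbitrary additive updates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "LayerSpec",
    "NetworkConfig",
    "NormState",
    "CompartmentParams",
    "NetworkParams",
    "ActivityState",
    "DriveCache",
    "softplus",
    "branch_drive",
    "basal_drive",
    "apical_drive",
    "top_variance_drive",
    "compartment_forward",
    "interpolate",
    "sample_wake",
    "sample_sleep",
    "init_network",
    "freeze_norms",
    "save_network",
    "load_network",
]

# Normalization denominator floor: bounds the batchnorm gain at
# 1/sqrt(eps) = 10.  Units whose pre-activation variance collapses during
# training (a common degeneracy in small Helmholtz machines) would otherwise
# have sub-noise fluctuations amplified by orders of magnitude, destabilizing
# frozen-statistics simulation and heavy-tailing every plasticity statistic.
_NORM_EPS = 1e-2


class DegenerateBatchError(ValueError):
    """Raised when training-mode normalization receives a batch of size 1."""


@dataclass(frozen=True)
class LayerSpec:
    """Width and branching of one layer."""

    width: int
    n_branches: int
    is_top: bool = False

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("width must be >= 1")
        if self.n_branches < 1:
            raise ValueError("n_branches must be >= 1")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and noise hyperparameters.

    ``layer_widths`` are the hidden-layer widths in ascending order from the
    sensory side; ``sigma_b``/``sigma_p`` are the bottom-up and top-down
    activity standard deviations; ``kappa`` is the sharpness of the soft-max
    interpolation between pathways.
    """

    layer_widths: tuple[int, ...] = (32, 16, 6)
    stimulus_dim: int = 784
    n_branches: int = 3
    sigma_b: float = 0.1
    sigma_p: float = 0.1
    kappa: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "layer_widths", tuple(int(w) for w in self.layer_widths))
        if any(w < 1 for w in self.layer_widths) or self.stimulus_dim < 1:
            raise ValueError("layer widths and stimulus_dim must be positive")
        if self.n_branches < 1:
            raise ValueError("n_branches must be >= 1")
        if not (self.sigma_b > 0 and self.sigma_p > 0 and self.kappa > 0):
            raise ValueError("sigma_b, sigma_p and kappa must be positive")

    @property
    def n_layers(self) -> int:
        """Number of hidden layers L (layer 0 is the stimulus)."""
        return len(self.layer_widths)

    @property
    def widths(self) -> tuple[int, ...]:
        """Full width list including the stimulus layer, index 0..L."""
        return (self.stimulus_dim, *self.layer_widths)


@dataclass
class NormState:
    """Running batch-normalization statistics for one nonlinearity site."""

    running_mean: np.ndarray
    running_var: np.ndarray
    momentum: float = 0.1
    mode: str = "training"  # "training" | "frozen"

    @classmethod
    def create(cls, shape: tuple[int, ...], momentum: float = 0.1) -> "NormState":
        return cls(np.zeros(shape), np.ones(shape), momentum=momentum)

    def stats(self, x: np.ndarray, training):
        """Return (mean, var) for normalizing ``x``.

        ``training`` may be True (batch statistics, running stats updated),
        False (stored running statistics), "batch" (batch statistics
        without touching the running stats — used for ensemble simulation),
        or None (follow ``self.mode``).
        """
        if training is None:
            training = self.mode == "training"
        if training:
            if x.shape[0] < 2:
                raise DegenerateBatchError(
                    "batch-statistics normalization needs a batch of size >= 2"
                )
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            if training != "batch":
                m = self.momentum
                self.running_mean = (1.0 - m) * self.running_mean + m * mean
                self.running_var = (1.0 - m) * self.running_var + m * var
            return mean, var
        return self.running_mean, self.running_var


@dataclass
class CompartmentParams:
    """Parameters of one compartmental mapping (basal, apical, or h2).

    Arrays are indexed [unit, branch, presynaptic] for ``W`` and
    [unit, branch] for the per-branch quantities.  ``rho`` is the softplus
    pre-parameter of the branch conductance.  ``soma="norm"`` applies
    tanh + affine-free batch normalization at the soma; ``soma="norm_affine"``
    adds a learnable per-unit scale/shift after the normalization (used for
    the generative drive into the stimulus layer, whose target is fixed
    pixel data rather than normalized unit activity); ``soma="exp"``
    (variance head) applies a bare exponential.
    """

    W: np.ndarray  # [width, n_branches, fan_in]
    c: np.ndarray  # [width, n_branches]
    rho: np.ndarray  # [width, n_branches]; conductance = softplus(rho)
    b: np.ndarray  # [width]
    gamma: np.ndarray  # [width, n_branches] branch-norm scale
    beta: np.ndarray  # [width, n_branches] branch-norm shift
    sg: np.ndarray = None  # type: ignore[assignment]  # [width] soma-affine scale
    sb: np.ndarray = None  # type: ignore[assignment]  # [width] soma-affine shift
    branch_norm: NormState = None  # type: ignore[assignment]
    soma_norm: NormState | None = None
    soma: str = "norm"

    @property
    def width(self) -> int:
        return self.W.shape[0]

    @property
    def n_branches(self) -> int:
        return self.W.shape[1]

    @property
    def fan_in(self) -> int:
        return self.W.shape[2]

    @property
    def conductance(self) -> np.ndarray:
        """Strictly positive branch conductances softplus(rho)."""
        return softplus(self.rho)

    @classmethod
    def create(
        cls,
        width: int,
        fan_in: int,
        n_branches: int,
        rng: np.random.Generator,
        soma: str = "norm",
        momentum: float = 0.1,
    ) -> "CompartmentParams":
        W = rng.standard_normal((width, n_branches, fan_in)) / np.sqrt(fan_in)
        # softplus(0.5413) ~= 1: start every branch at unit conductance
        rho = np.full((width, n_branches), float(np.log(np.expm1(1.0))))
        return cls(
            W=W,
            c=np.zeros((width, n_branches)),
            rho=rho,
            b=np.zeros(width),
            gamma=np.ones((width, n_branches)),
            beta=np.zeros((width, n_branches)),
            sg=np.ones(width),
            sb=np.zeros(width),
            branch_norm=NormState.create((width, n_branches), momentum),
            soma_norm=None if soma == "exp" else NormState.create((width,), momentum),
            soma=soma,
        )


@dataclass
class ActivityState:
    """Per-layer unit activities for a batch; ``r[0]`` is the stimulus."""

    r: list[np.ndarray]

    @property
    def batch_size(self) -> int:
        return self.r[0].shape[0]

    def copy(self) -> "ActivityState":
        return ActivityState([x.copy() for x in self.r])


@dataclass
class NetworkParams:
    """All recognition (basal) and generative (apical) parameters.

    ``recognition[l-1]`` maps layer l-1 activity to the basal drive of layer
    l (l = 1..L); ``h2`` maps layer L-1 to the top layer's diagonal
    variances; ``generative[l]`` maps layer l+1 to the apical drive of layer
    l (l = 0..L-1, with layer 0 having ``stimulus_dim`` units).
    """

    config: NetworkConfig
    recognition: list[CompartmentParams]
    h2: CompartmentParams
    generative: list[CompartmentParams]

    @property
    def n_layers(self) -> int:
        return self.config.n_layers

    def compartments(self):
        """Yield (name, CompartmentParams) for every compartment."""
        for l, p in enumerate(self.recognition):
            yield f"rec/{l + 1}", p
        yield "h2", self.h2
        for l, p in enumerate(self.generative):
            yield f"gen/{l}", p


def softplus(x: np.ndarray) -> np.ndarray:
    """Numerically stable log(1 + exp(x))."""
    return np.logaddexp(0.0, x)


def init_network(config: NetworkConfig) -> NetworkParams:
    """Initialize all parameters from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    widths = config.widths
    L = config.n_layers
    nb = config.n_branches
    recognition = [
        CompartmentParams.create(widths[l], widths[l - 1], nb, rng)
        for l in range(1, L + 1)
    ]
    h2 = CompartmentParams.create(widths[L], widths[L - 1], nb, rng, soma="exp")
    generative = [
        CompartmentParams.create(
            widths[l],
            widths[l + 1],
            nb,
            rng,
            soma="norm_affine" if l == 0 else "norm",
        )
        for l in range(0, L)
    ]
    return NetworkParams(config, recognition, h2, generative)


def freeze_norms(net: NetworkParams) -> NetworkParams:
    """Freeze every normalization site to its running statistics."""
    for _, p in net.compartments():
        p.branch_norm.mode = "frozen"
        if p.soma_norm is not None:
            p.soma_norm.mode = "frozen"
    return net


# ---------------------------------------------------------------------------
# forward drives


@dataclass
class DriveCache:
    """Intermediates of one compartment forward pass, for analytic updates."""

    x: np.ndarray  # input [batch, fan_in]
    tanh_v: np.ndarray  # branch tanh [batch, width, nb]
    u: np.ndarray  # branch output after norm+affine [batch, width, nb]
    branch_inv_std: np.ndarray  # 1/sqrt(var+eps) used for branch norm [width, nb]
    branch_that: np.ndarray  # normalized pre-affine branch activity
    v_total: np.ndarray  # soma input [batch, width]
    soma_inv_std: np.ndarray | None  # [width] (norm somas only)
    tanh_vt: np.ndarray | None  # soma tanh (norm somas only)
    soma_that: np.ndarray | None  # normalized pre-affine soma activity
    out: np.ndarray  # drive [batch, width]


def compartment_forward(
    params: CompartmentParams, x: np.ndarray, training: bool | None = None
) -> DriveCache:
    """Full drive of one compartment; returns the cache (``.out`` is the drive)."""
    if x.ndim != 2 or x.shape[1] != params.fan_in:
        raise ValueError(
            f"input shape {x.shape} incompatible with fan-in {params.fan_in}"
        )
    v = np.einsum("inj,bj->bin", params.W, x) + params.c
    tanh_v = np.tanh(v)
    mean, var = params.branch_norm.stats(tanh_v, training)
    inv_std = 1.0 / np.sqrt(var + _NORM_EPS)
    that = (tanh_v - mean) * inv_std
    u = params.gamma * that + params.beta
    w = params.conductance
    v_total = np.einsum("in,bin->bi", w, u) + params.b
    if params.soma == "exp":
        out = np.exp(v_total)
        soma_inv_std = None
        tanh_vt = None
        soma_that = None
    else:
        tanh_vt = np.tanh(v_total)
        s_mean, s_var = params.soma_norm.stats(tanh_vt, training)
        soma_inv_std = 1.0 / np.sqrt(s_var + _NORM_EPS)
        soma_that = (tanh_vt - s_mean) * soma_inv_std
        if params.soma == "norm_affine":
            out = params.sg * soma_that + params.sb
        else:
            out = soma_that
    return DriveCache(
        x=x,
        tanh_v=tanh_v,
        u=u,
        branch_inv_std=inv_std,
        branch_that=that,
        v_total=v_total,
        soma_inv_std=soma_inv_std,
        tanh_vt=tanh_vt,
        soma_that=soma_that,
        out=out,
    )


def branch_drive(
    params: CompartmentParams,
    x: np.ndarray,
    branch_index: int,
    training: bool | None = None,
) -> np.ndarray:
    """Output of a single dendritic branch, ``phi_d(W_n x + c_n)``."""
    if branch_index >= params.n_branches:
        raise ValueError(
            f"branch_index {branch_index} out of range ({params.n_branches} branches)"
        )
    cache = compartment_forward(params, x, training)
    return cache.u[:, :, branch_index]


def basal_drive(
    params: CompartmentParams, r_below: np.ndarray, training: bool | None = None
) -> np.ndarray:
    """Bottom-up drive h(r_below) of one layer."""
    return compartment_forward(params, r_below, training).out


def apical_drive(
    params: CompartmentParams, r_above: np.ndarray, training: bool | None = None
) -> np.ndarray:
    """Top-down drive mu(r_above) of one layer (same form as the basal drive)."""
    return compartment_forward(params, r_above, training).out


def top_variance_drive(
    params_h2: CompartmentParams, r_below: np.ndarray, training: bool | None = None
) -> np.ndarray:
    """Strictly positive diagonal variances of the top-layer inference distribution."""
    return compartment_forward(params_h2, r_below, training).out


# ---------------------------------------------------------------------------
# interpolation


def interpolate(a, b, alpha: float, kappa: float):
    """Soft-max interpolation ``kappa * log((1-alpha) e^{a/kappa} + alpha e^{b/kappa})``.

    Reduces to linear interpolation as kappa -> inf and to max(a, b) as
    kappa -> 0 (for interior alpha); the endpoints return ``a`` / ``b``
    exactly.  Applied elementwise; ``a`` and ``b`` broadcast.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if alpha == 0.0:
        return (a + 0.0 * b) if b.shape != a.shape else a.copy()
    if alpha == 1.0:
        return (b + 0.0 * a) if a.shape != b.shape else b.copy()
    m = np.maximum(a, b)
    out = m + kappa * np.log(
        (1.0 - alpha) * np.exp((a - m) / kappa) + alpha * np.exp((b - m) / kappa)
    )
    return out


# ---------------------------------------------------------------------------
# one-shot sampling


def sample_wake(
    net: NetworkParams,
    stimulus: np.ndarray,
    rng: np.random.Generator,
    training: bool | None = None,
) -> ActivityState:
    """Sequential bottom-up sample: r^l ~ N(h(r^{l-1}), sigma_b^2 I).

    The top layer is sampled with the learned diagonal variance
    ``diag(h2(r^{L-1}))``; ``r[0]`` is the stimulus unchanged.
    """
    cfg = net.config
    if stimulus.ndim != 2 or stimulus.shape[1] != cfg.stimulus_dim:
        raise ValueError(
            f"stimulus shape {stimulus.shape} incompatible with stimulus_dim "
            f"{cfg.stimulus_dim}"
        )
    L = cfg.n_layers
    r = [np.asarray(stimulus, dtype=float)]
    for l in range(1, L + 1):
        h = basal_drive(net.recognition[l - 1], r[l - 1], training)
        if l == L:
            var = top_variance_drive(net.h2, r[L - 1], training)
            noise = np.sqrt(var) * rng.standard_normal(h.shape)
        else:
            noise = cfg.sigma_b * rng.standard_normal(h.shape)
        r.append(h + noise)
    return ActivityState(r)


def sample_sleep(
    net: NetworkParams,
    batch: int,
    rng: np.random.Generator,
    training: bool | None = None,
) -> ActivityState:
    """Top-down ancestral sample from the generative model.

    The top layer is standard normal; each lower layer follows
    r^l ~ N(mu(r^{l+1}), sigma_p^2 I) down to a generated stimulus image.
    """
    if batch < 1:
        raise ValueError("batch must be >= 1")
    cfg = net.config
    L = cfg.n_layers
    r: list[np.ndarray | None] = [None] * (L + 1)
    r[L] = rng.standard_normal((batch, cfg.widths[L]))
    for l in range(L - 1, -1, -1):
        mu = apical_drive(net.generative[l], r[l + 1], training)
        r[l] = mu + cfg.sigma_p * rng.standard_normal(mu.shape)
    return ActivityState(r)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# serialization


def _compartment_arrays(name: str, p: CompartmentParams) -> dict[str, np.ndarray]:
    d = {
        f"{name}/W": p.W,
        f"{name}/c": p.c,
        f"{name}/rho": p.rho,
        f"{name}/b": p.b,
        f"{name}/gamma": p.gamma,
        f"{name}/beta": p.beta,
        f"{name}/sg": p.sg,
        f"{name}/sb": p.sb,
        f"{name}/branch_mean": p.branch_norm.running_mean,
        f"{name}/branch_var": p.branch_norm.running_var,
    }
    if p.soma_norm is not None:
        d[f"{name}/soma_mean"] = p.soma_norm.running_mean
        d[f"{name}/soma_var"] = p.soma_norm.running_var
    return d


def save_network(path: str | Path, net: NetworkParams) -> None:
    """Write parameters to ``<path>.npz`` plus a JSON config sidecar."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    modes: dict[str, str] = {}
    for name, p in net.compartments():
        arrays.update(_compartment_arrays(name, p))
        modes[name] = p.branch_norm.mode
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "config": dataclasses.asdict(net.config),
        "norm_modes": modes,
        "momentum": net.recognition[0].branch_norm.momentum,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_network(path: str | Path) -> NetworkParams:
    """Exact round-trip of :func:`save_network`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = dict(sidecar["config"])
    cfg_dict["layer_widths"] = tuple(cfg_dict["layer_widths"])
    config = NetworkConfig(**cfg_dict)
    net = init_network(config)
    with np.load(path.with_suffix(".npz")) as data:
        for name, p in net.compartments():
            p.W = data[f"{name}/W"]
            p.c = data[f"{name}/c"]
            p.rho = data[f"{name}/rho"]
            p.b = data[f"{name}/b"]
            p.gamma = data[f"{name}/gamma"]
            p.beta = data[f"{name}/beta"]
            p.sg = data[f"{name}/sg"]
            p.sb = data[f"{name}/sb"]
            p.branch_norm.running_mean = data[f"{name}/branch_mean"]
            p.branch_norm.running_var = data[f"{name}/branch_var"]
            p.branch_norm.momentum = sidecar["momentum"]
            p.branch_norm.mode = sidecar["norm_modes"][name]
            if p.soma_norm is not None:
                p.soma_norm.running_mean = data[f"{name}/soma_mean"]
                p.soma_norm.running_var = data[f"{name}/soma_var"]
                p.soma_norm.momentum = sidecar["momentum"]
                p.soma_norm.mode = sidecar["norm_modes"][name]
    return net
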