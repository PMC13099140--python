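"""Dose-dependent network dynamics: hallucination simulation and controls.

At each step every layer relaxes toward a soft-max interpolation between its
bottom-up drive ``h`` and top-down drive ``mu``:

    r_t = (1 - gamma) r_{t-1} + gamma f(h, mu, alpha)
          + f(sigma_b, sigma_p, alpha) sqrt(gamma (2 - gamma)) eta_t

with ``gamma`` the per-step update fraction and ``eta_t`` standard normal.
The noise prefactor is the standard AR(1) discretization choice: the
stationary noise variance equals f(sigma_b, sigma_p, alpha)^2 for every
gamma, so slow dynamics do not shrink the per-unit noise floor relative to
one-shot sampling.  With gamma = 1 a single step reproduces exactly the
sampling used during training (Wake at alpha=0, Sleep at alpha=1).  The stimulus layer's
"bottom-up drive" is the external image itself (closed-eye: an all-zeros
image), so at alpha=0 the sensory layer relaxes to the image plus noise and
at alpha>0 hallucinated top-down content mixes in through ``f``.  The top
layer's top-down drive is its standard-normal prior mean (0), with noise
interpolated between the learned Wake variance sqrt(h2) and the prior's 1.

A noise-based control replaces the apical contribution entirely: dynamics
follow the bottom-up drive alone while injected noise grows linearly with
alpha (s.d. sigma_b + alpha).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from wakesleep.model import (
    ActivityState,
    NetworkParams,
    basal_drive,
    apical_drive,
    interpolate,
    sample_wake,
    top_variance_drive,
)

__all__ = [
    "SimConfig",
    "DriveBundle",
    "HallucinationTrace",
    "apply_inactivation",
    "hallucinate_step",
    "simulate",
    "simulate_noise_control",
]

CONDITIONS = ("stimulus", "closed_eye", "noise_control")
INACTIVATIONS = ("none", "apical_stim_layer", "deepest_layer")


@dataclass(frozen=True)
class SimConfig:
    """Hallucination-simulation settings.

    ``mix`` is the per-step update fraction gamma; ``burn_in`` is the number
    of initial steps excluded from downstream statistics.
    """

    alpha: float = 0.0
    n_steps: int = 800
    mix: float = 0.1
    kappa: float = 0.35
    condition: str = "stimulus"
    inactivation: str = "none"
    burn_in: int = 200
    record_layers: tuple[int, ...] | None = None  # None = all layers
    record_stride: int = 1  # record every k-th step (final step always kept)
    # normalization during simulation: "frozen" running statistics (single
    # stimuli well-defined) or "batch" statistics across the simulated
    # ensemble (matches training-time normalization behavior)
    norm_mode: str = "frozen"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 < self.mix <= 1.0:
            raise ValueError("mix must lie in (0, 1]")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.inactivation not in INACTIVATIONS:
            raise ValueError(f"unknown inactivation {self.inactivation!r}")
        if not 0 <= self.burn_in < self.n_steps:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_steps")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if self.norm_mode not in ("frozen", "batch"):
            raise ValueError(f"unknown norm_mode {self.norm_mode!r}")


@dataclass
class DriveBundle:
    """Per-layer bottom-up and top-down drives for one dynamics step."""

    bottom_up: list[np.ndarray]
    top_down: list[np.ndarray]
    clamp_top: bool = False


def apply_inactivation(bundle: DriveBundle, kind: str) -> DriveBundle:
    """Apply a circuit manipulation to the drives of one step.

    ``apical_stim_layer`` zeroes the apical (top-down) drive into the
    stimulus layer before interpolation; ``deepest_layer`` marks the top
    layer for clamping to zero.
    """
    if kind == "none":
        return bundle
    if kind == "apical_stim_layer":
        bundle.top_down[0] = np.zeros_like(bundle.top_down[0])
    elif kind == "deepest_layer":
        bundle.clamp_top = True
    else:
        raise ValueError(f"unknown inactivation {kind!r}")
    return bundle


def _norm_flag(cfg: SimConfig):
    return "batch" if cfg.norm_mode == "batch" else False


def _compute_drives(
    net: NetworkParams, prev: ActivityState, stimulus: np.ndarray, training=False
) -> tuple[DriveBundle, np.ndarray]:
    """All drives from the previous state; returns (bundle, h2)."""
    L = net.config.n_layers
    bu = [np.asarray(stimulus, dtype=float)]
    for l in range(1, L + 1):
        bu.append(basal_drive(net.recognition[l - 1], prev.r[l - 1], training))
    td = [
        apical_drive(net.generative[l], prev.r[l + 1], training) for l in range(L)
    ]
    td.append(np.zeros_like(bu[L]))  # top layer: standard-normal prior mean
    h2 = top_variance_drive(net.h2, prev.r[L - 1], training)
    return DriveBundle(bu, td), h2


def hallucinate_step(
    net: NetworkParams,
    prev: ActivityState,
    stimulus: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> ActivityState:
    """One step of the interpolated stochastic dynamics."""
    c = net.config
    L = c.n_layers
    g = cfg.mix
    bundle, h2 = _compute_drives(net, prev, stimulus, _norm_flag(cfg))
    bundle = apply_inactivation(bundle, cfg.inactivation)
    new = []
    for l in range(L + 1):
        drive = interpolate(bundle.bottom_up[l], bundle.top_down[l], cfg.alpha, cfg.kappa)
        if l == L:
            noise_sd = interpolate(np.sqrt(h2), 1.0, cfg.alpha, cfg.kappa)
        else:
            noise_sd = interpolate(c.sigma_b, c.sigma_p, cfg.alpha, cfg.kappa)
        r = (
            (1.0 - g) * prev.r[l]
            + g * drive
            + noise_sd * np.sqrt(g * (2.0 - g)) * rng.standard_normal(prev.r[l].shape)
        )
        new.append(r)
    if bundle.clamp_top:
        new[L] = np.zeros_like(new[L])
    state = ActivityState(new)
    for l, r in enumerate(state.r):
        if not np.all(np.isfinite(r)):
            raise FloatingPointError(f"non-finite activity in layer {l}")
    return state


def _noise_control_step(
    net: NetworkParams,
    prev: ActivityState,
    stimulus: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> ActivityState:
    """One step of the noise-based control: bottom-up drive only, s.d. sigma_b+alpha."""
    c = net.config
    L = c.n_layers
    g = cfg.mix
    bundle, _ = _compute_drives(net, prev, stimulus, _norm_flag(cfg))
    bundle = apply_inactivation(bundle, cfg.inactivation)
    noise_sd = c.sigma_b + cfg.alpha
    new = []
    for l in range(L + 1):
        r = (
            (1.0 - g) * prev.r[l]
            + g * bundle.bottom_up[l]
            + noise_sd * np.sqrt(g * (2.0 - g)) * rng.standard_normal(prev.r[l].shape)
        )
        new.append(r)
    if bundle.clamp_top:
        new[L] = np.zeros_like(new[L])
    return ActivityState(new)


@dataclass
class HallucinationTrace:
    """Recorded activity over time.

    ``layers[l]`` has shape [T_rec, batch, width]; ``steps`` holds the
    simulation step index of each recorded frame (0-based).
    """

    layers: dict[int, np.ndarray]
    steps: np.ndarray
    config: SimConfig
    stimulus: np.ndarray

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def final(self, layer: int) -> np.ndarray:
        """Final-step activity, [batch, width]."""
        return self.layers[layer][-1]

    def post_burn(self, layer: int) -> np.ndarray:
        """Recorded activity after burn-in, [T', batch, width]."""
        return self.layers[layer][self.steps >= self.config.burn_in]


def _run(
    net: NetworkParams,
    stimuli: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    step_fn,
    callback=None,
) -> HallucinationTrace:
    L = net.config.n_layers
    stim = np.zeros_like(stimuli) if cfg.condition == "closed_eye" else np.asarray(
        stimuli, dtype=float
    )
    state = sample_wake(net, stim, rng, training=_norm_flag(cfg))
    if cfg.inactivation == "deepest_layer":
        state.r[L] = np.zeros_like(state.r[L])
    record = (
        tuple(range(L + 1)) if cfg.record_layers is None else tuple(cfg.record_layers)
    )
    buffers: dict[int, list[np.ndarray]] = {l: [] for l in record}
    steps: list[int] = []
    for t in range(cfg.n_steps):
        try:
            state = step_fn(net, state, stim, cfg, rng)
        except FloatingPointError as exc:
            raise FloatingPointError(f"step {t}: {exc}") from exc
        if (t + 1) % cfg.record_stride == 0 or t == cfg.n_steps - 1:
            steps.append(t)
            for l in record:
                buffers[l].append(state.r[l])
        if callback is not None:
            callback(t, state)
    layers = {l: np.stack(buffers[l]) for l in record}
    return HallucinationTrace(
        layers=layers,
        steps=np.asarray(steps, dtype=int),
        config=cfg,
        stimulus=np.asarray(stimuli),
    )


def simulate(
    net: NetworkParams,
    stimuli: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    callback=None,
) -> HallucinationTrace:
    """Simulate interpolated dynamics for ``cfg.n_steps`` steps.

    The state is initialized from a Wake sample of the stimulus (closed-eye:
    of the zero image), making alpha=0 trajectories stationary from the
    start.  ``callback(t, state)``, if given, is invoked after every step
    (used for streaming statistics without recording full traces).
    """
    if cfg.condition == "noise_control":
        return simulate_noise_control(net, stimuli, cfg, rng, callback)
    return _run(net, stimuli, cfg, rng, hallucinate_step, callback)


def simulate_noise_control(
    net: NetworkParams,
    stimuli: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    callback=None,
) -> HallucinationTrace:
    """Noise-based control protocol: no apical contribution, noise grows with alpha."""
    return _run(net, stimuli, cfg, rng, _noise_control_step, callback)
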