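"""Quantitative analyses of trained networks and hallucination traces.

Covers: apical/basal drive alignment, induced-plasticity magnitude (relative
parameter change) and alignment (cosine similarity), stimulus-conditioned
temporal variability, stimulus decoding with a separate perceptron
classifier, pairwise-correlation-matrix similarity, principal-component
explained-variance spectra, and inactivation variance ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from wakesleep.dynamics import HallucinationTrace, SimConfig, simulate
from wakesleep.model import (
    NetworkParams,
    basal_drive,
    apical_drive,
    sample_wake,
)
from wakesleep.training import (
    UpdateVector,
    generative_update,
    recognition_update,
)

__all__ = [
    "MetricRecord",
    "records_to_frame",
    "apical_basal_alignment",
    "alignment_from_drives",
    "accumulate_plasticity",
    "plasticity_magnitude",
    "relative_plasticity",
    "plasticity_alignment",
    "stimulus_conditioned_variability",
    "across_stimulus_reference",
    "ClassifierParams",
    "mlp_logits",
    "fit_mlp",
    "train_classifier",
    "evaluate_classifier",
    "logit_variability",
    "correlation_similarity",
    "pc_spectrum",
    "participation_ratio",
    "variance_ratio",
]


@dataclass(frozen=True)
class MetricRecord:
    """One long-format analysis result."""

    metric: str
    alpha: float
    layer: int | str
    condition: str
    value: float
    stderr: float
    n: int

    def __post_init__(self) -> None:
        if self.stderr < 0 or self.n < 1:
            raise ValueError("stderr must be >= 0 and n >= 1")


def records_to_frame(records: list[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    return float(x.std(ddof=1) / np.sqrt(x.size))


# ---------------------------------------------------------------------------
# alignment


class AlignmentResult(NamedTuple):
    same_neuron: float
    random_pair: float
    same_sem: float
    random_sem: float
    per_neuron_same: np.ndarray
    per_neuron_random: np.ndarray
    n_excluded: int


def apical_basal_alignment(
    net: NetworkParams, test_set: np.ndarray, rng: np.random.Generator
) -> AlignmentResult:
    """Correlation between a neuron's basal and apical drives across stimuli.

    Computes Wake responses on the test set, then for every neuron in layers
    that receive both pathways (1..L-1) the Pearson correlation across
    stimuli between h_i and mu_i; the baseline pairs each neuron's basal
    drive with a random *other* neuron's apical drive in the same layer.
    Zero-variance drives are excluded and counted.
    """
    L = net.config.n_layers
    act = sample_wake(net, test_set, rng, training=False)
    drive_pairs = []
    for l in range(1, L):
        h = basal_drive(net.recognition[l - 1], act.r[l - 1], training=False)
        mu = apical_drive(net.generative[l], act.r[l + 1], training=False)
        drive_pairs.append((h, mu))
    return alignment_from_drives(drive_pairs, rng)


def alignment_from_drives(
    drive_pairs: list[tuple[np.ndarray, np.ndarray]], rng: np.random.Generator
) -> AlignmentResult:
    """Same-neuron vs random-pair correlation from (basal, apical) drive arrays."""
    same, rand = [], []
    n_excluded = 0
    for h, mu in drive_pairs:
        hs = h.std(axis=0)
        ms = mu.std(axis=0)
        width = h.shape[1]
        perm = _derangement(width, rng)
        for i in range(width):
            j = perm[i]
            if hs[i] == 0 or ms[i] == 0 or ms[j] == 0:
                n_excluded += 1
                continue
            same.append(_pearson(h[:, i], mu[:, i]))
            rand.append(_pearson(h[:, i], mu[:, j]))
    same_arr = np.asarray(same)
    rand_arr = np.asarray(rand)
    return AlignmentResult(
        same_neuron=float(same_arr.mean()),
        random_pair=float(rand_arr.mean()),
        same_sem=_sem(same_arr),
        random_sem=_sem(rand_arr),
        per_neuron_same=same_arr,
        per_neuron_random=rand_arr,
        n_excluded=n_excluded,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random pairing i -> j with j != i (n >= 2)."""
    if n < 2:
        return np.zeros(n, dtype=int)
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


# ---------------------------------------------------------------------------
# plasticity


def accumulate_plasticity(
    net: NetworkParams,
    test_set: np.ndarray,
    alpha: float,
    gated: bool,
    eta: float,
    sim_cfg: SimConfig,
    rng: np.random.Generator,
    image_batch: int = 64,
    update_stride: int = 1,
) -> UpdateVector:
    """Net parameter increments induced by hallucination dynamics.

    For each image, simulates the interpolated dynamics and accumulates the
    delta-rule updates at every post-burn-in step; increments are summed
    over steps and images.  With ``gated`` the usual alpha / (1-alpha)
    plasticity gates apply; without, both pathways learn at full rate.
    ``update_stride`` > 1 accumulates every k-th post-burn-in step scaled by
    k — an unbiased thinning of the step sum used to keep long protocols
    cheap.
    """
    rec_alpha = alpha if gated else 1.0
    gen_alpha = alpha if gated else 0.0
    sim_cfg = replace(sim_cfg, alpha=alpha, record_layers=())
    total = UpdateVector()
    for start in range(0, len(test_set), image_batch):
        stim = test_set[start : start + image_batch]
        B = len(stim)

        norm_flag = "batch" if sim_cfg.norm_mode == "batch" else False

        def accumulate(t: int, state) -> None:
            if t < sim_cfg.burn_in or (t - sim_cfg.burn_in) % update_stride:
                return
            scale = B * update_stride  # batch-mean -> image sum, thinned steps
            ur = recognition_update(net, state, rec_alpha, eta, training=norm_flag)
            ug = generative_update(net, state, gen_alpha, eta, training=norm_flag)
            total.iadd(ur, scale=scale)
            total.iadd(ug, scale=scale)

        simulate(net, stim, sim_cfg, rng, callback=accumulate)
    return total


def relative_plasticity(
    net: NetworkParams, delta: UpdateVector, eps: float = 1e-2
) -> dict[str, tuple[float, float, int]]:
    """Mean relative parameter change |d_theta| / (|theta| + eps) per group.

    Returns {group: (mean, sem, n_parameters)} for the apical and basal
    parameter groups.
    """
    from wakesleep.training import iter_params

    params = {key: arr for key, arr, _ in iter_params(net)}
    out = {}
    for group in ("apical", "basal"):
        vals = []
        for key, inc in delta.entries.items():
            if delta.group[key] != group:
                continue
            rel = np.abs(inc) / (np.abs(params[key]) + eps)
            vals.append(rel.ravel())
        flat = np.concatenate(vals) if vals else np.zeros(0)
        out[group] = (float(flat.mean()) if flat.size else 0.0, _sem(flat), flat.size)
    return out


class PlasticityResult(NamedTuple):
    apical: float
    basal: float
    apical_sem: float
    basal_sem: float
    n_apical: int
    n_basal: int


def plasticity_magnitude(
    net: NetworkParams,
    test_set: np.ndarray,
    alpha: float,
    gated: bool,
    eta: float,
    sim_cfg: SimConfig,
    rng: np.random.Generator,
    eps: float = 1e-2,
    **accumulate_kwargs,
) -> PlasticityResult:
    """Relative plasticity induced by viewing the test ensemble at dose alpha."""
    delta = accumulate_plasticity(
        net, test_set, alpha, gated, eta, sim_cfg, rng, **accumulate_kwargs
    )
    rel = relative_plasticity(net, delta, eps=eps)
    (am, asem, na), (bm, bsem, nb) = rel["apical"], rel["basal"]
    return PlasticityResult(am, bm, asem, bsem, na, nb)


def plasticity_alignment(
    updates_drug: UpdateVector, updates_baseline: UpdateVector
) -> dict[str, float]:
    """Cosine similarity between drug and baseline update vectors, per group.

    A zero-norm vector makes the similarity undefined; it is reported as NaN.
    """
    if set(updates_drug.entries) != set(updates_baseline.entries):
        raise ValueError("update vectors cover different parameter sets")
    out = {}
    for group in ("apical", "basal"):
        a = updates_drug.flat(group)
        b = updates_baseline.flat(group)
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        out[group] = float(a @ b / (na * nb)) if na > 0 and nb > 0 else float("nan")
    return out


# ---------------------------------------------------------------------------
# variability


def stimulus_conditioned_variability(
    trace: HallucinationTrace, layer_index: int = 1
) -> MetricRecord:
    """Per-neuron temporal variance at fixed stimulus, averaged over units.

    Variance is taken across post-burn-in timesteps separately per (neuron,
    stimulus), then averaged; the standard error is over those per-(neuron,
    stimulus) values.
    """
    x = trace.post_burn(layer_index)  # [T', B, N]
    v = x.var(axis=0, ddof=1).ravel()  # [B*N]
    return MetricRecord(
        metric="stimulus_conditioned_variability",
        alpha=trace.config.alpha,
        layer=layer_index,
        condition=trace.config.condition,
        value=float(v.mean()),
        stderr=_sem(v),
        n=v.size,
    )


def across_stimulus_reference(
    trace: HallucinationTrace, layer_index: int = 1
) -> MetricRecord:
    """Across-stimulus variance of each neuron's time-averaged activity."""
    x = trace.post_burn(layer_index).mean(axis=0)  # [B, N]
    v = x.var(axis=0, ddof=1)  # per neuron
    return MetricRecord(
        metric="across_stimulus_variability",
        alpha=trace.config.alpha,
        layer=layer_index,
        condition=trace.config.condition,
        value=float(v.mean()),
        stderr=_sem(v),
        n=v.size,
    )


# ---------------------------------------------------------------------------
# classifier


@dataclass
class ClassifierParams:
    """One-hidden-layer (256 units, tanh) perceptron for stimulus decoding."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray


def mlp_logits(clf: ClassifierParams, X: np.ndarray) -> np.ndarray:
    return np.tanh(X @ clf.W1 + clf.b1) @ clf.W2 + clf.b2


def fit_mlp(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    rng: np.random.Generator,
    hidden: int = 256,
    n_epochs: int = 100,
    lr: float = 1e-3,
    batch_size: int = 64,
) -> tuple[ClassifierParams, float]:
    """Train the perceptron on cross-entropy by minibatch Adam.

    Returns the parameters and the final training accuracy.
    """
    n, d = X.shape
    clf = ClassifierParams(
        W1=rng.standard_normal((d, hidden)) / np.sqrt(d),
        b1=np.zeros(hidden),
        W2=rng.standard_normal((hidden, n_classes)) / np.sqrt(hidden),
        b2=np.zeros(n_classes),
    )
    m = {k: np.zeros_like(getattr(clf, k)) for k in ("W1", "b1", "W2", "b2")}
    v = {k: np.zeros_like(getattr(clf, k)) for k in ("W1", "b1", "W2", "b2")}
    t = 0
    onehot = np.eye(n_classes)[y]
    for _ in range(n_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X[idx], onehot[idx]
            hpre = xb @ clf.W1 + clf.b1
            h = np.tanh(hpre)
            logits = h @ clf.W2 + clf.b2
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            if not np.all(np.isfinite(p)):
                raise FloatingPointError("non-finite classifier loss")
            dlogits = (p - yb) / len(idx)
            grads = {
                "W2": h.T @ dlogits,
                "b2": dlogits.sum(axis=0),
            }
            dh = dlogits @ clf.W2.T * (1.0 - h**2)
            grads["W1"] = xb.T @ dh
            grads["b1"] = dh.sum(axis=0)
            t += 1
            for k, g in grads.items():
                m[k] += 0.1 * (g - m[k])
                v[k] += 0.001 * (g**2 - v[k])
                mhat = m[k] / (1.0 - 0.9**t)
                vhat = v[k] / (1.0 - 0.999**t)
                getattr(clf, k)[...] -= lr * mhat / (np.sqrt(vhat) + 1e-8)
    acc = float((mlp_logits(clf, X).argmax(axis=1) == y).mean())
    return clf, acc


def train_classifier(
    net: NetworkParams,
    images: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    layer_index: int = 2,
    **fit_kwargs,
) -> tuple[ClassifierParams, float]:
    """Train the decoder on Wake-phase activity of the chosen layer."""
    act = sample_wake(net, images, rng, training=False)
    n_classes = int(labels.max()) + 1
    return fit_mlp(act.r[layer_index], labels, n_classes, rng, **fit_kwargs)


def evaluate_classifier(
    clf: ClassifierParams,
    trace: HallucinationTrace,
    labels: np.ndarray,
    layer_index: int = 2,
) -> tuple[float, float]:
    """Decode final-step activity; returns (accuracy, mean logit variance).

    Logit variance is the variance of each logit dimension across the
    evaluation set, averaged over dimensions.
    """
    X = trace.final(layer_index)
    logits = mlp_logits(clf, X)
    acc = float((logits.argmax(axis=1) == labels).mean())
    logit_var = float(logits.var(axis=0, ddof=1).mean())
    return acc, logit_var


def logit_variability(
    clf: ClassifierParams, trace: HallucinationTrace, layer_index: int = 2
) -> float:
    """Stimulus-conditioned variability of the decoder's logits.

    Variance of each logit dimension across post-burn-in frames at fixed
    stimulus, averaged over stimuli and dimensions — the decoder-output
    analogue of stimulus-conditioned neural variability.  (The variance of
    final-step logits *across* the evaluation set, returned by
    :func:`evaluate_classifier`, is dominated by class signal at low dose.)
    """
    x = trace.post_burn(layer_index)  # [T', B, N]
    logits = mlp_logits(clf, x.reshape(-1, x.shape[2])).reshape(
        x.shape[0], x.shape[1], -1
    )
    return float(logits.var(axis=0, ddof=1).mean())


# ---------------------------------------------------------------------------
# population structure


def _final_correlations(
    x: np.ndarray, keep: np.ndarray
) -> np.ndarray:
    return np.corrcoef(x[:, keep].T)


def correlation_similarity(
    trace_a: HallucinationTrace,
    trace_b: HallucinationTrace,
    layer_index: int = 1,
) -> tuple[float, int]:
    """Similarity of pairwise neuron correlation structure between two traces.

    Builds each trace's neuron x neuron Pearson correlation matrix from
    final-step activity across the stimulus ensemble, then correlates the
    flattened off-diagonal entries.  Neurons constant in either trace are
    excluded; returns (similarity, n_excluded).
    """
    xa = trace_a.final(layer_index)
    xb = trace_b.final(layer_index)
    if xa.shape[1] != xb.shape[1]:
        raise ValueError("traces have different neuron counts")
    keep = (xa.std(axis=0) > 0) & (xb.std(axis=0) > 0)
    n_excluded = int((~keep).sum())
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant neurons")
    ca = _final_correlations(xa, keep)
    cb = _final_correlations(xb, keep)
    mask = ~np.eye(ca.shape[0], dtype=bool)
    return float(np.corrcoef(ca[mask], cb[mask])[0, 1]), n_excluded


def pc_spectrum(trace: HallucinationTrace, layer_index: int = 1) -> np.ndarray:
    """Descending explained-variance proportions of final-step activity."""
    x = trace.final(layer_index)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    cov = np.cov(x.T)
    evals = np.linalg.eigvalsh(np.atleast_2d(cov))[::-1]
    evals = np.clip(evals, 0.0, None)
    return evals / evals.sum()


def participation_ratio(proportions: np.ndarray) -> float:
    """Effective dimensionality 1 / sum(p_i^2) of an explained-variance spectrum."""
    p = np.asarray(proportions, dtype=float)
    return float(1.0 / np.sum(p**2))


def variance_ratio(
    trace_inact: HallucinationTrace,
    trace_base: HallucinationTrace,
    layer_index: int = 0,
    eps_v: float = 1e-3,
) -> tuple[np.ndarray, float, float]:
    """Regularized across-stimulus variance ratio after vs before inactivation.

    Per neuron of the chosen layer, VR = (Var_inact + eps_v)/(Var + eps_v)
    with variances across the stimulus ensemble at the final step; equal
    variances (including both zero) give exactly 1.  Returns (per-neuron
    VR, mean, sem).
    """
    vi = trace_inact.final(layer_index).var(axis=0)
    vb = trace_base.final(layer_index).var(axis=0)
    vr = (vi + eps_v) / (vb + eps_v)
    return vr, float(vr.mean()), _sem(vr)
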