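"""Independent finite-difference oracles for the learning rules.

The analytic delta-rule updates should equal gated, scaled gradients of the
corresponding Gaussian log-likelihoods; these helpers compute those
gradients by central differences, treating the network drives as black-box
functions of the parameters (frozen normalization statistics).
"""

import numpy as np

from wakesleep.model import apical_drive, basal_drive, top_variance_drive
from wakesleep.training import iter_params


def wake_loglik(net, act):
    """Batch-mean log N(r^l; h(r^{l-1}), sigma_b^2) summed over layers 1..L."""
    c = net.config
    L = c.n_layers
    total = 0.0
    for l in range(1, L + 1):
        h = basal_drive(net.recognition[l - 1], act.r[l - 1], training=False)
        if l < L:
            total += np.sum(-0.5 * (act.r[l] - h) ** 2 / c.sigma_b**2)
        else:
            var = top_variance_drive(net.h2, act.r[L - 1], training=False)
            total += np.sum(-0.5 * np.log(var) - 0.5 * (act.r[L] - h) ** 2 / var)
    return total / act.batch_size


def sleep_loglik(net, act):
    """Batch-mean log N(r^l; mu(r^{l+1}), sigma_p^2) summed over layers 0..L-1."""
    c = net.config
    total = 0.0
    for l in range(c.n_layers):
        mu = apical_drive(net.generative[l], act.r[l + 1], training=False)
        total += np.sum(-0.5 * (act.r[l] - mu) ** 2 / c.sigma_p**2)
    return total / act.batch_size


def fd_gradients(net, act, loglik, keys, eps=1e-6):
    """Central-difference gradient of ``loglik(net, act)`` for selected parameters."""
    params = {k: arr for k, arr, _ in iter_params(net)}
    grads = {}
    for key in keys:
        arr = params[key]
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            ix = it.multi_index
            old = arr[ix]
            arr[ix] = old + eps
            lp = loglik(net, act)
            arr[ix] = old - eps
            lm = loglik(net, act)
            arr[ix] = old
            g[ix] = (lp - lm) / (2.0 * eps)
        grads[key] = g
    return grads


def max_relative_error(analytic, expected, floor=1e-3):
    """Max |a - e| / max(|e|, floor) over all entries of matching dicts."""
    worst = 0.0
    for key, a in analytic.items():
        e = expected[key]
        rel = np.max(np.abs(a - e) / np.maximum(np.abs(e), floor))
        worst = max(worst, float(rel))
    return worst
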