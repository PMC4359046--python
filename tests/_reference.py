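"""Straight-line reference cross mapping used as an independent oracle.

Deliberately naive: plain Python loops, no precomputation, no shared code
with the package beyond numpy scalars and scipy's Pearson. Used to verify
the fast implementation on small inputs.
"""

import math

import numpy as np
from scipy.stats import pearsonr


def naive_embed(values, E, tau):
    """List of (point tuple, time index): point t = (x[t], x[t-tau], ...)."""
    points = []
    for t in range((E - 1) * tau, len(values)):
        points.append((tuple(values[t - j * tau] for j in range(E)), t))
    return points


def naive_window_sweep(x, y, E, tau, tau_p, lib_sizes, exclusion_window=0):
    """Mean windowed cross-map skill per library size, by brute force.

    Builds the manifold of ``y``, and for every sliding window of each
    library size predicts each held-out ``x[t - tau_p]`` from the E+1
    nearest neighbors (excluding the target and its Theiler window, ties
    broken toward the earlier time), with exponential weights
    exp(-d_i/d_1). Returns {L: (mean_rho, [per-window rho])}.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    manifold = naive_embed(y, E, tau)
    manifold = [(p, t) for (p, t) in manifold if t - tau_p >= 0]
    k = E + 1
    out = {}
    for L in lib_sizes:
        rhos = []
        for s in range(len(manifold) - L + 1):
            window = manifold[s : s + L]
            obs, pred = [], []
            for wi, (pt, t) in enumerate(window):
                cand = []
                for wj, (qt, u) in enumerate(window):
                    if abs(wj - wi) <= exclusion_window:
                        continue
                    dist = math.sqrt(sum((a - b) ** 2 for a, b in zip(pt, qt)))
                    cand.append((dist, u))
                cand.sort(key=lambda c: (c[0], c[1]))
                near = cand[:k]
                d1 = near[0][0]
                if d1 == 0.0:
                    raw = [1.0 if d == 0.0 else 0.0 for d, _ in near]
                else:
                    raw = [math.exp(-d / d1) for d, _ in near]
                total = sum(raw)
                weights = [r / total for r in raw]
                pred.append(sum(w * x[u - tau_p] for w, (_, u) in zip(weights, near)))
                obs.append(x[t - tau_p])
            if np.std(obs) == 0 or np.std(pred) == 0:
                rhos.append(0.0)
            else:
                rhos.append(float(pearsonr(obs, pred).statistic))
        out[L] = (float(np.mean(rhos)), rhos)
    return out
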