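"""Literal, loop-based reference implementations used as independent oracles.

These deliberately mirror the definitions, not the package's vectorised
code paths: plain Python loops, per-window least squares, per-sample
interpolation. Slow but unambiguous.
"""

import numpy as np
from scipy.signal import hilbert


def arrm_reference(x, window=40, overlap=0.5, order=2):
    """Windowed AR residual modulation, one lstsq fit per window."""
    step = int(round(window * (1.0 - overlap)))
    sds = []
    start = 0
    while start + window <= x.size:
        w = x[start:start + window]
        y = w[order:]
        X = np.column_stack([w[order - k - 1: window - k - 1]
                             for k in range(order)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        sds.append(np.std(y - X @ coef))
        start += step
    s = np.asarray(sds)
    med = np.median(s)
    return float(np.median(np.abs(s - med)) / med)


def plv_reference(x, y):
    phx = np.angle(hilbert(x))
    phy = np.angle(hilbert(y))
    acc = 0.0 + 0.0j
    for a, b in zip(phx, phy):
        acc += np.exp(1j * (a - b))
    return abs(acc) / len(phx)


def pli_reference(x, y):
    phx = np.angle(hilbert(x))
    phy = np.angle(hilbert(y))
    acc = 0.0
    for a, b in zip(phx, phy):
        acc += np.sign(np.sin(a - b))
    return abs(acc) / len(phx)


def h2_score_reference(xs, ys, n_bins=10):
    """Equal-count binned piecewise-linear regression of y on x, literally."""
    n = len(xs)
    order = np.argsort(xs, kind="stable")
    edges = [(n * b) // n_bins for b in range(n_bins + 1)]
    xm, ym = [], []
    for b in range(n_bins):
        idx = order[edges[b]: edges[b + 1]]
        xm.append(float(np.mean([xs[i] for i in idx])))
        ym.append(float(np.mean([ys[i] for i in idx])))
    preds = []
    for xv in xs:
        # locate the interpolation segment (clamped for extrapolation)
        s = 0
        while s < n_bins - 2 and xm[s + 1] <= xv:
            s += 1
        dx = xm[s + 1] - xm[s]
        w = (xv - xm[s]) / dx if dx > 0 else 0.0
        preds.append(ym[s] * (1 - w) + ym[s + 1] * w)
    resid = np.asarray(ys) - np.asarray(preds)
    h = 1.0 - resid.var() / np.asarray(ys).var()
    return max(0.0, float(h))


def h2_reference(x, y, delays, n_bins=10):
    """h2(x -> y) maximised over the delay grid."""
    n = len(x)
    best = -1.0
    for d in delays:
        if d >= 0:
            xs, ys = x[: n - d], y[d:]
        else:
            xs, ys = x[-d:], y[: n + d]
        best = max(best, h2_score_reference(xs, ys, n_bins))
    return best


def node_strength_reference(matrix):
    n = matrix.shape[0]
    out = []
    for i in range(n):
        s = 0.0
        for j in range(n):
            if j != i:
                s += matrix[i, j]
        out.append(s / (n - 1))
    return np.asarray(out)


def ks_dplus(pre, post):
    """One-sided statistic D+ = sup_x [F_post(x) - F_pre(x)], by definition."""
    grid = np.concatenate([pre, post])
    f_pre = np.searchsorted(np.sort(pre), grid, side="right") / len(pre)
    f_post = np.searchsorted(np.sort(post), grid, side="right") / len(post)
    return float(np.max(f_post - f_pre))


def ks_permutation_pvalue(pre, post, n_perm, rng):
    """Permutation null of D+ under exchangeability."""
    d_obs = ks_dplus(pre, post)
    pooled = np.concatenate([pre, post])
    n_pre = len(pre)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if ks_dplus(perm[:n_pre], perm[n_pre:]) >= d_obs - 1e-12:
            count += 1
    return count / n_perm
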