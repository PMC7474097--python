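"""Bivariate and multivariate connectivity biomarkers.

Phase-based couplings (PLV, PLI), the delayed nonlinear correlation h2, a
pooled time-domain conditional Granger causality, and the short-time direct
directed transfer function. Each produces one n x n matrix per 5 s segment
(GC: one pooled matrix per situation); matrices are reduced to per-channel
out-strengths downstream.

Vector-autoregressive fits use the lagged-autocovariance (Yule-Walker)
normal equations; pooled fits accumulate lag products within segments only,
never across a segment boundary.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.signal import hilbert


# ---------------------------------------------------------------------------
# phase synchrony

def analytic_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase of the analytic signal, along the last axis."""
    return np.angle(hilbert(x, axis=-1))


def plv_matrix(phases: np.ndarray) -> np.ndarray:
    """Phase locking value |mean_t e^{i(phi_x - phi_y)}| for every pair.

    Symmetric, entries in [0, 1]; identical signals (or any constant phase
    offset) give exactly 1.
    """
    z = np.exp(1j * phases)
    n = phases.shape[-1]
    m = np.abs(z @ z.conj().T) / n
    np.fill_diagonal(m, 0.0)
    return np.minimum(m, 1.0)


def pli_matrix(phases: np.ndarray) -> np.ndarray:
    """Phase lag index |mean_t sign(sin(phi_x - phi_y))| for every pair.

    Discards zero-lag (and anti-phase) synchrony: a consistent lead or lag
    gives 1, a symmetric phase-difference distribution gives 0.
    """
    n_ch = phases.shape[0]
    m = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        d = np.sign(np.sin(phases[i] - phases[i + 1:]))
        m[i, i + 1:] = np.abs(d.mean(axis=-1))
    return m + m.T


def plv_pair(x: np.ndarray, y: np.ndarray) -> float:
    return float(plv_matrix(analytic_phase(np.vstack([x, y])))[0, 1])


def pli_pair(x: np.ndarray, y: np.ndarray) -> float:
    return float(pli_matrix(analytic_phase(np.vstack([x, y])))[0, 1])


# ---------------------------------------------------------------------------
# nonlinear correlation coefficient h2

def _segment_order(full_order: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Sorted index order of x[lo:hi], derived from the full argsort."""
    sel = full_order[(full_order >= lo) & (full_order < hi)]
    return sel - lo


def _h2_score(xs: np.ndarray, ys: np.ndarray, order: np.ndarray,
              n_bins: int) -> float:
    """1 - var(residual)/var(y) of the piecewise-linear regression of y on x
    through equal-count bin means; clamped at 0."""
    n = xs.size
    vy = ys.var()
    if vy <= 0:
        raise ValueError("degenerate pair: var(y) is zero")
    edges = (n * np.arange(n_bins + 1)) // n_bins
    starts = edges[:-1]
    counts = np.diff(edges)
    xm = np.add.reduceat(xs[order], starts) / counts
    ym = np.add.reduceat(ys[order], starts) / counts
    pred = np.interp(xs, xm, ym)
    # extend the outer segments linearly beyond the end centroids
    if xm[1] > xm[0]:
        left = xs < xm[0]
        pred[left] = ym[0] + (ym[1] - ym[0]) / (xm[1] - xm[0]) * (xs[left] - xm[0])
    if xm[-1] > xm[-2]:
        right = xs > xm[-1]
        pred[right] = ym[-1] + (ym[-1] - ym[-2]) / (xm[-1] - xm[-2]) * (xs[right] - xm[-1])
    resid = ys - pred
    return max(0.0, 1.0 - float(resid.var()) / vy)


def h2_pair(x: np.ndarray, y: np.ndarray, delays: tuple[int, ...] = (0,),
            n_bins: int = 10) -> tuple[float, int]:
    """Directed nonlinear correlation h2(x -> y), maximised over delays.

    For delay d the pairing is (x_t, y_{t+d}); x is cut into ``n_bins``
    equal-count bins and y is predicted by linear interpolation through the
    (mean x, mean y) bin centroids, capturing monotone and non-monotone
    dependence alike. Returns (max h2 over the delay grid, argmax delay).
    """
    n = x.size
    if max(abs(d) for d in delays) >= n:
        raise ValueError("delay grid exceeds the segment length")
    full_order = np.argsort(x, kind="stable")
    best, best_d = -1.0, 0
    for d in delays:
        if d >= 0:
            lo, hi = 0, n - d
            ys = y[d:]
        else:
            lo, hi = -d, n
            ys = y[: n + d]
        order = _segment_order(full_order, lo, hi)
        h = _h2_score(x[lo:hi], ys, order, n_bins)
        if h > best:
            best, best_d = h, d
    return best, best_d


@njit(cache=False)
def _h2_all_pairs(data, orders, delays, n_bins):  # pragma: no cover
    n_ch, n = data.shape
    m = np.zeros((n_ch, n_ch))
    seg_order = np.empty(n, dtype=np.int64)
    bin_id = np.empty(n, dtype=np.int64)
    seg_idx = np.empty(n, dtype=np.int64)
    wgt = np.empty(n)
    edges = np.empty(n_bins + 1, dtype=np.int64)
    xm = np.empty(n_bins)
    ym = np.empty(n_bins)
    for i in range(n_ch):
        for d in delays:
            if d >= 0:
                lo, hi, toff = 0, n - d, d
            else:
                lo, hi, toff = -d, n, 0
            n_seg = hi - lo
            cnt = 0
            for t in range(n):
                o = orders[i, t]
                if lo <= o < hi:
                    seg_order[cnt] = o - lo
                    cnt += 1
            for b in range(n_bins + 1):
                edges[b] = (n_seg * b) // n_bins
            for b in range(n_bins):
                s = 0.0
                for p in range(edges[b], edges[b + 1]):
                    s += data[i, lo + seg_order[p]]
                    bin_id[seg_order[p]] = b
                xm[b] = s / (edges[b + 1] - edges[b])
            for t in range(n_seg):
                xv = data[i, lo + t]
                # binary search for the interpolation segment in xm
                a, b = 0, n_bins
                while a < b:
                    mid = (a + b) // 2
                    if xm[mid] <= xv:
                        a = mid + 1
                    else:
                        b = mid
                s = a - 1
                if s < 0:
                    s = 0
                elif s > n_bins - 2:
                    s = n_bins - 2
                dx = xm[s + 1] - xm[s]
                seg_idx[t] = s
                wgt[t] = (xv - xm[s]) / dx if dx > 0 else 0.0
            for j in range(n_ch):
                if j == i:
                    continue
                for b in range(n_bins):
                    ym[b] = 0.0
                sy = 0.0
                syy = 0.0
                for t in range(n_seg):
                    yv = data[j, toff + t]
                    ym[bin_id[t]] += yv
                    sy += yv
                    syy += yv * yv
                for b in range(n_bins):
                    ym[b] /= edges[b + 1] - edges[b]
                vy = syy / n_seg - (sy / n_seg) ** 2
                if vy <= 0:
                    m[i, j] = np.nan
                    continue
                sr = 0.0
                srr = 0.0
                for t in range(n_seg):
                    s = seg_idx[t]
                    p = ym[s] * (1.0 - wgt[t]) + ym[s + 1] * wgt[t]
                    r = data[j, toff + t] - p
                    sr += r
                    srr += r * r
                rv = srr / n_seg - (sr / n_seg) ** 2
                h = 1.0 - rv / vy
                if h < 0.0:
                    h = 0.0
                if h > m[i, j]:
                    m[i, j] = h
    return m


def h2_matrix(data: np.ndarray, delays: tuple[int, ...] = (0,),
              n_bins: int = 10) -> np.ndarray:
    """Directed h2 for every ordered channel pair of one segment.

    Entry (i, j) is h2(i -> j): how well channel i (at the best delay on the
    grid) predicts channel j. The bin partition and interpolation weights
    depend only on the predictor channel and the delay, so each (source,
    delay) pass regresses all target channels at once (compiled inner
    loops); results match the pairwise definition to floating-point
    accuracy.
    """
    data = np.ascontiguousarray(data, dtype=np.float64)
    n_ch, n = data.shape
    if max(abs(d) for d in delays) >= n:
        raise ValueError("delay grid exceeds the segment length")
    orders = np.argsort(data, axis=1, kind="stable")
    m = _h2_all_pairs(data, orders, np.asarray(delays, dtype=np.int64),
                      n_bins)
    if np.isnan(m).any():
        raise ValueError("degenerate channel: zero variance segment")
    return m


# ---------------------------------------------------------------------------
# vector autoregression via lagged autocovariances

def lagged_covariances(epochs: np.ndarray, p: int
                       ) -> tuple[list[np.ndarray], int]:
    """R(k) = E[x_t x_{t-k}^T] for k = 0..p, pooled over segments.

    ``epochs`` is (n_ch, n_epochs, n_samples); products never cross a
    segment boundary. Returns (R list, total sample count).
    """
    n_ch, n_ep, n = epochs.shape
    if p >= n:
        raise ValueError("model order exceeds the segment length")
    R = []
    for k in range(p + 1):
        a = epochs[:, :, k:].reshape(n_ch, -1)
        b = epochs[:, :, : n - k].reshape(n_ch, -1)
        R.append((a @ b.T) / (n_ep * (n - k)))
    return R, n_ep * n


def var_fit(R: list[np.ndarray], p: int) -> tuple[np.ndarray, np.ndarray]:
    """Solve the order-p Yule-Walker system from autocovariances R(0..>=p).

    Returns (A, Sigma): A is (p, n, n) lag-coefficient matrices, Sigma the
    innovation covariance R(0) - sum_k A_k R(k)^T (symmetrised).
    """
    n = R[0].shape[0]
    G = np.empty((p * n, p * n))
    for j in range(p):
        for k in range(p):
            diff = k - j
            blk = R[diff] if diff >= 0 else R[-diff].T
            G[j * n:(j + 1) * n, k * n:(k + 1) * n] = blk
    B = np.hstack([R[k + 1] for k in range(p)])  # (n, p*n)
    try:
        A_flat = np.linalg.solve(G, B.T).T  # (n, p*n)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular VAR({p}) normal equations: {e}") from e
    A = A_flat.reshape(n, p, n).transpose(1, 0, 2)
    sigma = R[0].copy()
    for k in range(p):
        sigma -= A[k] @ R[k + 1].T
    return A, (sigma + sigma.T) / 2.0


def select_order_aic(R: list[np.ndarray], n_total: int, p_max: int
                     ) -> tuple[int, np.ndarray]:
    """AIC(p) = ln det Sigma_p + 2 p n^2 / T over p = 1..p_max."""
    n = R[0].shape[0]
    aic = np.full(p_max, np.inf)
    for p in range(1, p_max + 1):
        try:
            _, sigma = var_fit(R, p)
        except ValueError:
            continue
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        aic[p - 1] = logdet + 2.0 * p * n * n / n_total
    if not np.isfinite(aic).any():
        raise ValueError("no VAR order produced a positive-definite fit")
    return int(np.argmin(aic)) + 1, aic


def gc_pooled(epochs: np.ndarray, p_max: int = 20,
              order: int | None = None) -> tuple[np.ndarray, int]:
    """Pairwise-conditional time-domain Granger causality, pooled fit.

    One VAR is fitted to all segments jointly (treated as separate
    realisations); the order minimises AIC over 1..p_max unless given.
    GC(i -> j) = ln( var_j(model without channel i) / var_j(full model) ),
    clamped at 0: the log-ratio of channel j's innovation variance when
    channel i's past is withheld from the conditioning set.

    Returns (matrix with entry [i, j] = GC(i -> j), selected order).
    """
    n_ch = epochs.shape[0]
    if n_ch < 2:
        raise ValueError("Granger causality needs at least 2 channels")
    R, n_total = lagged_covariances(epochs, p_max)
    if order is None:
        order, _ = select_order_aic(R, n_total, p_max)
    _, sigma_full = var_fit(R, order)
    if np.any(np.diag(sigma_full) <= 0):
        raise ValueError("non-positive innovation variance in full VAR fit")
    m = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        keep = [c for c in range(n_ch) if c != i]
        R_sub = [r[np.ix_(keep, keep)] for r in R]
        _, sigma_red = var_fit(R_sub, order)
        for jj, j in enumerate(keep):
            m[i, j] = max(0.0, float(np.log(sigma_red[jj, jj]
                                            / sigma_full[j, j])))
    return m, order


# ---------------------------------------------------------------------------
# short-time direct directed transfer function

def sddtf(data: np.ndarray, fs: float, order: int = 30,
          band: tuple[float, float] = (30.0, 80.0),
          n_freqs: int = 257) -> np.ndarray:
    """Direct directed transfer function of one segment, averaged over a band.

    A VAR(``order``) is fitted to the segment; from its spectral transfer
    matrix H(f) the full-frequency-normalised DTF is weighted by the partial
    coherence (suppressing cascade-mediated, indirect influence) and averaged
    over ``band``. Entry (i, j) is the influence of channel i on channel j,
    in [0, 1].
    """
    if data.ndim != 2:
        raise ValueError("data must be (n_channels, n_samples)")
    R, _ = lagged_covariances(data[:, None, :], order)
    A, sigma = var_fit(R, order)
    n_ch = data.shape[0]
    freqs = np.linspace(0.0, fs / 2.0, n_freqs)
    # A(f) = I - sum_k A_k e^{-2 pi i f k / fs}, stacked over frequencies
    ks = np.arange(1, order + 1)
    E = np.exp(-2j * np.pi * freqs[:, None] * ks[None, :] / fs)  # (nf, p)
    Af = np.eye(n_ch)[None] - np.einsum("fk,kij->fij", E, A)
    try:
        H = np.linalg.inv(Af)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular spectral matrix: {e}") from e
    S = H @ sigma[None] @ H.conj().transpose(0, 2, 1)
    # partial coherence from the inverse spectral matrix, with a small
    # relative ridge so a rank-deficient montage (e.g. common average, whose
    # channels sum to zero) does not abort the fit
    ridge = 1e-10 * float(np.abs(np.einsum("fii->", S).real) / (n_freqs * n_ch))
    try:
        P = np.linalg.inv(S + ridge * np.eye(n_ch)[None])
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular spectral matrix in band: {e}") from e
    pd = np.abs(np.einsum("fii->fi", P))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.abs(P) / np.sqrt(pd[:, :, None] * pd[:, None, :])
    C[~np.isfinite(C)] = 0.0
    # full-frequency normalisation per sink row
    den = np.sqrt(np.sum(np.abs(H) ** 2, axis=(0, 2)))  # (n_ch,) per sink
    eta = np.abs(H) / den[None, :, None]
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError(f"band {band} contains no evaluated frequency")
    ddtf = (eta * C)[in_band].mean(axis=0)  # (sink, source)
    m = ddtf.T.copy()  # entry (i, j): influence of i on j
    np.fill_diagonal(m, 0.0)
    return np.clip(m, 0.0, 1.0)


# ---------------------------------------------------------------------------

def node_strength(matrix: np.ndarray, directed: bool) -> np.ndarray:
    """Per-channel strength: mean of a channel's off-diagonal connections.

    Directed matrices reduce to the out-strength (mean over the row, the
    channel's average outgoing influence); undirected symmetric matrices
    reduce to the mean connection weight. Mean rather than sum keeps
    situations with different channel counts comparable.
    """
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("strength needs at least 2 channels")
    off = matrix.copy()
    np.fill_diagonal(off, 0.0)
    return off.sum(axis=1) / (n - 1)
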