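"""Univariate biomarkers: autoregressive residual modulation and
phase-amplitude coupling.

Both are computed per derived channel per 5 s segment and averaged across
segments downstream. Both are invariant to a global rescaling of the input:
ARRm is a ratio of residual spreads, PAC normalises the coupling vector by
the mean amplitude.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert

from .preprocess import bandpass_fir, design_fir


def ar_residual_sds(x: np.ndarray, window: int = 40, overlap: float = 0.5,
                    order: int = 2) -> np.ndarray:
    """Residual SD of a least-squares AR fit in each sliding window.

    Windows of ``window`` samples advance by ``window * (1 - overlap)``; in
    each, x_t is regressed on its ``order`` previous samples and the RMS
    residual is returned. Harmonic content is captured by the low-order AR
    polynomial, so the residual spread tracks the non-harmonic (spiky,
    HFO-like) part of the signal.
    """
    step = max(1, int(round(window * (1.0 - overlap))))
    n_win = (x.size - window) // step + 1
    if n_win < 1:
        raise ValueError("signal shorter than one window")
    idx = np.arange(window)[None, :] + step * np.arange(n_win)[:, None]
    w = x[idx]  # (n_win, window)
    y = w[:, order:]
    # lagged design per window: X[..., k] = x_{t-k-1}
    X = np.stack([w[:, order - k - 1: window - k - 1]
                  for k in range(order)], axis=-1)
    # solve per-window normal equations (order x order, vectorised)
    G = np.einsum("wti,wtj->wij", X, X)
    b = np.einsum("wti,wt->wi", X, y)
    coef = np.linalg.solve(G, b[..., None])[..., 0]
    resid = y - np.einsum("wti,wi->wt", X, coef)
    return resid.std(axis=1)


def arrm(x: np.ndarray, window: int = 40, overlap: float = 0.5,
         order: int = 2) -> float:
    """Auto-regressive residual modulation of one channel-segment.

    The robust modulation coefficient of the windowed residual SDs:
    median(|s - median(s)|) / median(s). Stationary signals give a small,
    stable value; intermittent sharp transients inflate a minority of window
    residuals and hence the coefficient.
    """
    try:
        s = ar_residual_sds(x, window=window, overlap=overlap, order=order)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"degenerate signal: singular AR fit "
                         f"(median residual SD is zero): {e}") from e
    med = np.median(s)
    if med <= 0:
        raise ValueError("degenerate signal: median residual SD is zero")
    return float(np.median(np.abs(s - med)) / med)


def mean_vector_length(phase: np.ndarray, amplitude: np.ndarray) -> float:
    """Amplitude-normalised mean vector length |mean(a e^{i phi})| / mean(a).

    Equals 0 when the amplitude is independent of phase (the coupling
    vectors cancel over full phase cycles) and 1 when all amplitude is
    concentrated at a single phase; lies in [0, 1] by the triangle
    inequality.
    """
    ma = amplitude.mean()
    if ma <= 0:
        raise ValueError("degenerate amplitude: mean is zero")
    return float(np.abs(np.mean(amplitude * np.exp(1j * phase))) / ma)


def pac(x: np.ndarray, fs: float,
        phase_band: tuple[float, float] = (3.0, 4.0),
        amp_band: tuple[float, float] = (80.0, 500.0),
        phase_taps: np.ndarray | None = None,
        amp_taps: np.ndarray | None = None) -> float:
    """Phase-amplitude coupling of one channel-segment.

    Phase comes from the analytic signal of the ``phase_band``-filtered
    segment, amplitude from the ``amp_band``-filtered one; the statistic is
    the amplitude-normalised mean vector length. One filter length of the
    slower (phase) filter is trimmed from each edge before averaging to keep
    filter edge transients out of the estimate.
    """
    if phase_taps is None:
        phase_taps = design_fir(phase_band, fs)
    if amp_taps is None:
        amp_taps = design_fir(amp_band, fs)
    lo = bandpass_fir(x, phase_band, fs, taps=phase_taps)
    hi = bandpass_fir(x, amp_band, fs, taps=amp_taps)
    phase = np.angle(hilbert(lo))
    amplitude = np.abs(hilbert(hi))
    trim = phase_taps.size
    if x.size <= 2 * trim:
        raise ValueError(
            f"segment of {x.size} samples too short to trim {trim}-tap "
            "filter edges"
        )
    return mean_vector_length(phase[trim:-trim], amplitude[trim:-trim])
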