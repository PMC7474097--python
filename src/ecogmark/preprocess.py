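"""Montage construction, segmentation, normalization and FIR filtering.

The processing chain per situation is: drop bad channels -> derive a bipolar
(or common-average) montage -> cut the selected minute into 5 s segments ->
per channel-segment linear detrend, demean, z-score. Band-pass filtering
happens inside each biomarker, on the normalized segments, with a zero-phase
windowed-sinc FIR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import SituationRecording

logger = logging.getLogger(__name__)


@dataclass
class DerivedChannel:
    """A montage-derived channel (bipolar pair or common-average electrode).

    ``resected`` follows the three-case rule for bipolar pairs: both parents
    resected -> ``resected``; neither -> ``not_resected``; exactly one ->
    ``cut`` (the pair straddles the resection border and is excluded from
    analysis pools). If either parent label is unknown the pair is unknown.
    A derived channel is mesiotemporal only if all parents are.
    """

    name: str
    parents: tuple[str, ...]
    orientation: str  # "horizontal" | "vertical" | "strip" | "common_average"
    resected: str
    mesiotemporal: bool


@dataclass
class DerivedRecording:
    patient_id: str
    situation_id: str
    phase: str
    fs: float
    data: np.ndarray  # (n_derived, n_samples)
    channels: list[DerivedChannel]


@dataclass
class EpochSet:
    """Normalized 5 s segments of one derived recording.

    ``data`` has shape (n_channels, n_epochs, n_samples); every channel-epoch
    has mean ~0 and SD ~1. Channels with a zero-variance epoch are dropped for
    the whole situation (and listed in ``dropped``).
    """

    patient_id: str
    situation_id: str
    phase: str
    fs: float
    data: np.ndarray
    channels: list[DerivedChannel]
    epoch_seconds: float = 5.0
    dropped: list[str] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]


def combine_resected(a: str, b: str) -> str:
    """Three-case resection label rule for a bipolar pair (plus unknowns)."""
    if "unknown" in (a, b):
        return "unknown"
    if a == "resected" and b == "resected":
        return "resected"
    if a == "not_resected" and b == "not_resected":
        return "not_resected"
    return "cut"


def make_bipolar(rec: SituationRecording) -> DerivedRecording:
    """Bipolar montage along grid rows and columns, and along strips.

    Grids are differenced both horizontally and vertically so that sources of
    either orientation under the array are represented; an electrode may
    therefore appear in several derived pairs. Bad channels are removed
    first; an electrode with no good neighbour simply yields no pair.
    """
    rec = rec.good_channels()
    by_pos = {(c.array_id, c.row, c.col): i for i, c in enumerate(rec.channels)}
    rows, names, meta = [], [], []

    def add_pair(i: int, j: int, orientation: str) -> None:
        a, b = rec.channels[i], rec.channels[j]
        rows.append(rec.data[i] - rec.data[j])
        names.append(f"{a.name}-{b.name}")
        meta.append(DerivedChannel(
            name=f"{a.name}-{b.name}", parents=(a.name, b.name),
            orientation=orientation,
            resected=combine_resected(a.resected, b.resected),
            mesiotemporal=a.mesiotemporal and b.mesiotemporal,
        ))

    for i, c in enumerate(rec.channels):
        if c.kind == "grid":
            right = by_pos.get((c.array_id, c.row, c.col + 1))
            below = by_pos.get((c.array_id, c.row + 1, c.col))
            if right is not None:
                add_pair(i, right, "horizontal")
            if below is not None:
                add_pair(i, below, "vertical")
        else:  # strip: consecutive positions
            nxt = by_pos.get((c.array_id, c.row, c.col + 1))
            if nxt is not None:
                add_pair(i, nxt, "strip")
    if not rows:
        raise ValueError(
            f"situation {rec.patient_id}/{rec.situation_id}: no adjacent good "
            "electrode pairs available for a bipolar montage"
        )
    return DerivedRecording(rec.patient_id, rec.situation_id, rec.phase,
                            rec.fs, np.asarray(rows), meta)


def make_common_average(rec: SituationRecording) -> DerivedRecording:
    """Common-average montage: each good channel minus the mean of all good
    channels. Labels pass through one-to-one ("cut" never occurs)."""
    rec = rec.good_channels()
    if len(rec.channels) < 2:
        raise ValueError(
            f"situation {rec.patient_id}/{rec.situation_id}: common average "
            "needs at least 2 good channels"
        )
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    meta = [
        DerivedChannel(name=f"{c.name}-avg", parents=(c.name,),
                       orientation="common_average", resected=c.resected,
                       mesiotemporal=c.mesiotemporal)
        for c in rec.channels
    ]
    return DerivedRecording(rec.patient_id, rec.situation_id, rec.phase,
                            rec.fs, data, meta)


def select_minute(rec: SituationRecording,
                  artefacts: list[tuple[float, float]] = (),
                  seconds: float = 60.0) -> SituationRecording:
    """Last contiguous artefact-free window of ``seconds`` in the recording.

    Searching from the end of the recording backwards keeps the analysed
    minute as far as possible from anaesthetic-induction effects. Annotated
    artefact spans (start, end in seconds) are excluded; if no clean window
    remains the situation is rejected.
    """
    n = rec.data.shape[1]
    need = int(round(seconds * rec.fs))
    bad = np.zeros(n, dtype=bool)
    for t0, t1 in artefacts:
        bad[max(0, int(np.floor(t0 * rec.fs))):
            min(n, int(np.ceil(t1 * rec.fs)))] = True
    end = n
    while end >= need:
        # last bad sample in the candidate window, if any
        window_bad = np.flatnonzero(bad[end - need:end])
        if window_bad.size == 0:
            sel = rec.data[:, end - need:end]
            return SituationRecording(rec.patient_id, rec.situation_id,
                                      rec.phase, rec.fs, sel, rec.channels)
        end = end - need + window_bad[0]  # jump past the artefact
    raise ValueError(
        f"situation {rec.patient_id}/{rec.situation_id}: no artefact-free "
        f"{seconds:g} s window available"
    )


def segment_and_normalize(rec: DerivedRecording, epoch_seconds: float = 5.0,
                          first_difference: bool = False) -> EpochSet:
    """Cut into epochs; per channel-epoch: detrend (least-squares linear),
    demean, z-score. With ``first_difference`` the detrended epoch is
    differenced (x_t - x_{t-1}) before the z-score, as the Granger-causality
    chain requires; epoch length then shrinks by one sample.

    Channels with any zero-variance epoch are dropped for this situation.
    """
    n_samp = int(round(epoch_seconds * rec.fs))
    n_ep = rec.data.shape[1] // n_samp
    if n_ep < 1:
        raise ValueError("recording shorter than one epoch")
    x = rec.data[:, : n_ep * n_samp].reshape(len(rec.channels), n_ep, n_samp)
    x = sps.detrend(x, axis=-1, type="linear")
    if first_difference:
        x = np.diff(x, axis=-1)
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    # relative floor: detrending a constant leaves only rounding residue
    floor = 1e-10 * np.abs(rec.data).max(initial=0.0)
    flat = (sd <= floor).any(axis=(1, 2))
    dropped = [c.name for c, f in zip(rec.channels, flat) if f]
    if dropped:
        logger.info("situation %s/%s: dropping zero-variance channels %s",
                    rec.patient_id, rec.situation_id, dropped)
    keep = ~flat
    x = x[keep] / sd[keep]
    channels = [c for c, k in zip(rec.channels, keep) if k]
    return EpochSet(rec.patient_id, rec.situation_id, rec.phase, rec.fs,
                    x, channels, epoch_seconds, dropped)


def design_fir(band: tuple[float, float], fs: float) -> np.ndarray:
    """Hamming windowed-sinc band-pass taps; order = 3 fs / low-cutoff.

    The order scales with the low cutoff so every band gets ~3 cycles of its
    slowest component; zero-phase application squares the stop-band
    attenuation.
    """
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band {band} outside (0, fs/2) = (0, {fs / 2})")
    ntaps = int(round(3 * fs / low)) | 1  # odd length, linear phase type I
    return sps.firwin(ntaps, [low, high], pass_zero=False, fs=fs,
                      window="hamming")


def bandpass_fir(x: np.ndarray, band: tuple[float, float], fs: float,
                 taps: np.ndarray | None = None) -> np.ndarray:
    """Zero-phase FIR band-pass along the last axis.

    Forward-backward application of a linear-phase FIR, implemented as one
    FFT convolution with the filter's autocorrelation; edges are odd-reflected
    by one filter length before convolving, as filtfilt does.
    """
    h = design_fir(band, fs) if taps is None else taps
    ntaps = h.size
    n = x.shape[-1]
    if n <= ntaps:
        raise ValueError(f"signal length {n} too short for {ntaps}-tap filter")
    # h is symmetric, so forward-backward == convolution with correlate(h, h)
    hh = np.convolve(h, h)
    pad_l = 2 * x[..., :1] - x[..., ntaps:0:-1]
    pad_r = 2 * x[..., -1:] - x[..., -2:-ntaps - 2:-1]
    ext = np.concatenate([pad_l, x, pad_r], axis=-1)
    y = sps.fftconvolve(ext, hh[(np.newaxis,) * (x.ndim - 1)], mode="same",
                        axes=-1)
    return y[..., ntaps:ntaps + n]


def first_difference(x: np.ndarray) -> np.ndarray:
    """First-order difference along the last axis, then z-score."""
    d = np.diff(x, axis=-1)
    d = d - d.mean(axis=-1, keepdims=True)
    sd = d.std(axis=-1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return d / sd
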