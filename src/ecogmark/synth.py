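"""Synthetic intra-operative ECoG cohort generator.

Each situation's background is, per channel, 1/f^2-weighted noise plus a
10 Hz rhythm at SNR 1 — a minimal caricature of the anaesthetised ECoG
spectrum (correct spectral slope and a dominant alpha-range rhythm), not a
biophysical model. Designated epileptogenic electrodes in pre-resection
situations additionally carry up to three signatures with tunable strength:

* theta-phase-modulated high-gamma noise (raises phase-amplitude coupling),
* Poisson trains of brief biphasic sharp transients (raises the
  autoregressive residual modulation), and
* lagged linear mixing from a driver electrode into its neighbours (raises
  the directed-coupling measures).

Randomness is keyed per (seed, patient, situation, electrode, component)
through ``numpy.random.SeedSequence`` so cohorts are bit-reproducible and a
change to one effect knob rescales only its own component: sweeps over a knob
are common-random-number comparisons. Spike times are thinned from a fixed
base-rate process, so the event set at a lower rate is a subset of the event
set at a higher rate.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .config import BANDS, CohortConfig, EffectConfig
from .io import (ChannelMeta, PatientMeta, SituationRecording,
                 write_participants, write_situation)
from .preprocess import bandpass_fir

# component codes for RNG stream derivation
_BG, _PAC, _SPK, _CPL = 0, 1, 2, 3


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                     exponent: float = 2.0) -> np.ndarray:
    """Gaussian noise with a ~1/f^exponent power spectrum, unit SD.

    The amplitude envelope is flattened below 1 Hz to keep the variance
    finite; the slope matters for the biomarkers, the infra-slow end does not.
    """
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f = np.maximum(f, 1.0)
    spectrum *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum, n=n)
    return x / x.std()


def background(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """1/f^2 noise plus a 10 Hz rhythm at equal power (SNR 1)."""
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    rhythm = np.sqrt(2.0) * np.sin(2 * np.pi * 10.0 * t + phase)
    return one_over_f_noise(rng, n, fs) + rhythm


def inject_pac(sig: np.ndarray, fs: float, depth: float,
               rng: np.random.Generator,
               phase_band: tuple[float, float] = BANDS["theta"],
               amp_band: tuple[float, float] = BANDS["high_gamma"],
               theta_amp: float = 1.0, gamma_sd: float = 1.0) -> np.ndarray:
    """Add theta-phase-modulated gamma-band noise to ``sig``.

    A theta oscillation (centre of ``phase_band``) is added as the phase
    carrier, and gamma-band noise is added with instantaneous amplitude
    scaled by (1 + depth*cos(phi_theta)) / 2. ``depth`` = 0 returns the
    signal untouched; amplitudes are in units of the background SD.
    """
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must be in [0, 1]")
    for band in (phase_band, amp_band):
        if not 0 < band[0] < band[1] < fs / 2:
            raise ValueError(f"band {band} outside (0, fs/2)")
    if depth == 0.0:
        return sig
    n = sig.size
    t = np.arange(n) / fs
    f0 = 0.5 * (phase_band[0] + phase_band[1])
    phi0 = rng.uniform(0, 2 * np.pi)
    phi = 2 * np.pi * f0 * t + phi0
    gamma = bandpass_fir(rng.standard_normal(n), amp_band, fs)
    gamma *= gamma_sd / gamma.std()
    envelope = (1.0 + depth * np.cos(phi)) / 2.0
    return sig + theta_amp * np.cos(phi) + gamma * envelope


def spike_template(fs: float, sigma_s: float = 0.007) -> np.ndarray:
    """Biphasic sharp transient: first derivative of a Gaussian, peak 1.

    With the default width the transient lasts ~40-50 ms, in the range of an
    inter-ictal epileptiform discharge.
    """
    half = int(round(3 * sigma_s * fs))
    t = np.arange(-half, half + 1) / fs
    w = -t * np.exp(-t**2 / (2 * sigma_s**2))
    return w / np.abs(w).max()


def inject_spikes(sig: np.ndarray, fs: float, rate: float, amplitude: float,
                  rng: np.random.Generator, base_rate: float = 2.0,
                  sd: float | None = None) -> np.ndarray:
    """Superimpose Poisson-timed biphasic transients.

    Events are drawn once at ``base_rate`` and thinned to ``rate`` with
    common uniforms, so raising the rate only adds events. ``amplitude`` is
    the peak in multiples of the background SD (``sd``; defaults to the SD of
    ``sig``). ``rate`` = 0 returns the signal untouched.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate > base_rate:
        raise ValueError(f"rate {rate} exceeds base rate {base_rate}")
    n = sig.size
    duration = n / fs
    n_events = rng.poisson(base_rate * duration)
    times = rng.uniform(0, duration, size=n_events)
    marks = rng.uniform(0, 1, size=n_events)
    if rate == 0 or amplitude == 0:
        return sig
    keep = times[marks < rate / base_rate]
    sd = float(np.std(sig)) if sd is None else sd
    tpl = spike_template(fs) * amplitude * sd
    half = tpl.size // 2
    out = sig.copy()
    for t0 in keep:
        c = int(round(t0 * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        out[lo:hi] += tpl[lo - (c - half): tpl.size - ((c + half + 1) - hi)]
    return out


def inject_coupling(signals: np.ndarray, source: int, targets: list[int],
                    gain: float, lag: int) -> np.ndarray:
    """Mix the lagged source channel into each target channel in place:
    target_t += gain * source_{t-lag}."""
    if lag < 1:
        raise ValueError("lag must be >= 1 sample")
    if lag >= signals.shape[1]:
        raise ValueError("lag must be shorter than the signal")
    if gain == 0 or not targets:
        return signals
    shifted = np.zeros(signals.shape[1])
    shifted[lag:] = signals[source, :-lag]
    for j in targets:
        signals[j] += gain * shifted
    return signals


# ---------------------------------------------------------------------------
# cohort assembly


def _electrode_layout(cfg: CohortConfig, temporal: bool) -> list[ChannelMeta]:
    """Grid + strip electrode table for one arrangement. For temporal
    patients the first three strip contacts are the mesiotemporal ones."""
    chans: list[ChannelMeta] = []
    rows, cols = cfg.grid_shape
    for r in range(rows):
        for c in range(cols):
            chans.append(ChannelMeta(name=f"G{r * cols + c + 1:02d}",
                                     array_id="grid", kind="grid",
                                     row=r, col=c))
    for s, length in enumerate(cfg.strip_lengths, start=1):
        for c in range(length):
            chans.append(ChannelMeta(
                name=f"S{s}{c + 1:02d}", array_id=f"strip{s}", kind="strip",
                row=0, col=c,
                mesiotemporal=temporal and c < 3,
            ))
    return chans


def _ez_electrodes(cfg: CohortConfig, chans: list[ChannelMeta],
                   temporal: bool) -> list[str]:
    """Contiguous epileptogenic block: row-major leading grid cells, or the
    leading strip contacts when the cohort places the EZ mesiotemporally
    (temporal patients only)."""
    k = cfg.effect.n_epileptogenic_channels
    if cfg.ez_location == "mesiotemporal" and temporal:
        pool = [c.name for c in chans if c.kind == "strip"]
    else:
        pool = [c.name for c in chans if c.kind == "grid"]
    if k + cfg.n_extra_resected > len(pool):
        raise ValueError("epileptogenic block plus margin larger than array")
    return pool[:k]


def _resected_electrodes(cfg: CohortConfig, chans: list[ChannelMeta],
                         ez: list[str]) -> list[str]:
    """EZ block plus a margin of adjacent electrodes (the resection is
    usually larger than the EZ); margin pairs straddle the border -> "cut"."""
    pool = [c.name for c in chans if c.kind == ("strip" if ez[0].startswith("S")
                                                else "grid")]
    i = pool.index(ez[-1])
    return ez + pool[i + 1: i + 1 + cfg.n_extra_resected]


def _assign_patients(cfg: CohortConfig) -> list[PatientMeta]:
    """Deterministic type and outcome assignment.

    Extra-temporal patients come first (ids E..), then temporal, matching the
    emulated cohort's presentation. Cured patients are spread evenly within
    each type group so every subgroup retains a cured reference whenever the
    cured count allows.
    """
    n = cfg.n_patients
    n_t = int(round(cfg.frac_temporal * n))
    n_e = n - n_t
    types = ["E"] * n_e + ["T"] * n_t
    n_cured = int(round(cfg.frac_cured * n))
    cured_idx: set[int] = set()
    # proportional split, at least one per non-empty group when possible
    for lo, hi in ((0, n_e), (n_e, n)):
        size = hi - lo
        if size == 0:
            continue
        share = int(round(n_cured * size / n))
        if n_cured >= 2:
            share = max(share, 1)
        share = min(share, size)
        for j in range(share):
            cured_idx.add(lo + (j * size) // max(share, 1))
    # adjust to the exact total
    extras = [i for i in range(n) if i not in cured_idx]
    while len(cured_idx) < n_cured and extras:
        cured_idx.add(extras.pop(0))
    while len(cured_idx) > n_cured:
        cured_idx.discard(max(cured_idx))
    return [
        PatientMeta(patient_id=f"{i + 1:04d}", epilepsy_type=types[i],
                    outcome="cured" if i in cured_idx else "improved")
        for i in range(n)
    ]


def _situation_signals(cfg: CohortConfig, p_idx: int, s_idx: int,
                       chans: list[ChannelMeta], ez: list[str],
                       effect_scale: float) -> tuple[np.ndarray, list[str]]:
    """Signals for one situation; returns (data, injected channel names).

    ``effect_scale`` multiplies every signature (1 for pre-resection
    epileptogenic tissue, 0 for clean tissue, a residual fraction for
    improved patients' post recordings when enabled).
    """
    eff = cfg.effect
    n = cfg.n_samples
    data = np.empty((len(chans), n))
    injected: list[str] = []
    name_to_idx = {c.name: i for i, c in enumerate(chans)}
    for i, ch in enumerate(chans):
        data[i] = background(_rng(cfg.seed, _BG, p_idx, s_idx, i), n, cfg.fs)
    if effect_scale > 0 and not eff.is_null:
        bg_sd = np.sqrt(2.0)  # background model SD by construction
        for name in ez:
            i = name_to_idx[name]
            injected.append(name)
            if eff.pac_depth > 0:
                data[i] = inject_pac(
                    data[i], cfg.fs, eff.pac_depth,
                    _rng(cfg.seed, _PAC, p_idx, s_idx, i),
                    theta_amp=effect_scale * bg_sd,
                    gamma_sd=effect_scale * bg_sd,
                )
            if eff.spike_rate > 0 and eff.spike_amplitude > 0:
                data[i] = inject_spikes(
                    data[i], cfg.fs, eff.spike_rate,
                    effect_scale * eff.spike_amplitude,
                    _rng(cfg.seed, _SPK, p_idx, s_idx, i),
                    base_rate=eff.spike_base_rate, sd=bg_sd,
                )
        if eff.coupling_gain > 0 and len(ez) > 1:
            src = name_to_idx[ez[0]]
            tgt = [name_to_idx[e] for e in ez[1:]]
            inject_coupling(data, src, tgt,
                            effect_scale * eff.coupling_gain,
                            eff.coupling_lag)
    return data, injected


def generate_cohort(cfg: CohortConfig, path: str | Path) -> dict:
    """Write a full synthetic cohort under ``path``; returns the ground truth.

    Layout and metadata follow :mod:`ecogmark.io`. The ground truth (also
    written to ``ground_truth.json``) records, per patient, the epileptogenic
    electrodes and resected set, and per situation its phase and the channels
    that actually received a signature — post-resection situations of cured
    patients never do.
    """
    cfg.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    patients = _assign_patients(cfg)
    gt: dict = {"seed": cfg.seed, "patients": {}, "situations": {}}
    for p_idx, pm in enumerate(patients):
        temporal = pm.epilepsy_type == "T"
        chans = _electrode_layout(cfg, temporal)
        ez = _ez_electrodes(cfg, chans, temporal)
        resected = _resected_electrodes(cfg, chans, ez)
        gt["patients"][pm.patient_id] = {
            "epileptogenic": ez, "resected": resected,
            "epilepsy_type": pm.epilepsy_type, "outcome": pm.outcome,
        }
        n_situ = cfg.n_pre_situations + cfg.n_post_situations
        for s_idx in range(n_situ):
            pre = s_idx < cfg.n_pre_situations
            phase = "pre" if pre else "post"
            sid = f"{phase}{(s_idx if pre else s_idx - cfg.n_pre_situations) + 1:02d}"
            if pre:
                situ_chans = [dataclasses.replace(
                    c, resected=("resected" if c.name in resected
                                 else "not_resected")) for c in chans]
                scale = 1.0
            else:
                situ_chans = [dataclasses.replace(c, resected="not_resected")
                              for c in chans]
                scale = (cfg.improved_residual
                         if pm.outcome == "improved" else 0.0)
            data, injected = _situation_signals(cfg, p_idx, s_idx, situ_chans,
                                                ez, scale)
            rec = SituationRecording(pm.patient_id, sid, phase, cfg.fs,
                                     data, situ_chans)
            write_situation(path, rec)
            gt["situations"][f"{pm.patient_id}/{sid}"] = {
                "phase": phase, "injected": injected,
            }
    write_participants(path, patients)
    (path / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    provenance = {"config": dataclasses.asdict(cfg), "seed": cfg.seed}
    provenance["config"]["grid_shape"] = list(cfg.grid_shape)
    provenance["config"]["strip_lengths"] = list(cfg.strip_lengths)
    (path / "cohort.json").write_text(json.dumps(provenance, indent=1))
    return gt
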