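"""Configuration objects for the simulator and the analysis pipeline.

All configs are plain dataclasses that round-trip losslessly through YAML so
that every run can be reproduced from its config file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Named frequency bands (Hz). ``theta`` modulates, ``high_gamma`` is the
#: modulated amplitude band for PAC; ``gamma`` is used by the phase-based and
#: spectral connectivity measures.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (3.0, 4.0),
    "gamma": (30.0, 80.0),
    "high_gamma": (80.0, 500.0),
}

#: Registry of the seven biomarkers, in reporting order.
BIOMARKERS: tuple[str, ...] = ("ARR", "PAC", "PLV", "PLI", "H2", "GC", "sdDTF")


@dataclass
class EffectConfig:
    """Strength of the epileptogenic signatures planted in a synthetic cohort.

    All-zero knobs produce a null cohort: pre- and post-resection recordings
    are then drawn from the identical background model, so any downstream
    pre/post difference is a false positive by construction.

    Parameters
    ----------
    pac_depth : float in [0, 1]
        Modulation depth of the high-gamma envelope by theta phase.
    spike_rate : float
        Inter-ictal sharp-transient rate, events/s. Must not exceed
        ``spike_base_rate`` (events are thinned from a fixed base process so
        that event sets are nested across rates).
    spike_amplitude : float
        Transient peak amplitude, in multiples of the background SD.
    coupling_gain : float
        Lagged linear mixing coefficient from the driver channel into the
        other epileptogenic channels.
    coupling_lag : int
        Mixing lag in samples (>= 1).
    n_epileptogenic_channels : int
        Number of contiguous electrodes carrying the signature per patient.
    """

    pac_depth: float = 0.8
    spike_rate: float = 1.0
    spike_amplitude: float = 8.0
    coupling_gain: float = 0.8
    coupling_lag: int = 10
    n_epileptogenic_channels: int = 4
    spike_base_rate: float = 2.0

    def validate(self) -> None:
        if not 0.0 <= self.pac_depth <= 1.0:
            raise ValueError("pac_depth must be in [0, 1]")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")
        if self.spike_rate > self.spike_base_rate:
            raise ValueError("spike_rate must not exceed spike_base_rate")
        if self.spike_amplitude < 0:
            raise ValueError("spike_amplitude must be >= 0")
        if self.coupling_gain < 0:
            raise ValueError("coupling_gain must be >= 0")
        if self.coupling_lag < 1:
            raise ValueError("coupling_lag must be >= 1 sample")
        if self.n_epileptogenic_channels < 1:
            raise ValueError("n_epileptogenic_channels must be >= 1")

    @property
    def is_null(self) -> bool:
        return (
            self.pac_depth == 0
            and self.spike_rate == 0
            and self.spike_amplitude == 0
            and self.coupling_gain == 0
        )

    @classmethod
    def null(cls, **kw) -> "EffectConfig":
        """An all-zero (no-signature) effect configuration."""
        return cls(pac_depth=0.0, spike_rate=0.0, spike_amplitude=0.0,
                   coupling_gain=0.0, **kw)


@dataclass
class CohortConfig:
    """Layout and clinical metadata of a simulated intra-operative cohort.

    Defaults mirror the clinical recording setup being emulated: 2048 Hz
    sampling, one-minute artefact-free situations, 4x5 subdural grids plus a
    1x6 strip, and a 47-patient cohort with ~30/47 temporal resections and
    ~13/47 cured (seizure-free off medication) outcomes.
    """

    n_patients: int = 47
    frac_temporal: float = 30 / 47
    frac_cured: float = 13 / 47
    fs: float = 2048.0
    duration: float = 60.0
    grid_shape: tuple[int, int] = (4, 5)
    strip_lengths: tuple[int, ...] = (6,)
    n_pre_situations: int = 2
    n_post_situations: int = 2
    effect: EffectConfig = field(default_factory=EffectConfig)
    seed: int = 0
    #: where the epileptogenic block sits: on the grid or on the first strip
    #: electrodes (the mesiotemporal contacts of temporal patients).
    ez_location: str = "grid"
    #: electrodes resected beyond the epileptogenic block (creates bipolar
    #: pairs straddling the resection border, i.e. "cut" channels).
    n_extra_resected: int = 1
    #: residual signature scale in post-resection recordings of improved
    #: (not cured) patients; 0 disables (cured post tissue is always clean).
    improved_residual: float = 0.0

    def validate(self) -> None:
        self.effect.validate()
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (0.0 <= self.frac_temporal <= 1.0 and 0.0 <= self.frac_cured <= 1.0):
            raise ValueError("fractions must be in [0, 1]")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.duration < 5.0:
            raise ValueError("duration must cover at least one 5 s segment")
        if min(self.grid_shape) < 1 or any(s < 2 for s in self.strip_lengths):
            raise ValueError("degenerate electrode array geometry")
        if self.n_pre_situations < 1 or self.n_post_situations < 1:
            raise ValueError("situation counts must be >= 1")
        if self.ez_location not in ("grid", "mesiotemporal"):
            raise ValueError("ez_location must be 'grid' or 'mesiotemporal'")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class RunConfig:
    """One analysis run: cohort in, biomarker tables and detections out."""

    cohort: str = "."
    out_dir: str = "ecogmark_out"
    montage: str = "bipolar"  # or "common_average"
    biomarkers: tuple[str, ...] = BIOMARKERS
    scopes: tuple[str, ...] = ("all", "T", "E")
    epoch_seconds: float = 5.0
    bands: dict = field(default_factory=lambda: dict(BANDS))
    pac_phase_band: str = "theta"
    pac_amp_band: str = "high_gamma"
    connectivity_band: str = "gamma"
    arrm_window: int = 40
    arrm_overlap: float = 0.5
    arrm_order: int = 2
    h2_n_bins: int = 10
    h2_delay_max: int = 68
    h2_delay_step: int = 17
    gc_p_max: int = 20
    sddtf_order: int = 30
    alpha: float = 0.01
    leave_one_out: bool = False

    def validate(self) -> None:
        if self.montage not in ("bipolar", "common_average"):
            raise ValueError(f"unknown montage {self.montage!r}")
        unknown = set(self.biomarkers) - set(BIOMARKERS)
        if unknown:
            raise ValueError(f"unknown biomarkers: {sorted(unknown)}")
        for s in self.scopes:
            if s not in ("all", "T", "E"):
                raise ValueError(f"unknown scope {s!r}")

    @property
    def h2_delays(self) -> tuple[int, ...]:
        """Symmetric delay grid in samples, e.g. -68..68 in steps of 17."""
        k = self.h2_delay_max // self.h2_delay_step
        return tuple(i * self.h2_delay_step for i in range(-k, k + 1))


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def _tupled(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name == "effect" and isinstance(v, dict):
            v = EffectConfig(**v)
        elif f.name == "grid_shape":
            v = tuple(v)
        elif f.name in ("strip_lengths", "biomarkers", "scopes"):
            v = tuple(v)
        elif f.name == "bands":
            v = {k: tuple(b) for k, b in v.items()}
        kwargs[f.name] = v
    return cls(**kwargs)


def to_yaml(config, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def cohort_config_from_yaml(path: str | Path) -> CohortConfig:
    cfg = _tupled(CohortConfig, yaml.safe_load(Path(path).read_text()))
    cfg.validate()
    return cfg


def run_config_from_yaml(path: str | Path) -> RunConfig:
    cfg = _tupled(RunConfig, yaml.safe_load(Path(path).read_text()))
    cfg.validate()
    return cfg
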