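import numpy as np
import pytest

from ecogmark import CohortConfig, EffectConfig, generate_cohort, read_cohort
from ecogmark.io import ChannelMeta, SituationRecording


def small_cohort_config(**overrides) -> CohortConfig:
    """Desk-scale cohort: 2x3 grid + 1x6 strip, 20 s situations, fs 2048.

    Effect sizes default to the strong-signature values; pass an
    ``EffectConfig`` to override.
    """
    kw = dict(
        n_patients=4, frac_temporal=0.5, frac_cured=0.5,
        duration=20.0, grid_shape=(2, 3), strip_lengths=(6,),
        n_pre_situations=1, n_post_situations=1,
        effect=EffectConfig(n_epileptogenic_channels=2), seed=11,
    )
    kw.update(overrides)
    return CohortConfig(**kw)


@pytest.fixture(scope="session")
def strong_cohort(tmp_path_factory):
    """A written strong-effect cohort plus its ground truth, shared
    session-wide (read-only)."""
    path = tmp_path_factory.mktemp("cohort_strong")
    cfg = small_cohort_config()
    gt = generate_cohort(cfg, path)
    return read_cohort(path), gt, cfg


def grid_recording(data: np.ndarray, rows: int, cols: int,
                   resected: dict[str, str] | None = None,
                   bad: set[str] = frozenset(), fs: float = 2048.0,
                   phase: str = "pre") -> SituationRecording:
    """Helper: wrap a matrix as a single-grid situation."""
    resected = resected or {}
    chans = []
    for r in range(rows):
        for c in range(cols):
            name = f"G{r * cols + c + 1:02d}"
            chans.append(ChannelMeta(
                name=name, array_id="grid", kind="grid", row=r, col=c,
                status="bad" if name in bad else "good",
                resected=resected.get(name, "unknown")))
    return SituationRecording("0001", "pre01", phase, fs, data, chans)
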