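"""Cohort directory layout: reading, writing, validation.

The on-disk layout is a BIDS-iEEG-inspired tree::

    cohort/
      participants.tsv                  # participant_id, epilepsy_type, outcome
      cohort.json                       # provenance: generator config + seed
      ground_truth.json                 # optional simulator sidecar
      sub-<id>/ses-<situation>/ieeg/
        sub-<id>_ses-<situation>_ieeg.bin       # float32, C-order, ch x samp
        sub-<id>_ses-<situation>_ieeg.json      # fs, shape, dtype, phase
        sub-<id>_ses-<situation>_channels.tsv   # electrode metadata

``channels.tsv`` extends the standard electrode table with ``resected`` and
``mesiotemporal`` columns, which have no standard BIDS equivalent. Grid
row/col indices are 0-based and enumerated row-major; strips use row=0 and
col=position. The reader validates rather than repairs: shape or metadata
mismatches raise with the offending situation named.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CHANNEL_COLUMNS = ["name", "array_id", "kind", "row", "col", "status",
                   "resected", "mesiotemporal"]


@dataclass
class ChannelMeta:
    """One monopolar electrode contact."""

    name: str
    array_id: str
    kind: str  # "grid" | "strip"
    row: int
    col: int
    status: str = "good"  # "good" | "bad"
    resected: str = "unknown"  # "resected" | "not_resected" | "unknown"
    mesiotemporal: bool = False


@dataclass
class PatientMeta:
    patient_id: str
    epilepsy_type: str  # "T" temporal | "E" extra-temporal
    outcome: str  # "cured" (Engel 1A, medication stopped) | "improved"


@dataclass
class SituationRecording:
    """One electrode arrangement's multichannel signal plus metadata."""

    patient_id: str
    situation_id: str
    phase: str  # "pre" | "post"
    fs: float
    data: np.ndarray  # (n_channels, n_samples)
    channels: list[ChannelMeta]

    def __post_init__(self):
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"situation {self.patient_id}/{self.situation_id}: "
                f"{len(self.channels)} channel rows but data has "
                f"{self.data.shape[0]} rows"
            )

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def good_channels(self) -> "SituationRecording":
        """Copy with visually-marked bad channels removed."""
        keep = [i for i, c in enumerate(self.channels) if c.status == "good"]
        return SituationRecording(
            self.patient_id, self.situation_id, self.phase, self.fs,
            self.data[keep], [self.channels[i] for i in keep],
        )


@dataclass
class Cohort:
    path: Path
    patients: dict[str, PatientMeta]
    situations: list[SituationRecording] = field(default_factory=list)

    def patient_situations(self, patient_id: str) -> list[SituationRecording]:
        return [s for s in self.situations if s.patient_id == patient_id]


def channels_to_frame(channels: list[ChannelMeta]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in channels], columns=CHANNEL_COLUMNS)


def _channels_from_frame(df: pd.DataFrame) -> list[ChannelMeta]:
    missing = set(CHANNEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"channels.tsv missing columns: {sorted(missing)}")
    out = []
    for rec in df.to_dict("records"):
        rec["row"] = int(rec["row"])
        rec["col"] = int(rec["col"])
        rec["mesiotemporal"] = str(rec["mesiotemporal"]).lower() in ("true", "1")
        if rec["resected"] in (None, "", "n/a") or pd.isna(rec["resected"]):
            rec["resected"] = "unknown"
        out.append(ChannelMeta(**{k: rec[k] for k in CHANNEL_COLUMNS}))
    return out


def write_situation(root: str | Path, rec: SituationRecording) -> Path:
    """Write one situation under ``root`` in the layout above."""
    root = Path(root)
    d = root / f"sub-{rec.patient_id}" / f"ses-{rec.situation_id}" / "ieeg"
    d.mkdir(parents=True, exist_ok=True)
    stem = f"sub-{rec.patient_id}_ses-{rec.situation_id}"
    data = np.ascontiguousarray(rec.data, dtype=np.float32)
    (d / f"{stem}_ieeg.bin").write_bytes(data.tobytes())
    sidecar = {
        "SamplingFrequency": rec.fs,
        "n_channels": data.shape[0],
        "n_samples": data.shape[1],
        "dtype": "float32",
        "order": "C",
        "phase": rec.phase,
    }
    (d / f"{stem}_ieeg.json").write_text(json.dumps(sidecar, indent=1))
    channels_to_frame(rec.channels).to_csv(d / f"{stem}_channels.tsv",
                                           sep="\t", index=False)
    return d


def write_participants(root: str | Path, patients: list[PatientMeta]) -> None:
    df = pd.DataFrame(
        [{"participant_id": f"sub-{p.patient_id}",
          "epilepsy_type": p.epilepsy_type, "outcome": p.outcome}
         for p in patients]
    )
    df.to_csv(Path(root) / "participants.tsv", sep="\t", index=False)


def read_situation(ieeg_dir: Path, patient_id: str, situation_id: str
                   ) -> SituationRecording:
    stem = f"sub-{patient_id}_ses-{situation_id}"
    sidecar = json.loads((ieeg_dir / f"{stem}_ieeg.json").read_text())
    fs = float(sidecar["SamplingFrequency"])
    n_ch, n_samp = int(sidecar["n_channels"]), int(sidecar["n_samples"])
    raw = np.frombuffer((ieeg_dir / f"{stem}_ieeg.bin").read_bytes(),
                        dtype=np.float32)
    if raw.size != n_ch * n_samp:
        raise ValueError(
            f"situation {patient_id}/{situation_id}: binary holds {raw.size} "
            f"values, sidecar declares {n_ch}x{n_samp}"
        )
    data = raw.reshape(n_ch, n_samp).astype(np.float64)
    channels = _channels_from_frame(
        pd.read_csv(ieeg_dir / f"{stem}_channels.tsv", sep="\t")
    )
    if len(channels) != n_ch:
        raise ValueError(
            f"situation {patient_id}/{situation_id}: channels.tsv has "
            f"{len(channels)} rows but the matrix has {n_ch}"
        )
    return SituationRecording(patient_id, situation_id, sidecar["phase"],
                              fs, data, channels)


def read_cohort(path: str | Path) -> Cohort:
    """Load a cohort tree; validates shapes, ids, and sampling rates."""
    path = Path(path)
    ptsv = path / "participants.tsv"
    if not ptsv.exists():
        raise FileNotFoundError(f"no participants.tsv under {path}")
    pdf = pd.read_csv(ptsv, sep="\t")
    patients: dict[str, PatientMeta] = {}
    for rec in pdf.to_dict("records"):
        pid = str(rec["participant_id"]).removeprefix("sub-")
        if pid in patients:
            raise ValueError(f"duplicate participant {pid}")
        patients[pid] = PatientMeta(pid, str(rec["epilepsy_type"]),
                                    str(rec["outcome"]))
    cohort = Cohort(path, patients)
    seen: set[tuple[str, str]] = set()
    for sub_dir in sorted(path.glob("sub-*")):
        pid = sub_dir.name.removeprefix("sub-")
        if pid not in patients:
            raise ValueError(f"situation data for unknown patient {pid}")
        for ses_dir in sorted(sub_dir.glob("ses-*")):
            sid = ses_dir.name.removeprefix("ses-")
            if (pid, sid) in seen:
                raise ValueError(f"duplicate situation {pid}/{sid}")
            seen.add((pid, sid))
            rec = read_situation(ses_dir / "ieeg", pid, sid)
            cohort.situations.append(rec)
    fss = {s.fs for s in cohort.situations}
    if len(fss) > 1:
        raise ValueError(f"inconsistent sampling rates across cohort: {fss}")
    return cohort


def read_ground_truth(path: str | Path) -> dict:
    return json.loads((Path(path) / "ground_truth.json").read_text())


def write_tables(biomarker_table: pd.DataFrame | None, out_dir: str | Path,
                 thresholds: dict | None = None,
                 detections: pd.DataFrame | None = None,
                 group_stats: dict | None = None) -> None:
    """Write pipeline outputs: per-channel TSV plus JSON summaries."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if biomarker_table is not None:
        cols = ["patient", "situation", "phase", "channel", "biomarker",
                "value", "resected", "mesiotemporal", "n_epochs"]
        df = biomarker_table.reindex(columns=cols)
        df.to_csv(out / "biomarkers.tsv", sep="\t", index=False)
    if thresholds is not None:
        (out / "thresholds.json").write_text(json.dumps(thresholds, indent=1))
    if detections is not None:
        detections.to_csv(out / "detections.tsv", sep="\t", index=False)
    if group_stats is not None:
        (out / "group_stats.json").write_text(json.dumps(group_stats, indent=1))
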