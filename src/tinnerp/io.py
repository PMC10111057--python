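"""Serialization helpers: WAV audio, flat-binary recordings, CSV events/cohorts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .eegsim import EEGRecording
from .preprocess import EpochSet
from .therapy import StimulationSchedule, TherapyProgram


def write_wav(path: str | Path, program: TherapyProgram) -> Path:
    """Write a therapy waveform as float32 WAV (mono or stereo)."""
    path = Path(path)
    wavfile.write(path, int(program.fs), program.waveform.astype(np.float32))
    return path


def schedule_to_csv(path: str | Path, schedule: StimulationSchedule,
                    fs: float | None = None) -> Path:
    """Onset table as CSV; with ``fs`` an extra sample-index column is added."""
    path = Path(path)
    lines = ["onset_s,sample,label" if fs else "onset_s,label"]
    for t in schedule.onsets:
        if fs:
            lines.append(f"{t:.6f},{int(round(t * fs))},stim")
        else:
            lines.append(f"{t:.6f},stim")
    path.write_text("\n".join(lines) + "\n")
    return path


def save_recording(prefix: str | Path, rec: EEGRecording) -> tuple[Path, Path]:
    """Flat binary (.npy, channels x samples float64 uV) + JSON sidecar."""
    prefix = Path(prefix)
    data_path = prefix.with_suffix(".npy")
    meta_path = prefix.with_suffix(".json")
    np.save(data_path, rec.data)
    meta = {"fs": rec.fs, "channels": list(rec.channels), "session": rec.session,
            "id": rec.id, "events": [[int(i), l] for i, l in rec.events]}
    meta_path.write_text(json.dumps(meta, indent=2))
    return data_path, meta_path


def load_recording(prefix: str | Path) -> EEGRecording:
    prefix = Path(prefix)
    data = np.load(prefix.with_suffix(".npy"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return EEGRecording(data=data, fs=meta["fs"], channels=tuple(meta["channels"]),
                        events=[(int(i), l) for i, l in meta["events"]],
                        session=meta["session"], id=meta["id"])


def save_epochs(prefix: str | Path, ep: EpochSet) -> tuple[Path, Path]:
    """Flat binary (trials x channels x samples) + JSON sidecar."""
    prefix = Path(prefix)
    data_path = prefix.with_suffix(".npy")
    meta_path = prefix.with_suffix(".json")
    np.save(data_path, ep.data)
    meta = {"fs": ep.fs, "channels": list(ep.channels),
            "times_ms": [float(t) for t in ep.times],
            "rejected": list(ep.rejected), "recording_id": ep.recording_id}
    meta_path.write_text(json.dumps(meta, indent=2))
    return data_path, meta_path


def load_epochs(prefix: str | Path) -> EpochSet:
    prefix = Path(prefix)
    data = np.load(prefix.with_suffix(".npy"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return EpochSet(data=data, times=np.array(meta["times_ms"]), fs=meta["fs"],
                    channels=tuple(meta["channels"]), rejected=meta["rejected"],
                    recording_id=meta["recording_id"])


def save_cohort(prefix: str | Path, cohort) -> tuple[Path, Path]:
    """Cohort as CSV (one row per participant-session) and JSON."""
    from .cohort import cohort_to_frame

    prefix = Path(prefix)
    frame = cohort_to_frame(cohort)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    frame.to_csv(csv_path, index=False)
    json_path.write_text(frame.to_json(orient="records", indent=2))
    return csv_path, json_path
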