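"""Personalized therapy-sound synthesis and stimulation schedules.

Five sound programs are synthesized from a participant record:

* **TRT** -- broadband noise band-pass filtered to the one-octave band
  centered at the tinnitus pitch (edges pitch/sqrt(2) .. pitch*sqrt(2)),
  presented below the perceived tinnitus level by a configurable dB offset.
* **ADT** -- an oddball train of tone pulses; the standard pulse is the
  tinnitus pitch, the deviant is 10% higher, and per-pulse level compensates
  the hearing loss at the pulse frequency (half-gain rule).
* **TEAE** -- a random tone sequence (bursts and pips) spanning the
  audiogram range, each tone's amplitude proportional to the interpolated
  hearing loss at its frequency, with a notch around the tinnitus pitch.
* **BBT** -- two pure tones, one per ear (stereo: column 0 = left carrier at
  the tinnitus pitch, column 1 = right carrier offset by the beat frequency);
  only eligible for pitches below 1 kHz.
* **placebo** -- procedurally generated relaxing music at 60-80 beats per
  minute, untuned to tinnitus parameters.

Digital level convention: the perceived tinnitus intensity maps to a
reference RMS of -20 dBFS, leaving headroom so that level offsets never
clip; all outputs keep |sample| <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .cohort import Participant
from .exceptions import EligibilityError, MissingDataError

__all__ = [
    "TherapyProgram",
    "StimulationSchedule",
    "synthesize_trt",
    "synthesize_adt",
    "synthesize_teae",
    "synthesize_bbt",
    "synthesize_placebo",
    "synthesize_for_group",
    "build_schedule",
    "session_stimulus",
    "REFERENCE_RMS_DBFS",
]

#: Digital RMS (dB re full scale) assigned to the perceived tinnitus level.
REFERENCE_RMS_DBFS = -20.0


@dataclass
class TherapyProgram:
    """Synthesized waveform plus the metadata needed to audit it."""

    waveform: np.ndarray          # (n,) mono or (n, 2) stereo, |x| <= 1
    fs: float
    therapy: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.waveform.size and np.max(np.abs(self.waveform)) > 1.0 + 1e-9:
            raise ValueError("therapy waveform exceeds full scale")

    @property
    def duration(self) -> float:
        return self.waveform.shape[0] / self.fs


@dataclass
class StimulationSchedule:
    """Stimulus-onset schedule for an EEG monitoring session."""

    onsets: np.ndarray            # seconds, strictly increasing
    stim_duration: float
    iti: float
    total_duration: float

    @property
    def n_stimuli(self) -> int:
        return int(self.onsets.size)


def _require_pitch(p: Participant) -> float:
    if p.tinnitus is None:
        raise MissingDataError(f"participant {p.id} has no tinnitus profile")
    return p.tinnitus.pitch


def _raised_cosine_ramps(x: np.ndarray, fs: float, ramp_s: float) -> np.ndarray:
    n_ramp = int(round(ramp_s * fs))
    if n_ramp == 0 or x.shape[0] < 2 * n_ramp:
        return x
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    if x.ndim == 2:
        ramp = ramp[:, None]
    x = x.copy()
    x[:n_ramp] *= ramp
    x[-n_ramp:] *= ramp[::-1]
    return x


def _tone(freq: float, duration: float, fs: float, ramp_s: float = 0.01) -> np.ndarray:
    t = np.arange(int(round(duration * fs))) / fs
    return _raised_cosine_ramps(np.sin(2 * np.pi * freq * t), fs, ramp_s)


# ---------------------------------------------------------------------------
# TRT
# ---------------------------------------------------------------------------

def synthesize_trt(p: Participant, duration: float, fs: float,
                   level_offset_db: float = 5.0,
                   seed: int | None = None) -> TherapyProgram:
    """Octave-band noise at the tinnitus pitch, ``level_offset_db`` below it.

    Band edges are pitch * 2^(+-1/2); the filter is a 4th-order Butterworth
    band-pass applied forward-backward (zero phase).  Output RMS equals the
    tinnitus-referenced RMS (-20 dBFS) minus the offset.
    """
    pitch = _require_pitch(p)
    lo, hi = pitch / np.sqrt(2.0), pitch * np.sqrt(2.0)
    if hi >= fs / 2:
        raise ValueError(f"octave band upper edge {hi:.0f} Hz exceeds Nyquist ({fs / 2:.0f} Hz)")
    meta = {
        "center_hz": pitch, "band_hz": (lo, hi),
        "level_offset_db": level_offset_db,
        "reference_rms_dbfs": REFERENCE_RMS_DBFS,
    }
    n = int(round(duration * fs))
    if n == 0:
        return TherapyProgram(np.zeros(0), fs, "TRT", meta)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, noise)
    target_rms = 10 ** ((REFERENCE_RMS_DBFS - level_offset_db) / 20.0)
    x *= target_rms / np.sqrt(np.mean(x ** 2))
    peak = np.max(np.abs(x))
    if peak > 1.0:  # never clip; noted in metadata
        x /= peak
        meta["renormalized"] = float(peak)
    return TherapyProgram(x, fs, "TRT", meta)


# ---------------------------------------------------------------------------
# ADT
# ---------------------------------------------------------------------------

def synthesize_adt(p: Participant, n_pulses: int = 60, p_deviant: float = 0.2,
                   duration: float | None = None, fs: float = 44100.0,
                   seed: int | None = None, deviant_factor: float = 1.10,
                   pulse_duration: float = 0.1) -> TherapyProgram:
    """Oddball tone train: standard = tinnitus pitch, deviant = +10%.

    Pulses are 100 ms with 10-ms raised-cosine ramps; gaps are drawn uniformly
    from 0.5-1.5 s.  Per-pulse level applies half the hearing loss at the
    pulse frequency as gain (half-gain compensation), capped below clipping.
    The pulse schedule (onset, frequency, label, amplitude) is recorded in
    the metadata for downstream verification.
    """
    pitch = _require_pitch(p)
    if not 0.0 <= p_deviant <= 1.0:
        raise ValueError("p_deviant must lie in [0, 1]")
    f_dev = deviant_factor * pitch
    if f_dev >= fs / 2:
        raise ValueError(f"deviant frequency {f_dev:.0f} Hz exceeds Nyquist")
    rng = np.random.default_rng(seed)
    labels = np.where(rng.random(n_pulses) < p_deviant, "deviant", "standard")
    gaps = rng.uniform(0.5, 1.5, n_pulses)

    base_amp = 10 ** (REFERENCE_RMS_DBFS / 20.0) * np.sqrt(2.0)  # tone peak at ref RMS
    schedule = []
    t = 0.0
    for lab, gap in zip(labels, gaps):
        t += gap
        freq = f_dev if lab == "deviant" else pitch
        loss = p.audiogram.loss_at(freq, "both")
        amp = min(base_amp * 10 ** (0.5 * loss / 20.0), 0.9)
        if duration is not None and t + pulse_duration > duration:
            break
        schedule.append({"onset": t, "duration": pulse_duration,
                         "freq": float(freq), "label": str(lab), "amplitude": float(amp)})
        t += pulse_duration
    total = duration if duration is not None else t + 0.5
    x = np.zeros(int(round(total * fs)))
    for ev in schedule:
        i0 = int(round(ev["onset"] * fs))
        tone = ev["amplitude"] * _tone(ev["freq"], ev["duration"], fs)
        x[i0:i0 + tone.size] += tone[: max(x.size - i0, 0)]
    meta = {
        "standard_hz": pitch, "deviant_hz": float(f_dev),
        "deviant_factor": deviant_factor, "p_deviant": p_deviant,
        "pulse_schedule": schedule,
        "n_deviant": int(sum(ev["label"] == "deviant" for ev in schedule)),
    }
    return TherapyProgram(x, fs, "ADT", meta)


# ---------------------------------------------------------------------------
# TEAE
# ---------------------------------------------------------------------------

def synthesize_teae(p: Participant, duration: float, fs: float,
                    seed: int | None = None, notch_octaves: float = 1.0 / 3.0,
                    tones_per_second: float = 3.0, floor_scale: float = 0.02,
                    scale_per_db: float = 0.01) -> TherapyProgram:
    """Random tone sequence with amplitude proportional to hearing loss.

    Tone frequencies are log-uniform over the audiogram range (125 Hz-8 kHz),
    excluding a ``notch_octaves``-wide band around the tinnitus pitch.  Each
    tone's linear amplitude scale is max(floor, scale_per_db * loss(f)), i.e.
    proportional to the interpolated dB HL loss with a floor for intact
    frequencies.  Tones are randomly bursts (150 ms) or pips (30 ms).
    """
    if p.audiogram is None:
        raise MissingDataError(f"participant {p.id} has no audiogram")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    x = np.zeros(n)
    f_lo, f_hi = min(AUDIOGRAM_RANGE), max(AUDIOGRAM_RANGE)
    notch = None
    if p.tinnitus is not None:
        half = 2 ** (notch_octaves / 2.0)
        notch = (p.tinnitus.pitch / half, p.tinnitus.pitch * half)
    n_tones = int(round(tones_per_second * duration))
    tones = []
    for _ in range(n_tones):
        while True:
            freq = float(np.exp(rng.uniform(np.log(f_lo), np.log(f_hi))))
            if notch is None or not (notch[0] <= freq <= notch[1]):
                break
        loss = p.audiogram.loss_at(freq, "both")
        scale = max(floor_scale, scale_per_db * loss)
        kind = "burst" if rng.random() < 0.5 else "pip"
        dur = 0.15 if kind == "burst" else 0.03
        onset = float(rng.uniform(0.0, max(duration - dur, 0.0)))
        tones.append({"onset": onset, "freq": freq, "duration": dur,
                      "kind": kind, "scale": float(scale)})
        i0 = int(round(onset * fs))
        tone = scale * _tone(freq, dur, fs)
        x[i0:i0 + tone.size] += tone[: max(n - i0, 0)]
    meta = {"notch_hz": notch, "floor_scale": floor_scale,
            "scale_per_db": scale_per_db, "tones": tones}
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak > 0.98:  # overlapping tones may stack; normalize, keep scales in metadata
        x *= 0.98 / peak
        meta["renormalized"] = float(peak / 0.98)
    return TherapyProgram(x, fs, "TEAE", meta)


AUDIOGRAM_RANGE = (125.0, 8000.0)


# ---------------------------------------------------------------------------
# BBT
# ---------------------------------------------------------------------------

def synthesize_bbt(p: Participant, beat_hz: float = 10.0, duration: float = 10.0,
                   fs: float = 44100.0, amplitude: float = 0.5) -> TherapyProgram:
    """Dichotic pure tones: left = tinnitus pitch, right = pitch + beat.

    Eligibility requires a tinnitus pitch below 1 kHz.  Column 0 of the
    stereo waveform is the left ear, column 1 the right ear.
    """
    pitch = _require_pitch(p)
    if pitch >= 1000.0:
        raise EligibilityError(f"BBT requires tinnitus pitch < 1 kHz, got {pitch:.0f} Hz")
    if beat_hz < 0:
        raise ValueError("beat frequency must be >= 0")
    left = amplitude * _tone(pitch, duration, fs)
    right = amplitude * _tone(pitch + beat_hz, duration, fs)
    x = np.column_stack([left, right])
    meta = {"carrier_hz": pitch, "beat_hz": beat_hz,
            "left_hz": pitch, "right_hz": pitch + beat_hz}
    return TherapyProgram(x, fs, "BBT", meta)


# ---------------------------------------------------------------------------
# placebo music
# ---------------------------------------------------------------------------

#: C-major pentatonic scale degrees (Hz), one octave around middle C.
_PENTATONIC = (261.63, 293.66, 329.63, 392.00, 440.00, 523.25)


def synthesize_placebo(duration: float, fs: float, tempo_bpm: float = 70.0,
                       seed: int | None = None) -> TherapyProgram:
    """Procedural relaxing music with one note per beat at ``tempo_bpm``.

    Notes are drawn from a pentatonic scale with a raised-cosine attack and
    exponential decay, giving a clear beat-onset envelope at 60/tempo
    seconds.  Nothing is tuned to tinnitus parameters (placebo by design).
    """
    if not 60.0 <= tempo_bpm <= 80.0:
        raise ValueError(f"tempo {tempo_bpm} bpm outside the relaxing-music range [60, 80]")
    rng = np.random.default_rng(seed)
    period = 60.0 / tempo_bpm
    n = int(round(duration * fs))
    x = np.zeros(n)
    onsets = np.arange(0.0, duration, period)
    for onset in onsets:
        freq = float(rng.choice(_PENTATONIC))
        dur = min(period, duration - onset)
        m = int(round(dur * fs))
        t = np.arange(m) / fs
        env = np.minimum(t / 0.02, 1.0) * np.exp(-t / (0.3 * period))
        note = 0.4 * env * np.sin(2 * np.pi * freq * t)
        i0 = int(round(onset * fs))
        x[i0:i0 + m] += note[: max(n - i0, 0)]
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak > 1.0:
        x /= peak
    meta = {"tempo_bpm": tempo_bpm, "beat_period_s": period, "n_beats": int(onsets.size)}
    return TherapyProgram(x, fs, "placebo", meta)


def synthesize_for_group(p: Participant, duration: float = 10.0, fs: float = 44100.0,
                         seed: int | None = None) -> TherapyProgram:
    """Dispatch to the synthesis routine of the participant's assigned group."""
    group = p.group
    if group in ("placebo", "control"):
        return synthesize_placebo(duration, fs, seed=seed)
    if group == "TRT":
        return synthesize_trt(p, duration, fs, seed=seed)
    if group == "ADT":
        return synthesize_adt(p, duration=duration, fs=fs, seed=seed)
    if group == "TEAE":
        return synthesize_teae(p, duration, fs, seed=seed)
    if group == "BBT":
        return synthesize_bbt(p, duration=duration, fs=fs)
    raise ValueError(f"participant {p.id} has no assigned group")


# ---------------------------------------------------------------------------
# stimulation schedule
# ---------------------------------------------------------------------------

def build_schedule(n_stimuli: int = 50, stim_duration: float = 1.0,
                   iti: float = 2.0) -> StimulationSchedule:
    """Regular stimulation schedule: onsets at k*(stim_duration + iti).

    The session default is 50 one-second stimuli with a 2-s inter-trial
    interval (last onset 147 s, total 150 s).
    """
    if n_stimuli < 1 or stim_duration <= 0 or iti <= 0:
        raise ValueError("n_stimuli, stim_duration and iti must be positive")
    spacing = stim_duration + iti
    onsets = np.arange(n_stimuli) * spacing
    return StimulationSchedule(onsets=onsets, stim_duration=stim_duration,
                               iti=iti, total_duration=n_stimuli * spacing)


def session_stimulus(program: TherapyProgram, stim_duration: float = 1.0) -> np.ndarray:
    """One-second stimulus token cut from the therapy program (session sounds
    match the therapy in use)."""
    n = int(round(stim_duration * program.fs))
    token = program.waveform[:n]
    if token.shape[0] < n:
        reps = int(np.ceil(n / max(token.shape[0], 1)))
        token = np.tile(token, (reps,) + (1,) * (token.ndim - 1))[:n]
    return _raised_cosine_ramps(np.array(token, dtype=float), program.fs, 0.01)
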