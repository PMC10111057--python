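"""Synthesize all five therapy sounds for one patient and write WAV files.

Each therapy is personalized from the tinnitus profile and the audiogram:
TRT centers an octave noise band on the pitch, ADT builds an oddball train
(deviant +10%), TEAE stimulates the hearing-loss region while notching the
pitch, BBT needs a sub-1-kHz pitch, and the placebo music ignores the
profile entirely.
"""

from pathlib import Path

import tinnerp as t
from tinnerp.io import write_wav

out = Path("scratch/sounds")
out.mkdir(parents=True, exist_ok=True)

audiogram = t.Audiogram(
    left={125.0: 10, 250.0: 10, 500.0: 15, 1000.0: 20, 2000.0: 30,
          4000.0: 45, 8000.0: 55},
    right={125.0: 10, 250.0: 15, 500.0: 15, 1000.0: 25, 2000.0: 35,
           4000.0: 50, 8000.0: 60})
patient = t.Participant(
    id="P1", condition="tinnitus", age=52, sex="F", heart_rate=70,
    audiogram=audiogram,
    tinnitus=t.TinnitusProfile(pitch=4000.0, intensity=45.0, laterality="B"))

fs = 44100.0
trt = t.synthesize_trt(patient, duration=5.0, fs=fs, seed=0)
adt = t.synthesize_adt(patient, n_pulses=10, fs=fs, seed=0)
teae = t.synthesize_teae(patient, duration=5.0, fs=fs, seed=0)
placebo = t.synthesize_placebo(duration=5.0, fs=fs, tempo_bpm=70.0, seed=0)

low_pitch = t.Participant(
    id="P2", condition="tinnitus", age=40, sex="M", heart_rate=65,
    audiogram=audiogram,
    tinnitus=t.TinnitusProfile(pitch=500.0, intensity=30.0, laterality="L"))
bbt = t.synthesize_bbt(low_pitch, beat_hz=10.0, duration=5.0, fs=fs)

for prog in (trt, adt, teae, placebo, bbt):
    path = write_wav(out / f"{prog.therapy.lower()}.wav", prog)
    print(f"{prog.therapy:8s} -> {path}  ({prog.duration:.1f} s)")

print(f"\nTRT band: {trt.metadata['band_hz'][0]:.0f}-"
      f"{trt.metadata['band_hz'][1]:.0f} Hz")
print(f"ADT deviant: {adt.metadata['deviant_hz']:.0f} Hz "
      f"(standard {adt.metadata['standard_hz']:.0f} Hz)")
print(f"TEAE notch: {teae.metadata['notch_hz'][0]:.0f}-"
      f"{teae.metadata['notch_hz'][1]:.0f} Hz")
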