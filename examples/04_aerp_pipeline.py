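"""Full AERP pipeline for one participant: IAF, ITC weighting, component peaks.

Stage 1 averages the cleaned epochs; stage 2 weights each channel by its
inter-trial coherence (ITC) around the individual alpha frequency (IAF);
stage 3 applies the scalar IAF normalization (10 Hz / IAF).
"""

import numpy as np

import tinnerp as t

# resting recording -> IAF
rest, rest_truth = t.simulate_resting(iaf=9.5, seed=4)
iaf = t.estimate_iaf(rest)
print(f"IAF: estimated {iaf:.2f} Hz (truth {rest_truth.iaf} Hz)")

# stimulation session -> cleaned epochs
schedule = t.build_schedule()
template = t.make_template(t.TINNITUS_COMPONENTS)
rec, truth = t.simulate_session(template, schedule, itc_level=0.8,
                                noise_sd=3.0, seed=4)
epochs, _ = t.preprocess_pipeline(rec)

# ITC-weighted AERP
itc = t.compute_itc(epochs, iaf)
aerp = t.weight_aerp(t.average_epochs(epochs), itc, iaf,
                     epochs.times, epochs.channels, participant="P1")
print(f"ITC range across channels: {itc.min():.2f}-{itc.max():.2f} "
      f"(jitter sd {truth.jitter_sd_ms:.0f} ms)")

# component peaks on the F3 average (unweighted, for comparison with truth)
f3 = epochs.channels.index("F3")
windows = {"N1": (80.0, 220.0), "P2": (220.0, 310.0), "P3": (310.0, 500.0)}
peaks = t.detect_components(t.average_epochs(epochs)[f3], epochs.times,
                            windows).peaks
print("\ndetected components at F3 (truth: N1 -1.7 uV/150 ms, "
      "P2 2.4/250, P3 2.6/380):")
for name, (amp, lat) in peaks.items():
    print(f"  {name}: {amp:+.2f} uV at {lat:.0f} ms")
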