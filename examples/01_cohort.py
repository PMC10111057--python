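"""Simulate a study cohort and inspect its questionnaire outcomes.

The default design follows the completed-group sizes 11/14/15/15/8/8
(71 participants); group assignment applies the clinical eligibility rules
(healthy -> control, pitch < 1 kHz -> BBT, well-identified pitch -> TRT/ADT,
otherwise placebo/TEAE).
"""

import tinnerp as t

cohort = t.simulate_cohort(seed=1)
frame = t.cohort_to_frame(cohort)

print(f"{len(cohort)} participants completed "
      f"(recruited {sum(t.DEFAULT_RECRUITED.values())}, "
      f"dropouts {sum(t.DEFAULT_RECRUITED.values()) - len(cohort)})")
print(frame.groupby("group", sort=False)["id"].nunique())

# THI handicap grades at the initial session
s0 = frame[(frame["session"] == "S0") & frame["thi"].notna()]
print("\nTHI grades at S0:")
print(s0["thi"].map(t.categorize_thi).value_counts())

# questionnaire effect directions per group and instrument
print("\nEffect summary (percent of participants per direction):")
print(t.effect_summary(cohort).to_string(index=False))
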