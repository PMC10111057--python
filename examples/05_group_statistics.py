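"""Two-session group comparison: grand averages, AUC and the statistics.

For one simulated therapy group the final session (Sf) carries a stronger
evoked response than the initial session (S0).  The per-channel AUC of the
grand-average difference summarizes the change; the Wilcoxon signed-rank
test (after a D'Agostino-Pearson normality check) decides whether the
sessions differ; the correlation screen looks for demographic covariates.
"""

import numpy as np

import tinnerp as t
from tinnerp.eegsim import DEFAULT_CHANNEL_WEIGHTS

schedule = t.build_schedule()
template = t.make_template(t.TINNITUS_COMPONENTS)


def session_aerp(seed, weights, session):
    rec, _ = t.simulate_session(template, schedule, itc_level=1.0,
                                noise_sd=1.5, seed=seed,
                                channel_weights=weights, session=session)
    ep = t.segment(rec)
    itc = t.compute_itc(ep, 10.0)
    return t.weight_aerp(t.average_epochs(ep), itc, 10.0, ep.times,
                         ep.channels, session=session)


# Sf responses are scaled up on the fronto-central channels (a therapy effect)
boosted = {ch: w * 1.4 for ch, w in DEFAULT_CHANNEL_WEIGHTS.items()}
s0 = [session_aerp(100 + i, DEFAULT_CHANNEL_WEIGHTS, "S0") for i in range(8)]
sf = [session_aerp(200 + i, boosted, "Sf") for i in range(8)]

ga_s0 = t.grand_average(s0, group="TRT", session="S0")
ga_sf = t.grand_average(sf, group="TRT", session="Sf")
cmp = t.auc_difference(ga_sf, ga_s0, s0[0].times, s0[0].channels, group="TRT")
print(f"AUCmax = {cmp.auc_max:.0f} uV*ms at {cmp.auc_channel} (AUCch)")

result = t.evaluate_therapy(
    np.trapezoid(ga_s0, s0[0].times, axis=1),
    np.trapezoid(ga_sf, s0[0].times, axis=1), group="TRT")
print(f"normality p = {result.normality_p:.3f}, "
      f"signed-rank p = {result.p_value:.4f} -> {result.decision}")

# correlation screen on a simulated cohort (recovers the built-in
# intensity <-> hearing-loss dependence)
cohort = t.simulate_cohort(seed=1)
table = t.participant_table(cohort)[["age", "hl_right",
                                     "tinnitus_intensity"]].dropna()
screen = t.correlation_screen(table)
rho = screen.rho.loc["hl_right", "tinnitus_intensity"]
print(f"\nintensity vs right-ear loss: rho = {rho:.2f} "
      f"(significant: {bool(screen.significant.loc['hl_right', 'tinnitus_intensity'])})")

report = t.build_report([result], auc_comparisons=[cmp], out_dir="scratch/report")
print("report written to scratch/report/")
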