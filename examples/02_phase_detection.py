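"""Detect exhalation phases from the isoprene ion trace of one acquisition.

Isoprene (C5H8, [M+H]+ at m/z 69.070) is consistently present in human
breath and near-absent in room air, so its trace switches between an
ambient baseline and an exhalation plateau.
"""

import breathomics as b

cfg = b.SimulationConfig(n_participants=1, duration=120.0, noise_sd=300.0, seed=7)
runs, truth = b.simulate_cohort(cfg)
run = runs[0]

result = b.process_run(run, b.PipelineParams())
iso = min(result.traces, key=lambda t: abs(t.consensus_mz - 69.0699))
print(f"isoprene trace: consensus m/z {iso.consensus_mz:.4f}, "
      f"support {iso.support:.2f}")

phases = result.phases
print(f"detected {phases.n_exhalations} exhalation phases:")
for (ds, de), (ts, te) in zip(phases.exhalations, truth.phases[run.run_id]):
    print(f"  detected [{ds:6.1f}, {de:6.1f}) s   truth [{ts:6.1f}, {te:6.1f}) s")
# Detected boundaries land within ~1 s of the planted windows; the
# detector thresholds at 30% of the trace's dynamic range, so it is
# invariant to the absolute intensity scale.

q = b.quantify_feature(iso, phases)
print(f"isoprene exhaled mean {q.exhaled_mean:.0f}, background {q.background_mean:.0f}, "
      f"one-sided p = {q.p_exh_vs_bg:.2e}")
# The tiny p-value confirms isoprene is exhalation-enriched, the signal
# every retained breath feature must show.
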