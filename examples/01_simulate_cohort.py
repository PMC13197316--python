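"""Generate a small synthetic breath-analysis cohort and write it to disk.

Each participant performs three deep exhalations during a ~2 min
acquisition; 30 exhaled VOCs (each with a 13C isotopologue) and 10
ambient ions (including the two siloxane lock masses) are planted with
known intensities.
"""

from pathlib import Path

import breathomics as b

cfg = b.SimulationConfig(n_participants=3, duration=120.0, scans_per_second=2.0,
                         noise_sd=300.0, mz_jitter_ppm=2.0, seed=42)
runs, truth = b.simulate_cohort(cfg)
outdir = b.write_cohort(runs, truth, cfg, Path("scratch_example_cohort"))

print(f"wrote {len(runs)} acquisitions to {outdir}/ "
      f"({runs[0].n_scans} scans each, {runs[0].scans[0].mz.size} ions per scan)")
print(f"planted: {len(truth.exhaled_mz)} exhaled compounds, "
      f"{len(truth.ambient_mz)} ambient ions, {len(truth.isotope_pairs)} isotopologues")
for rid, phases in truth.phases.items():
    label = " ".join(f"[{s:.1f},{e:.1f}]" for s, e in phases) or "(background: none)"
    print(f"  {rid}: true exhalation windows {label}")
# The mzML files are standard centroid spectra; truth_*.csv record exactly
# what was planted so downstream stages can be scored against it.
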