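# breathomics

Processing pipeline for **real-time exhaled-breath profiling by ambient
ionization high-resolution mass spectrometry**. A participant breathes
into an ionization source coupled to an HRMS instrument; the result is a
2–5 minute sequence of full-scan spectra (m/z 50–300, a few scans per
second) in which exhaled volatile organic compounds (VOCs) rise and fall
with each exhalation on top of a constant ambient background. This
package turns a cohort of such acquisitions (mzML) into a features ×
participants intensity matrix with putative compound annotations and
reproducibility statistics. It is written for analytical chemists and
data scientists working on breath-based biomarker discovery.

## What it computes

For each acquisition:

1. **Mass recalibration** — per scan, the relative mass error
   e(m/z) = a + b·m/z (ppm) is fitted by least squares to three
   ubiquitous reference ions: isoprene [C₅H₈+H]⁺ (m/z 69.070) and the
   siloxane lock masses [(Si(CH₃)₂O)₂+H]⁺ (149.045) and
   [(Si(CH₃)₂O)₃+H]⁺ (223.064); each scan's axis is divided by
   (1 + e·10⁻⁶).
2. **Peak detection** — local maxima with prominence and
   signal-to-noise thresholds (noise = median intensity, spread =
   1.4826 × MAD), centroided by intensity-weighted mean.
3. **Ion traces** — centroids are clustered along m/z (single linkage,
   8 ppm cut), giving one intensity-vs-time trace per ion.
4. **Exhalation phases** — detected on the isoprene trace by relative
   thresholding: baseline + 0.3 × (95th percentile − baseline).
5. **Quantification** — each feature's value is the mean intensity over
   the exhalation phases, minus the within-run ambient mean; a one-sided
   Mann–Whitney test compares exhalation vs background scans.

Across the cohort: feature lists are aligned (same clustering kernel),
features are kept only if detected in **> 30 %** of participants *and*
exhalation-significant (p < 0.05) in **> 30 %** of samples, missing
cells are imputed by probabilistic minimum imputation (MinProb), and
¹³C isotopologues (Δm = 1.00336 Da, across-participant r ≥ 0.8,
abundance ratio ≈ nC × 1.07 % or < 20 % without a formula) are removed.
Features are annotated against compound tables (HMDB/HBDB-style exports)
over five adduct types — [M+H]⁺, [M]⁺, [M−H]⁺, [M−OH]⁺, [M+NH₄]⁺ —
within 10 ppm, with the electron mass subtracted from every cation.

Reproducibility metrics: CV of the mean intensity across the three
exhalations, CV within a single exhalation, pairwise cosine similarity
of per-exhalation feature vectors, and the across-participant CV
averaged over features. Feature redundancy is summarised by hierarchical
clustering (distance 1 − Pearson r, groups retained at mean within-group
r > 0.8) and a census of within-group mass differences (O 15.995,
CH₂ 14.016, H₂ 2.016 …). Demographic associations use Mann–Whitney
(categorical) or Spearman (continuous) tests with raw p < 0.05.

Because clinical raw data of this kind are not publicly sharable, the
package ships a **truth-controlled synthetic acquisition generator**
(`breathomics.simulate`): every stage above is validated against planted
ground truth (compound m/z, phase windows, isotopologue ratios,
dispersion parameters).

## Worked example

```python
import breathomics as b

cfg = b.SimulationConfig(n_participants=8, duration=120.0, noise_sd=300.0,
                         mz_jitter_ppm=2.0, mass_drift_ppm=5.0, seed=3)
runs, truth = b.simulate_cohort(cfg)
res = b.process_cohort(runs, b.default_compound_db(), b.PipelineParams())
print(res.stage_counts)
```

prints (see `examples/03_full_pipeline.py`):

```
features_aligned: 70         # 30 exhaled + 30 isotopologues + 10 ambient
features_after_filter: 60    # ambient ions fail the exhalation-significance rule
isotopes_removed: 30         # every 13C twin identified and dropped
features_final: 30           # exactly the planted exhaled compounds
recovered 30/30 planted exhaled compounds, 0 spurious
median across-exhalation CV: 0.096 (planted 0.1)
```

The final count of 30 equals the planted exhaled parent compounds: the
filter removed the 10 ambient ions (present everywhere but never
exhalation-enriched) and isotope removal stripped all 30 ¹³C twins
without touching a parent. The `examples/` directory has one short
script per capability (simulation, phase detection, full pipeline,
annotation, metrics, demographics), and the `breathomics` command
exposes `simulate`, `run`, `annotate` and `metrics` subcommands.

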