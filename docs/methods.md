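# Methods

This note records the models, parameter choices and numerical
conventions behind `breathomics`, and what the synthetic validation does
and does not demonstrate.

## Signal model and processing assumptions

An acquisition is a time-ordered sequence of full-scan centroid (or
profile) spectra over m/z 50–300. The processing model assumes:

- **Additive composition per scan**: each spectrum is a superposition of
  exhaled-compound ions (gated by breathing), ambient ions (constant),
  their isotopologues, and noise sticks.
- **Slow multiplicative mass drift**: the mass-axis error is relative
  (ppm) and at most affine in m/z, e(m) = a + b·m. Three reference ions
  support at most an affine model, and ppm-linear drift is the standard
  behaviour of Orbitrap-class analyzers. Corrections are fitted per scan
  (temporal drift is not assumed constant over minutes); a block-average
  mode (`per_scan=False`) is available when per-scan statistics are too
  thin. Reference matching takes the **most intense** candidate within
  the ±30 ppm search window rather than the nearest — robust to low
  noise sticks landing closer to the reference than the true peak. Scans
  where a reference is missing inherit the nearest calibrated scan's
  coefficients (temporal smoothness).
- **No chromatography**: there is no retention-time dimension; alignment
  is purely along m/z.

## Peak detection and noise

Noise per spectrum is estimated robustly as (median, 1.4826 × MAD) of
the stick intensities, which presumes that the majority of data points
are noise. Profile spectra are picked with prominence-based local maxima
(default prominence 3 × noise sd, min SNR 3) and centroided by the
intensity-weighted mean over the maximum ± 1 samples. Already-centroided
spectra reduce to SNR thresholding. A non-positive `min_snr` disables
SNR gating entirely: this is the correct setting for noise-free inputs
(e.g. noiseless simulations), where the MAD of pure signal sticks is not
a noise estimate and any SNR cut would discard genuine low-intensity
ions.

## Trace building and alignment

Both within-run and across-participant alignment use one kernel:
single-linkage clustering along m/z with a relative cut — sorted
centroids are split wherever the gap between neighbours exceeds
`merge_ppm` (default 8 ppm). This guarantees every pair of output
features is separated by more than the merge width, is
permutation-invariant, and is O(n log n). The 8 ppm default is a design
choice (the only stated tolerance in this workflow is the 10 ppm
annotation window); it sits comfortably between the instrument's ppm-
scale jitter and the ~50 ppm spacing of the closest real features.
Within a scan, two peaks falling into one cluster keep the more intense
member (collisions are counted and logged). Traces below 10 % scan
support are dropped.

## Exhalation phases and quantification

Phases are detected on the isoprene trace (isoprene is consistently
present in breath and near-absent in room air) by relative thresholding:
baseline = 10th percentile, threshold = baseline + 0.3 × (95th
percentile − baseline). Percentile-based baselines make the detector
invariant to intensity scale and robust to isolated spikes.
Super-threshold runs shorter than 2 s are discarded, runs closer than
`merge_gap` (1 s) merged, and the background is the complement of the
phases padded by the merge gap. Intervals are half-open [start, end) in
seconds.

Each feature is quantified as the unweighted mean of its per-phase mean
intensities; the background-subtracted value is clipped at zero.
"Significantly higher during exhalation" is operationalised as a
**one-sided Mann–Whitney U test** on scan-level intensities at α = 0.05;
a Welch t alternative is available (`test_method="welch"`). Either group
having fewer than 3 scans yields a missing p, treated as not
significant. The background in this test is the **within-run ambient
portion** by default; separately recorded daily background acquisitions
are carried through the pipeline (traces built, excluded from the
cohort matrix) and can serve as an alternative background source.

## Cohort matrix rules

- Retention requires presence in **strictly more than** 30 % of
  participants *and* exhalation-significance in strictly more than 30 %
  of samples — exactly 12/40 fails, 13/40 passes. "Detected in a
  participant" means the participant contributed at least one aligned
  trace with a finite exhaled mean.
- **MinProb imputation**: per participant, missing cells are drawn from
  Normal(μ = 1st percentile of observed values, σ = sd of the observed
  values below the participant's median), truncated at 0, seeded. The
  quantile and sd definition follow the common usage of probabilistic
  minimum imputation for left-censored omics intensities and are
  config-exposed.
- **Isotopologue identification**: candidate pairs differ by the
  ¹³C–¹²C mass (1.0033548 Da) within 10 ppm of the parent m/z with the
  putative isotope less intense. Confirmation needs across-participant
  Pearson r ≥ 0.8 **and** an abundance ratio consistent with the
  parent's annotated carbon count (median ratio within ±50 % of
  nC × 1.07 %; the wide band absorbs counting noise at low intensity)
  or, with no formula available, a median ratio below 20 %.
  Correlations are computed across participants (not across scans)
  because cohort-level intensities are the quantities the matrix
  carries. The Δm list is extensible (e.g. ³⁴S) but defaults to ¹³C
  only.

## Annotation

Monoisotopic masses use the most-abundant-isotope atomic masses from
the NIST table shipped with `pyteomics` (C = 12 exactly,
H = 1.0078250, O = 15.9949146, Si = 27.9769265 …). All five cation
types subtract the electron mass (0.000549 Da); this is validated by
the 3-decimal reference values 137.132 (C₁₀H₁₆+H) and 87.044
(C₄H₆O₂+H), which only reproduce with the correction. [M−OH]⁺ is
defined as water loss from the protonated ion, algebraically identical
to [M+H−H₂O]⁺; the hydroxide-abstraction alternative (~1 mDa away) is
not used. Annotation hit counts are reported per source database and as
a union — compounds shared between databases are not deduplicated
before counting.

## Metrics and statistics

- Coefficients of variation are sample sd (ddof = 1) over mean; the
  across-exhalation CV uses the three per-phase means and cohort
  aggregation is by median.
- Cosine similarity operates on the three **per-exhalation
  feature-intensity vectors** of one participant (3 × 3 matrix); a
  trace-based mode would be the alternative reading of "temporal
  profiles" and can be assembled from `IonTrace` objects directly.
- Hierarchical clustering uses distance 1 − Pearson r with **average
  linkage**; the dendrogram is scanned from the root and the maximal
  subtrees whose **mean pairwise** within-group correlation exceeds 0.8
  are retained (mean-to-centroid was the other candidate; mean pairwise
  is what the retained-group audit recomputes). Constant features are
  excluded with a warning.
- Demographic tests report **raw p-values** at 0.05; no multiplicity
  correction is applied by default (Benjamini–Hochberg can be applied
  downstream on the returned p column and is deliberately not the
  default behaviour of this pipeline).
- PCA standardises features across participants and reports the first
  two components.

## The synthetic generator

`simulate_cohort` emulates: 2–5 min acquisitions at a few scans/s;
three exhalations per run, visible as plateaus on the isoprene trace;
a raised-cosine-edged gate (the gate crosses 0.5 exactly at the stated
interval boundaries; rise time 1 s) — smooth breath traces have no
published functional form, and the raised cosine is the simplest C¹
gate; 30 exhaled VOCs (isoprene always included) and 10 ambient ions
including both siloxane lock masses; first-order ¹³C isotopologues at
nC × 1.07 % of the parent (higher isotopologues are negligible below
~C₂₀ and the identification rules only use the first isotope);
log-normal between-participant variation (CV 0.70); ppm-scale drift
(constant and/or linear in m/z) and jitter; additive noise plus
low-intensity noise sticks so SNR estimation has a genuine noise floor.
All randomness flows from one seed through a spawned `SeedSequence` per
run, so output is bit-identical per seed.

**Exact realized dispersion.** Where the generator plants a dispersion
parameter that a metric must recover, it plants the *realized* sample
statistic, not a population parameter: the three per-phase multipliers
are a random zero-sum direction scaled to ddof-1 sample CV exactly equal
to the nominal value, and `simulate_phase_means` rescales each feature's
log-normal draws (in the exponent) to exact realized between-subject CV.
The sample CV of 3 draws from a distribution with population CV c has
median ≈ 0.83 c and the sample CV of 40 log-normal draws with CV 0.7 has
expectation ≈ 0.66 — a truth-controlled generator that planted
population parameters would make "recovery" tests assert the estimator's
small-sample bias instead of the pipeline's correctness. With realized
dispersion planted, a correct implementation recovers the nominal value
exactly and any deviation is attributable to the pipeline.

**What the simulation does not model**: within-exhalation dynamics
(plateaus are flat, so within-exhalation CV on simulated data reflects
noise only), expiratory flow and its fluctuations, split dilution,
ion-source competition/matrix effects, peak-shape and resolution
effects (spectra are generated as centroid sticks), and in-source
fragmentation. Passing the planted-truth suite therefore demonstrates
algorithmic correctness of the processing chain, not instrument-level
fidelity.

**Scan rate and duration** default to 2 Hz and 180 s; these are
plausible placeholders for this instrument class, not reported values.
Validation runs use 120 s acquisitions (360–480 scans per cohort
participant), which give every phase ≥ 20 scans and keep cohort-scale
suites fast.

## Degenerate inputs and tie-breaks

- A marker trace with no dynamic range (95th percentile at the
  baseline) raises a no-breath-detected error; a background run is the
  expected case.
- An exhalation containing no scan raises an error naming the phase.
- Equal-intensity within-scan cluster collisions keep the first
  encountered; exact m/z duplicates in simulation output are merged by
  intensity summation.
- Features with all-missing participants abort imputation (the
  participant, not the feature, is the imputation unit).
- Formula parsing reports the byte offset of the offending token.

## Known limitations

- The cosine metric's 3×3-per-participant form and the within-run
  background definition are interpretations of ambiguous methodology;
  both alternatives are reachable through the public API.
- Isotope identification considers single-Δ pairs only; full envelope
  deconvolution is out of scope.
- The annotation step is putative by construction — isomers share exact
  masses; MS/MS confirmation is outside this package.
- Absolute quantification is not attempted; all intensities are
  relative.
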