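"""Exhalation-phase detection and per-phase feature quantification.

Isoprene is consistently present in human breath and essentially absent
from ambient air, so its ion trace switches between a low ambient
baseline and an exhalation plateau; phases are detected by relative
thresholding of that trace.  Each feature is then quantified as the mean
intensity over the exhalation phases, and compared against the within-run
ambient (background) scans with a one-sided rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu, ttest_ind

from .errors import NoBreathDetectedError, PhaseQuantError
from .traces import IonTrace

__all__ = ["BreathPhaseSet", "FeatureQuant", "detect_phases", "quantify_feature",
           "exhalation_test"]


@dataclass
class BreathPhaseSet:
    """Exhalation intervals and background (ambient) intervals of one run.

    Intervals are half-open ``[start, end)`` in seconds from run start,
    non-overlapping and time-ordered; exhalations and background are
    disjoint (separated by the detector's merge gap padding).
    """

    exhalations: list[tuple[float, float]]
    background_intervals: list[tuple[float, float]]

    @property
    def n_exhalations(self) -> int:
        return len(self.exhalations)


@dataclass
class FeatureQuant:
    """Quantification of one feature against one phase set."""

    per_phase_mean: np.ndarray  # one mean per exhalation
    exhaled_mean: float  # unweighted mean of the per-phase means
    background_mean: float
    p_exh_vs_bg: float | None  # one-sided p, exhalation > background
    background_subtracted: float  # max(exhaled_mean - background_mean, 0)


def detect_phases(
    isoprene_trace: IonTrace,
    frac: float = 0.3,
    min_duration: float = 2.0,
    merge_gap: float = 1.0,
) -> BreathPhaseSet:
    """Detect exhalation phases by relative thresholding of the marker trace.

    The baseline is the 10th percentile of the trace and the threshold is
    ``baseline + frac * (95th percentile - baseline)``; the detection is
    therefore invariant to positive rescaling of the trace.  Super-
    threshold runs shorter than ``min_duration`` are discarded, runs
    separated by less than ``merge_gap`` merged, and the background is
    the complement of the exhalations padded by ``merge_gap``.

    Raises :class:`NoBreathDetectedError` when the trace is degenerate
    (95th percentile at the baseline, i.e. no gated signal).
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must be in (0, 1)")
    if min_duration <= 0:
        raise ValueError("min_duration must be > 0")
    t = np.asarray(isoprene_trace.times, dtype=float)
    x = np.asarray(isoprene_trace.intensities, dtype=float)
    baseline = np.percentile(x, 10)
    top = np.percentile(x, 95)
    if top <= baseline or not np.isfinite(top - baseline):
        raise NoBreathDetectedError(
            "marker trace has no dynamic range (95th percentile == baseline)")
    thr = baseline + frac * (top - baseline)
    above = x > thr
    # contiguous super-threshold runs as [start_time, end_time) intervals
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(x))
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    intervals = [(t[s], t[e - 1] + dt) for s, e in zip(starts, ends)]
    intervals = [(s, e) for s, e in intervals if e - s >= min_duration]
    merged: list[tuple[float, float]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    duration = float(t[-1] + dt)
    background: list[tuple[float, float]] = []
    prev_end = 0.0
    for s, e in merged:
        if s - merge_gap > prev_end:
            background.append((prev_end, s - merge_gap))
        prev_end = e + merge_gap
    if prev_end < duration:
        background.append((prev_end, duration))
    return BreathPhaseSet(exhalations=merged, background_intervals=background)


def _interval_mask(t: np.ndarray, intervals: list[tuple[float, float]]) -> np.ndarray:
    m = np.zeros(t.size, dtype=bool)
    for s, e in intervals:
        m |= (t >= s) & (t < e)  # half-open convention
    return m


def quantify_feature(trace: IonTrace, phases: BreathPhaseSet) -> FeatureQuant:
    """Mean intensity per exhalation phase and against background.

    Scans are attributed to a phase by the half-open convention
    ``start <= time < end``.  Raises :class:`PhaseQuantError` when an
    exhalation contains no scan.
    """
    if phases.n_exhalations < 1:
        raise ValueError("need >= 1 exhalation phase")
    t = np.asarray(trace.times, dtype=float)
    x = np.asarray(trace.intensities, dtype=float)
    per_phase = []
    for j, (s, e) in enumerate(phases.exhalations):
        m = (t >= s) & (t < e)
        if not m.any():
            raise PhaseQuantError(
                f"exhalation phase {j} [{s:g}, {e:g}) contains no scan", phase_index=j)
        per_phase.append(float(x[m].mean()))
    per_phase = np.asarray(per_phase)
    exhaled_mean = float(per_phase.mean())
    bg_mask = _interval_mask(t, phases.background_intervals)
    background_mean = float(x[bg_mask].mean()) if bg_mask.any() else 0.0
    p = exhalation_test(trace, phases)
    return FeatureQuant(
        per_phase_mean=per_phase,
        exhaled_mean=exhaled_mean,
        background_mean=background_mean,
        p_exh_vs_bg=p,
        background_subtracted=max(exhaled_mean - background_mean, 0.0),
    )


def exhalation_test(
    trace: IonTrace,
    phases: BreathPhaseSet,
    method: str = "mannwhitney",
) -> float | None:
    """One-sided test that exhalation scans exceed background scans.

    Default is the Mann-Whitney U rank test (alternative: Welch t via
    ``method="welch"``).  Returns None (missing, treated as not
    significant) when either group has fewer than 3 scans.
    """
    t = np.asarray(trace.times, dtype=float)
    x = np.asarray(trace.intensities, dtype=float)
    exh = x[_interval_mask(t, phases.exhalations)]
    bg = x[_interval_mask(t, phases.background_intervals)]
    if exh.size < 3 or bg.size < 3:
        return None
    if method == "mannwhitney":
        return float(mannwhitneyu(exh, bg, alternative="greater").pvalue)
    if method == "welch":
        return float(ttest_ind(exh, bg, equal_var=False, alternative="greater").pvalue)
    raise ValueError(f"unknown test method {method!r}")
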