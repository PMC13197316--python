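"""Align detected peaks across scans into temporal ion traces, and align
feature lists across participants.

Both alignments use the same clustering kernel: single-linkage along the
m/z axis with a ppm-relative cut.  Because the input is sorted by m/z,
single linkage reduces to breaking the sorted sequence wherever the gap
between neighbours exceeds ``merge_ppm`` relative width, which guarantees
that any two output features are separated by more than ``merge_ppm``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import Peak

logger = logging.getLogger(__name__)

__all__ = ["IonTrace", "CohortFeatureIndex", "build_traces", "align_cohort", "ppm_cluster"]


@dataclass
class IonTrace:
    """Per-feature intensity over scan time (one extracted-ion trace)."""

    consensus_mz: float
    times: np.ndarray
    intensities: np.ndarray  # 0 where the feature was not detected
    support: float  # fraction of scans with a detection

    def __post_init__(self):
        if len(self.times) != len(self.intensities):
            raise ValueError("times and intensities must have equal length")
        if not 0.0 <= self.support <= 1.0:
            raise ValueError("support must be in [0, 1]")


@dataclass
class CohortFeatureIndex:
    """Cohort-aligned feature list: consensus m/z + per-participant presence."""

    mz: np.ndarray  # strictly increasing consensus m/z
    presence: pd.DataFrame  # bool, features x participants
    source_traces: list[dict[str, list[int]]] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return len(self.mz)

    def presence_fraction(self) -> pd.Series:
        return self.presence.mean(axis=1)


def ppm_cluster(mz: np.ndarray, merge_ppm: float) -> np.ndarray:
    """Single-linkage cluster labels for sorted-by-m/z input.

    Adjacent values whose relative gap exceeds ``merge_ppm`` start a new
    cluster.  Input need not be sorted; labels refer to the original
    order.  Permutation-invariant by construction.
    """
    mz = np.asarray(mz, dtype=float)
    if mz.size == 0:
        return np.array([], dtype=int)
    order = np.argsort(mz, kind="stable")
    s = mz[order]
    gaps = np.diff(s) / s[:-1] > merge_ppm * 1e-6
    labels_sorted = np.concatenate([[0], np.cumsum(gaps)])
    labels = np.empty(mz.size, dtype=int)
    labels[order] = labels_sorted
    return labels


def build_traces(
    run_peaks: list[list[Peak]],
    merge_ppm: float = 8.0,
    min_support: float = 0.1,
    times: np.ndarray | None = None,
) -> list[IonTrace]:
    """Cluster per-scan centroids along m/z into temporal ion traces.

    Parameters
    ----------
    run_peaks : one peak list per scan, in time order.
    merge_ppm : single-linkage cut width, ppm (default 8).
    min_support : minimum fraction of scans in which a trace must be
        detected (default 0.1); traces below are dropped.
    times : scan start times in seconds (defaults to the scan indices).

    Within one scan, if two peaks fall in the same cluster the more
    intense one wins (the collision is logged).  Absent scans are
    zero-filled.
    """
    if merge_ppm <= 0:
        raise ValueError("merge_ppm must be > 0")
    if not 0.0 <= min_support <= 1.0:
        raise ValueError("min_support must be in [0, 1]")
    n_scans = len(run_peaks)
    if times is None:
        times = np.arange(n_scans, dtype=float)
    times = np.asarray(times, dtype=float)
    if times.size != n_scans:
        raise ValueError("times must match the number of scans")
    all_mz, all_int, all_scan = [], [], []
    for i, peaks in enumerate(run_peaks):
        for p in peaks:
            all_mz.append(p.mz)
            all_int.append(p.intensity)
            all_scan.append(i)
    if not all_mz:
        return []
    all_mz = np.asarray(all_mz)
    all_int = np.asarray(all_int)
    all_scan = np.asarray(all_scan)
    labels = ppm_cluster(all_mz, merge_ppm)

    traces = []
    collisions = 0
    for lab in range(labels.max() + 1):
        sel = labels == lab
        mzs, ints, scans = all_mz[sel], all_int[sel], all_scan[sel]
        inten = np.zeros(n_scans)
        seen = np.zeros(n_scans, dtype=bool)
        for m, v, s in zip(mzs, ints, scans):
            if seen[s]:
                collisions += 1
                if v <= inten[s]:
                    continue
            inten[s] = v
            seen[s] = True
        support = seen.mean()
        if support < min_support:
            continue
        consensus = float(np.average(mzs, weights=np.maximum(ints, 1e-300)))
        traces.append(IonTrace(consensus, times.copy(), inten, float(support)))
    if collisions:
        logger.info("build_traces: %d within-scan cluster collisions resolved "
                    "by intensity", collisions)
    traces.sort(key=lambda t: t.consensus_mz)
    return traces


def align_cohort(
    participant_features: dict[str, np.ndarray | list[float]],
    merge_ppm: float = 8.0,
) -> CohortFeatureIndex:
    """Align per-participant feature m/z lists into one cohort index.

    The same single-linkage ppm clustering is applied to the pooled
    consensus m/z values; a participant is flagged present in a cohort
    feature if they contributed at least one member.
    """
    if not participant_features:
        raise ValueError("need >= 1 participant")
    pids = list(participant_features)
    pooled_mz, pooled_pid, pooled_idx = [], [], []
    for pid in pids:
        arr = np.asarray(participant_features[pid], dtype=float)
        pooled_mz.extend(arr.tolist())
        pooled_pid.extend([pid] * arr.size)
        pooled_idx.extend(range(arr.size))
    pooled_mz = np.asarray(pooled_mz)
    labels = ppm_cluster(pooled_mz, merge_ppm)
    n_feat = labels.max() + 1 if labels.size else 0
    consensus = np.zeros(n_feat)
    presence = np.zeros((n_feat, len(pids)), dtype=bool)
    sources: list[dict[str, list[int]]] = [dict() for _ in range(n_feat)]
    pid_pos = {p: k for k, p in enumerate(pids)}
    for lab in range(n_feat):
        sel = labels == lab
        consensus[lab] = pooled_mz[sel].mean()
        for pid, idx in zip(np.asarray(pooled_pid)[sel], np.asarray(pooled_idx)[sel]):
            presence[lab, pid_pos[pid]] = True
            sources[lab].setdefault(str(pid), []).append(int(idx))
    order = np.argsort(consensus)
    return CohortFeatureIndex(
        mz=consensus[order],
        presence=pd.DataFrame(presence[order], columns=pids),
        source_traces=[sources[k] for k in order],
    )
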