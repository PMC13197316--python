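"""Reproducibility metrics, feature clustering, mass-difference census and
univariate demographic associations.

Four reproducibility metrics characterise a real-time breath dataset:
(1) per-feature CV of the mean intensity across the three exhalations,
(2) per-feature CV of the signal within a single exhalation (averaged
over exhalations), (3) pairwise cosine similarity between the three
per-exhalation feature-intensity vectors of one participant, and
(4) inter-subject variability: the across-participant CV of each
feature, averaged over features.  Feature redundancy is summarised by
hierarchical clustering with distance 1 - Pearson r, retaining maximal
groups whose mean pairwise within-group correlation exceeds 0.8, and by
the census of within-group mass differences (O, CH2, H2 ... ladders).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import iqr as _iqr, mannwhitneyu, spearmanr
from sklearn.decomposition import PCA

from .phases import BreathPhaseSet
from .traces import IonTrace

logger = logging.getLogger(__name__)

__all__ = [
    "cv", "repro_across_exhalations", "within_exhalation_cv", "cosine_matrix",
    "inter_subject_cv", "hca_groups", "ClusterGroup", "group_mass_differences",
    "univariate_association", "pca_scores", "MASS_DELTA_TABLE",
]


def cv(values) -> float:
    """Coefficient of variation: sample sd (ddof=1) / mean.

    NaN (missing) for fewer than 2 finite values or a zero mean.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        return float("nan")
    m = v.mean()
    if m == 0:
        return float("nan")
    return float(v.std(ddof=1) / m)


def repro_across_exhalations(phase_means: np.ndarray) -> tuple[np.ndarray, float, float]:
    """CV of the per-exhalation mean intensities.

    ``phase_means`` has the exhalation axis last (e.g. shape
    ``(n_features, n_participants, 3)``).  Returns the flattened CVs and
    their median and interquartile range (the median is the aggregation
    used for cohort-level reporting).
    """
    pm = np.asarray(phase_means, dtype=float)
    cvs = np.apply_along_axis(cv, -1, pm).ravel()
    finite = cvs[np.isfinite(cvs)]
    med = float(np.median(finite)) if finite.size else float("nan")
    spread = float(_iqr(finite)) if finite.size else float("nan")
    return cvs, med, spread


def within_exhalation_cv(trace: IonTrace, phases: BreathPhaseSet) -> float:
    """CV of the scan-level signal within each exhalation, averaged over
    the exhalations.  Phases with fewer than 2 scans are skipped; NaN if
    none remain."""
    t = np.asarray(trace.times, dtype=float)
    x = np.asarray(trace.intensities, dtype=float)
    per_phase = []
    for s, e in phases.exhalations:
        m = (t >= s) & (t < e)
        if m.sum() < 2:
            continue
        c = cv(x[m])
        if np.isfinite(c):
            per_phase.append(c)
    return float(np.mean(per_phase)) if per_phase else float("nan")


def cosine_matrix(vectors) -> np.ndarray:
    """Pairwise cosine similarity between equal-length vectors.

    Entry (i, j) = u_i . u_j / (|u_i| |u_j|); symmetric, unit diagonal,
    invariant to positive rescaling of any vector.  A zero vector yields
    a NaN row/column (its diagonal stays 1 by convention).
    """
    u = np.asarray(vectors, dtype=float)
    if u.ndim != 2:
        raise ValueError("expected a 2-D array of row vectors")
    norms = np.linalg.norm(u, axis=1)
    if np.all(norms == 0):
        raise ValueError("need at least one non-zero vector")
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = u / norms[:, None]
        out = unit @ unit.T
    out[norms == 0, :] = np.nan
    out[:, norms == 0] = np.nan
    np.fill_diagonal(out, 1.0)
    return np.clip(out, -1.0, 1.0)


def inter_subject_cv(matrix) -> tuple[float, float, pd.Series]:
    """Across-participant CV per feature, then averaged over features.

    Returns (mean CV, sd of the per-feature CVs, per-feature series).
    """
    vals = matrix.values if hasattr(matrix, "values") and isinstance(
        getattr(matrix, "values"), pd.DataFrame) else pd.DataFrame(matrix)
    if vals.shape[1] < 2:
        raise ValueError("need >= 2 participants")
    per_feature = vals.apply(lambda row: cv(row.to_numpy()), axis=1)
    finite = per_feature[np.isfinite(per_feature)]
    return float(finite.mean()), float(finite.std(ddof=1)), per_feature


@dataclass
class ClusterGroup:
    """One retained feature cluster."""

    members: list[float]  # feature m/z
    mean_correlation: float

    @property
    def size(self) -> int:
        return len(self.members)

    def pairwise_mass_differences(self) -> np.ndarray:
        m = np.asarray(self.members)
        d = np.abs(m[:, None] - m[None, :])
        return d[np.triu_indices(len(m), k=1)]


def _mean_pairwise_r(corr: np.ndarray, idx: list[int]) -> float:
    sub = corr[np.ix_(idx, idx)]
    n = len(idx)
    return float(sub[np.triu_indices(n, k=1)].mean()) if n > 1 else 1.0


def hca_groups(matrix, r_threshold: float = 0.8) -> tuple[list[ClusterGroup], list[float]]:
    """Hierarchical clustering of features with distance 1 - Pearson r.

    Average-linkage agglomeration; the dendrogram is scanned from the
    root and the maximal subtrees whose mean pairwise within-group
    correlation exceeds ``r_threshold`` are retained as groups (size
    >= 2).  Features in no retained group are returned as unclustered.
    Constant features (undefined correlation) are excluded with a
    warning.
    """
    vals = matrix.values if hasattr(matrix, "values") and isinstance(
        getattr(matrix, "values"), pd.DataFrame) else pd.DataFrame(matrix)
    if vals.shape[0] < 3:
        raise ValueError("need >= 3 features to cluster")
    mz = vals.index.to_numpy(dtype=float)
    arr = vals.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    const = sd == 0
    if const.any():
        logger.warning("hca_groups: excluding %d constant feature(s)", const.sum())
    keep = ~const
    arr, mz = arr[keep], mz[keep]
    if arr.shape[0] < 3:
        raise ValueError("fewer than 3 non-constant features")
    corr = np.corrcoef(arr)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    root = to_tree(z)
    groups: list[ClusterGroup] = []
    clustered: set[int] = set()

    def scan(node):
        leaves = node.pre_order()
        if len(leaves) >= 2:
            r = _mean_pairwise_r(corr, leaves)
            if r > r_threshold:
                groups.append(ClusterGroup([float(mz[i]) for i in sorted(leaves)], r))
                clustered.update(leaves)
                return
        if not node.is_leaf():
            scan(node.get_left())
            scan(node.get_right())

    scan(root)
    unclustered = [float(mz[i]) for i in range(len(mz)) if i not in clustered]
    groups.sort(key=lambda g: -g.size)
    return groups, unclustered


#: Small elemental interpretations for within-group mass differences, Da.
MASS_DELTA_TABLE: dict[str, float] = {
    "H2": 2.015650,
    "13C": 1.0033548,
    "CH2": 14.015650,
    "O": 15.994915,
    "H2O": 18.010565,
    "CO": 27.994915,
    "C2H4": 28.031300,
    "CH2O": 30.010565,
    "CO2": 43.989830,
}


def group_mass_differences(
    groups: list[ClusterGroup],
    bin_width: float = 0.005,
    top_k: int = 10,
    match_tol: float = 0.01,
) -> pd.DataFrame:
    """Histogram of within-group pairwise |delta m/z| values.

    All pairwise absolute mass differences within each group are binned
    at ``bin_width`` Da; the ``top_k`` most frequent bins are returned
    with candidate elemental interpretations (O, CH2, H2, 13C, H2O ...)
    matched within ``match_tol`` Da of the bin's mean difference.
    """
    diffs = np.concatenate([g.pairwise_mass_differences() for g in groups]
                           ) if groups else np.array([])
    if diffs.size == 0:
        return pd.DataFrame(columns=["delta_mz", "count", "label"])
    bins = np.round(diffs / bin_width).astype(int)
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        center = float(diffs[sel].mean())
        label = ""
        best = match_tol
        for name, d in MASS_DELTA_TABLE.items():
            if abs(center - d) < best:
                best = abs(center - d)
                label = name
        rows.append({"delta_mz": center, "count": int(sel.sum()), "label": label})
    out = pd.DataFrame(rows).sort_values("count", ascending=False, kind="stable")
    return out.head(top_k).reset_index(drop=True)


def univariate_association(
    matrix,
    covariate: pd.Series,
    kind: str = "categorical",
) -> pd.DataFrame:
    """Per-feature association tests against one demographic covariate.

    Categorical (binary) covariates use the two-sided Mann-Whitney
    rank-sum test; continuous covariates the Spearman correlation test.
    Returns a frame with columns p, direction (sign of the effect:
    median difference or Spearman rho) and significant (p < 0.05, raw).
    Constant features get missing p.
    """
    vals = matrix.values if hasattr(matrix, "values") and isinstance(
        getattr(matrix, "values"), pd.DataFrame) else pd.DataFrame(matrix)
    cov = covariate.loc[vals.columns]
    if cov.isna().any():
        raise ValueError("covariate must be complete for all participants")
    rows = []
    if kind == "categorical":
        levels = sorted(cov.unique())
        if len(levels) < 2:
            raise ValueError("categorical covariate has a single level")
        if len(levels) > 2:
            raise ValueError("only binary categorical covariates are supported")
        g0 = cov == levels[0]
        for mzv, row in vals.iterrows():
            x = row[g0.values].to_numpy(dtype=float)
            y = row[~g0.values].to_numpy(dtype=float)
            if np.nanstd(row.to_numpy(dtype=float)) == 0:
                rows.append((mzv, np.nan, 0.0))
                continue
            p = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
            rows.append((mzv, p, float(np.sign(np.median(y) - np.median(x)))))
    elif kind == "continuous":
        c = cov.to_numpy(dtype=float)
        for mzv, row in vals.iterrows():
            v = row.to_numpy(dtype=float)
            if np.nanstd(v) == 0:
                rows.append((mzv, np.nan, 0.0))
                continue
            rho, p = spearmanr(v, c)
            rows.append((mzv, float(p), float(np.sign(rho))))
    else:
        raise ValueError(f"unknown covariate kind {kind!r}")
    out = pd.DataFrame(rows, columns=["mz", "p", "direction"]).set_index("mz")
    out["significant"] = out["p"] < 0.05
    return out


def pca_scores(matrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Participant scores on the first two principal components.

    Features are column-standardised (z-scored across participants)
    before the decomposition; zero-variance features are dropped.
    Returns (scores frame indexed by participant, explained variance
    ratios).
    """
    vals = matrix.values if hasattr(matrix, "values") and isinstance(
        getattr(matrix, "values"), pd.DataFrame) else pd.DataFrame(matrix)
    x = vals.to_numpy(dtype=float).T  # participants x features
    sd = x.std(axis=0)
    x = x[:, sd > 0]
    if x.shape[1] < 2:
        raise ValueError("need >= 2 non-constant features for PCA")
    x = (x - x.mean(axis=0)) / x[:, :].std(axis=0)
    n_comp = min(2, x.shape[0], x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(x)
    frame = pd.DataFrame(scores, index=vals.columns,
                         columns=[f"PC{i + 1}" for i in range(n_comp)])
    return frame, pca.explained_variance_ratio_
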