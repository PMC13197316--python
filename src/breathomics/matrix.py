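"""Cohort matrix assembly: presence/significance filtering, left-censored
imputation, and 13C isotopologue identification and removal.

The retention rule mirrors untargeted breathomics practice: a feature is
kept only when detected in more than 30% of participants AND
significantly higher during exhalation than background in more than 30%
of samples (both strict inequalities).  Remaining missing cells are
imputed by probabilistic minimum imputation (MinProb): draws from a
normal centred on a low quantile of each participant's observed values.
Isotopologues are then recognised by the 13C mass difference
(~1.00335 Da), strong across-participant correlation with their parent,
and an abundance ratio consistent with the parent's carbon count (or
below 20% when no formula is available), and removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ImputationError
from .annotate import AnnotationHit, parse_formula
from .phases import FeatureQuant
from .traces import CohortFeatureIndex

logger = logging.getLogger(__name__)

__all__ = ["CohortMatrix", "IsotopePair", "select_quants", "filter_features",
           "impute_minprob", "find_isotopes", "remove_isotopes", "C13_DELTA"]

C13_DELTA = 1.0033548378


@dataclass
class CohortMatrix:
    """Features x participants intensity table with missingness.

    ``values`` has a float m/z index and one column per participant;
    NaN marks a missing cell.  ``signif`` flags cells whose feature was
    significantly exhalation-enriched in that participant.
    """

    values: pd.DataFrame
    signif: pd.DataFrame | None = None
    isotope_flags: pd.Series | None = None

    def __post_init__(self):
        if self.signif is not None and self.signif.shape != self.values.shape:
            raise ValueError("signif flags must match the value matrix shape")

    @property
    def mz(self) -> np.ndarray:
        return self.values.index.to_numpy(dtype=float)

    @property
    def participants(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class IsotopePair:
    parent_mz: float
    isotope_mz: float
    correlation: float
    median_ratio: float
    rule: str  # "formula" or "ratio"
    n_carbon: int | None = None


def select_quants(
    index: CohortFeatureIndex,
    quants: dict[str, list[FeatureQuant | None]],
) -> dict[tuple[int, str], FeatureQuant]:
    """Pick, per (cohort feature, participant), the participant's most
    intense contributing quantification.

    "Detected in a participant" means the participant contributed at
    least one trace with a finite exhaled mean.
    """
    out: dict[tuple[int, str], FeatureQuant] = {}
    for fi in range(index.n_features):
        for pid, trace_ids in index.source_traces[fi].items():
            best: FeatureQuant | None = None
            for ti in trace_ids:
                q = quants[pid][ti]
                if q is None or not np.isfinite(q.exhaled_mean):
                    continue
                if best is None or q.exhaled_mean > best.exhaled_mean:
                    best = q
            if best is not None:
                out[(fi, pid)] = best
    return out


def filter_features(
    index: CohortFeatureIndex,
    quants: dict[str, list[FeatureQuant | None]],
    presence_frac: float = 0.3,
    signif_frac: float = 0.3,
    alpha: float = 0.05,
) -> CohortMatrix:
    """Build the cohort matrix and apply the presence/significance filter.

    Parameters
    ----------
    index : cohort-aligned feature index (from :func:`align_cohort`).
    quants : per participant, quantifications aligned with that
        participant's own feature list (the lists ``align_cohort`` saw).
    presence_frac, signif_frac : strict lower bounds on the fraction of
        participants detecting the feature / showing p < alpha.

    A feature survives iff presence fraction > ``presence_frac`` and
    significant fraction > ``signif_frac`` (strict: exactly 30% is
    dropped).  Cell values are background-subtracted exhaled means; cells
    of absent participants are NaN.
    """
    if not 0.0 < presence_frac < 1.0 or not 0.0 < signif_frac < 1.0:
        raise ValueError("fractions must be in (0, 1)")
    pids = list(index.presence.columns)
    n = len(pids)
    values = np.full((index.n_features, n), np.nan)
    signif = np.zeros((index.n_features, n), dtype=bool)
    col_of = {p: k for k, p in enumerate(pids)}
    for (fi, pid), best in select_quants(index, quants).items():
        col = col_of[pid]
        values[fi, col] = best.background_subtracted
        signif[fi, col] = best.p_exh_vs_bg is not None and best.p_exh_vs_bg < alpha
    present = ~np.isnan(values)
    keep = (present.mean(axis=1) > presence_frac) & (signif.mean(axis=1) > signif_frac)
    logger.info("filter_features: %d/%d features retained (presence > %.0f%%, "
                "significant > %.0f%%)", keep.sum(), index.n_features,
                100 * presence_frac, 100 * signif_frac)
    idx = pd.Index(index.mz[keep], name="mz")
    return CohortMatrix(
        values=pd.DataFrame(values[keep], index=idx, columns=pids),
        signif=pd.DataFrame(signif[keep], index=idx, columns=pids),
    )


def impute_minprob(
    matrix: CohortMatrix,
    quantile_q: float = 0.01,
    sd_scale: float = 1.0,
    seed: int = 0,
) -> CohortMatrix:
    """Probabilistic minimum imputation of missing cells.

    Per participant, missing values are drawn from a normal centred on
    the ``quantile_q``-th quantile of that participant's observed values,
    with sd = ``sd_scale`` x the sd of the observed values below the
    participant's median, truncated at zero.  Seeded and reproducible.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = matrix.values.copy()
    for col in out.columns:
        v = out[col]
        obs = v.dropna().to_numpy()
        if obs.size == 0:
            raise ImputationError(f"participant {col!r} has no observed values")
        miss = v.isna()
        if not miss.any():
            continue
        mu = float(np.quantile(obs, quantile_q))
        low = obs[obs < np.median(obs)]
        sd = float(sd_scale * (low.std(ddof=1) if low.size >= 2 else obs.std(ddof=1)))
        if not np.isfinite(sd):
            sd = 0.0
        draws = np.clip(rng.normal(mu, sd, size=int(miss.sum())), 0.0, None)
        out.loc[miss, col] = draws
    return CohortMatrix(values=out, signif=matrix.signif,
                        isotope_flags=matrix.isotope_flags)


def _carbon_counts(annotations: list[AnnotationHit] | None) -> dict[float, int]:
    """Best-hit carbon count per annotated feature m/z."""
    out: dict[float, int] = {}
    if not annotations:
        return out
    for hit in sorted(annotations, key=lambda h: abs(h.ppm_error)):
        if hit.feature_mz not in out:
            out[hit.feature_mz] = parse_formula(hit.compound.formula)["C"]
    return out


def find_isotopes(
    matrix: CohortMatrix,
    annotations: list[AnnotationHit] | None = None,
    delta: float = C13_DELTA,
    tol_ppm: float = 10.0,
    r_min: float = 0.8,
    ratio_max: float = 0.20,
    isotope_abundance_per_C: float = 0.0107,
    ratio_rel_tol: float = 0.5,
) -> list[IsotopePair]:
    """Identify 13C isotopologue features.

    A candidate pair (parent f, isotope g) satisfies
    ``mz(g) - mz(f) = delta`` within ``tol_ppm`` (relative to the parent
    m/z) and median intensity(g) < median intensity(f).  The pair is
    confirmed iff the across-participant Pearson correlation is
    >= ``r_min`` AND either the parent has a formula annotation with nC
    carbons and the median ratio g/f lies within +-``ratio_rel_tol`` of
    nC x ``isotope_abundance_per_C``, or no formula is available and the
    median ratio is below ``ratio_max``.
    """
    mz = matrix.mz
    vals = matrix.values
    n_c = _carbon_counts(annotations)
    pairs: list[IsotopePair] = []
    for i, m_parent in enumerate(mz):
        tol = tol_ppm * 1e-6 * m_parent
        target = m_parent + delta
        js = np.flatnonzero(np.abs(mz - target) <= tol)
        for j in js:
            f = vals.iloc[i]
            g = vals.iloc[j]
            if np.nanmedian(g.to_numpy()) >= np.nanmedian(f.to_numpy()):
                continue
            both = f.notna() & g.notna()
            if both.sum() < 3:
                continue
            r = float(np.corrcoef(f[both], g[both])[0, 1])
            if not np.isfinite(r) or r < r_min:
                continue
            ratio = float(np.median(g[both] / f[both]))
            nc = n_c.get(float(m_parent))
            if nc is not None and nc > 0:
                expected = nc * isotope_abundance_per_C
                ok = abs(ratio - expected) <= ratio_rel_tol * expected
                rule = "formula"
            else:
                ok = ratio < ratio_max
                rule = "ratio"
            if ok:
                pairs.append(IsotopePair(float(m_parent), float(mz[j]), r, ratio,
                                         rule, nc))
    return pairs


def remove_isotopes(matrix: CohortMatrix, pairs: list[IsotopePair]) -> CohortMatrix:
    """Drop confirmed isotopologue features; parents are retained.

    Idempotent: removing an already-removed feature is a no-op.
    """
    iso_mz = {p.isotope_mz for p in pairs}
    keep = [m for m in matrix.values.index if float(m) not in iso_mz]
    removed = matrix.n_features - len(keep)
    if removed:
        logger.info("remove_isotopes: %d isotopologue feature(s) removed", removed)
    flags = pd.Series([float(m) in iso_mz for m in matrix.values.index],
                      index=matrix.values.index)
    return CohortMatrix(
        values=matrix.values.loc[keep],
        signif=matrix.signif.loc[keep] if matrix.signif is not None else None,
        isotope_flags=flags,
    )
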