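"""Cohort matrix filtering, MinProb imputation and isotopologue removal."""

import numpy as np
import pandas as pd
import pytest

import breathomics as b
from breathomics.errors import ImputationError
from breathomics.matrix import (C13_DELTA, CohortMatrix, filter_features,
                                find_isotopes, impute_minprob, remove_isotopes)
from breathomics.phases import FeatureQuant
from breathomics.traces import CohortFeatureIndex


def _quant(mean=10.0, p=0.001):
    pm = np.full(3, mean)
    return FeatureQuant(pm, mean, 1.0, p, max(mean - 1.0, 0.0))


def _index_and_quants(n_present, n_signif, n_participants=40):
    """One feature observed by the first n_present participants,
    significant for the first n_signif of those."""
    pids = [f"P{i:03d}" for i in range(n_participants)]
    presence = pd.DataFrame(
        [[i < n_present for i in range(n_participants)]], columns=pids)
    sources = [{pids[i]: [0] for i in range(n_present)}]
    index = CohortFeatureIndex(mz=np.array([100.0]), presence=presence,
                               source_traces=sources)
    quants = {}
    for i, pid in enumerate(pids):
        p = 0.001 if i < n_signif else 0.9
        quants[pid] = [_quant(p=p)] if i < n_present else []
    return index, quants


@pytest.mark.parametrize("n_present,n_signif,kept", [
    (12, 12, False),   # exactly 30% presence: strict > drops it
    (13, 13, True),    # just over 30% on both criteria
    (40, 12, False),   # ubiquitous but not exhalation-significant enough
])
def test_filter_boundary_semantics(n_present, n_signif, kept):
    index, quants = _index_and_quants(n_present, n_signif)
    cm = filter_features(index, quants)
    assert cm.n_features == (1 if kept else 0)


def test_filter_monotone_in_thresholds():
    index, quants = _index_and_quants(20, 20)
    n = [filter_features(index, quants, presence_frac=f, signif_frac=f).n_features
         for f in (0.1, 0.3, 0.49, 0.51)]
    assert n == sorted(n, reverse=True)


def test_ambient_compounds_filtered_out(small_cohort, small_result):
    _, _, truth = small_cohort
    _, res = small_result
    final = set(np.round(res.matrix.mz, 3))
    for amb in truth.ambient_mz:
        assert round(amb, 3) not in final
    for exh in truth.exhaled_mz:
        assert round(exh, 3) in final


def _matrix_with_missing(seed=0):
    rng = np.random.default_rng(seed)
    vals = pd.DataFrame(rng.lognormal(10, 1, size=(30, 8)),
                        index=pd.Index(np.linspace(60, 290, 30), name="mz"),
                        columns=[f"P{i}" for i in range(8)])
    vals.iloc[::4, 0] = np.nan
    vals.iloc[1::5, 3] = np.nan
    return CohortMatrix(values=vals)


def test_impute_no_missing_is_identity():
    cm = _matrix_with_missing()
    full = CohortMatrix(values=cm.values.dropna())
    out = impute_minprob(full, seed=1)
    pd.testing.assert_frame_equal(out.values, full.values)


def _censored_matrix(seed=0):
    """Left-censored-shaped intensities: a tight low cluster near the
    detection floor and a broad high cluster, as in real breath data."""
    rng = np.random.default_rng(seed)
    low = rng.normal(100.0, 5.0, size=(15, 8))
    high = rng.lognormal(9, 0.5, size=(15, 8))
    vals = pd.DataFrame(np.vstack([low, high]),
                        index=pd.Index(np.linspace(60, 290, 30), name="mz"),
                        columns=[f"P{i}" for i in range(8)])
    vals.iloc[::4, 0] = np.nan
    vals.iloc[1::5, 3] = np.nan
    return CohortMatrix(values=vals)


def test_imputed_values_below_participant_median():
    cm = _censored_matrix()
    for seed in range(100):
        out = impute_minprob(cm, seed=seed)
        for col in cm.values.columns:
            miss = cm.values[col].isna()
            if not miss.any():
                continue
            med = cm.values[col].median(skipna=True)
            assert (out.values.loc[miss, col] < med).all()
            assert (out.values.loc[miss, col] >= 0).all()


def test_impute_deterministic_per_seed():
    cm = _matrix_with_missing()
    a = impute_minprob(cm, seed=7).values
    z = impute_minprob(cm, seed=7).values
    pd.testing.assert_frame_equal(a, z)
    assert not a.equals(impute_minprob(cm, seed=8).values)


def test_impute_all_missing_participant_raises():
    cm = _matrix_with_missing()
    cm.values.iloc[:, 2] = np.nan
    with pytest.raises(ImputationError):
        impute_minprob(cm)


def _isotope_matrix(rng, ratio=3 * 0.0107, r_break=False):
    """Parent at 59.0491 with a 13C twin; one uncorrelated decoy pair."""
    n = 24
    parent = rng.lognormal(12, 0.6, n)
    iso = parent * ratio * (1 + (rng.uniform(-1, 1, n) if r_break else 0))
    decoy_a = rng.lognormal(12, 0.6, n)
    decoy_b = rng.lognormal(10, 0.6, n)  # same spacing, independent
    vals = pd.DataFrame(
        [parent, iso, decoy_a, decoy_b],
        index=pd.Index([59.0491, 59.0491 + C13_DELTA,
                        150.0, 150.0 + C13_DELTA], name="mz"),
        columns=[f"P{i}" for i in range(n)],
    )
    return CohortMatrix(values=vals)


def test_carbon13_pair_flagged_without_formula(rng):
    cm = _isotope_matrix(rng)
    pairs = find_isotopes(cm)
    assert [(round(p.parent_mz, 4), round(p.isotope_mz, 4)) for p in pairs] == [
        (59.0491, round(59.0491 + C13_DELTA, 4))]
    assert pairs[0].rule == "ratio"


def test_uncorrelated_pair_not_flagged(rng):
    cm = _isotope_matrix(rng, r_break=True)
    pairs = find_isotopes(cm)
    assert all(round(p.parent_mz, 1) != 150.0 for p in pairs)


def test_formula_rule_on_high_carbon_compound(rng):
    """A C10 compound has an isotope ratio ~0.107, above the 20% -free
    threshold's comfort zone but consistent with its formula."""
    n = 24
    parent = rng.lognormal(12, 0.6, n)
    ratio = 10 * 0.0107
    vals = pd.DataFrame(
        [parent, parent * ratio],
        index=pd.Index([137.1325, 137.1325 + C13_DELTA], name="mz"),
        columns=[f"P{i}" for i in range(n)],
    )
    cm = CohortMatrix(values=vals)
    db = [b.CompoundRecord("monoterpene", "C10H16", "HMDB", "1")]
    hits = b.annotate(cm.mz, db, ["[M+H]+"], tol_ppm=10)
    pairs = find_isotopes(cm, hits)
    assert len(pairs) == 1 and pairs[0].rule == "formula" and pairs[0].n_carbon == 10


def test_remove_isotopes_empty_and_idempotent(rng):
    cm = _isotope_matrix(rng)
    assert remove_isotopes(cm, []).n_features == cm.n_features
    pairs = find_isotopes(cm)
    once = remove_isotopes(cm, pairs)
    twice = remove_isotopes(once, pairs)
    assert once.n_features == twice.n_features == cm.n_features - 1


def test_all_planted_isotopes_removed_no_parents(small_cohort, small_result):
    _, _, truth = small_cohort
    _, res = small_result
    final = set(np.round(res.matrix.mz, 3))
    for parent, iso in truth.isotope_pairs:
        assert round(iso, 3) not in final
        assert round(parent, 3) in final
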