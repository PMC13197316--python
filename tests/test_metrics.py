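"""Reproducibility metrics, clustering, mass-difference census, statistics."""

import numpy as np
import pandas as pd
import pytest

from breathomics.metrics import (ClusterGroup, cosine_matrix, cv,
                                 group_mass_differences, hca_groups,
                                 inter_subject_cv, pca_scores,
                                 repro_across_exhalations,
                                 univariate_association, within_exhalation_cv)
from breathomics.phases import BreathPhaseSet
from breathomics.simulate import simulate_phase_means
from breathomics.traces import IonTrace


# ---------------------------------------------------------------- cv ------

def test_cv_examples():
    assert cv([5, 5, 5]) == 0.0
    assert cv([1, 2, 3]) == pytest.approx(0.5)  # sd 1, mean 2
    assert np.isnan(cv([0, 0, 0]))
    assert np.isnan(cv([4]))


def test_cv_matches_brute_force(rng):
    for _ in range(20):
        v = rng.lognormal(0, 1, size=rng.integers(2, 30))
        sd = np.sqrt(np.sum((v - v.mean()) ** 2) / (v.size - 1))
        assert cv(v) == pytest.approx(sd / v.mean(), rel=1e-12)


def test_repro_across_exhalations_recovery():
    pm = simulate_phase_means(n_features=500, n_participants=1,
                              across_cv=0.10, between_cv=0.0, seed=5)
    _, med, iqr = repro_across_exhalations(pm)
    assert med == pytest.approx(0.10, abs=0.01)
    assert iqr >= 0


def test_repro_single_phase_missing():
    cvs, med, _ = repro_across_exhalations(np.ones((4, 1, 1)))
    assert np.all(np.isnan(cvs)) and np.isnan(med)


# ------------------------------------------------- within-exhalation -----

def _phase_set():
    return BreathPhaseSet([(0, 100), (100, 200), (200, 300)], [(310, 400)])


def test_within_exhalation_constant_trace():
    t = np.arange(0, 400, 1.0)
    trace = IonTrace(100.0, t, np.full(t.size, 9.0), 1.0)
    assert within_exhalation_cv(trace, _phase_set()) == 0.0


def test_within_exhalation_sinusoid_closed_form():
    """CV of mu + a sin(wt) over whole periods is (a/mu)/sqrt(2)."""
    t = np.arange(0, 400, 0.5)
    mu, a = 50.0, 5.0
    x = mu + a * np.sin(2 * np.pi * t / 10.0)
    got = within_exhalation_cv(IonTrace(100.0, t, x, 1.0), _phase_set())
    assert got == pytest.approx((a / mu) / np.sqrt(2), rel=0.02)


def test_within_exhalation_skips_degenerate_phase():
    t = np.arange(0, 400, 1.0)
    x = np.full(t.size, 3.0)
    phases = BreathPhaseSet([(0, 100), (100, 200), (250, 250.5)], [(310, 400)])
    assert within_exhalation_cv(IonTrace(100.0, t, x, 1.0), phases) == 0.0


# ----------------------------------------------------------- cosine ------

def test_cosine_identical_and_orthogonal():
    m = cosine_matrix([[1, 2, 3], [1, 2, 3], [2, 4, 6]])
    np.testing.assert_allclose(m, 1.0)
    m = cosine_matrix([[1, 0], [0, 1]])
    np.testing.assert_allclose(m, [[1, 0], [0, 1]], atol=1e-12)


def test_cosine_hand_computed():
    m = cosine_matrix([[1, 0, 1], [1, 1, 0]])
    assert m[0, 1] == pytest.approx(0.5)


def test_cosine_properties(rng):
    u = rng.standard_normal((4, 30))
    m = cosine_matrix(u)
    np.testing.assert_allclose(m, m.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(m), 1.0)
    scaled = u * rng.uniform(0.1, 10, size=(4, 1))
    np.testing.assert_allclose(cosine_matrix(scaled), m, atol=1e-10)
    # brute-force oracle
    for i in range(4):
        for j in range(4):
            ref = np.dot(u[i], u[j]) / (np.linalg.norm(u[i]) * np.linalg.norm(u[j]))
            assert m[i, j] == pytest.approx(ref, abs=1e-10)


def test_cosine_zero_vector_missing():
    m = cosine_matrix([[0, 0, 0], [1, 2, 3], [3, 2, 1]])
    assert np.isnan(m[0, 1]) and np.isnan(m[1, 0])
    assert m[0, 0] == 1.0


# ----------------------------------------------------- inter-subject -----

def test_inter_subject_identical_participants():
    vals = pd.DataFrame(np.tile([[5.0], [9.0]], (1, 6)))
    mean_cv, _, per = inter_subject_cv(vals)
    assert mean_cv == 0.0


def test_inter_subject_needs_two_participants():
    with pytest.raises(ValueError):
        inter_subject_cv(pd.DataFrame({"P1": [1.0, 2.0]}))


def test_inter_subject_planted_recovery():
    pm = simulate_phase_means(n_features=200, n_participants=40,
                              across_cv=0.0, between_cv=0.70, seed=11)
    mean_cv, sd_cv, _ = inter_subject_cv(pd.DataFrame(pm.mean(axis=2)))
    assert mean_cv == pytest.approx(0.70, abs=0.05)


def test_inter_subject_matches_brute_force(rng):
    vals = pd.DataFrame(rng.lognormal(8, 1, size=(20, 12)))
    mean_cv, sd_cv, per = inter_subject_cv(vals)
    ref = [np.std(row, ddof=1) / np.mean(row) for row in vals.to_numpy()]
    assert mean_cv == pytest.approx(np.mean(ref), rel=1e-12)
    assert sd_cv == pytest.approx(np.std(ref, ddof=1), rel=1e-12)


# ----------------------------------------------------------- HCA ---------

def _block_matrix(rng, n_blocks=3, per_block=5, n_noise=6, n_obs=40):
    rows, mz = [], []
    m0 = 60.0
    for k in range(n_blocks):
        latent = rng.standard_normal(n_obs)
        for j in range(per_block):
            rows.append(10 + latent + 0.01 * rng.standard_normal(n_obs))
            mz.append(m0 + 20 * k + j * 1.1)
    for j in range(n_noise):
        rows.append(10 + rng.standard_normal(n_obs))
        mz.append(200.0 + j * 3.3)
    return pd.DataFrame(rows, index=pd.Index(mz, name="mz"))


def test_hca_recovers_planted_blocks(rng):
    df = _block_matrix(rng)
    groups, unclustered = hca_groups(df, r_threshold=0.8)
    assert len(groups) == 3
    assert sorted(g.size for g in groups) == [5, 5, 5]
    assert len(unclustered) == 6
    for g in groups:
        assert g.mean_correlation > 0.8


def test_hca_iid_noise_yields_no_groups(rng):
    df = pd.DataFrame(rng.standard_normal((30, 60)),
                      index=pd.Index(np.linspace(60, 290, 30), name="mz"))
    groups, unclustered = hca_groups(df, r_threshold=0.8)
    assert groups == []
    assert len(unclustered) == 30


def test_hca_duplicate_pair(rng):
    base = rng.standard_normal(30)
    df = pd.DataFrame([base, base.copy(), rng.standard_normal(30),
                       rng.standard_normal(30)],
                      index=pd.Index([100.0, 101.0, 150.0, 160.0], name="mz"))
    groups, _ = hca_groups(df)
    assert len(groups) == 1
    assert groups[0].size == 2 and groups[0].mean_correlation == pytest.approx(1.0)


def test_hca_group_audit_by_recomputation(rng):
    """Every retained group passes a direct mean-pairwise-r recomputation."""
    df = _block_matrix(rng, n_blocks=4, per_block=4, n_noise=8)
    groups, _ = hca_groups(df, r_threshold=0.8)
    arr = df.to_numpy()
    mz = df.index.to_numpy()
    for g in groups:
        idx = [int(np.argmin(np.abs(mz - m))) for m in g.members]
        sub = np.corrcoef(arr[idx])
        mean_r = sub[np.triu_indices(len(idx), k=1)].mean()
        assert mean_r > 0.8
        assert mean_r == pytest.approx(g.mean_correlation, abs=1e-9)


def test_hca_excludes_constant_features(rng):
    df = _block_matrix(rng)
    df.iloc[0] = 42.0
    groups, unclustered = hca_groups(df)
    assert all(df.index[0] not in g.members for g in groups)


# ----------------------------------------- mass-difference census --------

def test_oxygen_difference_labelled():
    groups = [ClusterGroup([100.000, 115.995], 0.9)]
    out = group_mass_differences(groups)
    assert out.iloc[0]["label"] == "O"


def test_singleton_group_no_pairs():
    assert group_mass_differences([ClusterGroup([100.0], 1.0)]).empty


def test_homologous_series_mode_is_ch2():
    ladder = [100.0 + k * 14.01565 for k in range(6)]
    groups = [ClusterGroup(ladder, 0.95)]
    out = group_mass_differences(groups)
    assert out.iloc[0]["label"] == "CH2"
    assert out.iloc[0]["count"] == 5


# ------------------------------------------------ associations, PCA ------

def test_sex_effect_power_simulation(rng):
    n_feat, n_part = 60, 40
    sex = pd.Series(["F"] * 20 + ["M"] * 20, index=[f"P{i}" for i in range(n_part)])
    vals = rng.lognormal(8, 0.3, size=(n_feat, n_part))
    affected = list(range(3))  # 5% of features get a 2-fold sex effect
    vals[affected, 20:] *= 2.0
    df = pd.DataFrame(vals, index=pd.Index(np.linspace(60, 290, n_feat), name="mz"),
                      columns=sex.index)
    res = univariate_association(df, sex, kind="categorical")
    sig = set(np.flatnonzero(res["significant"].to_numpy()))
    assert set(affected) <= sig
    assert len(sig - set(affected)) <= 6  # false positives near alpha rate
    assert (res["direction"].iloc[affected] > 0).all()


def test_identical_groups_p_near_one(rng):
    cov = pd.Series(["A"] * 10 + ["B"] * 10, index=[f"P{i}" for i in range(20)])
    row = np.tile(rng.lognormal(8, 0.5, 10), 2)  # B group == A group exactly
    df = pd.DataFrame([row], index=pd.Index([100.0], name="mz"), columns=cov.index)
    res = univariate_association(df, cov, kind="categorical")
    assert res["p"].iloc[0] > 0.9


def test_constant_feature_missing_p():
    cov = pd.Series(["A", "B"] * 5, index=[f"P{i}" for i in range(10)])
    df = pd.DataFrame([[3.0] * 10], index=pd.Index([100.0], name="mz"),
                      columns=cov.index)
    res = univariate_association(df, cov, kind="categorical")
    assert np.isnan(res["p"].iloc[0])


def test_single_level_covariate_rejected():
    cov = pd.Series(["A"] * 6, index=[f"P{i}" for i in range(6)])
    df = pd.DataFrame([[1, 2, 3, 4, 5, 6.0]], index=pd.Index([100.0], name="mz"),
                      columns=cov.index)
    with pytest.raises(ValueError):
        univariate_association(df, cov, kind="categorical")


def test_spearman_monotone_association(rng):
    age = pd.Series(np.arange(20.0, 60.0), index=[f"P{i}" for i in range(40)])
    up = age.to_numpy() ** 1.5 + rng.normal(0, 5, 40)
    flat = rng.normal(50, 5, 40)
    df = pd.DataFrame([up, flat], index=pd.Index([100.0, 150.0], name="mz"),
                      columns=age.index)
    res = univariate_association(df, age, kind="continuous")
    assert res["p"].iloc[0] < 0.001 and res["direction"].iloc[0] > 0
    assert res["p"].iloc[1] > 0.05


def test_pca_one_dim_latent_factor(rng):
    latent = rng.standard_normal(30)
    vals = np.outer(np.linspace(1, 3, 10), latent) + 0.05 * rng.standard_normal((10, 30))
    df = pd.DataFrame(vals, index=pd.Index(np.linspace(60, 100, 10), name="mz"))
    scores, evr = pca_scores(df)
    assert evr[0] > 0.90
    assert scores.shape == (30, 2)


def test_pca_explained_variance_permutation_invariant(rng):
    df = pd.DataFrame(rng.standard_normal((8, 25)),
                      index=pd.Index(np.linspace(60, 100, 8), name="mz"))
    _, evr = pca_scores(df)
    perm = df.sample(frac=1, random_state=0)
    _, evr_p = pca_scores(perm)
    np.testing.assert_allclose(evr, evr_p, atol=1e-10)


def test_pca_single_feature_rejected():
    df = pd.DataFrame([[1.0, 2.0, 3.0]], index=pd.Index([100.0], name="mz"))
    with pytest.raises(ValueError):
        pca_scores(df)
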