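"""Synthetic acquisition generator: gates, determinism, planted truth."""

import numpy as np
import pytest

import breathomics as b
from breathomics.simulate import (C13_DELTA, SimulationConfig, _exact_cv_multipliers,
                                  default_planted_compounds, gate_profile,
                                  simulate_cohort, simulate_phase_means)


def _tiny_cfg(**kw):
    defaults = dict(n_participants=2, duration=60.0, scans_per_second=2.0, seed=9)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_every_truth_phase_list_has_three_intervals():
    runs, truth = simulate_cohort(_tiny_cfg(n_exhalations=3))
    for run in runs:
        expected = 0 if run.is_background else 3
        assert len(truth.phases[run.run_id]) == expected


def test_phase_intervals_ordered_and_in_range():
    cfg = _tiny_cfg()
    _, truth = simulate_cohort(cfg)
    for intervals in truth.phases.values():
        prev_end = 0.0
        for s, e in intervals:
            assert 0 <= s < e <= cfg.duration
            assert s >= prev_end
            prev_end = e


def test_noiseless_peaks_at_exact_theoretical_mz():
    runs, truth = simulate_cohort(_tiny_cfg(noise_sd=0, mass_drift_ppm=0,
                                            mz_jitter_ppm=0))
    planted = np.sort(np.array(truth.feature_mz
                               + [m for _, m in truth.isotope_pairs]))
    np.testing.assert_array_equal(runs[0].scans[0].mz, planted)


def test_same_seed_bit_identical():
    r1, _ = simulate_cohort(_tiny_cfg(noise_sd=50.0, mz_jitter_ppm=2.0))
    r2, _ = simulate_cohort(_tiny_cfg(noise_sd=50.0, mz_jitter_ppm=2.0))
    for a, z in zip(r1, r2):
        assert a.n_scans == z.n_scans
        for sa, sz in zip(a.scans, z.scans):
            np.testing.assert_array_equal(sa.mz, sz.mz)
            np.testing.assert_array_equal(sa.intensity, sz.intensity)


@pytest.mark.parametrize("bad", [
    dict(duration=0.0), dict(duration=-5.0), dict(scans_per_second=0.0),
    dict(n_exhalations=0), dict(isotope_abundance_per_C=1.5),
    dict(between_subject_cv=-0.1),
])
def test_invalid_config_rejected(bad):
    with pytest.raises(ValueError):
        _tiny_cfg(**bad)


def test_empty_compound_list_rejected():
    with pytest.raises(ValueError):
        _tiny_cfg(planted_compounds=[])


def test_isoprene_always_planted_as_exhaled():
    other = [b.PlantedCompound("acetone", "C3H6O", 1e5, exhaled=True)]
    cfg = _tiny_cfg(planted_compounds=other)
    assert any(c.formula == "C5H8" and c.exhaled for c in cfg.planted_compounds)


def test_gate_profile_values():
    phases = [(10.0, 20.0)]
    assert gate_profile(15.0, phases, rise_time=1.0) == 1.0
    assert gate_profile(50.0, phases, rise_time=1.0) == 0.0
    assert gate_profile(10.0, phases, rise_time=1.0) == pytest.approx(0.5)
    # rise_time=0 degenerates to the half-open boxcar
    t = np.array([9.99, 10.0, 15.0, 19.99, 20.0])
    np.testing.assert_array_equal(gate_profile(t, phases, 0.0), [0, 1, 1, 1, 0])


def test_gate_monotone_on_ramps():
    phases = [(10.0, 20.0)]
    up = gate_profile(np.linspace(9.5, 10.5, 50), phases, rise_time=1.0)
    down = gate_profile(np.linspace(19.5, 20.5, 50), phases, rise_time=1.0)
    assert np.all(np.diff(up) >= 0)
    assert np.all(np.diff(down) <= 0)


def test_isotopologue_mass_and_ratio():
    runs, truth = simulate_cohort(_tiny_cfg())
    for parent, iso in truth.isotope_pairs:
        assert iso - parent == pytest.approx(C13_DELTA, abs=1e-9)
    # ratio = nC x abundance within 1% relative, on a plateau scan
    cfg = _tiny_cfg()
    run = runs[0]
    (s0, e0) = truth.phases[run.run_id][0]
    mid = int(((s0 + e0) / 2) * cfg.scans_per_second)
    scan = run.scans[mid]
    by_mz = dict(zip(np.round(scan.mz, 5), scan.intensity))
    for comp in cfg.planted_compounds:
        if not comp.exhaled:
            continue
        parent_i = by_mz[round(comp.mz, 5)]
        iso_i = by_mz[round(comp.mz + C13_DELTA, 5)]
        expected = comp.n_carbon * cfg.isotope_abundance_per_C
        assert iso_i / parent_i == pytest.approx(expected, rel=0.01)


def test_background_run_has_no_gated_signal():
    runs, _ = simulate_cohort(_tiny_cfg())
    bg = [r for r in runs if r.is_background][0]
    # isoprene intensity constant across scans (no exhalation gate)
    iso_mz = b.adduct_mz("C5H8", "[M+H]+")
    vals = [s.intensity[np.argmin(np.abs(s.mz - iso_mz))] for s in bg.scans]
    assert np.ptp(vals) == 0.0


def test_exact_cv_multipliers_construction(rng):
    for n, cv_target in [(3, 0.1), (3, 0.25), (5, 0.4)]:
        m = _exact_cv_multipliers(n, cv_target, rng)
        assert m.mean() == pytest.approx(1.0, abs=1e-12)
        assert m.std(ddof=1) / m.mean() == pytest.approx(cv_target, abs=1e-10)
        assert np.all(m > 0)


def test_phase_mean_generator_plants_exact_dispersion():
    pm = simulate_phase_means(n_features=20, n_participants=10,
                              across_cv=0.10, between_cv=0.70, seed=3)
    assert pm.shape == (20, 10, 3)
    cv3 = pm.std(axis=2, ddof=1) / pm.mean(axis=2)
    np.testing.assert_allclose(cv3, 0.10, atol=1e-9)
    exhaled = pm.mean(axis=2)
    cvp = exhaled.std(axis=1, ddof=1) / exhaled.mean(axis=1)
    np.testing.assert_allclose(cvp, 0.70, atol=1e-7)


def test_default_compound_list_composition():
    comps = default_planted_compounds()
    assert sum(c.exhaled for c in comps) == 30
    assert sum(not c.exhaled for c in comps) == 10
    mz = np.sort([c.mz for c in comps])
    assert mz[0] >= 50 and mz[-1] <= 300
    # all planted ions resolvable at the default 8 ppm merge width
    assert np.all(np.diff(mz) / mz[:-1] > 8e-6)
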