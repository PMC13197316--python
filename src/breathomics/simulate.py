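"""Synthetic breath acquisitions with known ground truth.

The generator emulates a real-time breath profiling session: a 2-5 minute
full-scan acquisition at a few scans per second, during which a
participant performs three deep inhalations each followed by an
exhalation.  Exhaled compounds rise and plateau during each exhalation
(a raised-cosine-edged gate), ambient ions (siloxane lock masses, lab
contaminants) stay constant, every exhaled compound carries a first-order
13C isotopologue at nC x 1.07% of the parent, and the mass axis may carry
ppm-scale drift and jitter.  Each simulated cohort comes with a
:class:`SyntheticTruth` describing exactly what was planted, so every
downstream stage can be tested for planted-truth recovery without access
to clinical raw data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .annotate import ADDUCTS, adduct_mz, parse_formula
from .io import AcquisitionRun, CompoundRecord, ScanSpectrum, write_compound_db, write_mzml

__all__ = [
    "PlantedCompound",
    "SimulationConfig",
    "SyntheticTruth",
    "gate_profile",
    "simulate_cohort",
    "simulate_phase_means",
    "default_planted_compounds",
    "default_compound_db",
    "write_cohort",
    "C13_DELTA",
    "ISOPRENE_FORMULA",
]

C13_DELTA = 1.0033548378  # Da, 13C - 12C
ISOPRENE_FORMULA = "C5H8"


@dataclass(frozen=True)
class PlantedCompound:
    """One compound planted into the simulation."""

    name: str
    formula: str
    base_intensity: float
    exhaled: bool
    adduct: str = "[M+H]+"

    @property
    def mz(self) -> float:
        return adduct_mz(self.formula, ADDUCTS[self.adduct])

    @property
    def n_carbon(self) -> int:
        return parse_formula(self.formula)["C"]


# 30 exhaled breath VOCs (isoprene always included) + 10 ambient-only ions,
# the two siloxane lock masses among them.  Intensities in arbitrary units.
_EXHALED: list[tuple[str, str, float]] = [
    ("isoprene", "C5H8", 8.0e5),
    ("acetone", "C3H6O", 1.0e6),
    ("butane-2,3-dione", "C4H6O2", 4.0e5),
    ("butan-2-one", "C4H8O", 3.5e5),
    ("2-methylprop-2-enal", "C4H6O", 3.0e5),
    ("pentenoic acid", "C5H8O2", 2.5e5),
    ("1-(2-butoxyethoxy)ethanol", "C8H18O3", 2.5e5),
    ("2-methylfuran", "C5H6O", 2.2e5),
    ("butanenitrile", "C4H7N", 2.0e5),
    ("4-vinylcyclohexene", "C8H12", 2.0e5),
    ("cyclohexa-1,3-diene", "C6H8", 1.8e5),
    ("monoterpene", "C10H16", 1.8e5),
    ("camphor", "C10H16O", 1.6e5),
    ("pent-1-en-3-one", "C5H8O", 1.6e5),
    ("1,3-benzothiazole", "C7H5NS", 1.5e5),
    ("2-furylmethanol", "C5H6O2", 1.4e5),
    ("cyclopenta-1,3-diene", "C5H6", 1.4e5),
    ("hexanal", "C6H12O", 1.3e5),
    ("pentanal", "C5H10O", 1.2e5),
    ("heptan-2-one", "C7H14O", 1.2e5),
    ("benzaldehyde", "C7H6O", 1.1e5),
    ("phenol", "C6H6O", 1.1e5),
    ("octanal", "C8H16O", 1.0e5),
    ("indole", "C8H7N", 1.0e5),
    ("nonanal", "C9H18O", 9.0e4),
    ("decanal", "C10H20O", 9.0e4),
    ("hex-2-enal", "C6H10O", 8.0e4),
    ("toluene", "C7H8", 8.0e4),
    ("xylene", "C8H10", 7.0e4),
    ("trimethylbenzene", "C9H12", 7.0e4),
]
_AMBIENT: list[tuple[str, str, float]] = [
    ("hexamethyldisiloxane", "Si2C4H12O2", 6.0e5),  # lock mass ~149.045
    ("hexamethylcyclotrisiloxane", "Si3C6H18O3", 5.0e5),  # lock mass ~223.064
    ("octamethylcyclotetrasiloxane", "Si4C8H24O4", 2.0e5),
    ("dibutyl phthalate", "C16H22O4", 1.5e5),
    ("dimethyl sulfoxide", "C2H6OS", 1.5e5),
    ("acetic acid", "C2H4O2", 1.2e5),
    ("pyridine", "C5H5N", 1.2e5),
    ("dichlorobenzene", "C6H4Cl2", 1.0e5),
    ("styrene", "C8H8", 1.0e5),
    ("naphthalene", "C10H8", 1.0e5),
]


def default_planted_compounds() -> list[PlantedCompound]:
    """The default study conditions: 30 exhaled VOCs + 10 ambient ions."""
    out = [PlantedCompound(n, f, i, exhaled=True) for n, f, i in _EXHALED]
    out += [PlantedCompound(n, f, i, exhaled=False) for n, f, i in _AMBIENT]
    return out


def default_compound_db() -> list[CompoundRecord]:
    """A small compound table emulating an HMDB/HBDB export, covering the
    default planted compounds (synthetic stand-in, not a real DB excerpt)."""
    recs = []
    for i, (n, f, _) in enumerate(_EXHALED):
        recs.append(CompoundRecord(n, f, "HBDB", f"HBDB{i:04d}", True))
    for i, (n, f, _) in enumerate(_AMBIENT):
        recs.append(CompoundRecord(n, f, "HMDB", f"HMDB{i:07d}", False))
    return recs


@dataclass
class SimulationConfig:
    """Knobs of the synthetic acquisition generator.

    Defaults are the study conditions the pipeline is validated under:
    40 participants, three exhalations per acquisition, log-normal
    between-participant intensity variation (CV 0.7) and phase-to-phase
    jitter of CV 0.10.
    """

    n_participants: int = 40
    scans_per_second: float = 2.0
    duration: float = 180.0
    n_exhalations: int = 3
    planted_compounds: list[PlantedCompound] = field(default_factory=default_planted_compounds)
    isotope_abundance_per_C: float = 0.0107
    plant_isotopes: bool = True
    mass_drift_ppm: float = 0.0  # constant ppm offset
    mass_drift_ppm_per_mz: float = 0.0  # ppm per m/z unit (linear drift)
    mz_jitter_ppm: float = 0.0
    noise_sd: float = 0.0
    n_noise_peaks: int = 150
    between_subject_cv: float = 0.70
    across_exhalation_cv: float = 0.10
    ambient_fraction: float = 0.05  # residual ambient level of exhaled VOCs
    rise_time: float = 1.0  # s, exhalation gate edge width
    exhalation_width: float = 12.0  # s, plateau width of one exhalation
    mz_window: tuple[float, float] = (50.0, 300.0)
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.scans_per_second <= 0:
            raise ValueError("scans_per_second must be > 0")
        if self.n_exhalations < 1:
            raise ValueError("n_exhalations must be >= 1")
        if not self.planted_compounds:
            raise ValueError("planted_compounds must be non-empty")
        for name, v in [
            ("isotope_abundance_per_C", self.isotope_abundance_per_C),
            ("between_subject_cv", self.between_subject_cv),
            ("across_exhalation_cv", self.across_exhalation_cv),
            ("ambient_fraction", self.ambient_fraction),
        ]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not any(c.formula == ISOPRENE_FORMULA and c.exhaled
                   for c in self.planted_compounds):
            # isoprene is the phase marker; it is always planted as exhaled
            self.planted_compounds = [
                PlantedCompound("isoprene", ISOPRENE_FORMULA, 8.0e5, exhaled=True)
            ] + list(self.planted_compounds)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort."""

    phases: dict[str, list[tuple[float, float]]]  # run_id -> exhalation intervals
    feature_mz: list[float]  # theoretical adduct m/z of planted compounds
    exhaled_mz: list[float]  # subset that is exhalation-gated
    ambient_mz: list[float]
    isotope_pairs: list[tuple[float, float]]  # (parent m/z, isotopologue m/z)
    exhaled_intensity: pd.DataFrame  # true plateau intensity, mz x participant
    compounds: list[PlantedCompound] = field(default_factory=list)


def gate_profile(t, phases: list[tuple[float, float]], rise_time: float):
    """Smoothed-boxcar exhalation gate in [0, 1].

    0 well outside all phases, 1 on each plateau, raised-cosine ramps of
    width ``rise_time`` centred on the interval edges (the gate crosses
    0.5 exactly at the stated start/end).  ``rise_time=0`` degenerates to
    the half-open boxcar indicator of the intervals.
    """
    if rise_time < 0:
        raise ValueError("rise_time must be >= 0")
    t = np.asarray(t, dtype=float)
    g = np.zeros_like(t, dtype=float)
    h = rise_time / 2.0
    for s, e in phases:
        if rise_time == 0:
            g = np.maximum(g, ((t >= s) & (t < e)).astype(float))
            continue
        up = np.clip((t - (s - h)) / rise_time, 0.0, 1.0)
        down = np.clip(((e + h) - t) / rise_time, 0.0, 1.0)
        ramp_up = 0.5 * (1.0 - np.cos(np.pi * up))
        ramp_down = 0.5 * (1.0 - np.cos(np.pi * down))
        g = np.maximum(g, np.minimum(ramp_up, ramp_down))
    return g if g.ndim else float(g)


def _exact_cv_multipliers(n: int, cv: float, rng: np.random.Generator) -> np.ndarray:
    """n multipliers with sample mean exactly 1 and ddof=1 sample CV exactly
    ``cv``, random orientation in the zero-sum subspace.

    Planting the realized (not population) dispersion gives the recovery
    tests exact ground truth: the sample CV of the returned values is
    ``cv`` by construction, not in expectation.
    """
    if cv == 0 or n < 2:
        return np.ones(n)
    for _ in range(100):
        z = rng.standard_normal(n)
        z -= z.mean()
        norm = np.linalg.norm(z)
        if norm > 1e-12:
            break
    u = z / norm * np.sqrt(n - 1)  # ddof=1 sd of u is exactly 1
    m = 1.0 + cv * u
    if np.any(m <= 0):  # extremely lopsided orientation at large cv; redraw
        return _exact_cv_multipliers(n, cv, rng)
    return m


def _phase_layout(cfg: SimulationConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Evenly spaced exhalation plateaus with a small random shift."""
    k = cfg.n_exhalations
    width = min(cfg.exhalation_width, 0.6 * cfg.duration / (k + 1))
    phases = []
    for j in range(1, k + 1):
        center = cfg.duration * j / (k + 1) + rng.uniform(-2.0, 2.0)
        s = max(center - width / 2, cfg.rise_time)
        e = min(center + width / 2, cfg.duration - cfg.rise_time)
        phases.append((float(s), float(e)))
    return phases


def _run_scans(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    phases: list[tuple[float, float]],
    subject_factor: np.ndarray,
    phase_mult: np.ndarray,
) -> list[ScanSpectrum]:
    compounds = cfg.planted_compounds
    n_scans = max(2, int(round(cfg.duration * cfg.scans_per_second)))
    times = np.arange(n_scans) / cfg.scans_per_second

    theo = np.array([c.mz for c in compounds])
    exhaled = np.array([c.exhaled for c in compounds])
    base = np.array([c.base_intensity for c in compounds]) * subject_factor
    n_c = np.array([c.n_carbon for c in compounds])

    gate = gate_profile(times, phases, cfg.rise_time)
    # which exhalation each scan belongs to (nearest plateau), for jitter
    phase_idx = np.zeros(n_scans, dtype=int)
    if phases:
        centers = np.array([(s + e) / 2 for s, e in phases])
        phase_idx = np.argmin(np.abs(times[:, None] - centers[None, :]), axis=1)

    # per-scan per-compound intensity matrix (n_scans x n_compounds)
    amb = cfg.ambient_fraction
    pm = phase_mult[phase_idx] if phases else np.ones(n_scans)
    gated = amb + (1.0 - amb) * gate[:, None] * pm[:, None] if phases else np.full(
        (n_scans, 1), amb)
    inten = np.where(exhaled[None, :], base[None, :] * gated, base[None, :])

    drift = cfg.mass_drift_ppm + cfg.mass_drift_ppm_per_mz * theo  # ppm per peak

    scans = []
    for i in range(n_scans):
        mz = theo.copy()
        intensity = inten[i].copy()
        if cfg.plant_isotopes:
            iso_mz = theo[exhaled] + C13_DELTA
            iso_int = intensity[exhaled] * n_c[exhaled] * cfg.isotope_abundance_per_C
            mz = np.concatenate([mz, iso_mz])
            intensity = np.concatenate([intensity, iso_int])
            drift_i = np.concatenate([drift, cfg.mass_drift_ppm
                                      + cfg.mass_drift_ppm_per_mz * iso_mz])
        else:
            drift_i = drift
        mz = mz * (1.0 + drift_i * 1e-6)
        if cfg.mz_jitter_ppm > 0:
            mz = mz * (1.0 + cfg.mz_jitter_ppm * 1e-6 * rng.standard_normal(mz.size))
        if cfg.noise_sd > 0:
            intensity = intensity + cfg.noise_sd * rng.standard_normal(intensity.size)
            noise_mz = rng.uniform(*cfg.mz_window, size=cfg.n_noise_peaks)
            noise_int = np.abs(cfg.noise_sd * rng.standard_normal(cfg.n_noise_peaks))
            mz = np.concatenate([mz, noise_mz])
            intensity = np.concatenate([intensity, noise_int])
        intensity = np.clip(intensity, 0.0, None)
        keep = (mz >= cfg.mz_window[0]) & (mz <= cfg.mz_window[1])
        mz, intensity = mz[keep], intensity[keep]
        order = np.argsort(mz)
        mz, intensity = mz[order], intensity[order]
        # merge exact m/z collisions (possible only under extreme jitter)
        if mz.size > 1 and np.any(np.diff(mz) <= 0):
            uniq, inv = np.unique(mz, return_inverse=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inv, intensity)
            mz, intensity = uniq, summed
        scans.append(ScanSpectrum(float(times[i]), mz, intensity, centroided=True))
    return scans


def simulate_cohort(config: SimulationConfig) -> tuple[list[AcquisitionRun], SyntheticTruth]:
    """Simulate one acquisition per participant plus one background run.

    Returns the runs and the :class:`SyntheticTruth` with planted phase
    intervals, feature m/z lists, isotopologue pairs and true exhaled
    plateau intensities.  Identical seeds give bit-identical output; all
    randomness flows from ``config.seed`` through one spawned seed
    sequence per run.
    """
    cfg = config
    compounds = cfg.planted_compounds
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_participants + 1)

    exhaled_mz = [c.mz for c in compounds if c.exhaled]
    ambient_mz = [c.mz for c in compounds if not c.exhaled]
    iso_pairs = ([(c.mz, c.mz + C13_DELTA) for c in compounds if c.exhaled]
                 if cfg.plant_isotopes else [])

    runs: list[AcquisitionRun] = []
    phases_truth: dict[str, list[tuple[float, float]]] = {}
    exhaled_truth: dict[str, np.ndarray] = {}
    n_cmp = len(compounds)
    exhaled_mask = np.array([c.exhaled for c in compounds])
    sigma = float(np.sqrt(np.log1p(cfg.between_subject_cv ** 2)))

    for p in range(cfg.n_participants):
        rng = np.random.default_rng(children[p])
        pid = f"P{p + 1:03d}"
        phases = _phase_layout(cfg, rng)
        subject_factor = np.where(
            exhaled_mask, np.exp(sigma * rng.standard_normal(n_cmp)), 1.0)
        phase_mult = _exact_cv_multipliers(cfg.n_exhalations, cfg.across_exhalation_cv, rng)
        scans = _run_scans(cfg, rng, phases, subject_factor, phase_mult)
        run = AcquisitionRun(run_id=pid, participant_id=pid, scans=scans,
                             acquired_date=date(2023, 8, 16))
        runs.append(run)
        phases_truth[pid] = phases
        base = np.array([c.base_intensity for c in compounds]) * subject_factor
        exhaled_truth[pid] = base[exhaled_mask]

    rng = np.random.default_rng(children[-1])
    bg_scans = _run_scans(cfg, rng, [], np.ones(n_cmp), np.ones(cfg.n_exhalations))
    bg = AcquisitionRun(run_id="background_day1", participant_id="background",
                        scans=bg_scans, acquired_date=date(2023, 8, 16))
    runs.append(bg)
    phases_truth[bg.run_id] = []

    truth = SyntheticTruth(
        phases=phases_truth,
        feature_mz=[c.mz for c in compounds],
        exhaled_mz=exhaled_mz,
        ambient_mz=ambient_mz,
        isotope_pairs=iso_pairs,
        exhaled_intensity=pd.DataFrame(
            exhaled_truth, index=pd.Index(exhaled_mz, name="mz")),
        compounds=list(compounds),
    )
    return runs, truth


def simulate_phase_means(
    n_features: int = 500,
    n_participants: int = 40,
    across_cv: float = 0.10,
    between_cv: float = 0.70,
    seed: int = 0,
) -> np.ndarray:
    """Light-weight generator of per-phase mean intensities.

    Returns an array of shape ``(n_features, n_participants, 3)``: for
    each feature, log-normal between-participant levels with realized
    across-participant CV exactly ``between_cv`` (log-normal shape,
    per-feature exponent rescaling), and three per-exhalation means with
    realized ddof=1 CV exactly ``across_cv`` (random zero-sum
    orientation).  Used for metric-recovery validation, where exact
    planted dispersion gives the tests exact expected values.
    """
    from scipy.optimize import brentq

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    base = np.exp(rng.standard_normal(n_features))  # feature-level scale
    sigma = float(np.sqrt(np.log1p(between_cv ** 2)))
    out = np.empty((n_features, n_participants, 3))
    for f in range(n_features):
        z = rng.standard_normal(n_participants)
        z -= z.mean()

        def _cv(c):
            y = np.exp(c * sigma * z)
            return y.std(ddof=1) / y.mean() - between_cv

        if between_cv > 0:
            c = brentq(_cv, 1e-3, 20.0, xtol=1e-10)
            levels = base[f] * 1e5 * np.exp(c * sigma * z)
        else:
            levels = np.full(n_participants, base[f] * 1e5)
        for p in range(n_participants):
            mult = _exact_cv_multipliers(3, across_cv, rng)
            out[f, p] = levels[p] * mult
    return out


def write_cohort(
    runs: list[AcquisitionRun],
    truth: SyntheticTruth,
    config: SimulationConfig,
    outdir: str | Path,
) -> Path:
    """Write a simulated cohort to disk: one mzML per run, the truth
    tables (delimited), the compound table, and the config as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for run in runs:
        write_mzml(run, outdir / f"{run.run_id}.mzML")
    rows = []
    for c in truth.compounds:
        rows.append({"name": c.name, "formula": c.formula, "adduct": c.adduct,
                     "mz": c.mz, "base_intensity": c.base_intensity,
                     "exhaled": c.exhaled})
    pd.DataFrame(rows).to_csv(outdir / "truth_features.csv", index=False)
    ph = [{"run_id": rid, "start": s, "end": e}
          for rid, iv in truth.phases.items() for s, e in iv]
    pd.DataFrame(ph, columns=["run_id", "start", "end"]).to_csv(
        outdir / "truth_phases.csv", index=False)
    truth.exhaled_intensity.to_csv(outdir / "truth_exhaled_intensity.csv")
    write_compound_db(default_compound_db(), outdir / "compounds.csv")
    cfg = {k: v for k, v in vars(config).items() if k != "planted_compounds"}
    cfg["mz_window"] = list(config.mz_window)
    cfg["n_planted_compounds"] = len(config.planted_compounds)
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2))
    return outdir
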