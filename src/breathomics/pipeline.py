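"""End-to-end orchestration: mzML acquisitions -> cohort feature matrix,
annotations and metrics.

Stage order: recalibrate -> per-scan peak detection -> temporal traces ->
exhalation-phase detection on the isoprene trace -> per-phase
quantification -> cohort alignment -> presence/significance filtering ->
MinProb imputation -> isotopologue removal -> annotation -> metrics.
A participant whose run fails any per-run stage is quarantined (logged,
excluded) rather than aborting the cohort.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .annotate import ADDUCTS as _ADDUCTS, AnnotationHit
from .annotate import adduct_mz as _adduct_mz, annotate as _annotate
from .calibrate import apply_correction, default_references, fit_correction
from .errors import BreathomicsError, SchemaError
from .io import AcquisitionRun, CompoundRecord, read_compound_db, read_mzml, \
    write_feature_table
from .matrix import CohortMatrix, IsotopePair, filter_features, find_isotopes, \
    impute_minprob, remove_isotopes, select_quants
from .metrics import ClusterGroup, cv, group_mass_differences, hca_groups, \
    inter_subject_cv
from .peaks import detect_peaks
from .phases import BreathPhaseSet, FeatureQuant, detect_phases, quantify_feature
from .traces import IonTrace, align_cohort, build_traces

logger = logging.getLogger(__name__)

__all__ = ["PipelineParams", "PipelineConfig", "PipelineResult", "process_run",
           "process_cohort", "run_pipeline"]

ISOPRENE_MZ = _adduct_mz("C5H8", "[M+H]+")


class PipelineParams(BaseModel):
    """All tunable parameters of the processing pipeline."""

    model_config = ConfigDict(extra="forbid")

    calibrate: bool = True
    search_ppm: float = Field(30.0, gt=0)
    min_snr: float = 3.0
    min_prominence: float | None = None
    merge_ppm: float = Field(8.0, gt=0)
    min_support: float = Field(0.1, ge=0, le=1)
    cohort_merge_ppm: float = Field(8.0, gt=0)
    phase_frac: float = Field(0.3, gt=0, lt=1)
    min_phase_duration: float = Field(2.0, gt=0)
    merge_gap: float = Field(1.0, ge=0)
    test_method: str = "mannwhitney"
    presence_frac: float = Field(0.3, gt=0, lt=1)
    signif_frac: float = Field(0.3, gt=0, lt=1)
    alpha: float = Field(0.05, gt=0, lt=1)
    impute_q: float = Field(0.01, gt=0, lt=1)
    impute_sd_scale: float = Field(1.0, ge=0)
    tol_ppm: float = Field(10.0, gt=0)
    adducts: list[str] = Field(default_factory=lambda: list(_ADDUCTS))
    isotope_tol_ppm: float = Field(10.0, gt=0)
    isotope_r_min: float = Field(0.8, ge=-1, le=1)
    isotope_ratio_max: float = Field(0.20, gt=0, le=1)
    isotope_abundance_per_C: float = Field(0.0107, ge=0, le=1)
    hca_r_threshold: float = Field(0.8, ge=-1, le=1)
    mz_window: tuple[float, float] = (50.0, 300.0)
    seed: int = 0


class PipelineConfig(BaseModel):
    """Paths + parameters for a disk-based pipeline run."""

    model_config = ConfigDict(extra="forbid")

    mzml_paths: list[str]
    compound_db: str | None = None
    covariates: str | None = None
    outdir: str = "breathomics_out"
    params: PipelineParams = Field(default_factory=PipelineParams)


@dataclass
class RunResult:
    """Per-acquisition intermediate products."""

    run_id: str
    participant_id: str
    traces: list[IonTrace]
    phases: BreathPhaseSet | None
    quants: list[FeatureQuant | None]
    feature_mz: np.ndarray
    calibration_residual_ppm: float | None = None


@dataclass
class PipelineResult:
    """Cohort-level pipeline output."""

    matrix: CohortMatrix
    annotations: list[AnnotationHit]
    isotope_pairs: list[IsotopePair]
    runs: dict[str, RunResult]
    quarantined: dict[str, str]
    groups: list[ClusterGroup] = field(default_factory=list)
    unclustered: list[float] = field(default_factory=list)
    stage_counts: dict[str, float] = field(default_factory=dict)
    across_exhalation_cv_median: float = float("nan")
    inter_subject_cv_mean: float = float("nan")


def process_run(run: AcquisitionRun, params: PipelineParams) -> RunResult:
    """Process one acquisition up to per-phase quantification."""
    if params.calibrate:
        model = fit_correction(run, default_references(), params.search_ppm)
        run = apply_correction(run, model)
        resid = float(np.nanmedian(np.abs(model.residual_ppm.to_numpy())))
    else:
        resid = None
    per_scan = [detect_peaks(s, params.min_snr, params.min_prominence, i)
                for i, s in enumerate(run.scans)]
    traces = build_traces(per_scan, params.merge_ppm, params.min_support,
                          times=run.times)
    phases = None
    quants: list[FeatureQuant | None] = [None] * len(traces)
    if not run.is_background:
        iso = _nearest_trace(traces, ISOPRENE_MZ, params.merge_ppm)
        if iso is None:
            raise BreathomicsError(
                f"run {run.run_id!r}: no isoprene trace found for phase detection")
        phases = detect_phases(iso, params.phase_frac, params.min_phase_duration,
                               params.merge_gap)
        quants = []
        for tr in traces:
            try:
                quants.append(quantify_feature(tr, phases))
            except BreathomicsError:
                quants.append(None)
    return RunResult(
        run_id=run.run_id,
        participant_id=run.participant_id,
        traces=traces,
        phases=phases,
        quants=quants,
        feature_mz=np.array([t.consensus_mz for t in traces]),
        calibration_residual_ppm=resid,
    )


def _nearest_trace(traces: list[IonTrace], mz: float, tol_ppm: float) -> IonTrace | None:
    best, best_ppm = None, 2 * tol_ppm
    for t in traces:
        ppm = abs(t.consensus_mz - mz) / mz * 1e6
        if ppm <= tol_ppm and ppm < best_ppm:
            best, best_ppm = t, ppm
    return best


def process_cohort(
    runs: list[AcquisitionRun],
    compound_db: list[CompoundRecord] | None = None,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run the full pipeline on in-memory acquisitions.

    Background runs are processed (traces only) but excluded from the
    cohort matrix; participant runs that fail are quarantined with the
    error message recorded.
    """
    params = params or PipelineParams()
    run_results: dict[str, RunResult] = {}
    quarantined: dict[str, str] = {}
    for run in runs:
        try:
            run_results[run.run_id] = process_run(run, params)
        except BreathomicsError as exc:
            logger.warning("quarantining run %s: %s", run.run_id, exc)
            quarantined[run.run_id] = str(exc)
    participant_results = {r.participant_id: r for r in run_results.values()
                           if r.phases is not None}
    if not participant_results:
        raise BreathomicsError("all participant runs failed")

    index = align_cohort({pid: r.feature_mz for pid, r in participant_results.items()},
                         params.cohort_merge_ppm)
    quants = {pid: r.quants for pid, r in participant_results.items()}
    cm = filter_features(index, quants, params.presence_frac, params.signif_frac,
                         params.alpha)
    n_filtered = cm.n_features
    cm = impute_minprob(cm, params.impute_q, params.impute_sd_scale, params.seed)
    hits = (_annotate(cm.mz, compound_db, params.adducts, params.tol_ppm)
            if compound_db else [])
    pairs = find_isotopes(cm, hits, tol_ppm=params.isotope_tol_ppm,
                          r_min=params.isotope_r_min,
                          ratio_max=params.isotope_ratio_max,
                          isotope_abundance_per_C=params.isotope_abundance_per_C)
    cm = remove_isotopes(cm, pairs)
    final_hits = (_annotate(cm.mz, compound_db, params.adducts, params.tol_ppm)
                  if compound_db else [])

    # reproducibility metrics on the retained features
    selected = select_quants(index, quants)
    kept_pos = {float(m): i for i, m in enumerate(index.mz)}
    cvs = []
    for m in cm.mz:
        fi = kept_pos[float(m)]
        for pid in participant_results:
            q = selected.get((fi, pid))
            if q is not None:
                cvs.append(cv(q.per_phase_mean))
    cvs = np.asarray(cvs, dtype=float)
    across_cv = float(np.nanmedian(cvs)) if cvs.size else float("nan")
    if cm.n_features >= 1 and len(cm.participants) >= 2:
        inter_cv_mean = inter_subject_cv(cm)[0]
    else:
        inter_cv_mean = float("nan")

    groups: list[ClusterGroup] = []
    unclustered: list[float] = []
    if cm.n_features >= 3:
        try:
            groups, unclustered = hca_groups(cm, params.hca_r_threshold)
        except ValueError as exc:
            logger.warning("clustering skipped: %s", exc)

    counts = {
        "runs": len(runs),
        "runs_quarantined": len(quarantined),
        "participants": len(participant_results),
        "mean_traces_per_run": float(np.mean(
            [len(r.traces) for r in participant_results.values()])),
        "features_aligned": index.n_features,
        "features_after_filter": n_filtered,
        "isotopes_removed": n_filtered - cm.n_features,
        "features_final": cm.n_features,
        "annotation_hits": len(final_hits),
        "clusters": len(groups),
    }
    logger.info("pipeline counts: %s", counts)
    return PipelineResult(
        matrix=cm,
        annotations=final_hits,
        isotope_pairs=pairs,
        runs=run_results,
        quarantined=quarantined,
        groups=groups,
        unclustered=unclustered,
        stage_counts=counts,
        across_exhalation_cv_median=across_cv,
        inter_subject_cv_mean=inter_cv_mean,
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Disk-based pipeline entry point: read mzML inputs, process, and
    write the feature table, annotations, isotope list, metrics and
    per-stage counts into ``config.outdir``."""
    for p in config.mzml_paths:
        if not Path(p).exists():
            raise SchemaError(f"input path does not exist: {p}")
    runs = [read_mzml(p, mz_window=config.params.mz_window) for p in config.mzml_paths]
    db = read_compound_db(config.compound_db) if config.compound_db else None
    result = process_cohort(runs, db, config.params)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_feature_table(result.matrix, outdir / "feature_table.csv")
    pd.DataFrame(
        [{"feature_mz": h.feature_mz, "compound": h.compound.name,
          "formula": h.compound.formula, "source_db": h.compound.source_db,
          "adduct": h.adduct.name, "theoretical_mz": h.theoretical_mz,
          "ppm_error": h.ppm_error} for h in result.annotations]
    ).to_csv(outdir / "annotations.csv", index=False)
    pd.DataFrame(
        [{"parent_mz": p.parent_mz, "isotope_mz": p.isotope_mz,
          "correlation": p.correlation, "median_ratio": p.median_ratio,
          "rule": p.rule} for p in result.isotope_pairs]
    ).to_csv(outdir / "isotope_pairs.csv", index=False)
    pd.DataFrame(
        [{"run_id": r.run_id, "start": s, "end": e}
         for r in result.runs.values() if r.phases is not None
         for s, e in r.phases.exhalations]
    ).to_csv(outdir / "phases.csv", index=False)
    if result.groups:
        diffs = group_mass_differences(result.groups)
        diffs.to_csv(outdir / "group_mass_differences.csv", index=False)
    metrics = {
        "across_exhalation_cv_median": result.across_exhalation_cv_median,
        "inter_subject_cv_mean": result.inter_subject_cv_mean,
        "n_clusters": len(result.groups),
        "n_unclustered": len(result.unclustered),
    }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    (outdir / "counts.json").write_text(json.dumps(result.stage_counts, indent=2))
    if result.quarantined:
        (outdir / "quarantined.json").write_text(json.dumps(result.quarantined, indent=2))
    return outdir
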