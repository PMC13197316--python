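"""Per-scan mass-axis recalibration against known reference ions.

Direct-infusion breath spectra always contain isoprene and two ambient
siloxane ions; their theoretical m/z anchor a relative (ppm) correction
e(m/z) = a + b*m/z fitted per scan by least squares.  Three references
support at most an affine model; ppm-linear is the standard drift model
for Orbitrap-class analyzers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .annotate import adduct_mz
from .errors import CalibrationError
from .io import AcquisitionRun, ScanSpectrum

__all__ = ["CalibrationModel", "default_references", "fit_correction", "apply_correction"]


@dataclass
class CalibrationModel:
    """Per-scan relative mass correction e(m/z) = a + b*m/z, in ppm."""

    a: np.ndarray  # ppm offset per scan
    b: np.ndarray  # ppm per m/z unit per scan
    references: list[tuple[float, str]]
    residual_ppm: pd.DataFrame | None = None  # scan x reference residuals

    def correction_ppm(self, scan_index: int, mz: np.ndarray) -> np.ndarray:
        return self.a[scan_index] + self.b[scan_index] * np.asarray(mz)


def default_references() -> list[tuple[float, str]]:
    """Isoprene [M+H]+ and the two siloxane lock masses, from theory.

    The values are computed from the formulas (not the rounded printed
    numbers): ~69.0699, ~149.0449 and ~223.0637.
    """
    return [
        (adduct_mz("C5H8", "[M+H]+"), "isoprene [M+H]+"),
        (adduct_mz("Si2C4H12O2", "[M+H]+"), "hexamethyldisiloxane [M+H]+"),
        (adduct_mz("Si3C6H18O3", "[M+H]+"), "hexamethylcyclotrisiloxane [M+H]+"),
    ]


def _find_reference(scan: ScanSpectrum, ref_mz: float, search_ppm: float) -> float | None:
    """Most intense observed peak within ``search_ppm`` of ``ref_mz``."""
    tol = search_ppm * 1e-6 * ref_mz
    lo = np.searchsorted(scan.mz, ref_mz - tol, side="left")
    hi = np.searchsorted(scan.mz, ref_mz + tol, side="right")
    if hi <= lo:
        return None
    k = lo + int(np.argmax(scan.intensity[lo:hi]))
    return float(scan.mz[k])


def fit_correction(
    run: AcquisitionRun,
    refs: list[tuple[float, str]] | None = None,
    search_ppm: float = 30.0,
    per_scan: bool = True,
) -> CalibrationModel:
    """Fit the per-scan ppm correction from the reference ions.

    For each scan, the most intense peak within ``search_ppm`` of each
    reference is taken as its observed position; the relative errors are
    fitted by least squares.  With fewer than two references found the
    slope is fixed at 0; scans with no reference found inherit the
    nearest calibrated scan's model.  ``per_scan=False`` averages the
    fitted coefficients over the whole acquisition (block calibration).
    """
    if search_ppm <= 0:
        raise ValueError("search_ppm must be > 0")
    refs = refs if refs is not None else default_references()
    if not refs:
        raise ValueError("reference list must have >= 1 entry")
    n = run.n_scans
    a = np.full(n, np.nan)
    b = np.zeros(n)
    resid = np.full((n, len(refs)), np.nan)
    any_found = False
    for i, scan in enumerate(run.scans):
        obs_mz, theo_mz = [], []
        for j, (ref, _label) in enumerate(refs):
            found = _find_reference(scan, ref, search_ppm)
            if found is not None:
                obs_mz.append(found)
                theo_mz.append(ref)
                resid[i, j] = (found - ref) / ref * 1e6
        if not obs_mz:
            continue
        any_found = True
        err_ppm = (np.array(obs_mz) - np.array(theo_mz)) / np.array(theo_mz) * 1e6
        if len(obs_mz) >= 2:
            bi, ai = np.polyfit(theo_mz, err_ppm, 1)
            a[i], b[i] = ai, bi
        else:
            a[i], b[i] = float(err_ppm[0]), 0.0
    if not any_found:
        raise CalibrationError(
            f"no calibration reference found in any of {n} scans of run {run.run_id!r}")
    # scans with no reference inherit the nearest calibrated scan's model
    good = np.flatnonzero(~np.isnan(a))
    missing = np.flatnonzero(np.isnan(a))
    if missing.size:
        nearest = good[np.argmin(np.abs(missing[:, None] - good[None, :]), axis=1)]
        a[missing] = a[nearest]
        b[missing] = b[nearest]
    if not per_scan:
        a[:] = a.mean()
        b[:] = b.mean()
    labels = [lab for _, lab in refs]
    return CalibrationModel(a=a, b=b, references=list(refs),
                            residual_ppm=pd.DataFrame(resid, columns=labels))


def apply_correction(run: AcquisitionRun, model: CalibrationModel) -> AcquisitionRun:
    """Divide each scan's m/z axis by (1 + e(m/z)*1e-6).

    Monotone (order-preserving) for any |e| below ~1e3 ppm.
    """
    new_scans = []
    for i, scan in enumerate(run.scans):
        e = model.correction_ppm(i, scan.mz)
        new_scans.append(ScanSpectrum(scan.scan_time, scan.mz / (1.0 + e * 1e-6),
                                      scan.intensity.copy(), centroided=scan.centroided))
    return _dc_replace(run, scans=new_scans)
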