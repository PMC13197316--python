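"""Per-spectrum peak detection, centroiding and signal-to-noise estimation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io import ScanSpectrum

__all__ = ["Peak", "estimate_noise", "detect_peaks"]


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    snr: float
    scan_index: int = 0


def estimate_noise(spectrum: ScanSpectrum) -> tuple[float, float]:
    """Robust noise estimate of one spectrum.

    Returns ``(noise_level, noise_sd)`` with the level as the median
    intensity and the sd as 1.4826x the median absolute deviation, both
    insensitive to a minority of genuine peaks riding on the baseline.
    """
    inten = spectrum.intensity
    if inten.size < 8:
        raise ValueError(f"need >= 8 data points to estimate noise, got {inten.size}")
    level = float(np.median(inten))
    sd = float(1.4826 * np.median(np.abs(inten - level)))
    return level, sd


def detect_peaks(
    spectrum: ScanSpectrum,
    min_snr: float = 3.0,
    min_prominence: float | None = None,
    scan_index: int = 0,
) -> list[Peak]:
    """Detect peaks in one spectrum.

    Profile spectra: local maxima with prominence >= ``min_prominence``
    (default 3x the robust noise sd) and (intensity - noise_level) /
    noise_sd >= ``min_snr``; centroid m/z is the intensity-weighted mean
    over the maximum +-1 samples.  Centroided spectra: detection reduces
    to the SNR threshold on each stick.  Output is sorted by m/z.
    """
    mz, inten = spectrum.mz, spectrum.intensity
    if mz.size == 0:
        return []
    if mz.size < 8:
        level, sd = float(np.median(inten)), 0.0
    else:
        level, sd = estimate_noise(spectrum)

    def _snr(x: np.ndarray) -> np.ndarray:
        if sd == 0:
            return np.where(x > level, np.inf, 0.0)
        return (x - level) / sd

    if spectrum.centroided:
        snr = _snr(inten)
        # The robust noise estimate presumes most sticks are noise; a
        # non-positive min_snr disables SNR gating (noise-free input).
        keep = (snr >= min_snr) & (inten > 0) if min_snr > 0 else inten > 0
        if min_prominence is not None:
            keep &= inten >= min_prominence
        return [Peak(float(m), float(v), float(s), scan_index)
                for m, v, s in zip(mz[keep], inten[keep], snr[keep])]

    prom = min_prominence if min_prominence is not None else max(3.0 * sd, 1e-12)
    idx, _props = find_peaks(inten, prominence=prom)
    out = []
    for k in idx:
        s = _snr(inten[k:k + 1])[0]
        if s < min_snr:
            continue
        lo, hi = max(k - 1, 0), min(k + 2, mz.size)
        w = inten[lo:hi]
        centroid = float(np.sum(mz[lo:hi] * w) / np.sum(w))
        out.append(Peak(centroid, float(inten[k]), float(s), scan_index))
    out.sort(key=lambda p: p.mz)
    return out
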