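"""Cleaning and rescaling of raw Raman spectra.

The stages mirror standard chemometric practice for fluorescence-contaminated
Raman data: replicate averaging, asymmetric-least-squares baseline removal,
Savitzky-Golay smoothing, linear interpolation to a uniform wavenumber grid,
and cropping to the analysis band (1240-1360 cm^-1 for the ripeness study).
All stages operate on :class:`RamanSpectrum` and return new instances; the
input is never mutated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.signal import find_peaks, savgol_filter
from scipy.sparse.linalg import spsolve

logger = logging.getLogger("palmraman")

CSV_HEADER = "raman_shift_cm-1,intensity_au"

#: analysis band of the ripeness study (cm^-1)
DEFAULT_BAND: Tuple[float, float] = (1240.0, 1360.0)
#: default uniform grid step after interpolation (cm^-1)
DEFAULT_STEP: float = 0.5


@dataclass(frozen=True)
class RamanSpectrum:
    """A single Raman spectrum on a strictly ascending wavenumber grid.

    Parameters
    ----------
    shifts
        Raman shifts in cm^-1, strictly ascending, length >= 2.
    intensities
        Scattered-light intensities in arbitrary units, same length as
        ``shifts`` and finite everywhere.
    metadata
        Free-form provenance (sample id, replicate spot, processing stage).
    """

    shifts: np.ndarray
    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        shifts = np.asarray(self.shifts, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "shifts", shifts)
        object.__setattr__(self, "intensities", intensities)
        if shifts.ndim != 1 or intensities.ndim != 1:
            raise ValueError("shifts and intensities must be 1-D")
        if shifts.size != intensities.size:
            raise ValueError("shifts and intensities must have equal length")
        if shifts.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(shifts) > 0):
            raise ValueError("shifts must be strictly ascending")
        if not np.all(np.isfinite(shifts)) or not np.all(np.isfinite(intensities)):
            raise ValueError("spectrum values must be finite")

    def __len__(self) -> int:
        return self.shifts.size

    @property
    def step(self) -> float:
        """Median grid spacing (cm^-1)."""
        return float(np.median(np.diff(self.shifts)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.shifts)
        return bool(np.allclose(d, d[0], rtol=rtol, atol=1e-9))

    def with_intensities(self, intensities: np.ndarray, **meta) -> "RamanSpectrum":
        md = dict(self.metadata)
        md.update(meta)
        return RamanSpectrum(self.shifts.copy(), np.asarray(intensities, float), md)


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``savgol_window`` is in points (odd, > ``savgol_order``); ``baseline_lam``
    and ``baseline_p`` are the Whittaker-smoother roughness penalty and
    asymmetry of the AsLS baseline; ``step`` is the interpolation grid spacing
    in cm^-1; ``band`` the inclusive crop interval in cm^-1.
    """

    savgol_window: int = 11
    savgol_order: int = 3
    baseline_lam: float = 1e8
    baseline_p: float = 0.01
    step: float = DEFAULT_STEP
    band: Tuple[float, float] = DEFAULT_BAND

    def __post_init__(self):
        if self.savgol_window % 2 == 0 or self.savgol_window <= self.savgol_order:
            raise ValueError("savgol_window must be odd and > savgol_order")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.band[0] >= self.band[1]:
            raise ValueError("band lower bound must be below upper bound")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_spectrum_csv(path) -> RamanSpectrum:
    """Read a two-column (raman shift, intensity) CSV.

    A single header line is tolerated.  Rows that do not parse as two numbers
    raise a ``ValueError`` naming the offending line.  Descending input is
    sorted ascending; duplicate shifts are rejected.
    """
    path = Path(path)
    shifts, intensities = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if lineno == 1:
                try:
                    float(parts[0])
                except ValueError:
                    continue  # header
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric row {line!r}") from exc
            shifts.append(x)
            intensities.append(y)
    if len(shifts) < 2:
        raise ValueError(f"{path}: fewer than 2 data points")
    shifts = np.asarray(shifts)
    intensities = np.asarray(intensities)
    order = np.argsort(shifts, kind="stable")
    shifts, intensities = shifts[order], intensities[order]
    if np.any(np.diff(shifts) == 0):
        raise ValueError(f"{path}: duplicate Raman shifts")
    return RamanSpectrum(shifts, intensities, {"source": str(path)})


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def average_replicates(spectra: Sequence[RamanSpectrum]) -> RamanSpectrum:
    """Pointwise mean of replicate spectra acquired at different spots.

    All spectra must share an identical wavenumber grid (interpolate first).
    """
    if len(spectra) == 0:
        raise ValueError("no spectra to average")
    ref = spectra[0]
    for s in spectra[1:]:
        if len(s) != len(ref) or not np.allclose(s.shifts, ref.shifts, atol=1e-9):
            raise ValueError("replicate grids do not match")
    mean = np.mean([s.intensities for s in spectra], axis=0)
    return ref.with_intensities(mean, replicates=len(spectra), stage="averaged")


def asls_baseline(y: np.ndarray, lam: float = 1e8, p: float = 0.01,
                  n_iter: int = 30, tol: float = 1e-6) -> np.ndarray:
    """Asymmetric least-squares (Whittaker smoother) baseline estimate.

    Minimises ``sum w_i (y_i - z_i)^2 + lam * sum (Delta^2 z)^2`` where points
    above the current baseline get weight ``p`` and points below ``1 - p``, so
    the smooth curve hugs the lower envelope of the signal — the standard
    behaviour wanted for broad fluorescence backgrounds under sharp Raman peaks.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = lam * (D.T @ D)
    w = np.ones(n)
    z = y.copy()
    for _ in range(n_iter):
        W = sparse.diags(w, format="csc")
        z_new = spsolve(W + penalty, w * y)
        w_new = np.where(y > z_new, p, 1.0 - p)
        converged = np.array_equal(w_new, w) or np.max(np.abs(z_new - z)) < tol * max(
            1.0, np.max(np.abs(y)))
        z, w = z_new, w_new
        if converged:
            break
    return z


def baseline_correct(spectrum: RamanSpectrum, lam: float = 1e8, p: float = 0.01
                     ) -> Tuple[RamanSpectrum, RamanSpectrum]:
    """Subtract an AsLS-estimated smooth baseline.

    Returns ``(corrected, baseline)`` with ``corrected + baseline == input``
    exactly (the subtraction defines the pair).
    """
    if lam <= 0 or not (0 < p < 1):
        raise ValueError("require lam > 0 and 0 < p < 1")
    z = asls_baseline(spectrum.intensities, lam=lam, p=p)
    corrected = spectrum.with_intensities(spectrum.intensities - z, stage="baseline_corrected")
    baseline = spectrum.with_intensities(z, stage="baseline")
    return corrected, baseline


def smooth_savgol(spectrum: RamanSpectrum, window: int = 11, order: int = 3) -> RamanSpectrum:
    """Savitzky-Golay smoothing: local least-squares polynomial at each point.

    Requires a uniform grid, odd ``window`` larger than ``order`` and shorter
    than the spectrum.  Edge values come from the polynomial fitted to the
    first/last full window.
    """
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and greater than order")
    if window >= len(spectrum):
        raise ValueError("window must be shorter than the spectrum")
    if not spectrum.is_uniform():
        raise ValueError("Savitzky-Golay smoothing requires a uniform grid")
    smoothed = savgol_filter(spectrum.intensities, window, order, mode="interp")
    return spectrum.with_intensities(smoothed, stage="smoothed")


def interpolate_uniform(spectrum: RamanSpectrum, step: float = DEFAULT_STEP) -> RamanSpectrum:
    """Linear interpolation onto the uniform grid of multiples of ``step``.

    The grid runs from ``ceil(min/step)*step`` to ``floor(max/step)*step`` so
    every output point lies inside the original support (no extrapolation).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    lo = int(np.ceil(spectrum.shifts[0] / step - 1e-9))
    hi = int(np.floor(spectrum.shifts[-1] / step + 1e-9))
    if hi <= lo:
        raise ValueError("step larger than the spectral span")
    grid = np.arange(lo, hi + 1, dtype=float) * step
    values = np.interp(grid, spectrum.shifts, spectrum.intensities)
    md = dict(spectrum.metadata)
    md["stage"] = "interpolated"
    return RamanSpectrum(grid, values, md)


def crop_band(spectrum: RamanSpectrum, lo: float, hi: float) -> RamanSpectrum:
    """Keep the closed wavenumber interval ``[lo, hi]``."""
    if lo >= hi:
        raise ValueError("lo must be below hi")
    mask = (spectrum.shifts >= lo - 1e-9) & (spectrum.shifts <= hi + 1e-9)
    if mask.sum() < 2:
        raise ValueError(f"crop [{lo}, {hi}] leaves fewer than 2 points")
    md = dict(spectrum.metadata)
    md["stage"] = "cropped"
    return RamanSpectrum(spectrum.shifts[mask], spectrum.intensities[mask], md)


def robust_noise_sd(y: np.ndarray) -> float:
    """Noise scale from the median absolute deviation of first differences.

    First differencing removes smooth structure; the 1.4826 factor maps MAD to
    a Gaussian standard deviation and sqrt(2) undoes the difference inflation.
    """
    d = np.diff(np.asarray(y, float))
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def find_reference_peak(spectrum: RamanSpectrum, ref_position: float, window: float = 10.0,
                        prominence_factor: float = 3.0
                        ) -> Optional[Tuple[float, float]]:
    """Locate the local maximum nearest ``ref_position`` within ``+-window``.

    Intended for reading reference band positions (e.g. the chlorophyll-a bands
    at 744/915/986/1325 cm^-1) off a raw spectrum without preprocessing.
    Returns ``(position, intensity)`` or ``None`` when no local maximum within
    the window clears a prominence threshold of ``prominence_factor`` times the
    robust noise estimate — the "absent" entries of sparse intensity tables.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not (spectrum.shifts[0] <= ref_position <= spectrum.shifts[-1]):
        raise ValueError("reference position outside the spectral range")
    threshold = prominence_factor * robust_noise_sd(spectrum.intensities)
    idx, _ = find_peaks(spectrum.intensities, prominence=max(threshold, 1e-12))
    if idx.size == 0:
        return None
    positions = spectrum.shifts[idx]
    in_window = np.abs(positions - ref_position) <= window
    if not np.any(in_window):
        return None
    idx = idx[in_window]
    best = idx[np.argmin(np.abs(spectrum.shifts[idx] - ref_position))]
    return float(spectrum.shifts[best]), float(spectrum.intensities[best])


# ---------------------------------------------------------------------------
# Chain
# ---------------------------------------------------------------------------

def preprocess_spectrum(spectrum: RamanSpectrum,
                        config: PreprocessConfig = PreprocessConfig(),
                        replicates: Optional[Iterable[RamanSpectrum]] = None,
                        smooth: bool = True) -> RamanSpectrum:
    """Full chain: interpolate, average replicates, baseline-correct, smooth, crop.

    ``replicates`` are additional spot spectra of the same sample; they are
    interpolated to the same grid and averaged in before baseline correction.
    Pass ``smooth=False`` when the result feeds a least-squares fit: the
    Savitzky-Golay filter correlates the noise across ~1 window, which biases
    residual-based inference (noise estimates, chi-squared, component
    significance tests) while adding nothing a model fit needs.
    """
    sid = spectrum.metadata.get("sample_id", "?")
    spec = interpolate_uniform(spectrum, config.step)
    logger.debug("sample %s: interpolated to step %.3g", sid, config.step)
    if replicates:
        reps = [spec] + [interpolate_uniform(r, config.step) for r in replicates]
        lo = max(r.shifts[0] for r in reps)
        hi = min(r.shifts[-1] for r in reps)
        reps = [crop_band(r, lo, hi) for r in reps]
        spec = average_replicates(reps)
        logger.debug("sample %s: averaged %d replicates", sid, len(reps))
    spec, _ = baseline_correct(spec, config.baseline_lam, config.baseline_p)
    logger.debug("sample %s: baseline corrected", sid)
    if smooth:
        spec = smooth_savgol(spec, config.savgol_window, config.savgol_order)
        logger.debug("sample %s: smoothed (window=%d order=%d)", sid,
                     config.savgol_window, config.savgol_order)
    spec = crop_band(spec, *config.band)
    logger.debug("sample %s: cropped to %s", sid, config.band)
    return spec
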