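"""BOLD signal cleaning: motion censoring, nuisance regression, filtering.

The pipeline owns the steps downstream of realignment: framewise-displacement
frame exclusion at a configurable threshold, linear detrend + WM/CSF/motion
nuisance regression (the global signal is deliberately NOT regressed),
a hard frequency-domain band-pass, and mask-normalized Gaussian smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class CleaningConfig:
    fd_threshold: float = 0.15  # mm
    rotation_radius: float = 5.0  # mm, converts radians to arc displacement
    band: tuple[float, float] = (0.01, 0.10)  # Hz
    fwhm: float = 0.7  # mm
    n_discard: int = 10
    censor_mode: str = "interpolate"  # {"drop", "interpolate"}
    tr: float = 1.0

    def __post_init__(self) -> None:
        nyquist = 1.0 / (2.0 * self.tr)
        low, high = self.band
        if not 0 < low < high < nyquist:
            raise ValueError(
                f"band must satisfy 0 < low < high < Nyquist ({nyquist} Hz)"
            )
        if self.fwhm < 0:
            raise ValueError("fwhm must be non-negative")
        if self.censor_mode not in ("drop", "interpolate"):
            raise ValueError("censor_mode must be 'drop' or 'interpolate'")


def framewise_displacement(motion: np.ndarray, radius: float = 5.0) -> np.ndarray:
    """Per-frame motion summary in mm.

    FD[0] = 0; FD[t] = sum |delta translation| + radius * sum |delta rotation|,
    for a motion table ordered as three translations (mm) then three rotations
    (radians).
    """
    motion = np.asarray(motion, float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(
            f"motion table must be T x 6 (3 translations, 3 rotations); "
            f"got shape {motion.shape}"
        )
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    d = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + radius * d[:, 3:].sum(axis=1)
    return fd


def censor_frames(
    series: np.ndarray,
    fd: np.ndarray,
    threshold: float = 0.15,
    mode: str = "drop",
) -> tuple[np.ndarray, np.ndarray]:
    """Remove or interpolate frames whose FD exceeds ``threshold``.

    Returns ``(cleaned, kept_index)``.  In drop mode the offending frames are
    removed and ``kept_index`` maps output rows to input rows; in interpolate
    mode the series keeps its length (needed for window grids) and offending
    frames are replaced by linear interpolation from the surviving ones.
    """
    series = np.asarray(series, float)
    fd = np.asarray(fd, float)
    if fd.shape[0] != series.shape[0]:
        raise ValueError("fd is not aligned to the series")
    bad = fd > threshold
    kept = np.flatnonzero(~bad)
    if bad.mean() > 0.5:
        warnings.warn(
            f"{bad.sum()}/{bad.size} frames exceed FD {threshold} mm; "
            "subject should be flagged for exclusion",
            stacklevel=2,
        )
    if not bad.any():
        return series.copy(), np.arange(series.shape[0])
    if mode == "drop":
        return series[kept], kept
    if mode == "interpolate":
        out = series.copy()
        t = np.arange(series.shape[0])
        for col in range(series.shape[1]):
            out[bad, col] = np.interp(t[bad], kept, series[kept, col])
        return out, np.arange(series.shape[0])
    raise ValueError(f"unknown censor mode {mode!r}")


def bandpass(
    series: np.ndarray, band: tuple[float, float], tr: float = 1.0
) -> np.ndarray:
    """Hard frequency-domain band-pass: zero all amplitudes outside ``band``."""
    series = np.asarray(series, float)
    T = series.shape[0]
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.fft.rfft(series, axis=0)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=T, axis=0)


def clean_timeseries(
    series: np.ndarray,
    confounds: np.ndarray | None,
    config: CleaningConfig,
) -> np.ndarray:
    """Detrend, regress nuisance signals, then band-pass.

    Each column is OLS-residualized against an intercept, a linear trend and
    the confound columns (WM mean, CSF mean, six motion parameters), then
    filtered with a hard frequency mask over ``config.band``.  The global mean
    signal is never added to the design.  Constant confound columns are
    dropped with a warning (they are spanned by the intercept).
    """
    series = np.asarray(series, float)
    T = series.shape[0]
    cols = [np.ones(T), np.linspace(-1.0, 1.0, T)]
    if confounds is not None:
        confounds = np.asarray(confounds, float)
        if confounds.shape[0] != T:
            raise ValueError("confounds are not aligned to the series")
        for j in range(confounds.shape[1]):
            c = confounds[:, j]
            if np.ptp(c) == 0:
                warnings.warn(
                    f"confound column {j} is constant; dropped from the design",
                    stacklevel=2,
                )
                continue
            cols.append(c)
    design = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(design, series, rcond=None)
    resid = series - design @ beta
    return bandpass(resid, config.band, config.tr)


def gaussian_smooth(
    volumes: np.ndarray,
    fwhm: float,
    voxel_size: float,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mask-normalized 3-D Gaussian smoothing of a (X, Y, Z[, T]) array.

    Kernel weights are renormalized over in-mask voxels so masked borders are
    not darkened; out-of-mask voxels are untouched.
    """
    volumes = np.asarray(volumes, float)
    if fwhm == 0:
        return volumes.copy()
    if fwhm < voxel_size / 2:
        warnings.warn(
            f"fwhm {fwhm} mm is below half the voxel size; smoothing is a near-no-op",
            stacklevel=2,
        )
    sigma_vox = fwhm * FWHM_TO_SIGMA / voxel_size
    spatial = volumes.shape[:3]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = mask.astype(bool)
    norm = ndimage.gaussian_filter(mask.astype(float), sigma_vox, mode="reflect")
    norm[~mask] = 1.0
    single = volumes.ndim == 3
    frames = volumes[..., None] if single else volumes
    out = frames.copy()
    for t in range(frames.shape[-1]):
        frame = np.where(mask, frames[..., t], 0.0)
        sm = ndimage.gaussian_filter(frame, sigma_vox, mode="reflect") / norm
        out[..., t] = np.where(mask, sm, frames[..., t])
    return out[..., 0] if single else out
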