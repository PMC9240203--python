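"""Resting-state preprocessing chain.

Stages, applied in this order by :func:`preprocess_subject`:

1. discard the first ``n_discard`` volumes (motion rows dropped in lockstep),
2. motion screen — reject a subject whose trace exceeds 2 mm translation or
   2 degrees rotation on any axis (strict inequalities: a peak of exactly
   2.0 is accepted),
3. nuisance regression (six motion parameters plus WM/CSF reference
   signals; the global signal is *not* regressed out),
4. spatial Gaussian smoothing (8 mm FWHM default),
5. linear detrending followed by an ideal 0.01-0.08 Hz bandpass.

Every stage except the screen is linear in the data and leaves the affine
and TR untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .core import MotionTrace, TimeSeriesImage

__all__ = [
    "PreprocessConfig",
    "MotionScreenResult",
    "PreprocessResult",
    "discard_initial_volumes",
    "screen_motion",
    "regress_nuisance",
    "detrend_bandpass",
    "gaussian_smooth",
    "preprocess_subject",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class PreprocessConfig:
    n_discard: int = 5
    max_translation_mm: float = 2.0
    max_rotation_deg: float = 2.0
    band_hz: tuple[float, float] = (0.01, 0.08)
    fwhm_mm: float = 8.0
    use_motion_regressors: bool = True
    use_wm_csf_regressors: bool = True
    preserve_global: bool = True

    def validate(self, tr: float) -> None:
        low, high = self.band_hz
        nyquist = 1.0 / (2.0 * tr)
        if not 0 < low < high < nyquist:
            raise ValueError(
                f"band {self.band_hz} must satisfy 0 < low < high < Nyquist ({nyquist:g} Hz)"
            )
        if self.fwhm_mm < 0:
            raise ValueError("FWHM must be non-negative")
        if self.n_discard < 0:
            raise ValueError("n_discard must be non-negative")


@dataclass(frozen=True)
class MotionScreenResult:
    accepted: bool
    axis: int | None = None  # offending axis (0-2 translation, 3-5 rotation)
    peak: float | None = None

    def __bool__(self) -> bool:
        return self.accepted


@dataclass
class PreprocessResult:
    """Outcome of the full chain: either a clean image or a typed rejection."""

    subject_id: str
    image: TimeSeriesImage | None
    rejected: bool
    screen: MotionScreenResult
    log: list = field(default_factory=list)


def discard_initial_volumes(img: TimeSeriesImage, n: int) -> TimeSeriesImage:
    """Drop the first ``n`` volumes (scanner equilibration period)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= img.n_volumes:
        raise ValueError(f"cannot discard {n} of {img.n_volumes} volumes")
    return img.with_data(img.data[..., n:])


def screen_motion(trace: MotionTrace, cfg: PreprocessConfig) -> MotionScreenResult:
    """Accept/reject by maximal displacement; thresholds are strict.

    Rejects iff any translation axis exceeds ``max_translation_mm`` or any
    rotation axis exceeds ``max_rotation_deg``; reports the worst offending
    axis and its peak.
    """
    if trace.n_volumes == 0:
        raise ValueError("empty motion trace")
    peaks = np.abs(trace.values).max(axis=0)
    limits = np.array(
        [cfg.max_translation_mm] * 3 + [cfg.max_rotation_deg] * 3, dtype=float
    )
    excess = peaks - limits
    worst = int(np.argmax(excess))
    if excess[worst] > 0:
        return MotionScreenResult(accepted=False, axis=worst, peak=float(peaks[worst]))
    return MotionScreenResult(accepted=True)


def regress_nuisance(img: TimeSeriesImage, regressors: np.ndarray) -> TimeSeriesImage:
    """Remove nuisance signals voxel-wise by least squares.

    An intercept is always included; each voxel keeps its own mean.  With an
    empty regressor set the image is returned unchanged.
    """
    if regressors is None or np.size(regressors) == 0:
        return img.with_data(img.data.copy())
    X = np.asarray(regressors, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    T = img.n_volumes
    if X.shape[0] != T:
        raise ValueError(f"regressors have {X.shape[0]} rows for {T} volumes")
    design = np.column_stack([np.ones(T), X - X.mean(axis=0)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns that add no rank when appended incrementally
        dependent = []
        kept = design[:, :1]
        for j in range(1, design.shape[1]):
            cand = np.column_stack([kept, design[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                dependent.append(j - 1)  # regressor index (0-based, sans intercept)
            else:
                kept = cand
        raise ValueError(f"rank-deficient nuisance design; dependent columns: {dependent}")

    Y = img.data.reshape(-1, T).T  # T x V
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ beta
    resid += Y.mean(axis=0)  # restore voxel means
    return img.with_data(resid.T.reshape(img.data.shape))


def detrend_bandpass(
    img: TimeSeriesImage, band: tuple[float, float] | None = None
) -> TimeSeriesImage:
    """Linear detrend plus ideal (FFT-mask) bandpass, voxel-wise.

    Implemented as one orthogonal projection: the removed subspace is the
    span of the out-of-band Fourier vectors (including DC) together with the
    linear ramp, so the operation is linear, idempotent, and leaves output
    series zero-mean with no residual trend.
    """
    low, high = band if band is not None else (0.01, 0.08)
    nyquist = 1.0 / (2.0 * img.tr)
    if not 0 < low < high <= nyquist:
        raise ValueError(f"band ({low}, {high}) outside (0, {nyquist:g}] Hz")
    T = img.n_volumes
    flat = img.data.reshape(-1, T)
    freqs = np.fft.rfftfreq(T, d=img.tr)
    keep = (freqs >= low) & (freqs <= high)

    def bandpass(x):
        spec = np.fft.rfft(x, axis=-1)
        spec[..., ~keep] = 0.0
        return np.fft.irfft(spec, n=T, axis=-1)

    out = bandpass(flat)
    # remove the in-band component of the linear trend as well
    ramp = np.arange(T, dtype=float)
    ramp -= ramp.mean()
    ramp_in = bandpass(ramp)
    denom = ramp_in @ ramp_in
    if denom > 0:
        out -= np.outer(out @ ramp_in / denom, ramp_in)
    return img.with_data(out.reshape(img.data.shape))


def gaussian_smooth(img: TimeSeriesImage, fwhm_mm: float) -> TimeSeriesImage:
    """Volume-wise 3-D Gaussian smoothing.

    Kernel width per axis is ``fwhm / voxel_size`` converted to a standard
    deviation; boundaries use zero padding (``mode='constant'``), so mass is
    conserved for interior voxels and attenuated at the edges.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return img.with_data(img.data.copy())
    sigmas = fwhm_mm / (img.voxel_sizes_mm * _FWHM_TO_SIGMA)
    out = ndimage.gaussian_filter(
        img.data, sigma=tuple(sigmas) + (0.0,), mode="constant", cval=0.0
    )
    return img.with_data(out)


def preprocess_subject(
    img: TimeSeriesImage,
    trace: MotionTrace,
    cfg: PreprocessConfig,
    nuisance_signals: np.ndarray | None = None,
    subject_id: str = "",
) -> PreprocessResult:
    """Run the full chain; returns a typed rejection when the screen fails.

    ``nuisance_signals`` are extra T x k columns (after discard) such as WM
    and CSF reference means; motion parameters are appended automatically
    when configured.
    """
    cfg.validate(img.tr)
    log: list[str] = []

    img = discard_initial_volumes(img, cfg.n_discard)
    trace = trace.discard_initial(cfg.n_discard) if cfg.n_discard else trace
    if trace.n_volumes != img.n_volumes:
        raise ValueError("motion trace length does not match volume count")
    log.append(f"discard: kept {img.n_volumes} volumes")

    screen = screen_motion(trace, cfg)
    if not screen:
        log.append(f"screen: rejected (axis {screen.axis}, peak {screen.peak:.3f})")
        return PreprocessResult(subject_id, None, True, screen, log)
    log.append("screen: accepted")

    cols = []
    if cfg.use_motion_regressors:
        cols.append(trace.values)
    if nuisance_signals is not None and cfg.use_wm_csf_regressors:
        ns = np.asarray(nuisance_signals, dtype=np.float64)
        if ns.ndim == 1:
            ns = ns[:, None]
        cols.append(ns)
    if cols:
        X = np.column_stack(cols)
        # zero-variance columns (e.g. a motionless trace) carry no signal
        X = X[:, X.std(axis=0) > 1e-12]
        if X.shape[1]:
            img = regress_nuisance(img, X)
        log.append(f"nuisance: removed {X.shape[1]} regressors")
    else:
        log.append("nuisance: none")

    img = gaussian_smooth(img, cfg.fwhm_mm)
    log.append(f"smooth: FWHM {cfg.fwhm_mm} mm")
    img = detrend_bandpass(img, cfg.band_hz)
    log.append(f"bandpass: {cfg.band_hz[0]}-{cfg.band_hz[1]} Hz + linear detrend")
    return PreprocessResult(subject_id, img, False, screen, log)
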