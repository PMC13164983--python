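"""Raman preprocessing chain: crop/resample -> smooth -> baseline -> normalise.

Maps a raw spectrum to the fixed-length nonnegative feature vector the model
consumes: the 500-1800 cm^-1 fingerprint region resampled to 2048 uniform
points by linear interpolation, Savitzky-Golay smoothed (window 5, order 2),
baseline-corrected by iterative polynomial fitting, then min-max normalised
and sharpened by a power-law transform (alpha = 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra import Spectrum


@dataclass
class PreprocConfig:
    fingerprint_lo: float = 500.0
    fingerprint_hi: float = 1800.0
    n_points: int = 2048
    sg_window: int = 5
    sg_order: int = 2
    baseline_order: int = 5
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-6
    alpha: float = 1.5

    def __post_init__(self) -> None:
        if self.fingerprint_lo >= self.fingerprint_hi:
            raise ValueError("fingerprint_lo must be < fingerprint_hi")
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_order >= self.sg_window:
            raise ValueError("sg_order must be < sg_window")
        if self.n_points < self.sg_window:
            raise ValueError("n_points must be >= sg_window")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def crop_resample(s: Spectrum, cfg: PreprocConfig) -> Spectrum:
    """Restrict to the fingerprint region and resample to a uniform axis.

    The output axis is ``n_points`` uniformly spaced values spanning
    ``[fingerprint_lo, fingerprint_hi]`` inclusive; intensities come from
    linear interpolation of the input.
    """
    lo, hi = cfg.fingerprint_lo, cfg.fingerprint_hi
    if s.wavenumber[0] > lo or s.wavenumber[-1] < hi:
        raise ValueError(
            f"spectrum covers [{s.wavenumber[0]:g}, {s.wavenumber[-1]:g}] cm^-1 "
            f"but the fingerprint region [{lo:g}, {hi:g}] is required"
        )
    axis = np.linspace(lo, hi, cfg.n_points)
    return Spectrum(axis, np.interp(axis, s.wavenumber, s.intensity))


def sg_smooth(s: Spectrum, window: int = 5, order: int = 2) -> Spectrum:
    """Savitzky-Golay least-squares local-polynomial smoothing."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window >= len(s):
        raise ValueError("window must be smaller than the spectrum length")
    if order >= window:
        raise ValueError("order must be < window")
    return Spectrum(s.wavenumber, savgol_filter(s.intensity, window, order, mode="interp"))


def baseline_correct(s: Spectrum, cfg: PreprocConfig) -> tuple[Spectrum, Spectrum]:
    """Iterative polynomial (modified-polyfit) baseline removal.

    Repeatedly fits an order-``baseline_order`` polynomial and clips the
    working spectrum to lie at or below the fit, so peaks are progressively
    excluded from the baseline estimate.  Stops when the fit changes by less
    than ``baseline_tol`` (relative L2) or after ``baseline_max_iter``
    iterations.  Returns ``(corrected, baseline)`` with the corrected
    intensities floored at zero.
    """
    y = np.asarray(s.intensity, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("spectrum contains non-finite values")
    if len(y) < cfg.baseline_order + 1:
        raise ValueError("spectrum shorter than baseline_order + 1")
    # Chebyshev basis on [-1, 1] for conditioning; projection matrix is
    # precomputed once since the axis is fixed across iterations.
    t = -1.0 + 2.0 * (s.wavenumber - s.wavenumber[0]) / (s.wavenumber[-1] - s.wavenumber[0])
    V = np.polynomial.chebyshev.chebvander(t, cfg.baseline_order)
    pinv = np.linalg.pinv(V)
    work = y.copy()
    fit = V @ (pinv @ work)
    for _ in range(cfg.baseline_max_iter):
        work = np.minimum(work, fit)
        new_fit = V @ (pinv @ work)
        denom = np.linalg.norm(fit) or 1.0
        if np.linalg.norm(new_fit - fit) / denom < cfg.baseline_tol:
            fit = new_fit
            break
        fit = new_fit
    corrected = np.clip(y - fit, 0.0, None)
    return Spectrum(s.wavenumber, corrected), Spectrum(s.wavenumber, fit)


def normalize_power(s: Spectrum, alpha: float = 1.5) -> np.ndarray:
    """Min-max normalisation followed by a power-law contrast transform.

    ``y = ((s - min) / (max - min)) ** alpha`` maps the spectrum into [0, 1]
    with the minimum at 0 and maximum at 1; ``alpha > 1`` sharpens peaks
    relative to valleys.
    """
    y = np.asarray(s.intensity, dtype=float)
    lo, hi = y.min(), y.max()
    if hi <= lo:
        raise ValueError("degenerate spectrum: constant intensity has no min-max range")
    return ((y - lo) / (hi - lo)) ** alpha


def preprocess(s: Spectrum, cfg: PreprocConfig | None = None) -> np.ndarray:
    """Full chain: crop/resample -> SG smooth -> baseline -> min-max + power.

    Returns the length-``n_points`` feature vector in [0, 1].
    """
    if cfg is None:
        cfg = PreprocConfig()
    out = crop_resample(s, cfg)
    out = sg_smooth(out, cfg.sg_window, cfg.sg_order)
    out, _ = baseline_correct(out, cfg)
    return normalize_power(out, cfg.alpha)


def feature_axis(cfg: PreprocConfig | None = None) -> np.ndarray:
    """The uniform wavenumber axis shared by all feature vectors."""
    if cfg is None:
        cfg = PreprocConfig()
    return np.linspace(cfg.fingerprint_lo, cfg.fingerprint_hi, cfg.n_points)
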