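"""Instantaneous period and phase from bioluminescence traces.

The rhythm-analysis stage mirrors common practice for PER2::LUC
recordings: a windowed-sinc high-pass detrend (cutoff period 48 h)
followed by a Morlet continuous wavelet transform on a linear period
grid (101 periods from 10 h to 48 h) and a maximum-power ridge readout
giving instantaneous period and phase per time point.

The Morlet mother wavelet uses base angular frequency 2π so that the
wavelet scale equals the period directly, and the transform is
normalised so a unit-amplitude cosine at an on-grid period attains
ridge amplitude ≈ 1 with ridge phase equal to the cosine's phase
(zero at each peak).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .model import PDSeries, wrap_pd_hours
from .params import HOURS_PER_RAD, TWO_PI

__all__ = [
    "WaveletSpectrum",
    "WaveletRidge",
    "sinc_detrend",
    "cwt_spectrum",
    "extract_ridge",
    "pd_from_ridges",
    "time_averaged_period",
    "ridge_from_phases",
]


def _sinc_kernel(dt: float, cutoff_period: float) -> np.ndarray:
    """Blackman-windowed sinc low-pass kernel, unit DC gain."""
    fc = dt / cutoff_period          # normalised cutoff frequency
    half = int(round(2.0 * cutoff_period / dt))
    n = np.arange(-half, half + 1)
    kern = 2.0 * fc * np.sinc(2.0 * fc * n) * np.blackman(2 * half + 1)
    return kern / kern.sum()


def sinc_detrend(series, dt: float = 1.0, cutoff_period: float = 48.0) -> np.ndarray:
    """Remove slow trends: subtract the windowed-sinc low-pass component.

    Oscillations with periods up to half the cutoff pass essentially
    unattenuated; baselines and slow drifts (periods above the cutoff)
    are removed.  A least-squares line is taken out before filtering and
    the remainder is extended by even reflection, so neither a linear
    drift nor the oscillation itself is kinked at the record ends.  The
    series must be uniformly sampled and longer than
    ``2 * cutoff_period / dt`` samples.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    kern = _sinc_kernel(dt, cutoff_period)
    half = (len(kern) - 1) // 2
    if len(x) <= half:
        raise ValueError(
            f"series too short for cutoff {cutoff_period} h: need more than "
            f"{half} samples, got {len(x)}")
    n = np.arange(len(x))
    design = np.vstack([np.ones_like(n), n]).T
    line = design @ np.linalg.lstsq(design, x, rcond=None)[0]
    resid = x - line
    padded = np.pad(resid, half, mode="reflect")
    slow = np.convolve(padded, kern, mode="valid")
    return resid - slow


@dataclass(frozen=True)
class WaveletSpectrum:
    """Complex Morlet coefficients on a time × period grid."""

    t: np.ndarray                # hours
    periods: np.ndarray          # hours, shape (n_periods,)
    coef: np.ndarray             # complex, shape (n_periods, n_t)

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coef) ** 2


@dataclass(frozen=True)
class WaveletRidge:
    """Maximum-power ridge: instantaneous period, phase and power.

    ``phase`` is unwrapped along time.  ``in_coi`` flags samples within
    one wavelet support of a record edge; averaged statistics exclude
    them.
    """

    t: np.ndarray
    period: np.ndarray           # hours
    phase: np.ndarray            # radians, unwrapped
    power: np.ndarray
    in_coi: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.in_coi is None:
            object.__setattr__(self, "in_coi",
                               np.zeros(len(self.t), dtype=bool))


def cwt_spectrum(series, t=None, dt: float = 1.0,
                 min_period: float = 10.0, max_period: float = 48.0,
                 n_periods: int = 101) -> WaveletSpectrum:
    """Morlet continuous wavelet transform on a linear period grid.

    For each grid period *p* the analytic kernel is
    ``exp(2πi·t/p) · exp(−t²/(2p²))``, normalised so a unit cosine at
    period *p* yields coefficient magnitude ≈ 1 on the ridge.
    """
    x = np.asarray(series, dtype=float)
    if t is None:
        t = np.arange(len(x)) * dt
    else:
        t = np.asarray(t, dtype=float)
        steps = np.diff(t)
        if steps.size and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be uniform")
        dt = float(steps[0]) if steps.size else dt
    if len(x) * dt < max_period:
        raise ValueError("series shorter than the maximum analysed period")
    periods = np.linspace(min_period, max_period, n_periods)
    coef = np.empty((n_periods, len(x)), dtype=complex)
    for k, p in enumerate(periods):
        half = int(np.ceil(4.0 * p / dt))      # ±4 envelope widths
        tau = np.arange(-half, half + 1) * dt
        env = np.exp(-tau ** 2 / (2.0 * p ** 2))
        kern = np.exp(1j * TWO_PI * tau / p) * env
        kern /= env.sum() / 2.0                # unit response to a matched cosine
        coef[k] = fftconvolve(x, np.conj(kern[::-1]), mode="same")
    return WaveletSpectrum(t=t, periods=periods, coef=coef)


def extract_ridge(spectrum: WaveletSpectrum, ridge_threshold: float = 0.0,
                  coi_factor: float = 1.0, refine: bool = True) -> WaveletRidge:
    """Maximum ridge: per time point, the period of maximal wavelet power.

    ``ridge_threshold`` suppresses ridge points whose power falls below
    it (the default 0 keeps every point).  With ``refine`` (default) the
    ridge period is sharpened below the grid spacing by parabolic
    interpolation of the power across the argmax and its neighbours.
    Samples closer than ``coi_factor`` × (local ridge period) to a
    record edge are flagged as inside the cone of influence.
    """
    power = spectrum.power
    idx = np.argmax(power, axis=0)
    cols = np.arange(power.shape[1])
    period = spectrum.periods[idx].copy()
    if refine:
        interior = (idx > 0) & (idx < len(spectrum.periods) - 1)
        ii = idx[interior]
        cc = cols[interior]
        p0 = power[ii - 1, cc]
        p1 = power[ii, cc]
        p2 = power[ii + 1, cc]
        denom = p0 - 2.0 * p1 + p2
        shift = np.where(np.abs(denom) > 1e-300,
                         0.5 * (p0 - p2) / denom, 0.0)
        shift = np.clip(shift, -0.5, 0.5)
        dp = spectrum.periods[1] - spectrum.periods[0]
        period[interior] = spectrum.periods[ii] + shift * dp
    ridge_coef = spectrum.coef[idx, cols]
    ridge_power = power[idx, cols]
    phase = np.unwrap(np.angle(ridge_coef))
    if ridge_threshold > 0:
        ridge_power = np.where(ridge_power >= ridge_threshold, ridge_power, np.nan)
    edge_dist = np.minimum(spectrum.t - spectrum.t[0], spectrum.t[-1] - spectrum.t)
    in_coi = edge_dist < coi_factor * period
    return WaveletRidge(t=spectrum.t, period=period, phase=phase,
                        power=ridge_power, in_coi=in_coi)


def pd_from_ridges(ridge_i: WaveletRidge, ridge_j: WaveletRidge,
                   name: str = "pd") -> PDSeries:
    """Phase difference i − j from two ridges, wrapped to (−12, 12] hours.

    Positive values mean oscillator *i* peaks before oscillator *j*.
    """
    if len(ridge_i.t) != len(ridge_j.t) or not np.allclose(ridge_i.t, ridge_j.t):
        raise ValueError("ridges must share a time grid")
    pd_h = wrap_pd_hours((ridge_i.phase - ridge_j.phase) * HOURS_PER_RAD)
    return PDSeries(t=ridge_i.t, pd=pd_h, name=name)


def time_averaged_period(ridge: WaveletRidge, window=None) -> float:
    """Mean ridge period (hours) over a window, excluding cone-of-influence samples.

    ``window`` is an inclusive ``(t_start, t_end)`` pair; default is the
    full record.  Falls back to including COI samples only if the window
    contains nothing else.
    """
    mask = np.ones(len(ridge.t), dtype=bool)
    if window is not None:
        t0, t1 = window
        mask &= (ridge.t >= t0) & (ridge.t <= t1)
    if not mask.any():
        raise ValueError("window contains no samples")
    interior = mask & ~ridge.in_coi
    use = interior if interior.any() else mask
    return float(np.mean(ridge.period[use]))


def ridge_from_phases(t, theta_rad) -> WaveletRidge:
    """Ridge-equivalent view of a simulated (noise-free) phase series.

    Instantaneous period is 2π over the numerical phase derivative;
    lets the plateau detector and estimators run directly on model
    output without the rendering/wavelet stages.
    """
    t = np.asarray(t, dtype=float)
    theta = np.asarray(theta_rad, dtype=float)
    freq = np.gradient(theta, t)
    period = TWO_PI / freq
    return WaveletRidge(t=t, period=period, phase=theta,
                        power=np.ones_like(period))
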