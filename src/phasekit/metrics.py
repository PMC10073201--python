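"""Phase-difference stability and constant-PD (plateau) detection.

Two complementary summaries of a PD trace:

* a *stability score* — the prominence ``y = max(h_i) / Σ h_i`` of the
  tallest bin in a 15-min-binned PD histogram; near 1 for a trace that
  sits on one plateau, near the uniform floor 1/96 for a freely
  drifting trace;
* *constant-PD segments* — maximal runs of at least 24 h over which the
  PD changes more slowly than 0.01 rad/h, each summarised by its mean
  PD θ* and the collective period τ* (the mean of the two oscillators'
  mean periods over the run).

Locked-segment observables (θ*, τ*) are the inputs to the closed-form
coupling estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import PDSeries, wrap_pd_hours
from .params import HOURS_PER_RAD
from .wavelet import WaveletRidge

__all__ = [
    "StabilityScore",
    "ConstantPDSegment",
    "stability_score",
    "find_constant_pd_segments",
    "period_mismatch_check",
    "PeriodMismatchWarning",
]

N_BINS = 96                      # 24 h in 15-min bins
RATE_THRESHOLD = 0.01            # rad/h
MIN_DURATION = 24.0              # h
SMOOTH_WINDOW = 3.0              # h, moving average before differentiating


@dataclass(frozen=True)
class StabilityScore:
    """Histogram prominence of a PD trace; ``1/N ≤ y ≤ 1``."""

    y: float
    histogram: np.ndarray
    bin_edges: np.ndarray


def stability_score(pd: PDSeries, bin_width_h: float = 0.25) -> StabilityScore:
    """Prominence of the tallest peak in the binned PD histogram.

    Bins cover (−12, 12] hours at 15-min width by default (96 bins).
    High values indicate one dominant plateau; a drifting PD spreads
    over many bins and scores near the uniform floor.
    """
    vals = wrap_pd_hours(np.asarray(pd.pd, dtype=float))
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty PD trace")
    n_bins = int(round(24.0 / bin_width_h))
    edges = np.linspace(-12.0, 12.0, n_bins + 1)
    # values are in (−12, 12]; histogram bins are right-closed to match
    counts, _ = np.histogram(np.nextafter(vals, -np.inf), bins=edges)
    y = counts.max() / counts.sum()
    return StabilityScore(y=float(y), histogram=counts, bin_edges=edges)


@dataclass(frozen=True)
class ConstantPDSegment:
    """A detected phase-locking plateau.

    ``theta_star`` is the mean PD over the segment (hours, wrapped);
    ``tau_star`` the collective period (hours): the mean of the two
    oscillators' mean periods while locked.  Per-oscillator means are
    kept for the period-mismatch diagnostic.
    """

    t_start: float
    t_end: float
    theta_star: float
    tau_star: float
    tau_i: float = np.nan
    tau_j: float = np.nan

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def theta_star_rad(self) -> float:
        return self.theta_star / HOURS_PER_RAD


def _smooth(x: np.ndarray, dt: float, window_h: float) -> np.ndarray:
    w = max(1, int(round(window_h / dt)))
    if w <= 1:
        return x
    kern = np.ones(w) / w
    pad = w // 2
    padded = np.pad(x, pad, mode="edge")
    sm = np.convolve(padded, kern, mode="valid")
    return sm[: len(x)]


def _mean_ridge_period(ridge: WaveletRidge | None, mask: np.ndarray) -> float:
    if ridge is None:
        return np.nan
    sel = mask & ~ridge.in_coi
    if not sel.any():
        sel = mask
    return float(np.mean(ridge.period[sel]))


def find_constant_pd_segments(pd: PDSeries,
                              ridge_i: WaveletRidge | None = None,
                              ridge_j: WaveletRidge | None = None,
                              rate_threshold: float = RATE_THRESHOLD,
                              min_duration: float = MIN_DURATION,
                              smooth_window: float = SMOOTH_WINDOW,
                              ) -> list[ConstantPDSegment]:
    """Maximal runs with |dθ/dt| below threshold for at least ``min_duration``.

    The derivative is taken on the unwrapped PD (radians) after a short
    moving average, so 1 h sampling ripple does not break up genuine
    plateaus.  Ridges, when given, supply the per-oscillator periods
    from which each segment's collective period is computed.  Returns an
    empty list when nothing qualifies.
    """
    t = np.asarray(pd.t, dtype=float)
    if len(t) < 3:
        return []
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("PD series must be uniformly sampled")
    dt = float(steps[0])

    theta = pd.unwrapped_rad()
    rate = np.gradient(_smooth(theta, dt, smooth_window), t)
    quiet = np.abs(rate) < rate_threshold

    segments: list[ConstantPDSegment] = []
    boundaries = np.flatnonzero(np.diff(quiet.astype(int)))
    starts = [0] if quiet[0] else []
    starts += [b + 1 for b in boundaries if quiet[b + 1]]
    ends = [b + 1 for b in boundaries if quiet[b]]
    ends += [len(t)] if quiet[-1] else []
    for a, b in zip(starts, ends):
        if t[b - 1] - t[a] < min_duration:
            continue
        mask = np.zeros(len(t), dtype=bool)
        mask[a:b] = True
        theta_star = wrap_pd_hours(float(np.mean(theta[a:b])) * HOURS_PER_RAD)
        tau_i = _mean_ridge_period(ridge_i, mask)
        tau_j = _mean_ridge_period(ridge_j, mask)
        tau_star = float(np.mean([tau_i, tau_j]))
        segments.append(ConstantPDSegment(
            t_start=float(t[a]), t_end=float(t[b - 1]),
            theta_star=float(theta_star), tau_star=tau_star,
            tau_i=tau_i, tau_j=tau_j))
    return segments


class PeriodMismatchWarning(UserWarning):
    """Per-oscillator periods differ by more than 4% within a locked segment."""


def period_mismatch_check(segment: ConstantPDSegment,
                          tolerance: float = 0.04) -> float:
    """Fractional period difference |τ_i − τ_j| / mean within a segment.

    Locked oscillators share a frequency, so large values indicate a
    spurious plateau; a warning (not an error) is emitted above the
    tolerance.
    """
    frac = abs(segment.tau_i - segment.tau_j) / np.mean(
        [segment.tau_i, segment.tau_j])
    if frac > tolerance:
        warnings.warn(
            f"period mismatch {frac:.3f} exceeds {tolerance:.2f} within "
            f"constant-PD segment [{segment.t_start}, {segment.t_end}] h",
            PeriodMismatchWarning, stacklevel=2)
    return float(frac)
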