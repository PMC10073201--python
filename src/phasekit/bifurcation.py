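"""Fixed points and the fold bifurcation of the PD system in global coupling s.

With both channels scaled by a single global coupling *s*, the steady
states of the PD system satisfy a *sine-linear* system: writing
``u = sin(θ_an − γ)`` and ``v = sin θ_av``,

    [[K̃_an, K_av], [K_an, K̃_av]] · (u, v)ᵀ = (ω_an, ω_av)ᵀ / s .

Solving the 2×2 linear system once (at s = 1) gives ``(U, V)``; the
sines at any s are ``(U/s, V/s)``, so real fixed points exist exactly
for ``s ≥ s_fold = max(|U|, |V|)`` — a closed form for the fold
(saddle-node) at which the synchronised state is born.  Each admissible
sine pair yields four branch combinations (arcsin vs π − arcsin);
stability follows from the 2×2 Jacobian

    J = −s · [[K̃_an cos α, K_av cos β], [K_an cos α, K̃_av cos β]],

α = θ_an − γ, β = θ_av.  This direct per-s solution doubles as an
independent oracle for generic continuation software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import PDSeries, pd_rhs, simulate_pd, wrap_pd_hours
from .params import HOURS_PER_RAD, OscillatorParams

__all__ = [
    "FixedPoint",
    "BifurcationBranch",
    "fixed_points",
    "fold_point",
    "continuation",
    "sweep_dynamics",
    "DegenerateCouplingError",
]

_EIG_TOL = 1e-9


class DegenerateCouplingError(ValueError):
    """The coupling matrix K̃_an·K̃_av − K_av·K_an is singular."""


@dataclass(frozen=True)
class FixedPoint:
    """A steady state of the PD system at one value of s (radians)."""

    theta_an: float
    theta_av: float
    eigenvalues: tuple
    stability: str          # "stable" | "unstable" | "fold/neutral"

    @property
    def stable(self) -> bool:
        return self.stability == "stable"


def _coupling_matrix(params: OscillatorParams) -> np.ndarray:
    return np.array([[params.K_tilde_an, params.K_av],
                     [params.K_an, params.K_tilde_av]])


def _base_sines(params: OscillatorParams) -> tuple[float, float]:
    """(U, V): the sine values solving the steady-state system at s = 1."""
    A = _coupling_matrix(params)
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if abs(det) < 1e-14:
        raise DegenerateCouplingError(
            "singular coupling matrix: K̃_an·K̃_av − K_av·K_an = 0")
    b = np.array([params.omega_an, params.omega_av])
    U, V = np.linalg.solve(A, b)
    return float(U), float(V)


def _classify(params: OscillatorParams, s: float,
              theta_an: float, theta_av: float) -> FixedPoint:
    ca = math.cos(theta_an - params.gamma)
    cb = math.cos(theta_av)
    J = -s * np.array([[params.K_tilde_an * ca, params.K_av * cb],
                       [params.K_an * ca, params.K_tilde_av * cb]])
    eig = np.linalg.eigvals(J)
    re = eig.real
    if np.all(re < -_EIG_TOL):
        label = "stable"
    elif np.any(re > _EIG_TOL):
        label = "unstable"
    else:
        label = "fold/neutral"
    return FixedPoint(theta_an=float(theta_an), theta_av=float(theta_av),
                      eigenvalues=tuple(complex(e) for e in eig),
                      stability=label)


def fixed_points(params: OscillatorParams, s: float) -> list[FixedPoint]:
    """All fixed points of the PD system at global coupling ``s``.

    Empty below the fold; generically four branch combinations above
    it.  Angles are reported in (−π, π] for θ_av and with θ_an near γ's
    branch, both in radians.
    """
    if s <= 0:
        raise ValueError("global coupling s must be positive")
    U, V = _base_sines(params)
    u, v = U / s, V / s
    if abs(u) > 1.0 or abs(v) > 1.0:
        return []
    out = []
    asu, asv = math.asin(u), math.asin(v)
    for th_an in (params.gamma + asu, params.gamma + math.pi - asu):
        for th_av in (asv, math.pi - asv):
            th_av_w = math.remainder(th_av, 2.0 * math.pi)
            th_an_w = math.remainder(th_an, 2.0 * math.pi)
            out.append(_classify(params, s, th_an_w, th_av_w))
    return out


def fold_point(params: OscillatorParams) -> float:
    """Closed-form fold location: s_fold = max(|U|, |V|).

    Below s_fold one of the steady-state sines would exceed 1 in
    magnitude and the synchronised state does not exist; at s_fold the
    binding sine equals ±1 and the Jacobian is singular.  Zero detuning
    gives s_fold = 0 (the locked state persists for all s > 0).
    """
    U, V = _base_sines(params)
    return max(abs(U), abs(V))


@dataclass(frozen=True)
class BifurcationBranch:
    """Fixed-point branches over an s grid, with stability labels."""

    s: np.ndarray
    points: list            # list of list[FixedPoint], one per s value
    s_fold: float

    def stable_theta(self, which: str = "av") -> np.ndarray:
        """Stable-branch angle (hours) per s; NaN where no stable point."""
        out = np.full(len(self.s), np.nan)
        for k, fps in enumerate(self.points):
            for fp in fps:
                if fp.stable:
                    ang = fp.theta_av if which == "av" else fp.theta_an
                    out[k] = ang * HOURS_PER_RAD
                    break
        return out


def continuation(params: OscillatorParams, s_min: float = 0.05,
                 s_max: float = 1.5, n_steps: int = 300) -> BifurcationBranch:
    """Trace all fixed-point branches over a linear s grid.

    The sine-linear structure permits exact per-s solution, so no
    predictor–corrector is needed; branch endpoints agree with
    :func:`fold_point` to grid resolution.
    """
    s_grid = np.linspace(s_min, s_max, n_steps)
    points = [fixed_points(params, s) for s in s_grid]
    return BifurcationBranch(s=s_grid, points=points,
                             s_fold=fold_point(params))


def sweep_dynamics(params: OscillatorParams, s_values,
                   initial_pd_rad=(0.0, 0.0), t_span=(0.0, 400.0),
                   output_step: float = 1.0) -> dict:
    """Simulate the PD system at each s and classify the long-run behaviour.

    Classification per s: ``"locked"`` (settles at the stable fixed
    point), ``"drifting"`` (PD grows without bound), or
    ``"near-threshold"`` (drifting, but with slip-separated plateaus —
    the ghost of the fold).  Returns per-s PD series and labels.
    """

    def _dist_mod_2pi(a, b):
        return abs(math.remainder(a - b, 2.0 * math.pi))

    block = t_span[1] - t_span[0]
    max_blocks = 8
    results = {}
    for s in s_values:
        stable = ([fp for fp in fixed_points(params, float(s)) if fp.stable]
                  if s > 0 else [])
        ts, ans, avs = [], [], []
        y = tuple(initial_pd_rad)
        t0 = t_span[0]
        label = None
        k = 0
        while k < max_blocks:
            t, th_an, th_av = simulate_pd(params, s=float(s),
                                          initial_pd_rad=y,
                                          t_span=(t0, t0 + block),
                                          output_step=output_step)
            sl = slice(1, None) if k else slice(None)
            ts.append(t[sl]); ans.append(th_an[sl]); avs.append(th_av[sl])
            y = (th_an[-1], th_av[-1])
            t0 += block
            k += 1
            speed = math.hypot(*pd_rhs(y[0], y[1], params, float(s)))
            if stable:
                fp = stable[0]
                if (speed < 2e-4
                        and _dist_mod_2pi(y[0], fp.theta_an) < 0.2
                        and _dist_mod_2pi(y[1], fp.theta_av) < 0.2):
                    label = "locked"
                    break
            # a full cycle of PD advance within one block means drift;
            # keep at least 4 blocks so slow slip cycles are resolved
            if (max(abs(th_an[-1] - th_an[0]),
                    abs(th_av[-1] - th_av[0])) > 2.0 * math.pi
                    and k >= 4):
                label = "drifting"
                break
        t = np.concatenate(ts)
        th_an = np.concatenate(ans)
        th_av = np.concatenate(avs)
        tail = slice(int(0.75 * len(t)), None)
        drift_rate = ((th_an[-1] - th_an[tail.start])
                      / (t[-1] - t[tail.start]))
        if label is None:
            label = "locked" if stable else "drifting"
        if label == "drifting":
            # a near-threshold trajectory spends most of its time on
            # near-invariant plateaus between rapid slips (the ghost of
            # the saddle-node); transient first block excluded
            rate = np.abs(np.gradient(th_an, t))
            settled = t > t_span[0] + block
            if np.mean(rate[settled] < 0.005) > 0.25:
                label = "near-threshold"
        results[float(s)] = {
            "pd_an": PDSeries(t=t, pd=wrap_pd_hours(th_an * HOURS_PER_RAD),
                              name="an"),
            "pd_av": PDSeries(t=t, pd=wrap_pd_hours(th_av * HOURS_PER_RAD),
                              name="av"),
            "theta_an_unwrapped_rad": th_an,
            "theta_av_unwrapped_rad": th_av,
            "classification": label,
            "drift_rate_rad_per_h": float(drift_rate),
        }
    return results
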