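"""Synthetic PER2::LUC-like bioluminescence recordings.

The experimental recordings this pipeline targets are hourly-binned,
multi-day (~150 h) bioluminescence traces from three brain regions,
with damped oscillation amplitude, a slow baseline, and measurement
noise.  The generator renders a simulated phase trajectory through a
raised-cosine observation model

    B_i(t) = A_i · exp(−t / damping_time) · (1 + cos θ_i(t))
             + trend(t) + ε(t),      ε ~ N(0, noise_sd²),

the simplest map from phase to a non-negative luminescence signal whose
trend the 48 h sinc detrend removes cleanly.  Ensembles emulate a
cohort of slice cultures: intrinsic periods of the AP and 4Vep jittered
recording-to-recording (the NTS period is held at its mean), and each
recording drawing its coupling schedule — constant or linearly decaying
to zero — from a menu.  Every recording's ground truth is logged so it
can be regenerated bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import PhaseTrajectory, simulate
from .params import CouplingSchedule, OscillatorParams

__all__ = [
    "RecordingConfig",
    "EnsembleConfig",
    "Recording",
    "make_bioluminescence",
    "make_ensemble",
    "make_ensemble_member",
    "DEFAULT_SCHEDULE_MENU",
    "REGIONS",
]

REGIONS = ("AP", "NTS", "4Vep")


@dataclass(frozen=True)
class RecordingConfig:
    """Observation-model settings for one rendered recording."""

    duration: float = 150.0          # h
    sample_step: float = 1.0         # h (hourly binning)
    amplitude: tuple = (100.0, 100.0, 100.0)   # a.u., per region
    damping_time: float = 150.0      # h, exponential amplitude decay
    trend: tuple = (0.0,)            # polynomial baseline coefficients, a.u.
    noise_sd: float = 2.0            # a.u.
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.duration < 72.0:
            raise ValueError("recordings shorter than 72 h are not usable "
                             "for plateau detection or estimation")


@dataclass(frozen=True)
class EnsembleConfig:
    """Cohort-level settings: period jitter and the schedule menu."""

    n_recordings: int = 11
    tau_a_sd: float = 1.75           # h
    tau_v_sd: float = 2.03           # h  (NTS period is never jittered)
    schedule_menu: tuple = None
    recording: RecordingConfig = field(default_factory=RecordingConfig)
    seed: int = 0

    def __post_init__(self):
        if self.n_recordings < 1:
            raise ValueError("n_recordings must be at least 1")
        if self.schedule_menu is None:
            object.__setattr__(self, "schedule_menu", DEFAULT_SCHEDULE_MENU)


#: Constant couplings spanning sub- and super-critical values plus linear
#: decays reaching zero between 100 and 200 h — the regimes a cohort of
#: deteriorating slice cultures is expected to span.
DEFAULT_SCHEDULE_MENU = (
    CouplingSchedule(s0_n=1.0, c_n=0.0, s0_v=1.0, c_v=0.0),
    CouplingSchedule(s0_n=0.5, c_n=0.0, s0_v=0.5, c_v=0.0),
    CouplingSchedule(s0_n=0.0, c_n=0.0, s0_v=0.0, c_v=0.0),
    CouplingSchedule(s0_n=1.0, c_n=1.0 / 100.0, s0_v=1.0, c_v=1.0 / 100.0),
    CouplingSchedule(s0_n=1.0, c_n=1.0 / 150.0, s0_v=1.0, c_v=1.0 / 150.0),
    CouplingSchedule(s0_n=1.0, c_n=1.0 / 200.0, s0_v=1.0, c_v=1.0 / 120.0),
)


@dataclass(frozen=True)
class Recording:
    """A rendered recording plus the ground truth that produced it.

    ``seed`` is the member's substream seed: re-running the member
    generator with the same seed, ensemble config and base parameters
    reproduces the recording bit-identically.
    """

    t: np.ndarray
    series: dict                     # region name -> intensity array
    params: OscillatorParams
    schedule: CouplingSchedule
    config: RecordingConfig
    initial_phases: tuple
    trajectory: PhaseTrajectory
    seed: int = 0


def make_bioluminescence(traj: PhaseTrajectory, cfg: RecordingConfig,
                         rng: np.random.Generator | None = None) -> dict:
    """Render per-region intensity series from a phase trajectory.

    The trajectory must cover ``cfg.duration``; output is sampled on the
    trajectory grid restricted to [0, duration].  Identical seeds give
    identical arrays.
    """
    if traj.t[-1] < cfg.duration - 1e-9:
        raise ValueError(
            f"trajectory ends at {traj.t[-1]} h, shorter than the "
            f"requested {cfg.duration} h recording")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    keep = traj.t <= cfg.duration + 1e-9
    t = traj.t[keep]
    envelope = np.exp(-t / cfg.damping_time)
    baseline = np.polyval(list(cfg.trend)[::-1], t)
    out = {"t": t}
    for region, amp, theta in zip(REGIONS, cfg.amplitude,
                                  (traj.theta_a, traj.theta_n, traj.theta_v)):
        clean = amp * envelope * (1.0 + np.cos(theta[keep])) + baseline
        noise = rng.normal(0.0, cfg.noise_sd, size=t.shape) if cfg.noise_sd else 0.0
        out[region] = clean + noise
    return out


def _draw_positive(rng: np.random.Generator, mean: float, sd: float,
                   max_tries: int = 100) -> float:
    for _ in range(max_tries):
        val = rng.normal(mean, sd)
        if val > 0:
            return float(val)
    raise RuntimeError("could not draw a positive intrinsic period")


def make_ensemble_member(ens: EnsembleConfig, base_params: OscillatorParams,
                         member_seed: int) -> Recording:
    """Generate one cohort member deterministically from its seed.

    Draws τ_a and τ_v (normal jitter around the base values; τ_n stays
    at its mean, redrawing any non-positive period), picks a schedule
    from the menu, simulates from uniform random initial phases and
    renders bioluminescence — all from one substream, so the recording
    is a pure function of ``(ens, base_params, member_seed)``.
    """
    rng = np.random.default_rng(member_seed)
    tau_a = _draw_positive(rng, base_params.tau_a, ens.tau_a_sd)
    tau_v = _draw_positive(rng, base_params.tau_v, ens.tau_v_sd)
    params = replace(base_params, tau_a=tau_a, tau_v=tau_v)
    schedule = ens.schedule_menu[rng.integers(len(ens.schedule_menu))]
    init = tuple(rng.uniform(-np.pi, np.pi, size=3))
    traj = simulate(params, schedule, initial_phases=init,
                    t_span=(0.0, ens.recording.duration),
                    output_step=ens.recording.sample_step)
    series = make_bioluminescence(traj, ens.recording, rng=rng)
    return Recording(
        t=series["t"], series={r: series[r] for r in REGIONS},
        params=params, schedule=schedule, config=ens.recording,
        initial_phases=init, trajectory=traj, seed=int(member_seed))


def make_ensemble(ens: EnsembleConfig,
                  base_params: OscillatorParams) -> list[Recording]:
    """Generate a cohort of recordings with jittered periods and varied coupling.

    The single ensemble seed fans out to per-recording substream seeds
    (logged on each :class:`Recording`), so every member can be
    regenerated independently via :func:`make_ensemble_member`.
    """
    child_seeds = np.random.SeedSequence(ens.seed).generate_state(ens.n_recordings)
    return [make_ensemble_member(ens, base_params, int(s)) for s in child_seeds]
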