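"""Model parameters for the three-oscillator DVC phase model.

The dorsal vagal complex (DVC) contains three adjacent circadian
oscillators — the area postrema (AP), the nucleus of the solitary tract
(NTS, treated as a single bilateral oscillator) and the ependymal cell
layer of the 4th ventricle (4Vep).  Each oscillator *i* has an intrinsic
period ``tau_i`` (hours) and the directed coupling constant ``K_ij``
(rad/h) measures the influence of oscillator *j* on oscillator *i*.  The
AP–NTS interaction carries a phase lag ``gamma`` (radians) that shifts
the locked AP−NTS phase difference away from zero.

Global coupling control parameters ``s_n(t)`` (AP–NTS channel) and
``s_v(t)`` (AP–4Vep channel) scale the coupling constants; they model
the deterioration of inter-oscillator communication in ex vivo slices
and may decay linearly to zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from importlib import resources
from pathlib import Path

TWO_PI = 2.0 * math.pi
#: hours per radian on a 24 h cycle; the only phase-unit conversion used anywhere
HOURS_PER_RAD = 24.0 / TWO_PI


def intrinsic_frequency(tau: float) -> float:
    """Angular frequency (rad/h) of an oscillator with period ``tau`` hours.

    Raises ``ValueError`` for non-positive periods.
    """
    if tau <= 0:
        raise ValueError(f"intrinsic period must be positive, got {tau}")
    return TWO_PI / tau


@dataclass(frozen=True)
class OscillatorParams:
    """Intrinsic periods, directed couplings and AN phase lag.

    ``K_ij`` is the influence of oscillator *j* on oscillator *i*, in
    rad/h; positive couplings are attractive (promote in-phase locking),
    negative are repulsive (promote antiphase locking).  NTS–4Vep
    interactions are assumed negligible, so ``K_nv = K_vn = 0`` by
    default.
    """

    tau_a: float
    tau_n: float
    tau_v: float
    K_an: float
    K_na: float
    K_av: float
    K_va: float
    gamma: float
    K_nv: float = 0.0
    K_vn: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tau_a", "tau_n", "tau_v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # --- derived angular frequencies -------------------------------------
    @property
    def omega_a(self) -> float:
        return intrinsic_frequency(self.tau_a)

    @property
    def omega_n(self) -> float:
        return intrinsic_frequency(self.tau_n)

    @property
    def omega_v(self) -> float:
        return intrinsic_frequency(self.tau_v)

    @property
    def omega_an(self) -> float:
        """AP−NTS frequency detuning, rad/h."""
        return self.omega_a - self.omega_n

    @property
    def omega_av(self) -> float:
        """AP−4Vep frequency detuning, rad/h."""
        return self.omega_a - self.omega_v

    # --- symmetric / antisymmetric coupling combinations ------------------
    @property
    def K_tilde_an(self) -> float:
        """Total AN-channel coupling K_an + K_na."""
        return self.K_an + self.K_na

    @property
    def K_tilde_av(self) -> float:
        """Total AV-channel coupling K_av + K_va."""
        return self.K_av + self.K_va

    @property
    def delta_K_an(self) -> float:
        """Coupling asymmetry K_na − K_an."""
        return self.K_na - self.K_an

    @property
    def delta_K_av(self) -> float:
        """Coupling asymmetry K_va − K_av."""
        return self.K_va - self.K_av

    # --- transforms -------------------------------------------------------
    def with_halved_K_an(self) -> "OscillatorParams":
        """Parameters after surgical removal of one bilateral NTS.

        Removing one side of the (bilateral, symmetric) NTS halves the
        NTS→AP influence: ``K_an → K_an / 2``; everything else is
        unchanged.
        """
        return replace(self, K_an=0.5 * self.K_an)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OscillatorParams":
        known = {f: d[f] for f in cls.__dataclass_fields__ if f in d}
        return cls(**known)


# Backwards-compatible functional alias used by the experiments module.
def disconnection_transform(params: OscillatorParams) -> OscillatorParams:
    """Halve K_an to emulate disconnecting one bilateral NTS from the AP."""
    return params.with_halved_K_an()


@dataclass(frozen=True)
class CouplingSchedule:
    """Time courses of the global coupling parameters.

    Each channel coupling is ``s_i(t) = max(s0_i − c_i·t, 0)``: constant
    for ``c_i = 0``, otherwise linearly decaying and clipped at zero.
    ``s0 = 1`` with ``c = 0`` reproduces the fitted coupling constants
    unchanged.
    """

    s0_n: float = 1.0
    c_n: float = 0.0
    s0_v: float = 1.0
    c_v: float = 0.0

    def __post_init__(self) -> None:
        if self.s0_n < 0 or self.s0_v < 0:
            raise ValueError("initial coupling s0 must be non-negative")
        if self.c_n < 0 or self.c_v < 0:
            raise ValueError("decay rates c must be non-negative")

    def s_n(self, t):
        import numpy as np

        return np.maximum(self.s0_n - self.c_n * np.asarray(t, dtype=float), 0.0)

    def s_v(self, t):
        import numpy as np

        return np.maximum(self.s0_v - self.c_v * np.asarray(t, dtype=float), 0.0)

    def to_dict(self) -> dict:
        return asdict(self)


CONSTANT_COUPLING = CouplingSchedule()


# --- parameter file I/O ----------------------------------------------------

def load_params(path: str | Path) -> tuple[OscillatorParams, CouplingSchedule | None]:
    """Read an ``OscillatorParams`` (and optional schedule) from JSON.

    The file carries keys ``tau_a .. gamma`` and optionally a
    ``schedule`` object with ``s0_n, c_n, s0_v, c_v``.
    """
    with open(path) as fh:
        d = json.load(fh)
    sched = None
    if "schedule" in d:
        sched = CouplingSchedule(**d.pop("schedule"))
    return OscillatorParams.from_dict(d), sched


def save_params(params: OscillatorParams, path: str | Path,
                schedule: CouplingSchedule | None = None) -> None:
    d = params.to_dict()
    if schedule is not None:
        d["schedule"] = schedule.to_dict()
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)
        fh.write("\n")


def default_params() -> OscillatorParams:
    """The fitted DVC parameter means shipped with the package.

    AP intrinsic period 25.7 h, NTS 22.5 h, 4Vep 23.4 h; attractive
    reciprocal AP–NTS coupling (K_an=0.031, K_na=0.041 rad/h) with phase
    lag 0.770 rad; repulsive AP–4Vep coupling (K_av=−0.045,
    K_va=−0.007 rad/h); no NTS–4Vep coupling.
    """
    with resources.files("phasekit.data").joinpath("dvc_fitted_params.json").open() as fh:
        return OscillatorParams.from_dict(json.load(fh))
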