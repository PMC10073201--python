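"""End-to-end in-silico experiments on the DVC oscillator model.

Three scripted scenarios, each returning plain tables:

* a global-coupling sweep — PD dynamics across the synchronisation
  transition, with the bifurcation branch overlay;
* a cohort of recordings with constant or decaying coupling — the full
  simulate → render → wavelet → PD → metrics pipeline per member;
* the NTS-disconnection experiment — one bilateral NTS removed halves
  the NTS→AP coupling, while the detached NTS runs free at its
  intrinsic period.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import wavelet
from .bifurcation import continuation, fixed_points, fold_point, sweep_dynamics
from .metrics import find_constant_pd_segments, stability_score
from .model import phases_to_pd, simulate
from .params import (
    HOURS_PER_RAD,
    CouplingSchedule,
    OscillatorParams,
    disconnection_transform,
)
from .synth import EnsembleConfig, Recording, RecordingConfig, make_ensemble

__all__ = [
    "run_coupling_sweep",
    "run_decay_ensemble",
    "run_disconnection",
    "analyze_recording",
]


def run_coupling_sweep(params: OscillatorParams, s_values=None,
                       initial_pd_rad=(1.5, 1.5),
                       t_span=(0.0, 200.0)) -> dict:
    """PD dynamics and steady states across a grid of global couplings.

    Returns a summary table (per s: classification, steady PDs in hours
    when locked, drift slope when not), the per-s PD series, and the
    fixed-point branch data for overlay.
    """
    if s_values is None:
        s_values = np.round(np.arange(0.1, 1.25, 0.05), 3)
    dyn = sweep_dynamics(params, s_values, initial_pd_rad=initial_pd_rad,
                         t_span=t_span)
    rows = []
    for s, d in dyn.items():
        stable = [fp for fp in fixed_points(params, s) if fp.stable] if s > 0 else []
        locked = d["classification"] == "locked"
        rows.append({
            "s": s,
            "classification": d["classification"],
            "theta_an_h": stable[0].theta_an * HOURS_PER_RAD if locked and stable else np.nan,
            "theta_av_h": stable[0].theta_av * HOURS_PER_RAD if locked and stable else np.nan,
            "drift_rate_rad_per_h": np.nan if locked else d["drift_rate_rad_per_h"],
        })
    summary = pd.DataFrame(rows).sort_values("s").reset_index(drop=True)
    branch = continuation(params, s_min=max(0.05, min(s_values)),
                          s_max=max(s_values), n_steps=300)
    return {"summary": summary, "dynamics": dyn, "branch": branch,
            "s_fold": fold_point(params)}


def analyze_recording(rec_t, rec_series: dict, sample_step: float = 1.0,
                      cutoff: float = 48.0, min_period: float = 10.0,
                      max_period: float = 48.0, n_periods: int = 101) -> dict:
    """Wavelet stage for one recording: ridges, PDs, scores and segments."""
    ridges = {}
    for region, series in rec_series.items():
        det = wavelet.sinc_detrend(series, dt=sample_step, cutoff_period=cutoff)
        spec = wavelet.cwt_spectrum(det, t=rec_t, min_period=min_period,
                                    max_period=max_period, n_periods=n_periods)
        ridges[region] = wavelet.extract_ridge(spec)
    regions = list(rec_series)
    ref = regions[0]
    pds, scores, segments = {}, {}, {}
    for other in regions[1:]:
        key = f"{ref}-{other}"
        pd_series = wavelet.pd_from_ridges(ridges[ref], ridges[other], name=key)
        pds[key] = pd_series
        scores[key] = stability_score(pd_series).y
        segments[key] = find_constant_pd_segments(
            pd_series, ridges[ref], ridges[other])
    periods = {r: wavelet.time_averaged_period(ridges[r]) for r in regions}
    return {"ridges": ridges, "pds": pds, "stability": scores,
            "segments": segments, "periods": periods}


def run_decay_ensemble(base_params: OscillatorParams,
                       ens: EnsembleConfig) -> dict:
    """Full pipeline over a synthetic cohort.

    Per member: simulate, render, wavelet-analyse, score PD stability
    and detect plateaus.  Returns the recordings (with ground truth),
    per-member analyses, and two summary tables: observed periods per
    oscillator and PD stability/plateau counts per channel.
    """
    recordings = make_ensemble(ens, base_params)
    analyses, period_rows, pd_rows = [], [], []
    for k, rec in enumerate(recordings):
        res = analyze_recording(rec.t, rec.series,
                                sample_step=ens.recording.sample_step)
        analyses.append(res)
        row = {"recording": k, "seed": rec.seed,
               "tau_a_true": rec.params.tau_a, "tau_v_true": rec.params.tau_v,
               "s0_n": rec.schedule.s0_n, "c_n": rec.schedule.c_n,
               "s0_v": rec.schedule.s0_v, "c_v": rec.schedule.c_v}
        for region, per in res["periods"].items():
            row[f"period_{region}_h"] = per
        period_rows.append(row)
        for channel, segs in res["segments"].items():
            pd_rows.append({
                "recording": k, "channel": channel,
                "stability_y": res["stability"][channel],
                "n_plateaus": len(segs),
                "multistable": len(segs) > 1,
                "theta_star_h": segs[0].theta_star if segs else np.nan,
            })
    return {"recordings": recordings, "analyses": analyses,
            "period_table": pd.DataFrame(period_rows),
            "pd_table": pd.DataFrame(pd_rows)}


def _observed_period(params: OscillatorParams, schedule: CouplingSchedule,
                     which: str, duration: float,
                     initial_phases=(0.0, 0.0, 0.0)) -> float:
    """Ridge time-averaged period of one oscillator in a noise-free render."""
    traj = simulate(params, schedule, initial_phases=initial_phases,
                    t_span=(0.0, duration))
    cfg = RecordingConfig(duration=duration, noise_sd=0.0)
    series = (traj.theta_a, traj.theta_n, traj.theta_v)
    theta = dict(zip(("AP", "NTS", "4Vep"), series))[which]
    intensity = 100.0 * np.exp(-traj.t / cfg.damping_time) * (1 + np.cos(theta))
    det = wavelet.sinc_detrend(intensity, dt=traj.t[1] - traj.t[0])
    spec = wavelet.cwt_spectrum(det, t=traj.t)
    return wavelet.time_averaged_period(wavelet.extract_ridge(spec))


def _locked_initial_phases(params: OscillatorParams):
    stable = [fp for fp in fixed_points(params, 1.0) if fp.stable]
    if not stable:
        return (0.0, 0.0, 0.0)
    fp = stable[0]
    return (0.0, -fp.theta_an, -fp.theta_av)


def run_disconnection(params: OscillatorParams,
                      duration: float = 150.0) -> pd.DataFrame:
    """In-silico NTS disconnection: observed periods before and after.

    The intact system (AP, NTS, 4Vep; full coupling) is compared with
    the operated one: APx–NTSc–4Vep with K_an halved, plus the detached
    NTSd simulated fully uncoupled.  Periods are ridge time-averages
    over the recording, as for real data.
    """
    constant = CouplingSchedule()
    rows = []
    ic = _locked_initial_phases(params)
    for osc in ("AP", "NTS", "4Vep"):
        rows.append({"oscillator": osc, "preparation": "intact",
                     "period_h": _observed_period(params, constant, osc,
                                                  duration, ic)})
    cut = disconnection_transform(params)
    ic_cut = _locked_initial_phases(cut)
    for osc, label in (("AP", "APx"), ("NTS", "NTSc"), ("4Vep", "4Vep")):
        rows.append({"oscillator": label, "preparation": "disconnected",
                     "period_h": _observed_period(cut, constant, osc,
                                                  duration, ic_cut)})
    free = OscillatorParams(tau_a=params.tau_a, tau_n=params.tau_n,
                            tau_v=params.tau_v, K_an=0.0, K_na=0.0,
                            K_av=0.0, K_va=0.0, gamma=params.gamma)
    rows.append({"oscillator": "NTSd", "preparation": "disconnected",
                 "period_h": _observed_period(free, constant, "NTS", duration)})
    return pd.DataFrame(rows)
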