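#!/usr/bin/env python
"""How PD dynamics change as the global coupling weakens.

Sweeps the global coupling parameter s of the fitted three-oscillator
DVC model, classifies the long-run PD behaviour at each value, and
traces the fixed-point branches.  The locked state disappears at a fold
bifurcation near s ≈ 0.31: above it the two phase differences settle at
constants (θ*_an ≈ 1.7 h, θ*_av ≈ 10.9 h at s = 1); just below it the
PDs linger on long plateaus between rapid slips; far below they drift
at nearly the intrinsic detuning rate.

Writes results/coupling_sweep.csv and results/bifurcation_branches.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import phasekit as pk
from phasekit.experiments import run_coupling_sweep


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    params = pk.default_params()
    s_values = np.round(np.arange(0.10, 1.25, 0.05), 3)
    res = run_coupling_sweep(params, s_values=s_values)

    res["summary"].to_csv(args.out_dir / "coupling_sweep.csv", index=False)
    rows = []
    for s, fps in zip(res["branch"].s, res["branch"].points):
        for fp in fps:
            rows.append({"s": s,
                         "theta_an_h": fp.theta_an * pk.HOURS_PER_RAD,
                         "theta_av_h": fp.theta_av * pk.HOURS_PER_RAD,
                         "stability": fp.stability})
    pd.DataFrame(rows).to_csv(args.out_dir / "bifurcation_branches.csv",
                              index=False)

    locked = res["summary"].query("classification == 'locked'")
    print(f"fold bifurcation at s_fold = {res['s_fold']:.4f}")
    print(f"locked for s >= {locked.s.min():.2f}; at s = 1 the stable PDs are "
          f"theta_an* = {locked.query('s == 1.0').theta_an_h.iloc[0]:.2f} h, "
          f"theta_av* = {locked.query('s == 1.0').theta_av_h.iloc[0]:.2f} h")
    print(f"wrote {args.out_dir/'coupling_sweep.csv'} and "
          f"{args.out_dir/'bifurcation_branches.csv'}")


if __name__ == "__main__":
    main()
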