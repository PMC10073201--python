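#!/usr/bin/env python
"""A cohort of synthetic recordings with constant or decaying coupling.

Simulates an ensemble of 11 DVC-like slice recordings (AP and 4Vep
intrinsic periods jittered recording-to-recording; coupling either
constant or decaying linearly to zero between 100 and 200 h), renders
each as hourly-binned bioluminescence, and runs the full wavelet → PD →
metrics pipeline on every member.  The cohort reproduces the
qualitative menagerie seen in ex vivo data: persistently locked PDs,
immediate drifters, and plateau-then-drift traces whose drift onset
follows the coupling's crossing of the fold.

Writes results/ensemble_periods.csv, results/ensemble_pd_metrics.csv
and per-recording CSVs under results/ensemble_recordings/.
"""

import argparse
from pathlib import Path

import phasekit as pk
from phasekit import io as pkio
from phasekit.experiments import run_decay_ensemble


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-recordings", type=int, default=11)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    rec_dir = args.out_dir / "ensemble_recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)

    params = pk.default_params()
    ens = pk.EnsembleConfig(n_recordings=args.n_recordings, seed=args.seed)
    res = run_decay_ensemble(params, ens)

    res["period_table"].to_csv(args.out_dir / "ensemble_periods.csv",
                               index=False)
    res["pd_table"].to_csv(args.out_dir / "ensemble_pd_metrics.csv",
                           index=False)
    for k, rec in enumerate(res["recordings"]):
        pkio.write_recording(rec_dir / f"recording_{k:02d}.csv",
                             rec.t, rec.series)

    pdt = res["pd_table"]
    print(f"{args.n_recordings} recordings, seed {args.seed}")
    print(f"stability scores span {pdt.stability_y.min():.3f} – "
          f"{pdt.stability_y.max():.3f} "
          f"(uniform-histogram floor is {1/96:.3f})")
    locked = pdt[pdt.n_plateaus >= 1]
    print(f"{len(locked)}/{len(pdt)} channel traces show at least one "
          f"constant-PD segment; {int(pdt.multistable.sum())} are multistable")
    print(f"wrote tables to {args.out_dir}/ and recordings to {rec_dir}/")


if __name__ == "__main__":
    main()
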