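#!/usr/bin/env python
"""In-silico analogue of the surgical NTS disconnection experiment.

Removing one bilateral NTS halves the NTS→AP coupling (K_an → K_an/2)
while the detached half (NTSd) runs completely uncoupled.  Because the
halving removes only ~21.5% of the total AN-channel coupling, the AP's
observed period barely moves, whereas the detached NTS reverts to its
much faster intrinsic 22.5 h period — matching the asymmetry seen
experimentally.

Writes results/disconnection_periods.csv.
"""

import argparse
from pathlib import Path

import phasekit as pk
from phasekit.experiments import run_disconnection


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    params = pk.default_params()
    table = run_disconnection(params)
    table.to_csv(args.out_dir / "disconnection_periods.csv", index=False)

    get = lambda osc: table.query(f"oscillator == '{osc}'").period_h.iloc[0]
    print(table.to_string(index=False))
    print()
    print(f"AP period shift after halving K_an: "
          f"{abs(get('APx') - get('AP')):.3f} h (< 0.5 h: 'relatively unaffected')")
    print(f"detached NTS reverts to its intrinsic period: "
          f"{get('NTSd'):.2f} h vs connected {get('NTSc'):.2f} h")
    cut = pk.disconnection_transform(params)
    frac = (params.K_tilde_an - cut.K_tilde_an) / params.K_tilde_an
    print(f"halving K_an removes {100*frac:.1f}% of the total AN coupling")


if __name__ == "__main__":
    main()
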