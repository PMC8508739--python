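#!/usr/bin/env python
"""Generate the synthetic study inputs for the downstream analysis steps.

Produces, under results/inputs/:
* a 19-wavelength TCSPC decay bundle (320-410 nm, 5 nm step) with lifetimes
  5.1/1.9/0.1 ns at peak 1e4 counts, plus the Gaussian IRF (FWHM 1.2 ns) and
  a manifest;
* a steady-state emission spectrum;
* urea transition curves for three optical parameters (tau1, ellipticity at
  222 nm, I320/I360) sharing midpoints 1.5 and 4.0 M;
* a toy two-tryptophan structure and a 200-frame jittered trajectory.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from unfoldscope import cli_io, simulate
from unfoldscope.transitions import DoubleBoltzmannParams

SEED = 2021
OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    bundle = simulate.simulate_decays(simulate.DecaySimSpec(seed=SEED))
    rows = []
    for tr in bundle.traces:
        name = f"decay_{int(tr.wavelength)}nm.tsv"
        pd.DataFrame({"channel": np.arange(tr.n_channels),
                      "counts": tr.counts}).to_csv(OUT / name, sep="\t",
                                                   index=False)
        rows.append({"file": name, "wavelength_nm": tr.wavelength})
    pd.DataFrame(rows).to_csv(OUT / "manifest.tsv", sep="\t", index=False)
    pd.DataFrame({"channel": np.arange(bundle.irf.counts.size),
                  "counts": bundle.irf.counts}).to_csv(OUT / "irf.tsv",
                                                       sep="\t", index=False)
    print(f"wrote {len(bundle.traces)} decay traces + IRF")

    wl = np.arange(305.0, 451.0)
    pd.DataFrame({
        "wavelength_nm": wl,
        "intensity": 100.0 * np.exp(-0.5 * ((wl - 345.0) / 28.0) ** 2),
    }).to_csv(OUT / "spectrum.tsv", sep="\t", index=False)

    # three optical probes of the same two-step unfolding: native baseline,
    # signed amplitude and noise level differ per probe
    truths = {
        "tau1_ns": DoubleBoltzmannParams(6.0, -2.5, 0.5, 1.5, 4.0, 0.3, 0.3),
        "theta222": DoubleBoltzmannParams(-12.0, 10.0, 0.4, 1.5, 4.0,
                                          0.35, 0.45),
        "I320_over_I360": DoubleBoltzmannParams(1.6, -0.5, 0.25, 1.5, 4.0,
                                                0.3, 0.35),
    }
    for name, truth in truths.items():
        curve = simulate.simulate_transition_curve(simulate.CurveSimSpec(
            truth=truth, noise_sd=0.01, signal_name=name, seed=SEED,
        ))
        pd.DataFrame({"urea_M": curve.denaturant,
                      "signal": curve.signal}).to_csv(
            OUT / f"curve_{name}.tsv", sep="\t", index=False)
    print(f"wrote {len(truths)} transition curves")

    toy = simulate.build_toy_structure(simulate.ToyStructureSpec(
        indole_pairs=(simulate.IndolePairSpec(separation=6.0),),
        n_background_atoms=150, placement_box=30.0, seed=SEED,
    ))
    cli_io.write_pdb(toy, OUT / "structure.pdb")
    traj = simulate.simulate_trajectory(toy, 200, 0.3, seed=SEED)
    cli_io.write_pdb(traj, OUT / "trajectory.pdb")
    print(f"wrote structure ({toy.n_atoms} atoms) and 200-frame trajectory")


if __name__ == "__main__":
    main()
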