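#!/usr/bin/env python
"""Global reconvolution fit of the synthetic decay bundle + DAS.

Fits the three shared lifetimes across all 19 emission wavelengths, reports
the reduced chi^2, and partitions the steady-state spectrum into
decay-associated spectra.  Writes results/decay_fit.json and results/das.tsv.
"""

from pathlib import Path

from unfoldscope import cli_io, tcspc

SEED = 2021
ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    traces = cli_io.load_decay_bundle(ROOT / "inputs" / "manifest.tsv")
    irf = cli_io.read_irf(ROOT / "inputs" / "irf.tsv")
    fit = tcspc.global_fit(traces, irf, n_components=3, seed=SEED)
    cli_io.dump_json(cli_io.fit_report_dict(fit), ROOT / "decay_fit.json")
    taus = fit.model.lifetimes
    print(f"lifetimes: tau1 = {taus[0]:.3f} ns, tau2 = {taus[1]:.3f} ns, "
          f"tau3 = {taus[2]:.3f} ns (generated: 5.1 / 1.9 / 0.1)")
    print(f"reduced chi^2 = {fit.chi2_reduced:.3f}, converged = {fit.converged}")

    spectrum = cli_io.read_spectrum(ROOT / "inputs" / "spectrum.tsv")
    frac, mean_frac = tcspc.spectral_fractions(fit)
    das = tcspc.decay_associated_spectra(frac, fit.model.wavelengths, spectrum)
    cli_io.write_das_table(das, ROOT / "das.tsv")
    resolvable = mean_frac[:2] / mean_frac[:2].sum()
    print(
        "mean spectral fractions: "
        + ", ".join(f"f{i + 1} = {f:.3f}" for i, f in enumerate(mean_frac))
    )
    print(f"tau1:tau2 split = {100 * resolvable[0]:.1f}% : "
          f"{100 * resolvable[1]:.1f}% (generated 45:55)")


if __name__ == "__main__":
    main()
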