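# unfoldscope

Analysis toolkit for equilibrium protein-unfolding studies that combine
time-resolved tryptophan fluorescence, steady-state spectroscopy and
structure-based reasoning — the workflow used to compare the conformational
stability of homologous multi-tryptophan proteins (e.g. the two-subunit
bacterial luciferases) along a urea denaturation series.

It is aimed at spectroscopists and structural biologists who need to go from
raw photon-count histograms and denaturation series to interpretable
thermodynamic and structural quantities, with every stage testable on
synthetic data.

## What it computes

**Global TCSPC decay analysis.** The photon histogram at emission wavelength
λ is modelled as the instrument response S(t) reconvolved with a
multi-exponential decay,

    I_λ(t) = S(t) ⊗ Σᵢ α_{iλ} e^(−t/τᵢ) + b_λ ,

with the lifetimes τᵢ shared across all wavelengths (default three
components) and the amplitudes α_{iλ} and backgrounds b_λ free per trace.
Fitting uses Poisson weights 1/max(counts, 1) and variable projection
(non-negative weighted least squares for the amplitudes inside a damped
least-squares loop over the lifetimes, with a seeded multi-start).  The
spectral fraction of component i at λ is

    f_{iλ} = α_{iλ} τᵢ / Σⱼ α_{jλ} τⱼ ,

and the decay-associated spectra partition the steady-state spectrum as
I_{iλ} = f_{iλ} · I_ss(λ).

**Denaturation thermodynamics.** A scalar optical parameter y(u) versus
denaturant molarity u (a lifetime, the 222 nm molar ellipticity Θ₂₂₂, or the
intensity ratio I₃₂₀/I₃₆₀) is fit with the double-Boltzmann model

    y(u) = y₀ + A·[ p/(1+e^((c₁−u)/k₁)) + (1−p)/(1+e^((c₂−u)/k₂)) ] ,

giving per-transition midpoints [Urea]₅₀% = cᵢ, widths kᵢ and amplitude
fractions.  Each transition is mapped to two-state linear-extrapolation
thermodynamics: mᵢ = RT/kᵢ and ΔG_H₂O,ᵢ = mᵢ·cᵢ.

**Tryptophan microenvironments.** Per tryptophan and per structural model:
the number of protein atoms within 7 Å (N_Σ) and the polar atoms among them
(N_pol), absolute and relative solvent-accessible surface area
(Shrake–Rupley), the share of neighbors in a chosen domain (e.g. the
α-subunit C-terminal domain, residues 236–355) and in helices/strands, atoms
of the other subunit near the side chain, and contacts with recognised
indole quenchers (Lys/Tyr proton donors, Cys sulfur, His/Gln/Asn amides,
Asp/Glu carboxyls, backbone carbonyls near the ring Cε3 atom).

**Trp–Trp FRET geometry.** Indole ring centers, ¹La transition-dipole
vectors (in-plane, at a configurable angle from the projected CE3→NE1 axis),
the orientation factor

    κ² = (cos θ − 3 cos θ_A cos θ_D)²  ∈ [0, 4] ,

the transfer efficiency E = 1/(1 + (2/3)/κ²·(R/R₀)⁶) with R₀ = 7.8 Å for
the Trp–Trp pair, and center–center distance distributions across
multi-model (trajectory) files.

**Synthetic data.** Seedable generators for every input: Poisson-noised
reconvolved decay bundles with known lifetimes, noised double-sigmoid
transition curves, and toy indole-pair structures/trajectories with
controlled distance and orientation.

## Worked example

```sh
python analysis/01_simulate_inputs.py
python analysis/02_fit_decays.py
```

prints, for a bundle generated with lifetimes 5.1/1.9/0.1 ns and a 45:55
spectral split between the two resolvable components:

```
lifetimes: tau1 = 5.172 ns, tau2 = 1.913 ns, tau3 = 0.104 ns (generated: 5.1 / 1.9 / 0.1)
reduced chi^2 = 1.034, converged = True
mean spectral fractions: f1 = 0.399, f2 = 0.501, f3 = 0.100
tau1:tau2 split = 44.3% : 55.7% (generated 45:55)
```

The lifetimes are recovered to ~1%, the reduced χ² of the Poisson-weighted
global fit sits at 1, and the decay-associated spectra return the generated
spectral split.  `analysis/03…05` continue the same narrative: transition
midpoints 1.5/4.0 M urea recovered to ±0.1 M with their m-values and
ΔG_H₂O, the per-tryptophan microenvironment table over trajectory frames,
and the FRET report, e.g.

```
static pair: R = 6.00 A, kappa2 = 1.000 (range 1.000-1.000 over +/-15 deg of dipole angle), E = 87.9% at R0 = 7.8 A
trajectory: 200 frames, R = 6.02 +/- 0.14 A (range 5.57-6.33 A)
```

The same stages are available as a CLI (`unfoldscope fit-decays`,
`unfoldscope das`, `unfoldscope transitions`, `unfoldscope microenv`,
`unfoldscope fret`, `unfoldscope trp-dist`, `unfoldscope simulate …`,
`unfoldscope run --config run.yaml`).

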