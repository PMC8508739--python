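# Methods

This note records the models, conventions and numerical choices behind
unfoldscope, and what the synthetic-data tests do and do not demonstrate.

## TCSPC forward model and global fit

The expected count in channel k of the trace at wavelength λ is the measured
IRF histogram reconvolved with a sum of exponentials plus a flat background.
Two discretisation conventions matter:

* **Bin-integrated kernel.** The IRF mass of each channel is treated as
  uniform across the bin and the exponential is integrated over it
  analytically; the emission bin coinciding with the excitation bin
  contributes only its causal half.  This makes the discrete model agree
  with the continuous convolution integral to better than 0.1% wherever the
  signal exceeds 10% of its peak (the plain lattice convolution is biased by
  half a channel, several percent on the rising edge).  The residual
  consequence: a delta-function IRF yields the pure exponential shape with
  a constant amplitude factor 1 + (Δt/τ)²/24 (≈10⁻⁵ at Δt = 0.027 ns) and a
  half-weight excitation channel.
* **Grid.** Channels are 0-based with width 0.027 ns (the instrument's
  time resolution); wavelengths in nm.  An optional fractional-channel IRF
  shift (linear interpolation) can be fit globally to absorb color-shift
  artifacts; it is off by default.

Weights are Neyman, 1/max(counts, 1) — standard TCSPC practice,
well-behaved at empty channels.  The background is one additive constant per
trace, estimated as a free non-negative column in the linear solve.  The fit
window runs from 5 channels before the IRF peak to the last channel with at
least one count (configurable).

**Optimisation.** For trial lifetimes, the per-trace amplitudes and
background are profiled out by weighted non-negative least squares (variable
projection), so the outer damped least-squares loop sees only the
log-parameterised lifetimes (plus the optional shift).  Five starting points
(one geometric spread over the observable range, the rest seeded
log-uniform) guard against local minima; the lowest global χ² wins.
Lifetimes are reported sorted descending, so τ₁ is always the longest.
Adjacent lifetime estimates within 5% of each other, and a shortest lifetime
below 1.5× the channel width, are recorded as warnings rather than errors —
the instrument cannot resolve components much shorter than its channel
width, so τ₃ ≈ 0.1 ns is reported but treated as qualitative.  The reduced
χ² on correctly specified Poisson data sits slightly above 1 (≈1.04 at peak
10⁴ counts), the known small bias of Neyman weights.

## Decay-associated spectra

f_{iλ} = α_{iλ}τᵢ / Σⱼ α_{jλ}τⱼ; the total fraction per component is the
unweighted mean of f_{iλ} over the fitted wavelengths.  Wavelengths where
all amplitudes vanish yield missing fractions and are excluded from means.
Component spectra are f_{iλ}·I_ss(λ) with I_ss linearly interpolated onto
the decay wavelengths; sums over components reproduce I_ss identically by
construction, and the conservation is asserted to 1e-9 in tests.

## Transition fitting and thermodynamics

The double-Boltzmann uses a shared baseline y₀, one signed total amplitude A
and an amplitude fraction p for the first transition; with p = 1 it reduces
exactly to a single Boltzmann.  Midpoints are reported ordered (c₁ < c₂;
swapping relabels p → 1−p), which also makes the fit invariant to swapped
initial midpoint guesses.  Initialisation takes the two largest interior
steps of an edge-padded smoothed derivative; three additional deterministic
starts with evenly spaced midpoints protect against local minima.  A
constant signal is flagged as non-converged, not raised; amplitude fractions
collapsing below 0.05 or above 0.95 warn that the data may hold a single
transition.  Standard errors come from the Jacobian at the optimum scaled by
the residual variance.

The mapping to thermodynamics treats each sigmoid as an independent
two-state transition under the linear extrapolation model: m = RT/k
(R = 8.314 J·mol⁻¹·K⁻¹, default T = 298.15 K, i.e. 25 °C) and
ΔG_H₂O = m·[Urea]₅₀%.  This is the standard width→m-value identification;
it is an interpretation layered on the curve fit, not part of it, and users
comparing against other software should check which convention it used.
Sloping native/unfolded baselines are not fit by default.

## Structure descriptors

* Hydrogens are excluded from all counts and areas by default so crystal
  structures and MD frames are comparable; configurable.
* Polar atoms are N and O; sulfur can be included by flag.
* The tryptophan's own atoms never count toward its microenvironment.
* Neighbor counting takes the minimum distance from the candidate atom to
  the reference set (all atoms, or side-chain atoms for the other-subunit
  count) with a ≤ cutoff test at 7 Å default; it is verified exactly
  against an exhaustive all-pairs oracle.
* SASA is Shrake–Rupley with a deterministic golden-spiral quadrature
  (960 points/atom default), probe 1.4 Å, and the fixed vdW radii
  C 1.70 / N 1.55 / O 1.52 / S 1.80 / H 1.20 / P 1.80 Å; unknown elements
  fall back to 1.70 Å with a warning.  Relative SASA divides by the residue
  computed in isolation (all other residues deleted) — the most literal
  "percent of the residue's total surface".
* Secondary structure comes from PDB HELIX/SHEET records when present; the
  fallback is a φ/ψ-window heuristic (helix: φ ∈ (−100°, −30°),
  ψ ∈ (−80°, −5°); strand: φ ∈ (−180°, −80°), ψ > 90° or < −170°) requiring
  runs of ≥ 3 residues.  It approximates, and does not reproduce, DSSP.
* Quencher screening reports Lys NZ / Tyr OH (proton transfer), Cys SG,
  His/Gln/Asn amide and Asp/Glu carboxyl atoms (electron transfer) by
  minimum distance to the nine ring atoms, and backbone carbonyl carbons by
  distance from the ring CE3 atom (the residue's own carbonyl included),
  within 5.5 Å by default.  The carbonyl distance endpoint is the carbon
  atom; the oxygen would differ by ≲1 Å.
* Multi-model files are analysed per model with mean ± sd summaries.

## FRET geometry

The ¹La transition dipole direction in the indole plane is not uniquely
standardised; the package uses the CE3→NE1 long axis projected into the
best-fit ring plane, rotated about the plane normal by a configurable angle
with default −38° (a common literature convention), and always reports a
κ² sensitivity range over ±15° of that angle.  Static-structure FRET uses
unweighted geometric ring centroids; trajectory distance distributions use
mass-weighted centers (C 12.011, N 14.007) — each overridable.  κ² = 0 maps
to E = 0 by continuity.  R₀ defaults to 7.8 Å for the Trp–Trp pair and is
configurable; the package does not compute R₀ from spectra.

The plane normal is oriented deterministically by the ring's atom order
(cross product of CG→NE1 and CG→CD2), so rigid motions transform dipoles
rigidly and κ² is exactly invariant under rigid-body moves and under
donor/acceptor exchange.

## Synthetic-data generators

The generators produce data with exactly the statistical structure the
fitting stages assume — which is what makes recovery tests meaningful and
also bounds what they show:

* **Decays.** Expectations are the same reconvolution forward model used in
  fitting; counts are Poisson.  Defaults mirror the instrument conditions:
  19 wavelengths 320–410 nm (5 nm step), 0.027 ns/channel, 1024 channels,
  Gaussian IRF of FWHM 1.2 ns (peak 10⁴ counts, rounded, noiseless),
  expected peak 10⁴ counts, background 2 counts/channel, lifetimes
  5.1/1.9/0.1 ns.  The component amplitude bands are Gaussians (centers
  355/340/330 nm, σ 25 nm, component 1 reddest so fractions vary with
  wavelength); their amplitudes are solved so the wavelength-mean spectral
  fractions are exactly 40.5/49.5/10% — a 45:55 split between the two
  resolvable components with 10% in the sub-resolution component.
* **Transition curves.** Double-Boltzmann truth (defaults: baseline 6.0,
  amplitude −2.5, equal fractions, midpoints 1.5/4.0 M, widths 0.3 M —
  a lifetime-like probe with transitions below 2 M and near 4 M urea) with
  multiplicative Gaussian noise (default 1%) on a 24-point 0–8 M grid.
* **Structures.** Idealised planar indole rings (regular hexagon + pentagon,
  1.40 Å bonds) placed at controlled separation/orientation — the default
  pair has parallel in-plane dipoles perpendicular to the separation, so
  κ² = 1 by construction — plus uniformly random background carbon atoms
  with a 2 Å minimum separation (resampled, then an error after a retry
  limit).  Coordinates are rounded to 0.001 Å so PDB round-trips are exact.
* **Trajectories.** i.i.d. Gaussian per-atom jitter per frame: frame
  bookkeeping only, no physics.

What passing tests therefore show: the estimators are consistent and
well-calibrated when their model is correct, and the geometric/counting code
is exact.  What they do not show: robustness to model misspecification in
real measurements — detector afterpulsing and pile-up, wavelength-dependent
IRF shift, correlated baseline drift, non-two-state transitions, sloping
baselines, real side-chain dynamics, or hydrogen placement differences.
Real Trp-containing proteins also have non-ring side-chain atoms that the
toy rings omit (only the nine ring atoms are generated).

## Problem sizes and runtimes

Recovery statistics use 20 seeds of the full 19-wavelength bundle (global
fit ≈ 0.5 s each), 20 seeds of 24-point transition curves, 50 random toy
structures for the neighbor-count oracle, and 10⁶ Monte-Carlo draws for the
isotropic ⟨κ²⟩ = 2/3 check; the trajectory analyses use 200 frames of a
~170-atom structure.  These sizes give sub-percent standard errors on every
reported quantity while keeping the whole acceptance run under a minute.

## Known limitations

* No maximum-entropy lifetime distributions, anisotropy or phasor analysis.
* No mmCIF input; no protonation assignment.
* ΔG_H₂O values depend on the width→m-value interpretation noted above.
* The ¹La angle convention is a parameter, not a prediction; κ² for real
  structures should be read together with its sensitivity range.
* τ₃ estimates below ~1.5 channel widths are reported but unreliable.
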