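# Methods

## Models

**Stern-Volmer.** F₀/F = 1 + K_sv[Q] is fitted by ordinary least squares of
F₀/F on the *total added* quencher concentration in mol L⁻¹ (no free-ligand
correction — at ligand:protein ratios of 1–16 with micromolar binding this
is the conventional approximation). The intercept is estimated rather than
fixed at the theoretical 1: a freely fitted intercept is a diagnostic, and
a deviation beyond ±0.1 triggers a warning that is surfaced in the study
report. F₀/F noise is heteroscedastic (errors grow with the ratio), so at
strong quenching the intercept estimate is the noisiest quantity and the
warning fires well before the slope becomes unreliable; the slope (K_sv)
itself is empirically unbiased at the 2% noise level (checked by Monte
Carlo in the test suite).

**Mechanism call.** Dynamic quenching is diffusion-limited and speeds up
with temperature; static complexes dissociate on heating. The call uses the
relative change (K_sv,high − K_sv,low)/K_sv,low between the extreme
temperatures with a default decision threshold of 0.05: published
two-temperature comparisons come with no uncertainty statement, so the
threshold formalizes "clearly increased/decreased", and changes inside the
band are reported as ambiguous rather than forced. Because the change is
referenced to the low-temperature constant, dynamic↔static antisymmetry
under order reversal is exact only away from the threshold boundary.

**Double-log binding fit.** log₁₀[(F₀−F)/F] = log₁₀K_a + n·log₁₀[Q],
base-10 throughout. This is the standard independent-equivalent-sites form;
it is the only dimensionally consistent reading of the quenched-fraction
expression, and with n = 1 it reduces algebraically to 1:1 static
quenching, so the fitted K_a then equals the slope of (F₀−F)/F vs [Q]
(tested). Points with F ≥ F₀ carry no signal and are dropped with a
warning; at least three usable points are required. [Q] enters in a
configurable unit (default μM, matching how albumin binding constants are
usually tabulated), and K_a carries units of (unit)⁻ⁿ with the exact
transformation law K_a′ = K_a·cⁿ under a unit change by factor c (tested
both directions).

**Thermodynamics.** ln K = −ΔH/(RT) + ΔS/R with R = 8.314 J mol⁻¹ K⁻¹ is
fitted by least squares of ln K on 1/T; with exactly two temperatures this
coincides with the closed-form two-point solution and R² is reported as
undefined (NaN / null) rather than a meaningless 1. The K fed to the fit
defaults to the Stern-Volmer constant, following the convention of the
quenching literature that treats K_sv as analogous to an association
constant; this is thermodynamically loose for a dynamic quencher, so the
source is recorded on the result (`k_source`) and the double-log K_a
(converted to a mol L⁻¹ basis via the unit law) is accepted as the
alternative. ΔG is computed as ΔH − TΔS from the fitted parameters, not as
−RT ln K (the two agree identically when K lies on a perfect Van't Hoff
line; tested). `check_gibbs_consistency` flags externally reported ΔG
values that do not follow from their own ΔH/ΔS — published tables
occasionally contain such rows.

**Force classification.** Ross–Subramanian sign rules with a near-zero
enthalpy band ε (default 1000 J mol⁻¹, roughly the resolution of a
two-point Van't Hoff estimate): ΔH>ε ∧ ΔS>0 → hydrophobic; ΔH<−ε ∧ ΔS<0 →
H-bond + van der Waals; |ΔH|≤ε ∧ ΔS>0 → electrostatic. The remaining sign
patterns are outside the canonical table; they map to the nearest rule by
the enthalpy axis and the decision trace says so, keeping the classifier a
total function.

**Residue attribution.** The statistic is max over matched concentrations
of |F/F₀(280 nm) − F/F₀(293 nm)|, with default threshold 0.05 on the F/F₀
scale; above it, tyrosine is called as participating alongside tryptophan.
The published comparison this formalizes is purely visual. A geometric
caveat: if the two excitations differ only by a constant factor c on the
quenching constant, the statistic is bounded by the maximum of
1/(1+x) − 1/(1+cx) over x = K[Q]; for c = 1.2 that bound is ≈ 0.046,
attained near K[Q] ≈ 0.9. With quenching as strong as in the reference
system (K[Q] ≥ 2.5 at the first titration point) the achievable statistic
is ≈ 0.036, below the threshold — so a constant-factor excitation contrast
of 1.2 is, by construction, not "obvious" under this statistic, and the
default simulated study reports Trp-dominant. Curves that differ by a
constant offset in F/F₀ (e.g. 20% extra quenched fraction at every point)
clear the threshold easily.

## Synthetic data generator

`simulate_titration`/`simulate_study` emulate the reference experimental
design: 20 μM protein; quencher at (0, 20, 40, 80, 120, 160, 240, 320) μM;
298 and 308 K; excitation 280 and 293 nm; emission 320–460 nm on a 1 nm
grid; three replicate scans. Defaults for the truth parameters are the
reference system's constants (K_sv = 1.27×10⁵ L mol⁻¹; K_a = 0.1021 μM⁻¹,
n = 1.036; ΔH = 14.051 kJ mol⁻¹, ΔS = 144.913 J mol⁻¹ K⁻¹).

* Spectra are Gaussian bands centred at 348 nm with σ = 25 nm (typical
  albumin tryptophan emission). Band centre and width are configurable and
  provably irrelevant to every fitted constant (intensity-rescaling
  invariance, tested); the band centre is concentration-invariant,
  matching the absence of an emission-maximum shift in albumin quenching.
* Noise is multiplicative Gaussian, σ = 2% per point per replicate by
  default — detector shot noise scales with signal, and 2% reproduces the
  scatter level at which triplicate averaging is worthwhile.
* The 280 vs 293 nm contrast is an excitation-specific efficiency factor
  multiplying the quenching constant (default 1.2 at 280 nm, 1.0 at
  293 nm), giving `compare_excitations` a controllable input. Note the
  bound above: this contrast mechanism cannot exceed the 0.05 attribution
  threshold, whatever K; tests of the positive attribution case therefore
  construct offset curves directly.
* Determinism: one master seed; `simulate_study` spawns independent child
  streams per (temperature, excitation) series via `SeedSequence.spawn`.

What the generator does **not** emulate: inner-filter attenuation, Raman
and scatter peaks, photobleaching, baseline drift, wavelength-dependent
detector response. Passing round-trip tests therefore demonstrate
correctness of the estimators under the stated model, not robustness of
the method to those instrumental artefacts on real spectra.

## Numerical choices

* Internal units: mol L⁻¹, K, nm; conversions only at I/O and reporting
  boundaries. Files written by the package store concentrations in mol L⁻¹
  at 17 significant digits and are re-read with pandas' `round_trip` float
  parser, so read(write(series)) is bit-exact.
* Intensity extraction defaults to the peak maximum over 320–460 nm; since
  the band does not shift, fixed-wavelength extraction at the band centre
  is equivalent (tested) and available as an option.
* Replicates are averaged pointwise before extraction and fitting (one
  constant per condition, as titration studies report), and
  `extract_intensities` refuses unaveraged input rather than averaging
  silently.
* A constant ordinate (no quenching) yields slope 0 with R² reported NaN
  rather than a division-by-zero warning. NaN-flagged R² values serialize
  to JSON null.
* Reported fits require ≥3 points; the underlying estimator classes accept
  2 (where least squares equals the line through the points, used as a
  closed-form oracle in tests).
* Presentation CSVs round to the conventional printed precisions (K_sv 3
  s.f.; ΔH, ΔS 3 decimals; K_a 4 decimals; n 3 decimals); `report.json`
  keeps full precision and regenerating a report from the same config and
  seed is byte-identical.

## Problem sizes

Round-trip and property tests run on the 8-concentration design (7 nonzero
points, 141-wavelength spectra). Monte-Carlo bias checks use 200 simulated
triplicate titrations at σ = 2% with a fixed seed; at that size the mean
K_sv and n estimates resolve biases of roughly 0.2% and 0.001 respectively,
and both are statistically indistinguishable from the truth (within 2
standard errors).

## Known limitations

* No inner-filter correction: at 320 μM quencher, absorbance at the
  excitation wavelength can attenuate apparent intensities; constants from
  uncorrected data inherit that bias.
* No bimolecular rate constant k_q (requires the fluorophore lifetime), no
  modified (Lehrer) or combined static+dynamic Stern-Volmer models, no
  FRET distance analysis, no heat-capacity correction to the Van't Hoff
  line (ΔH, ΔS assumed temperature-independent over the 10 K span).
* Feeding K_sv into the Van't Hoff equation (the default `k_source`)
  presumes the quenching constant behaves as an association constant; for
  a genuinely collisional quencher the derived ΔH/ΔS characterize the
  temperature dependence of quenching, not of complexation.
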