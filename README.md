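# fluorobind

Analysis of drug–serum-albumin binding from fluorescence quenching
titrations.

When a drug binds a plasma transport protein such as bovine serum albumin
(BSA), it quenches the protein's intrinsic tryptophan/tyrosine
fluorescence. Titrating the protein with the drug and recording emission
spectra at several temperatures yields, through three small linear
regressions, the complete binding picture pharmacologists need:

1. **Stern-Volmer quenching constant** — from F₀/F = 1 + K_sv·[Q], where F₀
   and F are the intensities without and with quencher at concentration
   [Q]. K_sv rising with temperature ⇒ dynamic (collisional) quenching;
   falling ⇒ static (ground-state complex).
2. **Binding constant and binding number** — from the double-log form
   log₁₀[(F₀−F)/F] = log₁₀ K_a + n·log₁₀[Q]: slope n (number of equivalent
   sites), intercept log₁₀ K_a.
3. **Thermodynamics** — Van't Hoff regression ln K = −ΔH/RT + ΔS/R gives
   the enthalpy and entropy change; ΔG = ΔH − TΔS the spontaneity; the
   Ross–Subramanian sign rules classify the dominant force (ΔH>0, ΔS>0 ⇒
   hydrophobic; ΔH<0, ΔS<0 ⇒ H-bond/van der Waals; ΔH≈0, ΔS>0 ⇒
   electrostatic).
4. **Residue attribution** — comparing F/F₀ curves excited at 280 nm
   (Trp + Tyr) versus 293 nm (Trp only) tells whether tyrosine residues
   participate.

Because raw spectrofluorometer exports for such studies are rarely
deposited, the package includes a seeded titration simulator
(`fluorobind.simulate`) that reproduces the standard experimental design —
20 μM BSA, quencher at 0–320 μM, 298/308 K, excitation 280/293 nm,
emission 320–460 nm, triplicate scans — with known ground truth, so every
estimator is validated by round trip.

The three fits are exposed both as scikit-learn style estimators
(`SternVolmerRegressor`, `DoubleLogRegressor`, `VantHoffRegressor`, each
with `fit`/`predict` and trailing-underscore attributes) and as one-call
functions operating on titration data (`stern_volmer_fit`,
`double_log_fit`, `vant_hoff_fit`).

## Worked example

Analyze a simulated study (2% multiplicative noise, triplicates) whose
generating thermodynamics are ΔH = 14.051 kJ mol⁻¹, ΔS = 144.913 J mol⁻¹ K⁻¹:

```sh
cat > study.yml <<EOF
simulate:
  model: vant-hoff-family
  delta_h: 14051.0
  delta_s: 144.913
  noise_sigma: 0.02
  replicates: 3
EOF
fluorobind analyze --config study.yml --out-dir out --seed 1
fluorobind report out/report.json
```

prints

```
Stern-Volmer constants:
  T=298 K  ex=280 nm  Ksv=1.52e+05 L/mol  R2=0.9999502098703369
  T=298 K  ex=293 nm  Ksv=1.28e+05 L/mol  R2=0.9998845473933085
  T=308 K  ex=280 nm  Ksv=1.82e+05 L/mol  R2=0.9998953306683857
  T=308 K  ex=293 nm  Ksv=1.54e+05 L/mol  R2=0.9999433955270833
mechanism: dynamic
dH=13.629 kJ/mol  dS=144.953 J/mol/K
  dG(298 K) = -29.57 kJ/mol
  dG(308 K) = -31.02 kJ/mol
force: hydrophobic
  T=298 K  Ka=0.1530 uM^-n  n=0.999
  T=308 K  Ka=0.1887 uM^-n  n=0.995
residues: Trp-dominant
```

Reading: K_sv grew from 298 to 308 K, so the quenching is dynamic
(collisional). The fitted ΔH (13.6 kJ/mol, vs 14.05 generated) and ΔS are
both positive ⇒ hydrophobic forces dominate; ΔG is negative at both
temperatures ⇒ binding is spontaneous. The binding number n ≈ 1 means one
drug molecule per protein. The 280 nm constants sit 1.2× above the 293 nm
ones because the simulator's default excitation-efficiency contrast is
1.2; the per-point F/F₀ difference this produces stays below the 0.05
attribution threshold at these strong quenching levels, hence the
Trp-dominant call. The same pipeline runs on measured data by replacing
the `simulate` block with an `inputs` list of long-format CSV files (see
`fluorobind.spectra_io.ColumnSchema` for the column conventions).

`out/` also contains `report.json` (full precision, with provenance) and
three CSV tables: Stern-Volmer constants, thermodynamic parameters, and
binding constants.

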