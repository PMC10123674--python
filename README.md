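# dscthermo

Thermodynamic analysis of protein unfolding from differential scanning
calorimetry (DSC).

DSC measures the molar excess heat capacity C_p(T) of a protein in
solution — the one observable that is itself a thermodynamic function.
`dscthermo` turns a baseline-corrected thermogram into the full
model-free unfolding thermodynamics

```
ΔH(T) = Σ C_p ΔT        ΔS(T) = Σ (C_p / T) ΔT        ΔG(T) = ΔH − T·ΔS
```

and then compares those experimental profiles against four unfolding
models:

* **standard chemical-equilibrium two-state** — the textbook N ⇌ U
  van't Hoff model (ΔH₀, T_m, ΔC_p⁰).  Its parabolic ΔG is positive for
  the native protein; the package computes it so that failure is visible
  in comparison plots.
* **Θ_U-weighted two-state** — the same functions multiplied by the
  extent of unfolding Θ_U(T), restoring zero thermodynamics for the deep
  native state.
* **statistical-mechanical two-state** — a canonical partition function
  Z(T) = 1 + exp[−ΔE(T)(1/RT − 1/RT_m)] with ΔE(T) = ΔE₀ + C_v(T − T_m).
  Free energy F = −RT ln Z ≤ 0 always, and the same parameters predict
  cold denaturation at T_cold = T_m − ΔE₀/C_v.
* **Zimm–Bragg multistate cooperative** — the helix–coil transfer-matrix
  partition function with per-residue energy h₀, cooperativity σ and
  chain length N; at σ = 1, N = 1 it reduces exactly to the statistical
  two-state model.  ΔG_σ = −RT ln σ is the nucleation free energy, a
  quantitative cooperativity/stability measure.

The package covers thermogram I/O (CSV/TSV, °C or K, heating and cooling
scans), transition detection, enthalpy decomposition
ΔH_DSC = ΔH₀ + ΔC_p⁰·(T_end − T_ini)/3, midpoint prediction
T_m = ΔH_DSC/ΔS_DSC, least-squares model fitting (multistart, seeded,
simultaneous two-transition fits), model comparison on C_p *and* on the
integrated ΔH/ΔS/ΔG profiles, stability reports, and a seeded generator
of synthetic thermograms for all of the above.

## Worked example

```python
import dscthermo as dt

# synthetic lysozyme heating scan (statistical two-state:
# dE0 = 110 kcal/mol, Cv = 1.05 kcal/mol/K, Tm = 335 K; 0.17 K grid,
# 0.05 kcal/mol/K Gaussian noise)
spec = dt.scenario("fig1_lysozyme", seed=2)
thermogram, truth = dt.generate(spec)

profile = dt.integrate_profiles(thermogram)
(window,) = dt.detect_transitions(thermogram)
totals = dt.total_changes(profile, window)
print(f"T_m(peak) = {window.t_m:.1f} K, width = {window.width:.1f} K")
print(f"dH_DSC = {totals.dH_total:.1f} kcal/mol")
print(f"T_m(dH/dS) = {dt.midpoint_from_ratio(totals.dH_total, totals.dS_total):.1f} K")

fit = dt.fit_model(thermogram, "stat_two_state", seed=1)
p = fit.params
print(f"fit: dE0 = {p.dE0:.1f} kcal/mol, Tm = {p.t_m:.2f} K, Cv = {p.cv:.2f}")
print(f"T_cold = {dt.cold_denaturation_temperature(p):.1f} K")
```

prints

```
T_m(peak) = 335.5 K, width = 38.6 K
dH_DSC = 170.6 kcal/mol
T_m(dH/dS) = 340.0 K
fit: dE0 = 109.9 kcal/mol, Tm = 335.00 K, Cv = 1.05
T_cold = 230.3 K
```

The detected C_p maximum sits at 335.5 K (the C_v tilt shifts the peak
slightly above the 335 K midpoint), the integrated enthalpy over the
detected window is 170.6 kcal/mol (the window spans well past the
transition, so it includes the ΔC_p⁰ baseline contribution), and the fit
recovers the generating parameters to within the noise.  The fitted
model predicts cold denaturation 105 K below the heat-unfolding
midpoint — far outside the scanned range, which is why lysozyme cold
denaturation is not observed in water.

The same analyses are available from the shell:

```sh
dscthermo simulate --scenario fig1_lysozyme --seed 2 --out lys.csv
dscthermo integrate lys.csv --out profile.csv --report-out report.json
dscthermo fit lys.csv --model stat2 --seed 1 --out fit.json
dscthermo report lys.csv --model stat2 --markdown
```

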