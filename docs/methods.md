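# Methods

## Scope and conventions

`dscthermo` analyses baseline-corrected molar excess heat-capacity
traces C_p(T) of protein unfolding.  "Baseline-corrected" means the
buffer scan and the native protein's intrinsic heat capacity have
already been subtracted, so the native state has C_p = 0; vendor binary
formats and raw-instrument corrections are out of scope.  Units are
kcal/mol for energies, kcal·mol⁻¹·K⁻¹ for heat capacities and kelvin for
temperatures (Celsius is accepted and converted at the I/O boundary
with a fixed offset of 273.15).  The gas constant is
R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹.

Thermograms are stored in recorded scan order — ascending temperature
for heating scans, descending for cooling scans.  Both scan types start
at the native protein, so the first recorded point is always the
native-state reference.

## Model-free evaluation

Because C_p = (∂H/∂T)_p, the unfolding enthalpy, entropy and free
energy follow from the trace without any model:

    ΔH(T) = Σ C_p(T_i)·ΔT_i
    ΔS(T) = Σ [C_p(T_i)/T_i]·ΔT_i
    ΔG(T) = ΔH(T) − T·ΔS(T)

The default rule is the left-Riemann running sum over the recorded
discrete steps, mirroring how a DSC instrument samples; trapezoidal
integration is available as an option.  At the default 0.17 K grid the
left rule carries an O(ΔT) bias of roughly 0.1% of the total for a
typical transition; the two rules converge as the grid is refined, which
the test suite asserts.  On a cooling scan the steps ΔT are negative, so
an exothermic cold-denaturation transition accumulates negative ΔH — the
expected sign convention.

Transition detection finds peaks of |C_p| above a noise floor of 5×
the median absolute deviation of the flattest decile of the trace
(configurable).  Window edges t_ini/t_end are placed where |C_p| falls
to 2% of the peak height (configurable), bounded by the valleys toward
neighbouring peaks.  ΔC_p⁰ is estimated as the mean C_p difference
between the plateaus flanking the window (outer 10% of the span).

The enthalpy decomposition ΔH_DSC = ΔH₀ + ΔH_ΔCp⁰ uses the triangle
approximation ΔH_ΔCp⁰ = ΔC_p⁰·(T_end − T_ini)/3.  The denominator is 3
rather than the plain triangle's 2 because the step rises along a
sigmoidal rather than straight hypotenuse.  For cold-unfolding windows
stated in scan order (T_end < T_ini) the formula is negative, as it
should be.  For the β-lactoglobulin cold-unfolding window
(ΔC_p⁰ = 0.86, 310→259 K) the formula gives −14.6 kcal/mol; a value of
−18.9 kcal/mol circulates for the same inputs, which the formula does
not reproduce — this package always reports the formula value.

Midpoint prediction T_m = ΔH_DSC/ΔS_DSC treats unfolding as a
first-order transition (ΔG = 0 at the midpoint).  It applies equally to
heat and cold denaturation since both totals change sign together.

When a heating scan starts from the cold-denatured state, the cumulative
profiles reach the native plateau at the totals of the low-temperature
disorder→order transition.  `rebase_profiles` subtracts those totals so
the native state sits at ΔH = ΔS = 0, after which ΔG = ΔH − T·ΔS shows
the characteristic trapezoidal shape: ≈0 across the native plateau,
negative beyond both midpoints.

## Unfolding models

**Standard chemical-equilibrium two-state.**  ΔH_NU(T) = ΔH₀ +
ΔC_p⁰(T − T_m), ΔS_NU(T) = ΔH₀/T_m + ΔC_p⁰ ln(T/T_m),
ΔG_NU = ΔH_NU − TΔS_NU, K = exp(−ΔG_NU/RT), Θ_U = K/(1+K).  Θ_U is
evaluated as a logistic of −ΔG/(RT) so it never overflows.  The model's
heat capacity is the derivative of Θ_U·ΔH_NU:

    C_p = Θ_U·ΔC_p⁰ + ΔH_NU²·Θ_U(1−Θ_U)/(RT²)

which fits C_p peaks well, but the model's own profiles are linear
(ΔH, ΔS) and parabolic with a positive native-side branch (ΔG), in
conflict with the measured sigmoidal/trapezoidal shapes.  The package
deliberately reports these unmodified so model comparison can display
the failure.

**Θ_U-weighted two-state.**  The same three functions multiplied
pointwise by Θ_U(T).  All three vanish in the deep native limit and
ΔG_Θ(T_m) = 0 exactly.  Residual flaw: a small positive ΔG bump just
below T_m, which the comparison table flags.

**Statistical-mechanical two-state.**  Canonical partition function

    Z(T) = 1 + exp[−ΔE(T)·(1/(RT) − 1/(RT_m))],
    ΔE(T) = ΔE₀ + C_v·(T − T_m)

so Z(T_m) = 2 and F(T_m) = −RT_m ln 2 (−0.46 kcal/mol at 335 K).
ΔE(T) crosses zero at T_cold = T_m − ΔE₀/C_v, giving an analytic
cold-denaturation midpoint and separation ΔT = ΔE₀/C_v.  C_v plays the
role of the heat-capacity step (no separate additive ΔC_p⁰ term is
introduced).  Because unfolding volume changes are small, E ≅ H,
S_v ≅ S_p and F ≅ G when comparing with calorimetric profiles.

**Zimm–Bragg multistate cooperative.**  Largest-eigenvalue form of the
helix–coil transfer matrix:

    s(T) = exp[−h(T)·(1/(RT) − 1/(RT_m))],  h(T) = h₀ + c_v(T − T_m)
    λ = (1+s)/2 + √(((1−s)/2)² + σs),       ln Z = N ln λ

with the extent of unfolding Θ_U = (s/N)·∂lnZ/∂s evaluated from the
analytic eigenvalue derivative.  At σ = 1 the eigenvalue is exactly
1 + s, so N = 1 recovers the statistical two-state model — a reduction
the tests pin to 1e-12.  The nucleation free energy ΔG_σ = −RT ln σ
quantifies cooperativity (9.6 kcal/mol for lysozyme's σ = 5×10⁻⁷ at
335 K; 6.2 kcal/mol for β-lactoglobulin's σ = 7×10⁻⁵ at 326 K, each
evaluated at the protein's unfolding midpoint).

**Thermodynamics from ln Z.**  E = RT²·dlnZ/dT, F = −RT·lnZ,
S = (E−F)/T, model C_p = dE/dT.  Derivatives are central differences on
the caller's grid (one-sided at the ends) so that any alternative
partition function drops in unchanged; a spacing ≤ 0.5 K keeps the
boundary error negligible, and a refinement test asserts convergence.
Since Z ≥ 1, F ≤ 0 everywhere — both partition models share the
never-positive free energy that the calorimetric profiles show.

## Fitting

The objective is the C_p-space residual (what DSC measures); the
integrated-profile residuals are post-fit diagnostics.  Minimisation
uses trust-region-reflective least squares with 8 multistart
initialisations: the supplied (or auto-derived) start plus seeded random
perturbations, the best converged result kept.  Fits are deterministic
given (data, seed), and the seed is recorded in the result.

Auto-initialisation derives T_m from the detected |C_p| peak, the
enthalpy from the window's integrated area net of the
heat-capacity-step triangle, and ΔC_p⁰/C_v from the plateau difference.
Bounds: T_m within the data span ± 20 K, heat-capacity parameters
non-negative, σ log-parameterised in [10⁻⁹, 1], enthalpies sign-free so
cold-denaturation-only scans (negative ΔH₀/ΔE₀) fit naturally.  For the
Zimm–Bragg model the chain length N is held fixed at its initialisation
value: N trades off almost exactly against h₀ and σ in the C_p curve,
so it must come from the protein's sequence (or a deliberate choice),
not from the optimizer.

Two transitions in one scan are fitted as the sum of two independent
transitions; an optional shared constant baseline is available but fixed
at 0 by default (inputs are baseline-corrected).

Model comparison ranks fits by the summed RMS residuals of the
dH/dS/dG profiles against the model-free integration (models that
merely fit the C_p peak are not rewarded), with ties preserved in input
order.  A fit is flagged when its model ΔG exceeds the integrated ΔG's
maximum by more than 0.05 kcal/mol anywhere — this catches both the
standard model's positive parabola and the Θ-weighted model's small
positive bump near T_m.

## Synthetic data

The generator forward-simulates a model C_p curve on a regular grid
(default 0.17 K, a typical instrument resolution), optionally adds a
linear baseline drift, and adds i.i.d. Gaussian noise (default
0.05 kcal·mol⁻¹·K⁻¹ in the presets, a realistic protein-DSC noise
level) from `numpy.random.default_rng(seed)`.  Ground truth is computed
on a 10× finer noise-free grid by trapezoidal quadrature, and the
planted peak positions are the actual extrema of the noise-free model
curve (for a tilted transition these sit slightly off the Θ_U = 1/2
midpoint).

Presets:

* `fig1_lysozyme` — heating scan 293–363 K, statistical two-state with
  ΔE₀ = 110 kcal/mol, C_v = 1.05 kcal/mol/K, T_m = 335 K (lysozyme heat
  unfolding at pH 2.5).
* `fig2_cold` — cooling scan 310→259 K, ΔE₀ = −42 kcal/mol,
  C_v = 0.45 kcal/mol/K, T_m = 279.15 K (β-lactoglobulin cold
  denaturation in 4 M urea; integration yields negative ΔH, an
  exothermic transition).
* `fig3_double` — heating scan 264–344 K with both the disorder→order
  and the heat-unfolding transition of β-lactoglobulin in 2 M urea.
  One statistical two-state parameter set (C_v = 1.15 kcal/mol/K from
  the two-transition analysis) is calibrated so the model's two C_p
  maxima fall exactly at the observed peak temperatures 277.15 K (4 °C)
  and 330.15 K (57 °C); the calibrated ΔE₀ = 54.9 kcal/mol is within
  0.2% of the reported 55 kcal/mol.  A single cold+heat parameter set
  reproduces the measured peak positions and shapes, but not the large
  measured disorder→order enthalpy (≈78 kcal/mol), which in the real
  experiment is boosted by urea-binding contributions the two-state
  inner energy does not carry.

What the synthetic data do *not* emulate: scan-rate effects, refolding
hysteresis, aggregation exotherms, autocorrelated instrument noise, and
imperfect baseline correction.  Passing tests therefore demonstrate the
correctness of the numerics and estimators under ideal instrument
physics, not robustness to those artefacts.

## Numerical choices and edge cases

* Θ_U and partition weights are evaluated in log space (logistic /
  `logaddexp`) so deep native/unfolded limits stay finite.
* Finite-difference oracles in the tests use 0.002 K grids where a
  1e-6 relative agreement is asserted, keeping the oracle's own
  second-order truncation error below the tolerance.
* Window edges snap to the nearest grid point; a window collapsing onto
  one grid point yields exactly zero totals.
* `cold_denaturation_temperature` returns `None` (not an exception)
  when C_v = 0: a temperature-independent ΔE never re-crosses zero.
* A flat thermogram yields an empty transition list; fitting without
  either a detectable transition or explicit initial values raises an
  initialisation error.
* Zero total entropy makes the midpoint ratio undefined and raises a
  `ZeroDivisionError` with a message, rather than returning ±inf.

## Known limitations

* The left-Riemann default integration has an O(ΔT) bias (≈0.1% at
  0.17 K); use `rule="trapezoid"` when totals matter more than fidelity
  to the instrument's discrete sampling.
* Partition-model C_p curves are differentiated numerically on the
  evaluation grid; very coarse grids (> 0.5 K) blur sharp Zimm–Bragg
  peaks.
* The two-transition fit assumes additive, parameter-independent
  transitions; genuinely coupled domains are out of scope.
* Absolute (non-excess) heat capacities and Kirchhoff extrapolation of
  ΔH to reference temperatures are not implemented.
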