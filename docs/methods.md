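# Methods

`btkact` implements the quantitative models used to explain how Bruton's
tyrosine kinase (Btk) switches on: an autocatalytic trans-autophosphorylation
scheme whose rate is set by transient PH-TH dimerization, a geometric
estimate of the local concentration of membrane-recruited Btk, one-site ITC
binding thermodynamics for inositol-phosphate ligands, and the estimators
used on coupled-kinase-assay and dose-response data. This note records the
models, their assumptions, and the numerical and design choices.

## Kinetic scheme (`btkact.kinetics`)

Four mass-action reactions over species M (Btk monomer), P (pBtk, the
activation-loop-phosphorylated monomer), MM (Btk·Btk encounter complex) and
PM (pBtk·Btk complex):

    (1) M + M  <=[k1, k-1]=>  MM
    (2) MM     --[k2]-->      P + M
    (3) P + M  <=[k3, k-3]=>  PM
    (4) PM     --[k4]-->      P + P

ODEs (forward dimerization flux k1·M², so the equilibrium constant is
M²/MM = k-1/k1):

    dM/dt  = -2(k1 M² - k-1 MM) + k2 MM - (k3 P M - k-3 PM)
    dP/dt  = k2 MM - (k3 P M - k-3 PM) + 2 k4 PM
    dMM/dt = k1 M² - k-1 MM - k2 MM
    dPM/dt = k3 P M - k-3 PM - k4 PM

Defaults: k1 = k3 = 1e4 M⁻¹s⁻¹ (no IP6) or 1e5 M⁻¹s⁻¹ (saturating IP6,
a 10-fold on-rate enhancement via the peripheral site), k-1 = k-3 = 20 s⁻¹,
k2 = 0.1 s⁻¹, k4 = 1.0 s⁻¹. The dimer Kd = k-1/k1 is therefore 2 mM
without and 200 μM with IP6 — both far above the ~1 μM assay
concentrations, so the complexes are trace species and activation is
encounter-limited. Because k4 = 10·k2, phosphorylated Btk is the better
kinase and the scheme is autocatalytic: progress curves are sigmoidal, and
a 10-fold on-rate change shifts the half-activation time about 10-fold
(t50 ≈ 4960 s → 500 s at 1 μM).

Assumptions inherited from the scheme: no pBtk + pBtk association, no
dephosphorylation (the phospho-fraction (P + PM)/total is monotone and
tends to 1), one phosphotransfer per catalytic event, and a well-mixed
solution (membrane effects enter only as a concentration rescaling).
The printed scheme is ambiguous about the product of reaction (3)
(a pBtk·pBtk complex would leave reaction (4) without a substrate); we take
the product to be the heterocomplex PM, which is the only stoichiometrically
consistent reading.

Numerics: the ODEs are integrated in μM/seconds units with LSODA
(rtol 1e-8, atol 1e-9 μM) and an analytic Jacobian; monomer conservation
M + P + 2MM + 2PM = total holds to better than 1e-6 relative at every
output time. `time_to_half` interpolates the phospho-fraction linearly in
time and signals explicitly when 0.5 is never reached; ties break to the
first crossing.

Two independent cross-checks run in the test suite: a fixed-step explicit
Euler integration (step 1 ms over [0, 1e4] s, agreement to 0.1% per
species, in practice ~1e-5) and an exact Gillespie ensemble in a 1 fL
virtual volume (~602 molecules at 1 μM; 200 runs; deterministic trajectory
within 3 standard errors of the ensemble mean). The femtoliter volume is a
compromise: small enough for exact simulation at interactive speed, large
enough that finite-copy-number corrections (~1/n ≈ 0.2%) stay inside the
Monte-Carlo error. Homodimerization propensity is c·n(n−1)/2 with
c = 2k1/(NaV), matching the deterministic flux convention.

## Membrane local concentration (`btkact.membrane`)

Treating every PIP3 headgroup as Btk-occupied, the protein on a vesicle is
confined to a shell of thickness L over the surface, giving

    C = f / (A0 · L · Na)

with f the PIP3 mole fraction (default 0.05), A0 the per-lipid headgroup
area (60 Å²), L the protein extent normal to the membrane (100 Å), and Na
Avogadro's number (CODATA 6.02214076e23; using the rounded 6.03e23 changes
C by <0.2%). The vesicle area cancels analytically, which the tests also
assert numerically. These inputs evaluate to 13.8 mM; the originally
reported rounded figure is 12 mM, and both lie within the ±2 mM acceptance
band used here. Against a 2 μM bulk assay this is a ~7000-fold
enhancement — the published qualitative statement ("100-fold") understates
its own numbers, and we report the ratio without reconciling it. Lipid
counts N0 = A/A0 and N = f·N0 are returned as reals; no curvature,
leaflet-asymmetry or binding-equilibrium corrections are applied.

## ITC one-site model (`btkact.itc`)

Forward model: fixed-volume (overflow) cell of active volume V0 = 200 μl
(the loaded volume is larger; the instrument senses only the cell).
Injection i of volume v dilutes both totals by (1 − v/V0) and adds
v·X_syr/V0 of ligand; the single-site equilibrium with S = N·Mt sites is
solved by the numerically stable quadratic root
b = 2SX/(S + X + Kd + sqrt((S + X + Kd)² − 4SX)), and the measured heat is
ΔH·V0·(b_i − b_{i−1}(1 − v/V0)), normalized per mole of injectant. The
default schedule is the published protocol: 20 μM cell, 300 μM syringe, a
0.5 μl pre-injection (simulated, because it changes concentrations, but
excluded from fitting) followed by 14 × 3 μl at 180 s spacing, 20 °C.
Cumulative heat equals ΔH times total moles bound (cell content plus the
bound complex expelled by later injections) to 1e-6 relative.

Fit: unweighted least squares over (N, log10 Ka, ΔH) with
Levenberg–Marquardt, multi-started over Ka = 1e5..1e9 M⁻¹ when no
initialization is given; standard errors from the local curvature, with
se(Ka) by the delta method. Noiseless round trips recover parameters to
1e-4 relative across that grid, and under 2% Gaussian noise the nominal
95% intervals for Ka cover the truth in 85–100% of seeded replicates.
A flat isotherm (range below 1e-3 kcal/mol by default) raises an explicit
no-binding outcome rather than returning a degenerate fit — the behaviour
of a binding-site knockout. Derived quantities use Kd = 1e9/Ka nM and
ΔS = (ΔH + RT ln Ka)/T with R = 1.9872e-3 kcal/(mol·K), T = 293.15 K.

`pipeline.report_table3` recomputes both derived columns from the printed
central fit values of the three titrations (wild-type PH-TH with IP6 and
IP4, and the R28C/D24N canonical-site mutant with IP6). The two wild-type
rows reproduce to within 0.25 cal/mol/K and 0.4 nM; the mutant row's
printed ΔS (17.5) differs by ~1.1 cal/mol/K from the identity evaluated on
its rounded inputs (18.55) — consistent with it having been computed from
unrounded fit values — and is flagged, not reconciled.

## Assay estimators (`btkact.assays`)

* `initial_rate`: ordinary least-squares slope (with intercept) over points
  with t ≤ 150 s, converted to min⁻¹; invariant to signal offsets.
* `activation_slope`: early-window slope of activity vs pre-incubation
  time with a curvature caveat flag (partial F-test of a quadratic term at
  α = 0.01), since activation time courses are sigmoidal and a slope is
  only a rough comparative measure.
* `fit_michaelis_menten`: v = Vmax·S/(Km + S) by nonlinear least squares,
  initialized from the Lineweaver–Burk linearization; requires ≥4 distinct
  positive substrate levels and reports unidentifiable designs explicitly.
  The reference peptide Km (925 μM) round-trips exactly from noiseless data
  and within 2 SE under 5% noise.
* `fit_ec50`: four-parameter logistic on log10 dose with zero doses
  anchoring the floor (not log-transformed); EC50 is invariant under affine
  response transforms; standard error by the delta method from the log10
  scale.

All estimators are deterministic, seed-free functions of their inputs.
The absorbance-to-turnover conversion of the coupled assay is left as a
caller-supplied constant (no extinction coefficients are modeled).

## Synthetic data (`btkact.synthetic`)

Generators are pure functions of their arguments including one integer
seed. Each returns an observation table plus a truth record (clean signal
and generating parameters) so recovery tests never peek beyond the
observation. Noise is additive i.i.d. Gaussian, default 2% of the dynamic
range — chosen to make recovery non-trivial but reliable; real assay noise
(baseline drift, heteroscedastic photometry, blot saturation) is not
emulated, so passing recovery tests demonstrates estimator correctness, not
robustness to instrument artifacts.

The mechanistic dose–response maps peripheral-site occupancy
θ = dose/(Kd + dose) (Kd default 7 μM, within the measured 5–10 μM
residual-binding range) linearly onto the dimerization on-rates,
k1 = k3 = k_base·(1 + 9θ), reaching the 10-fold enhancement at saturation;
the response is the phospho-fraction at 600 s for 2 μM Btk. The linear map
is the simplest mechanism consistent with a 10-fold enhancement at
saturation and is recorded in the truth metadata; switch-like alternatives
would shift the apparent EC50 upward.

**Known discrepancy.** Under these defaults the fitted apparent EC50 is
≈4 μM, below both the 7 μM occupancy Kd and the experimentally reported
~20 μM. The reason is kinetic amplification: at 2 μM Btk the basal
half-activation time is ≈2480 s and scales roughly inversely with the
on-rate multiplier, so an endpoint readout at 600 s half-saturates already
where the multiplier is ~4 (θ ≈ 1/3, dose ≈ Kd/2). An earlier readout or a
sublinear occupancy-to-rate map would raise the apparent EC50 toward the
experimental value; we keep the stated conditions and report the computed
number. The corresponding acceptance check against the 5–50 μM
plausibility band therefore fails by design and the discrepancy is
documented here rather than papered over.

## Pipeline (`btkact.pipeline`)

Run configurations are pydantic-validated with unknown keys rejected and
errors naming the offending field. `run` executes the selected stages,
writes CSV/JSON with 6-significant-digit floats, and returns a manifest
with the SHA-256 of every output plus the seeds and parameters used;
identical configs give byte-identical outputs. Comparisons in tests always
use explicit numerical tolerances, never printed strings.

## Problem sizes

Defaults keep every analysis at desk scale: 201–501 output points per ODE
trajectory ([0, 1e4] s), 200 Gillespie runs in 1 fL, 15-injection
isotherms, 50-seed calibration/bias studies, 100-seed ordering studies,
and 13-dose response curves. The full test suite runs in a few minutes on
one CPU.

## Limitations

* No spatial or membrane-diffusion modeling; membranes enter only through
  the local-concentration rescaling.
* No fitting of rate constants to blot densitometry (no tabulated time
  courses exist), and no raw-power-trace ITC processing (the model starts
  from integrated heats).
* The scheme omits pBtk·pBtk association and dephosphorylation, exactly as
  printed; long-time behaviour is therefore complete activation by
  construction.
* Two published numbers are reported but deliberately not reconciled: the
  12 mM vs 13.8 mM rounding of the membrane estimate, and the "100-fold"
  local-concentration phrasing vs the computed ~7000-fold ratio.
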