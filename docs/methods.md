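# Methods

## Model structure and assumptions

The PBK model has six compartments — GI tract, liver, fat, rapidly
perfused tissue, slowly perfused tissue and blood — connected by the
systemic circulation. The GI tract is a pure absorption depot: an oral
bolus enters the liver via a first-order process with Ka = 1.0 h⁻¹
(complete, fast absorption). The liver mass balance uses the
venous-equilibrium substrate concentration CL/PL in every saturable term,
the hallmark of flow-limited (perfusion-limited) kinetics; fat, rapidly
and slowly perfused tissues are standard flow-limited balances
dA/dt = Q·(CA − C/P), and the blood pool collects the venous returns. The
total blood-side flow is taken as the **sum of the tissue flows** derived
from the flow fractions rather than re-imposing the cardiac-output formula;
the Chinese flow fractions sum to 100.15% (a rounding artifact of the
source physiology table) and using their sum conserves mass exactly, which
the tests assert to 10⁻⁶ relative.

1′-Hydroxyestragole has only a liver partition coefficient (1.6) in the
parameter set, and all of its conversions are hepatic. It is modelled as a
liver pool exchanging with a blood pool at the liver blood flow. The 24-h
metabolite split is insensitive to this disposition choice: removing the
blood exchange entirely (a liver-only pool) changes every 24-h summary by
less than 0.1%, because in the low-occupancy regime the split converges to
the ratio of the scaled catalytic efficiencies regardless of the
intermediate's distribution. The test suite asserts that first-order limit
explicitly.

Only single-bolus dosing over 24 h is supported. Further metabolism of
the terminal metabolites (e.g. GSH/DNA adduct formation from
1′-sulfooxyestragole), extrahepatic metabolism, enterohepatic
recirculation and urinary excretion sub-models are out of scope.

## Parameters

* **Physiology** (per population): body weight (60 / 70 kg for the Chinese
  / Caucasian parameterization), tissue fractions (% bw), flow fractions
  (% cardiac output), cardiac output 15·BW^0.74 L/h.
* **Partition coefficients** (tissue:blood): estragole liver 6.5, fat 105,
  rapidly 6.5, slowly 4.1; 1′-hydroxyestragole liver 1.6. Taken as given
  in the bundled files; log Kow-based estimation is not reimplemented.
* **Pathway kinetics**: apparent Km (µM) and Vmax (nmol/min/mg protein)
  per pathway and population, fitted from incubations with pooled liver
  fractions. Scaling to whole liver multiplies Vmax by the protein yield
  (35 mg microsomal, 143 mg S9 protein per g liver) × 60/1000, giving
  µmol/h/(g liver). Glucuronidation was assayed in microsomes (with
  UDPGA) and uses the microsomal yield; oxidation and sulfation were
  assayed in S9. No Chinese-specific yields exist, so the Caucasian values
  are used for both populations.
* **Molecular weight** of estragole: 148.20 g/mol (standard value,
  configurable) for the mg → µmol dose conversion; tissue density 1 kg/L.

## Numerical choices

Integration uses LSODA with rtol 10⁻⁸ and atol 10⁻¹² µmol, with dense
output every 0.01 h for Cmax and (trapezoidal) AUC of liver
1′-hydroxyestragole. Halving the tolerances changes every 24-h summary by
far less than 0.1% (asserted). A zero dose short-circuits to an exactly
zero trajectory.

Michaelis–Menten fitting is unweighted nonlinear least squares on
replicate means (SEMs are carried but not used in the loss, matching the
common GraphPad-style workflow), with bounds Km ∈ (0, 10⁷] µM,
Vmax ∈ [0, 10³], initial guesses Vmax₀ = max rate and Km₀ = interpolated
half-maximum concentration, and a multistart over {0.1×, 1×, 10×} Km₀.
Parameter uncertainties are asymptotic standard errors; "95% intervals"
in the recovery studies use the t-quantile with n − 2 degrees of freedom,
the appropriate small-sample definition. An all-zero dataset yields
Vmax = 0 with a `km_unidentifiable` diagnostic rather than an error.

Sensitivity coefficients use one-sided forward +5% perturbations by
default, exactly as in the printed method; a central-difference variant
sits behind a flag. Note that one-sided differences carry an intrinsic
O(δ) bias of up to |SC|·δ (for a hyperbolic dependence the forward
estimate is exactly −1/(1+δ)); the near-linearity check across δ values
therefore uses the central scheme. The parameter universe is all 35
scalar primitives — physiology, partition coefficients, protein yields,
Ka and every Km/Vmax — with derived quantities (volumes, flows, scaled
Vmax) re-derived after each perturbation. Outputs are 24-h cumulative
amounts formed (µmol); because dose is specified per kg body weight, the
body-weight coefficient includes the dose-scaling effect (SC ≈ +1).

Dose equivalence (`equivalent_dose`) matches 24-h cumulative
1′-sulfooxyestragole. `method="root"` brackets the dose in
[10⁻⁶, 10⁴] mg/kg and bisects to 0.1% relative on the matched amount.
`method="linear"` (default) scales the reference dose by the inter-ethnic
fold in cumulative amount at the reference dose — the linear-extrapolation
argument conventionally used for genotoxic carcinogens, and the
arithmetic behind the published equivalence statement. The two methods
agree in the first-order regime and diverge above it: matching a
Caucasian 5 mg/kg bw intake, the linear method gives ≈26 mg/kg bw for the
Chinese model while the exact root is ≈33 mg/kg bw, because Chinese
detoxification saturates between 5 and 30 mg/kg.

## Comparison bases for fold-differences

Inter-ethnic folds can be formed from %-of-dose values (body size cancels;
the default) or from absolute cumulative amounts at the same mg/kg dose.
The two differ exactly by the body-weight ratio (70/60). The published
glucuronide fold-differences correspond to the percent basis, while the
published sulfation folds at 5 and 150 mg/kg bw correspond to the amount
basis; `interethnic_fold` exposes `basis=` so either convention can be
reproduced, and the acceptance script reports the basis that matches the
quantity each published number actually describes (documented inline).

## Synthetic incubation data

The generator emulates the assay design behind the kinetic tables:
triplicate incubations on substrate grids of 25–1000 µM (estragole
pathways; extended to 8 mM for glucuronidation, whose Km ≈ 4.7 mM must be
spanned) with multiplicative Gaussian noise, rate = v(S)·(1 + ε),
ε ~ N(0, cv), truncated at −0.99, default cv = 10% — assay CVs scale with
signal, which additive noise would not capture. It reproduces means and
SEMs exactly as computed from bench replicates and is bit-reproducible
under a fixed seed. It does **not** emulate donor-to-donor variability
(pooled-sample semantics only), systematic calibration error, or
non-Michaelis–Menten behaviour (substrate inhibition, Hill kinetics);
passing recovery tests therefore demonstrate correctness of the estimation
pipeline under the assumed error model, not robustness to model
misspecification in real assays.

Pathways whose Km lies at or beyond the top of the assay grid (M5,
glucuronidation, sulfation) are weakly identified — single-triplicate Km
errors of tens of percent are expected, mirroring the large published
SEMs — while the catalytic efficiency Vmax/Km, which controls the
low-dose model behaviour, is much better determined.

## Problem sizes

The ODE system has 16 states; a 24-h simulation takes tens of
milliseconds, so the full analysis (dose–response over four doses and two
populations, 35-parameter sensitivity sweeps at three doses, root-finding
for dose equivalence, and 200-seed Monte-Carlo fitting studies) runs on
one CPU in well under a minute.

## Known limitations

* The non-liver compartment equations are a reconstruction from the
  standard flow-limited template; only the liver balances are fixed by the
  source. The reconstruction reproduces the published low- and high-dose
  predictions within a few percent, which bounds the structural
  uncertainty that matters here.
* The printed Chinese 1′-hydroxyestragole catalytic efficiency (7.9
  µL/min/mg) is not reproducible from the printed constants
  (0.35/49 × 1000 = 7.1); the package reports the recomputed value.
* BMDL₁₀ is an input, not modelled; no BMD fitting from tumor-incidence
  data, no population variability layer, no SULT/CYP polymorphism
  genetics.
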