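# Methods

## Pharmacokinetic simulation

Effect-site concentrations are produced by a linear mammillary compartment
model (central volume `v1` in L; first-order micro rate constants `k10`,
`k12`, `k21`, `k13`, `k31` in 1/min) with a first-order effect compartment
(`ke0`, 1/min). Two-compartment and one-compartment models are expressed by
zeroing the unused rate pairs. Because the system is linear and
time-invariant and dosing is piecewise constant, the solver advances the
state with a cached matrix exponential per grid step — the solution is
exact at the grid nodes (no truncation error), which is why the unit tests
can hold it to analytic closed forms at 1e-6 relative tolerance and to
linearity/superposition at 1e-9. The input-response vector is read off an
augmented-matrix exponential so the scheme remains valid for singular
system matrices (e.g. the zero-elimination mass-conservation check).
Bolus times are snapped to the nearest grid node; infusion segments that
straddle grid steps contribute their overlap-weighted average rate, so
administered dose is conserved on any grid.

Two named parameter presets come from the published PK literature and are
marked as such in their docstrings: the Schnider covariate-adjusted
propofol model (the standard effect-site TCI model; James lean-body-mass
formula, `ke0` = 0.456/min) and the Scott-Stanski fentanyl model
(`v1` = 12.7 L, `ke0` = 0.147/min, effect-site peak ≈ 3.8 min after a
bolus). The Scott set was preferred over the alternative small-central-
volume fentanyl parameterizations because its bolus peaks are consistent
with the concentration envelope this study design reports
(remifentanil-equivalent ≤ ~5.3 ng/mL for 3-5 µg/kg dosing). Everything
also runs on fully generic `PkParams`, and all solver tests use synthetic
parameters.

Opioid equivalence: remifentanil-equivalent Ce = fentanyl Ce / 1.2, from
the 1:1.2 remifentanil:fentanyl potency ratio (1 unit of remifentanil ≡
1.2 units of fentanyl). The stated ratio's direction is ambiguous in
clinical shorthand; this package fixes the convention "divide fentanyl by
1.2" and exposes both the factor and, through it, the direction.

## Interaction surface

The Greco model treats the two drugs as contributing a combined
dimensionless potency `U = CeP/C50P + CeR/C50R + α·(CeP/C50P)(CeR/C50R)`
and maps it through a Hill sigmoid `P(LOR) = E0 + (Emax−E0)·U^N/(U^N+1)`.
The baseline effect `E0` appears in narrative descriptions of the model but
not in the canonical equation; implementing the affine form with default
`E0 = 0` reproduces the canonical equation exactly while keeping a nonzero
baseline available. `P(RR)` is defined as exactly `1 − P(LOR)`.

The shipped `"oaas_lt4"` preset (C50P = 1.8 µg/mL, C50R = 12.5 ng/mL,
N = 3.8, α = 5.1, Emax = 1) is a published volunteer-study fit for the
endpoint "OAA/S < 4". Two documentation flags on the source tables: the
propofol concentration unit is printed there as "mg/mL", which is treated
as a typo for µg/mL (propofol effect-site concentrations of milligrams per
millilitre are physically implausible); and a table footnote names a
sevoflurane-remifentanil interaction although the parameters are for
propofol-remifentanil — treated as an erratum.

Numerics: `U^N/(U^N+1)` is evaluated as `expit(N·ln U)` (exactly 0 at
U = 0), so the sigmoid never overflows. Isoboles are solved per grid point
by bracketed Brent root-finding in CeR with the closed-form axis intercepts
as brackets; contour points satisfy |P(LOR) − level| < 1e-9. The predicted
50%-response time along a trajectory is the earliest grid crossing of
P(RR) ≥ threshold, refined by linear interpolation between the bracketing
samples (the per-minute clinical grid is coarse relative to emergence
kinetics); a tie at exactly the threshold counts as crossed.

## Labels

RR is detected as the earliest pair of consecutive OAA/S observations both
≥ 4 and stamped, by default, at the *first* observation of the pair (the
earliest evidence of sustained responsiveness); the second-of-pair
convention is available. The labeled dataset joins each trajectory sample
between LOR and RR + window to a binary label: 0 on [LOR, RR), 1 on
[RR, RR + 10 min], everything else excluded. Samples before LOR
(induction) are excluded because the modeling frame runs from LOR (coded
0) to awake (coded 1). Patients with no detected RR contribute only
0-rows. An alternative `endpoints` scheme keeps a single 0-row at LOR for
endpoint-anchored analyses; the default `interval` scheme labels every
maintenance sample 0, which is the reconstruction that yields the tens of
thousands of pooled concentration sets a per-case record produces.

## Logistic comparator

Maximum likelihood by iteratively reweighted least squares (Newton steps
with step-halving on the log-likelihood; acceptance slack relative to |ll|
so round-off at the optimum is not rejected). Convergence is declared when
the score norm falls below `tol` (default 1e-8) or when the Newton step
becomes numerically negligible at a near-zero score. Complete separation —
every positive scored strictly above every negative by the fitted linear
predictor — is detected explicitly and surfaced as a `SeparationWarning`
with `converged_ = False`, never a silent failure.

Forward selection starts from the intercept-only model and repeatedly adds
the candidate with the smallest likelihood-ratio chi-square (1 df) p-value
while it is below the threshold (default 0.05). The likelihood-ratio test
was chosen over the score test some commercial packages use because it is
well-defined against the package's own likelihood; the two can diverge
slightly in borderline selections, which is documented as a possible
source of difference from legacy software. The estimator follows the
scikit-learn contract (`fit`, `predict_proba`, `coef_`, `intercept_`,
`get_params`), so it composes with sklearn pipelines and model selection.

A convenience constructor builds the model with the published 29-patient
VATS cohort slopes (remifentanil +2.652 per ng/mL, propofol −3.403 per
µg/mL). The intercept of that published fit was not reported, so the
constructor requires one; absolute probabilities (though not ROC
orderings, which are intercept-invariant) depend on this unreported value.

## ROC analysis

AUC is computed as the Mann-Whitney concordance with ties counted 1/2 (via
midranks), which equals the trapezoidal integral of the empirical ROC
curve; the test suite holds the two to 1e-12 against exhaustive pair
counting. Confidence intervals use the DeLong U-statistic variance
(bootstrap alternative behind a switch); the paired two-model comparison
uses the paired DeLong test for correlated curves. Both are cross-checked
in the tests against R's pROC implementation to 1e-6. "Prediction
accuracy" is operationalized as the fraction correctly classified calling
P(RR) ≥ 0.5 awake — the standard classification-table accuracy, consistent
with the ~93-95% figures this kind of pooled-row design reports. Rows are
treated as independent in all ROC statistics; with pooled per-case rows
this understates the variance relative to a patient-clustered analysis,
so the confidence intervals and p-values are anti-conservative for
patient-level inference.

## Synthetic cohort

Defaults are the study conditions: 29 patients; age 54.6 ± 11.6 y, weight
60.6 ± 12.2 kg, height 159.5 ± 8.8 cm (truncated normals), 11/29 male;
operation time 198 ± 43 min; fentanyl bolus uniform 3-5 µg/kg at
induction; propofol effect-site target uniform 4-6 µg/mL (inside the
stated 4-10 µg/mL titration band and consistent with the reported cohort
maximum CeP of 7.89 µg/mL).

Propofol dosing uses the exact constant-target (bolus-elimination-
transfer) infusion profile for the Schnider model — an idealized TCI pump
holding plasma at the target, with the effect site equilibrating via
`ke0`. The opioid defaults to fentanyl-kinetic decay from the induction
bolus ("decay" mode); a "constant" mode holds the remifentanil-equivalent
at its induction peak, covering the ambiguity in how a sustained converted
fentanyl concentration is carried through a case.

The concentration/label grid defaults to 0.1 min. A strict per-minute grid
over 29 × ~198-min cases yields only ~5.7 × 10³ rows, which cannot
reconcile with the > 57,000 pooled concentration sets this design reports;
ten records per minute reproduces that count (29 × 198 × 10 ≈ 57,400), so
the fine grid is the package's default reconstruction. OAA/S is scored
every 20 s during a 90-min post-stop emergence window: each observation is
a Bernoulli draw of "responsive" with probability P(RR) from the
ground-truth Greco surface, emitted as the score dichotomy 4 vs 3 (the
analysis never uses finer scale structure). A noise-free variant
thresholds P(RR) at 0.5 instead of sampling, which makes the
OAA/S-detected RR time coincide with the surface's predicted
50%-probability crossing to within one 20-s observation step — the
end-to-end self-consistency check in the acceptance suite. LOR is the
first grid time with P(LOR) ≥ 0.5 during induction.

A null-cohort constructor replaces the labels with fair-coin draws
independent of the concentrations: on it, both models' AUC sits near 0.5
and forward selection almost always admits nothing — the pipeline's
negative control.

What passing tests on this generator do **not** show: performance on real
patients. The generator's responses come from the same family of surfaces
one of the scored models belongs to, so absolute AUCs here are best-case;
the informative comparisons are relative (surface vs logistic, real vs
null labels) and structural (self-consistency, parameter recovery).

## Problem sizes

The default test suite and acceptance checks run, on one CPU, with: one
29-patient cohort (~6 × 10⁴ labeled rows) for end-to-end checks; 50,000
rows for logistic parameter recovery; five 8-patient cohorts for the
coefficient-sign sweep; twenty 5-patient null cohorts (~10⁴ rows each) for
the negative control; 200-300 small instances for the ROC and coverage
oracles. These sizes were chosen to keep Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

- No pharmacodynamic inter-patient variability: every virtual patient
  shares the ground-truth surface; real C50s vary.
- No surgical stimulus or BIS-feedback titration; the propofol target is
  constant per patient.
- Greco parameters are consumed, never refitted (no hierarchical PD
  estimation); three-drug surfaces are out of scope.
- The published-coefficient logistic model cannot reproduce absolute
  published probabilities without its unreported intercept.
- Published AUC figures for this design conflict internally across their
  own report (0.979 vs 0.988 for the surface; logistic CI 0.989-0.990 vs
  0.992-0.994); the package does not adjudicate between them.
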