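# Methods

## Chemical model and assumptions

One well of the chromogenic FXa assay is modeled as three coupled rapid
equilibria: competitive inhibition of the enzyme (E·I, constant Ki, nM),
sequestration of the inhibitor by the decoy protein (A·I, constant Kd,
nM), and the Michaelis complex (E·S, constant Km, μM). Assumptions, in
decreasing order of importance:

* **Rapid equilibrium / initial rate.** Pre-incubation reaches binding
  equilibrium before the substrate read, and rates are taken before
  substrate depletion or product inhibition matter. The long (2 h)
  pre-incubation is assumed to equilibrate even the lowest-concentration
  wells.
* **Substrate non-depletion.** Free S is fixed at S₀ because S₀
  (100 μM) exceeds E₀ (≤ 3 nM) by more than four orders of magnitude;
  the ES complex is computed from the enzyme partition only.
* **Inert decoy.** No E·A or A·S species: the decoy is catalytically
  dead and its only modeled interaction is with the inhibitor.
  Decoy–cofactor interactions (e.g. with TFPI or FVa) are out of scope.
* **1:1 stoichiometries** throughout; no cooperativity.

## Numerics

The mass balances reduce to one scalar equation in free inhibitor x on
[0, I₀]: f(x) = x + E₀x/(D·Ki + x) + A₀x/(Kd + x) − I₀ with
D = 1 + S₀/Km. f is strictly increasing and brackets its unique root,
so Brent iteration (xtol 1e-15·max(I₀, 1e-3) nM) followed by a few
Newton polish steps reaches machine precision; Newton from x ≈ I₀ alone
can diverge in the tight-binding regime, which is why the bracketed
method is the primary path. All other species are closed-form in x,
each computed as a product (never by subtracting near-equal totals,
which loses all precision when x ≪ Kd). A state is "converged" when
every mass balance closes to 1e-9 relative; the solver raises nothing
on non-convergence but flags it, and the velocity model refuses to use
a non-converged state. Infinite Ki or Kd is the documented "no binding"
sentinel. Units are nM for E/I/A species and μM for S and Km, converted
only at module boundaries.

An independent oracle (`oracle_solve`) locates the same root by a dense
grid scan (≥10⁴ points) plus interval halving; it exists purely to
cross-check the fast path and is compared to it at 1e-6 relative in the
acceptance suite.

## Global fitting

(Ki, kcat) or (Kd, kcat) are estimated jointly across all series of one
experiment by unweighted least squares on velocities, optimizing log
parameters (positivity without constraints; no weighting scheme is
assumed). Residuals are scaled to nM/s internally for conditioning.
Starts are deterministic and data-driven: kcat from closed-form
Michaelis inversion of the uninhibited wells, Ki/Kd from the titration
level nearest 50% residual activity (1 nM fallback). kcat is fitted
per experiment, not shared between the two designs, mirroring the
separately reported turnover numbers (156 vs 176 s⁻¹). Standard errors
are Jacobian-based linear approximations at the optimum and are
reported as plain approximations. Designs that cannot constrain the
parameter (no inhibitor wells for Ki; no inhibitor-plus-decoy wells for
Kd) raise an identifiability error instead of returning a fit.

The 4PL calibration OD = bottom + (top − bottom)/(1 + (c/EC50)^h) is
fitted the same way (log-EC50), with analytic inversion for unknowns.
ODs outside the invertible span, or inverting beyond the standard
range, are flagged and censored at the nearest curve limit. A
non-monotone standard series (|Kendall tau| < 0.5) triggers a warning
diagnostic rather than a failure.

## Reversal predictions and reporting precision

Predicted percent residual anti-FXa activity is identified with percent
unbound inhibitor from the two-species quadratic — the minimal
assay-transfer assumption (activity linear in free inhibitor over the
assay range), stated explicitly because no transfer function is
otherwise defined. Reported precision is fixed to match conventional
printing: percents to the nearest integer, grams/folds/molar ratios to
1 decimal, μM conversions to 2 decimals, all half-up; exact values are
always retained alongside. Molecular masses: edoxaban 548.06 g/mol;
andexanet alfa is taken as 41 kg/mol, the effective mass consistent
with the reported μg/mL ↔ μM pairings for the glycoprotein.

## Study statistics

Group comparisons use the two-tailed pooled-variance (homoscedastic)
t-test with Mann–Whitney rank-sum confirmation (the arms are unpaired,
so the "Wilcoxon rank test" of the design is the rank-sum form).
Correlations are Spearman (average ranks for ties) with Kendall tau-b
confirmation; the Spearman p-value uses the large-sample approximation,
switching to the exact permutation distribution for n ≤ 9. Constant
inputs or zero-variance pairs are flagged (degenerate/undefined) rather
than silently propagated. Significance is read at P ≤ 0.05. No
multiplicity adjustment is applied.

## Synthetic-data generator

The generator defines the study conditions the tests exercise.

**Kinetic plates.** The two concentration designs are the published
ones: inhibitor titration at FXa 0.5/1.0 nM over 12 edoxaban levels
(0–12 nM), quadruplicate; decoy titration at FXa 3.0 nM, edoxaban
0/2.5/5.0/7.5 nM over 11 andexanet levels (0–500 nM), duplicate; S₀ =
100 μM, Km = 82.2 μM. Generating constants are the published best-fit
values (Ki 0.101 nM, kcat 156 s⁻¹; Kd 0.98 nM, kcat 176 s⁻¹ with Ki
fixed at 0.122 nM). Noise is proportional Gaussian, velocity·(1 +
N(0, CV)) truncated at 0, with CV = 2% by default — no noise model is
published, and 2% is typical replicate scatter for a kinetic plate
reader.

**Rabbit study.** Each animal draws a latent standard-normal
anticoagulation intensity z. Anticoagulation-sensitive endpoints are
affine in z around arm-specific targets (half the configured variance
from z, half from independent measurement noise, preserving the
marginal SD). Blood loss is μ + σ·(ρ·z + √(1−ρ²)·w) with independent w.
Arm targets use the published group statistics wherever they exist
(anti-FXa 548±87 → 100±41 and 507±72 → 447±64 around the infusion;
unbound inhibitor 99±10 → 21±6; blood loss 9.3±3.0 / 22.2±8.9 /
11.9±3.7 g; end-of-infusion drug levels 443 μg/mL decoy and a total
inhibitor level equivalent to 6.7 μM). Cells the study does not print —
per-arm n (default 10), PT/aPTT absolute levels (chosen consistent with
the reported 1.9× and 1.6× prolongations and the 31%/7% corrections),
assay background levels, 40-minute anti-FXa — are plausible fixed
choices documented in `DEFAULT_GROUP_PARAMS`. Decoy plasma
concentration decays exponentially from its end-of-infusion draw with
half-life 17.5 min (mid-range of the reported 15–20 min in small
animals). The within-arm correlation ρ = 0.48 was calibrated once by a
large-n scan so the pooled Spearman r between blood loss and
end-of-infusion anti-FXa is ≈ 0.70 over the three arms that enter the
correlation analysis (the decoy-only arm receives no anticoagulant and
is excluded); this latent-affine construction is a modeling choice of
this package, the minimal structure reproducing the printed means/SDs
and correlation scale.

**What passing tests do and do not show.** The generator reproduces the
first two moments per arm, the designed monotonicities and a realistic
pooled rank correlation. It does not emulate pharmacokinetic time
courses beyond the one exponential decay, inter-endpoint correlation
structure beyond the single latent, assay drift, censoring at
quantification limits, or animal dropout — so green tests validate the
pipeline's arithmetic and estimation behavior under the assumed
structure, not the biology of any particular dataset.

## Problem sizes

Defaults keep everything desk-scale: one kinetic plate is 96 or 88
wells; Monte-Carlo recovery uses 20 seeded replicate plates per design;
solver/oracle equivalence uses 1000 random systems at 2×10⁴ grid
points; the correlation calibration check uses 10⁴ animals per arm.
The full suite runs in about a minute on one CPU.

## Known limitations

* Percent residual activity ≡ percent unbound inhibitor ignores any
  nonlinearity of the anti-FXa assay readout in free drug.
* Assay dilution effects on effective plasma concentrations are not
  modeled; predictions use nominal concentrations.
* The 4PL quantifier assumes a decreasing calibration (hill > 0), the
  orientation of an inhibition assay.
* No clot-based (PT/aPTT) or thrombin-generation mechanistic model is
  included; those endpoints pass through as measured values only.
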