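# Methods

## Model structure

Drug disposition is simulated over a reduced whole-body compartment set: 14
organs (lung, brain, heart, muscle, adipose, skin, bone, kidney, spleen, gut
wall, liver, arterial blood, venous blood, and a lumped "rest" compartment)
with literature-standard adult volumes and regional blood flows (73 kg,
cardiac output 5.4 L/min). The systemic flows sum exactly to cardiac output;
the liver receives the hepatic artery (0.32 L/min) plus portal drainage from
gut wall (1.0 L/min) and spleen (0.08 L/min). Distribution is flow-limited
(perfusion-limited): every organ is well stirred and the blood leaving it is
in equilibrium with tissue, `C_out = C_tissue · B:P / Kp`. Permeability-
limited kinetics, transporters, enterohepatic recirculation and metabolite
kinetics are out of scope. Tissue partition coefficients (Kp) are model
inputs per drug (a per-tissue map with a `default` fallback), not predicted
from physicochemical properties.

## Metabolism and inhibition

Metabolic rates are evaluated at the unbound plasma-referenced tissue
concentration `C_u = fu · C_tissue / Kp` — the well-stirred assumption that
intracellular unbound equals plasma unbound. Three pathway kinetics are
supported: linear (intrinsic clearance per µmol enzyme), saturable
(Michaelis–Menten per µmol enzyme) and unspecific hepatic (an apparent
clearance acting on unbound liver concentration, used where a drug's main
clearance is scaled from an in vivo apparent clearance rather than from
enzyme kinetics; it is insensitive to inhibitors by construction).

Competitive inhibition multiplies the Km (or the linear denominator) by
`1 + Σ I_u/K_i`, summing over every co-dosed inhibitor of that enzyme plus
any clamped (constant-exposure) inhibitors supplied for verification.
Inhibitor concentrations are corrected for plasma protein binding
(`I_u = fu_inhibitor · C/Kp`) by default; `assemble(...,
inhibitor_unbound_correction=False)` switches to total plasma-referenced
concentrations, since which correction applies to in-vivo-derived constants
is a modeling decision that deserves an explicit switch.

Time-dependent (mechanism-based) inhibition gives each targeted enzyme one
dynamic active-amount state per expressing organ, shared by all drugs, with
turnover `dE/dt = kdeg·(E0 − E) − E·Σ kinact·I_u/(KI + I_u)`. Default
degradation rate constants (1/min): CYP3A4 3.2e-4, CYP1A2 3.0e-4, CYP2C19
4.4e-4, CYP2D6 2.3e-4, CYP2C9 1.1e-4, UGT1A1 2.4e-4 (turnover half-lives of
roughly 1–4 days); all overridable per simulation. Enzyme states exist only
when some TDI targets the enzyme — otherwise expression enters the rate laws
as a constant, keeping the state vector minimal.

The enzyme pool is shared across co-dosed drugs, so autoinhibition
(omeprazole enantiomers and moclobemide inactivating CYP2C19) automatically
becomes cross-inhibition when a second CYP2C19 substrate is present, and the
racemate is represented as the two enantiomers co-dosed at half dose each
with their separate constants.

## Phenotypes and gut expression

The reference individual expresses all six enzymes in liver and CYP3A4 plus
CYP2C19 in gut wall (the enzymes driving intestinal first-pass in this
network). Expression amounts are scalers — only the product of expression
and per-µmol rates is identifiable — so EM/PM genotypes are activity
multipliers applied to an enzyme's expression in every organ (EM 1.0, PM
0.0, intermediates allowed), and gut-wall expression can additionally be
scaled independently of liver (`scale_gut_expression`) to represent the
reduced intestinal CYP2C19 used for R-omeprazole's oral bioavailability.
The reduction factor is a configuration parameter with no default claim.

## Absorption and dosing

Oral doses enter a gut-lumen state absorbed at first-order rate ka into the
gut wall (where gut enzymes act before the portal vein); the fraction
1 − f_abs is routed to an unabsorbed sink. An optional Weibull release
(scale, shape) precedes absorption; shape = 1 recovers first-order release.
With multiple oral doses the Weibull hazard is evaluated against the time
since the most recent dose — an approximation that is exact for shape 1 and
for dosing intervals long relative to release. IV bolus and constant-rate
infusion enter venous blood. Doses may be declared in µmol or mg (converted
via molecular weight). A zero dose is a placebo arm.

## Numerics

`simulate` integrates with scipy's stiff-capable solvers (LSODA default,
rtol 1e-8 / atol 1e-10) with a hard restart at every dose event and infusion
edge, so no discontinuity is stepped over. Grid points coinciding with a
dose instant report the post-dose state (the t = 0 convention), which keeps
the mass-balance comparison against the administered-dose step function
exact. States are floored at zero between segments, warning if the excursion
exceeds 100·atol. Every simulation carries per-drug bookkeeping states
(cumulative metabolized, unabsorbed) and reports the maximum relative
mass-balance error over the output grid; the test suite requires < 0.1%
everywhere (typically ~1e-14). Network trials use rtol 1e-6 / atol 1e-9 —
ample for ratio endpoints — to keep the 11-pair sweep around five seconds.

PK endpoints use the linear-up/log-down trapezoid; the AUC method is a
package choice, documented here because profiles are positive and
log-linear on decline. λz comes from a log-linear fit of the trailing
strictly-descending positive points (≥ 3) and extrapolation adds C_last/λz.
Tmax ties break to the first occurrence. Interval endpoints interpolate the
cut points linearly, making AUC additive across adjacent intervals on a
shared grid.

## Sensitivity analysis

`S_ij = (ΔPK_j/PK_j)/(Δp_i/p_i)` is averaged over the perturbation set
Δ ∈ {−0.1, −0.05, +0.05, +0.1} (configurable); symmetric pairs cancel the
leading quadratic bias. Parameters with baseline 0 are skipped with a
sentinel (a relative perturbation is undefined). The perturbable set is a
documented whitelist of string handles — clearances, Vmax/Km, Ki/KI/kinact,
fu, Kp, ka, f_abs, organ volumes and flows, expression, dose — structural
choices are not addressable, preventing accidental structural changes.
Editing an organ blood flow rebalances cardiac output to preserve the flow
topology. Cumulative ranking sorts by |S| descending (name-ordered on ties)
and returns the minimal prefix strictly exceeding the threshold share
(default 90%); ranking is per endpoint, with AUC and Cmax reported side by
side, since pooling across endpoints would conflate scales.

## Synthetic observed data

The generator emulates the statistical shape of digitized clinical
mean(±SD) data: sparse schedules (6–16 samples), multiplicative log-normal
residual error (σ = sqrt(ln(1+CV²)), so the empirical CV equals the nominal
one), optional log-normal inter-individual variability (resimulated per
subject when a resimulator is supplied, otherwise pooled into a profile-
level amplitude as a documented scaling approximation), and LLOQ censoring
(values below the floor are reported at the floor and flagged BLQ — never
negative). Datasets are byte-reproducible from their seed and carry the true
generating parameters as metadata. What synthetic data do *not* emulate:
digitization error, inter-study heterogeneity in design and assay, real
covariate structure, and model misspecification — so passing recovery tests
demonstrates the estimation machinery and identifiability under the assumed
error model, not clinical predictive accuracy.

Observed DDI-ratio tables for qualification exercises are emulated as the
predicted ratios under log-normal study-level noise (default CV 0.2, a
typical between-study spread for exposure ratios).

## Parameter estimation

Middle-out fitting uses bounded least squares on log concentrations (BLQ
excluded) with parameters estimated on the log scale — bounds must be
positive and finite — via scipy's trust-region reflective algorithm and
three geometric multi-starts across the bound interval (ties by lowest
objective, then start order). Standard errors (of log-parameters) and the
pairwise correlation matrix come from the Jacobian at the optimum; a
rank-deficient or ill-conditioned (cond > 1e8) normal matrix flags
non-identifiability, with correlations reported as NA (the raw Jacobian
correlation structure is shown where computable, which is how perfectly
confounded pairs such as Vmax × enzyme amount surface with |r| ≈ 1). The
log-least-squares objective is a declared stand-in for the original
platform's internal objective, which is not public.

## Design choices and defaults

* Canonical internal units: µM, µmol, L, min; config files carry explicit
  unit strings (the interaction table mixes nM and µM) and conversion is
  idempotent.
* Interaction constants are pair-specific where the network says so:
  `run_trial` overrides the perpetrator drug-file inhibition entries with
  the library constants for the (perpetrator, victim) pair by default
  (`use_pair_ki=False` disables this).
* The k_inact for the omeprazole-enantiomer and moclobemide TDI entries is
  not tabulated in the source network; an illustrative 0.05 min⁻¹ is used
  and flagged in entry metadata. Ethinylestradiol's tested inactivation
  rates (100 and 200 min⁻¹) are both exposed; `compare_mechanisms` reports
  every variant so the alternative stays visible, ranked by
  |log(predicted/observed AUC ratio)|.
* Bundled drug parameterizations are illustrative (labeled in each file):
  pathway structures and interaction constants follow the network, PK
  parameters are plausible placeholders. Quantitative agreement with any
  specific clinical study is not claimed, and package checks are designed
  not to depend on these values except where structure forces the result
  (e.g. the PM zero-interaction prediction).
* Default qualification trial design: perpetrator dosed to steady state
  from time zero, single victim dose on day 2, victim exposure read over
  the following 24 h on a 3-min output grid (1441 points over 3 days) —
  sizes chosen so the full 11-pair sweep and the recovery experiments run
  in seconds to a few minutes on one core.

## Known limitations

Adults only (no ontogeny or population generation); no induction modeling;
no renal/biliary transporter mechanics; no food effects or
formulation-specific dissolution beyond the Weibull option; flow-limited
distribution throughout; single mean individual per arm (EM/PM arms reuse
one physiology with multipliers, isolating the genotype effect rather than
sampling population variability).
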