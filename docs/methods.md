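# Methods

`eposignal` implements a three-layer quantitative model of erythropoietin
(Epo)-driven proliferation in hematopoietic cells: a mechanistic ODE model of
EpoR → AKT/ERK → S6 signal transduction, a sensitivity analysis of the
integrated pS6 output, and linear regression links from signaling integrals
and a cell-cycle indicator to proliferation. This note records the model, its
assumptions, the numerical choices, and the design decisions taken where the
design was genuinely open.

## Signaling model

### Structure and rate laws

The network is a mass-action ODE system with one phenomenological Hill term
at the receptor. Dynamic species (44 states) cover the receptor module
(pEpoR and its complexes with Sos, PI3K, SHIP1 and GTP-Ras; inducible SHP1),
the lipid second-messenger layer (PIP2/PIP3 with membrane recruitment of AKT
and PDK1), AKT two-site activation (Thr308 by membrane PDK1, Ser473 by
TORC2), mTOR complex assembly (TORC1 with Raptor, TORC2 with Rictor), the
dual-phosphorylation cascade Ras → Raf → MEK → ERK with DUSP-mediated ERK
dephosphorylation, RSK downstream of ppERK, two-site S6 phosphorylation by
TORC1 and RSK (the integration point of the two pathways), and three
transcript fold-change variables (cyclinD2 induced, cyclinG2 and p27
repressed by pAKT/ppERK).

Every enzyme-mediated step uses the catalytic decomposition
`rate = k_cat × [enzyme] × [substrate]`, so the kinetic constant is a
property of the enzyme (shared across cell types) while the enzyme
concentration carries the cell-type specificity. Reversible binding steps
carry separate on/off constants. Seventeen conserved moieties (EpoR, Sos,
PI3K, SHIP1, SHP1, PIP2 pool, AKT, PDK1, mTOR, Raptor, Rictor, Ras, Raf,
MEK, ERK, RSK, S6) receive their totals from the cell-type context;
conservation is implied by reaction stoichiometry and checked post hoc
(relative drift < 1e-6 over any simulation).

Gab1/Gab2 adaptors are omitted from the fast receptor binding equilibrium
(their binding is either too fast or too slow to shape it); contexts carry
their abundances for reporting only. Membrane recruitment treats PIP3 as a
catalytic scaffold (not stoichiometrically consumed), keeping the PIP2+PIP3
pool a clean moiety. DUSP is a constitutive ppERK/pERK phosphatase whose
abundance is a per-cell-type quantity rather than a dynamic state. Transcript
synthesis terms are saturating regulatory laws
`k_deg · (1 + Σ w·x/(K + x))` (induced) and the reciprocal form (repressed),
normalized so the basal steady state is fold-change ≈ 1; these are the only
non-mass-action rates besides the receptor Hill input.

### Global kinetic parameters (82)

| module | parameters | count |
| --- | --- | --- |
| receptor activation / SHP1 loop | k_act_basal, k_act_epo, K_epo, n_epo, k_shp1_act, k_shp1_basal, k_shp1_deact, kcat_shp1_pepor, k_dephos_pepor | 9 |
| receptor complexes (4 × on/off) | kon/koff for Sos, PI3K, SHIP1, GTP-Ras | 8 |
| complex dephosphorylation (4 × SHP1-catalyzed + 4 × constitutive) | kcat_shp1_*, k_dephos_*_cplx | 8 |
| ligand depletion | k_epo_deg | 1 |
| PIP3 turnover | kcat_pip3, k_pip3_basal, kcat_ship1_m, kcat_ship1_c, kcat_pten | 5 |
| membrane recruitment | kon/koff for AKT and PDK1 | 4 |
| AKT activation | kcat_akt_308, kcat_akt_473, k_dephos_pakt_mem, k_dephos_pakt | 4 |
| mTOR / TORC assembly | kcat_mtor_act, k_mtor_deact, kon/koff TORC1, kon/koff TORC2 | 6 |
| Ras | kcat_ras_act, k_ras_basal, k_ras_gap, kcat_ras_gap_rec | 4 |
| Raf | kcat_raf_act, k_raf_deact | 2 |
| MEK (two sites) | kcat_mek_p1/p2, k_mek_dp1/dp2 | 4 |
| ERK (two sites) | kcat_erk_p1/p2, kcat_dusp_pp/p | 4 |
| RSK | kcat_rsk_act, k_rsk_deact | 2 |
| S6 (two sites, two kinases) | kcat_s6_torc1_a/b, kcat_s6_rsk_a/b, k_s6_dp_a/b | 6 |
| transcripts (3 genes × 5) | k_deg, w_akt, w_erk, K_akt, K_erk per gene | 15 |
| **total** | | **82** |

Units: /min for first-order constants, /(nM·min) for second-order constants,
U/ml for `K_epo`; weights and the Hill exponent dimensionless. The default
values (`network.DEFAULT_THETA`) are a reduced, fast-simulating synthetic
truth tuned once so that (i) the three phospho-degree anchors are satisfiable,
(ii) receptor phosphorylation is transient, (iii) the cell-type-specific
signal-flow pattern emerges from the measured abundances (see Sensitivity
below). They are not fitted values from experimental data.

### Cell-type contexts

The three measured contexts (murine primary CFU-E progenitors, BaF3-EpoR,
32D-EpoR) carry cytoplasmic volume (399 / 1400 / 1406 μm³), surface area
(378.5 / 600.3 / 607 μm²), and absolute concentrations in nM for EpoR, AKT,
PI3K, SHIP1, PTEN, PDK1, Ras, Raf, MEK, ERK, S6, Gab1/2. Four components
(mTOR, Rictor, Raptor, RSK) were measured only relative to the primary-cell
level; they are stored as ratios and resolved against declared reference
concentrations (mTOR 150, Rictor 120, Raptor 150, RSK 350 nM in mCFU-E) —
model reference scales, not measurements. Components the abundance table
does not cover receive nominal values chosen once: SHP1 100 nM, Sos 100 nM,
PIP2 pool 4000 nM (identical across cell types, so they do not contribute to
cell-type differences), and DUSP 30 nM in mCFU-E with a BaF3:mCFU-E basal
ratio of 2^5.27 (a model-identified quantity) and an assumed ratio of 35 for
32D-EpoR. Copy numbers convert to concentrations via
`c[nM] = N / (V[μm³]·1e-15·N_A) · 1e9`; the same path builds contexts for new
cell types (e.g. a human-progenitor-like context from proteome copy
numbers).

### Receptor input and units

Epo enters in U/ml (no conversion to molarity) and drives receptor
phosphorylation through `v·epo^n/(K^n + epo^n)` acting on the activation
*rate* (not on occupancy). The truth uses n = 1 and K = 1 U/ml; the exponent
is a free parameter everywhere else. Ligand depletion is first order,
catalyzed by total receptor. Time is in minutes for signaling (0–60 min
horizon) and hours only in growth-curve fits.

### Simulation

Trajectories integrate with LSODA (rtol 1e-8, atol 1e-10 nM) using an
analytic sparse-free Jacobian generated symbolically. Before stimulation the
deprived system is relaxed at epo = 0 until the derivative sup-norm is below
1e-8 nM/min (at most 1e4 min); steady states are cached keyed on everything
they depend on (model identity, abundances, kinetics, receptor scaling).
Inhibitors act as constant multiplicative factors `1/(1 + dose/strength)` on
their target process (AKT VIII → AKT phosphorylation, U0126 → MEK activity
toward ERK, BI-D1870 → RSK phosphorylation, rapamycin → TORC1 activity),
applied from −30 min (pretreatment segment after pre-equilibration); the
strength is one cell-type-specific parameter per inhibitor. Overexpression
multiplies a conserved total; knockdown sets it.

### Observable scaling (phospho-degree anchors)

Immunoblot observables are defined up to a scale. Three anchors convert
arbitrary units to nM: the receptor phosphorylation degree reaches at most
75% at saturating Epo; 54% of AKT is phosphorylated in the primary-cell
context at 2.5 U/ml and 10 min; at most 10% of ERK is double-phosphorylated
in that context. `anchor_scalings` simulates the anchor conditions and sets
each observable scale so the scaled trajectory meets the anchor exactly;
anchored trajectories are in nM via the measured totals.

## Calibration

The objective is the weighted residual sum of squares with the blot error
model σ = 0.10·y + 0.05·max(condition), where a condition group is
(cell type, observable, perturbation). Parameters are estimated on log10
scale (default box [−5, 3]) by trust-region reflective least squares with
finite-difference gradients, started from Latin hypercube samples; the LHS
pool is prefix-stable in the seed so adding starts can only improve the
optimum. Simulation failures return a large penalty residual instead of
raising. Cell-type-specific fitted quantities are limited by construction to
inhibitor strengths, observable scales, per-context abundances (e.g. basal
DUSP), and receptor-module activation/deactivation multipliers; everything
else is global.

Identifiability uses the profile likelihood: each parameter is scanned on a
log10 grid outward from the optimum, re-optimizing the others with warm
starts; the 95% pointwise interval is where the profile stays within 3.84
(χ², 1 df) of the minimum, with open directions reported as
non-identifiable. A branch stops once the profile exceeds the threshold by a
margin (default 10), the crossing already being bracketed.

### Reduced cascade and the recovery study

The reduced 10-parameter model is a single activation chain
Epo → pR → pA → pS (Hill input, first-order deactivations, ligand
depletion) with the primary-cell totals. Because each tier is a scalar
linear ODE given the tier above, the package also ships an exponential
midpoint integrator on a fixed 0.25-min grid — unconditionally stable at any
sampled rate constants and ~1e-4-accurate against the stiff solver (asserted
in tests) — which makes replicated studies affordable.

The parameter-recovery study simulates 3 doses (0.5/2.5/10 U/ml) × 4 times
(0/10/30/60 min) × 3 observables, adds error-model noise, and runs 20
seeded replicates of multi-start fitting (12 starts) plus profiles of all 10
parameters (span 2.5 decades, 17 points). Per-parameter log bounds reflect
parameter type (second-order constants narrower because the effective rate
is k_cat times a conserved total of order 10²–10³ nM). Coverage counts a
replicate when the true value lies inside the 95% profile interval, with
open directions counting as covering (non-identifiable). Observed coverage
is ≥ 17/20 for every parameter, consistent with nominal 95% pointwise
intervals at this sample size.

## Sensitivity analysis

The response coefficient S_p^X = (∂X/∂p)·(p/X) is computed for X = pS6
integrated over the first hour and p each context protein abundance, by
central finite differences with relative step 1e-3 (optionally
Richardson-checked by step halving). The evaluation dose is 5 U/ml (the dose
of the inhibitor/link experiments); integrated responses use the trapezoidal
rule on a 0.5-min grid for model output and on the measured grid for sparse
data (adaptive quadrature on the dense ODE interpolant is available). The
PIP2 pool is treated as a context "protein". Proteins group into four
network modules (receptor; PI3K/AKT; Ras/MEK/ERK; S6 integration).

On the synthetic-truth parametrization the measured abundances alone produce
the cell-type-specific signal flow: integrated pS6 is dominated by the
AKT/TORC1 route in the primary cells (low SHIP1/PTEN → high PIP3 → strong
membrane recruitment of AKT and PDK1, a quadratic effect) and by the
ERK/RSK route in both cell lines (high Ras/Raf/MEK/ERK and 2.8–7.4-fold
higher RSK), with correspondingly low RSK sensitivity in mCFU-E and high RSK
sensitivity in the lines, and PTEN negative everywhere.

## Phenotype link

The cell cycle indicator CCI = fc_cyclinD2 / (fc_cyclinG2 · fc_p27)
condenses one activator and two repressors of G1→S progression; it is 1 at
baseline and multiplicative by construction, so the stage-1 regression uses
log CCI as response (raw scale available) on the 1-h integrated pAKT and
ppERK with intercept, fitted per cell type (pooling optional). Stage 2
regresses proliferation on {integrated pS6}, {CCI} or both, and selects by
Akaike's information criterion; candidates within ΔAIC < 2 are reported as
indistinguishable, exact ties break toward fewest parameters. AIC is the
default; the small-sample AICc correction is used for the n = 9 selection
studies, where plain AIC over-selects the richer model at the textbook
~16% rate. Predicted proliferation is scaled per cell type by the Epo-only
condition (so the unperturbed condition equals 1). Linear links extrapolated
to strong inhibition can fall below zero; an optional floor clips
predictions but is off by default.

Dose–response curves use the four-parameter Hill regression
y = y0 + a·x^b/(c^b + x^b) (EC50 = c) fitted by nonlinear least squares from
a deterministic multi-start grid, with a degenerate-fit flag for flat
responses; growth curves use exponential regression of log counts (doubling
time ln 2 / slope; non-positive slopes flagged as no growth).

## Synthetic-data generator

`GroundTruth` declares the generating process: the kinetic truth and
contexts, per-cell-type inhibitor strengths (0.5 μM half-inhibition doses,
except U0126 in 32D-EpoR at 2.0 μM, consistent with elevated MEK buffering
the drug), anchored observable scales, positive stage-1 coefficients
calibrated so the Epo-only condition reproduces 13-fold (primary cells) and
16-fold (cell lines) CCI induction with a declared AKT share (0.6 / 0.4),
and a stage-2 class per cell type (growth-limited: proliferation follows
integrated pS6 — the fast-cycling primary cells; cycle-limited: follows
CCI — the larger, slower cell lines).

The design defaults are the study's: three cell types, 5 U/ml Epo, AKT VIII
and U0126 at 0/0.05/0.5/5 μM, samples at 0/10/30/60 min. Time-course noise
is Gaussian with SD 0.10·y + 0.05·max(condition); the stored σ column always
follows this canonical error model even when the injected noise is scaled
down, so a zero-noise dataset equals the simulation exactly while remaining
fittable. CCI values decompose into fold changes as fc_ccnd2 = CCI^(1/2),
fc_ccng2 = fc_cdkn1b = CCI^(−1/4) (balanced up/down regulation; no published
triple pins the split), with independent lognormal qPCR noise (σ_log 0.15, a
typical RT-PCR replicate CV). Proliferation readouts are scaled to 1 at the
Epo-only condition before additive noise (SD 5% of the per-cell-type
maximum).

What the generator does **not** emulate: blot image processing and
spline-based lane normalization, biological replicate structure and
between-experiment scale drift, day-to-day variability of protein
abundances, receptor trafficking, and any STAT5-dependent biology. Passing
tests therefore demonstrate that the machinery recovers a truth of this
model class under the stated noise — not that the shipped default
parametrization describes real cells.

A practical consequence of realistic qPCR noise: the CCI predictor carries
~26% multiplicative noise (three genes × σ_log 0.15), which attenuates its
regression against proliferation; with only 9 conditions per cell type,
class recovery for the cycle-limited cell lines from fully noisy data is
marginal, while the growth-limited class is recovered robustly. The
selection-consistency guarantee (≥ 90%) holds at the controlled
signal-to-noise ratio of 10 used in the dedicated study.

## Numerical choices and degenerate inputs

* ODE tolerances rtol 1e-8 / atol 1e-10 nM; the Hill input floors Epo at
  1e-12 U/ml so the Jacobian stays finite at zero dose.
* Trapezoidal integration is exact for piecewise-linear signals, matching
  how sparse measured time courses are integrated.
* σ is undefined for an all-zero condition group (configuration error
  rather than a silent zero weight); relative sensitivities are undefined
  at zero output (raise, never silently 0).
* Exact AIC ties break deterministically (fewest parameters, then
  candidate name); rank-deficient regression designs are flagged
  degenerate, underdetermined candidates are excluded with notice.
* Flat dose–response curves return a degenerate Hill fit (a ≈ 0, EC50
  unidentifiable) instead of an arbitrary EC50.

## Known limitations

* The default kinetic parametrization is a synthetic truth constrained by
  the anchors and the qualitative signal-flow pattern; absolute rate values
  are not literature estimates.
* SHP1 activation is a single step (no delay chain); receptor trafficking
  and internalization are absorbed into the phenomenological receptor
  module; no STAT5 branch; no spatial or stochastic effects.
* SBML support covers the constructs this package emits (species,
  parameters, reactions with content-MathML rate laws); events, rules and
  function definitions in foreign files are reported as unmapped, not
  interpreted.
* The human-progenitor-like context builder is exercised with synthetic
  copy numbers; no measured human abundance table ships with the package.
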