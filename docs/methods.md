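# Methods

## Model

The receptor pool is described by five species — monomer M, liganded monomer
ML, unliganded dimer D, singly liganded dimer DL and doubly liganded dimer
DL2 — under mass action at equilibrium. All concentrations are nM.
Assumptions:

* **Clamped free ligand.** Whole-cell binding is done in a medium volume
  vastly larger than the cell volume, so free ligand is treated as fixed
  (no depletion). A depletion-aware solver is deliberately out of scope.
* **Detailed balance.** The two routes from 2M + 2L to DL2 (bind-then-
  dimerize vs dimerize-then-bind) close a thermodynamic cycle, so
  `Kd_A² · Kd_B = Kd_C · Kd_D1 · Kd_D2`. Kd_B is always derived from the
  other four constants and cannot be set directly.
* **Macroscopic constants.** Kd_D1 and Kd_D2 are macroscopic. Two identical
  independent sites on a dimer give Kd_D2/Kd_D1 = 4 purely statistically,
  so macroscopic positive cooperativity requires Kd_D2/Kd_D1 < 1/4, not
  merely < 1.
* **Equilibrium only.** No kinetics: association/dissociation rates,
  nuclear transport, chaperone cycling and receptor turnover are out of
  scope.

Given clamped l, every species follows from [M], and receptor mass balance
is a quadratic in [M]; its unique positive root is evaluated with the
cancellation-safe form `m = 2r / (b + sqrt(b² + 4ar))`. A bisection oracle
on the mass-balance residual cross-checks the closed form in the tests at
1e-8 relative tolerance.

DNA binding is a competitive single-site occupancy over the four species
classes. Default affinities: monomer 62 nM and unliganded dimer 1.21 nM
(literature electromobility-shift values), liganded dimer 0.23 nM (likewise);
the liganded-monomer 30 nM default is an assumption chosen to satisfy the
observed hierarchy (liganded dimer < unliganded dimer ≤ liganded monomer <
unliganded monomer). Activity weights default to 1.0 for the liganded dimer,
0.2 for the unliganded dimer and 0 for monomers, so that basal priming
(ligand-independent activity roughly a tenth of maximal) emerges; both maps
are configurable.

## Units and conversions

Receptor densities are measured as Bmax in cpm/mg protein and converted with
a counting efficiency of 0.43 and a specific activity of 76.5 Ci/mmol (the
midpoint of the supplier's 68–85 range; configurable). With ~20% of cells
transfected, densities in expressing cells are bulk values / 0.20. The
fmol/mg → molecules/cell conversion uses 0.13 ng protein per cell,
back-computed from the printed 335 fmol/mg ↔ 26,200 receptors/cell pair;
the nM conversion additionally assumes a 2 pL cell volume. The protein mass
and cell volume are explicit, configurable assumptions — absolute
intracellular nM values inherit their uncertainty, while all within-study
ratios are unaffected.

## Calibration

`calibrate_presets` fits (Kd_A, Kd_C, Kd_D1, Kd_D2) by deterministic
trust-region least squares on log-ratios from a fixed starting point
(30, 40, 40, 1 nM) against five observables: pre-ligand dimer mole fractions
of 1/3, 2/3 and 2/3 at the low/medium/high receptor pools (21.8, 49.6 and
92.3 nM), and an apparent one-site Kd of 16.8 nM plus a variable-slope Hill
coefficient of 1.72 for the high-pool binding curve. The apparent Kd and
Hill observables are evaluated on the same nine-dose hot-ligand design the
binding assay uses, because fitted summaries of a cooperative curve are
design-dependent.

Three properties of the solution are worth knowing:

* A single Kd_C cannot reproduce the dimer-fraction triple (1/3, 2/3, 2/3)
  exactly — the 2M ⇌ D law ties the fraction to the pool monotonically — so
  the fit is a least-squares compromise (achieved 0.40/0.54/0.63, max |log
  residual| ≈ 0.22, reported and flagged). The synthetic FRET generator
  therefore carries the target fractions directly as programmed truths
  rather than deriving them from the model.
* The apparent Kd and Hill targets pin the high-pool curve tightly
  (residuals < 2%), but leave a shallow trade-off direction among Kd_A,
  Kd_D1 and Kd_D2: the monomer affinity Kd_A is only weakly identified by
  these observables. Absolute values of individual constants should be read
  with that caveat; the preset constants are the frozen output of the
  documented deterministic fit.
* Because the model at the low pool already holds ~40% of receptors in
  dimers, its noiseless low-pool binding curve fits with a Hill slope ≈ 1.5
  — steeper than the near-1 slope observed at low expression. The
  compromise is inherited from the dimer-fraction targets.

The dimerization-impaired mutant is modeled by scaling Kd_C (and, through
the cycle, Kd_B) by a single impairment factor. The data constrain only its
direction ("impaired, not abolished"); the default of 1000× is the smallest
round factor at which the mutant's fitted binding Hill slope is ~1 at both
expression levels studied — at 100× the liganded-dimerization route still
produces visible cooperativity (fitted slope ≈ 1.2), contradicting the
mutant phenotype. The factor is an exposed knob.

## Assay analyses

**Saturation binding.** Specific = total − nonspecific counts per matched
tube, normalized to protein; negative values (noise) are clipped to zero
with a logged warning. Fits are unweighted nonlinear least squares
(Prism-style): the one-site hyperbola `b = Bmax·l/(Kd+l)`, and the
variable-slope sigmoid on log10 concentration with bottom fixed at 0.
Responses are rescaled to O(1) inside the fitters so convergence tolerances
act relatively. Data must span ≥ 2 decades for the Hill fit.

**FRET.** Corrected FRET = raw − a·donor − b·acceptor (defaults a = 0.5,
b = 0.02 are placeholders in a plausible CFP/YFP range, configurable; real
instruments need their own calibration). Each cell's series is normalized
to its pre-stimulus value and fitted with a variable-slope sigmoid in time,
bottom fixed at 1; the fitted top is the maximal fold-induction f. Because
FRET intensity is proportional to dimer count and saturating agonist drives
(essentially) complete dimerization, pre-ligand dimers are Dmax/f, i.e. a
dimer mole fraction of 1/f and % monomers = 100·(1 − 1/f). The FRET-to-dimer
proportionality constant and the ~50% donor–acceptor hetero-pairing
probability under equimolar co-transfection multiply both numerator and
denominator of f and cancel exactly, so no absolute FRET calibration is
needed. If saturating ligand dimerizes only a fraction φ_max of the pool
the partition becomes φ_max/f; φ_max is an exposed knob (default 1) because
the completeness assumption cannot be verified from fold-induction alone.
Donor gating (low < 600 ≤ medium < 1200 ≤ high) uses the t = 30 min donor
signal, left-closed bins.

**Dose–response.** 4PL on log10 molar concentration; vehicle (conc = 0) is
assigned a pseudo-dose one decade below the lowest tested dose and anchors
the lower asymptote. This convention perturbs "exact" noiseless recovery at
the ~1e-5 relative level (the model at the pseudo-dose is not exactly the
basal value), which is why the tests assert recovery at 1e-4 rather than
machine precision. Slope mode defaults to fixed-1 for potency comparisons
and variable for slope analysis; both are first-class and reported side by
side, since whether the original fits constrained the slope is not stated.
Potency shifts are EC50 ratios with seeded bootstrap CIs (replicate
resampling within concentration, 1000 resamples by default) in place of
ANOVA machinery. qPCR data are converted by ΔΔCt with the vehicle as
calibrator before 4PL fitting.

**Co-IP / ChIP.** Pure normalization arithmetic (pull-down/bait,
% of reference, input-normalized loading vs the no-receptor vehicle
baseline, agonist/vehicle fold recruitment); all four operations are
invariant to common rescaling of the raw values. The IgG negative-control
channel is generated but never subtracted — it is a control, not a
correction.

## Synthetic data

Generators emulate each experimental design with programmed truths from the
expression presets and seeded noise: Poisson counts plus Gaussian background
(sd 10 cpm) for scintillation; multiplicative log-normal (CV 0.15) for
luminescence; additive Gaussian at 3% of signal per FRET channel; Gaussian
sd 0.2 cycles on Ct values; log-normal CV 0.10 on band/qPCR abundances. The
noise laws themselves are modeling choices — the source data report only
SEMs of triplicates.

Preset truths encode the observed fold-relations. Wild-type reporter
dose–response: basal 1×/3×/10×, efficacy 1×/4×/12×, potency 1×/650×/2600×
of the low level; endogenous-gene potency 1×/80×/500×. The three printed
relations basal, efficacy and fold-induction are mutually inconsistent with
fold-induction lying in 9–11 at every level (fold = 1 + efficacy/basal is
forced to 10/13/11.8 once basal and efficacy ratios are fixed); the package
prioritizes the exact basal and efficacy multipliers and accepts the
resulting fold-inductions, which still bracket the printed band. Absolute
anchors never printed — the low-level reference-agonist EC50 (10 nM), the
endogenous-gene anchor (5 nM), RLU scales, band intensities — are arbitrary
documented choices; only ratios are calibrated. Cortisol uses its printed
1.7 nM (low) and 0.03 nM (medium) anchors. Nonspecific binding is linear in
dose with slope set so it is 20% of total at the top dose (no value is
reported; this is an assumption).

What the generators do **not** emulate: plate/batch effects, inter-
experiment variability beyond the seeded noise, image-level FRET artifacts
(photobleaching, movement, segmentation error), PCR efficiency ≠ 2,
receptor turnover during the assay, and ligand depletion. Passing
recovery tests therefore demonstrates that the analysis chain is correct
and unbiased under its own assumptions — not that those assumptions hold
for any particular instrument or cell line.

## Problem sizes and determinism

Default problem sizes: 9 hot-ligand doses × 3 replicates for binding; 50
cells × 31 time points for FRET; 10 decades × 3 replicates (plus vehicle)
for dose–response, with three independent triplicate experiments pooled
where the original design pooled experiments. All generators take explicit
seeds and identical seeds give byte-identical tables; pipeline reports
contain no timestamps so reruns are byte-identical. The acceptance script
derives every stage seed from its single `--seed` argument.

## Known limitations

* The stoichiometric FRET inversion is a reconstruction: the original
  supplementary derivation is not reproduced in the main text, and the
  treatment of incomplete dimerization or hetero-pairing there is unknown.
  The φ_max knob bounds the consequence.
* Absolute nM concentrations rest on the assumed cell volume and
  protein-per-cell mass; only their ratios are data-anchored.
* The calibrated equilibrium constants are one member of a shallow
  trade-off family (see Calibration) and should not be quoted as measured
  affinities.
* The occupancy-span statistic is exposed for any pair of Hill
  coefficients; the commonly quoted ~6-fold shrinkage corresponds to a 1.0
  baseline, while a 1.08 baseline gives ~4.5-fold. Both are computable with
  `occupancy_span_ratio`.
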