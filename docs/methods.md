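# Methods

`morbidosim` is a software twin of a low-cost morbidostat: a continuous
culture device that feeds antibiotic back into a growing bacterial
population to hold growth inhibition roughly constant, so that selection
pressure escalates as resistance evolves. The package implements the four
computational pieces such a device needs — culture dynamics, optical
sensing, the dosing feedback rule, and the endpoint resistance assay — and
wires them into a closed loop that runs entirely in simulated time.

## The virtual culture

Each culture unit holds a well-mixed volume `V` (default 12 mL) containing
one or more phenotypes, each described by a maximal per-capita growth rate
`r`, a half-inhibitory drug concentration `IC50`, and a Hill steepness `n`.
Densities are tracked in OD600-equivalent units. At drug concentration `c`
and total density `N`, the net per-capita rate of a phenotype is

    g(c, N) = r (1 − N/K)(1 − E(c)) − d E(c),
    E(c)    = c^n / (c^n + IC50^n),

logistic growth attenuated by Hill inhibition plus a Hill-shaped kill term.
This is the simplest pharmacodynamic form that (a) reduces to pure logistic
growth without drug, (b) is strictly decreasing and saturating in `c`, and
(c) allows net death at high drug — a morbidostat cannot hold a culture at
constant inhibition unless the drug can push net growth below zero.
Defaults: `r = 1.0 h⁻¹`, `K = 1.0` OD, `d = 0.2 h⁻¹`, `n = 2`.

The per-phenotype ODEs (coupled through `N`) are integrated with fixed-step
classical RK4 using internal substeps of at most 0.01 h; against the
logistic closed form the relative error at these settings is ~1e-12 per 8 h,
far below every tolerance used in the tests. Pump events are applied
instantaneously between steps (stirring is assumed perfect): additions mix
drug mass exactly, `c' = (cV + c_in ΔV)/(V + ΔV)`, and scale every density
by `V/(V + ΔV)`; waste removal takes well-mixed culture, leaving
concentrations untouched. Drug mass and cell number are conserved to
floating-point accuracy, which the test suite checks through 10⁴ random
pump events.

Resistance evolves on a single-locus ladder: each mutation multiplies the
IC50 by `α = 2`, at probability `µ = 1e-8` per division. Division counts
come from the birth part of the rate (`g` with the kill term dropped) times
`density · V · cells_per_od` with `cells_per_od = 8e8`. Stochastic mode
draws Poisson mutant counts per substep from one seeded generator per
simulation; deterministic mode moves the expected flux. With `µ = 0` the
two modes coincide exactly. Mutant density is transferred from the parent
subpopulation so the re-labeling conserves total cell number. This ladder is
deliberately minimal: it produces stepwise IC50 escalation without modeling
the genetics of any particular resistance mechanism, and the quantitative
IC50 trajectory it yields is illustrative, not a reproduction of any
particular wet-lab run.

## The optical chain

The forward model is true Beer–Lambert attenuation,
`V = gain · V₀ · 10^(−k·OD)`, with `V₀ = 2.93 V` (a typical blank-vial
photodiode voltage on this class of hardware) and effective absorptivity
`k = 0.3` per OD unit. `k` is well below the 1.0 of a 1 cm cuvette because a
scintillation-vial light path is short and a wide-acceptance photodiode
recaptures forward-scattered light; the practical consequence, reproduced
here, is that a *linear* voltage→OD calibration is accurate over the
working range (error < 2% of full scale for OD 0–0.3) while quadratic and
cubic fits do slightly better (typical R² 0.99 / 0.9997 / 0.9999 on a noisy
0–1 OD table).

Unit-to-unit variability — 3D-printed vial holders position the diodes
slightly differently — is modeled as a multiplicative lognormal gain with
mean 1 and coefficient of variation 8% (the scale reported for this class
of device; note that a mean of 2.93 V with sd 0.23 V is a CV of 7.85%, and
`unit_variability` implements exactly the cross-unit CV, 100·sd/mean).
Additive Gaussian read noise (sd 0.01 V) sits on top. Calibration is
ordinary polynomial least squares of OD on voltage (degree 1–3), with R²
computed on the OD response axis and predictions clamped at 0; the fit is
checked against a normal-equations oracle to 1e-8.

## The feedback rule

Every cycle (default 12 min) the controller reads the calibrated OD,
appends it to the unit's history, estimates the recent growth rate as the
OLS slope of ln OD over the last `window = 5` readings, and applies the
morbidostat rule: deliver drug-containing medium if and only if the density
exceeds the threshold `θ = 0.3` OD **and** the estimated rate exceeds 0;
otherwise deliver drug-free medium. Both inequalities are strict, so ties
get permissive medium. Every cycle moves `ΔV = 1 mL` in and an equal waste
volume out, holding the volume constant. During the first `window − 1`
ticks the rate is treated as 0, which forces the permissive choice.

Two consequences worth knowing. First, the rate estimate spans dilution
events, so it measures growth *net of washout* (≈ `g − D` with
`D = ΔV/(V·Δt) ≈ 0.42 h⁻¹`); drug addition therefore stops while the
culture still grows slightly faster than washout, and the drug
concentration a susceptible culture settles at is the one where net growth
roughly balances dilution. Second, because permissive medium flows every
cycle, drug washes out with a ~2.6 h time constant once additions stop —
which is what produces the characteristic knockdown/recovery oscillation
and, over longer runs, the upward ratchet of drug pressure as resistant
phenotypes raise the concentration at which growth stalls.

Nonpositive OD readings (possible after blank subtraction on noisy
hardware) are floored at 1e-4 OD with a warning rather than crashing the
loop.

## The endpoint assay

Resistance is quantified the way a plate assay would: a sample is
inoculated at 0.005 OD across a two-fold dilution series (default top dose
32 µg/mL, 8 wells, plus a drug-free control), grown 18 h at constant drug
concentration with mutation off, and the endpoint ODs are fit with the
four-parameter Hill curve

    OD(c) = od_min + (od_max − od_min) / (1 + (c/IC50)^h).

The optimizer (trust-region least squares) works on log IC50 with bounds
IC50 ≤ 10× the top dose and h ∈ (0, 10]; three starting points are always
tried and the best sum of squares kept. The IC50 variance is the delta-
method propagation of the log-IC50 covariance; a residual bootstrap is
available behind a flag. A fit is flagged non-converged when the optimizer
fails, the IC50 lands near its upper bound, the fitted amplitude is
indistinguishable from zero, or the IC50 standard error exceeds the
estimate — all signatures of a plate that resolved no inhibition, where a
finite midpoint would be spurious. Zero-dose wells are included in the fit
and anchor `od_max`.

Note the endpoint IC50 is a different quantity from the pharmacodynamic
`IC50` parameter of the growth law: 18 h of near-saturating growth
compresses the curve, so the ancestral strain (parameter 4 µg/mL) assays at
≈ 4.6 µg/mL with a steeper apparent Hill coefficient. The assay is
monotone in the underlying parameter, which is what a resistance
*trajectory* needs.

Effluent snapshots taken every 12 h record the full phenotype composition,
and the assay runs on that mixture — mirroring the fact that a frozen
effluent sample contains the whole population, not its majority genotype.
Because the endpoint assay is sensitive to minority resistant
subpopulations, the fitted IC50 rises smoothly as a resistant clone
expands, giving a graded, monotone resistance trajectory rather than a
single step.

## Seeding and determinism

A master seed derives independent streams per (unit, subsystem) through
`SeedSequence([master, unit, stream])`: gains, read noise, calibration
noise, mutation draws, and assay noise never share a stream. Adding a
culture unit therefore does not perturb existing units, and two runs with
the same master seed produce byte-identical log files.

## Problem sizes used in the checks

The acceptance script runs a 100 h single-unit evolving experiment (501
control cycles, 9 effluent assays), a 28 h demo pair for determinism and
phase structure, 200 noisy plate fits, a 50 h discrete chemostat, 10⁴ pump
events, and 1000 seven-unit variability draws — sizes chosen so the whole
script completes in well under a minute on one core while leaving each
estimate's Monte-Carlo error far below the property margins it is compared
against.

## Known limitations

- No temperature, oxygenation, wall growth, or nutrient dynamics; the drug
  is the only environmental variable and it does not degrade.
- The resistance ladder ignores fitness costs; evolved phenotypes keep the
  ancestral `r`, so trajectories overstate how cleanly resistance sweeps.
- The ODE treatment is deterministic between mutation events; demographic
  noise at small population sizes (early mutant lineages) enters only
  through Poisson origination, not through birth-death fluctuations, so
  lineage-loss stochasticity is understated.
- Pumps are exact and instantaneous; real peristaltic pumps have flow-rate
  error that would need per-pump calibration.
- Passing the closed-loop properties here demonstrates the control and
  analysis chain is correct under the stated model, not that any particular
  organism/drug pair will reproduce these trajectories.
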