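# Methods

This note documents the models, conventions and numerical choices behind
`pmrflux`, and what the synthetic-data tests do and do not establish.

## Quantification model

**Time base.** The gated acquisition sums saturated FIDs into bins (64 at
rest; 6×32 during stimulation; 7×32, 3×64, 1×96 during recovery; 1.875 s
repetition time), and every binned value is assigned to the midpoint of
its acquisition interval. The analysis clock starts at the onset of the
saturated acquisition, so the single rest bin spans 120 s and stimulation
begins at t = 120 s. The physiological rest period is longer than the
acquired rest bin; only the acquired window enters the analysis.

**Concentrations.** Per-metabolite saturation factors are ratios of fully
relaxed to saturated rest areas, computed once at rest and applied to all
bins — saturation depends on T1 and repetition time, not on exercise
phase. Corrected areas are scaled linearly so resting β-ATP equals the
biochemical reference (default 7.22 µmol/g wet wt). The anchoring is
invariant to any uniform rescaling of raw areas.

**pH.** `pH = pK + log10((δ − δ_acid)/(δ_base − δ))` with δ the Pᵢ shift
relative to PCr. The calibration constants (pK 6.75, endpoints 3.27 and
5.69 ppm) are the conventional phosphate-titration values for skeletal
muscle; they are exposed in `PhCalibration` because published calibrations
differ at the second decimal and a lab should substitute its own.

**ADP.** `[ADP] = [ATP]·[Cr] / ([PCr]·K·[H⁺])` with `K = 1.67×10⁹ M⁻¹`
and `[Cr] = TCr − [PCr]`. Contents per g wet weight enter as molarities
through `density_factor` (default 1, i.e. µmol/g ≡ mM and nmol/g ≡ µM);
the factor cancels inside the equilibrium and only matters where nmol/g
meets K_m in µM. The total creatine pool TCr is not measurable by ³¹P-MRS;
it is calibrated from a resting ADP value when one is available
(`calibrate_tcr`, exact algebraic inversion) and otherwise defaults to
`PCr_rest / 0.85`, the textbook resting PCr fraction of total creatine.

## Kinetics and fluxes

Onset and recovery PCr time courses are fitted by Levenberg–Marquardt
(lmfit) to the mono-exponential forms given above, with time re-zeroed at
the phase boundary reconstructed from bin midpoints (bins are contiguous,
so edges follow from the recursion `edge[i+1] = 2·mid[i] − edge[i]`).
Initialisation: resting level from the rest bins, amplitude from the
phase range, k = 1 min⁻¹ (recovery) or 2 min⁻¹ (onset), k bounded in
(0, 20] min⁻¹; tolerances 1e-10 with a retry at solver defaults when the
data cannot support the tight request; no random restarts. A fitted
amplitude of the wrong sign (PCr rising during stimulation) is returned
flagged rather than raised, so that screening large simulated cohorts
does not abort.

`D(t)` defaults to the analytic derivative of the onset fit; centred
finite differences on the binned PCr are available (`d_mode="fd"`) for
sensitivity analysis but are noisy at 60 s bins. "ADP at end of
stimulation" is the final stimulation bin's value, not a plateau average.

**Proton ledger.** Fluxes are positive as proton load into the cytosol.
`H_CK = φ·D` (positive while PCr is consumed), `H_β = −β_total·d(ΔpH)/dt`
(rate form — the level form `−β_total·ΔpH` is a cumulative quantity and
does not balance per-bin rates), `H_Efflux = −λ·ΔpH`, and during
stimulation `H_Ox = m(pH)·Q(t)` per bin (the recovery-onset form
`m·V_PCr_rec` applies only where the oxidative rate has relaxed to the
resynthesis rate). β_total uses per-bin Pᵢ and pH. pH derivatives use
centred differences with one-sided stencils at phase edges. Negative
instantaneous `H_Gly` (possible under noise, and during the early
alkaline transient when CK proton consumption dominates) is floored at
zero for the ATP rate `L = 1.5·H_Gly`, with the raw value retained in the
ledger.

**λ estimation.** `λ = −V_eff/ΔpH` with
`V_eff = (φ + m)·V + β_total·dpH/dt` at the start of recovery. All terms
are discretised at one instant — the midpoint between the first two
recovery bins — with V taken from the recovery fit evaluated there.
Pairing the fit's t = 0 rate with a finite difference centred 60 s later
is dimensionally the same formula but biases λ by more than a factor of
two at 60 s bins; time-consistent evaluation reduces the error to a few
percent (discretisation level).

**Totals.** Flux series are bin values, so window totals are
bin-duration-weighted sums (equivalently, the trapezoid rule on the
piecewise-constant extension over bin edges). Trapezoid over bin
midpoints alone would ignore the first and last half-bins of the
stimulation window, which carry the largest CK flux.

## The forward simulator

`simulate_bout` integrates the same equations forward: ADP from the CK
equilibrium at every step; `Q` from the hyperbola; during stimulation a
demand `U(t)` decaying exponentially from `u_start` to `u_ss` (contractile
demand falls as force fatigues) split by a logistic glycolytic fraction
`g(t)` into `L = g·(U − Q)` and `D = U − Q − L`; `dPCr/dt = −D`, so PCr
rebuilds whenever oxidation exceeds demand, which is what produces the
recovery. The pH trajectory integrates the ledger:
`dpH/dt = −H_β/β_total` with `H_β` defined by exact closure, so the
ground truth satisfies both the ATP balance `D + Q + L = U` and the
proton closure identically at every step. The simulated efflux carries a
constant offset `m(pH_rest)·U_basal` on top of `−λ·ΔpH` so that rest is
an exact fixed point; basal demand is defined as the resting oxidative
rate `Q([ADP]_rest)`, making the resting metabolite state a fixed point
too. Integration is Heun's method (explicit trapezoid) at 1 s steps;
halving the step changes noise-free binned output by well under 0.1%.
Binned series are within-bin means of the fine grid; Gaussian noise is
added per channel after binning (defaults: PCr 1.0, Pᵢ 0.5, ATP 0.2
µmol/g, pH 0.02), and the noisy ADP column is recomputed from the noisy
PCr/ATP/pH exactly as the analysis would. Force is a 3.3 Hz train of
triangular twitches (1 kHz sampling) whose peaks follow the supra-basal
demand envelope. Everything is reproducible from the seed.

Group simulation draws subject-level parameters log-normally (default CV
10%, keeping rates positive) and simulates one bout per subject,
deterministically under a master seed.

### Default and validation conditions

Two frozen configurations are provided.

`SimParams()` mimics the fatiguing in vivo protocol: resting PCr 32
µmol/g, ATP 7.22 µmol/g, pH 7.06, Q_max 26 µmol/g/min, K_m 50 µM; demand
55 → 22 µmol/g/min (τ = 22 s) with the glycolytic fraction ramping
0.05 → 0.95; λ = 12 µmol/g/min per pH unit. This yields ~70% PCr
depletion, end-stimulation ADP ≈ 35 µM, ΔpH ≈ −0.5 and an initial
resynthesis rate near 9 µmol/g/min — the scale of the published group
means.

`SimParams.validation()` is a moderate bout (demand 30 → 8, λ = 60,
~30% depletion, ΔpH under 0.1) in which the assumptions of the
recovery-based capacity estimator hold: resynthesis far above basal
oxidation, negligible pH excursion, end-stimulation ADP below K_m.
Closure, ATP-conservation and Q_max-recovery properties are verified
there; λ and glycolytic-flux recovery are verified on the default bout,
whose larger pH signal conditions them better.

One deliberate departure from the published resting state: the
simulator's total creatine pool (TCr ≈ 32.1 µmol/g) puts resting free ADP
near 0.2 µM rather than the ~9 µM the CK equilibrium gives with a
physiological creatine pool. With K_m = 50 µM, a 9 µM resting ADP implies
a resting oxidative rate of ~15% of Q_max, and the recovery-based
estimator `Q_max = V·(1 + K_m/[ADP]_end)` — which neglects basal
turnover — is then structurally biased low by ~30% on simulated data.
The simulator instead realises the regime the estimator assumes. The
corresponding limitation of the real method is inherited, not hidden: on
the default (deep) bout the recovery is visibly non-mono-exponential
because ADP couples to the slowly recovering pH (ADP ∝ 10^pH at fixed
metabolites), and the fitted V underestimates the true initial
resynthesis rate, biasing Q_max low by roughly 20%. This pH sensitivity
of PCr-recovery capacity estimates is a known property of the method in
acidotic exercise, and is why the validation configuration exists.

### What the simulator does not emulate

Raw FIDs and spectral fitting (the pipeline starts from fitted peak
areas); ATP depletion during stimulation (simulated ATP is constant,
while real stimulated muscle shows a small linear decline); lactate
transport and CO₂/bicarbonate buffering beyond the lumped λ·ΔpH efflux;
fibre-type heterogeneity; blood-flow limitation. Passing the recovery
tests therefore shows the inversion chain is self-consistent at realistic
noise and binning — not that the model captures every feature of real
muscle.

## Statistics

Unpaired two-tailed t-tests default to pooled variance (the classical
"Student" reading), with Welch as an option; a summary-statistics route
(mean, SEM, n per group) uses the closed-form t and is exact when the
summaries come from the samples. The group×time repeated-measures design
is the standard univariate mixed ANOVA (pingouin), with Tukey pairwise
contrasts per time point (statsmodels) when the interaction is
significant at α = 0.05. No correction across endpoints is applied.
Display conventions: integer percent differences, means ± SEM.

## Problem sizes in the test suite

Monte-Carlo checks are sized to be informative yet quick: 20–60 noisy
bouts for parameter-recovery means; 25 replicates × 18 subjects for the
group power check; 1000 replicates for t-test and 500 for ANOVA type-I
calibration; 120 replicates for the ANOVA null-uniformity KS diagnostic.
Monte-Carlo fits of rates ≥ 0.7 min⁻¹ use a 10 s-bin protocol variant
(repetition time 1.25 s, packets of 8), since a 60 s bin cannot resolve
a decay whose time constant is shorter than the bin.

## Known limitations

- The recovery-based Q_max estimator inherits the method's pH sensitivity
  (above); per-bout estimates under deep acidosis are biased low.
- The V = k·ΔPCr product and group-mean arithmetic do not commute: means
  of per-subject products differ from products of group means. The
  pipeline always computes per-subject endpoints first.
- λ is estimated from a single instant at recovery onset; it is exact for
  the model's single-pool efflux but sensitive to the first two recovery
  bins under noise.
- The glycolytic flux is a closure residual: every systematic error in
  D, Q, buffering or efflux lands in L. Its integral is accurate to ~10%
  at 60 s bins on noiseless deep bouts, tightening with finer binning.
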