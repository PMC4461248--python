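# pmrflux

Non-invasive quantification of skeletal-muscle energetics from dynamic
³¹P-MRS and force data.

During electrically stimulated contractions, the phosphorus spectrum of
muscle reports the full energetic state of the tissue: phosphocreatine
(PCr) and inorganic phosphate (Pᵢ) peak areas give absolute metabolite
concentrations once corrected for magnetic saturation and anchored to a
biochemically measured ATP concentration; the Pᵢ–PCr chemical shift gives
intracellular pH; and the creatine-kinase (CK) equilibrium gives free
cytosolic ADP. From the binned time courses of these quantities, `pmrflux`
derives the rates of ATP production of the three pathways that power
contraction, with no biopsy and no tracer:

- **CK flux** — `D = −dPCr/dt`, from a mono-exponential fit of PCr
  depletion at stimulation onset, `PCr(t) = PCr_ss + (PCr_rest − PCr_ss)·e^(−k·t)`;
- **oxidative phosphorylation** — `Q = Q_max / (1 + K_m/[ADP])`, with
  `K_m = 50 µM`; the maximal oxidative capacity comes from the
  post-stimulation recovery, `Q_max = V_PCr_rec · (1 + K_m/[ADP]_end)`,
  where `V_PCr_rec = k_rec · PCr_cons` is the initial PCr resynthesis rate
  of the recovery fit `PCr(t) = PCr_rest − PCr_cons·e^(−k_rec·t)`;
- **glycolysis** — by cytosolic proton bookkeeping,
  `H_Gly = H_CK + H_β + H_Efflux − H_Ox` and `L = 1.5·H_Gly`, using the
  Pᵢ-protonation stoichiometry `φ(pH)`, the buffer capacities
  `β_Pᵢ(Pᵢ, pH)` and `β_tissue = −21·pH + 163` (Slykes), the oxidative
  proton stoichiometry `m(pH)`, and a proton-efflux term `−λ·ΔpH` whose
  constant λ is calibrated at the start of recovery.

Mechanical output is summarised as the tension–time integral of the force
trace, normalised by muscle volume computed from serial MR cross-sections;
total ATP turnover over the stimulation window divided by the force output
gives the ATP cost of contraction. A statistics layer reproduces the usual
two-group reporting (means ± SEM, percent differences, unpaired t-tests,
two-way group×time repeated-measures ANOVA with Tukey contrasts).

Because in vivo datasets of this kind are not publicly deposited, the
package ships a forward simulator (`pmrflux.synthetic_data`) that runs the
same equations forward — CK equilibrium, ADP-controlled oxidation, a
prescribed glycolytic partition, and the proton ledger integrated into a
pH trajectory — then bins the trajectories exactly like the gated MR
acquisition (768 saturated FIDs: 64 at rest, 6×32 during 6 min of
stimulation, 7×32 + 3×64 + 1×96 during 16 min of recovery; 1.875 s
repetition time) and adds per-channel Gaussian noise. Every analysis stage
is verified by parameter recovery and closure against this ground truth.

## Worked example

Simulate a fatiguing bout with known ground truth (Q_max = 26 µmol/g/min,
rest PCr 32 µmol/g, pH 7.06) and run the full analysis:

```python
import json
import pmrflux as pm

sim = pm.simulate_bout(pm.SimParams(seed=42))
res = pm.analyze_bout(sim.series, tti=sim.tti)
print(json.dumps({k: round(v, 3) for k, v in res.endpoints().items()}, indent=2))
```

```json
{
  "k_stim": 0.719,
  "vpcr_stim": 10.053,
  "k_rec": 0.428,
  "vpcr_rec": 10.055,
  "pcr_rest": 32.163,
  "pcr_cons": 23.48,
  "pcr_cons_pct": 68.595,
  "adp_end": 32.483,
  "qmax": 25.531,
  "lambda": 14.269,
  "total_atp": 142.621,
  "atp_cost": 0.765
}
```

Reading the output: PCr fell by ~69% of its resting level over the 6-min
stimulation and recovered with rate constant `k_rec ≈ 0.43 min⁻¹`, an
initial resynthesis rate of ~10 µmol/g/min; with end-stimulation ADP at
~32 µM the recovery operating point puts the maximal oxidative capacity at
~25.5 µmol/g/min (generating value 26 — the remaining gap is the
documented pH-coupling bias of recovery-based capacity estimation, see
`docs/methods.md`). `total_atp` is the integral of `D + Q + L` over the
stimulation window (µmol/g) and `atp_cost` scales it to the tension–time
integral (µmol/g per N·s). The per-bin proton ledger and flux partition
are in `res.fluxes`.

The same pipeline runs from the shell on CSV inputs:

```sh
pmrflux simulate --seed 42 --out bout/
pmrflux fit --series bout/series.csv --phase recovery
pmrflux fluxes --series bout/series.csv --out ledger.csv
```

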