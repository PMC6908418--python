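# cfm-croco

A coarse-grained cell flux model of the unicellular marine diazotroph
*Crocosphaera watsonii*, for researchers studying how nitrogen-fixing
cyanobacteria manage intracellular oxygen over the day-night cycle.

*Crocosphaera* fixes N₂ at night, using carbohydrate stored by daytime
photosynthesis, because nitrogenase is destroyed by O₂. The model couples
four budgets over a repeating 24-h cycle:

- **Carbon** — dC_S/dt = P_I·Chl − λ(1+E) − P_CO₂^N2fix − P_CO₂^RP − Exc:
  photosynthesis fills a starch store C_S that fuels nighttime respiration
  and biosynthesis; the population grows as dX/dt = X·λ/Q_C.
- **Nitrogen** — dN_S/dt = N₂fix − λ·Y_bio^N:C, with fixation kinetics
  N₂fix = A_N2fix · Fe_N · f_N(C_S, N_S, O₂cell): linear in nitrogenase iron,
  saturating in C storage, linearly inhibited by N storage (zero at NS_max)
  and by intracellular O₂ (zero at a critical concentration).
- **Oxygen** — a pseudo-steady diffusion-respiration balance for a spherical
  cell, [O₂]cell = [O₂] − r²γ_net/(3κ_O₂), with an effective envelope
  diffusivity κ_O₂ far below that of seawater (1/6.45×10⁴ of the O₂
  diffusivity in water). At night, respiratory protection — extra
  respiration whose only job is to scrub O₂ — drives [O₂]cell to zero so
  fixation can proceed.
- **Iron** — Fe shuttles daily between photosystems (Fe_P, which sets
  chlorophyll and photosynthesis), a ferritin-like buffer (Fe_B), and
  nitrogenase (Fe_N), with total cellular Fe conserved; dChl/dt tracks the
  photosystem Fe balance through a fixed Chl:Fe ratio.

Temperature acts through an Arrhenius factor f_T(T) = exp(A_T(1/T_ref−1/T))
on fixation, photosynthesis and respiration; light through a saturating
factor f_I(I) = 1 − e^(−A_I·I) − Ω(I) with a photoinhibition hinge Ω.

The package also implements the measurement-side computations used to
confront such models with culture data: PSII electron transfer rates from
FRRf fluorescence (ETR = σ_PSII · n_PSII · Fq′/Fv′ · Φ_RCII · E),
Eilers–Peeters P-vs-E curve fitting (ETR_max, α, E_K), the theoretical
3:1 C₂H₄:N₂ acetylene-reduction conversion, synthetic diel observation
generators, and weighted least-squares calibration of model parameters.

## Worked example

Simulate the two canonical culture treatments (12 h light : 12 h dark,
28 °C, 150 µmol photons m⁻² s⁻¹, aeration at 20 % or 5 % O₂) to their
periodic steady state:

```python
import cfm_croco as cc
from cfm_croco.simulator import run_diel, daily_integrals

for frac in (0.20, 0.05):
    res = run_diel(cc.canonical_forcing(frac), dt=0.01)
    d = daily_integrals(res).iloc[-1]
    print(f"{int(frac*100)}% O2: converged after {res.days_run} days; "
          f"intracellular O2 first zero at {res.first_zero_o2_hour():.2f} h; "
          f"daily N2 fixation {d['n2fix']:.3e} mol N/cell/d; "
          f"daily respiration {d['resp_o2']:.3e} mol O2/cell/d")
```

prints

```
20% O2: converged after 7 days; intracellular O2 first zero at 18.07 h; daily N2 fixation 6.862e-16 mol N/cell/d; daily respiration 8.770e-15 mol O2/cell/d
5% O2: converged after 18 days; intracellular O2 first zero at 12.00 h; daily N2 fixation 6.943e-16 mol N/cell/d; daily respiration 2.200e-15 mol O2/cell/d
```

Read: at 46 µM ambient O₂ (the 5 % treatment) the small diffusive influx is
scrubbed the moment the lights go off, so intracellular O₂ hits zero at
hour 12 and N₂ fixation starts early; at 186 µM (20 %) protection plus the
growing respiratory demand of fixation need until after hour 15 to
eliminate intracellular O₂, fixation is delayed, and dark respiration is
several-fold higher — yet both treatments fix a similar amount of N per
day. The same physics makes the sensitivity scenarios behave as expected:
with no size acclimation the 20 % treatment loses fixation; with no
respiratory protection it cannot fix at all; with the membrane diffusivity
of a non-diazotroph the influx overwhelms respiration at either treatment.

The same runs from the shell:

```sh
cfm-croco simulate --o2-percent 20 --out series.csv --summary summary.json
cfm-croco scan --variable temperature --grid 20:35:1 --out tscan.csv
cfm-croco etr-fit --input frr.csv --out fit.json
```

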