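# Methods

## Model structure

The cell is a sphere of radius *r* carrying five per-cell pools — carbon
storage C_S, nitrogen storage N_S, and iron in photosystems (Fe_P), buffer
(Fe_B) and nitrogenase (Fe_N) — plus chlorophyll slaved to Fe_P and a
population density X. The light and dark halves of the day run different
flux sets: photosynthesis, biomass production and excretion exist only in
the light; N₂ fixation and its respiratory costs, and respiratory
protection, only in the dark. This phase exclusivity is imposed exactly
(the fluxes are set to zero, not merely made small).

Intracellular O₂ is not an integrated state variable. Because it
equilibrates much faster than the other pools, it is computed at every
step from the pseudo-steady diffusion–respiration balance of a sphere:
per-cell diffusive influx 4πrκ(O₂_env − O₂cell) equals net consumption.
Equivalently O₂cell = O₂_env − r²γ_net/(3κ), floored at zero.

### The dark-period O₂/fixation solver

At night three processes are mutually coupled: fixation kinetics respond
to O₂cell; fixation's respiratory energy demand consumes O₂; and
respiratory protection tops respiration up toward the level that zeroes
O₂cell, limited by a capacity R_max·(r/r_ref)³·f_T·C_S/(C_S+K_CS). The
solver resolves the coupling by regimes, in order:

1. **Supply-limited fixation.** If the fixation energy demand at
   O₂cell = 0 already meets or exceeds the diffusive influx, respiration is
   O₂-limited: O₂cell = 0, protection is idle, and fixation runs at
   influx / Y_resp^C:N. This is the usual mid-night state of the low-O₂
   treatment, where the influx is small.
2. **Protection-balanced.** Otherwise, if capacity covers the shortfall,
   O₂cell = 0 with protection throttled to exactly the shortfall.
3. **Capacity-limited.** Otherwise protection runs flat out and O₂cell
   settles at the interior balance point, found by damped fixed-point
   iteration (damping 0.5, initial guess 0, relative tolerance 10⁻⁸,
   ≤100 iterations) with a bisection fallback for slow contraction.

In every regime total respiration equals the diffusive influx at the
returned O₂cell to 10⁻⁸ relative — the balance is an invariant, not an
approximation. The capacity scales with cell volume ((r/r_ref)³) because
respiratory machinery scales with biomass; this is what makes size
acclimation an effective protection strategy: a small cell at high ambient
O₂ faces a larger volumetric O₂ load than its volumetric respiratory
capacity can scrub, and fixation stays blocked.

### Iron schedule

All Fe exchange routes through the buffer. In the light, the buffer
rebuilds the photosystems toward a target early in the day; once C storage
crosses a threshold fraction of its ceiling (there is no benefit to
further photosynthesis with full stores), surplus photosystem Fe above a
retained baseline is returned to the buffer. The activation of this
drawdown ramps linearly over a narrow band (4 % of CS_max) rather than
switching discontinuously: a hard switch chatters against the
photosynthesis shutdown it causes and prevents the trajectory from
settling into a clean periodic orbit under explicit Euler. In the dark the
buffer feeds nitrogenase at a first-order rate until a fixed pre-dawn
clock hour (22 h, i.e. 2 h before lights-on), after which nitrogenase is
dismantled back into the buffer — a circadian trigger, consistent with the
observation that the fixation peak timing is insensitive to the O₂
treatment. The retained photosystem baseline (Fe_P floor) reflects that
photosystems are downgraded, not eliminated, in the afternoon; it also
keeps afternoon photosynthesis responsive to irradiance.

Fe transport amounts (not rates) are capped at the donor pool per step,
and the buffer is closed by difference, so total cellular Fe is conserved
to rounding over arbitrarily long runs.

### Growth and dilution

Division is continuous: X grows by 1 + (λ/Q_C)·dt per step and the C and N
stores are diluted by the inverse factor, so the population totals
X·(Q_C + C_S) and X·(Q_C·Y_bio^N:C + N_S) close exactly against the
integrated fluxes within each Euler step. Fe pools and chlorophyll are not
diluted — total cellular Fe is held constant, with implicit uptake
balancing growth.

## Numerical integration

Explicit forward Euler, default dt = 0.01 h, with the daily grid split at
the light/dark boundary and the nitrogenase-teardown hour so no step
straddles a flux discontinuity. Runs repeat 24-h cycles until the maximum
day-over-day relative change of every per-cell state variable at matched
clock times falls below 10⁻⁴ (population density is excluded — it grows
geometrically by construction). Convergence typically takes 6–20 days;
non-convergence within max_days (default 30) sets a flag in the result
metadata rather than raising. Halving dt changes the canonical daily
integrals by well under 1 %. Daily integrals are trapezoidal sums of the
recorded instantaneous series. Storage drains are flux-limited so pools
cannot be driven negative within a step; biomass production is likewise
limited to the stores it draws on.

## Parameters

Rate constants, yields and thresholds are calibration values: they were
set once so that the canonical culture conditions (12L:12D square light at
150 µmol photons m⁻² s⁻¹, 28 °C, 20 % and 5 % O₂ aeration at 186 and
46 µM) reproduce the observed phenomenology — dark O₂ elimination before
14 h at 5 % and after 15 h at 20 %, similar daily N₂ fixation across
treatments with a delayed onset at 20 %, daily photosynthesis maximal near
700 µmol photons m⁻² s⁻¹, N₂ fixation saturating near 100, and the loss of
fixation when size acclimation, respiratory protection or diffusion
management is disabled — and were not revisited afterwards.

| parameter | value | units | meaning |
|---|---|---|---|
| A_T | 8000 | K | Arrhenius slope (Q₁₀ ≈ 2.4 at 28 °C) |
| T_ref | 301.15 | K | reference temperature (28 °C) |
| A_I | 0.004 | (µmol m⁻² s⁻¹)⁻¹ | light absorption/processing factor |
| I₀, s | 700, 5×10⁻⁴ | µmol m⁻² s⁻¹, per unit | photoinhibition hinge and slope |
| D_ref | 2.3×10⁻⁹ | m² s⁻¹ | O₂ diffusivity in water at 28 °C |
| membrane factor | 1/(6.45×10⁴) | – | envelope diffusivity fraction |
| A_N2fix | 80 | mol N (mol Fe)⁻¹ h⁻¹ | fixation rate constant |
| K_CS | 2×10⁻¹⁶ | mol C cell⁻¹ | C-storage half-saturation |
| NS_max | 1.2×10⁻¹⁴ | mol N cell⁻¹ | N-storage ceiling |
| O₂_cri | 0.08 | mol m⁻³ | critical intracellular O₂ (80 µM) |
| CS_max | 3×10⁻¹⁴ | mol C cell⁻¹ | C-storage ceiling |
| P_max^Chl | 45 | mol C (mol Chl)⁻¹ h⁻¹ | photosynthesis per chlorophyll |
| λ_max | 1.2×10⁻¹⁵ | mol C cell⁻¹ h⁻¹ | biomass production ceiling |
| K_NS | 3×10⁻¹⁶ | mol N cell⁻¹ | N half-saturation for growth |
| E | 0.1 | – | biosynthetic CO₂ overhead |
| Q_C | 6×10⁻¹⁴ | mol C cell⁻¹ | baseline biomass C quota |
| Y_bio^N:C | 0.16 | mol N (mol C)⁻¹ | N:C of produced biomass |
| Y_resp^C:N | 2.0 | mol C (mol N)⁻¹ | respiratory C per N fixed |
| R_max | 6×10⁻¹⁶ | mol O₂ cell⁻¹ h⁻¹ | protection capacity at r_ref = 2.5 µm |
| Fe_total | 2×10⁻¹⁸ | mol Fe cell⁻¹ | conserved cellular iron |
| k_BP, k_PB, k_BN, k_NB | 1.2, 1.5, 0.2, 0.6 | h⁻¹ | Fe translocation rates |
| Fe_P target / floor | 1.4, 0.5 ×10⁻¹⁸ | mol Fe cell⁻¹ | photosystem build/retain levels |
| CS threshold | 0.35 | of CS_max | afternoon drawdown trigger |
| t_NB | 22 | h | nitrogenase teardown hour |
| Y_Chl:Fe | 100 | mol Chl (mol Fe)⁻¹ | chlorophyll per photosystem Fe |
| r at 46 / 186 µM | 2.0 / 2.5 | µm | size-acclimation anchors |

Respiratory and photosynthetic quotients are fixed at 1 mol O₂ : 1 mol C,
so O₂ fluxes equal the corresponding C fluxes numerically. The two
canonical treatment concentrations are pinned (0.20 → 186 µM, 0.05 →
46 µM at 28 °C, S = 35); away from them the treatment conversion scales a
Garcia–Gordon air-saturation fit linearly in the gas fraction. Walden's
rule with a Vogel-type pure-water viscosity correlation gives the
temperature dependence of diffusivity (≈ +2.5 %/K).

## Synthetic observations and calibration

The fixture generator runs the model itself at stated "truth" parameters
for both canonical treatments, samples the five observable channels
(photosynthetic and respiratory O₂ flux, N₂ fixation, C and N per cell) at
1-h resolution, and adds seeded Gaussian noise with a default relative
standard deviation of 10 %, the scale of replicate scatter in published
diel culture series. It emulates the mean diel cycle only: no
autocorrelated instrument drift, no cell-cycle heterogeneity, no gas
exchange dynamics of the incubation vessel. Passing recovery tests on
these fixtures therefore demonstrates identifiability of the targeted
parameters under the model's own dynamics, not robustness to structural
mismatch with real cultures.

Calibration minimizes the sd-weighted sum of squared residuals over all
channels and treatments with Nelder–Mead in log-parameter space (all
tunables are positive, rate-like quantities); noiseless channels fall back
to a 1 %-of-scale weight. Ethylene-based fixation measurements convert
with the theoretical factor of 3 mol C₂H₄ per mol N₂. ETR is linear in
σ_PSII, n_PSII, Φ_RCII and E; since the absolute units of σ_PSII·n_PSII
vary by instrument convention, ETR is treated in consistent relative units
and only curve-shape parameters (ETR_max, α, E_K = ETR_max/α) are
interpreted. The Eilers–Peeters fit uses multistart Levenberg–Marquardt on
log(a, b, c) of ETR(E) = E/(aE² + bE + c).

## Design choices in open territory

- **Ω(I)** is a hinge: zero to 700 µmol m⁻² s⁻¹, linear above, with slope
  above the saturation derivative at the hinge so the light factor peaks
  exactly at the onset. Simplest shape with Ω(0) = 0 and a high-light
  decline.
- **f_N factor shapes**: Michaelis–Menten in C_S, linear decline in N_S
  (zero at NS_max), linear decline in O₂cell (zero at O₂_cri).
- **Biomass production** λ = λ_max·f_T·MM(C_S)·MM(N_S), zero in the dark;
  it carries the respiration temperature mask, being respiration-powered.
- **Excretion** is overflow only: photosynthate that cannot enter a full C
  store. With the linear storage shutdown of photosynthesis it activates
  only at the ceiling itself.
- **Initial condition** (dawn, all Fe in buffer, half-full stores) is
  erased by convergence to the periodic orbit; the periodicity check
  verifies this.
- Light-period intracellular O₂ is reported as the pseudo-steady value
  capped at ambient (supersaturation from net photosynthesis is vented,
  not tracked); nighttime photosynthetic O₂ production is exactly zero.

## Known limitations

- The temperature response of daily N₂ fixation rises steeply through the
  mid-twenties — below ~25 °C the Arrhenius-damped respiratory capacity
  cannot pull intracellular O₂ below the critical level against a
  saturating ambient concentration, and fixation is essentially blocked,
  matching the organism's warm-water niche — but it saturates rather than
  declines toward 35 °C. With a monotone Arrhenius factor on all three
  metabolisms and dark respiration balanced against the diffusive O₂
  influx, every nighttime constraint on fixation (kinetics, elimination
  onset, C budget, N-storage room) is non-decreasing in temperature over
  20–35 °C, so the model cannot reproduce a fixation *optimum* near 30 °C
  without an explicit high-temperature deactivation term, which the
  present temperature factor deliberately omits.
- Ambient O₂ is constant within a run; diel fluctuation of dissolved O₂
  (~10 µM in the field) is not modeled.
- A single effective envelope diffusivity folds the molecular boundary
  layer and the membrane layers into one coefficient; no series-resistance
  decomposition, no spatially resolved intracellular gradients, and no
  explicit starch-granule or EPS barrier geometry.
- Division is continuous dilution; there is no cell-cycle or
  size-structure within the population, and no Fe uptake kinetics from
  seawater (total cellular Fe is fixed).
- The fixation window's pre-dawn end is a fixed clock hour; the model
  cannot test hypotheses about what entrains the teardown.
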