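"""Intracellular O2 balance of a spherical cell.

The cell exchanges O2 with the environment by diffusion through its boundary
layer and membrane layers, folded into one effective diffusivity.  At pseudo-
steady state the intracellular concentration obeys

    O2cell = O2_env - r^2 gamma_net / (3 kappa)

with gamma_net the net volumetric consumption.  Equivalently, the per-cell
diffusive influx at a given intracellular concentration is

    V_O2 = 4 pi r kappa (O2_env - O2cell)

(the steady diffusion flux to a sphere), so the consumption that drives the
interior to exactly zero is 4 pi r kappa O2_env per cell.

The dark-period solver couples three processes: N2-fixation kinetics (which
respond to intracellular O2), the respiratory energy demand of fixation, and
respiratory protection (extra respiration whose only role is to scrub O2),
limited by a temperature- and C-storage-dependent capacity.  Respiration can
never consume more O2 than diffusion supplies; when the fixation energy
demand alone would exceed the influx, fixation is throttled to the supply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

from .environment import water_o2_diffusivity, temperature_factor
from .metabolism import n2_fixation_rate

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import Parameters
    from .metabolism import CellState
    from .environment import Forcing

__all__ = [
    "DiffusivityParams",
    "O2State",
    "effective_diffusivity",
    "intracellular_o2",
    "critical_volumetric_respiration",
    "cell_o2_conductance",
    "solve_dark_o2_state",
    "DEFAULT_MEMBRANE_FACTOR",
    "HIGH_DIFFUSIVITY_MEMBRANE_FACTOR",
]

# Effective membrane-layer diffusivity as a fraction of the diffusivity of
# O2 in water: the default is the value required to reproduce the culture
# observations; the high-diffusivity alternative is the cell-wall
# permeability inferred for Azotobacter vinelandii.
DEFAULT_MEMBRANE_FACTOR = 1.0 / 6.45e4
HIGH_DIFFUSIVITY_MEMBRANE_FACTOR = 1.0 / 1.27e3

SECONDS_PER_HOUR = 3600.0


@dataclass
class DiffusivityParams:
    """Effective O2 diffusivity of the cell envelope.

    ``D_ref`` is the diffusivity of O2 in water at ``T_ref``;
    ``membrane_factor`` scales it down to the effective envelope value.
    """

    D_ref: float = 2.3e-9  # m2 s-1 at T_ref
    T_ref: float = 301.15  # K
    membrane_factor: float = DEFAULT_MEMBRANE_FACTOR

    def __post_init__(self) -> None:
        if self.D_ref <= 0:
            raise ValueError("D_ref must be > 0")
        if not 0.0 < self.membrane_factor <= 1.0:
            raise ValueError("membrane_factor must be in (0, 1]")


@dataclass
class O2State:
    """Solved pseudo-steady O2 balance for one instant."""

    o2cell: float  # mol O2 m-3
    n2fix: float  # mol N cell-1 h-1
    rp: float  # respiratory-protection O2 flux, mol O2 cell-1 h-1
    resp_n2fix: float  # O2 for N2-fixation energy, mol O2 cell-1 h-1
    resp_total: float  # mol O2 cell-1 h-1
    v_o2: float  # diffusive O2 influx, mol O2 cell-1 h-1
    residual: float  # |respiration - influx| / scale at the solution
    iterations: int


def effective_diffusivity(T: float, p: DiffusivityParams) -> float:
    """Effective envelope O2 diffusivity (m2 s-1) at temperature T."""
    return water_o2_diffusivity(T, p.D_ref, p.T_ref) * p.membrane_factor


def intracellular_o2(o2_env: float, r: float, gamma_net: float, kappa: float) -> float:
    """Pseudo-steady intracellular O2 (mol m-3), floored at zero.

    ``gamma_net`` is the net volumetric consumption (mol O2 m-3 s-1).
    """
    if r <= 0 or kappa <= 0:
        raise ValueError("r and kappa must be positive")
    if min(o2_env, gamma_net) < 0:
        raise ValueError("o2_env and gamma_net must be >= 0")
    return max(0.0, o2_env - r * r * gamma_net / (3.0 * kappa))


def critical_volumetric_respiration(o2_env: float, r: float, kappa: float) -> float:
    """Volumetric consumption (mol O2 m-3 s-1) that drives O2cell to zero."""
    if r <= 0 or kappa <= 0:
        raise ValueError("r and kappa must be positive")
    if o2_env < 0:
        raise ValueError("o2_env must be >= 0")
    return 3.0 * kappa * o2_env / (r * r)


def cell_o2_conductance(r: float, kappa: float) -> float:
    """Per-cell diffusive conductance (mol O2 h-1 per mol O2 m-3).

    Influx = conductance * (O2_env - O2cell); equals the critical volumetric
    rate times the cell volume when O2cell = 0.
    """
    return 4.0 * math.pi * r * kappa * SECONDS_PER_HOUR


def _respiratory_protection_capacity(c_s: float, r: float, T: float,
                                     p: "Parameters") -> float:
    """Capacity of protective respiration (mol O2 cell-1 h-1).

    Michaelis-Menten in C storage, optionally temperature-scaled with the
    respiration mask, and proportional to cell volume (respiratory machinery
    scales with biomass): small cells face a larger volumetric O2 load for
    the same capacity, which is why size acclimation matters.
    """
    m = p.metabolism
    if c_s <= 0.0 or not m.respiratory_protection:
        return 0.0
    ft = temperature_factor(T, p.temp_light) if m.temp_on_resp else 1.0
    size = (r / m.r_ref) ** 3
    return m.R_max * size * ft * c_s / (c_s + m.K_CS)


def solve_dark_o2_state(state: "CellState", f: "Forcing", p: "Parameters",
                        tol: float = 1e-8, max_iter: int = 100) -> O2State:
    """Self-consistent dark-period O2 state, fixation rate and respiration.

    Resolution order:

    1. If the fixation energy demand at O2cell = 0 alone meets or exceeds the
       diffusive influx, fixation is O2-supply-limited: O2cell = 0, no
       respiratory protection, and N2 fixation runs at influx / Y_resp_CN.
    2. Otherwise, if the protective capacity covers the shortfall, O2cell = 0
       with protection throttled to exactly the shortfall.
    3. Otherwise protection runs at capacity and O2cell settles at the
       interior balance point, found by damped fixed-point iteration
       (damping 0.5, initial guess O2cell = 0).

    In every case total respiration equals the diffusive influx at the
    returned O2cell.
    """
    m = p.metabolism
    kappa = effective_diffusivity(f.temperature, p.diffusivity)
    cond = cell_o2_conductance(state.r, kappa)
    influx_at_zero = cond * f.ambient_o2
    cap = _respiratory_protection_capacity(state.c_s, state.r, f.temperature, p)

    def kinetic(o2: float) -> float:
        return n2_fixation_rate(state.fe_n, state.c_s, state.n_s, o2,
                                f.temperature, m, p.temp_light)

    demand_at_zero = m.Y_resp_CN * kinetic(0.0)

    if demand_at_zero >= influx_at_zero:
        # supply-limited fixation: all influx goes to fixation energy
        n2fix = influx_at_zero / m.Y_resp_CN
        return O2State(o2cell=0.0, n2fix=n2fix, rp=0.0,
                       resp_n2fix=influx_at_zero, resp_total=influx_at_zero,
                       v_o2=influx_at_zero, residual=0.0, iterations=0)

    shortfall = influx_at_zero - demand_at_zero
    if cap >= shortfall:
        # protection closes the balance at O2cell = 0
        return O2State(o2cell=0.0, n2fix=kinetic(0.0), rp=shortfall,
                       resp_n2fix=demand_at_zero, resp_total=influx_at_zero,
                       v_o2=influx_at_zero, residual=0.0, iterations=0)

    # capacity-limited: O2cell > 0 where influx balances demand + capacity
    scale = max(influx_at_zero, cap, 1e-300)
    o2 = 0.0
    its = 0
    for its in range(1, max_iter + 1):
        total = m.Y_resp_CN * kinetic(o2) + cap
        o2_new = max(0.0, f.ambient_o2 - total / cond)
        if abs(o2_new - o2) <= tol * max(f.ambient_o2, 1e-300):
            o2 = o2_new
            break
        o2 = 0.5 * o2 + 0.5 * o2_new  # damped update of a monotone map
    else:
        # slow contraction: fall back to bisection on the balance residual,
        # which brackets the interior root by construction
        lo, hi = 0.0, f.ambient_o2
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            total = m.Y_resp_CN * kinetic(mid) + cap
            bal = f.ambient_o2 - total / cond - mid
            if bal > 0.0:
                lo = mid
            else:
                hi = mid
        o2 = 0.5 * (lo + hi)
    n2fix = kinetic(o2)
    resp_n2fix = m.Y_resp_CN * n2fix
    total = resp_n2fix + cap
    influx = cond * (f.ambient_o2 - o2)
    residual = abs(total - influx) / scale
    return O2State(o2cell=o2, n2fix=n2fix, rp=cap, resp_n2fix=resp_n2fix,
                   resp_total=total, v_o2=influx, residual=residual,
                   iterations=its)
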