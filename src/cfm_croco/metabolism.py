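"""Carbon and nitrogen fluxes of the cell quota model.

Per-cell pools (C storage, N storage, the three Fe pools, chlorophyll) and
the instantaneous fluxes acting on them: photosynthesis, biomass production
and continuous division, N2 fixation kinetics, respiration components,
overflow excretion, and the cell-size acclimation to ambient O2.

All per-cell pools are mol cell-1 and rates mol cell-1 h-1.  N2 fixation is
proportional to the nitrogenase Fe pool and throttled by C storage
(Michaelis-Menten), N storage (linear inhibition, zero at the storage
ceiling) and intracellular O2 (linear inhibition, zero at the critical
concentration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .environment import TempLightParams, temperature_factor

__all__ = [
    "CellState",
    "MetabolicParams",
    "CellSizeParams",
    "n2_fixation_rate",
    "photosynthesis_rate",
    "biomass_production_rate",
    "respiration_fluxes",
    "excretion_rate",
    "growth_and_dilution",
    "cell_radius_for_o2",
]


@dataclass
class CellState:
    """Per-cell pools plus population density and diagnostics.

    ``o2cell`` is a diagnostic of the pseudo-steady intracellular O2 balance,
    not an integrated pool.
    """

    c_s: float  # C storage, mol C cell-1
    n_s: float  # N storage, mol N cell-1
    fe_p: float  # Fe in photosystems, mol Fe cell-1
    fe_b: float  # Fe in the buffer, mol Fe cell-1
    fe_n: float  # Fe in nitrogenase, mol Fe cell-1
    chl: float  # chlorophyll, mol Chl cell-1
    x: float  # population density, cells m-3
    r: float  # cell radius, m
    o2cell: float = 0.0  # mol O2 m-3

    @property
    def fe_total(self) -> float:
        return self.fe_p + self.fe_b + self.fe_n

    @property
    def volume(self) -> float:
        """Cell volume (m3) of the equivalent sphere."""
        return 4.0 / 3.0 * math.pi * self.r**3

    def copy(self) -> "CellState":
        return replace(self)


@dataclass
class MetabolicParams:
    """Rate constants, yields and thresholds of the C/N metabolism.

    ``temp_mask`` selects which of {N2 fixation, photosynthesis, respiration}
    carry the Arrhenius temperature factor; all three by default.  The
    respiratory quotient is 1 mol O2 : 1 mol CO2 and the photosynthetic
    quotient 1 mol O2 : 1 mol C, so O2 fluxes equal the corresponding C
    fluxes numerically.
    """

    A_N2fix: float = 80.0  # mol N (mol Fe)-1 h-1
    K_CS: float = 2.0e-16  # mol C cell-1, C-storage half-saturation
    NSmax: float = 1.2e-14  # mol N cell-1, N storage ceiling
    O2cri: float = 0.08  # mol O2 m-3, critical intracellular O2
    CSmax: float = 3.0e-14  # mol C cell-1, C storage ceiling
    P_max_chl: float = 45.0  # mol C (mol Chl)-1 h-1
    lambda_max: float = 1.2e-15  # mol C cell-1 h-1
    K_NS: float = 3.0e-16  # mol N cell-1, N-storage half-saturation for growth
    E: float = 0.1  # biosynthesis CO2 overhead, dimensionless
    Q_C: float = 6.0e-14  # baseline biomass C quota, mol C cell-1
    Y_bio_NC: float = 0.16  # mol N (mol C)-1 of produced biomass
    Y_resp_CN: float = 2.0  # mol C respired per mol N fixed
    R_max: float = 6.0e-16  # mol O2 cell-1 h-1, protection capacity at r_ref
    r_ref: float = 2.5e-6  # m, radius at which R_max is defined (scales ~volume)
    respiratory_protection: bool = True  # scenario switch: protective respiration
    temp_on_n2fix: bool = True
    temp_on_photo: bool = True
    temp_on_resp: bool = True

    def __post_init__(self) -> None:
        for name in ("A_N2fix", "K_CS", "NSmax", "O2cri", "CSmax", "P_max_chl",
                     "lambda_max", "K_NS", "Q_C", "Y_bio_NC", "Y_resp_CN", "R_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.E < 0:
            raise ValueError("E must be >= 0")


@dataclass
class CellSizeParams:
    """Anchors of the piecewise-linear radius acclimation to ambient O2."""

    o2_low: float = 0.046  # mol m-3
    r_low: float = 2.0e-6  # m, radius at the low-O2 anchor
    o2_high: float = 0.186  # mol m-3
    r_high: float = 2.5e-6  # m, radius at the high-O2 anchor
    fixed: bool = False  # no-size-change scenario: always the low anchor

    def __post_init__(self) -> None:
        if self.r_high < self.r_low:
            raise ValueError("radius must be non-decreasing in ambient O2")
        if self.o2_high <= self.o2_low:
            raise ValueError("anchor O2 values must be increasing")


def _ft(T: float, tl: TempLightParams, active: bool) -> float:
    return temperature_factor(T, tl) if active else 1.0


def n2_fixation_rate(fe_n: float, c_s: float, n_s: float, o2cell: float,
                     T: float, p: MetabolicParams, tl: TempLightParams) -> float:
    """N2 fixation rate (mol N cell-1 h-1).

    Linear in nitrogenase Fe; multiplied by a Michaelis-Menten C-storage
    factor, a linear N-storage inhibition vanishing at ``NSmax``, a linear
    O2 inhibition vanishing at the critical concentration ``O2cri``, and
    optionally the temperature factor.
    """
    if fe_n <= 0.0:
        return 0.0
    f_cs = min(1.0, c_s / (c_s + p.K_CS)) if c_s > 0 else 0.0
    f_ns = max(0.0, 1.0 - n_s / p.NSmax)
    f_o2 = max(0.0, 1.0 - o2cell / p.O2cri)
    ft = _ft(T, tl, p.temp_on_n2fix)
    return p.A_N2fix * ft * fe_n * f_cs * f_ns * f_o2


def photosynthesis_rate(chl: float, I: float, T: float, c_s: float,
                        p: MetabolicParams, tl: TempLightParams) -> float:
    """Gross photosynthesis (mol C cell-1 h-1); also the O2 production rate.

    Proportional to chlorophyll (itself slaved to photosystem Fe), shaped by
    the light factor, optionally the temperature factor, and shut down
    linearly as C storage fills.
    """
    if chl <= 0.0 or I <= 0.0:
        return 0.0
    from .environment import light_factor  # local to avoid a wide import surface
    f_store = max(0.0, 1.0 - c_s / p.CSmax)
    return p.P_max_chl * light_factor(I, tl) * _ft(T, tl, p.temp_on_photo) * chl * f_store


def biomass_production_rate(c_s: float, n_s: float, T: float, phase: str,
                            p: MetabolicParams, tl: TempLightParams) -> float:
    """Biomass production rate lambda (mol C cell-1 h-1); zero in the dark.

    Michaelis-Menten in both stores: production needs C for skeletons and
    respiration and N from storage.  Carries the respiration temperature
    mask since biosynthesis is respiration-powered.
    """
    if phase == "dark":
        return 0.0
    if phase != "light":
        raise ValueError(f"unknown phase {phase!r}")
    if c_s <= 0.0 or n_s <= 0.0:
        return 0.0
    f_cs = c_s / (c_s + p.K_CS)
    f_ns = n_s / (n_s + p.K_NS)
    return p.lambda_max * _ft(T, tl, p.temp_on_resp) * f_cs * f_ns


def respiration_fluxes(lam: float, n2fix: float, rp: float,
                       p: MetabolicParams) -> tuple[float, float, float, float]:
    """Respiratory C and O2 fluxes.

    Returns ``(biosynthetic CO2, CO2 for N2 fixation, CO2 for respiratory
    protection, total O2 consumption)``, all mol cell-1 h-1.  The
    N2-fixation term covers both electron donation and respiratory ATP;
    the respiratory-protection term is passed through from the O2 balance.
    A 1:1 respiratory quotient makes total O2 equal total CO2.
    """
    if min(lam, n2fix, rp) < 0:
        raise ValueError("rates must be >= 0")
    co2_bio = p.E * lam
    co2_n2fix = p.Y_resp_CN * n2fix
    co2_rp = rp
    return co2_bio, co2_n2fix, co2_rp, co2_bio + co2_n2fix + co2_rp


def excretion_rate(photo: float, c_s: float, p: MetabolicParams) -> float:
    """Overflow C excretion (mol C cell-1 h-1).

    Gross photosynthesis that cannot enter a full C store is excreted; zero
    while the store is below capacity.  With the linear storage shutdown of
    photosynthesis this only activates at the ceiling itself.
    """
    if photo <= 0.0 or c_s < p.CSmax:
        return 0.0
    return photo


def growth_and_dilution(state: CellState, lam: float, dt: float,
                        p: MetabolicParams) -> CellState:
    """Apply continuous division over ``dt`` hours at production rate ``lam``.

    Population grows by the factor 1 + (lambda/Q_C) dt; the per-cell C and N
    stores are diluted by the inverse factor so the population totals X*C_S
    and X*N_S are conserved by the division step itself.  Fe pools and
    chlorophyll are not diluted: total cellular Fe is held constant, with
    implicit uptake balancing growth.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    g = 1.0 + (lam / p.Q_C) * dt
    out = state.copy()
    out.x = state.x * g
    out.c_s = state.c_s / g
    out.n_s = state.n_s / g
    return out


def cell_radius_for_o2(o2_env: float, sp: CellSizeParams) -> float:
    """Acclimated cell radius (m) for an ambient O2 concentration.

    Piecewise-linear between the two configured anchors and clamped outside;
    larger cells at higher O2 reduce the surface-to-volume ratio and hence
    the volumetric O2 load.  With ``fixed`` set the low anchor is returned
    for every input (the no-size-change scenario).
    """
    if o2_env < 0:
        raise ValueError("o2_env must be >= 0")
    if sp.fixed or o2_env <= sp.o2_low:
        return sp.r_low
    if o2_env >= sp.o2_high:
        return sp.r_high
    w = (o2_env - sp.o2_low) / (sp.o2_high - sp.o2_low)
    return sp.r_low + w * (sp.r_high - sp.r_low)
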