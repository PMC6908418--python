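"""Diel iron translocation between photosystems, buffer and nitrogenase.

All exchange is routed through an intracellular buffer (ferritin-like
storage): photosystem Fe and nitrogenase Fe never trade directly.  Total
cellular Fe is conserved exactly.  Chlorophyll is slaved to photosystem Fe
through a fixed Chl:Fe ratio, so the chlorophyll balance mirrors the
photosystem Fe balance.

Phase rules (lights-on at 0 h):

* light: no buffer-to-nitrogenase flux; any residual nitrogenase Fe is torn
  down (first order).  The buffer feeds the photosystems until a target is
  reached, and once C storage crosses a configured fraction of its ceiling
  the photosystems are drawn back down into the buffer (no further benefit
  to photosynthesis once the C store is nearly full).
* dark: no buffer-to-photosystem flux.  The buffer feeds nitrogenase until a
  fixed clock hour late in the night, after which buffer-to-nitrogenase
  stops and nitrogenase is dismantled back into the buffer (circadian
  pre-dawn teardown).
"""

from __future__ import annotations

from dataclasses import dataclass

from .metabolism import CellState, MetabolicParams

__all__ = ["IronSchedule", "IronFluxes", "iron_fluxes", "update_iron_and_chl"]


@dataclass
class IronSchedule:
    """Rate constants and triggers of the Fe translocation schedule."""

    k_BP: float = 1.2  # buffer -> photosystems, h-1
    k_PB: float = 1.5  # photosystems -> buffer, h-1
    k_BN: float = 0.2  # buffer -> nitrogenase, h-1 (slow nightly ramp-up)
    k_NB: float = 0.6  # nitrogenase -> buffer, h-1
    FeP_target: float = 1.4e-18  # mol Fe cell-1, light-phase photosystem ceiling
    FeP_floor: float = 5.0e-19  # mol Fe cell-1 retained in photosystems by drawdown
    CS_drawdown_threshold: float = 0.35  # fraction of CSmax triggering drawdown
    switch_width: float = 0.04  # fractional width of the drawdown ramp
    t_NB_start: float = 22.0  # clock hour of nitrogenase teardown
    Y_Chl_Fe: float = 100.0  # mol Chl per mol photosystem Fe

    def __post_init__(self) -> None:
        for name in ("k_BP", "k_PB", "k_BN", "k_NB"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.CS_drawdown_threshold <= 1.0:
            raise ValueError("CS_drawdown_threshold must be in (0, 1]")
        if not 12.0 <= self.t_NB_start < 24.0:
            raise ValueError("t_NB_start must lie in the dark period [12, 24)")


@dataclass
class IronFluxes:
    """Instantaneous translocation fluxes, mol Fe cell-1 h-1."""

    f_bp: float  # buffer -> photosystems
    f_pb: float  # photosystems -> buffer
    f_bn: float  # buffer -> nitrogenase
    f_nb: float  # nitrogenase -> buffer


def iron_fluxes(t: float, phase: str, state: CellState, sched: IronSchedule,
                mp: MetabolicParams) -> IronFluxes:
    """Phase-appropriate Fe translocation fluxes at clock hour ``t``."""
    if phase == "light":
        f_nb = sched.k_NB * state.fe_n  # residual nitrogenase teardown
        cs_frac = state.c_s / mp.CSmax
        # drawdown activation ramps linearly over a narrow band around the
        # C-storage threshold (a smooth switch integrates cleanly; a hard
        # one chatters against the photosynthesis shutdown it causes)
        w = sched.switch_width
        s = min(1.0, max(0.0, (cs_frac - (sched.CS_drawdown_threshold - w)) / w))
        # drawdown dismantles surplus light-harvesting capacity but retains a
        # baseline photosystem stock (photosystems are never fully degraded)
        f_pb = s * sched.k_PB * max(0.0, state.fe_p - sched.FeP_floor)
        room = min(1.0, max(0.0, (sched.FeP_target - state.fe_p)
                            / (0.05 * sched.FeP_target)))
        f_bp = (1.0 - s) * sched.k_BP * state.fe_b * room
        return IronFluxes(f_bp, f_pb, 0.0, f_nb)
    if phase == "dark":
        if t % 24.0 < sched.t_NB_start:
            return IronFluxes(0.0, 0.0, sched.k_BN * state.fe_b, 0.0)
        return IronFluxes(0.0, 0.0, 0.0, sched.k_NB * state.fe_n)
    raise ValueError(f"unknown phase {phase!r}")


def update_iron_and_chl(state: CellState, fx: IronFluxes, dt: float,
                        sched: IronSchedule) -> CellState:
    """Advance the Fe pools and chlorophyll one Euler step of ``dt`` hours.

    Fluxes are limited so no pool is driven negative within the step; the
    donor-pool cap preserves exact conservation.  Chlorophyll follows the net
    photosystem flux scaled by the Chl:Fe ratio and is floored at zero.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    # cap transported amounts (not rates) at the donor pool so subtraction
    # is exact in floating point
    d_bp = min(fx.f_bp * dt, state.fe_b)
    d_bn = min(fx.f_bn * dt, state.fe_b - d_bp)
    d_pb = min(fx.f_pb * dt, state.fe_p)
    d_nb = min(fx.f_nb * dt, state.fe_n)

    total = state.fe_p + state.fe_b + state.fe_n
    out = state.copy()
    out.fe_p = (state.fe_p - d_pb) + d_bp
    out.fe_n = (state.fe_n - d_nb) + d_bn
    # buffer by difference: total Fe is conserved exactly, not just to
    # rounding of three independent updates
    out.fe_b = total - out.fe_p - out.fe_n
    out.chl = max(0.0, state.chl + (d_bp - d_pb) * sched.Y_Chl_Fe)
    if min(out.fe_p, out.fe_b, out.fe_n) < -8e-16 * max(total, 1e-300):
        raise ArithmeticError("Fe pool went negative despite flux limiting")
    out.fe_b = max(0.0, out.fe_b)  # absorb sub-ulp rounding of the difference
    return out
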