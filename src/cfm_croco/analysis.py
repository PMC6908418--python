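"""Measurement-side computations and calibration utilities.

Covers the laboratory workflow around the cell flux model: photosystem II
electron transfer rates (ETR) from fast-repetition-rate fluorometry (FRRf)
quantities, Eilers-Peeters photosynthesis-versus-irradiance fits, the
acetylene-reduction conversion to N2 fixation, synthetic observation
generators for testing, and weighted least-squares calibration of model
parameters against diel observations.

ETR convention: sigma_PSII and n_PSII are taken in whatever consistent units
the instrument pipeline provides; ETR is reported in the corresponding
relative units (linear in each input), which is sufficient for P-vs-E curve
shape parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .parameters import Parameters
from .simulator import canonical_forcing, daily_integrals, run_diel

__all__ = [
    "FRRSample",
    "PvsEFit",
    "DielObservationSet",
    "etr",
    "fit_eilers_peeters",
    "eilers_peeters_curve",
    "acetylene_to_n2",
    "generate_pve_points",
    "generate_diel_observations",
    "calibrate",
    "CALIBRATION_TUNABLES",
]


@dataclass
class FRRSample:
    """FRRf-derived quantities at one actinic light level."""

    E: float  # actinic irradiance, umol photons m-2 s-1
    sigma_psii: float  # effective PSII absorption cross-section
    f_prime: float  # operational fluorescence
    fm_prime: float  # maximum fluorescence in the light
    fo_prime: float  # minimum fluorescence in the light
    n_psii: float = 0.002  # functional RCII per total chlorophyll a
    phi_rcii: float = 1.0  # mol e- (mol photons)-1 within RCII

    def __post_init__(self) -> None:
        if not self.fo_prime <= self.f_prime <= self.fm_prime:
            raise ValueError("fluorescence must satisfy Fo' <= F' <= Fm'")
        if self.E < 0:
            raise ValueError("E must be >= 0")
        if not 0.0 < self.phi_rcii <= 1.0:
            raise ValueError("phi_rcii must be in (0, 1]")


@dataclass
class PvsEFit:
    """Eilers-Peeters fit summary: ETR(E) = E / (a E^2 + b E + c)."""

    a: float
    b: float
    c: float
    etr_max: float
    alpha: float  # initial slope
    e_k: float  # light saturation parameter, ETR_max / alpha
    residual_sse: float


def etr(s: FRRSample) -> float:
    """Electron transfer rate through PSII.

    ETR = sigma_PSII * n_PSII * (Fq'/Fv') * Phi_RCII * E with
    Fq' = Fm' - F' and Fv' = Fm' - Fo'.
    """
    fv = s.fm_prime - s.fo_prime
    if fv <= 0:
        raise ZeroDivisionError("Fv' = Fm' - Fo' must be positive")
    fq = s.fm_prime - s.f_prime
    return s.sigma_psii * s.n_psii * (fq / fv) * s.phi_rcii * s.E


def eilers_peeters_curve(E, a: float, b: float, c: float):
    """The Eilers-Peeters production-irradiance form E / (a E^2 + b E + c)."""
    E = np.asarray(E, dtype=float)
    return E / (a * E * E + b * E + c)


def _fit_params(a: float, b: float, c: float) -> tuple[float, float, float]:
    etr_max = 1.0 / (b + 2.0 * math.sqrt(a * c))
    alpha = 1.0 / c
    return etr_max, alpha, etr_max * c


def fit_eilers_peeters(points) -> PvsEFit:
    """Least-squares Eilers-Peeters fit of (E, ETR) pairs.

    Multistart Levenberg-Marquardt with positivity enforced through a
    log-parameterisation; starting values are scaled from the observed
    maximum rate and initial slope.  Derived quantities:
    ETR_max = 1/(b + 2 sqrt(a c)), alpha = 1/c, E_K = ETR_max / alpha.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("need >= 4 (E, ETR) points")
    E, y = pts[:, 0], pts[:, 1]
    pos = (E > 0) & (y > 0)
    if pos.sum() < 3:
        raise ArithmeticError("degenerate input: too few positive ETR values")

    ymax = float(np.max(y[pos]))
    slope0 = float(np.median(y[pos] / E[pos]))
    # moment-style starting values: alpha ~ slope, ETR_max ~ ymax, peak near
    # the largest observed E; multistart over the peak position
    starts = []
    for e_opt in (np.median(E[pos]), np.max(E), 2.0 * np.max(E)):
        c0 = 1.0 / slope0
        a0 = c0 / max(e_opt, 1.0) ** 2
        b0 = max(1.0 / ymax - 2.0 * math.sqrt(a0 * c0), 1e-8 / ymax)
        starts.append(np.log([a0, b0, c0]))

    def resid(logp):
        a, b, c = np.exp(logp)
        return eilers_peeters_curve(E, a, b, c) - y

    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, method="lm", max_nfev=20000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise ArithmeticError("Eilers-Peeters fit failed from all starts")
    a, b, c = np.exp(best.x)
    etr_max, alpha, e_k = _fit_params(a, b, c)
    if not (etr_max > 0 and np.isfinite(etr_max)):
        raise ArithmeticError("fit produced a non-positive maximum rate")
    return PvsEFit(a=a, b=b, c=c, etr_max=etr_max, alpha=alpha, e_k=e_k,
                   residual_sse=float(2.0 * best.cost))


# one mol of N2 reduced corresponds to three mol of acetylene reduced to
# ethylene (theoretical electron-equivalence factor)
C2H4_PER_N2 = 3.0


def acetylene_to_n2(ethylene_rate: float) -> tuple[float, float]:
    """Convert an ethylene production rate to (N2, N-atom) fixation rates."""
    if ethylene_rate < 0:
        raise ValueError("ethylene rate must be >= 0")
    n2 = ethylene_rate / C2H4_PER_N2
    return n2, 2.0 * n2


# ---------------------------------------------------------------------------
# synthetic observations


_DIEL_CHANNELS = ("photo_o2", "resp_o2", "n2fix", "c_per_cell", "n_per_cell")


@dataclass
class DielObservationSet:
    """Synthetic diel observations for two O2 treatments.

    ``data`` is tidy: one row per (treatment, time, channel) with mean and
    standard deviation.  The generator seed and the true parameters are
    recorded so recovery tests can close the loop.
    """

    data: pd.DataFrame
    treatments: tuple[float, ...]
    seed: int
    noise_sd: float
    truth: Parameters
    forcing_kwargs: dict = field(default_factory=dict)


def _model_diel_channels(p: Parameters, gas_fraction: float, times: np.ndarray,
                         dt: float = 0.02, max_days: int = 30,
                         **forcing_kwargs) -> pd.DataFrame:
    f = canonical_forcing(o2_gas_fraction=gas_fraction, **forcing_kwargs)
    res = run_diel(f, p, dt=dt, max_days=max_days)
    sl = res.converged_day
    clock = res.clock[sl]
    clock[-1] = 24.0  # closing dawn sample
    m = p.metabolism
    cols = {
        "photo_o2": res.series["photo_o2"][sl],
        "resp_o2": res.series["resp_o2"][sl],
        "n2fix": res.series["n2fix"][sl],
        "c_per_cell": m.Q_C + res.series["c_s"][sl],
        "n_per_cell": m.Q_C * m.Y_bio_NC + res.series["n_s"][sl],
    }
    out = {}
    for k, v in cols.items():
        out[k] = np.interp(times, clock, v)
    return pd.DataFrame(out, index=times)


def generate_diel_observations(seed: int, truth: Parameters | None = None,
                               noise_sd: float = 0.10,
                               treatments: tuple[float, ...] = (0.20, 0.05),
                               times: np.ndarray | None = None,
                               dt: float = 0.02, max_days: int = 30,
                               **forcing_kwargs) -> DielObservationSet:
    """Simulate both canonical treatments and add relative Gaussian noise.

    ``noise_sd`` is the relative standard deviation applied per sample; the
    reported sd column scales each channel's typical magnitude, emulating
    culture replicate scatter.
    """
    truth = Parameters.default() if truth is None else truth
    times = np.arange(0.0, 24.1, 1.0) if times is None else np.asarray(times, float)
    rng = np.random.default_rng(seed)
    rows = []
    for frac in treatments:
        model = _model_diel_channels(truth, frac, times, dt=dt,
                                     max_days=max_days, **forcing_kwargs)
        for ch in _DIEL_CHANNELS:
            v = model[ch].to_numpy()
            scale = max(float(np.max(np.abs(v))), 1e-300)
            sd = noise_sd * scale
            noisy = v + rng.normal(0.0, sd, size=v.shape) if noise_sd > 0 else v
            for t, mean in zip(times, noisy):
                rows.append({"treatment": frac, "time_h": float(t),
                             "channel": ch, "mean": float(mean), "sd": float(sd)})
    df = pd.DataFrame(rows)
    return DielObservationSet(data=df, treatments=tuple(treatments), seed=seed,
                              noise_sd=noise_sd, truth=truth,
                              forcing_kwargs=dict(forcing_kwargs))


def generate_pve_points(seed: int, truth: tuple[float, float, float],
                        E_grid=None, noise_sd: float = 0.0) -> np.ndarray:
    """Evaluate an Eilers-Peeters curve on an E grid with seeded noise."""
    a, b, c = truth
    E = np.asarray(E_grid if E_grid is not None else
                   [0, 20, 50, 100, 150, 250, 400, 600, 900, 1300, 1600], float)
    y = eilers_peeters_curve(E, a, b, c)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd * max(y.max(), 1e-300), size=y.shape)
    return np.column_stack([E, y])


# ---------------------------------------------------------------------------
# calibration

# tunables with loose positivity bounds (log-scale search)
CALIBRATION_TUNABLES = {
    "membrane_factor": "diffusivity.membrane_factor",
    "K_CS": "metabolism.K_CS",
    "A_N2fix": "metabolism.A_N2fix",
    "R_max": "metabolism.R_max",
    "P_max_chl": "metabolism.P_max_chl",
    "lambda_max": "metabolism.lambda_max",
    "Y_resp_CN": "metabolism.Y_resp_CN",
    "O2cri": "metabolism.O2cri",
}


def _objective(p: Parameters, obs: DielObservationSet, dt: float,
               max_days: int) -> float:
    sse = 0.0
    times = np.unique(obs.data["time_h"].to_numpy())
    for frac in obs.treatments:
        model = _model_diel_channels(p, frac, times, dt=dt, max_days=max_days,
                                     **obs.forcing_kwargs)
        sub = obs.data[obs.data["treatment"] == frac]
        for ch in _DIEL_CHANNELS:
            rows = sub[sub["channel"] == ch]
            mean = rows["mean"].to_numpy()
            pred = np.interp(rows["time_h"].to_numpy(), times,
                             model[ch].to_numpy())
            # sd-weighted; noiseless channels fall back to a 1%-of-scale
            # weight so exact fixtures stay finite
            floor = 1e-2 * max(float(np.max(np.abs(mean))), 1e-300)
            w = 1.0 / np.maximum(rows["sd"].to_numpy(), floor)
            sse += float(np.sum(((pred - mean) * w) ** 2))
    return sse


def calibrate(free_params, obs: DielObservationSet,
              p0: Parameters | None = None, dt: float = 0.05,
              max_days: int = 12, maxiter: int = 60):
    """Fit the named tunables to diel observations by weighted least squares.

    Derivative-free Nelder-Mead in log-parameter space (all tunables are
    positive rate-like quantities).  Returns ``(fitted Parameters,
    diagnostics dict)`` with the objective at the solution and the per-name
    fitted values.
    """
    p0 = Parameters.default() if p0 is None else p0
    free = list(free_params)
    unknown = [k for k in free if k not in CALIBRATION_TUNABLES]
    if unknown:
        raise KeyError(f"not calibratable: {unknown}")
    if not free:
        return p0.copy(), {"objective": _objective(p0, obs, dt, max_days),
                           "fitted": {}, "n_eval": 1}

    keys = [CALIBRATION_TUNABLES[k] for k in free]
    x0 = np.log([p0.get(k) for k in keys])
    n_eval = 0

    def fun(logx):
        nonlocal n_eval
        n_eval += 1
        try:
            trial = p0.with_overrides(**dict(zip(keys, np.exp(logx))))
            return _objective(trial, obs, dt, max_days)
        except (ArithmeticError, ValueError):
            return 1e30

    sol = minimize(fun, x0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-8})
    fitted_vals = dict(zip(free, np.exp(sol.x)))
    fitted = p0.with_overrides(**dict(zip(keys, np.exp(sol.x))))
    return fitted, {"objective": float(sol.fun), "fitted": fitted_vals,
                    "n_eval": n_eval, "success": bool(sol.success)}
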