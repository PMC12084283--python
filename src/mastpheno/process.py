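"""Transport-resistance carbon/nitrogen growth model on a weekly time step.

Six pools: shoot and root structural mass (MS, MR), shoot and root carbon
substrate (CS, CR), shoot and root nitrogen substrate (NS, NR). Carbon is
assimilated into the shoot carbon pool, nitrogen is taken up into the root
nitrogen pool; substrates move between shoot and root down concentration
gradients through conductance-limited transport, and structural growth
consumes substrate in fixed stoichiometric fractions (f_C carbon, f_N
nitrogen per unit structural mass).

Assimilation and uptake rates are forced by weekly climate (temperature,
a bucket soil-moisture proxy driven by precipitation, and radiation)
through piecewise-linear trapezoidal response functions bounded in [0, 1].

Two derived quantities feed the ordinal observation model: the carbon
assimilation flux U_C (leaf display predictor) and the whole-plant
substrate index

    S = (1/f_C) (CS+CR)/(MS+MR) + (1/f_N) (NS+NR)/(MS+MR)

(flower and fruit predictor, acting with a species-specific lag).

Integration is explicit Euler at dt = 1 week, the native grid of the
forcing and of the state-space analysis; pools are clipped at zero after
each step and clip events are counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

#: guard for structural-mass denominators
EPS_MASS = 1e-9

STATE_VARS = ("MS", "MR", "CS", "CR", "NS", "NR")


@dataclass(frozen=True)
class EnvResponse:
    """Trapezoidal piecewise-linear environmental response in [0, 1].

    Zero below ``b1``, rising linearly to 1 on [b1, b2], plateau 1 on
    [b2, b3], falling linearly to 0 on [b3, b4], zero above ``b4``.
    """

    b1: float
    b2: float
    b3: float
    b4: float

    def __post_init__(self):
        if not (self.b1 <= self.b2 <= self.b3 <= self.b4):
            raise ValueError(f"unordered breakpoints {(self.b1, self.b2, self.b3, self.b4)}")

    def __call__(self, value):
        v = np.asarray(value, dtype=float)
        out = np.zeros_like(v)
        if self.b2 > self.b1:
            rising = (v > self.b1) & (v < self.b2)
            out[rising] = (v[rising] - self.b1) / (self.b2 - self.b1)
        out[(v >= self.b2) & (v <= self.b3)] = 1.0
        if self.b4 > self.b3:
            falling = (v > self.b3) & (v < self.b4)
            out[falling] = (self.b4 - v[falling]) / (self.b4 - self.b3)
        return out if out.ndim else float(out)


def env_response(value, breakpoints) -> float:
    """Evaluate a trapezoidal response given ``(b1, b2, b3, b4)``."""
    return EnvResponse(*breakpoints)(value)


@dataclass
class ProcessParams:
    """Rate and stoichiometry parameters of the growth model.

    Units: masses in arbitrary consistent units, rates per week.
    ``f_C`` and ``f_N`` are the substrate fractions consumed per unit of
    structural growth (defaults: half carbon, 2.5% nitrogen by mass).
    """

    a_C: float = 1.2  # max carbon assimilation rate
    a_N: float = 0.3  # max nitrogen uptake rate
    K_S: float = 5.0  # shoot self-limitation half-saturation mass
    K_R: float = 5.0  # root self-limitation half-saturation mass
    g: float = 4.0  # growth rate coefficient
    t_C: float = 0.5  # carbon transport conductance
    t_N: float = 0.5  # nitrogen transport conductance
    m_S: float = 0.12  # shoot turnover per week
    m_R: float = 0.12  # root turnover per week
    f_C: float = 0.5  # carbon per unit structural growth
    f_N: float = 0.025  # nitrogen per unit structural growth
    J_C: float = 0.3  # substrate-concentration half-inhibition of assimilation
    J_N: float = 0.008  # substrate-concentration half-inhibition of N uptake
    # trapezoidal response breakpoints
    temp_response: tuple = (5.0, 16.0, 32.0, 45.0)  # deg C
    moisture_response: tuple = (3.0, 40.0, 500.0, 1000.0)  # mm in bucket
    rad_response: tuple = (40.0, 140.0, 1000.0, 2000.0)  # W m-2
    # moisture-dominated nitrogen-uptake response (mineralisation/diffusion
    # both need wet soil)
    moisture_response_N: tuple = (5.0, 60.0, 500.0, 1000.0)
    bucket_capacity: float = 150.0  # mm
    bucket_drain: float = 0.25  # fraction lost per week

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ProcessParams":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("temp_response", "moisture_response", "rad_response", "moisture_response_N"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class ProcessState:
    """The six pools; all non-negative."""

    MS: float = 1.0
    MR: float = 1.0
    CS: float = 0.3
    CR: float = 0.3
    NS: float = 0.05
    NR: float = 0.05

    def as_array(self) -> np.ndarray:
        return np.array([self.MS, self.MR, self.CS, self.CR, self.NS, self.NR])

    @classmethod
    def from_array(cls, x) -> "ProcessState":
        return cls(*(float(v) for v in x))


def soil_moisture_series(precip: np.ndarray, params: ProcessParams, w0: float = 50.0) -> np.ndarray:
    """Weekly bucket soil-moisture proxy from weekly precipitation totals.

    w_t = min(capacity, (1 - drain) * w_{t-1} + precip_t).
    """
    w = np.empty(len(precip))
    prev = w0
    keep = 1.0 - params.bucket_drain
    for i, p in enumerate(precip):
        prev = min(params.bucket_capacity, keep * prev + p)
        w[i] = prev
    return w


def forcing_responses(forcing: pd.DataFrame, params: ProcessParams):
    """Per-week (phi, psi) multipliers for carbon assimilation and N uptake.

    phi is the product of the temperature, moisture and radiation
    responses; psi is the product of the temperature response and the
    nitrogen-specific (wetter-optimum) moisture response.
    """
    temp = forcing["temperature"].to_numpy(dtype=float)
    rad = forcing["radiation"].to_numpy(dtype=float)
    moist = soil_moisture_series(forcing["precip"].to_numpy(dtype=float), params)
    f_T = EnvResponse(*params.temp_response)(temp)
    f_W = EnvResponse(*params.moisture_response)(moist)
    f_R = EnvResponse(*params.rad_response)(rad)
    f_WN = EnvResponse(*params.moisture_response_N)(moist)
    return f_T * f_W * f_R, f_T * f_WN


def carbon_assimilation(MS: float, phi: float, params: ProcessParams, CS: float = 0.0) -> float:
    """Carbon assimilation flux with product (substrate) inhibition.

    U_C = a_C * phi * MS / (1 + MS/K_S) * 1 / (1 + (CS/MS)/J_C).

    Saturates at a_C * K_S * phi as shoot mass grows (at fixed substrate
    concentration); accumulating shoot carbon substrate down-regulates
    further assimilation, which gives the pool system a genuine stable
    equilibrium under constant forcing.
    """
    if MS <= 0.0:
        return 0.0
    inhib = 1.0 / (1.0 + CS / (MS * params.J_C))
    return params.a_C * phi * MS / (1.0 + MS / params.K_S) * inhib


def nitrogen_uptake(MR: float, psi: float, params: ProcessParams, NR: float = 0.0) -> float:
    """Nitrogen uptake flux, mirroring assimilation on the root side."""
    if MR <= 0.0:
        return 0.0
    inhib = 1.0 / (1.0 + NR / (MR * params.J_N))
    return params.a_N * psi * MR / (1.0 + MR / params.K_R) * inhib


def substrate_index(state, params: ProcessParams) -> float:
    """Whole-plant substrate concentration index S (>= 0)."""
    arr = state.as_array() if isinstance(state, ProcessState) else np.asarray(state)
    MS, MR, CS, CR, NS, NR = arr
    M = MS + MR
    if M <= 0:
        raise ValueError("substrate_index: MS + MR must be positive")
    return float((CS + CR) / (params.f_C * M) + (NS + NR) / (params.f_N * M))


def step_process(
    state,
    phi: float,
    psi: float,
    params: ProcessParams,
    noise: np.ndarray | None = None,
    return_fluxes: bool = False,
):
    """One explicit-Euler week of the six-pool dynamics.

    Growth G = g * C * N / M per organ, gradient-driven substrate
    transport, turnover losses, assimilation into CS and uptake into NR.
    Optional additive per-pool noise; pools clipped at zero afterwards.

    Returns ``(new_state_array, U_C, n_clipped)``, plus a dict of the
    realised fluxes (U_C, U_N, G_S, G_R, tau_C, tau_N) when
    ``return_fluxes`` is set.
    """
    x = state.as_array() if isinstance(state, ProcessState) else np.asarray(state, dtype=float)
    if not np.all(np.isfinite(x)):
        bad = STATE_VARS[int(np.flatnonzero(~np.isfinite(x))[0])]
        raise FloatingPointError(f"non-finite pool {bad} entering step")
    MS, MR, CS, CR, NS, NR = x
    U_C = carbon_assimilation(MS, phi, params, CS)
    U_N = nitrogen_uptake(MR, psi, params, NR)
    G_S = params.g * CS * NS / max(MS, EPS_MASS)
    G_R = params.g * CR * NR / max(MR, EPS_MASS)
    tau_C = params.t_C * (CS / max(MS, EPS_MASS) - CR / max(MR, EPS_MASS))
    tau_N = params.t_N * (NR / max(MR, EPS_MASS) - NS / max(MS, EPS_MASS))
    # flux limiting: scale a pool's drains down if they would overdraw it
    # within the weekly Euler step (explicit integration stability guard)
    drains = {
        "CS": (CS, params.f_C * G_S + max(tau_C, 0.0)),
        "CR": (CR, params.f_C * G_R + max(-tau_C, 0.0)),
        "NS": (NS, params.f_N * G_S + max(-tau_N, 0.0)),
        "NR": (NR, params.f_N * G_R + max(tau_N, 0.0)),
    }
    scale = {k: (pool / d if d > pool and d > 0 else 1.0) for k, (pool, d) in drains.items()}
    G_S *= min(scale["CS"], scale["NS"])
    G_R *= min(scale["CR"], scale["NR"])
    tau_C *= scale["CS"] if tau_C > 0 else scale["CR"]
    tau_N *= scale["NR"] if tau_N > 0 else scale["NS"]
    new = np.array(
        [
            MS + G_S - params.m_S * MS,
            MR + G_R - params.m_R * MR,
            CS + U_C - params.f_C * G_S - tau_C,
            CR + tau_C - params.f_C * G_R,
            NS + tau_N - params.f_N * G_S,
            NR + U_N - params.f_N * G_R - tau_N,
        ]
    )
    if noise is not None:
        new = new + noise
    clipped = new < 0.0
    new[clipped] = 0.0
    if return_fluxes:
        fluxes = {
            "U_C": float(U_C), "U_N": float(U_N),
            "G_S": float(G_S), "G_R": float(G_R),
            "tau_C": float(tau_C), "tau_N": float(tau_N),
        }
        return new, float(U_C), int(clipped.sum()), fluxes
    return new, float(U_C), int(clipped.sum())


def simulate_trajectory(
    forcing: pd.DataFrame,
    params: ProcessParams,
    initial_state: ProcessState | None = None,
    noise_sd: float | np.ndarray | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Weekly trajectory of pools, assimilation flux and substrate index.

    Parameters
    ----------
    forcing
        Weekly climate table (``week_start_date``, ``temperature``,
        ``precip``, ``radiation``); should start well before the
        observation window (the study runs the model from the year 2000
        so that by 2015 initial conditions have washed out).
    noise_sd
        Per-pool additive normal process-error sd (scalar or length-6);
        None or 0 gives the deterministic trajectory.
    seed
        Seeds the noise stream; deterministic given seed.

    Returns a DataFrame with columns
    ``date, MS, MR, CS, CR, NS, NR, U_C, S`` (one row per forcing week,
    state recorded after the week's step).
    """
    if initial_state is None:
        initial_state = ProcessState()
    phi, psi = forcing_responses(forcing, params)
    n = len(forcing)
    rng = np.random.default_rng(seed)
    use_noise = noise_sd is not None and np.any(np.asarray(noise_sd) > 0)
    if use_noise:
        noise = rng.normal(0.0, 1.0, size=(n, 6)) * np.asarray(noise_sd, dtype=float)
    out = np.empty((n, 8))
    x = initial_state.as_array()
    n_clipped = 0
    for i in range(n):
        x, u_c, nc = step_process(x, phi[i], psi[i], params, noise[i] if use_noise else None)
        n_clipped += nc
        out[i, :6] = x
        out[i, 6] = u_c
        out[i, 7] = substrate_index(x, params)
    traj = pd.DataFrame(out, columns=[*STATE_VARS, "U_C", "S"])
    traj.insert(0, "date", pd.DatetimeIndex(forcing["week_start_date"]).to_numpy())
    traj.attrs["n_clipped"] = n_clipped
    return traj


def interp_at(trajectory: pd.DataFrame, column: str, dates) -> np.ndarray:
    """Linear interpolation of a trajectory column at arbitrary dates."""
    t0 = trajectory["date"].iloc[0]
    grid = (pd.DatetimeIndex(trajectory["date"]) - t0).days.to_numpy() / 7.0
    query = (pd.DatetimeIndex(dates) - t0) / pd.Timedelta(days=7)
    query = np.atleast_1d(np.asarray(query, dtype=float))
    if np.any(query < grid[0]) or np.any(query > grid[-1]):
        raise ValueError("interp_at: requested date outside the trajectory window")
    return np.interp(query, grid, trajectory[column].to_numpy(dtype=float))


def lagged_predictor(trajectory: pd.DataFrame, lam_weeks: float, t) -> float:
    """Substrate index S evaluated ``lam_weeks`` before observation time t.

    Linear interpolation between bracketing weekly values; a zero lag at a
    grid date returns the stored value exactly.
    """
    target = pd.Timestamp(t) - pd.Timedelta(days=7.0 * lam_weeks)
    if target < trajectory["date"].iloc[0]:
        raise ValueError(
            f"lagged_predictor: lag {lam_weeks} weeks reaches before the "
            f"trajectory start {trajectory['date'].iloc[0].date()}"
        )
    return float(interp_at(trajectory, "S", [target])[0])
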