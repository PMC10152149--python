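"""Deterministic kinetics of bead-propelled actin comet tails in a sealed well.

The model tracks a conserved actin pool partitioned into tail F-actin,
non-tail F-actin, ADP-G-actin, ATP-G-actin, and an aged (polymerization
incompetent) bookkeeping pool.  All pools are carried in length-equivalent
units (``l = l_max * G / G_bar``), so the conservation law reads

    l + l_tilde + G_D + G_T + aged = l_max        (exactly, at all times)

Time is in minutes, lengths in micrometres.  The tail elongation speed is
linear in the ATP-monomer pool, ``V = k_tilde * G_T``; disassembly feeds the
ADP pool at rate ``gamma * l``; recycling converts ADP- to ATP-monomers at
rate ``k_DT``; aging removes material from all active pools at rate ``psi``.
With ``gamma = k_DT = psi = 0`` and ``sigma > 0`` the system reduces to
pure saturating assembly (tail plus a non-tail "unproductive" fraction),
which has a closed-form solution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "TurnoverParams",
    "PoolState",
    "Trajectory",
    "SteadyStateSolution",
    "derive_k_tilde",
    "k_tilde_from_velocity",
    "assembly_rate",
    "assembly_closed_form",
    "saturation_timescale",
    "simulate",
    "steady_state",
    "flux_triplet",
    "load_presets",
    "preset_params",
]

SECONDS_PER_MINUTE = 60.0

#: default relative tolerance for the supplied-vs-derived k_tilde check
K_TILDE_RTOL = 0.05


class ConservationError(ValueError):
    """Raised when a pool state does not add up to the total pool."""


@dataclass(frozen=True)
class TurnoverParams:
    """Kinetic and geometric constants of the turnover model.

    Parameters
    ----------
    kon : float
        Barbed-end association rate constant, per (uM * s).
    delta : float
        Monomer half-size contributing to elongation, um.
    phi : float
        Dimensionless efficiency factor in (0, 1] lumping geometric,
        mechanical and diffusion-limited corrections to the speed law.
    G_bar : float
        Total actin concentration, uM.
    l_max : float
        Length-equivalent of the whole pool, um (tail length if every
        monomer were in one tail).
    k_tilde : float, optional
        Lumped first-order assembly constant, per minute.  Derived from
        ``kon * phi * delta * G_bar * 60 / l_max`` when not supplied.
    gamma, k_DT, psi : float
        Tail disassembly, ADP->ATP recycling, and aging rates, per minute.
    sigma : float
        Non-tail assembly fraction factor (assembly mode only).
    k_tilde_rtol : float or None
        When not ``None`` and ``k_tilde`` is supplied, the supplied value
        must agree with the derived one within this relative tolerance.
        Default ``None`` (no check): published parameter sets pair a
        fitted ``k_tilde`` with an l_max that the derivation was not run
        against.
    """

    kon: float = 10.0
    delta: float = 0.003
    phi: float = 0.2
    G_bar: float = 3.0
    l_max: float = 110.0
    k_tilde: float | None = None
    gamma: float = 0.0
    k_DT: float = 0.0
    psi: float = 0.0
    sigma: float = 0.0
    k_tilde_rtol: float | None = None

    def __post_init__(self) -> None:
        for name in ("kon", "delta", "G_bar", "gamma", "k_DT", "psi", "sigma"):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"{name} must be nonnegative, got {value}")
        if self.l_max <= 0:
            raise ValueError(f"l_max must be positive, got {self.l_max}")
        if not 0.0 < self.phi <= 1.0:
            raise ValueError(f"phi must be in (0, 1], got {self.phi}")
        if self.k_tilde is not None:
            if self.k_tilde < 0:
                raise ValueError(f"k_tilde must be nonnegative, got {self.k_tilde}")
            if self.k_tilde_rtol is not None:
                derived = derive_k_tilde(replace(self, k_tilde=None))
                if derived > 0 and abs(self.k_tilde - derived) > self.k_tilde_rtol * derived:
                    raise ValueError(
                        f"supplied k_tilde={self.k_tilde} disagrees with derived "
                        f"{derived:.6g} beyond rtol={self.k_tilde_rtol}"
                    )

    @property
    def rate(self) -> float:
        """Effective lumped assembly constant, per minute."""
        if self.k_tilde is not None:
            return self.k_tilde
        return derive_k_tilde(self)

    @property
    def v0(self) -> float:
        """Maximal assembly velocity ``k_tilde * l_max``, um/min."""
        return self.rate * self.l_max


def derive_k_tilde(params: TurnoverParams) -> float:
    """Lumped assembly constant ``kon * phi * delta * G_bar / l_max``, per minute.

    ``kon`` is given per (uM * s); the factor of 60 converts to minutes.

    >>> round(derive_k_tilde(TurnoverParams(l_max=100.0)), 4)
    0.0108
    """
    if params.l_max <= 0:
        raise ValueError("l_max must be positive")
    return params.kon * params.phi * params.delta * params.G_bar * SECONDS_PER_MINUTE / params.l_max


def k_tilde_from_velocity(v0: float, l_max: float) -> float:
    """Assembly constant from the maximal velocity: ``k_tilde = V0 / l_max``."""
    if l_max <= 0:
        raise ValueError("l_max must be positive")
    if v0 < 0:
        raise ValueError("v0 must be nonnegative")
    return v0 / l_max


@dataclass(frozen=True)
class PoolState:
    """Actin pools in length-equivalent micrometres."""

    l: float = 0.0
    l_tilde: float = 0.0
    G_D: float = 0.0
    G_T: float = 0.0
    aged: float = 0.0

    def __post_init__(self) -> None:
        for name in ("l", "l_tilde", "G_D", "G_T", "aged"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> float:
        return self.l + self.l_tilde + self.G_D + self.G_T + self.aged

    @property
    def active_total(self) -> float:
        """Polymerization-competent material: everything but the aged pool."""
        return self.l + self.l_tilde + self.G_D + self.G_T

    @classmethod
    def all_monomer(cls, l_max: float) -> "PoolState":
        """Fresh well: the whole pool as ATP-G-actin."""
        return cls(G_T=l_max)

    def check_conservation(self, l_max: float, rtol: float = 1e-9) -> None:
        if abs(self.total - l_max) > rtol * l_max:
            raise ConservationError(
                f"pools sum to {self.total:.9g}, expected l_max={l_max:.9g}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.l, self.l_tilde, self.G_D, self.G_T, self.aged])


@dataclass(frozen=True)
class Trajectory:
    """Time course of the pools with the instantaneous assembly velocity."""

    times: np.ndarray
    l: np.ndarray
    l_tilde: np.ndarray
    G_D: np.ndarray
    G_T: np.ndarray
    aged: np.ndarray
    velocities: np.ndarray
    l_max: float

    def __len__(self) -> int:
        return len(self.times)

    def state_at(self, i: int) -> PoolState:
        return PoolState(
            l=float(self.l[i]),
            l_tilde=float(self.l_tilde[i]),
            G_D=float(self.G_D[i]),
            G_T=float(self.G_T[i]),
            aged=float(self.aged[i]),
        )

    @property
    def states(self) -> list[PoolState]:
        return [self.state_at(i) for i in range(len(self))]

    def conservation_residual(self) -> np.ndarray:
        total = self.l + self.l_tilde + self.G_D + self.G_T + self.aged
        return total - self.l_max

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "l_um": self.l,
                "l_tilde_um": self.l_tilde,
                "GD_um": self.G_D,
                "GT_um": self.G_T,
                "aged_um": self.aged,
                "V_um_per_min": self.velocities,
            }
        )


@dataclass(frozen=True)
class SteadyStateSolution:
    """Analytic steady state of the aging-free turnover system."""

    alpha: float
    beta: float
    S: float
    G_T_star: float
    G_D_star: float
    l_star: float
    V_star: float


def assembly_rate(G_T: float, params: TurnoverParams) -> float:
    """Tail elongation speed ``V = k_tilde * G_T`` in um/min."""
    if G_T < 0:
        raise ValueError(f"G_T must be nonnegative, got {G_T}")
    return params.rate * G_T


def assembly_closed_form(t, v0: float, l_max: float, sigma: float = 0.0):
    """Closed-form assembly-mode solution for (tail, non-tail) lengths.

    l(t) = l_max/(1+sigma) * (1 - exp(-(1+sigma) V0 t / l_max)),
    l_tilde(t) = sigma * l(t).

    Accepts scalar or array ``t`` (minutes).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    if l_max <= 0:
        raise ValueError("l_max must be positive")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    l = l_max / (1.0 + sigma) * (1.0 - np.exp(-(1.0 + sigma) * v0 * t / l_max))
    l_tilde = sigma * l
    if t.ndim == 0:
        return float(l), float(l_tilde)
    return l, l_tilde


def saturation_timescale(l_max: float, v0: float, sigma: float = 0.0) -> float:
    """Time constant of the saturating assembly phase, ``l_max/((1+sigma) V0)``."""
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    if l_max <= 0:
        raise ValueError("l_max must be positive")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    return l_max / ((1.0 + sigma) * v0)


def _rhs(t, y, k_tilde, gamma, k_DT, psi, sigma):
    l, l_tilde, g_d, g_t, aged = y
    v = k_tilde * g_t
    return (
        v - (gamma + psi) * l,
        sigma * v,
        gamma * l - (k_DT + psi) * g_d,
        k_DT * g_d - (1.0 + sigma) * v - psi * g_t,
        psi * (l + g_d + g_t),
    )


def simulate(
    params: TurnoverParams,
    initial: PoolState | None = None,
    t_grid: Sequence[float] | np.ndarray | None = None,
    *,
    duration_min: float | None = None,
    dt_min: float = 2.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the turnover system on an explicit time grid.

    ``t_grid`` must be strictly increasing and start at 0 (alternatively
    give ``duration_min``/``dt_min`` to build a uniform grid).  The initial
    state defaults to the all-monomer well and must satisfy conservation
    against ``params.l_max``.  ``sigma > 0`` is only meaningful in
    assembly mode and is rejected when combined with disassembly or
    recycling.
    """
    if t_grid is None:
        if duration_min is None:
            raise ValueError("provide either t_grid or duration_min")
        n = int(round(duration_min / dt_min))
        t_grid = np.linspace(0.0, n * dt_min, n + 1)
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("t_grid must be a 1-D grid with at least two points")
    if t[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if params.sigma > 0 and (params.gamma > 0 or params.k_DT > 0):
        raise ValueError(
            "sigma > 0 (non-tail assembly) is only valid in assembly mode "
            "(gamma = k_DT = 0); mixing it with turnover is not supported"
        )
    if initial is None:
        initial = PoolState.all_monomer(params.l_max)
    initial.check_conservation(params.l_max)

    k_tilde = params.rate
    sol = solve_ivp(
        _rhs,
        (t[0], t[-1]),
        initial.as_array(),
        t_eval=t,
        method=method,
        rtol=rtol,
        atol=atol,
        args=(k_tilde, params.gamma, params.k_DT, params.psi, params.sigma),
    )
    if not sol.success:  # pragma: no cover - solver failure is exceptional
        raise RuntimeError(f"ODE integration failed: {sol.message}")

    y = sol.y
    if np.any(y < -1e-7 * params.l_max):
        raise RuntimeError("integration produced significantly negative pools")
    y = np.clip(y, 0.0, None)
    traj = Trajectory(
        times=t,
        l=y[0],
        l_tilde=y[1],
        G_D=y[2],
        G_T=y[3],
        aged=y[4],
        velocities=k_tilde * y[3],
        l_max=params.l_max,
    )
    residual = np.abs(traj.conservation_residual())
    if residual.max() > 1e-6 * params.l_max:
        raise ConservationError(
            f"conservation residual {residual.max():.3g} exceeds 1e-6 * l_max"
        )
    return traj


def steady_state(params: TurnoverParams) -> SteadyStateSolution:
    """Analytic steady state: alpha = k~/k_DT, beta = k~/gamma, S = 1+alpha+beta.

    Only defined without aging (psi = 0) and with strictly positive
    disassembly and recycling rates.
    """
    if params.psi != 0:
        raise ValueError("no nontrivial steady state with aging (psi != 0)")
    if params.gamma <= 0 or params.k_DT <= 0:
        raise ValueError("steady state requires gamma > 0 and k_DT > 0")
    k_tilde = params.rate
    alpha = k_tilde / params.k_DT
    beta = k_tilde / params.gamma
    s = 1.0 + alpha + beta
    g_t = params.l_max / s
    g_d = alpha * params.l_max / s
    l = beta * params.l_max / s
    v = k_tilde * params.l_max / s
    return SteadyStateSolution(
        alpha=alpha, beta=beta, S=s, G_T_star=g_t, G_D_star=g_d, l_star=l, V_star=v
    )


def flux_triplet(state: PoolState, params: TurnoverParams) -> tuple[float, float, float]:
    """(assembly, disassembly, recycling) fluxes in um/min; equal at steady state."""
    return (
        params.rate * state.G_T,
        params.gamma * state.l,
        params.k_DT * state.G_D,
    )


# ---------------------------------------------------------------------------
# condition presets


def load_presets() -> dict:
    """Raw preset documents (rates per minute, lengths in um) shipped as data."""
    text = resources.files("cometpool.data").joinpath("presets.json").read_text()
    return json.loads(text)


def preset_params(name: str, **overrides) -> TurnoverParams:
    """Build :class:`TurnoverParams` from a named preset, with overrides.

    >>> preset_params("recycling").gamma
    0.12
    """
    presets = load_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    doc = presets[name]
    kwargs = {
        "k_tilde": doc["k_tilde_per_min"],
        "gamma": doc["gamma_per_min"],
        "k_DT": doc["k_DT_per_min"],
        "psi": doc["psi_per_min"],
        "sigma": doc["sigma"],
        "l_max": doc["l_max_um"],
    }
    kwargs.update(overrides)
    return TurnoverParams(**kwargs)
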