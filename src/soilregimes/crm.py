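"""Two-resource consumer-resource model of community nitrate reduction.

The model describes the anaerobic nitrate metabolism of a soil community
through a single effective functional biomass ``x`` consuming two
non-substitutable resources: nitrate ``A`` (electron acceptor) and a
growth-limiting nutrient ``C`` (electron donor, typically carbon).  Both
uptake terms are Monod; growth requires both resources:

    dA/dt = -rA * x * A / (A + KA)
    dC/dt = -rC * x * C / (C + KC)
    dx/dt = gamma * x * [A / (A + KA)] * [C / (C + KC)]

Only the combinations ``x~ = rA*x``, ``C~ = C*rA/rC`` and ``K~C = KC*rA/rC``
are identifiable from nitrate time series, so the package works exclusively
in the rescaled variables, where everything carries units of nitrate
concentration (mM) or rate (mM/day):

    dA/dt  = -x~ * A / (A + KA)
    dC~/dt = -x~ * C~ / (C~ + K~C)
    dx~/dt = gamma * x~ * [A / (A + KA)] * [C~ / (C~ + K~C)]

Under chloramphenicol (``chl=True``) growth is arrested (dx~/dt = 0) and
nitrate falls linearly at rate x~(0) while A >> KA.

Because the affinities are small (K ~ 0.01 mM) the dynamics admit a
piecewise closed form: biomass grows as ``x~(0) * exp(gamma*t)`` until the
scarcer of the two resources is exhausted at

    t* = log(min(A0, C~0) * gamma / x~0 + 1) / gamma,

after which nitrate declines linearly at rate ``gamma*C~0 + x~0`` (when the
nutrient ran out first) until depletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "CRMParams",
    "Trajectory",
    "NoGrowthError",
    "IntegrationError",
    "simulate_numeric",
    "simulate_analytic",
    "growth_stop_time",
    "DEFAULT_GAMMA",
    "DEFAULT_KA",
    "DEFAULT_KC",
    "TIMEPOINTS_HR",
]

#: Growth rate fixed for fitting, 1/day.
DEFAULT_GAMMA = 4.8
#: Nitrate affinity fixed for fitting, mM.
DEFAULT_KA = 0.01
#: Rescaled nutrient affinity fixed for fitting, mM.
DEFAULT_KC = 0.01
#: Measurement grid of the microcosm incubations, hours.
TIMEPOINTS_HR = (0.0, 4.0, 8.0, 19.0, 25.0, 31.0, 43.0, 55.0, 67.0, 91.0)

HOURS_PER_DAY = 24.0

_ODE_RTOL = 1e-8
_ODE_ATOL = 1e-10


class NoGrowthError(ValueError):
    """Raised when a growth-phase quantity is requested for a non-growing system."""


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails on a given condition."""


@dataclass(frozen=True)
class CRMParams:
    """Rescaled parameter set of the consumer-resource model.

    Parameters
    ----------
    x0_tilde : float
        Initial rescaled functional biomass, mM/day.  Equals the initial
        nitrate consumption rate.
    C0_tilde : float
        Initial rescaled growth-limiting nutrient, mM.
    A0 : float
        Initial nitrate in the growth-permissive (CHL-) arm, mM.
    A0c : float, optional
        Initial nitrate in the growth-arrested (CHL+) arm, mM.  Defaults
        to ``A0``.
    gamma : float
        Maximum per-biomass growth rate, 1/day.
    KA : float
        Nitrate half-saturation constant, mM.  Must be positive.
    KC_tilde : float
        Rescaled nutrient half-saturation constant, mM.  Must be positive.
    """

    x0_tilde: float
    C0_tilde: float
    A0: float = 2.0
    A0c: Optional[float] = None
    gamma: float = DEFAULT_GAMMA
    KA: float = DEFAULT_KA
    KC_tilde: float = DEFAULT_KC

    def __post_init__(self) -> None:
        vals = {
            "x0_tilde": self.x0_tilde,
            "C0_tilde": self.C0_tilde,
            "A0": self.A0,
            "gamma": self.gamma,
            "KA": self.KA,
            "KC_tilde": self.KC_tilde,
        }
        if self.A0c is not None:
            vals["A0c"] = self.A0c
        for name, v in vals.items():
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v!r}")
        if self.KA <= 0:
            raise ValueError("KA must be strictly positive")
        if self.KC_tilde <= 0:
            raise ValueError("KC_tilde must be strictly positive")

    @property
    def a0c(self) -> float:
        """Initial nitrate of the CHL+ arm (falls back to ``A0``)."""
        return self.A0 if self.A0c is None else self.A0c

    @property
    def gamma_C0_tilde(self) -> float:
        """Available limiting nutrient expressed as a rate, mM/day."""
        return self.gamma * self.C0_tilde

    def with_(self, **kwargs) -> "CRMParams":
        return replace(self, **kwargs)


@dataclass
class Trajectory:
    """State of one simulated or measured microcosm over time.

    ``times`` are stored in days (``time_unit`` records the convention);
    nitrate ``A`` is in mM.  ``C_tilde`` and ``x_tilde`` are only present
    for simulated trajectories.
    """

    times: np.ndarray
    A: np.ndarray
    chl: bool
    C_tilde: Optional[np.ndarray] = None
    x_tilde: Optional[np.ndarray] = None
    time_unit: str = "day"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.A.shape:
            raise ValueError("times and A must be 1-d arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation: time_hr, nitrate_mM, chl plus model states."""
        t_hr = self.times * HOURS_PER_DAY if self.time_unit == "day" else self.times
        out = pd.DataFrame(
            {"time_hr": t_hr, "nitrate_mM": self.A, "chl": int(self.chl)}
        )
        if self.C_tilde is not None:
            out["c_tilde_mM"] = self.C_tilde
        if self.x_tilde is not None:
            out["x_tilde_mM_per_day"] = self.x_tilde
        return out


def _validate_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("times must be a 1-d grid with at least two points")
    if not np.isfinite(times).all():
        raise ValueError("times must be finite")
    if times[0] != 0.0:
        raise ValueError("time grid must start at 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return times


def simulate_numeric(params: CRMParams, times: np.ndarray, chl: bool = False) -> Trajectory:
    """Integrate the rescaled model on a time grid (days).

    Uses a stiff-capable adaptive solver (LSODA, rtol 1e-8 / atol 1e-10);
    the Monod terms become mildly stiff near depletion.  Concentrations are
    floored at zero after integration.
    """
    times = _validate_times(times)
    a0 = params.a0c if chl else params.A0
    y0 = [a0, params.C0_tilde, params.x0_tilde]
    ka, kc, gamma = params.KA, params.KC_tilde, params.gamma

    def rhs(t, y):
        A, C, x = max(y[0], 0.0), max(y[1], 0.0), max(y[2], 0.0)
        fa = A / (A + ka)
        fc = C / (C + kc)
        dA = -x * fa
        dC = -x * fc
        dx = 0.0 if chl else gamma * x * fa * fc
        return (dA, dC, dx)

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        y0,
        method="LSODA",
        t_eval=times,
        rtol=_ODE_RTOL,
        atol=_ODE_ATOL,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed (chl={chl}, params={params}): {sol.message}"
        )
    A, C, x = (np.clip(sol.y[i], 0.0, None) for i in range(3))
    return Trajectory(times=times, A=A, chl=chl, C_tilde=C, x_tilde=x)


def growth_stop_time(params: CRMParams) -> float:
    """Time at which biomass growth stops, days.

    ``t* = log(min(A0, C~0) * gamma / x~0 + 1) / gamma``: the moment the
    cumulative consumption ``x~0 (exp(gamma t)-1)/gamma`` equals the scarcer
    initial resource.
    """
    if params.x0_tilde == 0 or params.gamma == 0:
        raise NoGrowthError(
            "growth never stops because it never starts (x0_tilde or gamma is 0)"
        )
    m = min(params.A0, params.C0_tilde)
    return math.log(m * params.gamma / params.x0_tilde + 1.0) / params.gamma


def simulate_analytic(params: CRMParams, times: np.ndarray, chl: bool = False) -> Trajectory:
    """Piecewise closed-form solution, valid for small affinities (K <= 0.1 mM).

    Growth phase (t < t*): ``x~ = x~0 exp(gamma t)`` and both resources fall
    by ``x~0 (exp(gamma t) - 1)/gamma``.  Afterwards consumption is linear at
    the arrested-biomass rate; when the nutrient ran out first this rate is
    ``gamma*C~0 + x~0``.  Concentrations are clipped at exactly zero.  With
    ``chl`` (or ``gamma == 0`` or no biomass) nitrate is simply
    ``max(A0 - x~0 t, 0)``.
    """
    times = _validate_times(times)
    if max(params.KA, params.KC_tilde) > 0.1:
        raise ValueError(
            "analytic solution assumes saturated Monod terms (K <= 0.1 mM); "
            f"got KA={params.KA}, KC_tilde={params.KC_tilde}"
        )
    x0, c0, g = params.x0_tilde, params.C0_tilde, params.gamma
    a0 = params.a0c if chl else params.A0

    if chl or g == 0.0 or x0 == 0.0:
        A = np.clip(a0 - x0 * times, 0.0, None)
        C = np.clip(c0 - x0 * times, 0.0, None)
        x = np.full_like(times, x0)
        return Trajectory(times=times, A=A, chl=chl, C_tilde=C, x_tilde=x)

    tstar = growth_stop_time(params)
    grow = times < tstar
    eat = x0 * (np.expm1(g * np.minimum(times, tstar))) / g  # cumulative uptake
    A = a0 - eat
    C = c0 - eat
    x = x0 * np.exp(g * np.minimum(times, tstar))

    late = ~grow
    if np.any(late):
        dt = times[late] - tstar
        x_star = x0 * math.exp(g * tstar)
        if c0 < a0:
            # nutrient exhausted first: linear nitrate decline at gamma*C0 + x0
            a_star = a0 - c0
            A[late] = a_star - x_star * dt
            C[late] = 0.0
        else:
            # nitrate exhausted first: A stays at 0, nutrient declines linearly
            A[late] = 0.0
            c_star = c0 - min(a0, c0)
            C[late] = c_star - x_star * dt
    A = np.clip(A, 0.0, None)
    C = np.clip(C, 0.0, None)
    return Trajectory(times=times, A=A, chl=chl, C_tilde=C, x_tilde=x)


def model_nitrate(
    params: CRMParams, times: np.ndarray, chl: bool, model: str = "auto"
) -> np.ndarray:
    """Nitrate curve A(t) under the requested solution method.

    ``model`` is one of ``"numeric"``, ``"analytic"`` or ``"auto"`` (analytic
    when both affinities are at the small fixed values used for fitting,
    numeric otherwise — the numeric solver is authoritative whenever the
    affinities matter).
    """
    if model == "auto":
        model = "analytic" if max(params.KA, params.KC_tilde) <= 0.02 else "numeric"
    if model == "analytic":
        return simulate_analytic(params, times, chl=chl).A
    if model == "numeric":
        return simulate_numeric(params, times, chl=chl).A
    raise ValueError(f"unknown model {model!r}")
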