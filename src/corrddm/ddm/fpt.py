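"""First-passage-time densities for the DDM with linearly collapsing bounds.

The decision variable follows ``dX = m dt + dW`` (unit diffusion) from
``X(0) = 0`` between symmetric absorbing bounds ``±(b0 - slope t)``.  The
Fokker-Planck equation for the survivor density is integrated with a
Crank-Nicolson scheme on a fixed spatial grid; the collapsing bound is
handled by shrinking the active window and crediting the mass of newly
excluded cells to the adjacent bound.  The probability flux through each
absorbing edge is recovered exactly from the discrete mass balance of the
implicit step, so ``p_correct + p_error + survival == 1`` to round-off.

A Rannacher start (a few backward-Euler steps) suppresses the oscillations
Crank-Nicolson exhibits with the delta initial condition.

The first-passage density at the *upper* bound is reported as the
correct-choice density, i.e. conditions are parameterized with drift
oriented toward the correct response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .specs import ConditionParams, DDMSpec, condition_params


__all__ = [
    "FirstPassageSolution",
    "solve_first_passage",
    "predicted_rt_distribution",
    "trial_log_densities",
    "ResolutionError",
]

DENSITY_FLOOR = 1e-10  # per second; keeps log-likelihoods finite


class ResolutionError(ValueError):
    """Grid too coarse for the requested bound trajectory."""


@njit(cache=True)
def _cn_fpt(drift, b0, slope, dt, dx, nt, n_rannacher):
    """Integrate the bounded Fokker-Planck equation; return edge fluxes.

    Returns (g_up, g_lo, survival): defective densities (per second) of
    absorption at the upper/lower bound on the time grid ``t_n = n dt``,
    and the probability mass still unabsorbed at the horizon.
    """
    nx_half = int(np.ceil(b0 / dx))
    m = 2 * nx_half + 1
    c = nx_half
    p = np.zeros(m)
    p[c] = 1.0 / dx

    g_up = np.zeros(nt + 1)
    g_lo = np.zeros(nt + 1)

    # spatial operator L = -drift d/dx + 0.5 d2/dx2 (central differences)
    l_m1 = drift / (2.0 * dx) + 0.5 / dx**2
    l_0 = -1.0 / dx**2
    l_p1 = -drift / (2.0 * dx) + 0.5 / dx**2

    lower = np.zeros(m)
    diag = np.zeros(m)
    upper = np.zeros(m)
    rhs = np.zeros(m)
    cp = np.zeros(m)
    dp = np.zeros(m)

    floor = dx  # bound clamped one cell above zero
    hw_prev = nx_half - 1
    survival = 1.0

    for n in range(nt):
        t_next = (n + 1) * dt
        b_next = b0 - slope * t_next

        if b_next <= floor:
            # collapsed bound: force absorption, split by current sign
            mass_up = 0.0
            mass_lo = 0.0
            for i in range(m):
                if i > c:
                    mass_up += p[i]
                elif i < c:
                    mass_lo += p[i]
                else:
                    mass_up += 0.5 * p[i]
                    mass_lo += 0.5 * p[i]
                p[i] = 0.0
            g_up[n + 1] += mass_up * dx / dt
            g_lo[n + 1] += mass_lo * dx / dt
            survival = 0.0
            break

        hw = int(np.ceil(b_next / dx)) - 1
        if hw < 1:
            hw = 1

        # bound moved inward: absorb mass of cells now outside the window
        if hw < hw_prev:
            shr_up = 0.0
            shr_lo = 0.0
            for i in range(c + hw + 1, c + hw_prev + 1):
                shr_up += p[i]
                p[i] = 0.0
            for i in range(c - hw_prev, c - hw):
                shr_lo += p[i]
                p[i] = 0.0
            g_up[n + 1] += shr_up * dx / dt
            g_lo[n + 1] += shr_lo * dx / dt
        hw_prev = hw

        theta = 1.0 if n < n_rannacher else 0.5
        il = c - hw
        iu = c + hw

        a_m1 = -dt * theta * l_m1
        a_0 = 1.0 - dt * theta * l_0
        a_p1 = -dt * theta * l_p1
        om = 1.0 - theta

        p_il_old = p[il]
        p_iu_old = p[iu]

        for i in range(il, iu + 1):
            pm = p[i - 1] if i > il else 0.0
            pp = p[i + 1] if i < iu else 0.0
            rhs[i] = p[i] + dt * om * (l_m1 * pm + l_0 * p[i] + l_p1 * pp)
            lower[i] = a_m1
            diag[i] = a_0
            upper[i] = a_p1

        # Thomas algorithm on [il, iu]
        cp[il] = upper[il] / diag[il]
        dp[il] = rhs[il] / diag[il]
        for i in range(il + 1, iu + 1):
            denom = diag[i] - lower[i] * cp[i - 1]
            cp[i] = upper[i] / denom
            dp[i] = (rhs[i] - lower[i] * dp[i - 1]) / denom
        p[iu] = dp[iu]
        for i in range(iu - 1, il - 1, -1):
            p[i] = dp[i] - cp[i] * p[i + 1]

        # exact discrete outflux through each absorbing edge
        loss_up = dt * l_m1 * (om * p_iu_old + theta * p[iu]) * dx
        loss_lo = dt * l_p1 * (om * p_il_old + theta * p[il]) * dx
        g_up[n + 1] += loss_up / dt
        g_lo[n + 1] += loss_lo / dt

        survival = 0.0
        for i in range(il, iu + 1):
            survival += p[i]
        survival *= dx
        if survival < 1e-10:
            survival = max(survival, 0.0)
            break

    return g_up, g_lo, survival


@dataclass
class FirstPassageSolution:
    """Discretized defective RT densities for the two choice outcomes."""

    t: np.ndarray
    density_correct: np.ndarray
    density_error: np.ndarray
    survival: float

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def p_correct(self) -> float:
        return float(np.sum(self.density_correct) * self.dt)

    @property
    def p_error(self) -> float:
        return float(np.sum(self.density_error) * self.dt)

    def mean_rt(self, which: str = "correct") -> float:
        """Mean absorption time conditional on the given outcome."""
        g = self.density_correct if which == "correct" else self.density_error
        mass = np.sum(g) * self.dt
        if mass <= 0:
            return np.nan
        return float(np.sum(self.t * g) * self.dt / mass)

    def cdf(self, which: str = "correct") -> np.ndarray:
        g = self.density_correct if which == "correct" else self.density_error
        return np.cumsum(g) * self.dt

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "density_correct": self.density_correct,
                "density_error": self.density_error,
            }
        )


def solve_first_passage(
    params: ConditionParams,
    dt: float = 0.005,
    dx: float = 0.005,
    horizon: float = 15.0,
) -> FirstPassageSolution:
    """Defective first-passage densities for one condition's drift and bound."""
    if dt <= 0 or dx <= 0:
        raise ValueError("dt and dx must be positive")
    if params.b0 <= 0:
        raise ValueError("initial bound must be positive")
    if params.slope * dt > dx:
        raise ResolutionError(
            f"bound collapses {params.slope * dt:.4g} per step but cells are "
            f"{dx:.4g} wide; decrease dt or increase dx"
        )
    nt = int(round(horizon / dt))
    g_up, g_lo, survival = _cn_fpt(
        params.drift, params.b0, params.slope, dt, dx, nt, 4
    )
    t = np.arange(nt + 1) * dt
    return FirstPassageSolution(
        t=t,
        density_correct=np.maximum(g_up, 0.0),
        density_error=np.maximum(g_lo, 0.0),
        survival=survival,
    )


def predicted_rt_distribution(
    spec: DDMSpec,
    rho: float,
    evidence_level: str,
    dt: float = 0.005,
    dx: float = 0.005,
    horizon: float = 15.0,
) -> FirstPassageSolution:
    """Predicted RT distribution: first-passage solution shifted by the
    non-decision time and mixed with a uniform lapse component.

    With lapse rate ``lam`` the density becomes
    ``(1 - lam) * g(t - ndt) + lam / (2 * horizon)`` for each choice, i.e.
    lapses are uniform over the horizon and split evenly between choices.
    """
    cp = condition_params(spec, rho, evidence_level)
    sol = solve_first_passage(cp, dt=dt, dx=dx, horizon=horizon)
    shift = int(round(spec.ndt / dt))
    n = len(sol.t)

    def _shift(g):
        out = np.zeros_like(g)
        if shift < n:
            out[shift:] = g[: n - shift]
        return out

    lam = spec.lapse
    unif = lam / (2.0 * horizon)
    return FirstPassageSolution(
        t=sol.t,
        density_correct=(1.0 - lam) * _shift(sol.density_correct) + unif,
        density_error=(1.0 - lam) * _shift(sol.density_error) + unif,
        survival=(1.0 - lam) * sol.survival,
    )


def trial_log_densities(
    sol: FirstPassageSolution,
    rt: np.ndarray,
    correct: np.ndarray,
    ndt: float,
    lapse: float,
    horizon: float = 15.0,
) -> np.ndarray:
    """Log predicted density at each trial's (choice, RT).

    ``sol`` is the *decision-time* solution (no ndt shift, no lapse); the
    shift and lapse mixture are applied analytically here so ``ndt`` need
    not be grid-aligned.  Densities are floored at a small positive value.
    """
    rt = np.asarray(rt, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    td = rt - ndt
    g_c = np.interp(td, sol.t, sol.density_correct, left=0.0, right=0.0)
    g_e = np.interp(td, sol.t, sol.density_error, left=0.0, right=0.0)
    g = np.where(correct, g_c, g_e)
    dens = (1.0 - lapse) * g + lapse / (2.0 * horizon)
    return np.log(np.maximum(dens, DENSITY_FLOOR))
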