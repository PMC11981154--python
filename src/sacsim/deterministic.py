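"""Deterministic analyses: ODE integration, steady states, bifurcation scans,
saddle-node location and the transient Mps1-overexpression protocol.

Unattached kinetochores enter as a continuous external parameter here (the
bifurcation diagrams use fractional values); stochastic attachment dynamics
live in :mod:`sacsim.stochastic`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import network
from .params import (UNIT_MOLECULES, ModelParameters, ModelState, MutantSpec,
                     apply_mutant, checkpoint_off_state, checkpoint_on_state)


@dataclass
class Trajectory:
    """Time-stamped deterministic solution of the eight species."""

    t: np.ndarray                  # minutes
    y: np.ndarray                  # (n_times, 8) species in canonical order
    nUK: np.ndarray                # external kinetochore signal per sample
    unit_system: str = UNIT_MOLECULES

    def state(self, i: int = -1) -> ModelState:
        return ModelState.from_vector(self.y[i], nUK=float(self.nUK[i]),
                                      unit_system=self.unit_system)

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.y, columns=list(network.SPECIES))
        df.insert(0, "time", self.t)
        df["nUK"] = self.nUK
        return df


class IntegrationError(RuntimeError):
    def __init__(self, message: str, time: float):
        super().__init__(f"{message} (t = {time:.3f} min)")
        self.time = time


def _rhs(t, y, params, nuk):
    return network.ode_rhs(y, params, nUK=nuk)


def integrate(state0: ModelState, params: ModelParameters, t_end: float,
              nUK_schedule=None, t_eval=None,
              rtol: float = 1e-9, atol: float = 1e-9,
              mutant: MutantSpec | None = None) -> Trajectory:
    """Integrate the mean-field model with a piecewise-constant kinetochore
    schedule.

    ``nUK_schedule`` may be ``None`` (hold the initial state's nUK), a number,
    or a list of ``(t_start, nUK)`` breakpoints sorted by time.  A time-
    windowed Mps1-synthesis mutant introduces additional breakpoints so every
    segment has constant parameters.
    """
    if state0.unit_system != params.unit_system:
        raise ValueError("state/parameter unit-system mismatch")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if nUK_schedule is None:
        nUK_schedule = [(0.0, state0.nUK)]
    elif np.isscalar(nUK_schedule):
        nUK_schedule = [(0.0, float(nUK_schedule))]

    breaks = sorted({t for t, _ in nUK_schedule} | {0.0, t_end})
    if mutant is not None and mutant.mps1_window is not None:
        breaks = sorted(set(breaks) | set(mutant.mps1_window))
    breaks = [b for b in breaks if 0.0 <= b <= t_end]
    if breaks[-1] < t_end:
        breaks.append(t_end)

    def nuk_at(t):
        val = nUK_schedule[0][1]
        for ts, v in nUK_schedule:
            if ts <= t:
                val = v
        return val

    ts_all, ys_all, nuk_all = [], [], []
    y = state0.vector()
    for a, b in zip(breaks[:-1], breaks[1:]):
        if b <= a:
            continue
        p_seg = params if mutant is None else apply_mutant(params, mutant,
                                                           time=a)
        nuk = nuk_at(a)
        seg_eval = None
        if t_eval is not None:
            seg_eval = [t for t in t_eval if a <= t <= b]
            if not seg_eval or seg_eval[-1] < b:
                seg_eval = (seg_eval or []) + [b]
        sol = solve_ivp(_rhs, (a, b), y, args=(p_seg, nuk), method="LSODA",
                        rtol=rtol, atol=atol, t_eval=seg_eval)
        if not sol.success:
            raise IntegrationError(sol.message, sol.t[-1] if len(sol.t)
                                   else a)
        ts_all.append(sol.t)
        ys_all.append(sol.y.T)
        nuk_all.append(np.full(len(sol.t), nuk))
        y = sol.y[:, -1]

    t = np.concatenate(ts_all)
    keep = np.concatenate(([True], np.diff(t) > 0))
    return Trajectory(t=t[keep], y=np.concatenate(ys_all)[keep],
                      nUK=np.concatenate(nuk_all)[keep],
                      unit_system=params.unit_system)


# -- steady states ----------------------------------------------------------

def _characteristic_flux(y, params, nuk):
    a = network._rates_from_arrays(np.asarray(y, float), nuk, 0, 0, params,
                                   deterministic=True)
    a[21] = 0.0
    return max(np.max(np.abs(a)), 1e-12)


# The APC and Mad moieties are conserved by the dynamics, so the full
# 8-species Jacobian has two exact zero modes and fixed points come in
# conserved-total families.  Root finding and stability analysis therefore
# work in reduced coordinates (C, AC, Mada, Mps1, MC, ACMC) with
# A = Atot - AC - ACMC and Madi = Mtot - Mada - MC - ACMC eliminated.
_REDUCED = [0, 2, 3, 5, 6, 7]  # indices into the canonical species order


def _expand(z, atot, mtot):
    C, AC, Mada, X, MC, ACMC = z
    A = atot - AC - ACMC
    Madi = mtot - Mada - MC - ACMC
    return np.array([C, A, AC, Mada, Madi, X, MC, ACMC])


def _reduced_fun(z, params, nuk, atot, mtot):
    return network.ode_rhs(_expand(z, atot, mtot), params,
                           nUK=nuk)[_REDUCED]


def _polish(y0, params, nuk):
    y0 = np.asarray(y0, float)
    atot = y0[1] + y0[2] + y0[7]
    mtot = y0[3] + y0[4] + y0[6] + y0[7]
    z0 = y0[_REDUCED]
    sol = root(_reduced_fun, z0, args=(params, nuk, atot, mtot),
               method="hybr")
    if not sol.success:
        sol = root(_reduced_fun, z0, args=(params, nuk, atot, mtot),
                   method="lm")
    if not sol.success:
        return None
    y = _expand(sol.x, atot, mtot)
    if np.any(y < -1e-6):
        return None
    return np.clip(y, 0.0, None)


def _reduced_jacobian(y, params, nuk, eps=1e-6):
    y = np.asarray(y, float)
    atot = y[1] + y[2] + y[7]
    mtot = y[3] + y[4] + y[6] + y[7]
    z = y[_REDUCED]
    f0 = _reduced_fun(z, params, nuk, atot, mtot)
    J = np.empty((6, 6))
    for j in range(6):
        h = eps * max(abs(z[j]), 1.0)
        zp = z.copy()
        zp[j] += h
        J[:, j] = (_reduced_fun(zp, params, nuk, atot, mtot) - f0) / h
    return J


def is_stable(y, params, nuk) -> bool:
    """Linear stability on the moiety-conserving manifold."""
    eig = np.linalg.eigvals(_reduced_jacobian(y, params, nuk))
    return bool(np.max(eig.real) < 0.0)


def _settle(y0, params, nuk, t_end=8000.0):
    sol = solve_ivp(_rhs, (0.0, t_end), np.asarray(y0, float),
                    args=(params, nuk), method="LSODA", rtol=1e-9, atol=1e-9)
    return sol.y[:, -1]


def find_steady_states(params: ModelParameters, nUK: float,
                       mad_total_factor: float = 1.0,
                       residual_tol: float = 1e-8):
    """All fixed points at the given kinetochore signal.

    Stable states are found by settling long integrations started from the
    published ON and OFF conditions (and their midpoint) and polishing with a
    damped Newton step; when two stable states coexist the separating
    (unstable) fixed point is located by bisecting the basin boundary along
    the ON-OFF segment in state space.  Returns a list of
    ``(ModelState, stable: bool)`` sorted by increasing APC/C^Cdc20.
    """
    us = params.unit_system
    # the state builders normalize the conserved totals, so all seeds start
    # on the same conserved leaf and their fixed points are comparable
    on0 = checkpoint_on_state(us, mad_total_factor, nUK=nUK).vector()
    off0 = checkpoint_off_state(us, mad_total_factor, nUK=nUK).vector()
    seeds = [on0, off0, 0.5 * (on0 + off0)]
    found: list[np.ndarray] = []
    for seed in seeds:
        y = _settle(seed, params, nUK)
        y = _polish(y, params, nUK)
        if y is None:
            continue
        res = np.linalg.norm(network.ode_rhs(y, params, nUK=nUK))
        if res > residual_tol * _characteristic_flux(y, params, nUK):
            continue
        if not any(np.allclose(y, f, rtol=1e-4, atol=1e-5) for f in found):
            found.append(y)
    if not found:
        raise RuntimeError("no steady state converged from any start")

    stable = [(y, is_stable(y, params, nUK)) for y in found]
    n_stable = sum(s for _, s in stable)
    if n_stable == 2:
        ya, yb = (y for y, s in stable if s)
        lo, hi = 0.0, 1.0
        ref = _settle(ya, params, nUK, t_end=2000.0)

        def basin(lmbda):
            yf = _settle((1 - lmbda) * ya + lmbda * yb, params, nUK,
                         t_end=4000.0)
            return np.linalg.norm(yf - ref) < 0.5 * np.linalg.norm(yb - ya)

        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if basin(mid):
                lo = mid
            else:
                hi = mid
        y_mid = _polish((1 - 0.5 * (lo + hi)) * ya + 0.5 * (lo + hi) * yb,
                        params, nUK)
        if y_mid is not None and not any(
                np.allclose(y_mid, f, rtol=1e-3, atol=1e-3) for f, _ in
                stable):
            res = np.linalg.norm(network.ode_rhs(y_mid, params, nUK=nUK))
            if res <= 1e-6 * _characteristic_flux(y_mid, params, nUK):
                stable.append((y_mid, is_stable(y_mid, params, nUK)))

    out = [(ModelState.from_vector(y, nUK=nUK, unit_system=us), bool(s))
           for y, s in stable]
    out.sort(key=lambda pair: pair[0].AC)
    return out


def on_state_exists(params: ModelParameters, nUK: float,
                    mad_total_factor: float = 1.0) -> bool:
    """Whether the checkpoint-ON attractor (low APC/C^Cdc20) exists.

    Decided by settling from the published ON state: inside the bistable
    window the trajectory stays at low AC, below the saddle node it falls
    onto the OFF branch.
    """
    us = params.unit_system
    y0 = checkpoint_on_state(us, mad_total_factor, nUK=nUK).vector()
    y = _settle(y0, params, nUK)
    half = 0.5 * (params.ac_threshold_native)
    return bool(y[2] < half)


@dataclass
class SaddleNodeResult:
    nUK_saddle: float         # kinetochores, left knee of the ON branch
    bracket: tuple[float, float]
    mutant: MutantSpec = field(default_factory=MutantSpec.wild_type)

    @property
    def resolution(self) -> float:
        return self.bracket[1] - self.bracket[0]


def locate_saddle_node(params: ModelParameters, nUK_lo: float = 0.02,
                       nUK_hi: float = 4.0, tol: float = 0.01,
                       mutant: MutantSpec | None = None) -> SaddleNodeResult:
    """Bisection on existence of the checkpoint-ON fixed point.

    The ON state must exist at ``nUK_hi`` and be absent at ``nUK_lo``.
    """
    mutant = mutant or MutantSpec.wild_type()
    p = apply_mutant(params, mutant)
    mad = mutant.mad_total_factor
    if not on_state_exists(p, nUK_hi, mad):
        raise ValueError(f"no checkpoint-ON state at nUK_hi={nUK_hi}")
    if on_state_exists(p, nUK_lo, mad):
        raise ValueError(f"checkpoint-ON state persists at nUK_lo={nUK_lo}")
    lo, hi = nUK_lo, nUK_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if on_state_exists(p, mid, mad):
            hi = mid
        else:
            lo = mid
    return SaddleNodeResult(nUK_saddle=0.5 * (lo + hi), bracket=(lo, hi),
                            mutant=mutant)


@dataclass
class SteadyStateBranch:
    """Fixed points along an nUK grid, for plotting AC against nUK."""

    nUK_grid: np.ndarray
    states: list[list[tuple[ModelState, bool]]]
    mutant: MutantSpec = field(default_factory=MutantSpec.wild_type)

    def counts(self) -> list[int]:
        return [len(s) for s in self.states]

    def on_unstable_distance(self, i: int) -> float | None:
        """Distance (in AC) between the ON state and the unstable middle
        state at grid point ``i`` -- the model's proxy for checkpoint
        strength (larger distance = harder for fluctuations to escape)."""
        pts = self.states[i]
        stables = [s for s, st in pts if st]
        unstables = [s for s, st in pts if not st]
        if len(stables) < 2 or not unstables:
            return None
        on = min(stables, key=lambda s: s.AC)
        mid = unstables[0]
        return abs(mid.AC - on.AC)

    def to_frame(self):
        import pandas as pd
        rows = []
        for nuk, pts in zip(self.nUK_grid, self.states):
            for st, stable in pts:
                label = "unstable"
                if stable:
                    label = "ON" if st.AC < (
                        0.5 * st.cdc20_total + 1e-12) and st.AC == min(
                        s.AC for s, b in pts if b) else "OFF"
                for sp in network.SPECIES:
                    rows.append(dict(nUK=nuk, species=sp,
                                     value=getattr(st, sp), branch=label,
                                     stable=stable))
        return pd.DataFrame(rows)


def bifurcation_scan(params: ModelParameters, nUK_grid,
                     mutant: MutantSpec | None = None) -> SteadyStateBranch:
    mutant = mutant or MutantSpec.wild_type()
    p = apply_mutant(params, mutant)
    grid = np.asarray(sorted(nUK_grid), dtype=float)
    states = [find_steady_states(p, nuk, mutant.mad_total_factor)
              for nuk in grid]
    return SteadyStateBranch(nUK_grid=grid, states=states, mutant=mutant)


def simulate_pulse(params: ModelParameters, signal_level: float = 10.0,
                   pulse: MutantSpec | None = None,
                   t_end: float = 600.0) -> tuple[Trajectory, str]:
    """Transient Mps1-overexpression protocol.

    Start on the checkpoint-OFF branch at a nonzero activating signal (lack
    of tension), overexpress Mps1 for a time window, and report whether the
    system is captured by the checkpoint-ON attractor and stays there after
    synthesis returns to normal (hysteresis).  Raises if the signal lies
    below the saddle node, where no ON attractor exists to be trapped in.
    """
    pulse = pulse or MutantSpec.mps1_pulse()
    sn = locate_saddle_node(params, tol=0.02)
    if signal_level <= sn.nUK_saddle:
        raise ValueError(
            f"signal level {signal_level} is below the saddle node at "
            f"{sn.nUK_saddle:.2f}: no checkpoint-ON attractor exists")
    state0 = checkpoint_off_state(params.unit_system, nUK=signal_level)
    traj = integrate(state0, params, t_end, nUK_schedule=signal_level,
                     mutant=pulse)
    label = "ON" if traj.y[-1, 2] < 0.5 * params.ac_threshold_native \
        else "OFF"
    return traj, label
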