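"""Reaction network shared by the deterministic and stochastic engines.

The network has 22 reactions: bursty (two-state promoter) synthesis of Cdc20
and Mps1, background turnover, the saturating Mad activation/inactivation
pair, mass-action assembly and disassembly of MCC, APC/C^Cdc20 and APC/C^MCC,
APC/C^MCC self-degradation, and first-order kinetochore attachment.

APC/C^MCC carries two Cdc20 moieties.  Its main degradation channel
(``ACMC -> A + C + Mada``) destroys one Cdc20 and releases the other together
with APC/C and Mad; background degradation (``ACMC -> A + Mada``) destroys
both.  Only this bookkeeping reproduces the published total-Cdc20 values
(40 in arrest, ~222 nM after checkpoint silencing).  Mad released by complex
turnover returns to the *active* pool; returning it to the inactive pool is
incompatible with the published arrest steady state (the required
inactivation flux would be negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (SPECIES, UNIT_MOLECULES, ModelParameters, ModelState)

#: extended state layout used by the simulators
STATE_LAYOUT = SPECIES + ("nUK", "ponCDC20", "ponX")

_I = {name: i for i, name in enumerate(STATE_LAYOUT)}
N_REACTIONS = 22


@dataclass(frozen=True)
class Reaction:
    name: str
    scheme: str
    rate_law: str
    changes: dict[str, int]


REACTIONS: tuple[Reaction, ...] = (
    Reaction("Cdc20 promoter activation", "poffCDC20 -> ponCDC20",
             "konCDC20*poffCDC20", {"ponCDC20": +1}),
    Reaction("Cdc20 promoter inactivation", "ponCDC20 -> poffCDC20",
             "koffCDC20*ponCDC20", {"ponCDC20": -1}),
    Reaction("Cdc20 synthesis", "ponCDC20 -> C + ponCDC20",
             "ksynCDC20*ponCDC20", {"C": +1}),
    Reaction("Mps1 promoter activation", "poffX -> ponX",
             "konX*poffX", {"ponX": +1}),
    Reaction("Mps1 promoter inactivation", "ponX -> poffX",
             "koffX*ponX", {"ponX": -1}),
    Reaction("Mps1 synthesis", "ponX -> Mps1 + ponX",
             "ksynX*ponX", {"Mps1": +1}),
    Reaction("Cdc20 background degradation", "C -> 0",
             "kdegBG*C", {"C": -1}),
    Reaction("Mps1 degradation", "Mps1 -> 0",
             "kdegX*Mps1*AC", {"Mps1": -1}),
    Reaction("Mps1 background degradation", "Mps1 -> 0",
             "kdegBGX*Mps1", {"Mps1": -1}),
    Reaction("Mad activation", "Madi -> Mada",
             "kact*Mps1*signal(nUK)*Madi/(J+Madi)",
             {"Madi": -1, "Mada": +1}),
    Reaction("Mad inactivation", "Mada -> Madi",
             "vinact*Mada/(Jinact+Mada)", {"Mada": -1, "Madi": +1}),
    Reaction("MCC formation", "Mada + C -> MC",
             "kassMC*Mada*C", {"Mada": -1, "C": -1, "MC": +1}),
    Reaction("MCC dissociation", "MC -> Mada + C",
             "kdissMC*MC", {"MC": -1, "Mada": +1, "C": +1}),
    Reaction("APC/C^Cdc20 formation", "A + C -> AC",
             "kassAC*A*C", {"A": -1, "C": -1, "AC": +1}),
    Reaction("APC/C^Cdc20 dissociation", "AC -> A + C",
             "kdissAC*AC", {"AC": -1, "A": +1, "C": +1}),
    Reaction("APC/C^MCC formation", "MC + AC -> ACMC",
             "kassACMC*MC*AC", {"MC": -1, "AC": -1, "ACMC": +1}),
    Reaction("APC/C^MCC dissociation", "ACMC -> MC + AC",
             "kdissACMC*ACMC", {"ACMC": -1, "MC": +1, "AC": +1}),
    Reaction("APC/C^MCC degradation", "ACMC -> A + C + Mada",
             "kdeg*ACMC", {"ACMC": -1, "A": +1, "C": +1, "Mada": +1}),
    Reaction("MCC background degradation", "MC -> Mada",
             "kdegBG*MC", {"MC": -1, "Mada": +1}),
    Reaction("APC/C^Cdc20 background degradation", "AC -> A",
             "kdegBG*AC", {"AC": -1, "A": +1}),
    Reaction("APC/C^MCC background degradation", "ACMC -> A + Mada",
             "kdegBG*ACMC", {"ACMC": -1, "A": +1, "Mada": +1}),
    Reaction("Kinetochore attachment", "nUK -> 0",
             "katt*nUK", {"nUK": -1}),
)


def stoichiometry_matrix() -> np.ndarray:
    """Column j holds the state change of reaction j (extended layout)."""
    S = np.zeros((len(STATE_LAYOUT), N_REACTIONS), dtype=int)
    for j, rx in enumerate(REACTIONS):
        for name, delta in rx.changes.items():
            S[_I[name], j] = delta
    return S


STOICHIOMETRY = stoichiometry_matrix()

#: moiety composition vectors over the molecular species
APC_MOIETY = np.array([0, 1, 1, 0, 0, 0, 0, 1], dtype=float)
MAD_MOIETY = np.array([0, 0, 0, 1, 1, 0, 1, 1], dtype=float)
CDC20_MOIETY = np.array([1, 0, 1, 0, 0, 0, 1, 2], dtype=float)


def checkpoint_signal(nUK, params: ModelParameters):
    """Saturating checkpoint-activating signal generated by unattached
    kinetochores: kprime * nUK / (Jn + nUK).

    Monotone in ``nUK`` and bounded by ``kprime``; zero when every
    kinetochore is attached (tension-free arrest protocols feed a nonzero
    effective ``nUK`` instead).
    """
    nUK = np.asarray(nUK, dtype=float)
    if np.any(nUK < 0):
        raise ValueError("nUK must be nonnegative")
    out = params.kprime * nUK / (params.Jn + nUK)
    return out if out.ndim else float(out)


def _rates_from_arrays(y8, nUK, pon_c, pon_x, p: ModelParameters,
                       deterministic: bool) -> np.ndarray:
    C, A, AC, Mada, Madi, X, MC, ACMC = y8
    s = p.kprime * nUK / (p.Jn + nUK)
    a = np.empty(N_REACTIONS)
    if deterministic:
        duty = p.synthesis_duty_factor
        a[0] = a[1] = a[3] = a[4] = 0.0
        a[2] = p.ksynCDC20 * duty
        a[5] = p.ksynX * duty
    else:
        a[0] = p.konCDC20 * (1.0 - pon_c)
        a[1] = p.koffCDC20 * pon_c
        a[2] = p.ksynCDC20 * pon_c
        a[3] = p.konX * (1.0 - pon_x)
        a[4] = p.koffX * pon_x
        a[5] = p.ksynX * pon_x
    a[6] = p.kdegBG * C
    a[7] = p.kdegX * X * AC
    a[8] = p.kdegBGX * X
    a[9] = p.kact * X * s * Madi / (p.J + Madi)
    a[10] = p.vinact * Mada / (p.Jinact + Mada)
    a[11] = p.kassMC * Mada * C
    a[12] = p.kdissMC * MC
    a[13] = p.kassAC * A * C
    a[14] = p.kdissAC * AC
    a[15] = p.kassACMC * MC * AC
    a[16] = p.kdissACMC * ACMC
    a[17] = p.kdeg * ACMC
    a[18] = p.kdegBG * MC
    a[19] = p.kdegBG * AC
    a[20] = p.kdegBG * ACMC
    a[21] = p.katt * nUK
    return a


def reaction_rates(state: ModelState, params: ModelParameters,
                   attachment: bool = False) -> np.ndarray:
    """Per-reaction rate (propensity) vector at ``state``.

    In stochastic mode (promoter states set on the state) synthesis is gated
    by the promoters; in deterministic mode promoter switching rates are zero
    and synthesis is the effective rate.  The attachment channel is only
    active when ``attachment`` is requested.
    """
    if state.unit_system != params.unit_system:
        raise ValueError(
            f"state is in {state.unit_system!r} but parameters are in "
            f"{params.unit_system!r}")
    deterministic = state.ponCDC20 is None
    pon_c = 0 if state.ponCDC20 is None else state.ponCDC20
    pon_x = 0 if state.ponX is None else state.ponX
    a = _rates_from_arrays(state.vector(), state.nUK, pon_c, pon_x,
                           params, deterministic)
    if not attachment:
        a[21] = 0.0
    return a


def ode_rhs(state: ModelState | np.ndarray, params: ModelParameters,
            nUK: float | None = None) -> np.ndarray:
    """Mean-field time derivative of the eight molecular species.

    ``nUK`` is treated as an external bifurcation parameter (no attachment
    term); promoter states must not be set.  The APC and Mad moiety sums of
    the returned derivative are exactly zero by construction.
    """
    if isinstance(state, ModelState):
        if state.ponCDC20 is not None or state.ponX is not None:
            raise ValueError("ode_rhs is deterministic; promoter states must "
                             "be unset")
        y8 = state.vector()
        if nUK is None:
            nUK = state.nUK
    else:
        y8 = np.asarray(state, dtype=float)
        if nUK is None:
            raise ValueError("nUK required when passing a bare vector")
    a = _rates_from_arrays(y8, nUK, 0, 0, params, deterministic=True)
    a[21] = 0.0
    return STOICHIOMETRY[:8].astype(float) @ a


def params_array(p: ModelParameters) -> np.ndarray:
    """Flat constant array consumed by the numba SSA kernel."""
    return np.array([
        p.kdeg, p.ksynCDC20, p.kassMC, p.kdissMC, p.kassAC, p.kdissAC,
        p.kassACMC, p.kdissACMC, p.kdegBG, p.kact, p.vinact, p.Jinact,
        p.ksynX, p.kdegX, p.kdegBGX, p.katt, p.kprime, p.Jn, p.J,
        p.konCDC20, p.koffCDC20, p.konX, p.koffX,
    ], dtype=np.float64)
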