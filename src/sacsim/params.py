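"""Parameters, states and mutant transforms for the mitotic-checkpoint model.

The model describes the spindle assembly checkpoint (SAC) of budding yeast as
a bistable switch built from eight molecular species: free Cdc20 (``C``), free
APC/C (``A``), the active ligase APC/C^Cdc20 (``AC``), active and inactive Mad
pools (``Mada``, ``Madi``), the checkpoint kinase Mps1, the free mitotic
checkpoint complex (``MC``) and the inhibited assembly APC/C^MCC (``ACMC``).
Unattached kinetochores (``nUK``) drive Mad activation through a saturating
signal; APC/C^Cdc20 degrades Mps1, closing a double-negative (i.e. positive)
feedback loop.

Two unit systems are supported.  The canonical parameterization is expressed
in molecules per nucleus and is used verbatim by the stochastic engine; the
mean field of the same system, rescaled to nanomolar through the nuclear
volume factor (2.5 molecules per nM), drives the deterministic analyses.  A
third, "as printed" nanomolar set is kept for serialization completeness; its
bimolecular constants are not volume-consistent with the molecule column and
it does not reproduce the reference steady states (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

#: molecules per nanomolar in the haploid yeast nucleus (~4.15 fL):
#: 40 nM of APC/C corresponds to 100 molecules.  Used for reporting and
#: threshold conversion only, never to convert rate constants between the
#: printed columns.
MOLECULES_PER_NM = 2.5

#: APC/C^Cdc20 level marking anaphase entry, in molecules per cell.
AC_THRESHOLD_MOLECULES = 80.0

UNIT_MOLECULES = "stochastic-molecules"
UNIT_NM = "deterministic-nM"

#: ordered molecular species of the network
SPECIES = ("C", "A", "AC", "Mada", "Madi", "Mps1", "MC", "ACMC")

_RATE_FIELDS = (
    "kdeg", "ksynCDC20", "kassMC", "kDMC", "kassAC", "kDAC", "kassACMC",
    "kDACMC", "kdegBG", "kact", "kinact", "ksynX", "kdegX", "kdegBGX",
    "katt", "kprime", "Jn", "J", "vinact", "Jinact",
    "konCDC20", "koffCDC20", "konX", "koffX",
)


@dataclass(frozen=True)
class ModelParameters:
    """Rate and saturation constants of the checkpoint network.

    All first-order rates are in 1/min.  Concentration-bearing quantities
    (synthesis rates, KD values, Michaelis constants, ``vinact``) are in the
    active unit system: nM for ``deterministic-nM``, molecules/nucleus for
    ``stochastic-molecules``.  Bimolecular association constants are per
    (conc x min).

    ``vinact`` is the zero-order capacity of the constitutive Mad-inactivating
    activity (conc/min) and ``Jinact`` its Michaelis constant; both were
    reconstructed by balancing the published checkpoint-ON and checkpoint-OFF
    steady states (``vinact`` is numerically ``kinact`` x 4900 in each
    column's own units).
    """

    kdeg: float          # Cdc20 degradation inside APC/C^MCC, 1/min
    ksynCDC20: float     # Cdc20 synthesis, conc/min (promoter-gated in SSA)
    kassMC: float        # Mada + C -> MC association, 1/(conc min)
    kDMC: float          # MC dissociation constant, conc
    kassAC: float        # A + C -> AC association, 1/(conc min)
    kDAC: float          # AC dissociation constant, conc
    kassACMC: float      # MC + AC -> ACMC association, 1/(conc min)
    kDACMC: float        # ACMC dissociation constant, conc
    kdegBG: float        # background degradation of C, MC, AC, ACMC, 1/min
    kact: float          # Mad activation rate constant, 1/min per Mps1
    kinact: float        # printed Mad inactivation constant, 1/(conc min)
    ksynX: float         # Mps1 synthesis, conc/min (promoter-gated in SSA)
    kdegX: float         # APC/C^Cdc20-mediated Mps1 degradation, 1/(conc min)
    kdegBGX: float       # Mps1 background degradation, 1/min
    katt: float          # kinetochore attachment rate, 1/min
    kprime: float        # amplitude of the unattached-kinetochore signal
    Jn: float            # half-saturation of the signal, kinetochores
    J: float             # Michaelis constant for Mad activation, conc
    vinact: float        # Mad inactivation capacity, conc/min
    Jinact: float        # Michaelis constant for Mad inactivation, conc
    konCDC20: float = 1.0    # CDC20 promoter ON switching, 1/min
    koffCDC20: float = 0.1   # CDC20 promoter OFF switching, 1/min
    konX: float = 1.0        # MPS1 promoter ON switching, 1/min
    koffX: float = 0.1       # MPS1 promoter OFF switching, 1/min
    ac_threshold: float = AC_THRESHOLD_MOLECULES  # anaphase threshold on AC
    unit_system: str = UNIT_MOLECULES
    synthesis_duty_factor: float = 1.0  # optional kon/(kon+koff) multiplier
                                        # for deterministic synthesis

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name!r} must be >= 0")
        if self.unit_system not in (UNIT_MOLECULES, UNIT_NM):
            raise ValueError(f"unknown unit system {self.unit_system!r}")

    # -- derived dissociation rates (kdiss = KD x kass) ---------------------
    @property
    def kdissMC(self) -> float:
        return self.kDMC * self.kassMC

    @property
    def kdissAC(self) -> float:
        return self.kDAC * self.kassAC

    @property
    def kdissACMC(self) -> float:
        return self.kDACMC * self.kassACMC

    @property
    def promoter_duty_cycle(self) -> float:
        """Stationary fraction of time a bursty promoter spends ON."""
        return self.konCDC20 / (self.konCDC20 + self.koffCDC20)

    @property
    def ac_threshold_native(self) -> float:
        """Anaphase threshold expressed in the active unit system."""
        if self.unit_system == UNIT_MOLECULES:
            return self.ac_threshold
        return self.ac_threshold / MOLECULES_PER_NM

    # -- factories ----------------------------------------------------------
    @classmethod
    def molecules(cls, **overrides) -> "ModelParameters":
        """Canonical molecule-unit parameter set (wild type)."""
        base = dict(
            kdeg=1.3, ksynCDC20=4.2e1, kassMC=2.2e-2, kDMC=1.4,
            kassAC=1.1e-1, kDAC=8.5, kassACMC=5.8e-1, kDACMC=1.1,
            kdegBG=3.8e-2, kact=2.4e-2, kinact=6.7e-3, ksynX=1.1e1,
            kdegX=2.4e-2, kdegBGX=6.2e-2, katt=3.0e-2, kprime=1.7e2,
            Jn=4.0e-1, J=2.1, vinact=6.7e-3 * 4900.0, Jinact=1.15,
            unit_system=UNIT_MOLECULES,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def nanomolar(cls, **overrides) -> "ModelParameters":
        """Volume-consistent nM parameter set (the molecule-unit mean field
        rescaled by 2.5 molecules/nM; dynamically equivalent)."""
        v = MOLECULES_PER_NM
        m = cls.molecules()
        base = dict(
            kdeg=m.kdeg, ksynCDC20=m.ksynCDC20 / v, kassMC=m.kassMC * v,
            kDMC=m.kDMC / v, kassAC=m.kassAC * v, kDAC=m.kDAC / v,
            kassACMC=m.kassACMC * v, kDACMC=m.kDACMC / v, kdegBG=m.kdegBG,
            kact=m.kact, kinact=2.7e-3, ksynX=m.ksynX / v, kdegX=m.kdegX * v,
            kdegBGX=m.kdegBGX, katt=m.katt, kprime=m.kprime, Jn=m.Jn,
            J=m.J / v, vinact=m.vinact / v, Jinact=m.Jinact / v,
            unit_system=UNIT_NM,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def nanomolar_printed(cls, **overrides) -> "ModelParameters":
        """The nM column exactly as published.

        Kept for the record: its bimolecular constants are not
        volume-consistent with the molecule column, it does not balance the
        published nM steady states, and the deterministic analyses do not use
        it (see docs/methods.md).
        """
        base = dict(
            kdeg=1.3, ksynCDC20=1.7e1, kassMC=8.8e-3, kDMC=5.6e-1,
            kassAC=4.4e-2, kDAC=3.4, kassACMC=2.3e-1, kDACMC=4.4e-1,
            kdegBG=3.8e-2, kact=2.4e-2, kinact=2.7e-3, ksynX=4.4,
            kdegX=9.6e-3, kdegBGX=6.2e-2, katt=3.0e-2, kprime=1.7e2,
            Jn=4.0e-1, J=8.4e-1, vinact=2.7e-3 * 4900.0,
            Jinact=1.15 / MOLECULES_PER_NM, unit_system=UNIT_NM,
        )
        base.update(overrides)
        return cls(**base)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        path.write_text(text)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)


@dataclass
class ModelState:
    """Copy numbers (or concentrations) of the eight species plus the
    kinetochore count and, in stochastic mode, the two promoter states."""

    C: float
    A: float
    AC: float
    Mada: float
    Madi: float
    Mps1: float
    MC: float
    ACMC: float
    nUK: float = 0.0
    ponCDC20: int | None = None
    ponX: int | None = None
    unit_system: str = UNIT_MOLECULES

    def __post_init__(self) -> None:
        for name in SPECIES:
            if getattr(self, name) < 0:
                raise ValueError(f"species {name} must be nonnegative")
        if self.nUK < 0:
            raise ValueError("nUK must be nonnegative")
        for p in (self.ponCDC20, self.ponX):
            if p is not None and p not in (0, 1):
                raise ValueError("promoter states must be 0 or 1")

    def vector(self) -> np.ndarray:
        """Species copy numbers in canonical order."""
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_vector(cls, y, nUK=0.0, unit_system=UNIT_MOLECULES,
                    ponCDC20=None, ponX=None) -> "ModelState":
        y = np.asarray(y, dtype=float)
        # integrators legitimately return -0.0 / O(atol) negative dust
        if np.any(y < -1e-6):
            raise ValueError("species vector has negative components")
        y = np.clip(y, 0.0, None)
        return cls(*[float(v) for v in y], nUK=nUK, ponCDC20=ponCDC20,
                   ponX=ponX, unit_system=unit_system)

    # conserved moieties ----------------------------------------------------
    @property
    def apc_total(self) -> float:
        return self.A + self.AC + self.ACMC

    @property
    def mad_total(self) -> float:
        return self.Madi + self.Mada + self.MC + self.ACMC

    @property
    def cdc20_total(self) -> float:
        """C + MC + AC + 2 ACMC: APC/C^MCC carries two Cdc20 moieties (one
        APC-bound, one inside the MCC)."""
        return self.C + self.MC + self.AC + 2.0 * self.ACMC


def _reference_state(y, unit_system, mad_total_factor, nUK, normalize):
    apc_ref = 100.0 if unit_system == UNIT_MOLECULES else 40.0
    mad_ref = (175.0 if unit_system == UNIT_MOLECULES else 70.0) \
        * mad_total_factor
    st = ModelState(*y, nUK=nUK, unit_system=unit_system)
    st.Madi += (175.0 if unit_system == UNIT_MOLECULES else 70.0) \
        * (mad_total_factor - 1.0)
    if normalize:
        # the published per-species values are rounded and their sums can
        # miss the published conserved totals by a molecule or two; absorb
        # the difference into the free pools so every run starts on the
        # canonical conserved leaf
        st.A = max(st.A + apc_ref - st.apc_total, 0.0)
        st.Madi = max(st.Madi + mad_ref - st.mad_total, 0.0)
    return st


def checkpoint_on_state(unit_system: str = UNIT_MOLECULES,
                        mad_total_factor: float = 1.0,
                        nUK: float = 10.0,
                        normalize_totals: bool = True) -> ModelState:
    """Published checkpoint-ON initial condition (arrest with unattached
    kinetochores).  Extra Mad from overexpression is added to the inactive
    pool.  With ``normalize_totals`` (default) the free APC and inactive Mad
    pools are adjusted so the conserved totals equal the published 100/175
    molecules (40/70 nM) exactly; pass ``False`` for the verbatim column."""
    if unit_system == UNIT_MOLECULES:
        y = [13, 45, 25, 140, 2, 17, 4, 29]
    else:
        y = [5.2, 18, 10, 56, 0.8, 6.8, 1.6, 11.6]
    return _reference_state(y, unit_system, mad_total_factor, nUK,
                            normalize_totals)


def checkpoint_off_state(unit_system: str = UNIT_MOLECULES,
                         mad_total_factor: float = 1.0,
                         nUK: float = 10.0,
                         normalize_totals: bool = True) -> ModelState:
    """Published checkpoint-OFF initial condition (high APC/C^Cdc20)."""
    if unit_system == UNIT_MOLECULES:
        y = [440, 2, 82, 2, 156, 6, 0, 16]
    else:
        y = [176, 0.8, 32.8, 0.8, 62.4, 2.4, 0, 6.4]
    return _reference_state(y, unit_system, mad_total_factor, nUK,
                            normalize_totals)


@dataclass(frozen=True)
class MutantSpec:
    """Multiplicative perturbations implementing the experimental strains.

    ``kassAC_factor`` scales APC/C-Cdc20 association (the APC-A phospho-site
    mutant; dissociation rate held fixed, so KD rises), ``mad_total_factor``
    scales the conserved Mad pool (GAL1-driven Mad2 overexpression; the extra
    protein starts inactive), and ``mps1_synthesis_factor`` scales Mps1
    synthesis inside an optional time window (transient overexpression).
    """

    kassAC_factor: float = 1.0
    mad_total_factor: float = 1.0
    mps1_synthesis_factor: float = 1.0
    mps1_window: tuple[float, float] | None = None  # minutes (start, end)
    name: str = "wt"

    def __post_init__(self) -> None:
        for f in (self.kassAC_factor, self.mad_total_factor,
                  self.mps1_synthesis_factor):
            if f <= 0:
                raise ValueError("mutant factors must be positive")
        if self.mps1_window is not None:
            start, end = self.mps1_window
            if not start < end:
                raise ValueError("mps1 window start must precede end")

    @classmethod
    def wild_type(cls) -> "MutantSpec":
        return cls()

    @classmethod
    def apc_a(cls, factor: float = 0.65) -> "MutantSpec":
        return cls(kassAC_factor=factor, name=f"apc-a-{factor:g}")

    @classmethod
    def gal1_mad2(cls, factor: float = 1.25) -> "MutantSpec":
        return cls(mad_total_factor=factor, name=f"gal1-mad2-{factor:g}")

    @classmethod
    def mps1_pulse(cls, factor: float = 3.0,
                   window: tuple[float, float] = (0.0, 60.0)) -> "MutantSpec":
        return cls(mps1_synthesis_factor=factor, mps1_window=window,
                   name=f"mps1-pulse-{factor:g}x")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["mps1_window"] is not None:
            d["mps1_window"] = list(d["mps1_window"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MutantSpec":
        d = dict(d)
        if d.get("mps1_window") is not None:
            d["mps1_window"] = tuple(d["mps1_window"])
        return cls(**d)


def apply_mutant(params: ModelParameters, spec: MutantSpec,
                 time: float | None = None) -> ModelParameters:
    """Return parameters with the mutant transform applied.

    ``kassAC`` is scaled while the dissociation *rate* is preserved (KD
    rescaled accordingly): the mutant is impaired in association, not helped
    in dissociation, and keeping KD fixed would leave the bifurcation diagram
    unchanged.  The Mad-pool factor acts on initial conditions, not on the
    parameters, and is handled by the state builders.  The Mps1-synthesis
    factor applies only inside its window when ``time`` is given (and always
    when the spec has no window).
    """
    p = params
    if spec.kassAC_factor != 1.0:
        kdiss_wt = p.kdissAC
        new_kass = p.kassAC * spec.kassAC_factor
        p = replace(p, kassAC=new_kass, kDAC=kdiss_wt / new_kass)
    fac = spec.mps1_synthesis_factor
    if fac != 1.0:
        if spec.mps1_window is not None:
            if time is None:
                fac = 1.0  # windowed overexpression needs a time point
            else:
                start, end = spec.mps1_window
                if not (start <= time < end):
                    fac = 1.0
        if fac != 1.0:
            p = replace(p, ksynX=p.ksynX * fac)
    return p


def export_reaction_table(path: str | Path | None = None) -> str:
    """Human-readable table of the reaction network (mirrors the model's
    published reaction list)."""
    from . import network

    lines = [f"{'#':>2}  {'name':<34} {'reaction':<28} rate law"]
    for i, rx in enumerate(network.REACTIONS, 1):
        lines.append(f"{i:>2}  {rx.name:<34} {rx.scheme:<28} {rx.rate_law}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
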