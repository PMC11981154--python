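"""Exact stochastic simulation of the checkpoint network in molecule units.

The direct-method SSA samples the jump process of the 22-reaction network,
including two-state (bursty) promoters for Cdc20 and Mps1 and, in washout
mode, first-order kinetochore attachment.  Copy numbers are of order 10^2,
so no leaping approximation is used.  Escape from the checkpoint-ON state
("adaptation") is detected as the first passage of APC/C^Cdc20 above the
anaphase threshold; the kinetochore count at that moment distinguishes
adaptation (nUK > 0) from checkpoint satisfaction (nUK = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

from . import network
from .params import (UNIT_MOLECULES, ModelParameters, ModelState, MutantSpec,
                     apply_mutant, checkpoint_off_state, checkpoint_on_state)

# state layout inside the kernel:
# 0:C 1:A 2:AC 3:Mada 4:Madi 5:X 6:MC 7:ACMC 8:nUK 9:ponC 10:ponX


@njit(cache=True)
def _ssa_core(seed, y0, par, t_max, attach, threshold, stop_at_cross,
              xsyn_factor, xwin_start, xwin_end, sample_dt, max_events):
    (kdeg, ksynC, kassMC, kdissMC, kassAC, kdissAC, kassACMC, kdissACMC,
     kdegBG, kact, vinact, Jinact, ksynX, kdegX, kdegBGX, katt, kprime,
     Jn, J, konC, koffC, konX, koffX) = (
        par[0], par[1], par[2], par[3], par[4], par[5], par[6], par[7],
        par[8], par[9], par[10], par[11], par[12], par[13], par[14],
        par[15], par[16], par[17], par[18], par[19], par[20], par[21],
        par[22])
    np.random.seed(seed)
    y = y0.astype(np.float64).copy()
    n_samples = int(t_max / sample_dt) + 1
    samples = np.zeros((n_samples, 11), dtype=np.float64)
    samples[0] = y
    next_sample = 1
    t = 0.0
    t_cross = -1.0
    nuk_at_cross = -1.0
    t_attached = -1.0
    a = np.zeros(22)
    events = 0
    while t < t_max and events < max_events:
        C, A, AC = y[0], y[1], y[2]
        Mada, Madi, X = y[3], y[4], y[5]
        MC, ACMC, nuk = y[6], y[7], y[8]
        ponC, ponX = y[9], y[10]
        s = kprime * nuk / (Jn + nuk)
        xs = ksynX
        if xwin_start <= t < xwin_end:
            xs = ksynX * xsyn_factor
        a[0] = konC * (1.0 - ponC)
        a[1] = koffC * ponC
        a[2] = ksynC * ponC
        a[3] = konX * (1.0 - ponX)
        a[4] = koffX * ponX
        a[5] = xs * ponX
        a[6] = kdegBG * C
        a[7] = kdegX * X * AC
        a[8] = kdegBGX * X
        a[9] = kact * X * s * Madi / (J + Madi)
        a[10] = vinact * Mada / (Jinact + Mada)
        a[11] = kassMC * Mada * C
        a[12] = kdissMC * MC
        a[13] = kassAC * A * C
        a[14] = kdissAC * AC
        a[15] = kassACMC * MC * AC
        a[16] = kdissACMC * ACMC
        a[17] = kdeg * ACMC
        a[18] = kdegBG * MC
        a[19] = kdegBG * AC
        a[20] = kdegBG * ACMC
        a[21] = katt * nuk if attach else 0.0
        total = 0.0
        for i in range(22):
            total += a[i]
        if total <= 0.0:
            break
        t_next = t - math.log(np.random.random()) / total
        while next_sample < n_samples and next_sample * sample_dt <= t_next:
            samples[next_sample] = y
            next_sample += 1
        t = t_next
        if t > t_max:
            break
        events += 1
        r = np.random.random() * total
        k = 0
        cum = a[0]
        while cum < r and k < 21:
            k += 1
            cum += a[k]
        if k == 0:
            y[9] = 1.0
        elif k == 1:
            y[9] = 0.0
        elif k == 2:
            y[0] += 1.0
        elif k == 3:
            y[10] = 1.0
        elif k == 4:
            y[10] = 0.0
        elif k == 5:
            y[5] += 1.0
        elif k == 6:
            y[0] -= 1.0
        elif k == 7:
            y[5] -= 1.0
        elif k == 8:
            y[5] -= 1.0
        elif k == 9:
            y[4] -= 1.0
            y[3] += 1.0
        elif k == 10:
            y[3] -= 1.0
            y[4] += 1.0
        elif k == 11:
            y[3] -= 1.0
            y[0] -= 1.0
            y[6] += 1.0
        elif k == 12:
            y[6] -= 1.0
            y[3] += 1.0
            y[0] += 1.0
        elif k == 13:
            y[1] -= 1.0
            y[0] -= 1.0
            y[2] += 1.0
        elif k == 14:
            y[2] -= 1.0
            y[1] += 1.0
            y[0] += 1.0
        elif k == 15:
            y[6] -= 1.0
            y[2] -= 1.0
            y[7] += 1.0
        elif k == 16:
            y[7] -= 1.0
            y[6] += 1.0
            y[2] += 1.0
        elif k == 17:
            y[7] -= 1.0
            y[1] += 1.0
            y[0] += 1.0
            y[3] += 1.0
        elif k == 18:
            y[6] -= 1.0
            y[3] += 1.0
        elif k == 19:
            y[2] -= 1.0
            y[1] += 1.0
        elif k == 20:
            y[7] -= 1.0
            y[1] += 1.0
            y[3] += 1.0
        elif k == 21:
            y[8] -= 1.0
            if y[8] <= 0.0 and t_attached < 0.0:
                t_attached = t
        if t_cross < 0.0 and y[2] >= threshold:
            t_cross = t
            nuk_at_cross = y[8]
            if stop_at_cross:
                break
    while next_sample < n_samples and next_sample * sample_dt <= \
            min(t, t_max):
        samples[next_sample] = y
        next_sample += 1
    # hold the final state over any remaining grid points (absorbing or
    # early-terminated runs)
    for i in range(next_sample, n_samples):
        samples[i] = y
    return samples, t_cross, nuk_at_cross, t_attached


@dataclass(frozen=True)
class ProtocolSpec:
    """One in-silico experiment.

    ``arrest`` holds nUK fixed (the attachment channel never fires);
    ``washout`` enables attachment from t = 0; ``pulse`` starts from the
    checkpoint-OFF state and transiently overexpresses Mps1.
    """

    mode: str = "arrest"               # arrest | washout | pulse
    nUK0: int = 10
    t_max: float | None = None         # minutes; per-mode default if None
    initial: str = "on"                # on | off | custom
    mutant: MutantSpec = field(default_factory=MutantSpec.wild_type)
    katt: float | None = None          # override attachment rate, 1/min
    seed: int = 0
    sample_dt: float = 1.0             # trajectory output grid, minutes
    stop_at_cross: bool = False

    _DEFAULT_TMAX = {"arrest": 700.0, "washout": 960.0, "pulse": 600.0}

    def __post_init__(self):
        if self.mode not in self._DEFAULT_TMAX:
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.nUK0 < 0 or self.nUK0 != int(self.nUK0):
            raise ValueError("nUK0 must be a nonnegative integer")

    @property
    def horizon(self) -> float:
        return self.t_max if self.t_max is not None else \
            self._DEFAULT_TMAX[self.mode]

    @property
    def attachment_enabled(self) -> bool:
        return self.mode == "washout"


@dataclass
class StochasticTrajectory:
    """Grid-sampled sample path plus exact first-passage metadata."""

    t: np.ndarray
    y: np.ndarray                  # (n, 11) extended state layout
    t_cross: float | None
    nUK_at_cross: int | None
    t_all_attached: float | None
    seed: int
    protocol: ProtocolSpec

    @property
    def species(self) -> np.ndarray:
        return self.y[:, :8]

    @property
    def AC(self) -> np.ndarray:
        return self.y[:, 2]

    @property
    def nUK(self) -> np.ndarray:
        return self.y[:, 8]

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.y, columns=list(network.STATE_LAYOUT))
        df.insert(0, "time", self.t)
        return df


def _initial_vector(protocol: ProtocolSpec, params: ModelParameters,
                    custom: ModelState | None = None) -> np.ndarray:
    mad = protocol.mutant.mad_total_factor
    if protocol.initial == "custom":
        if custom is None:
            raise ValueError("custom initial condition not provided")
        st = custom
    elif protocol.initial == "off" or protocol.mode == "pulse":
        st = checkpoint_off_state(UNIT_MOLECULES, mad, nUK=protocol.nUK0)
    else:
        st = checkpoint_on_state(UNIT_MOLECULES, mad, nUK=protocol.nUK0)
    y0 = np.empty(11)
    y0[:8] = np.round(st.vector())
    y0[8] = protocol.nUK0
    y0[9] = 1.0   # promoters start ON
    y0[10] = 1.0
    return y0


def ssa_run(protocol: ProtocolSpec, params: ModelParameters,
            custom_initial: ModelState | None = None,
            max_events: int = 50_000_000) -> StochasticTrajectory:
    """One statistically exact sample path of the jump process."""
    if params.unit_system != UNIT_MOLECULES:
        raise ValueError("stochastic simulation requires molecule-unit "
                         "parameters")
    p = apply_mutant(params, protocol.mutant)
    if protocol.katt is not None:
        from dataclasses import replace
        p = replace(p, katt=protocol.katt)
    par = network.params_array(p)
    if protocol.mutant.mps1_window is not None:
        # windowed overexpression is applied inside the kernel; the base
        # parameter array carries the unscaled synthesis rate
        xw0, xw1 = protocol.mutant.mps1_window
        xfac = protocol.mutant.mps1_synthesis_factor
    else:
        xw0, xw1, xfac = 0.0, -1.0, 1.0
    y0 = _initial_vector(protocol, p, custom_initial)
    samples, t_cross, nuk_cross, t_att = _ssa_core(
        protocol.seed, y0, par, protocol.horizon,
        protocol.attachment_enabled, float(p.ac_threshold),
        protocol.stop_at_cross, xfac, xw0, xw1, protocol.sample_dt,
        max_events)
    n = samples.shape[0]
    t = np.arange(n) * protocol.sample_dt
    return StochasticTrajectory(
        t=t, y=samples,
        t_cross=None if t_cross < 0 else float(t_cross),
        nUK_at_cross=None if t_cross < 0 else int(nuk_cross),
        t_all_attached=None if t_att < 0 else float(t_att),
        seed=protocol.seed, protocol=protocol)


@dataclass(frozen=True)
class OutcomeRecord:
    """Per-trajectory result of an arrest or washout protocol."""

    seed: int
    t_cross: float | None         # first passage of AC above threshold, min
    nUK_at_cross: int | None
    t_all_attached: float | None
    classification: str           # adapted | exited | arrested

    def to_dict(self) -> dict:
        return dict(seed=self.seed, t_cross=self.t_cross,
                    nUK_at_cross=self.nUK_at_cross,
                    t_all_attached=self.t_all_attached,
                    classification=self.classification)


def classify_outcome(traj: StochasticTrajectory,
                     params: ModelParameters) -> OutcomeRecord:
    """Adaptation = threshold crossing with at least one unattached
    kinetochore; checkpoint satisfaction (exit) = crossing at nUK = 0;
    arrested = no crossing within the horizon."""
    t_cross, nuk_cross = traj.t_cross, traj.nUK_at_cross
    if t_cross is None:
        # fall back to the sampled grid (trajectories not produced by
        # ssa_run, e.g. replays loaded from disk)
        if traj.y.shape[1] < 9:
            raise ValueError("trajectory lacks an nUK channel")
        above = np.nonzero(traj.AC >= params.ac_threshold)[0]
        if above.size:
            i = above[0]
            t_cross = float(traj.t[i])
            nuk_cross = int(traj.nUK[i])
    if t_cross is None:
        cls = "arrested"
    elif nuk_cross > 0:
        cls = "adapted"
    else:
        cls = "exited"
    return OutcomeRecord(seed=traj.seed, t_cross=t_cross,
                         nUK_at_cross=nuk_cross,
                         t_all_attached=traj.t_all_attached,
                         classification=cls)


@dataclass
class EnsembleSummary:
    protocol: ProtocolSpec
    records: list[OutcomeRecord]
    seed0: int

    @property
    def n(self) -> int:
        return len(self.records)

    def fraction(self, cls: str) -> float:
        return sum(r.classification == cls for r in self.records) / self.n

    @property
    def adapted_fraction(self) -> float:
        return self.fraction("adapted")

    @property
    def exited_fraction(self) -> float:
        return self.fraction("exited")

    @property
    def arrested_fraction(self) -> float:
        return self.fraction("arrested")

    def crossing_times(self, cls: str | None = None) -> np.ndarray:
        ts = [r.t_cross for r in self.records if r.t_cross is not None
              and (cls is None or r.classification == cls)]
        return np.sort(np.array(ts, dtype=float))

    def ecdf(self) -> tuple[np.ndarray, np.ndarray]:
        """Empirical CDF of crossing times over the whole ensemble."""
        ts = self.crossing_times()
        return ts, np.arange(1, ts.size + 1) / self.n

    def pearson_adapters(self) -> tuple[float, float]:
        """Pearson R and p between crossing time and kinetochores still
        unattached at crossing, among adapting trajectories."""
        pairs = [(r.t_cross, r.nUK_at_cross) for r in self.records
                 if r.classification == "adapted"]
        if len(pairs) < 3:
            return float("nan"), float("nan")
        t, k = zip(*pairs)
        if np.ptp(t) == 0 or np.ptp(k) == 0:
            return float("nan"), float("nan")
        r, p = stats.pearsonr(t, k)
        return float(r), float(p)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([r.to_dict() for r in self.records])


def run_ensemble(protocol: ProtocolSpec, params: ModelParameters,
                 n: int = 100, seed0: int | None = None,
                 stop_at_cross: bool = True) -> EnsembleSummary:
    """n independent seeded runs (seeds seed0, seed0+1, ...)."""
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    from dataclasses import replace
    seed0 = protocol.seed if seed0 is None else seed0
    records = []
    for i in range(n):
        proto_i = replace(protocol, seed=seed0 + i,
                          stop_at_cross=stop_at_cross)
        traj = ssa_run(proto_i, params)
        records.append(classify_outcome(traj, params))
    return EnsembleSummary(protocol=protocol, records=records, seed0=seed0)


@dataclass
class AdaptationTimeFit:
    times: np.ndarray
    rate: float                   # 1/min, MLE of the exponential tail
    delay: float                  # minutes
    cv: float                     # coefficient of variation
    exponential_like: bool        # CV compatible with a memoryless escape

    def ecdf(self):
        t = np.sort(self.times)
        return t, np.arange(1, t.size + 1) / t.size


def adaptation_time_distribution(summary: EnsembleSummary,
                                 delay: float | None = None,
                                 min_events: int = 20) -> AdaptationTimeFit:
    """Maximum-likelihood exponential fit of the crossing-time distribution.

    A memoryless (barrier-escape) mechanism predicts an exponential
    distribution, CV ~ 1.  The delay is an explicit shift; by default it is
    zero because simulated arrests start with APC/C^Cdc20 already formed.
    """
    times = summary.crossing_times()
    if times.size < min_events:
        raise ValueError(
            f"only {times.size} crossings; need >= {min_events}")
    delay = 0.0 if delay is None else float(delay)
    shifted = times - delay
    if np.any(shifted < 0):
        raise ValueError("delay exceeds some crossing times")
    mean = shifted.mean()
    sd = shifted.std(ddof=1)
    cv = sd / mean if mean > 0 else 0.0
    rate = 1.0 / mean if mean > 0 else float("inf")
    return AdaptationTimeFit(times=times, rate=rate, delay=delay, cv=cv,
                             exponential_like=bool(0.7 <= cv <= 1.3))


@dataclass
class AdaptersVsExiters:
    adapter_times: np.ndarray
    exiter_times: np.ndarray
    pearson_r: float
    pearson_p: float
    adapters_empty: bool
    exiters_empty: bool

    @property
    def complete(self) -> bool:
        return not (self.adapters_empty or self.exiters_empty)


def adapters_vs_exiters(summary: EnsembleSummary) -> AdaptersVsExiters:
    """Timing distributions of adapting vs checkpoint-satisfying cells, and
    the correlation between adaptation time and unattached kinetochores at
    adaptation (early adapters escape with many unattached kinetochores)."""
    ta = summary.crossing_times("adapted")
    te = summary.crossing_times("exited")
    r, p = summary.pearson_adapters()
    return AdaptersVsExiters(adapter_times=ta, exiter_times=te,
                             pearson_r=r, pearson_p=p,
                             adapters_empty=ta.size == 0,
                             exiters_empty=te.size == 0)
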