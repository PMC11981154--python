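"""Ground-truth-labeled synthetic observables.

Generates the single-cell readouts the trace-analysis rules expect, with the
statistical structure of time-lapse arrest experiments: a Clb2-like mean
fluorescence that rises after budding, holds a plateau for a random arrest
length (delay + exponential), then falls exponentially (never, for arrested
cells; slowly/incompletely for partially degrading cells); a Mad2
Localization Index that delocalizes before the Clb2 fall for checkpoint
satisfaction and after it for adaptation; and tiny two-dimensional images
with zero or one diffraction-limited spot on a noisy background.  A mapping
from stochastic model trajectories to the same observables supports
end-to-end round trips (simulate, observe, classify).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .traces import AnalysisConfig, CellTrace

LABELS = ("adapted", "exited", "partial", "arrested")


@dataclass(frozen=True)
class CohortSpec:
    """Statistical description of a synthetic single-cell cohort."""

    n: int = 100
    fraction_adapting: float = 0.6     # among cells that fully degrade Clb2
    fraction_partial: float = 0.0
    fraction_arrested: float = 0.0
    arrest_delay: float = 100.0        # minutes before the exponential tail
    arrest_rate: float = 1.0 / 150.0   # 1/min of the exponential tail
    clb2_decay_rate: float = 0.05      # 1/min, full degradation
    partial_decay_rate: float = 0.005  # 1/min, below the partial cutoff
    mad2_lead: float = 30.0            # Mad2 delocalizes this long BEFORE
                                       # the Clb2 fall in exiting cells
    mad2_lag: float = 30.0             # ... and this long AFTER it when
                                       # adapting
    noise_level: float = 0.02          # Gaussian sigma / plateau
    frame_spacing: float = 10.0        # minutes
    plateau: float = 100.0             # a.u.
    g1_level: float = 1.0              # baseline Mad2 index in G1
    localized_level: float = 3.0       # Mad2 index during the arrest
    budding_time: float = 30.0
    rise_duration: float = 30.0
    t_total: float = 900.0
    seed: int = 0

    def __post_init__(self):
        fr = (self.fraction_adapting, self.fraction_partial,
              self.fraction_arrested)
        if any(not 0.0 <= f <= 1.0 for f in fr):
            raise ValueError("fractions must lie in [0, 1]")
        if self.fraction_partial + self.fraction_arrested > 1.0:
            raise ValueError("partial + arrested fractions exceed 1")
        if self.arrest_rate <= 0 or self.clb2_decay_rate <= 0:
            raise ValueError("rates must be positive")


def _clb2_profile(t, spec: CohortSpec, t_fall, decay_rate):
    """Rise / plateau / exponential-fall template."""
    s = np.zeros_like(t)
    rise_end = spec.budding_time + spec.rise_duration
    rising = (t >= spec.budding_time) & (t < rise_end)
    s[rising] = spec.plateau * (t[rising] - spec.budding_time) \
        / spec.rise_duration
    if t_fall is None:
        s[t >= rise_end] = spec.plateau
    else:
        plateau_zone = (t >= rise_end) & (t < t_fall)
        s[plateau_zone] = spec.plateau
        falling = t >= t_fall
        s[falling] = spec.plateau * np.exp(-decay_rate * (t[falling]
                                                          - t_fall))
    return s


def _mad2_profile(t, spec: CohortSpec, t_deloc):
    """Localization-index template: G1 baseline, localized during the
    arrest, back to baseline at delocalization."""
    s = np.full_like(t, spec.g1_level)
    rise_end = spec.budding_time + spec.rise_duration
    if t_deloc is None:
        s[t >= rise_end] = spec.localized_level
    else:
        s[(t >= rise_end) & (t < t_deloc)] = spec.localized_level
    return s


def draw_arrest_length(rng: np.random.Generator, spec: CohortSpec) -> float:
    return spec.arrest_delay + rng.exponential(1.0 / spec.arrest_rate)


def make_trace(label: str, spec: CohortSpec, seed: int) -> CellTrace:
    """One labeled synthetic cell.

    ``exited`` cells delocalize Mad2 ``mad2_lead`` minutes before the Clb2
    fall; ``adapted`` cells keep it localized until ``mad2_lag`` minutes
    after; ``arrested`` cells never fall; ``partial`` cells decay below the
    rate cutoff.  Additive Gaussian noise scales with the plateau.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, spec.t_total + 0.5 * spec.frame_spacing,
                  spec.frame_spacing)
    arrest = draw_arrest_length(rng, spec)
    t_fall = spec.budding_time + spec.rise_duration + arrest
    t_fall = min(t_fall, spec.t_total - 200.0)  # keep the fall observable

    if label == "arrested":
        clb2 = _clb2_profile(t, spec, None, 0.0)
        mad2 = _mad2_profile(t, spec, None)
    elif label == "partial":
        clb2 = _clb2_profile(t, spec, t_fall, spec.partial_decay_rate)
        mad2 = _mad2_profile(t, spec, None)
    elif label == "adapted":
        clb2 = _clb2_profile(t, spec, t_fall, spec.clb2_decay_rate)
        mad2 = _mad2_profile(t, spec, t_fall + spec.mad2_lag)
    else:  # exited
        clb2 = _clb2_profile(t, spec, t_fall, spec.clb2_decay_rate)
        mad2 = _mad2_profile(t, spec, t_fall - spec.mad2_lead)

    clb2 = clb2 + rng.normal(0.0, spec.noise_level * spec.plateau, t.size)
    mad2 = mad2 + rng.normal(0.0, spec.noise_level * spec.g1_level, t.size)
    return CellTrace(time=t, clb2=clb2, mad2_index=mad2,
                     budding_time=spec.budding_time, label=label,
                     cell_id=f"cell-{seed}")


def make_cohort(spec: CohortSpec) -> list[CellTrace]:
    """n labeled traces; labels drawn per cell, reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    traces = []
    for i in range(spec.n):
        u = rng.random()
        if u < spec.fraction_arrested:
            label = "arrested"
        elif u < spec.fraction_arrested + spec.fraction_partial:
            label = "partial"
        else:
            label = "adapted" if rng.random() < spec.fraction_adapting \
                else "exited"
        traces.append(make_trace(label, spec, seed=spec.seed * 100_003 + i))
    return traces


def make_spot_image(size: int = 15, spot: bool = True,
                    amplitude: float = 50.0, background: float = 10.0,
                    noise: float = 1.0, sigma: float = 1.0,
                    seed: int = 0):
    """Tiny fluorescence image with zero or one Gaussian spot.

    Returns ``(image, mask, truth)`` where the mask covers the central cell
    region and truth records the spot parameters.
    """
    if size < 5:
        raise ValueError("image must be at least 5x5")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    c = size // 2
    image = np.full((size, size), background, dtype=float)
    if spot:
        image += amplitude * np.exp(-((yy - c) ** 2 + (xx - c) ** 2)
                                    / (2.0 * sigma ** 2))
    if noise > 0:
        image += rng.normal(0.0, noise, image.shape)
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= (c + 0.5) ** 2
    truth = dict(spot=spot, amplitude=amplitude, background=background,
                 center=(c, c), sigma=sigma)
    return image, mask, truth


@dataclass(frozen=True)
class ObservableMap:
    """How a stochastic trajectory is rendered as microscope observables.

    The rendered movie mirrors the experimental protocol: a G1 calibration
    stretch, budding and Clb2 accumulation, a pre-recorded arrest phase
    (cells sit in the checkpoint-ON state under drug before washout /
    before the recorded window), and only then the simulated trajectory.
    """

    clb2_decay_rate: float = 0.05     # 1/min once APC/C^Cdc20 is active
    plateau: float = 100.0
    g1_level: float = 1.0
    index_gain: float = 2.0           # Mad2-index gain over baseline
    g1_minutes: float = 20.0          # baseline prepended for calibration
    rise_minutes: float = 30.0        # Clb2 accumulation after budding
    pre_arrest_minutes: float = 180.0  # drug arrest before trajectory t=0
    frame_spacing: float = 10.0
    noise_level: float = 0.0


def model_to_observables(traj, mapping: ObservableMap | None = None,
                         seed: int = 0) -> CellTrace:
    """Render an SSA trajectory as a (Clb2, Mad2-index) cell trace.

    Clb2 holds its plateau until the first APC/C^Cdc20 threshold crossing,
    then decays exponentially; the Mad2 index is a saturating function of
    the current unattached-kinetochore count (baseline when all are
    attached).  A G1 calibration stretch is prepended so the localization
    threshold can be computed; the SSA outcome classification is carried as
    ground truth.
    """
    mapping = mapping or ObservableMap()
    rng = np.random.default_rng(seed)
    if traj.y.shape[1] < 9:
        raise ValueError("trajectory lacks AC or nUK channels")
    m = mapping
    # movie timeline: [G1 baseline][budding + Clb2 rise][drug arrest]
    # [simulated trajectory]; the calibration window is inclusive of
    # t = g1_minutes, so one extra baseline frame is kept
    n_g1 = int(round(m.g1_minutes / m.frame_spacing)) + 1
    budding = n_g1 * m.frame_spacing
    sim_start = budding + m.rise_minutes + m.pre_arrest_minutes
    t_cross = traj.t_cross
    time = np.arange(0.0, sim_start + traj.t[-1] + 0.5 * m.frame_spacing,
                     m.frame_spacing)
    rising = (time >= budding) & (time < budding + m.rise_minutes)
    clb2 = np.full(time.size, m.plateau)
    clb2[time < budding] = 0.0
    clb2[rising] = m.plateau * (time[rising] - budding) / m.rise_minutes
    if t_cross is not None:
        after = time >= sim_start + t_cross
        clb2[after] = m.plateau * np.exp(
            -m.clb2_decay_rate * (time[after] - sim_start - t_cross))
    # Mad2 index: baseline in G1, then driven by the current kinetochore
    # count; sampling at t_rel = 0 holds the trajectory's initial count
    # throughout the pre-recorded arrest
    dt_traj = traj.t[1] - traj.t[0]
    t_rel = np.clip(time - sim_start, 0.0, traj.t[-1])
    nuk = traj.nUK[np.minimum((t_rel / dt_traj).astype(int),
                              traj.t.size - 1)].astype(float)
    nuk[time < budding] = 0.0
    mad2 = m.g1_level * (1.0 + m.index_gain * nuk / (1.0 + nuk))
    if m.noise_level > 0:
        clb2 += rng.normal(0.0, m.noise_level * m.plateau, time.size)
        mad2 += rng.normal(0.0, m.noise_level * m.g1_level, time.size)

    if t_cross is None:
        label = "arrested"
    elif traj.nUK_at_cross and traj.nUK_at_cross > 0:
        label = "adapted"
    else:
        label = "exited"
    return CellTrace(time=time, clb2=clb2, mad2_index=mad2,
                     budding_time=budding, label=label,
                     cell_id=f"sim-{traj.seed}")
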