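"""Single-cell trace quantification and classification.

Implements the image/trace rules used to score live-cell experiments:
a Laplacian-of-Gaussian Localization Index calling Mad2 recruitment to
kinetochores, summed kinetochore fluorescence, detection of the Clb2
degradation onset on Savitzky-Golay-smoothed traces, an exponential fit of
the degradation rate, and the resulting cell classifications (full/partial/
arrested Clb2 degradation; adaptation vs checkpoint satisfaction).  The
missegregation predictor 1-(1-p)^n closes the loop from adaptation frequency
to expected chromosome-loss frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

#: 3x3 Laplacian-of-Gaussian kernel used for the Localization Index
LOG_KERNEL = np.array([
    [-0.0085, 0.0038, -0.0085],
    [0.0038, 0.0187, 0.0038],
    [-0.0085, 0.0038, -0.0085],
])


@dataclass
class CellTrace:
    """Sampled single-cell observables on a common time grid (minutes)."""

    time: np.ndarray
    clb2: np.ndarray                      # mean fluorescence, a.u.
    mad2_index: np.ndarray                # LoG localization index
    budding_time: float = 0.0             # minutes
    label: str | None = None              # optional ground truth
    cell_id: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.clb2 = np.asarray(self.clb2, dtype=float)
        self.mad2_index = np.asarray(self.mad2_index, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not (np.all(np.isfinite(self.clb2))
                and np.all(np.isfinite(self.mad2_index))):
            raise ValueError("signals must be finite")

    @property
    def frame_spacing(self) -> float:
        return float(np.median(np.diff(self.time)))


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable constants of the quantification rules.

    The localization threshold is calibrated per cell as 110% of the maximum
    Localization Index over the G1 window at the start of the movie; the
    degradation-rate fit uses four frames; cells degrading slower than
    0.01/min or losing less than half of their Clb2 within 90 minutes count
    as partial.
    """

    threshold_factor: float = 1.10
    g1_window: float = 20.0               # minutes of G1 calibration
    kinetochore_window: int = 5           # pixels (odd)
    smoothing_window: int = 7             # Savitzky-Golay frames (odd)
    smoothing_order: int = 2
    fall_frames: int = 2                  # consecutive lower frames = "falls"
    fall_confirm_fraction: float = 0.9    # smoothed signal must drop below
                                          # this fraction of the onset level
    fall_confirm_frames: int = 6          # ... within this many frames
    rise_guard_fraction: float = 0.10     # reject onsets on a steep rise
                                          # (smoothing-overshoot artifacts)
    rate_fit_points: int = 4
    partial_rate_cutoff: float = 0.01     # 1/min
    partial_fraction: float = 0.5
    partial_horizon: float = 90.0         # minutes

    def __post_init__(self):
        if self.kinetochore_window <= 0 or self.kinetochore_window % 2 == 0:
            raise ValueError("kinetochore window must be odd and positive")
        if self.smoothing_window <= self.smoothing_order:
            raise ValueError("smoothing window must exceed the order")


# -- image operations -------------------------------------------------------

def log_localization_index(image: np.ndarray, mask: np.ndarray,
                           config: AnalysisConfig | None = None) -> float:
    """Maximum of the LoG-filtered image over the segmented cell pixels.

    A bright diffraction-limited spot produces a strong positive response of
    the kernel; diffuse signal responds with the (near-zero) kernel sum, so
    the index is insensitive to overall fluorescence level.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    if mask.shape != image.shape or not mask.any():
        raise ValueError("mask must be a nonempty boolean image of the same "
                         "shape")
    filtered = ndimage.correlate(image, LOG_KERNEL, mode="nearest")
    return float(filtered[mask].max())


def kinetochore_signal(avg_projection: np.ndarray,
                       peak: tuple[int, int],
                       config: AnalysisConfig | None = None
                       ) -> tuple[float, bool]:
    """Summed fluorescence in the square window centred on the spot peak.

    Computed on the non-deconvolved average projection, whose intensities
    scale linearly with protein amount.  Windows clipped at image borders are
    renormalized by the covered area and flagged (second return value).
    """
    config = config or AnalysisConfig()
    img = np.asarray(avg_projection, dtype=float)
    r, c = peak
    if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
        raise ValueError("peak lies outside the image")
    h = config.kinetochore_window // 2
    r0, r1 = max(0, r - h), min(img.shape[0], r + h + 1)
    c0, c1 = max(0, c - h), min(img.shape[1], c + h + 1)
    window = img[r0:r1, c0:c1]
    full_area = config.kinetochore_window ** 2
    clipped = window.size < full_area
    total = float(window.sum())
    if clipped and window.size:
        total *= full_area / window.size
    return total, clipped


# -- Mad2 localization ------------------------------------------------------

def mad2_threshold(trace: CellTrace, config: AnalysisConfig | None = None
                   ) -> float:
    """Per-cell threshold: 110% of the maximum raw Localization Index in the
    G1 calibration window at the start of the movie."""
    config = config or AnalysisConfig()
    in_g1 = trace.time <= trace.time[0] + config.g1_window
    if not in_g1.any() or trace.time[0] > config.g1_window:
        raise ValueError("trace does not cover the G1 calibration window")
    return config.threshold_factor * float(trace.mad2_index[in_g1].max())


def mad2_localized(trace: CellTrace, config: AnalysisConfig | None = None
                   ) -> np.ndarray:
    """Boolean per frame: is the Localization Index strictly above the
    calibrated threshold?"""
    thr = mad2_threshold(trace, config)
    return trace.mad2_index > thr


# -- Clb2 degradation -------------------------------------------------------

def smoothed_clb2(trace: CellTrace, config: AnalysisConfig | None = None
                  ) -> np.ndarray:
    config = config or AnalysisConfig()
    if trace.clb2.size < config.smoothing_window:
        raise ValueError("trace shorter than the smoothing window")
    return signal.savgol_filter(trace.clb2, config.smoothing_window,
                                config.smoothing_order)


def clb2_degradation_time(trace: CellTrace,
                          config: AnalysisConfig | None = None
                          ) -> float | None:
    """Time when the smoothed Clb2 signal starts decreasing and falls.

    Operationalized in three steps.  A candidate onset is the first
    post-budding local maximum of the smoothed signal followed by
    ``fall_frames`` consecutive strictly lower values.  The fall must then be
    confirmed: within the partial-degradation horizon the smoothed signal
    has to drop below ``fall_confirm_fraction`` of the candidate level
    (filter edge artifacts at the rise-plateau corner produce small transient
    declines that never develop into a fall).  Finally the onset is refined
    on the raw trace, because polynomial smoothing leaks the decline a few
    frames backwards: the onset advances while the raw signal still sits
    within 10% of the local plateau.  Returns ``None`` when the signal never
    falls.
    """
    config = config or AnalysisConfig()
    s = smoothed_clb2(trace, config)
    raw = trace.clb2
    t = trace.time
    k = config.fall_frames
    n = s.size
    confirm_frames = max(config.fall_confirm_frames, k + 1)
    for i in range(1, n - k):
        if t[i] < trace.budding_time:
            continue
        if s[i] < s[i - 1]:
            continue
        if i >= 2 and s[i] - s[i - 2] > config.rise_guard_fraction * \
                max(abs(s[i]), 1e-12):
            continue  # still climbing: smoothing overshoot, not a maximum
        if not all(s[i + j + 1] < s[i + j] for j in range(k)):
            continue
        stop = min(n, i + confirm_frames + 1)
        if not np.any(s[i:stop] < config.fall_confirm_fraction * s[i]):
            continue
        plateau = raw[max(0, i - 2):i + 1].max()
        j = i
        cap = min(n - 1, i + config.smoothing_window)
        while j < cap and raw[j + 1] >= 0.9 * plateau:
            j += 1
        return float(t[j])
    return None


def clb2_degradation_rate(trace: CellTrace, t_deg: float,
                          config: AnalysisConfig | None = None) -> float:
    """Exponential (log-linear least-squares) fit of the decay rate on the
    first frames after the degradation onset; positive for decay.

    Nonpositive intensities cannot be log-transformed; the fit is then done
    on the signal shifted minimally above zero.
    """
    config = config or AnalysisConfig()
    idx = np.nonzero(trace.time >= t_deg - 1e-9)[0]
    if idx.size < config.rate_fit_points:
        raise ValueError("fewer than the required fit points after t_deg")
    sel = idx[:config.rate_fit_points]
    t = trace.time[sel]
    y = trace.clb2[sel].copy()
    if np.any(y <= 0):
        y = y - y.min() + 1e-3 * max(np.ptp(y), 1.0)
    slope = np.polyfit(t, np.log(y), 1)[0]
    return float(-slope)


def classify_clb2_behavior(trace: CellTrace,
                           config: AnalysisConfig | None = None) -> str:
    """``arrested`` (never degrades), ``partial`` (slow or incomplete
    degradation) or ``full``."""
    config = config or AnalysisConfig()
    t_deg = clb2_degradation_time(trace, config)
    if t_deg is None:
        return "arrested"
    rate = clb2_degradation_rate(trace, t_deg, config)
    if rate < config.partial_rate_cutoff:
        return "partial"
    s = smoothed_clb2(trace, config)
    i0 = int(np.nonzero(trace.time >= t_deg - 1e-9)[0][0])
    horizon = trace.time <= t_deg + config.partial_horizon
    level0 = s[i0]
    if level0 > 0:
        lowest = s[horizon & (trace.time >= t_deg - 1e-9)].min()
        degraded_fraction = (level0 - lowest) / level0
        if degraded_fraction < config.partial_fraction:
            return "partial"
    return "full"


def classify_adaptation(trace: CellTrace,
                        config: AnalysisConfig | None = None) -> str:
    """``adapted`` when Mad2 is still localized at the moment Clb2
    degradation starts (escape with an active checkpoint), ``exited`` when it
    has delocalized first (checkpoint satisfied), ``not-applicable`` for
    cells that do not fully degrade Clb2."""
    config = config or AnalysisConfig()
    if classify_clb2_behavior(trace, config) != "full":
        return "not-applicable"
    t_deg = clb2_degradation_time(trace, config)
    localized = mad2_localized(trace, config)
    i = int(np.argmin(np.abs(trace.time - t_deg)))
    return "adapted" if localized[i] else "exited"


def missegregation_probability(p: float, n: int = 16) -> float:
    """Probability that at least one of n chromosomes missegregates when
    each does so independently with probability p: 1 - (1-p)^n."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("per-chromosome probability must lie in [0, 1]")
    if n < 1:
        raise ValueError("chromosome count must be >= 1")
    return 1.0 - (1.0 - p) ** n
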