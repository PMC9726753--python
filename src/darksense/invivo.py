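"""In vivo imaging-session analysis.

Pipeline for ~30 Hz fluorescence recordings with a simultaneous
locomotion (speed) channel and event lists: detrending and smoothing,
z-score standardization, stimulation- and reward-triggered averaging,
speed-gated comparison, movement-stop detection, and estimation of the
fluorescence decay time after movement stops.

The darkening convention matters throughout: a rise in extracellular
serotonin *lowers* fluorescence, so reward and stimulation responses
appear as dips in z-score and movement stops are followed by a
fluorescence decay (serotonin rising at rest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .traces import Trace

log = logging.getLogger(__name__)

__all__ = [
    "InVivoSession",
    "ZScoreTransform",
    "EventAverage",
    "RewardAnalysis",
    "SpeedGateResult",
    "StopDecayResult",
    "preprocess",
    "zscore",
    "stim_triggered_average",
    "reward_analysis",
    "speed_gate",
    "detect_movement_stops",
    "stop_decay_fit",
]

#: Running/rest classification threshold (cm/s).
SPEED_THRESHOLD_CM_S = 3.0


@dataclass
class InVivoSession:
    """One imaging session: fluorescence, speed and events on a shared clock."""

    fluorescence: Trace
    speed_cm_s: np.ndarray
    stim_times: np.ndarray = field(default_factory=lambda: np.array([]))
    reward_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.speed_cm_s = np.asarray(self.speed_cm_s, dtype=float)
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        self.reward_times = np.asarray(self.reward_times, dtype=float)
        if self.speed_cm_s.shape != self.fluorescence.time_s.shape:
            raise ValueError("speed channel must share the fluorescence time grid")
        if np.any(self.speed_cm_s < 0):
            raise ValueError("speeds must be nonnegative")

    @property
    def time_s(self) -> np.ndarray:
        return self.fluorescence.time_s

    @property
    def rate_hz(self) -> float:
        return self.fluorescence.rate_hz


@dataclass(frozen=True)
class ZScoreTransform:
    """Standardization x -> (x - mu)/sigma with population statistics."""

    mu: float
    sigma: float

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mu) / self.sigma


@dataclass
class EventAverage:
    """Event-aligned trace segments and their mean."""

    window: tuple[float, float]
    time_rel_s: np.ndarray
    per_event: np.ndarray          # (n_events, n_samples)
    mean: np.ndarray
    event_times: np.ndarray
    n_excluded: int = 0


@dataclass
class RewardAnalysis:
    """Per-event baseline vs post-reward comparison."""

    event_average: EventAverage
    baseline_per_event: np.ndarray
    post_per_event: np.ndarray
    median_baseline: float
    median_post: float
    wilcoxon_p: float | None


@dataclass
class SpeedGateResult:
    mean_running: float | None
    mean_rest: float | None
    n_running: int
    n_rest: int
    flagged: bool


@dataclass
class StopDecayResult:
    """Half-range crossing time of a polynomial fit to the scaled decay."""

    tau_s: float | None
    poly_coeffs: np.ndarray
    scaled_mean: np.ndarray
    time_rel_s: np.ndarray
    n_stops: int
    flagged: bool


def preprocess(session: InVivoSession, detrend: str = "linear",
               smooth_window_s: float = 0.0, poly_degree: int = 3) -> InVivoSession:
    """Detrend the fluorescence channel and optionally smooth it.

    ``detrend`` is ``"linear"`` or ``"polynomial"`` (degree
    ``poly_degree``); the fitted trend is subtracted over the whole
    trace.  Smoothing is a centred moving average of
    ``smooth_window_s`` seconds (0 = no smoothing).  The speed channel
    is never modified.
    """
    tr = session.fluorescence
    t, y = tr.time_s, tr.value.copy()
    if detrend == "linear":
        deg = 1
    elif detrend == "polynomial":
        deg = poly_degree
    else:
        raise ValueError(f"unknown detrend mode {detrend!r}")
    # centre time for conditioning
    tc = t - t.mean()
    trend = np.polyval(np.polyfit(tc, y, deg), tc)
    y = y - trend
    if smooth_window_s > 0:
        n = int(round(smooth_window_s * tr.rate_hz))
        n = max(n, 1)
        if n % 2 == 0:
            n += 1
        if n >= len(y):
            raise ValueError("smoothing window must be shorter than the trace")
        if n > 1:
            kernel = np.ones(n) / n
            # reflect-pad so edges keep local mean
            pad = n // 2
            ypad = np.concatenate([y[pad:0:-1], y, y[-2:-pad - 2:-1]])
            y = np.convolve(ypad, kernel, mode="valid")
    return replace(session, fluorescence=replace(tr, value=y))


def zscore(trace: Trace) -> tuple[Trace, ZScoreTransform]:
    """Standardize a trace to mean 0, s.d. 1 (population s.d.)."""
    y = trace.value
    if len(y) < 2:
        raise ValueError("need at least 2 samples to z-score")
    mu = float(np.mean(y))
    sigma = float(np.std(y))           # population (ddof=0)
    if sigma == 0:
        raise ValueError("cannot z-score a constant trace (sigma = 0)")
    tf = ZScoreTransform(mu=mu, sigma=sigma)
    return replace(trace, value=tf.apply(y), channel="zscore"), tf


def _extract_segments(trace: Trace, event_times: np.ndarray,
                      window: tuple[float, float]) -> EventAverage:
    rate = trace.rate_hz
    n_pre = int(round(-window[0] * rate))
    n_post = int(round(window[1] * rate))
    time_rel = np.arange(-n_pre, n_post + 1) / rate
    rows, used = [], []
    n_excluded = 0
    for ev in np.sort(np.asarray(event_times, dtype=float)):
        idx = int(np.searchsorted(trace.time_s, ev))
        lo, hi = idx - n_pre, idx + n_post + 1
        if lo < 0 or hi > len(trace):
            n_excluded += 1
            log.info("event at %.3f s excluded: window not fully covered", ev)
            continue
        rows.append(trace.value[lo:hi])
        used.append(ev)
    per_event = np.array(rows) if rows else np.empty((0, len(time_rel)))
    mean = per_event.mean(axis=0) if len(rows) else np.full(len(time_rel), np.nan)
    return EventAverage(window=window, time_rel_s=time_rel, per_event=per_event,
                        mean=mean, event_times=np.array(used),
                        n_excluded=n_excluded)


def stim_triggered_average(session: InVivoSession,
                           window: tuple[float, float] = (-1.5, 2.5)) -> EventAverage:
    """Mean z-score trace aligned to the stimulation train events.

    The session fluorescence is used as given (typically already
    preprocessed and z-scored).  Events whose window does not fit are
    excluded with a log entry.
    """
    if len(session.stim_times) == 0:
        raise ValueError("session has no stimulation events")
    ea = _extract_segments(session.fluorescence, session.stim_times, window)
    if len(ea.event_times) == 0:
        raise ValueError("no stimulation event fully covered by the window")
    return ea


def reward_analysis(session: InVivoSession,
                    window: tuple[float, float] = (-1.5, 2.5),
                    n_baseline_samples: int = 6,
                    post_window: tuple[float, float] = (0.5, 0.7)) -> RewardAnalysis:
    """Baseline vs post-reward comparison per reward event.

    Per event, baseline is the mean of the ``n_baseline_samples``
    samples immediately preceding reward delivery (about -0.2 to 0 s at
    30.3 Hz) and the post value is the mean over ``post_window``
    seconds after it.  Events with too few pre-samples are excluded
    with a log entry.  A Wilcoxon signed-rank test compares the paired
    values when enough events remain.
    """
    if len(session.reward_times) == 0:
        raise ValueError("session has no reward events")
    tr = session.fluorescence
    ea = _extract_segments(tr, session.reward_times, window)
    baselines, posts = [], []
    for ev in ea.event_times:
        idx = int(np.searchsorted(tr.time_s, ev))
        if idx < n_baseline_samples:
            log.info("reward at %.3f s excluded: fewer than %d pre-samples",
                     ev, n_baseline_samples)
            continue
        baselines.append(float(np.mean(tr.value[idx - n_baseline_samples:idx])))
        sl = tr.window_slice(ev + post_window[0], ev + post_window[1])
        posts.append(float(np.mean(tr.value[sl])))
    baselines = np.array(baselines)
    posts = np.array(posts)
    p = None
    if len(baselines) >= 5 and np.any(baselines != posts):
        p = float(stats.wilcoxon(baselines, posts).pvalue)
    return RewardAnalysis(event_average=ea,
                          baseline_per_event=baselines, post_per_event=posts,
                          median_baseline=float(np.median(baselines)),
                          median_post=float(np.median(posts)),
                          wilcoxon_p=p)


def speed_gate(session: InVivoSession,
               threshold_cm_s: float = SPEED_THRESHOLD_CM_S) -> SpeedGateResult:
    """Mean fluorescence during running vs rest.

    Running means speed strictly above the threshold; samples exactly
    at the threshold count as rest.  An empty class flags the result
    instead of raising.
    """
    running = session.speed_cm_s > threshold_cm_s
    y = session.fluorescence.value
    n_run, n_rest = int(running.sum()), int((~running).sum())
    mean_run = float(y[running].mean()) if n_run else None
    mean_rest = float(y[~running].mean()) if n_rest else None
    return SpeedGateResult(mean_running=mean_run, mean_rest=mean_rest,
                           n_running=n_run, n_rest=n_rest,
                           flagged=(n_run == 0 or n_rest == 0))


def detect_movement_stops(session: InVivoSession,
                          threshold_cm_s: float = SPEED_THRESHOLD_CM_S,
                          run_min_s: float = 4.0,
                          still_min_s: float = 4.0) -> np.ndarray:
    """Movement-stop times.

    A stop is the first sub-threshold sample after the animal has run
    (speed > threshold) continuously for at least ``run_min_s`` and
    then produces no supra-threshold sample for ``still_min_s``.
    Returns an array of stop times (possibly empty).
    """
    t = session.time_s
    running = session.speed_cm_s > threshold_cm_s
    rate = session.rate_hz
    n_run = int(round(run_min_s * rate))
    n_still = int(round(still_min_s * rate))
    stops = []
    i = 0
    n = len(t)
    while i < n:
        if running[i]:
            j = i
            while j < n and running[j]:
                j += 1
            run_len = j - i
            if run_len >= n_run and j < n:
                still_end = min(j + n_still, n)
                if still_end - j >= n_still and not running[j:still_end].any():
                    stops.append(t[j])
            i = j
        else:
            i += 1
    return np.array(stops)


def stop_decay_fit(session: InVivoSession, stops: np.ndarray,
                   window_s: float = 4.0) -> StopDecayResult:
    """Fluorescence decay time constant after movement stops.

    The stop-triggered average over ``window_s`` seconds is min-max
    scaled to [0, 1], a second-degree polynomial is fitted, and tau is
    the time at which the fitted curve first crosses one half of its
    range.  If the fitted curve never crosses 1/2 inside the window
    (e.g. the average is not decaying) the result is flagged.
    """
    stops = np.asarray(stops, dtype=float)
    if len(stops) == 0:
        raise ValueError("no movement stops supplied")
    tr = session.fluorescence
    rate = tr.rate_hz
    n_win = int(round(window_s * rate))
    rows = []
    for st in stops:
        idx = int(np.searchsorted(tr.time_s, st))
        if idx + n_win + 1 > len(tr):
            log.info("stop at %.3f s excluded: window extends past trace end", st)
            continue
        rows.append(tr.value[idx:idx + n_win + 1])
    if not rows:
        raise ValueError("no stop fully covered by the window")
    mean = np.mean(rows, axis=0)
    rng_span = float(mean.max() - mean.min())
    t_rel = np.arange(len(mean)) / rate
    if rng_span == 0:
        return StopDecayResult(tau_s=None, poly_coeffs=np.zeros(3),
                               scaled_mean=np.zeros_like(mean), time_rel_s=t_rel,
                               n_stops=len(rows), flagged=True)
    scaled = (mean - mean.min()) / rng_span
    coeffs = np.polyfit(t_rel, scaled, 2)
    # first crossing of the fitted curve through 1/2 within the window
    roots = np.roots(coeffs - np.array([0.0, 0.0, 0.5]))
    real = np.sort([r.real for r in roots
                    if abs(r.imag) < 1e-9 and 0 <= r.real <= window_s])
    if len(real) == 0:
        return StopDecayResult(tau_s=None, poly_coeffs=coeffs, scaled_mean=scaled,
                               time_rel_s=t_rel, n_stops=len(rows), flagged=True)
    return StopDecayResult(tau_s=float(real[0]), poly_coeffs=coeffs,
                           scaled_mean=scaled, time_rel_s=t_rel,
                           n_stops=len(rows), flagged=False)
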