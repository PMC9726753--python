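"""Per-trace analysis: dF/F, baseline correction, sweep averaging,
single-exponential kinetics, Hill dose-response fits, ROI extraction.

Sign convention: internally dF/F is signed (negative for a darkening
sensor).  :class:`DoseResponseData` stores the response as a positive
magnitude, -dF/F, matching the convention of dose-response plots; the
two never mix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Trace",
    "ExpFitResult",
    "HillFitResult",
    "DoseResponseData",
    "compute_dff",
    "baseline_correct",
    "average_sweeps",
    "fit_exponential",
    "fit_hill",
    "extract_roi_timeseries",
    "pulse_response_amplitudes",
]

_GRID_RTOL = 1e-6


@dataclass
class Trace:
    """A uniformly sampled fluorescence time series.

    ``value`` holds raw fluorescence (a.u.) or dF/F (dimensionless)
    depending on ``channel``.  ``annotations`` carries protocol
    metadata; the key ``"application"`` is a ``(t_on, t_off)`` pair in
    seconds, ``"events"`` a list of event times.
    """

    time_s: np.ndarray
    value: np.ndarray
    rate_hz: float
    channel: str = "fluorescence"
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_s.shape != self.value.shape or self.time_s.ndim != 1:
            raise ValueError("time_s and value must be 1-D arrays of equal length")
        if len(self.time_s) >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise ValueError("time grid must be strictly increasing")
            if np.max(np.abs(dt * self.rate_hz - 1.0)) > _GRID_RTOL * max(1.0, self.rate_hz):
                raise ValueError("time grid spacing inconsistent with rate_hz")

    def __len__(self) -> int:
        return len(self.time_s)

    def window_slice(self, t0: float, t1: float) -> slice:
        """Index slice of samples with t0 <= t <= t1."""
        i0 = int(np.searchsorted(self.time_s, t0 - 1e-12))
        i1 = int(np.searchsorted(self.time_s, t1 + 1e-12))
        return slice(i0, i1)


@dataclass(frozen=True)
class ExpFitResult:
    """Single-exponential fit ``offset + amplitude * exp(-(t - t0)/tau)``."""

    tau_s: float
    amplitude: float
    offset: float
    residual_rms: float
    converged: bool
    window: tuple[float, float]

    def to_dict(self) -> dict:
        return {"tau_s": self.tau_s, "amplitude": self.amplitude,
                "offset": self.offset, "residual_rms": self.residual_rms,
                "converged": self.converged, "window_s": list(self.window)}


@dataclass(frozen=True)
class HillFitResult:
    """Hill fit ``response = max_response * c^n / (c^n + kd^n)``."""

    kd: float
    hill_n: float
    max_response: float
    kd_stderr: float | None = None
    hill_n_stderr: float | None = None
    max_response_stderr: float | None = None

    def to_dict(self) -> dict:
        return {"kd_M": self.kd, "hill_n": self.hill_n,
                "max_response": self.max_response,
                "kd_stderr_M": self.kd_stderr,
                "hill_n_stderr": self.hill_n_stderr,
                "max_response_stderr": self.max_response_stderr}


@dataclass
class DoseResponseData:
    """Paired (concentration, response) observations.

    ``response`` is the positive response magnitude -dF/F.
    ``replicate`` identifies repeated measurements at one concentration.
    """

    concentration_M: np.ndarray
    response: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentration_M = np.asarray(self.concentration_M, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentration_M.shape != self.response.shape:
            raise ValueError("concentration and response must have equal length")
        if np.any(self.concentration_M <= 0):
            raise ValueError("concentrations must be positive")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("responses must be finite")
        if self.replicate is None:
            self.replicate = np.zeros(len(self.response), dtype=int)


def compute_dff(trace: Trace, baseline_window: tuple[float, float]) -> Trace:
    """dF/F = (F - F0)/F0 with F0 the mean over ``baseline_window`` (s).

    Background subtraction must have happened upstream; a non-positive
    F0 signals that it has not and raises.
    """
    sl = trace.window_slice(*baseline_window)
    if sl.stop - sl.start < 1:
        raise ValueError("baseline window contains no samples")
    f0 = float(np.mean(trace.value[sl]))
    if f0 <= 0:
        raise ValueError(
            f"baseline F0 = {f0:g} is not positive; background subtraction missing?")
    return replace(trace, value=(trace.value - f0) / f0, channel="dff")


def baseline_correct(trace: Trace,
                     baseline_window: tuple[float, float] | None = None) -> Trace:
    """Subtract a linear baseline fitted over the pre-application segment.

    The fit window defaults to everything before the annotated
    application onset; pass ``baseline_window`` to override.
    """
    if baseline_window is None:
        app = trace.annotations.get("application")
        if app is None:
            raise ValueError("no baseline window given and no application annotation")
        # pre-application segment: everything strictly before the onset sample
        baseline_window = (float(trace.time_s[0]),
                           float(app[0]) - 0.5 / trace.rate_hz)
    sl = trace.window_slice(*baseline_window)
    if sl.stop - sl.start < 2:
        raise ValueError("need at least 2 baseline samples for a linear fit")
    t, y = trace.time_s[sl], trace.value[sl]
    slope, intercept = np.polyfit(t, y, 1)
    return replace(trace, value=trace.value - (slope * trace.time_s + intercept))


def average_sweeps(traces: list[Trace]) -> Trace:
    """Pointwise mean of sweeps recorded on identical time grids."""
    if not traces:
        raise ValueError("no sweeps to average")
    ref = traces[0]
    for tr in traces[1:]:
        if len(tr) != len(ref) or not np.allclose(tr.time_s, ref.time_s,
                                                  rtol=0, atol=_GRID_RTOL / ref.rate_hz):
            raise ValueError("sweeps have mismatched time grids")
        if tr.channel != ref.channel:
            raise ValueError("sweeps have mismatched channels")
    mean = np.mean([tr.value for tr in traces], axis=0)
    return replace(ref, value=mean)


def fit_exponential(dff_trace: Trace,
                    window: tuple[float, float] | None = None,
                    direction: str = "on") -> ExpFitResult:
    """Least-squares single-exponential fit with free offset.

    ``direction`` selects the default window from the trace's
    application annotation: ``"on"`` fits from the first sample after
    application onset to the application end (solution exchange is
    faster than one frame, so the onset sample already carries signal);
    ``"off"`` fits from application end to the end of the trace.
    """
    if direction not in ("on", "off"):
        raise ValueError(f"direction must be 'on' or 'off', got {direction!r}")
    if window is None:
        app = dff_trace.annotations.get("application")
        if app is None:
            raise ValueError("no fit window given and no application annotation")
        window = (float(app[0]), float(app[1])) if direction == "on" \
            else (float(app[1]), float(dff_trace.time_s[-1]))
    sl = dff_trace.window_slice(*window)
    t, y = dff_trace.time_s[sl], dff_trace.value[sl]
    if len(t) < 5:
        raise ValueError(f"fit window has {len(t)} samples; need at least 5")
    t = t - t[0]

    span = float(y[0] - y[-1])
    model = lmfit.Model(lambda t, tau, amplitude, offset:
                        offset + amplitude * np.exp(-t / tau))
    params = model.make_params(
        tau=dict(value=max(t[-1] / 5.0, 2.0 / dff_trace.rate_hz),
                 min=1e-2 / dff_trace.rate_hz, max=t[-1] * 100),
        amplitude=span if span != 0 else 1e-3,
        offset=float(y[-1]),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(y, params, t=t)
    resid_rms = float(np.sqrt(np.mean(result.residual**2)))
    amp = float(result.params["amplitude"].value)
    tau = float(result.params["tau"].value)
    scale = float(np.max(np.abs(y))) if len(y) else 0.0
    converged = bool(result.success) and tau > 0 and np.isfinite(tau) \
        and abs(amp) >= max(2.0 * resid_rms, 1e-6 * max(scale, 1.0))
    return ExpFitResult(tau_s=tau, amplitude=amp,
                        offset=float(result.params["offset"].value),
                        residual_rms=resid_rms, converged=converged,
                        window=(float(window[0]), float(window[1])))


def fit_hill(dose_response: DoseResponseData,
             fix_n: float | None = None) -> HillFitResult:
    """Hill-function fit of a dose-response curve.

    The Hill coefficient is free by default; pass ``fix_n`` to pin it.
    Requires at least 4 distinct concentrations that actually span the
    transition (the response must vary).
    """
    c = dose_response.concentration_M
    r = dose_response.response
    if len(np.unique(c)) < 4:
        raise ValueError("need at least 4 distinct concentrations for a Hill fit")
    rmax = float(np.max(r))
    if rmax <= 0 or (rmax - float(np.min(r))) < 0.05 * rmax:
        raise ValueError("degenerate dose-response span: response does not vary")

    def hill(c, kd, n, max_response):
        cn = np.power(c, n)
        return max_response * cn / (cn + np.power(kd, n))

    # initial kd: concentration nearest half-max response
    kd0 = float(c[np.argmin(np.abs(r - rmax / 2.0))])
    model = lmfit.Model(hill)
    params = model.make_params(
        kd=dict(value=kd0, min=float(np.min(c)) * 1e-4, max=float(np.max(c)) * 1e4),
        n=dict(value=1.0 if fix_n is None else fix_n, min=0.2, max=5.0,
               vary=fix_n is None),
        max_response=dict(value=rmax, min=0.0),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(r, params, c=c)

    def _err(name):
        p = result.params[name]
        return float(p.stderr) if p.stderr is not None else None

    return HillFitResult(kd=float(result.params["kd"].value),
                         hill_n=float(result.params["n"].value),
                         max_response=float(result.params["max_response"].value),
                         kd_stderr=_err("kd"), hill_n_stderr=_err("n"),
                         max_response_stderr=_err("max_response"))


def extract_roi_timeseries(stack: np.ndarray, roi, background_roi,
                           rate_hz: float) -> Trace:
    """Per-frame ROI mean minus per-frame background-ROI mean.

    ``stack`` is (n_frames, rows, cols); ROIs provide ``mask(shape)``.
    """
    stack = np.asarray(stack)
    shape = stack.shape[1:]
    m = roi.mask(shape)
    mb = background_roi.mask(shape)
    if not m.any() or not mb.any():
        raise ValueError("empty ROI mask")
    vals = stack[:, m].mean(axis=1) - stack[:, mb].mean(axis=1)
    time = np.arange(stack.shape[0]) / rate_hz
    return Trace(time_s=time, value=vals.astype(float), rate_hz=rate_hz)


def pulse_response_amplitudes(dff_trace: Trace, event_times: np.ndarray,
                              search_window: float) -> np.ndarray:
    """Peak response magnitude |dF/F| per event.

    For each event time the most negative dF/F within
    ``[event, event + search_window]`` seconds is located and returned
    as a positive magnitude.  Events whose window runs past the end of
    the trace are dropped with a log entry; overlapping windows warn.
    """
    event_times = np.sort(np.asarray(event_times, dtype=float))
    if len(event_times) > 1 and np.any(np.diff(event_times) < search_window):
        warnings.warn("pulse search windows overlap", stacklevel=2)
    amps = []
    t_end = float(dff_trace.time_s[-1])
    for ev in event_times:
        if ev + search_window > t_end + 1e-9:
            log.info("event at %.3f s dropped: window extends past trace end", ev)
            continue
        sl = dff_trace.window_slice(ev, ev + search_window)
        amps.append(-float(np.min(dff_trace.value[sl])))
    return np.array(amps)
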