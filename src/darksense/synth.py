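"""Synthetic-data generators for every protocol the pipeline analyses.

Each generator is a pure function of its configuration and the seed
carried by :class:`NoiseModel` / :class:`InVivoConfig`, and emits the
ground truth (state occupancies, latent ligand concentration, per-ROI
traces) alongside the observations so that downstream recovery can be
tested quantitatively.

Protocol defaults mirror the experimental designs they emulate:
fast-perfusion patch fluorometry at 91 Hz with 1 s ligand applications
averaged over 6-8 sweeps, steady-state titrations with n = 20
replicates, and ~30.3 fps in vivo sessions with stimulation trains of
9 pulses spaced 20 s apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kinetics import (FluorescenceModel, KineticScheme, predict_dff,
                       propagate_path, rate_matrix, steady_state)
from .invivo import InVivoSession, SPEED_THRESHOLD_CM_S
from .traces import DoseResponseData, Trace

__all__ = [
    "ApplicationProtocol",
    "SamplingConfig",
    "NoiseModel",
    "InVivoConfig",
    "simulate_patch_sweeps",
    "simulate_dose_response",
    "simulate_pulse_train",
    "simulate_invivo_session",
    "simulate_roi_stack",
    "sensor_dff_path",
]


@dataclass(frozen=True)
class ApplicationProtocol:
    """Timing of one fast-perfusion application sweep."""

    concentration: float           # molar
    pre_s: float = 0.5
    app_s: float = 1.0             # up to ~4 s for low concentrations
    post_s: float = 3.0
    n_sweeps: int = 7

    def __post_init__(self) -> None:
        if min(self.pre_s, self.app_s, self.post_s) <= 0:
            raise ValueError("all protocol durations must be positive")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be at least 1")
        if self.concentration < 0:
            raise ValueError("concentration must be nonnegative")

    @property
    def total_s(self) -> float:
        return self.pre_s + self.app_s + self.post_s

    @property
    def application_window(self) -> tuple[float, float]:
        return (self.pre_s, self.pre_s + self.app_s)


@dataclass(frozen=True)
class SamplingConfig:
    """Camera sampling: 91 Hz / 10 ms exposure for patch work, 30.3 fps in vivo."""

    rate_hz: float = 91.0
    exposure_s: float = 0.010

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.exposure_s * self.rate_hz > 1.0 + 1e-9:
            raise ValueError("exposure longer than the frame interval")


@dataclass(frozen=True)
class NoiseModel:
    """Additive measurement noise, slow drift and optional photobleaching.

    ``gaussian_sd_frac`` is the white-noise s.d. as a fraction of the
    baseline fluorescence; ``drift_slope_frac_per_s`` a linear baseline
    drift in fractions of baseline per second; ``bleach_tau_s`` an
    optional mono-exponential bleaching time constant.
    """

    gaussian_sd_frac: float = 0.01
    drift_slope_frac_per_s: float = 0.0
    bleach_tau_s: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sd_frac < 0:
            raise ValueError("gaussian_sd_frac must be nonnegative")


NOISELESS = NoiseModel(gaussian_sd_frac=0.0)


def _corrupt(f: np.ndarray, t: np.ndarray, f_base: float,
             noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    out = f.copy()
    if noise.bleach_tau_s is not None:
        out = out * np.exp(-t / noise.bleach_tau_s)
    if noise.drift_slope_frac_per_s:
        out = out + f_base * noise.drift_slope_frac_per_s * t
    if noise.gaussian_sd_frac:
        out = out + rng.normal(0.0, noise.gaussian_sd_frac * f_base, size=len(t))
    return out


def sensor_dff_path(scheme: KineticScheme, fluor: FluorescenceModel,
                    c_path: np.ndarray, dt: float,
                    x0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sensor dF/F along a piecewise-constant concentration path.

    ``c_path[i]`` is held during the interval ``[i*dt, (i+1)*dt)``; the
    occupancy is advanced analytically over each interval.  Returns
    ``(dff, f3)`` sampled at the start of each interval.  Starts from
    the steady state at ``c_path[0]`` unless ``x0`` is given.
    """
    c_path = np.asarray(c_path, dtype=float)
    x = steady_state(scheme, float(c_path[0])).as_array() if x0 is None \
        else np.asarray(x0, dtype=float)
    f3 = np.empty(len(c_path))
    prev_c = None
    w = v = vinv = None
    for i, c in enumerate(c_path):
        f3[i] = x[2]
        if c != prev_c:
            q = rate_matrix(scheme, float(c))
            w, v = np.linalg.eig(q)
            w, v = np.real(w), np.real(v)
            vinv = np.linalg.inv(v)
            prev_c = c
        x = v @ (np.exp(w * dt) * (vinv @ x))
    dff = -(1.0 - fluor.epsilon) * f3
    return dff, f3


def application_dff(scheme: KineticScheme, fluor: FluorescenceModel,
                    times: np.ndarray, t_on: float, t_off: float,
                    c: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact noise-free ``(dff, f3)`` for a step application of ``c``
    over ``[t_on, t_off)``, starting fully unbound."""
    times = np.asarray(times, dtype=float)
    f3 = np.empty(len(times))
    f3[times < t_on] = 0.0
    x_on0 = np.array([1.0, 0.0, 0.0])
    app = (times >= t_on) & (times < t_off)
    f3[app] = propagate_path(scheme, c, times[app] - t_on, x_on0)[:, 2]
    x_off0 = propagate_path(scheme, c, np.array([t_off - t_on]), x_on0)[0]
    post = times >= t_off
    f3[post] = propagate_path(scheme, 0.0, times[post] - t_off, x_off0)[:, 2]
    return -(1.0 - fluor.epsilon) * f3, f3


def simulate_patch_sweeps(scheme: KineticScheme, fluor: FluorescenceModel,
                          protocol: ApplicationProtocol,
                          sampling: SamplingConfig = SamplingConfig(),
                          noise: NoiseModel = NoiseModel()) -> list[Trace]:
    """Fast-perfusion fluorometry sweeps with a step ligand application.

    Solution exchange is instantaneous (experimentally sub-millisecond,
    faster than a frame).  Each sweep is the camera-sampled fluorescence
    ``f_base * (1 + dF/F)`` plus noise and drift; the noise-free dF/F
    and dark-state occupancy are stored under
    ``annotations["ground_truth"]``.
    """
    rate = sampling.rate_hz
    n = int(np.floor(protocol.total_s * rate)) + 1
    t = np.arange(n) / rate
    t_on, t_off = protocol.application_window
    dff_true, f3 = application_dff(scheme, fluor, t, t_on, t_off,
                                   protocol.concentration)
    f_clean = fluor.f_base * (1.0 + dff_true)

    rng = np.random.default_rng(noise.seed)
    sweeps = []
    for i in range(protocol.n_sweeps):
        value = _corrupt(f_clean, t, fluor.f_base, noise, rng)
        sweeps.append(Trace(
            time_s=t, value=value, rate_hz=rate, channel="fluorescence",
            annotations={
                "application": protocol.application_window,
                "concentration_M": protocol.concentration,
                "sweep": i,
                "ground_truth": {"dff": dff_true, "f3": f3},
            }))
    return sweeps


def simulate_dose_response(scheme: KineticScheme, fluor: FluorescenceModel,
                           concentrations: np.ndarray, replicates: int = 20,
                           noise: NoiseModel = NoiseModel()) -> DoseResponseData:
    """Steady-state titration: response magnitude -dF/F per concentration.

    Each replicate is the closed-form steady-state response plus
    Gaussian noise.  The default of 20 replicates matches typical
    titration group sizes.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if len(concentrations) == 0:
        raise ValueError("empty concentration list")
    if np.any(concentrations <= 0):
        raise ValueError("titration concentrations must be positive")
    rng = np.random.default_rng(noise.seed)
    clean = np.array([-predict_dff(scheme, fluor, steady_state(scheme, c))
                      for c in concentrations])
    conc = np.repeat(concentrations, replicates)
    resp = np.repeat(clean, replicates)
    if noise.gaussian_sd_frac:
        resp = resp + rng.normal(0.0, noise.gaussian_sd_frac, size=len(resp))
    rep = np.tile(np.arange(replicates), len(concentrations))
    return DoseResponseData(concentration_M=conc, response=resp, replicate=rep)


def simulate_pulse_train(scheme: KineticScheme, fluor: FluorescenceModel,
                         n_pulses: int, pulse_rate_hz: float = 40.0,
                         per_pulse_increment: float = 50e-9,
                         clearance_rate: float = 2.0,
                         sampling: SamplingConfig = SamplingConfig(),
                         noise: NoiseModel = NoiseModel(),
                         pre_s: float = 0.5, post_s: float = 4.0,
                         internal_dt: float = 5e-4) -> Trace:
    """Sensor response to a train of release pulses.

    Each pulse instantaneously adds ``per_pulse_increment`` (molar) of
    ligand which then clears mono-exponentially at ``clearance_rate``
    (s^-1); the summed latent concentration drives the three-state
    sensor.  Returned as a dF/F trace with the latent concentration in
    the annotations.
    """
    if n_pulses < 1:
        raise ValueError("n_pulses must be at least 1")
    train_s = (n_pulses - 1) / pulse_rate_hz
    total = pre_s + train_s + post_s
    nt = int(np.floor(total / internal_dt)) + 1
    ti = np.arange(nt) * internal_dt
    pulse_times = pre_s + np.arange(n_pulses) / pulse_rate_hz
    c = np.zeros(nt)
    for tp in pulse_times:
        after = ti >= tp
        c[after] += per_pulse_increment * np.exp(-clearance_rate * (ti[after] - tp))
    dff_i, f3_i = sensor_dff_path(scheme, fluor, c, internal_dt,
                                  x0=np.array([1.0, 0.0, 0.0]))
    # camera sampling of the internal path
    t_cam = np.arange(int(np.floor(total * sampling.rate_hz)) + 1) / sampling.rate_hz
    idx = np.minimum((t_cam / internal_dt).round().astype(int), nt - 1)
    dff = dff_i[idx]
    rng = np.random.default_rng(noise.seed)
    value = _corrupt(dff, t_cam, 1.0, noise, rng) if noise.gaussian_sd_frac \
        or noise.drift_slope_frac_per_s or noise.bleach_tau_s else dff
    return Trace(time_s=t_cam, value=value, rate_hz=sampling.rate_hz,
                 channel="dff",
                 annotations={"events": pulse_times.tolist(),
                              "ground_truth": {"dff": dff, "f3": f3_i[idx],
                                               "latent_c": c[idx]}})


@dataclass(frozen=True)
class InVivoConfig:
    """Configuration of a simulated awake-imaging session.

    The latent extracellular serotonin signal is a tonic baseline plus
    per-stimulation biphasic transients (fast positive lobe, slower
    negative lobe), reward transients, and a locomotion-coupled term:
    serotonin is high at rest and drops during running, relaxing with
    ``coupling_rise_s`` after transitions (so a movement stop is
    followed by a serotonin rise, i.e. a fluorescence decay).
    """

    duration_s: float = 240.0
    rate_hz: float = 30.3
    # locomotion bout process
    run_dwell_s: float = 8.0
    rest_dwell_s: float = 10.0
    run_speed_cm_s: float = 12.0
    # stimulation train: 9 pulses spaced 20 s by default
    n_stim: int = 0
    stim_spacing_s: float = 20.0
    stim_start_s: float = 20.0
    stim_amp_M: float = 150e-9
    stim_rise_s: float = 0.3
    stim_decay_s: float = 1.5
    stim_undershoot_frac: float = 0.3
    stim_undershoot_decay_s: float = 6.0
    # rewards
    reward_times: tuple = ()
    reward_amp_M: float = 120e-9
    reward_rise_s: float = 0.2
    reward_decay_s: float = 1.0
    # latent serotonin
    baseline_c_M: float = 80e-9
    locomotion_coupling_M: float = 100e-9
    coupling_rise_s: float = 1.0
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration and rate must be positive")
        for ev in self.reward_times:
            if not 0 <= ev <= self.duration_s:
                raise ValueError(f"reward time {ev} outside session")
        if self.baseline_c_M < 0:
            raise ValueError("baseline concentration must be nonnegative")

    @property
    def stim_times(self) -> np.ndarray:
        return self.stim_start_s + np.arange(self.n_stim) * self.stim_spacing_s


def _biphasic_kernel(dt: np.ndarray, amp: float, rise: float, decay: float,
                     undershoot_frac: float = 0.0,
                     undershoot_decay: float = 1.0) -> np.ndarray:
    """Difference-of-exponentials transient, optionally with a slow
    opposite-sign lobe producing a biphasic shape."""
    k = np.where(dt >= 0, np.exp(-np.maximum(dt, 0) / decay)
                 - np.exp(-np.maximum(dt, 0) / rise), 0.0)
    k = k / k.max() if k.max() > 0 else k
    out = amp * k
    if undershoot_frac:
        ku = np.where(dt >= 0, np.exp(-np.maximum(dt, 0) / undershoot_decay)
                      - np.exp(-np.maximum(dt, 0) / (2 * rise)), 0.0)
        ku = ku / ku.max() if ku.max() > 0 else ku
        out = out - undershoot_frac * amp * ku
    return out


def simulate_invivo_session(config: InVivoConfig,
                            scheme: KineticScheme,
                            fluor: FluorescenceModel) -> InVivoSession:
    """One simulated awake-imaging session.

    Builds the speed channel from alternating exponential run/rest
    bouts, assembles the latent serotonin concentration (baseline,
    stimulation and reward transients, locomotion coupling), drives the
    three-state sensor through it and adds measurement noise.  Ground
    truth (latent concentration, noise-free dF/F) lives in the
    fluorescence trace annotations.
    """
    rng = np.random.default_rng(config.noise.seed)
    n = int(np.floor(config.duration_s * config.rate_hz)) + 1
    t = np.arange(n) / config.rate_hz
    dt = 1.0 / config.rate_hz

    # alternating rest/run bouts with exponential dwell times
    speed = np.zeros(n)
    pos, running = 0, False
    while pos < n:
        dwell = rng.exponential(config.run_dwell_s if running
                                else config.rest_dwell_s)
        n_dwell = max(int(round(dwell * config.rate_hz)), 1)
        if running:
            bout = max(rng.normal(config.run_speed_cm_s,
                                  0.15 * config.run_speed_cm_s),
                       SPEED_THRESHOLD_CM_S + 1.0)
            speed[pos:pos + n_dwell] = bout
        pos += n_dwell
        running = not running
    speed = np.maximum(speed + rng.normal(0, 0.2, n), 0.0)

    # latent serotonin concentration
    c = np.full(n, config.baseline_c_M)
    for ts in config.stim_times:
        c += _biphasic_kernel(t - ts, config.stim_amp_M, config.stim_rise_s,
                              config.stim_decay_s, config.stim_undershoot_frac,
                              config.stim_undershoot_decay_s)
    for tr_ in config.reward_times:
        c += _biphasic_kernel(t - tr_, config.reward_amp_M,
                              config.reward_rise_s, config.reward_decay_s)
    if config.locomotion_coupling_M:
        rest = (speed <= SPEED_THRESHOLD_CM_S).astype(float)
        filt = np.empty(n)
        filt[0] = rest[0]
        alpha = dt / config.coupling_rise_s
        for i in range(1, n):
            filt[i] = filt[i - 1] + alpha * (rest[i] - filt[i - 1])
        c += config.locomotion_coupling_M * filt
    c = np.maximum(c, 0.0)

    dff, f3 = sensor_dff_path(scheme, fluor, c, dt)
    f_clean = fluor.f_base * (1.0 + dff)
    value = _corrupt(f_clean, t, fluor.f_base, config.noise, rng)

    fluo = Trace(time_s=t, value=value, rate_hz=config.rate_hz,
                 channel="fluorescence",
                 annotations={"ground_truth": {"latent_c": c, "dff": dff,
                                               "f3": f3}})
    return InVivoSession(fluorescence=fluo, speed_cm_s=speed,
                         stim_times=config.stim_times,
                         reward_times=np.asarray(config.reward_times, dtype=float))


def simulate_roi_stack(frame_shape: tuple[int, int], rois: list,
                       traces: list[np.ndarray], background_level: float = 100.0,
                       noise: NoiseModel = NoiseModel()) -> tuple[np.ndarray, list]:
    """Image stack whose ROI means follow assigned traces.

    Every pixel holds ``background_level``; pixels inside ROI *i*
    additionally hold ``traces[i]`` at each frame.  Overlapping ROIs
    warn (their pixels sum both traces).  Returns ``(stack,
    ground_truth)`` where ``stack`` has shape
    ``(n_frames, rows, cols)`` and ``ground_truth`` is the list of
    assigned traces.
    """
    if len(rois) != len(traces):
        raise ValueError("one trace per ROI required")
    n_frames = len(traces[0])
    masks = []
    for roi in rois:
        m = roi.mask(frame_shape)
        if not m.any():
            raise ValueError("ROI lies outside the frame")
        masks.append(m)
    cover = np.zeros(frame_shape, dtype=int)
    for m in masks:
        cover += m
    if np.any(cover > 1):
        warnings.warn("ROIs overlap; overlapping pixels sum their traces",
                      stacklevel=2)
    stack = np.full((n_frames,) + tuple(frame_shape), float(background_level))
    for m, trv in zip(masks, traces):
        trv = np.asarray(trv, dtype=float)
        if len(trv) != n_frames:
            raise ValueError("all ROI traces must have the same length")
        stack[:, m] += trv[:, None]
    if noise.gaussian_sd_frac:
        rng = np.random.default_rng(noise.seed)
        stack = stack + rng.normal(
            0.0, noise.gaussian_sd_frac * max(background_level, 1.0), stack.shape)
    return stack, [np.asarray(trv, dtype=float) for trv in traces]
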