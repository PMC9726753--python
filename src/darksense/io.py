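"""File formats: CSV traces and sessions, YAML configs, JSON results, TIFF stacks.

All physical quantities carry their unit in the column name
(``time_s``, ``speed_cm_s``, ``concentration_M``); trace-level
metadata travels in ``#``-prefixed header lines so a trace CSV
round-trips losslessly.  See FORMATS.md for the full layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .invivo import InVivoSession
from .scheme_fit import KineticsSummary
from .traces import DoseResponseData, Trace

__all__ = [
    "write_trace_csv", "read_trace_csv",
    "write_session_csv", "read_session_csv",
    "write_events_csv", "read_events_csv",
    "write_summary_csv", "read_summary_csv",
    "write_dose_csv", "read_dose_csv",
    "load_config", "save_json",
    "write_tiff_stack", "read_tiff_stack",
]

_FLOAT_FMT = "%.17g"


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer, np.bool_)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_trace_csv(trace: Trace, path: str | Path) -> None:
    path = Path(path)
    meta = {"rate_hz": trace.rate_hz, "channel": trace.channel,
            "annotations": {k: v for k, v in trace.annotations.items()
                            if k != "ground_truth"}}
    with open(path, "w") as fh:
        fh.write("# darksense-trace v1\n")
        fh.write("# " + json.dumps(meta, default=_json_default) + "\n")
        fh.write("time_s,value\n")
        for t, v in zip(trace.time_s, trace.value):
            fh.write(f"{t:.17g},{v:.17g}\n")


def read_trace_csv(path: str | Path) -> Trace:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# darksense-trace"):
            raise ValueError(f"{path}: not a trace CSV (missing format header)")
        meta = json.loads(fh.readline().lstrip("# ").strip())
        df = pd.read_csv(fh)
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    return Trace(time_s=df["time_s"].to_numpy(), value=df["value"].to_numpy(),
                 rate_hz=float(meta["rate_hz"]), channel=meta.get("channel", ""),
                 annotations=meta.get("annotations", {}))


def write_session_csv(session: InVivoSession, path: str | Path) -> None:
    path = Path(path)
    tr = session.fluorescence
    with open(path, "w") as fh:
        fh.write("# darksense-session v1\n")
        fh.write("# " + json.dumps({"rate_hz": tr.rate_hz}) + "\n")
        fh.write("time_s,fluorescence_au,speed_cm_s\n")
        for t, f, s in zip(tr.time_s, tr.value, session.speed_cm_s):
            fh.write(f"{t:.17g},{f:.17g},{s:.17g}\n")


def read_session_csv(path: str | Path,
                     events_path: str | Path | None = None) -> InVivoSession:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# darksense-session"):
            raise ValueError(f"{path}: not a session CSV (missing format header)")
        meta = json.loads(fh.readline().lstrip("# ").strip())
        df = pd.read_csv(fh)
    for col in ("time_s", "fluorescence_au", "speed_cm_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    tr = Trace(time_s=df["time_s"].to_numpy(),
               value=df["fluorescence_au"].to_numpy(),
               rate_hz=float(meta["rate_hz"]), channel="fluorescence")
    stim, reward = np.array([]), np.array([])
    if events_path is not None:
        ev = read_events_csv(events_path)
        stim = ev.loc[ev["type"] == "stimulation", "time_s"].to_numpy()
        reward = ev.loc[ev["type"] == "reward", "time_s"].to_numpy()
    return InVivoSession(fluorescence=tr, speed_cm_s=df["speed_cm_s"].to_numpy(),
                         stim_times=stim, reward_times=reward)


def write_events_csv(events: dict[str, np.ndarray], path: str | Path) -> None:
    """``events`` maps type name ('stimulation', 'reward', ...) to times."""
    rows = [(float(t), kind) for kind, times in sorted(events.items())
            for t in np.asarray(times, dtype=float)]
    rows.sort()
    with open(path, "w") as fh:
        fh.write("time_s,type\n")
        for t, kind in rows:
            fh.write(f"{t:.17g},{kind}\n")


def read_events_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("time_s", "type"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    return df


def write_summary_csv(summary: KineticsSummary, path: str | Path) -> None:
    cols = {"concentration_M": summary.concentration_M,
            "tau_on_s": summary.tau_on_s, "tau_off_s": summary.tau_off_s,
            "dff_ss": summary.dff_ss}
    for name in ("sd_tau_on_s", "sd_tau_off_s", "sd_dff_ss", "n_patches"):
        v = getattr(summary, name)
        if v is not None:
            cols[name] = v
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_summary_csv(path: str | Path) -> KineticsSummary:
    df = pd.read_csv(path)
    for col in ("concentration_M", "tau_on_s", "tau_off_s", "dff_ss"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    kw = {}
    for name in ("sd_tau_on_s", "sd_tau_off_s", "sd_dff_ss", "n_patches"):
        if name in df.columns:
            kw[name] = df[name].to_numpy()
    return KineticsSummary(concentration_M=df["concentration_M"].to_numpy(),
                           tau_on_s=df["tau_on_s"].to_numpy(),
                           tau_off_s=df["tau_off_s"].to_numpy(),
                           dff_ss=df["dff_ss"].to_numpy(), **kw)


def write_dose_csv(data: DoseResponseData, path: str | Path) -> None:
    pd.DataFrame({"concentration_M": data.concentration_M,
                  "response": data.response,
                  "replicate": data.replicate}).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def read_dose_csv(path: str | Path) -> DoseResponseData:
    df = pd.read_csv(path)
    for col in ("concentration_M", "response"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return DoseResponseData(concentration_M=df["concentration_M"].to_numpy(),
                            response=df["response"].to_numpy(), replicate=rep)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def save_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def write_tiff_stack(stack: np.ndarray, path: str | Path) -> None:
    """Multi-frame grayscale TIFF, 16-bit unsigned, frame order = time."""
    stack = np.asarray(stack)
    out = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, out, photometric="minisblack")


def read_tiff_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    return arr.astype(float)
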