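"""ROI time-series extraction from an image stack.

Builds a small synthetic movie in which an annular ROI around a cell
membrane follows a known fluorescence transient on top of a uniform
background, writes it to TIFF, reads it back and recovers the trace by
ROI averaging with background subtraction.
"""

import tempfile
from pathlib import Path

import numpy as np

from darksense import AnnulusROI, DiskROI, extract_roi_timeseries
from darksense.io import read_tiff_stack, write_tiff_stack
from darksense.synth import NoiseModel, simulate_roi_stack

rate_hz = 30.3
t = np.arange(90) / rate_hz
transient = -60.0 * np.exp(-np.maximum(t - 1.0, 0) / 0.4) * (t >= 1.0)

membrane = AnnulusROI(row=24, col=24, r_inner=6, r_outer=10)
background = DiskROI(row=50, col=50, radius=5)

stack, truth = simulate_roi_stack(
    (64, 64), [membrane], [500.0 + transient], background_level=200.0,
    noise=NoiseModel(gaussian_sd_frac=0.01, seed=5))

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "movie.tif"
    write_tiff_stack(stack, path)
    stack_back = read_tiff_stack(path)

trace = extract_roi_timeseries(stack_back, membrane, background,
                               rate_hz=rate_hz)
err = np.abs(trace.value - truth[0]).max()
print(f"stack: {stack.shape[0]} frames of {stack.shape[1]}x{stack.shape[2]} px")
print(f"ROI mean at baseline      = {trace.value[:20].mean():7.1f} a.u.")
print(f"ROI mean at transient dip = {trace.value.min():7.1f} a.u.")
print(f"max |recovered - truth|   = {err:.2f} a.u. "
      "(pixel noise + 16-bit rounding)")
print("\nThe per-frame ROI mean minus the background-ROI mean recovers the "
      "assigned membrane trace; the dip is the sensor darkening.")
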