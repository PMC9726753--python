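"""Fast-perfusion patch fluorometry: simulate sweeps, average, fit kinetics.

Simulates 7 noisy sweeps of a 1 s application of 100 uM serotonin
sampled at 91 Hz, averages them, converts to dF/F against the
pre-application baseline and fits single exponentials to the ON and
OFF phases — the standard analysis of such recordings.
"""

from darksense import (REFERENCE_FLUOR, REFERENCE_SCHEME, ApplicationProtocol,
                       SamplingConfig, average_sweeps, baseline_correct,
                       compute_dff, fit_exponential, observed_rates,
                       simulate_patch_sweeps)
from darksense.synth import NoiseModel

protocol = ApplicationProtocol(concentration=100e-6, pre_s=0.5, app_s=1.0,
                               post_s=3.0, n_sweeps=7)
noise = NoiseModel(gaussian_sd_frac=0.01, drift_slope_frac_per_s=0.002, seed=42)
sweeps = simulate_patch_sweeps(REFERENCE_SCHEME, REFERENCE_FLUOR, protocol,
                               SamplingConfig(rate_hz=91.0), noise)
avg = baseline_correct(average_sweeps(sweeps))
avg.value += REFERENCE_FLUOR.f_base          # restore absolute baseline
dff = compute_dff(avg, (0.0, 0.49))

on = fit_exponential(dff, direction="on")
off = fit_exponential(dff, direction="off")
print(f"averaged {protocol.n_sweeps} sweeps at 91 Hz, 100 uM application")
print(f"peak dF/F       = {dff.value.min():+.3f}")
print(f"tau_ON  (fit)   = {on.tau_s * 1e3:6.1f} ms  (model slow eigenvalue "
      f"{1e3 / observed_rates(REFERENCE_SCHEME, 100e-6)[0]:.1f} ms)")
print(f"tau_OFF (fit)   = {off.tau_s * 1e3:6.1f} ms  (model washout "
      f"{1e3 / observed_rates(REFERENCE_SCHEME, 0.0)[0]:.1f} ms)")
print("\nThe ON fit tracks the slow relaxation eigenvalue at the applied "
      "concentration; the OFF fit tracks the concentration-independent "
      "washout eigenvalue.")
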