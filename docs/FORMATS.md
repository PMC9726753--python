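# File formats

All physical quantities carry their unit in the column name; times are
seconds, concentrations molar (scientific notation), speeds cm/s,
ΔF/F dimensionless and signed (negative = darkening). Floats are
written with 17 significant digits so write → read round-trips are
lossless.

## Trace CSV (`write_trace_csv` / `read_trace_csv`)

```
# darksense-trace v1
# {"rate_hz": 91.0, "channel": "dff", "annotations": {"application": [0.5, 1.5], ...}}
time_s,value
0,0.0012...
```

Line 1 identifies the format, line 2 is a JSON metadata object
(sampling rate, channel kind, protocol annotations; bulky ground-truth
arrays are not serialized). The time grid must be uniform and
consistent with `rate_hz`; violations raise on read.

## Session CSV (`write_session_csv` / `read_session_csv`)

```
# darksense-session v1
# {"rate_hz": 30.3}
time_s,fluorescence_au,speed_cm_s
```

Events travel in a separate CSV with columns `time_s,type`, where
`type` is `stimulation` or `reward` (`write_events_csv`).

## Kinetics summary CSV (`write_summary_csv`)

Columns: `concentration_M, tau_on_s, tau_off_s, dff_ss` plus optional
`sd_tau_on_s, sd_tau_off_s, sd_dff_ss, n_patches`. `dff_ss` is the
positive magnitude |ΔF/F| at steady state.

## Dose-response CSV (`write_dose_csv`)

Columns: `concentration_M, response, replicate`; `response` is the
positive magnitude −ΔF/F.

## Configs and results

Run configurations are YAML mappings (see `examples/` and the CLI
docstrings); fit results are JSON with unit-suffixed keys
(`k23_s-1`, `kd_M`, ...). Every stochastic step takes an explicit
seed.

## Image stacks

Multi-frame grayscale TIFF, 16-bit unsigned, frame order = time
(`write_tiff_stack`; values are rounded and clipped to [0, 65535]).
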