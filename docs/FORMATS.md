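# File formats

All persistent artifacts are plain text (CSV, JSON) except image stacks
(multi-page TIFF). Floats are written with 17 significant digits, so
write-then-read is the identity.

## ThT trace CSV

```
# label: hh
# normalized: False
# variant: wildtype
# seed: 123
time_min,intensity
0,1
0.1,1.0435...
```

`#` lines are comment headers (`label` and `normalized` are honoured on
read; anything else is provenance). Columns: `time_min` (strictly
increasing) and `intensity` (arbitrary fluorescence units, >= 0). Readers
reject missing columns and non-monotone time.

## FDF frames CSV (long format)

Columns: `t_min, cell_id, x_um, y_um, z_um, state, tht` — one row per
cell per recorded frame. `state` is one of `quiescent`, `firing`,
`refractory`, `habituated`. Cell positions are constant across frames;
readers reconstruct the position table from any frame.

## Wavefront track CSV

Columns: `phase, time_min, R_um`. `phase` is `centrifugal` or
`centripetal`; times restart at 0 per phase (centripetal origin at
collapse onset); `R_um` is the front radius (absolute, decreasing for the
centripetal phase).

## Fits JSON

```json
{"fits": [{"phase": "centrifugal", "Rc": 2.1, "b": 7.3, "gamma": 1.22,
           "sds": {"Rc": 0.4, "b": 0.8, "gamma": 0.05},
           "residual_norm": 3.2, "n_points": 51}]}
```

## Peaks / stats JSON

`peaks`: `{"n_peaks": 2, "peak_times_min": [...], "peak_heights": [...],
"prominence": 0.15}`. Latency statistics: `{"n": ..., "mean": ...,
"sd": ..., "se": ...}` (minutes).

## Run configuration JSON

Top-level keys: `hh`, `fdf`, `template`, `stack` (parameter blocks whose
fields match the corresponding dataclasses exactly — unknown keys are
rejected with an aggregated error report), `seed` (integer), `log_level`.
Gate sigmoids inside the `hh` block are objects `{"v_half": ...,
"slope": ...}`. `save_config` / `load_config` round-trip exactly.

## Image stacks

Multi-page TIFF, axes `TZYX`, float32 photon counts; metadata records the
frame times (min) and isotropic voxel size (um). The stack center maps to
the biofilm origin.
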