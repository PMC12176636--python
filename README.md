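# twoprocess

Simulator and entrainment-analysis toolkit for the **two-process model of
sleep-wake regulation**: a scalar homeostatic sleep pressure rises
exponentially toward an upper asymptote during wake, decays toward a lower
asymptote during sleep, and the vigilance state switches at a pair of
circadian-modulated thresholds.

Because the pressure is in closed form inside each state, the simulation is
event-driven — no ODE integration anywhere.  The forced model reduces to a
circle map (upper-threshold hit phase to next hit phase), and the package
builds the standard machinery on top of it: rotation numbers,
rational-locking classification, Arnold-tongue grid scans and
Devil's-staircase sweeps.

## Layout

| module                     | contents                                                                 |
|----------------------------|--------------------------------------------------------------------------|
| `twoprocess.core_model`    | `ModelParams` (8 parameters + waveform), pressure/threshold closed forms, shift-and-rescale reduction, natural-period formulas and their inverse |
| `twoprocess.simulator`     | first-crossing search, event-driven `simulate`, raster folding, circadian-minimum times |
| `twoprocess.entrainment`   | `circle_map_step`, `rotation_number`, `classify_rotation`, `sleeps_per_day`, `tongue_scan`, `staircase` |
| `twoprocess.presets`       | canonical parameter sets (`fig1b` ... `fig8_base`, `mouse`)              |
| `twoprocess.io` / `cli`    | JSON config loading, CSV writers with provenance headers, `twoprocess` CLI |

## CLI

```bash
# closed-form periods for the unforced standard parameters
twoprocess periods --fixture fig6a

# episode log for the polyphasic regime (two sleeps per day)
twoprocess simulate --fixture fig1e --horizon-days 80 --out episodes.csv

# parameters from a JSON file, with a flag override
twoprocess simulate --config params.json --amplitude 0.1 --out episodes.csv

# scaled-down Arnold-tongue scan (long-format CSV)
twoprocess tongue --fixture fig7_base --sweep H0_plus \
    --sweep-range 0.3:0.95:60 --amp-range 0:0.12:40 --out tongue.csv

# Devil's staircase at fixed amplitude
twoprocess staircase --fixture fig8_base --h0plus-range 0.3:0.95:120 --out stairs.csv

# tabulate the circle map
twoprocess circlemap --fixture fig1b --phases 64
```

JSON parameter files use the keys
`chi_w, chi_s, mu_w, mu_s, H0_plus, H0_minus, a, T_f, waveform`; omitted
`mu_w`/`mu_s`/`T_f`/`waveform` default to `1 / 0 / 24 / "cosine"` (the
scaled form).  Exit codes: 0 success, 2 configuration error,
3 non-terminating dynamics.

All exports are plain CSV with `#`-prefixed provenance headers; plotting is
left to the user (the raster helper `episodes_to_raster` and the sampled
trajectories give figure-ready columns).

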