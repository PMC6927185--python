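# phenopam

Automated extraction of photosynthetic phenotypes from chlorophyll-fluorescence
image stacks recorded with a Walz IMAGING-PAM fluorometer.

Screening a mutant panel with an IMAGING-PAM produces one multi-frame TIFF per
tray per measurement — the dark-adapted Fo/Fm pair, two absorptivity frames,
and an induction curve of F′/Fm′ pairs captured under actinic light. Analysing
these by hand in the instrument software does not scale past a handful of
trays. `phenopam` turns a directory of such exports into one tidy table of
per-plant phenotypes with QC flags, plus false-colour renderings, a QC report
and time-lapse animations. It is written for plant photosynthesis labs running
daily screening campaigns (e.g. *Arabidopsis* rosettes under fluctuating
light), but nothing in it is specific to one species.

## What it computes

For every plant (ROI) and induction step, from the pixelwise fluorescence
frames:

- **Fv/Fm = (Fm − Fo) / Fm** — maximum quantum yield of photosystem II of the
  dark-adapted plant (equal to YII at induction step 1 when the protocol
  starts dark-adapted, which is how it is reported here);
- **YII = (Fm′ − F′) / Fm′** — operating PSII quantum yield in the light;
- **NPQ = (Fm − Fm′) / Fm′** — non-photochemical quenching, displayed as
  NPQ/4 on a [0, 1] colour scale by convention;
- **plant area** in mm², from the segmented pixel count and a mm-per-pixel
  calibration (measured once per camera setup from an object of known size:
  `pixel_resolution = diameter_mm / diameter_px`).

Plants are separated from the background by an automatic threshold maximising
Yen's entropic-correlation criterion on the image histogram, followed by
small-object removal and hole filling; connected components are attributed to
a configurable grid of circular ROIs. Every record carries two QC flags:
*complete* (the plant does not run off the image edge) and *independent* (it
does not merge with a neighbour). Flags are never used to drop rows — removal
is the analyst's decision.

A fully ground-truthed synthetic scene generator (`phenopam.synthetic`)
emulates the instrument's export format end to end, including defective
scenes, so the whole pipeline is testable without an instrument.

## Worked example

Simulate a small two-tray, three-day experiment and process it:

```python
from phenopam import RunConfig, process_directory, make_experiment

indir, layout = make_experiment("demo/data", n_trays=2, plants_per_tray=8,
                                n_days=3, n_steps=15, seed=42)
cfg = RunConfig(indir=indir, outdir="demo/run",
                frame_map_path=indir / "pimframes_map.csv",
                genotype_map_path=indir / "genotype_map.csv",
                pixel_resolution=0.2)           # mm per pixel
table = process_directory(cfg)
print(f"{len(table)} records")
```

```
1488 records
```

1488 = 3 days × 16 plants × (2 photosynthetic parameters × 15 induction steps
+ 1 area estimate). For one plant, the area trend and the NPQ induction curve
look like:

```
      date genotype parameter  value
2019-09-01       WT  area_mm2   7.40
2019-09-02       WT  area_mm2  10.44
2019-09-03       WT  area_mm2  14.52

parameter  induction_step  value  qc_complete  qc_independent
      NPQ               1 0.0000         True            True
      NPQ               8 1.8836         True            True
      NPQ              15 2.0523         True            True
```

The rosette grows day by day; NPQ is zero at step 1 (dark-adapted, Fm′ = Fm)
and rises toward its saturating value along the induction curve. The same run
directory then feeds the report and the animations:

```sh
phenopam report --table demo/run/phenotypes.csv --out demo/report
phenopam video --run demo/run/run_config.json --parameter NPQ
```

The command line mirrors the library: `phenopam simulate | process | report |
video` (see `phenopam --help`).

## Layout

| module | contents |
|---|---|
| `phenopam.config_maps` | filename convention, frame map, genotype map |
| `phenopam.stack_io` | multi-page TIFF read/write, frame access by role |
| `phenopam.segmentation` | Yen threshold, mask cleaning, ROI grid, QC flags |
| `phenopam.phenotypes` | Fv/Fm, YII, NPQ, area, false-colour rendering |
| `phenopam.synthetic` | ground-truthed scene and experiment generator |
| `phenopam.pipeline` | directory processing, QC report, time-lapse GIFs |
| `phenopam.cli` | `phenopam` command-line entry point |

See `docs/methods.md` for the model, parameter defaults and numerical
choices.
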