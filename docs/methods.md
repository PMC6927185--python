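# Methods

## Input model

A measurement is a multi-page grayscale TIFF (8- or 16-bit) whose page order
follows the instrument's fixed export convention: frames 1–2 are the
dark-adapted minimal and maximal fluorescence (Fo, Fm), frames 3–4 the red and
NIR absorptivity images, and frames 5 onward come in F′/Fm′ pairs, one pair
per induction step. When the protocol measures Fo/Fm as the first induction
period, frames 5/6 repeat frames 1/2; the default frame map
(`default_frame_map()`, 15 pairs → 34 frames) assumes this. Filenames encode
the measurement identity as `treatment-YYYYMMDD-sampleid.tif`; the treatment
and sample tokens may not themselves contain hyphens, which the parser
enforces. Two CSV metadata maps accompany a run: the frame map
(`frameid,parameter,induction_step,induction_time` — the column dialect is
this package's choice) and the genotype map (`sampleid,roi,genotype`).

Intensities are kept as raw integer counts end to end; every ratio is
computed in floating point at use time. Absorptivity frames are read and
stored but feed no phenotype.

## Segmentation

Plants are segmented on the dark-adapted **Fm frame** (configurable):
maximal fluorescence gives the strongest plant/background contrast.

**Threshold.** `yen_threshold` maximises Yen's entropic-correlation
criterion

C(t) = 2 ln(P1(t)·(1 − P1(t))) − ln(S1(t)·S2(t)),

where P1 is the cumulative histogram mass at bin t, S1 the cumulative squared
mass and S2 the tail squared mass, over a 256-bin histogram spanning the full
dtype range (16-bit images are binned, not truncated). Because the
normalisation constants cancel, C is evaluated from exact integer histogram
sums; histogram plateaus therefore tie *exactly* and the documented
tie-break (smallest t) is well defined — with floating-point cumulative sums
the tie-break was at the mercy of summation order. Foreground is every pixel
strictly greater than the returned gray level. A constant image raises a
degenerate-input error; the caller decides the fallback. The test suite pins
the implementation to an independent brute-force scan of the criterion and,
on 8-bit images, to scikit-image's `threshold_yen`.

**Cleaning.** 8-connected components smaller than `min_object_px` (default
100 px for 640×480 frames) are removed; 4-connected interior holes smaller
than `max_hole_px` (default 100 px) are filled. Both bounds are strict
("smaller than"), the operation is idempotent, and both values are exposed —
imaging setups differ and these defaults only suit rosettes of at least a
few hundred pixels.

**ROI attribution.** ROIs are disjoint circles on a regular grid, numbered
row-major from 1 (reading order of a tray photo). A connected component
belongs to every circle it shares at least one pixel with — membership by
intersection, not centroid, because a leaf extending beyond the circle still
belongs to its plant. Flags per ROI: `independent=False` iff some component
intersects ≥ 2 circles (all involved ROIs are flagged); `complete=False` iff
the ROI's component touches the image border. Components intersecting no
circle are excluded from per-ROI masks but counted in the diagnostics.
Per-ROI masks are pairwise disjoint exactly when all ROIs are independent; a
merged component is deliberately attributed to all its ROIs so that neither
plant's record silently loses pixels.

## Phenotypes

Per-pixel ratios on the plant mask: Fv/Fm = (Fm − Fo)/Fm,
YII_t = (Fm′_t − F′_t)/Fm′_t, NPQ_t = (Fm − Fm′_t)/Fm′_t. The per-plant
summary is the **mean of the pixelwise ratio**, not the ratio of mean
intensities — the two differ under heterogeneity, and averaging pixelwise
keeps the summary consistent with the false-colour images. The reported
Fv/Fm equals YII at step 1 of a dark-adapted protocol, so the complete
per-plant record per measurement is 2 parameters × n steps + 1 area.

Pixels whose denominator (Fm or Fm′) falls below a signal floor ε are
excluded from the image and from the average. ε defaults to 5% of the
*maximum of the denominator frame* rather than a fixed fraction of the dtype
maximum: a dtype-relative floor makes the cutoff depend on container bit
depth instead of signal, and at realistic 16-bit count levels (Fm ≈ 4000) it
would swallow strongly quenched pixels (Fm′ = Fm/(1+NPQ) ≈ 1600 at NPQ 1.5).
An absolute floor in counts can be given instead. A plant whose defined
pixel set is empty yields a null value with a warning, never a crash.

Stored values are never clamped — out-of-range values are themselves a QC
signal. Clamping happens only in the display transform: Fv/Fm and YII map to
[0, 1] directly, NPQ is divided by 4 first (the conventional NPQ/4 display
scale). False-colour rendering uses one fixed perceptual colormap (viridis)
over exactly [0, 1] so colours are comparable across every image and
animation frame of an experiment; undefined pixels take a neutral dark gray.

Area is `pixel_count · pixel_resolution²` (mm²), with
`pixel_resolution = diameter_mm / diameter_px` calibrated once per setup
from an imaged object of known size; the default 0.2 mm/px corresponds to a
6 mm hole punch spanning 30 px.

## Synthetic scenes

The generator inverts the phenotype equations. Given per-plant prescriptions
(Fo level, Fv/Fm, YII and NPQ trajectories with YII₁ = Fv/Fm and NPQ₁ = 0),
every frame's plant level follows from

Fm = Fo/(1 − Fv/Fm), Fm′_t = Fm/(1 + NPQ_t), F′_t = Fm′_t·(1 − YII_t),

rendered as disks or k-lobed rosettes at ROI centres over a uniform
background, with additive zero-mean Gaussian noise clipped to the dtype
range. Frames 5/6 are verbatim copies of the (noisy) frames 1/2 — the export
convention repeats the dark-adapted measurement — so the step-1 identities
YII₁ ≡ Fv/Fm and NPQ₁ ≡ 0 hold pixel for pixel even under noise.

Plant pixels carry mild multiplicative lognormal texture (`texture_sd`,
default 0.04), identical in every frame of a scene. Real leaves are not
flat fields, and the idealised flat disk is actively misleading for
segmentation: its spiky foreground histogram can make the entropy criterion
split *between plants* instead of between plants and background (scikit-image's
Yen does the same on such images). Because the texture scales Fo, Fm, F′ and
Fm′ together, every ratio parameter is pixelwise invariant to it; only the
integer quantisation of the textured levels (≤ 0.5 count) perturbs recovered
ratios, at the few-×10⁻⁴ level. Exact-inversion tests therefore use
`texture_sd=0` together with trajectories built from integer fluorescence
levels (`exact_trajectories`), for which the rendered frames realise the
prescription exactly and recovery is accurate to 10⁻¹²; arbitrary float
prescriptions are realised to quantisation accuracy.

Defect injection drives the QC tests: `BorderClip` shifts a plant toward the
nearest image edge (keeping it inside its ROI circle, extending a leaf to
the border if the shift alone does not reach) so `complete` must trip;
`Merge` draws a 3-px bridge of foreground between two plants so
`independent` must trip on exactly those ROIs.

`make_experiment` simulates a screening campaign: one stack per tray per day
with convention-conforming filenames, both metadata maps, and a
`ground_truth.csv` of every prescribed value. Defaults mirror the
demonstration experiment this package is sized for: 6 trays × 8 plants
(2×4 grid of 60-px ROIs on 640×480 frames), 11 days, the 15-step protocol,
half the trays `control` and half `fluc`. Genotype baselines (Fv/Fm,
steady-state YII, saturating NPQ) cover a wild type and three photosynthesis
mutants with low/high NPQ character; trajectories are saturating-exponential
induction kinetics with small seeded wiggle, plant radii grow linearly
(~1.1–1.6 px/day from ~8–10 px) so area trends are monotone, and noise
defaults to 80 counts ≈ 2% of the typical Fm level of 4000. One integer seed
determines the directory bit for bit.

**What the generator does not emulate:** optics (vignetting, actinic light
gradients, focus), leaf morphology beyond lobed blobs, movement between
measurements, algae/moss contamination, Poisson photon statistics, or the
biological parameter values of any published experiment. Passing tests
demonstrate that the pipeline inverts its own forward model and counts,
flags and round-trips correctly — not that segmentation parameters are right
for any particular instrument, which always needs the per-setup tuning
described above.

## Pipeline

`process_directory` walks the input directory in sorted filename order; a
file whose name does not parse is skipped and logged, never fatal (a run
with zero parsable files is an error). Each stack is segmented once; YII and
NPQ images are computed for all steps; records are emitted for every ROI
position of the layout, so the tidy table has exactly
`n_days · n_plants · (2·n_steps + 1)` rows for a complete run and missing
plants appear as explicit null/zero records rather than silently missing
rows. Genotype joining is strict by default — a missing map entry aborts the
run before anything is written; the lenient flag substitutes the sentinel
`unknown` with a logged warning. Output is a long-format CSV (one value per
row: treatment, date, sample_id, roi, genotype, parameter, induction_step,
value, qc_complete, qc_independent), identical byte for byte across reruns
of the same configuration; the configuration is echoed to
`run_config.json` for provenance, and a per-file processing log and optional
mask-overlay PNGs accompany it.

`qc_report` renders a storyboard markdown report: a date × tray completeness
matrix, the list of tripped QC flags, and bar *and* line timeseries per
phenotype grouped by genotype × treatment. YII and NPQ timeseries are
summarised at the final induction step (closest to steady state); empty
groups render as annotated empty panels.

`timelapse` compiles false-colour GIFs per tray group (default: consecutive
pairs of trays, since no pairing rule is inherent to the data — the grouping
is configurable), frames in date order, genotype labels drawn beside each
ROI, colour scale fixed across the animation. A date missing for part of a
group is skipped with a log note; a single surviving time point degrades to
a one-frame still with a warning.

## Numerical and design notes

- Histogram bins: 256 spanning the dtype range; integer-sum criterion (see
  above) for exact ties.
- Connectivity: 8 for objects, 4 for holes — the choice changes counts, so
  it is fixed and stated.
- ROI grids reject overlapping (radius > spacing/2) or out-of-bounds
  circles at construction.
- `plant_value` uses the arithmetic mean over defined pixels; empty → null.
- The tidy table is sorted on (date, sample_id, roi, parameter, step) before
  writing, which together with deterministic processing gives byte-identical
  output.
- Problem sizes in the test suite are chosen small (1–2 trays, 3–5 steps,
  140×300 frames) except the one full-campaign count check, which runs the
  complete 66-stack simulation at native 640×480 resolution.

## Known limitations

- No reader for the proprietary `.pim` format; only exported TIFFs.
- Absorptivity frames are carried but unused; no qP/qN, ETR or light-curve
  fitting.
- Segmentation assumes a dark background and bright plants; severe algae
  growth or low-contrast setups need retuned cleaning parameters, a
  different threshold frame, or an externally supplied mask.
- The QC `complete` flag tests border contact only; a plant occluded inside
  the frame is not detected.
- RGB exports are rejected rather than converted; the instrument exports
  grayscale.
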