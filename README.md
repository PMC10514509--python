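# orgwound

Single-cell spatial quantification of airway-organoid repair after targeted
laser ablation — nucleus detection and LAP tracking, circle-fit geometry
with arc distances to the ablation site, 30-µm distance-binned
proliferation and migration statistics, z-averaged diameter morphometry —
plus a synthetic organoid time-lapse generator that makes every stage
verifiable against ground truth without any external data.

## Who this is for

Groups doing laser nanosurgery / wound-healing experiments on spherical
epithelial organoids who need reproducible, scriptable quantification of
multi-channel TIFF time-lapse z-stacks: how fast does the organoid regain
its size, where do cells proliferate relative to the wound, and how far do
cells migrate as a function of distance from the wound.

## The model in brief

An organoid cross-section is a near-circular epithelial shell. For each
frame the cell positions (x_i, y_i) are fitted with an algebraic
least-squares circle (Kåsa): minimize Σ (x² + y² + Dx + Ey + F)², giving
centre c and radius r. A cell at angle θ and the ablation site at θ₀ are
separated by the **arc distance**

    d = r · min(|θ − θ₀|, 2π − |θ − θ₀|)  ∈ [0, πr],

binned into half-open 30-µm bins [0,30), [30,60), … Readouts per organoid:

- **proliferation**: EdU⁺/all cells, overall and per bin (positivity by
  per-organoid Otsu threshold on nuclear EdU intensity);
- **migration**: per-track path length Σ‖Δx‖ (net displacement and maximum
  excursion also computed), mean per bin of the track's reference-frame
  distance; tracks from LAP linking with gap closing;
- **growth**: mean of the segmented mask's second-moment ellipse axes per
  z-slice, averaged over slices, normalized to the pre-ablation timepoint.

Condition summaries are mean ± SEM **across organoids** (n = organoids),
compared with Student's unpaired t-test / one-way ANOVA at α = 0.05.

## Worked example

Simulate a 20-cell organoid, ablate two cells, run the whole pipeline:

```sh
orgwound e2e --set synth.organoid.n_cells=20 \
             --set synth.organoid.radius_um=40 \
             --set synth.organoid.n_frames=3 \
             --set synth.ablate_k=2 \
             --set outdir=demo_run
```

which logs, among other lines,

```
orgwound INFO detect: 59 detections over 3 frames, 0.04s
orgwound INFO track: 21 tracks
orgwound INFO prolif: overall rate 0.105 over 19 cells
orgwound INFO migrate: overall mean 1.17 um over 19 tracks
orgwound INFO morph: rel diameter at last timepoint 99.0%
```

and writes `detections.csv`, `tracks.csv`, `geometry.csv`,
`proliferation.csv`, `migration.csv`, `diameter.csv`, bar/line figures, a
run log and the fully resolved config into `demo_run/`. Reading: 59
detections over 3 frames is ~20 per frame (18 surviving cells plus the
wound's autofluorescent scar, which can be suppressed with
`detect.exclusion_radius_um`); the proliferation table gives the EdU⁺
fraction per 30-µm arc-distance bin (2/19 cells called positive here); the
relative diameter stays at ~100 % because 1 h of default growth (0.25 %/h)
is below the measurement's resolution.

The same stages are available as a library (`orgwound.make_organoid`,
`detect_nuclei`, `build_tracks`, `fit_circle`, `proliferation_map`,
`migration_map`, `diameter_series`, `aggregate_condition`, …) and accept
plain point tables wherever images are optional.

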