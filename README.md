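# rodmotion

Quantitative fluorescence-imaging analysis of bacterial Rod-complex
(elongasome) dynamics, with a synthetic-microscopy test bench.

Rod-shaped bacteria build their side wall with a multiprotein machine
(MreB + RodA/PBP2 and partners) whose complexes move *circumferentially* —
around the cell's short axis — at tens of nm/s, driven by wall synthesis.
Comparing a wild type against an activated synthase variant then comes down
to a handful of image-derived numbers: per-track speeds, directional tracks
per μm² of cell area, filament lengths from super-resolution snapshots, and
the TIRF:widefield fluorescence ratio as a proxy for membrane recruitment.
This package implements that measurement pipeline for people who do this
kind of single-particle TIRF microscopy on bacteria — and, because such raw
movies are rarely shareable, ships a synthetic generator of rod-shaped
(spherocylindrical) cells with moving membrane foci and known ground truth,
so every stage is testable end to end.

## What it computes

* **Geometry** — total, projected and TIRF-illuminated surface areas of a
  spherocylinder of length L and width W resting on the coverslip. The
  illuminated area under a hard cutoff at depth d is
  2r·θmax·(L − 2r) + 2πr·d with θmax = arccos(1 − d/r), r = W/2.
* **Tracking** — Gaussian matched-filter spot detection, mutual-nearest-
  neighbour linking (no gap closing), the survival filter (keep tracks with
  ≥ 5 consecutive frames **and** ≥ 70 nm net displacement), per-track speed
  (principal-axis fit, mean-step, or geometry-aware arc-length estimators),
  kymographs and their ridge slopes, and surviving tracks per μm² of
  projected cell area.
* **Filament lengths** — orient each ROI by intensity moments, rotate it to
  horizontal, line-scan at 2-pixel width, and report the longest contiguous
  run above background + 50% of the amplitude, in nm.
* **Membrane fraction** — per-cell integrated TIRF / widefield fluorescence
  for two strains mixed in one field, demultiplexed by a cytoplasmic red
  marker, pooled over both marker orientations.
* **Statistics** — mean ± SD summaries, two-sided Mann-Whitney U (exact for
  small tie-free samples), fixed-width histograms anchored at 0.

See `docs/methods.md` for the model, estimators and their assumptions.

## Worked example

Illuminated area of an average wild-type cell (3.57 × 1.00 μm) under 200 nm
evanescent illumination:

```sh
$ rodmotion geometry --length 3.57 --width 1.0 --depth 0.2
total surface area (um^2)    11.2155
illuminated area (um^2)      3.0115
illuminated fraction         0.2685
projected area (um^2)        3.3554
```

So ~27% of this cell's membrane lies within the evanescent field; dividing a
cell's directional-track count by the projected area (3.36 μm²) gives the
tracks/μm² used to compare strains. The same numbers are available in
Python:

```python
from rodmotion.geometry import (Spherocylinder, IlluminationModel,
                                illuminated_surface_area)
illuminated_surface_area(Spherocylinder(3.57, 1.00), IlluminationModel(0.2))
# 3.011467240982102
```

A full synthetic experiment — simulate a field of cells with moving foci,
detect, link, filter, estimate speeds — runs from one config:

```sh
rodmotion simulate --config sim.yaml --out out/ --seed 1   # TIFF + truth CSV
rodmotion track --movie out/movie_green_tirf.tif --out out/trk
rodmotion run --config pipeline.yaml --out out/ --seed 1   # all stages + JSON
```

or from Python via `rodmotion.run_pipeline(config, out_dir, seed)`. The
validation studies in `rodmotion.experiments` recover generator truth
through the full chain; for example `velocity_recovery(seed=1)` simulates
~300 emitters at a true 22 ± 6 nm/s and returns a measured population mean
of 22.4 nm/s over 202 surviving tracks.

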