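# Methods

`rodmotion` quantifies the dynamics of the bacterial Rod complex
(elongasome) from fluorescence microscopy of rod-shaped cells: the
circumferential speed of wall-synthesis complexes, their surface density per
cell, the length of membrane-associated cytoskeletal (MreB-like) filaments,
and the membrane-recruited fraction of a fluorescent fusion protein. Because
such measurements are made on movies that are rarely redistributable, the
package pairs every measurement chain with a synthetic-microscopy generator
of known ground truth, and its validation studies are parameter-recovery
experiments on that generator.

## Cell and illumination model

A cell is a spherocylinder — a cylinder of diameter W capped by two
hemispheres, tip-to-tip length L — resting on the coverslip, whose plane is
z = 0. A membrane point at circumferential angle θ from the bottom contact
line sits at height z = r(1 − cos θ) on the cylinder flank (r = W/2); on the
caps the cross-section circle shrinks to ρ = √(r² − a²) at axial overshoot a
and z = r − ρ cos θ.

Closed-form areas (lengths in μm):

* total surface: 2πr(L − 2r) + 4πr²
* projected footprint (the segmentation area used to normalise track
  counts): W(L − W) + π(W/2)²
* illuminated surface under a hard evanescent cutoff at depth d:
  flank band 2r·θmax·(L − 2r) with θmax = arccos(1 − d/r), plus the
  spherical zone 2πr·d contributed by the two caps together; equals the
  total area once d ≥ W.

All three are cross-checked in the test suite against independent numeric
quadrature/triangulation of the surface of revolution and against pixel
rasterisation (agreement within 0.5%/1%).

Two illumination modes are modelled. TIRF excitation decays as exp(−z/d)
with d = 200 nm when rendering images (an evanescent field is exponential),
while the *area* bookkeeping above uses the hard cutoff z ≤ d — an area
requires a boundary, and the published illuminated-area calculation is of
that form. Widefield collects every fluorophore up to its ~800 nm depth of
field with unit efficiency and nothing beyond it; for a 1 μm-wide cell this
loses the topmost membrane band, which is why even a purely cytoplasmic
population has a TIRF:widefield ratio well below 1 rather than exactly the
depth-weighted value.

### Default cell dimensions

The published worked example reports illuminated areas of 3.01 μm²
(wild type) and 3.38 μm² (the activated PBP2 variant) at 200 nm depth, from
"adjusted" average cell dimensions shown only graphically. Inverting the
illuminated-area formula under the reported "~20% longer, ~10% thinner"
relation has no realistic solution (it forces W ≈ 0.49 μm), so the package
fixes realistic widths — 1.00 μm (wild type) and 0.90 μm (10% thinner
variant) — and solves for the lengths that reproduce the printed areas:
L = 3.57 μm and L = 4.09 μm. With these defaults the model returns 3.011 and
3.384 μm² (0.2% from the printed values); they are defaults, not constants,
and every geometry function takes dimensions as arguments.

## Synthetic movies

Foci (wall-synthesis complexes) are membrane-anchored point emitters that
rotate about the cell's long axis: θ(t) = θ₀ ± v·t/r with the axial
coordinate fixed. Speeds are Gaussian (default 22 ± 6 nm/s, resampled to
stay above 5 nm/s); per-cell emitter counts are Poisson(density × projected
area) with density default 3 μm⁻². Filaments are static circumferential
arcs; for length studies a dedicated snapshot generator renders straight,
randomly oriented filaments in tiles (isolating the measurement algorithm
from membrane-curvature foreshortening, which the movie generator retains
for realism).

Rendering integrates the Gaussian PSF over each pixel with error functions,
so total flux is conserved exactly; filaments are dense midpoint-sampled
lines of point sources sharing one photon budget. Noise is per-pixel Poisson
(shot) plus Gaussian read noise, clipped at zero. With one seed the whole
movie and its ground-truth table are bit-reproducible.

Acquisition defaults follow the emulated experiment: 1 s frame interval,
60 frames, 65 nm pixels (100× objective, 6.5 μm camera pixels), PSF
σ = 80 nm for conventional TIRF and σ = 40 nm with 40.6 nm pixels for
SIM-like snapshots (≈2× resolution gain). The real study does not state
spot intensities or background, so the photon budget is chosen to put a
single focus at SNR ≈ 8 at the coverslip (1200 photons/frame over a
100-photon background); SIM-like snapshots get 6000 photons per filament —
each SIM frame integrates several raw exposures — putting the 2-pixel line
profile at SNR ≈ 10. Whole-cell fluorescence for ratio experiments uses 150
fluorophores of 200 photons per cell, and 20 000 photons of cytoplasmic red
marker in marked cells, far brighter than single complexes as a fully
labelled cell is.

What the generator does **not** emulate: photobleaching and blinking, cell
growth during the 1-minute movie, complex assembly/disassembly (emitters
persist forever, so track durations are set purely by TIRF visibility),
vectorial/astigmatic PSFs, SIM reconstruction artefacts, bent or tilted
cells, and camera fixed-pattern noise. Passing recovery tests therefore show
the measurement chain is unbiased under these idealised conditions, not that
it is robust to every property of real movies.

## Particle tracking

Detection is a matched Gaussian filter at the expected PSF scale followed by
local-maximum picking at ≥ 5 robust noise SDs and sub-pixel refinement by
intensity-weighted centroid; maxima within one PSF σ are merged. Linking is
greedy mutual-nearest-neighbour between consecutive frames with a hard
250 nm gate (≈10× the per-second motion, far below typical inter-emitter
spacing) and **no gap closing** — a missed frame ends the track, matching
the "consecutive frames" wording of the survival filter. Survival filtering
keeps exactly the tracks with ≥ 5 consecutive frames **and** ≥ 70 nm net
(straight-line first-to-last) displacement and reports discard counts by
reason; the literal alternative reading (discard only when both conditions
fail) is available behind `rule="discard_both_fail"`. LAP/global linking and
motion-model tracking are deliberately out of scope; at the simulated
densities the greedy linker is exact, which the tests check against an
independently written brute-force linker.

### Velocity estimation and projection bias

The camera sees the chord of circumferential motion: a focus at angle θ has
apparent lateral speed v·cos θ, so any straight-line fit to the projected
positions underestimates v. For a track spanning a symmetric window
[−a, a] of the visible band, the least-squares slope recovers only
3(sin a − a cos a)/a³ of the true speed — about 0.88 even for a hard
z ≤ 200 nm visibility cutoff, and less when detection reaches deeper. Three
estimators are provided:

* `fit` (function default): |LS slope| of positions projected on the
  track's principal axis — the conventional estimator, biased low for
  circumferential motion as above;
* `mean_step`: mean frame-to-frame step over the interval — inflated by
  localisation noise;
* `arc`: unwraps the lateral offset y from the cell axis to arc length
  s = r·asin(y/r) (clipped at |y/r| ≤ 0.98 so localisation noise at the
  band edge cannot leave the domain) before the same LS fit. This removes
  the projection bias entirely (≤ 2% with 25 nm localisation noise) and is
  what the pipeline and the validation studies use, since the cell axis and
  width are known — from the segmentation outline on real data, exactly on
  synthetic data.

The package deliberately applies no post-hoc bias correction factor; the
`arc` estimator is a measurement, not a calibration.

## Filament length

Each user-supplied ROI (one filament per window, mirroring by-eye selection
in the emulated workflow) is measured as: principal-axis orientation from
intensity-weighted second moments, restricted to the connected component of
supra-noise pixels containing the brightest pixel (isolated noise pixels at
large lever arms would otherwise swamp the anisotropy of a short filament);
bicubic rotation about the intensity centroid to horizontal (flux-preserving
to ~1%); a 2-pixel-wide line profile (sum of the two rows straddling the
axis); and the length = longest contiguous run of profile values above the
local threshold × pixel size, in nm.

The threshold "background + 50%" is interpreted as background + 0.5 × (peak −
background) — a half-amplitude cut, invariant to camera offset and the value
for which a box ⊛ Gaussian profile crosses at very nearly the true box edge.
The literal reading, 1.5 × background, is kept behind
`threshold_mode="background_x1.5"`; the ordering of the two test populations
is invariant to the choice (asserted in the tests). The longest *contiguous*
run (not the total supra-threshold count) is used for robustness to detached
noise pixels. Local background is the median outside the dilated
supra-threshold core of the window.

The PSF sets a resolution floor: an object shorter than the PSF FWHM
(2.355σ ≈ 94 nm for SIM-like snapshots) measures near the FWHM, never 0, and
is flagged `at_resolution` (as is any ROI with no usable axis); ROIs with no
signal at all are flagged `degenerate`. Nothing is silently dropped. As in
the emulated study, lengths are relative, not absolute: the package reports
its own calibration bias from synthetic data (about −1 to −2% at
520/360 nm, see the recovery studies) rather than claiming absolute
accuracy.

## Membrane-recruitment ratio

Per cell: integrated background-subtracted fluorescence under TIRF divided
by the same under widefield (first frame of each mode by default; the
emulated study does not state which frame it integrated). Background is the
per-frame median outside all cell masks. Because absolute TIRF intensity is
extremely sensitive to incident angle and focus, two strains are always
compared within one field: they are mixed, one carries a cytoplasmic red
marker, and identity is read from the red channel by an isodata
(iterated-midpoint) two-class threshold. Cells within 10% of the threshold
are flagged ambiguous and excluded rather than misassigned; if the class gap
is under 4 within-class SDs the red distribution is treated as unimodal and
every cell is flagged (splitting a unimodal normal at its mean yields a gap
of ~2.7 within-class SDs, so 4 separates real bimodality from noise). The
experiment is run in both marker orientations and pooled, with a marker-swap
consistency statistic reported, so marker-associated bias cancels.

## Statistics

Samples are summarised as mean ± SD (n − 1 denominator) with n, median and
quartiles, the convention of the emulated figures. Two-sample comparisons
use the two-sided Mann-Whitney U test: the exact null distribution for
tie-free samples with n₁ + n₂ ≤ 16, otherwise the tie-corrected normal
approximation with continuity correction (the exact route is verified
against full permutation enumeration for all n₁, n₂ ≤ 8). Histograms use
fixed-width half-open bins [k·w, (k+1)·w) anchored at 0 — 5 nm/s for
velocities, 120 nm for lengths. No multiple-testing correction is applied:
each comparison is a single pre-planned two-group test, and reports say so.

## Validation studies and problem sizes

`rodmotion.experiments` contains the recovery studies run by the test suite
and by `scripts/acceptance.py`, sized to complete in a few minutes on one
CPU as the package's standard desk-scale check:

* geometry worked example: the default strain dimensions at 200 nm depth;
* velocity recovery: 30 cells at 3 emitters/μm² (~300 emitters), 60 frames,
  full detect → link → filter → arc-velocity chain; recovered mean within a
  few per cent of truth, 5 nm/s histogram unimodal;
* filament discrimination: 500 filaments per group at 520 ± 190 vs
  360 ± 130 nm (truncated > 120 nm); group means within ~2% of the true
  sample means, Mann-Whitney p ≈ 10⁻⁵⁰;
* density linearity: a 4× emitter-density sweep (1.5–6 μm⁻², 24 cells per
  level — fewer cells leaves the per-level track count too noisy for a
  stable R²), R² ≈ 0.97–0.99; the absolute track yield is ~55% of emitters (TIRF
  visibility and the survival filter), which cancels in ratios;
* density-ratio recovery: two strains at the published 3.85/2.8 = 1.375
  density ratio on their own cell dimensions; the measured track-density
  ratio runs ~5–10% high because the thinner mutant cell has a larger
  illuminated fraction (more of its surface near the coverslip), an expected
  geometric effect that stays within the ±15% recovery band;
* membrane-ratio null: 200 replicate mixed-field marker-swap experiments
  with identical membrane fractions (12 cells/strain/orientation); the
  comparison is non-significant in ≥ 93% of replicates (measured ~96%).

## Numerical choices and degenerate inputs

Truncated Gaussians are drawn by resampling (exact, no renormalisation
bias). Detection noise scales are robust (median/MAD). The kymograph ridge
is the per-frame intensity-weighted centroid around the column maximum,
fitted by least absolute deviations (Nelder-Mead from the LS initialiser);
columns without supra-noise signal are skipped, and a kymograph with fewer
than two usable columns raises. Zero-area cells, empty masks, empty samples,
self-intersecting outlines, negative noise-free intensities and
out-of-surface anchors raise `ValueError`/`MeasurementError` rather than
propagating NaNs; degenerate filament ROIs come back flagged.

## Known limitations

Tracks are not split at cell boundaries (synthetic fields place cells far
apart; real crowded fields would need per-cell assignment before counting).
The widefield hard cutoff slightly undercounts tall cells' fluorescence.
The arc velocity estimator assumes the track's cell axis and width are
correct; mis-segmentation propagates into speeds. Filament ROIs containing
crossing filaments are not resolved, only flagged by their measurement
behaviour. The demultiplexer assumes a single global red threshold per
field (no spatial illumination gradient model).
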