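"""Per-cell TIRF:widefield fluorescence ratios and strain demultiplexing.

The TIRF:widefield ratio approximates the membrane-recruited fraction of a
fluorescent protein: integrated fluorescence of a cell under evanescent
(TIRF) illumination — which excites only the membrane-proximal ~200 nm —
divided by its integrated fluorescence under widefield illumination, which
approximates the entire cellular population.  Because absolute TIRF intensity
is very sensitive to incident angle and focus, two strains are imaged mixed
in the same field and separated afterwards by a cytoplasmic red marker
carried by one of them; measurements are made with the marker on either
strain and pooled, so any marker-associated bias cancels.

This module also contains the forward simulator for that experiment: cells
are populated with a chosen membrane-bound fraction of fluorophores (the
rest cytoplasmic), rendered under both illumination modes, and measured by
the same code path as real data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import mann_whitney_u, summarize
from .synthetic import ImagingConfig, _add_gaussian

__all__ = [
    "CellMask",
    "RatioMeasurement",
    "integrate_cell_fluorescence",
    "tirf_widefield_ratio",
    "demultiplex_by_marker",
    "paired_ratio_experiment",
    "estimate_field_background",
    "simulate_ratio_field",
    "simulate_mixed_field",
]


@dataclass
class CellMask:
    """Binary footprint of one cell in a co-registered field."""

    footprint: np.ndarray         # 2-D bool
    cell_id: int
    strain: str = "unassigned"    # "marked" | "unmarked" | "ambiguous" | ...

    def __post_init__(self) -> None:
        self.footprint = np.asarray(self.footprint, dtype=bool)
        if self.footprint.ndim != 2 or not self.footprint.any():
            raise ValueError("footprint must be a non-empty 2-D mask")


@dataclass(frozen=True)
class RatioMeasurement:
    cell_id: int
    tirf_sum: float
    widefield_sum: float
    ratio: float                  # nan when widefield_sum <= 0
    flag: str = ""


def estimate_field_background(frame: np.ndarray,
                              masks: list[CellMask]) -> float:
    """Median intensity of pixels outside every cell mask."""
    frame = np.asarray(frame, dtype=float)
    covered = np.zeros(frame.shape, dtype=bool)
    for m in masks:
        covered |= m.footprint
    outside = frame[~covered]
    if outside.size == 0:
        raise ValueError("no background pixels outside the cell masks")
    return float(np.median(outside))


def integrate_cell_fluorescence(frame: np.ndarray, mask: CellMask,
                                background: float) -> float:
    """Sum of background-subtracted intensity over the mask, floored at 0
    per pixel."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != mask.footprint.shape:
        raise ValueError("frame and mask shapes differ")
    vals = frame[mask.footprint] - background
    return float(np.clip(vals, 0.0, None).sum())


def tirf_widefield_ratio(tirf_frame: np.ndarray, widefield_frame: np.ndarray,
                         mask: CellMask,
                         backgrounds: tuple[float, float]
                         ) -> RatioMeasurement:
    """Per-cell ratio of integrated TIRF to widefield fluorescence."""
    if np.shape(tirf_frame) != np.shape(widefield_frame):
        raise ValueError("TIRF and widefield frames must be co-registered "
                         "and the same shape")
    t = integrate_cell_fluorescence(tirf_frame, mask, backgrounds[0])
    w = integrate_cell_fluorescence(widefield_frame, mask, backgrounds[1])
    if w <= 0:
        return RatioMeasurement(mask.cell_id, t, w, float("nan"),
                                flag="zero_widefield")
    return RatioMeasurement(mask.cell_id, t, w, t / w)


def demultiplex_by_marker(red_frame: np.ndarray, masks: list[CellMask],
                          ambiguity_band: float = 0.10,
                          max_iter: int = 100) -> list[str]:
    """Assign each cell "marked" / "unmarked" from its mean red intensity.

    A two-class threshold is found by iterating the midpoint of the class
    means to convergence (the isodata rule); cells whose mean red intensity
    lies within ``ambiguity_band`` (fractional) of the threshold are flagged
    "ambiguous".  If the red distribution is effectively unimodal (one class
    empties, or the class gap is small relative to the within-class spread),
    every cell is returned "ambiguous" with a warning.  Assignments are also written back onto the
    masks' ``strain`` attribute.
    """
    if not masks:
        return []
    red = np.asarray(red_frame, dtype=float)
    bg = estimate_field_background(red, masks)
    means = np.array([
        float(np.mean(red[m.footprint])) - bg for m in masks
    ])
    thr = float(means.mean())
    for _ in range(max_iter):
        hi, lo = means[means > thr], means[means <= thr]
        if hi.size == 0 or lo.size == 0:
            break
        new = 0.5 * (hi.mean() + lo.mean())
        if abs(new - thr) < 1e-9 * (abs(thr) + 1e-12):
            thr = new
            break
        thr = new
    hi, lo = means[means > thr], means[means <= thr]
    # the split is real only if the class gap dwarfs the within-class
    # spread; splitting a unimodal normal at its mean gives a gap of
    # ~2.7 within-class SDs, so require > 4
    if hi.size == 0 or lo.size == 0:
        unimodal = True
    else:
        within = math.sqrt(0.5 * (np.var(hi) + np.var(lo))) + 1e-12
        unimodal = (hi.mean() - lo.mean()) / within < 4.0
    if unimodal:
        warnings.warn("red marker intensities look unimodal; "
                      "all cells flagged ambiguous")
        labels = ["ambiguous"] * len(masks)
    else:
        half_band = ambiguity_band * abs(thr)
        labels = []
        for m in means:
            if abs(m - thr) <= half_band:
                labels.append("ambiguous")
            else:
                labels.append("marked" if m > thr else "unmarked")
    for m, lab in zip(masks, labels):
        m.strain = lab
    return labels


def paired_ratio_experiment(
    orientation_a: pd.DataFrame | None,
    orientation_b: pd.DataFrame | None,
) -> dict:
    """Pool per-strain ratios over the two marker orientations.

    Each orientation DataFrame needs columns ``strain`` (actual strain name,
    resolved from the marker assignment) and ``ratio``.  Returns per-strain
    pooled summaries, the between-strain comparison, and a marker-swap
    consistency statistic (relative difference of per-strain means between
    the two orientations).  A missing orientation is tolerated with a
    warning and flagged unpaired.
    """
    frames = []
    unpaired = False
    for tag, df in (("A", orientation_a), ("B", orientation_b)):
        if df is None or len(df) == 0:
            warnings.warn(f"marker orientation {tag} missing; "
                          "proceeding unpaired")
            unpaired = True
            continue
        d = df.copy()
        d["orientation"] = tag
        frames.append(d)
    if not frames:
        raise ValueError("no ratio data in either marker orientation")
    pooled = pd.concat(frames, ignore_index=True)
    pooled = pooled[np.isfinite(pooled["ratio"])]

    strains = sorted(pooled["strain"].unique())
    result: dict = {"unpaired": unpaired, "per_strain": {}, "consistency": {}}
    for s in strains:
        sub = pooled[pooled["strain"] == s]
        result["per_strain"][s] = summarize(sub["ratio"].to_numpy())
        if not unpaired:
            by = {o: g["ratio"].mean()
                  for o, g in sub.groupby("orientation") if len(g)}
            if len(by) == 2:
                a, b = by.values()
                result["consistency"][s] = abs(a - b) / (0.5 * (a + b))
    if len(strains) == 2:
        x = pooled[pooled["strain"] == strains[0]]["ratio"].to_numpy()
        y = pooled[pooled["strain"] == strains[1]]["ratio"].to_numpy()
        result["comparison"] = mann_whitney_u(x, y)
    return result


# ---------------------------------------------------------------------------
# forward simulation of the mixed-field ratio experiment
# ---------------------------------------------------------------------------

def _sample_membrane(rng, n, length, radius):
    """(axial, angle, rho) uniform by area on the spherocylinder surface."""
    flank_len = length - 2 * radius
    flank_area = 2 * math.pi * radius * flank_len
    cap_area = 4 * math.pi * radius**2
    on_flank = rng.random(n) < flank_area / (flank_area + cap_area)
    axial = np.empty(n)
    rho = np.empty(n)
    axial[on_flank] = rng.uniform(-flank_len / 2, flank_len / 2,
                                  on_flank.sum())
    rho[on_flank] = radius
    n_cap = (~on_flank).sum()
    a = rng.uniform(0, radius, n_cap)  # sphere zone: uniform in axial offset
    sign = rng.choice([-1.0, 1.0], n_cap)
    axial[~on_flank] = sign * (flank_len / 2 + a)
    rho[~on_flank] = np.sqrt(radius**2 - a**2)
    angle = rng.uniform(0, 2 * math.pi, n)
    return axial, angle, rho


def _sample_cytoplasm(rng, n, length, radius):
    """(axial, lateral, z) uniform in the spherocylinder volume (rejection)."""
    out = np.empty((0, 3))
    flank_half = length / 2 - radius
    while out.shape[0] < n:
        m = 2 * (n - out.shape[0]) + 8
        s = rng.uniform(-length / 2, length / 2, m)
        y = rng.uniform(-radius, radius, m)
        zc = rng.uniform(-radius, radius, m)
        a = np.clip(np.abs(s) - flank_half, 0.0, None)
        inside = a**2 + y**2 + zc**2 <= radius**2
        out = np.vstack([out, np.column_stack([s, y, zc + radius])[inside]])
    return out[:n]


def simulate_ratio_field(
    n_cells: int,
    membrane_fraction: float,
    rng: np.random.Generator,
    marked: bool = False,
    **kwargs,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[CellMask]]:
    """Render a single-strain acquisition: every cell shares one membrane
    fraction and marker state.

    See :func:`simulate_mixed_field` for the two-strain mixed experiment and
    :func:`_render_cells` for the rendering parameters.  Returns (green TIRF
    frame, green widefield frame, red widefield frame, masks); all frames
    share one mosaic and are co-registered.
    """
    return _render_cells([(membrane_fraction, marked)] * n_cells, rng,
                         **kwargs)


def simulate_mixed_field(
    n_per_strain: int,
    membrane_fractions: tuple[float, float],
    marked_strain: int,
    rng: np.random.Generator,
    **kwargs,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[CellMask], list[int]]:
    """Two strains mixed in one field, one of them carrying the red marker.

    ``marked_strain`` (0 or 1) selects which strain expresses the cytoplasmic
    marker; cells of the two strains are interleaved in random order, as in
    the real mixed acquisition.  Returns (tirf, widefield, red, masks,
    true_strains) with the ground-truth strain index per mask.
    """
    if marked_strain not in (0, 1):
        raise ValueError("marked_strain must be 0 or 1")
    strains = np.repeat([0, 1], n_per_strain)
    rng.shuffle(strains)
    cell_specs = [(membrane_fractions[s], s == marked_strain)
                  for s in strains]
    tirf, wf, red, masks = _render_cells(cell_specs, rng, **kwargs)
    return tirf, wf, red, masks, [int(s) for s in strains]


def _render_cells(
    cell_specs: list[tuple[float, bool]],
    rng: np.random.Generator,
    config: ImagingConfig | None = None,
    fluorophores_per_cell: int = 150,
    photons_per_fluorophore: float = 200.0,
    marker_photons: float = 20000.0,
    tile_px: int = 56,
    cell_length_nm: float = 3570.0,
    cell_width_nm: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[CellMask]]:
    """Render one tile-mosaic field given per-cell (membrane_fraction,
    marked) pairs.

    Each cell gets ``fluorophores_per_cell`` green fluorophores of
    ``photons_per_fluorophore`` each (a fully labelled cell is far brighter
    than a single focus), the given fraction on the membrane surface and the
    rest uniform in the cytoplasm; marked cells additionally carry
    ``marker_photons`` of diffuse cytoplasmic red marker.
    """
    n_cells = len(cell_specs)
    if n_cells == 0:
        raise ValueError("need at least one cell")
    if not all(0.0 <= f <= 1.0 for f, _ in cell_specs):
        raise ValueError("membrane_fraction must lie in [0, 1]")
    cfg = config or ImagingConfig()
    px = cfg.pixel_size
    n_side = math.ceil(math.sqrt(n_cells))
    shape = (n_side * tile_px, n_side * tile_px)
    tirf = np.full(shape, float(cfg.background_level))
    wf = np.full(shape, float(cfg.background_level))
    red = np.full(shape, float(cfg.background_level))
    masks: list[CellMask] = []
    r = cell_width_nm / 2.0
    half_flank = cell_length_nm / 2 - r

    for i, (membrane_fraction, marked) in enumerate(cell_specs):
        gx, gy = i % n_side, i // n_side
        cx = (gx + 0.5) * tile_px * px
        cy = (gy + 0.5) * tile_px * px
        theta = float(rng.uniform(0, math.pi))
        ux, uy = math.cos(theta), math.sin(theta)
        nx, ny = -uy, ux

        n_mem = int(round(membrane_fraction * fluorophores_per_cell))
        pts = []  # (x, y, z) per fluorophore
        if n_mem:
            axial, angle, rho = _sample_membrane(rng, n_mem,
                                                 cell_length_nm, r)
            lat = rho * np.sin(angle)
            z = r - rho * np.cos(angle)
            pts.append(np.column_stack([axial, lat, z]))
        n_cyt = fluorophores_per_cell - n_mem
        if n_cyt:
            pts.append(_sample_cytoplasm(rng, n_cyt, cell_length_nm, r))
        flux = photons_per_fluorophore
        for s, lat, z in np.vstack(pts):
            x = cx + ux * s + nx * lat
            y = cy + uy * s + ny * lat
            _add_gaussian(tirf, x, y, flux * math.exp(-z / cfg.tirf_depth),
                          cfg.psf_sigma, px)
            _add_gaussian(wf, x, y,
                          flux * (1.0 if z <= cfg.widefield_depth else 0.0),
                          cfg.psf_sigma, px)
        if marked:
            cyt = _sample_cytoplasm(rng, 60, cell_length_nm, r)
            for s, lat, z in cyt:
                x = cx + ux * s + nx * lat
                y = cy + uy * s + ny * lat
                _add_gaussian(red, x, y, marker_photons / 60,
                              cfg.psf_sigma, px)

        # footprint mask from the exact spherocylinder outline
        ii, jj = np.mgrid[gy * tile_px:(gy + 1) * tile_px,
                          gx * tile_px:(gx + 1) * tile_px]
        xs = (jj + 0.5) * px - cx
        ys = (ii + 0.5) * px - cy
        s_ax = xs * ux + ys * uy
        lat = xs * nx + ys * ny
        a = np.clip(np.abs(s_ax) - half_flank, 0.0, None)
        inside = a**2 + lat**2 <= r**2
        foot = np.zeros(shape, dtype=bool)
        foot[gy * tile_px:(gy + 1) * tile_px,
             gx * tile_px:(gx + 1) * tile_px] = inside
        masks.append(CellMask(footprint=foot, cell_id=i))

    tirf = _shot_noise(tirf, cfg, rng)
    wf = _shot_noise(wf, cfg, rng)
    red = _shot_noise(red, cfg, rng)
    return tirf, wf, red, masks


def _shot_noise(frame, cfg, rng):
    noisy = rng.poisson(frame).astype(float)
    if cfg.read_noise_sd > 0:
        noisy += rng.normal(0.0, cfg.read_noise_sd, frame.shape)
    return np.clip(noisy, 0.0, None)
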