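"""Synthetic TIRF / widefield microscopy of rod-shaped cells.

Generates movies of spherocylindrical cells lying on a coverslip that carry
membrane-bound fluorescent foci moving circumferentially around the long
axis (the motion signature of wall-synthesis complexes) and static membrane
filaments, together with a full ground-truth table.  Every downstream stage
of the pipeline — detection, linking, velocity estimation, filament length
measurement, TIRF:widefield ratios — is validated against this generator.

Geometry and units
------------------
All positions are in nanometres.  The coverslip is the plane z = 0; a cell of
width W (diameter) rests on it, so a membrane point at circumferential angle
theta from the bottom line of the cylinder flank sits at height
z = r*(1 - cos theta), r = W/2.  The image x/y axes are the lateral
(projected) coordinates; pixel (row i, col j) covers
[j*p, (j+1)*p) x [i*p, (i+1)*p) nm with p the pixel size.

Illumination
------------
TIRF excitation decays as exp(-z/d) with d the evanescent depth (~200 nm);
widefield collects every fluorophore up to its depth of field (~800 nm) with
unit efficiency.  Emitters are rendered as integrated (error-function)
Gaussians so that total flux is conserved exactly; filaments are dense lines
of point sources sharing one flux budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import erf

__all__ = [
    "ImagingConfig",
    "CellSpec",
    "EmitterSpec",
    "MovieStack",
    "generate_population",
    "membrane_position",
    "advance_emitters",
    "render_frame",
    "apply_noise",
    "simulate_movie",
    "simulate_filament_snapshot",
    "write_outputs",
    "read_movie",
    "truncated_normal",
]

GROUND_TRUTH_COLUMNS = [
    "emitter_id", "cell_id", "frame", "t_s", "x_nm", "y_nm", "z_nm",
    "tirf_visible", "speed_nm_s", "length_nm",
]


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition constants of the simulated microscope.

    Defaults follow the experimental setup being emulated: 1 s frame
    interval for 60 frames, ~200 nm evanescent depth, ~800 nm widefield
    depth of field, 65 nm pixels (100x objective, 6.5 um camera pixels) and
    a diffraction-limited PSF sigma of 80 nm (40 nm for SIM-like
    super-resolution snapshots).  ``photon_rate`` and ``background_level``
    are chosen to put single foci at SNR ~ 8 at the coverslip.
    """

    pixel_size: float = 65.0          # nm / pixel
    frame_interval: float = 1.0       # s
    n_frames: int = 60
    tirf_depth: float = 200.0         # nm
    widefield_depth: float = 800.0    # nm
    psf_sigma: float = 80.0           # nm
    background_level: float = 100.0   # photons / pixel
    photon_rate: float = 1200.0       # photons / emitter / frame
    read_noise_sd: float = 2.0        # photons
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size", "frame_interval", "tirf_depth",
                     "widefield_depth", "psf_sigma", "photon_rate"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be strictly positive")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("background_level and read_noise_sd must be >= 0")
        if not (self.tirf_depth < self.widefield_depth):
            raise ValueError("tirf_depth must be smaller than widefield_depth")


@dataclass
class EmitterSpec:
    """A membrane-anchored fluorescent object.

    ``axial_nm`` runs along the cell axis from the cell centre;
    ``angle_rad`` is the circumferential angle from the bottom line (the
    coverslip contact).  Foci move circumferentially at ``speed_nm_s``;
    filaments are arcs of ``filament_length_nm`` centred on the anchor and
    static by default.
    """

    kind: str                    # "focus" | "filament"
    axial_nm: float
    angle_rad: float
    speed_nm_s: float = 0.0
    filament_length_nm: float = 0.0
    intensity_scale: float = 1.0
    direction: int = 1           # +1 / -1, sense of circumferential motion

    def __post_init__(self) -> None:
        if self.kind not in ("focus", "filament"):
            raise ValueError(f"unknown emitter kind {self.kind!r}")
        if self.speed_nm_s < 0 or self.filament_length_nm < 0:
            raise ValueError("speed and filament_length must be >= 0")


@dataclass
class CellSpec:
    """One spherocylindrical cell in the field, with its emitters."""

    center: tuple[float, float]  # (x, y) nm in the image plane
    orientation: float           # rad, axis direction in the image plane
    length: float                # tip-to-tip, nm
    width: float                 # diameter, nm
    strain_label: str = ""
    has_marker: bool = False
    emitters: list[EmitterSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.width > 0) or self.length < self.width:
            raise ValueError("require length >= width > 0")

    @property
    def radius(self) -> float:
        return self.width / 2.0

    @property
    def projected_area_um2(self) -> float:
        r_um = self.radius / 1000.0
        return (self.width / 1000.0) * (self.length - self.width) / 1000.0 \
            + math.pi * r_um**2


@dataclass
class MovieStack:
    """A time-ordered image stack with its acquisition metadata."""

    frames: np.ndarray           # (n_frames, H, W), float, photons
    mode: str                    # "tirf" | "widefield"
    channel: str                 # "green" | "red"
    config: ImagingConfig

    def __post_init__(self) -> None:
        if self.mode not in ("tirf", "widefield"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.channel not in ("green", "red"):
            raise ValueError(f"unknown channel {self.channel!r}")
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if not np.all(np.isfinite(f)) or f.min() < 0:
            raise ValueError("intensities must be finite and >= 0")


def truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                     size: int, lower: float = 0.0) -> np.ndarray:
    """Normal(mean, sd) draws resampled until strictly above ``lower``."""
    if sd == 0:
        if mean <= lower:
            raise ValueError("degenerate distribution entirely below bound")
        return np.full(size, float(mean))
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, todo.size)
        ok = draw > lower
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------

def generate_population(
    n_cells: int,
    dimension_distributions: dict | None = None,
    emitter_density: float = 3.0,
    speed_distribution: tuple[float, float] = (22.0, 6.0),
    length_distribution: tuple[float, float] = (520.0, 190.0),
    seed: int = 0,
    *,
    emitter_kind: str = "focus",
    speed_lower: float = 5.0,
    length_lower: float = 120.0,
    strain_label: str = "",
    has_marker: bool = False,
    field_margin_nm: float = 2000.0,
) -> list[CellSpec]:
    """Draw a field of non-overlapping cells with membrane emitters.

    Parameters
    ----------
    n_cells
        Number of cells placed on a square grid (no overlaps by
        construction).
    dimension_distributions
        ``{"length": (mean_nm, sd_nm), "width": (mean_nm, sd_nm)}``.
        Defaults to the wild-type dimensions used for the illuminated-area
        normalisation (3.57 x 1.00 um) with modest cell-to-cell variation.
    emitter_density
        Mean emitters per um^2 of projected cell area; the per-cell count is
        Poisson(density x projected area).
    speed_distribution, length_distribution
        (mean, sd) of circumferential speed (nm/s) and filament arc length
        (nm), truncated above ``speed_lower`` / ``length_lower`` by
        resampling.
    emitter_kind
        "focus" for moving complexes, "filament" for static arcs.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be strictly positive")
    if emitter_density < 0:
        raise ValueError("emitter_density must be >= 0")
    dims = dimension_distributions or {
        "length": (3570.0, 350.0),
        "width": (1000.0, 50.0),
    }
    rng = np.random.default_rng(seed)
    lengths = truncated_normal(rng, *dims["length"], n_cells, lower=0.0)
    widths = truncated_normal(rng, *dims["width"], n_cells, lower=0.0)
    lengths = np.maximum(lengths, widths)  # enforce length >= width

    # grid placement: cell i at grid node, pitch large enough for any pose
    pitch = float(lengths.max()) + field_margin_nm
    n_side = math.ceil(math.sqrt(n_cells))
    cells: list[CellSpec] = []
    for i in range(n_cells):
        gx, gy = i % n_side, i // n_side
        center = (field_margin_nm / 2 + pitch * (gx + 0.5),
                  field_margin_nm / 2 + pitch * (gy + 0.5))
        cell = CellSpec(
            center=center,
            orientation=float(rng.uniform(0, math.pi)),
            length=float(lengths[i]),
            width=float(widths[i]),
            strain_label=strain_label,
            has_marker=has_marker,
        )
        n_emit = int(rng.poisson(emitter_density * cell.projected_area_um2))
        if n_emit:
            speeds = truncated_normal(rng, *speed_distribution, n_emit,
                                      lower=speed_lower)
            flen = truncated_normal(rng, *length_distribution, n_emit,
                                    lower=length_lower)
            half = cell.length / 2 - cell.radius  # keep on the cylinder flank
            axial = rng.uniform(-half, half, n_emit) if half > 0 else np.zeros(n_emit)
            angles = rng.uniform(0, 2 * math.pi, n_emit)
            dirs = rng.choice([-1, 1], n_emit)
            for k in range(n_emit):
                if emitter_kind == "focus":
                    em = EmitterSpec("focus", float(axial[k]), float(angles[k]),
                                     speed_nm_s=float(speeds[k]),
                                     direction=int(dirs[k]))
                else:
                    em = EmitterSpec("filament", float(axial[k]), float(angles[k]),
                                     speed_nm_s=0.0,
                                     filament_length_nm=float(flen[k]))
                cell.emitters.append(em)
        cells.append(cell)
    return cells


def membrane_position(cell: CellSpec, axial_nm: float, angle_rad: float
                      ) -> tuple[float, float, float]:
    """Map a membrane anchor (axial, angle) to lab coordinates (x, y, z) nm.

    On the cylinder flank the cross-section is a circle of radius r and
    z = r*(1 - cos theta); on the hemispherical caps the circle shrinks to
    rho = sqrt(r^2 - a^2) at axial overshoot a, keeping the point on the
    sphere (z = r - rho*cos theta).
    """
    r = cell.radius
    half = cell.length / 2.0
    flank_half = half - r
    s = float(axial_nm)
    if abs(s) > half + 1e-9:
        raise ValueError(
            f"axial coordinate {s} nm outside the cell (half-length {half} nm)")
    a = max(abs(s) - flank_half, 0.0)
    rho = math.sqrt(max(r * r - a * a, 0.0))
    lateral = rho * math.sin(angle_rad)
    z = r - rho * math.cos(angle_rad)
    ux, uy = math.cos(cell.orientation), math.sin(cell.orientation)
    # in-plane normal to the axis
    nx, ny = -uy, ux
    x = cell.center[0] + ux * s + nx * lateral
    y = cell.center[1] + uy * s + ny * lateral
    return x, y, z


def advance_emitters(cells: list[CellSpec], t: float) -> list[CellSpec]:
    """Anchors at time t: pure rotation about the long axis.

    theta(t) = theta0 + direction * v * t / r, axial coordinate unchanged.
    Returns new cell objects; the inputs (anchors at t = 0) are untouched.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    out = []
    for cell in cells:
        moved = [
            replace(em, angle_rad=em.angle_rad
                    + em.direction * em.speed_nm_s * t / cell.radius)
            for em in cell.emitters
        ]
        new_cell = replace(cell, emitters=moved)
        out.append(new_cell)
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _add_gaussian(img: np.ndarray, x_nm: float, y_nm: float, flux: float,
                  sigma_nm: float, pixel_size: float) -> None:
    """Accumulate an integrated Gaussian of total ``flux`` photons in place."""
    if flux <= 0:
        return
    h, w = img.shape
    sig_px = sigma_nm / pixel_size
    cx, cy = x_nm / pixel_size, y_nm / pixel_size
    half = max(int(math.ceil(6 * sig_px)) + 1, 2)
    j0, j1 = max(int(cx) - half, 0), min(int(cx) + half + 1, w)
    i0, i1 = max(int(cy) - half, 0), min(int(cy) + half + 1, h)
    if j0 >= j1 or i0 >= i1:
        return
    s = sig_px * math.sqrt(2.0)
    ex = 0.5 * (erf((np.arange(j0, j1 + 1) - cx) / s))
    ey = 0.5 * (erf((np.arange(i0, i1 + 1) - cy) / s))
    img[i0:i1, j0:j1] += flux * np.outer(np.diff(ey), np.diff(ex))


def _attenuation(z: np.ndarray | float, config: ImagingConfig, mode: str):
    if mode == "tirf":
        return np.exp(-np.asarray(z, dtype=float) / config.tirf_depth)
    if mode == "widefield":
        return (np.asarray(z, dtype=float) <= config.widefield_depth).astype(float)
    raise ValueError(f"unknown mode {mode!r}")


def _filament_points(cell: CellSpec, em: EmitterSpec, pixel_size: float):
    """Arc of point-source anchors spanning the filament, spacing <= px/4."""
    r = cell.radius
    L = em.filament_length_nm
    n_pts = max(int(math.ceil(L / (pixel_size / 4.0))), 2)
    # midpoint sampling: each point stands for an equal sub-segment, so the
    # rendered edge falls exactly at +/- L/2
    arc = ((np.arange(n_pts) + 0.5) / n_pts - 0.5) * L
    angles = em.angle_rad + arc / r
    return [(em.axial_nm, float(a)) for a in angles]


def render_frame(cells: list[CellSpec], t: float, config: ImagingConfig,
                 mode: str, shape: tuple[int, int],
                 psf_sigma: float | None = None) -> np.ndarray:
    """Noise-free frame at time t.

    Each visible emitter contributes an integrated Gaussian PSF of total
    flux photon_rate * intensity_scale * attenuation(z); filaments are
    uniform arcs of point sources sharing that budget.  ``background_level``
    is added everywhere.
    """
    sigma = psf_sigma if psf_sigma is not None else config.psf_sigma
    img = np.full(shape, float(config.background_level))
    moved = advance_emitters(cells, t) if t > 0 else cells
    for cell in moved:
        for em in cell.emitters:
            if em.kind == "focus":
                x, y, z = membrane_position(cell, em.axial_nm, em.angle_rad)
                amp = config.photon_rate * em.intensity_scale \
                    * float(_attenuation(z, config, mode))
                _add_gaussian(img, x, y, amp, sigma, config.pixel_size)
            else:
                pts = _filament_points(cell, em, config.pixel_size)
                flux_each = config.photon_rate * em.intensity_scale / len(pts)
                for ax, ang in pts:
                    x, y, z = membrane_position(cell, ax, ang)
                    amp = flux_each * float(_attenuation(z, config, mode))
                    _add_gaussian(img, x, y, amp, sigma, config.pixel_size)
    return img


def apply_noise(frame: np.ndarray, config: ImagingConfig,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Shot noise (Poisson, mean = pixel value) plus Gaussian read noise.

    Deterministic for a fixed generator state; with ``rng=None`` a fresh
    generator is seeded from ``config.seed``.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.min() < 0:
        raise ValueError("noise-free frame must be non-negative")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    noisy = rng.poisson(frame).astype(float)
    if config.read_noise_sd > 0:
        noisy += rng.normal(0.0, config.read_noise_sd, frame.shape)
    return np.clip(noisy, 0.0, None)


def field_shape(cells: list[CellSpec], config: ImagingConfig,
                margin_nm: float = 1500.0) -> tuple[int, int]:
    """Smallest image shape containing every cell plus a margin."""
    xmax = max(c.center[0] + c.length / 2 for c in cells) + margin_nm
    ymax = max(c.center[1] + c.length / 2 for c in cells) + margin_nm
    return (int(math.ceil(ymax / config.pixel_size)),
            int(math.ceil(xmax / config.pixel_size)))


def simulate_movie(cells: list[CellSpec], config: ImagingConfig,
                   mode: str = "tirf", channel: str = "green",
                   shape: tuple[int, int] | None = None,
                   noise: bool = True,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[MovieStack, pd.DataFrame]:
    """Render a full movie and its ground-truth table.

    Returns the stack and one truth row per (emitter, frame) with the
    projected position, depth z, TIRF-visibility flag (z <= tirf_depth),
    true speed and true filament length.
    """
    if shape is None:
        shape = field_shape(cells, config)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    frames = np.empty((config.n_frames, *shape))
    rows: list[tuple] = []
    for f in range(config.n_frames):
        t = f * config.frame_interval
        frames[f] = render_frame(cells, t, config, mode, shape)
        if noise:
            frames[f] = apply_noise(frames[f], config, rng)
        moved = advance_emitters(cells, t) if t > 0 else cells
        eid = 0
        for ci, cell in enumerate(moved):
            for em in cell.emitters:
                x, y, z = membrane_position(cell, em.axial_nm, em.angle_rad)
                rows.append((eid, ci, f, t, x, y, z,
                             bool(z <= config.tirf_depth),
                             em.speed_nm_s, em.filament_length_nm))
                eid += 1
    truth = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    return MovieStack(frames=frames, mode=mode, channel=channel,
                      config=config), truth


def simulate_filament_snapshot(
    n_filaments: int,
    length_distribution: tuple[float, float] = (520.0, 190.0),
    config: ImagingConfig | None = None,
    seed: int = 0,
    length_lower: float = 120.0,
    roi_px: int = 48,
) -> tuple[np.ndarray, pd.DataFrame]:
    """A SIM-like still of isolated straight filaments for length studies.

    Each filament is rendered in its own tile of a mosaic as a straight,
    randomly oriented line of point sources blurred by the SIM PSF
    (sigma 40 nm by default), isolating the length-measurement algorithm
    from membrane-curvature foreshortening (see the movie generator for the
    curved-arc case).  Returns the image and a table with one row per
    filament: id, true length, orientation, tile bounds (x0, y0, x1, y1,
    half-open pixel rectangle).
    """
    # SIM-like snapshots integrate several raw images per frame, so the
    # per-snapshot photon budget is higher than a single 1 s TIRF exposure;
    # 6000 photons/filament puts the 2-px line profile at SNR ~ 10
    cfg = config or ImagingConfig(pixel_size=40.6, psf_sigma=40.0,
                                  n_frames=1, photon_rate=6000.0)
    rng = np.random.default_rng(seed)
    lengths = truncated_normal(rng, *length_distribution, n_filaments,
                               lower=length_lower)
    angles = rng.uniform(0, math.pi, n_filaments)
    n_side = math.ceil(math.sqrt(n_filaments))
    img = np.full((n_side * roi_px, n_side * roi_px),
                  float(cfg.background_level))
    rows = []
    for i in range(n_filaments):
        gx, gy = i % n_side, i // n_side
        cx = (gx + 0.5) * roi_px * cfg.pixel_size
        cy = (gy + 0.5) * roi_px * cfg.pixel_size
        L, ang = float(lengths[i]), float(angles[i])
        n_pts = max(int(math.ceil(L / (cfg.pixel_size / 4.0))), 2)
        s = ((np.arange(n_pts) + 0.5) / n_pts - 0.5) * L
        flux_each = cfg.photon_rate / n_pts
        for sk in s:
            _add_gaussian(img, cx + sk * math.cos(ang), cy + sk * math.sin(ang),
                          flux_each, cfg.psf_sigma, cfg.pixel_size)
        rows.append((i, L, ang, gx * roi_px, gy * roi_px,
                     (gx + 1) * roi_px, (gy + 1) * roi_px))
    img = apply_noise(img, cfg, rng)
    table = pd.DataFrame(rows, columns=[
        "filament_id", "length_nm", "angle_rad", "x0", "y0", "x1", "y1"])
    return img, table


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_outputs(movie: MovieStack, truth: pd.DataFrame, out_dir) -> dict:
    """Write the stack as a multi-frame TIFF and the truth table as CSV.

    Frames are stored as float32; a round-trip read reproduces them
    bit-exactly.  Returns the paths written.
    """
    import pathlib

    import tifffile

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tif_path = out / f"movie_{movie.channel}_{movie.mode}.tif"
    csv_path = out / "ground_truth.csv"
    try:
        tifffile.imwrite(tif_path, np.asarray(movie.frames, dtype=np.float32))
        truth.to_csv(csv_path, index=False)
    except OSError as exc:  # pragma: no cover - depends on the filesystem
        raise OSError(f"failed writing outputs under {out}: {exc}") from exc
    return {"movie": tif_path, "truth": csv_path}


def read_movie(path, mode: str, channel: str = "green",
               config: ImagingConfig | None = None) -> MovieStack:
    """Read a multi-frame TIFF back into a MovieStack."""
    import tifffile

    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return MovieStack(frames=np.asarray(frames, dtype=float), mode=mode,
                      channel=channel, config=config or ImagingConfig())
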