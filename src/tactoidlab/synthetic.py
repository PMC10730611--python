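"""Seeded generators of synthetic inputs for every analysis stage.

Real inputs to this package are microscopy-derived: tactoid morphometry
tables, FRAP traces, two-channel cell/tactoid images and tomogram filament
boxes.  The generators here produce inputs with the statistical structure
each stage assumes, together with the ground truth that produced them, so
the whole pipeline is testable end-to-end without any downloads:

* tactoid populations obeying R/r = C * V**(-1/5) with multiplicative
  log-normal scatter (volumes log-uniform over the observed range);
* FRAP traces I(t) = 100*A*(1 - exp(-t/T)) sampled on the experimental grid
  (1.62 s interval, 46 s, bleach after 5 frames) with additive Gaussian
  noise;
* two-channel scenes of capsule-shaped rod cells, a stated fraction of
  which carry an enclosing ellipsoidal tactoid at a small orientation
  offset, plus an optional antibiotic-uptake channel where tactoid-
  associated cells take up less drug; Gaussian PSF blur and
  Poisson-Gaussian noise;
* cubic boxes of parallel cylindrical filaments, on a square lattice or
  randomly placed without overlap.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frap import FrapTrace
from .packing import FilamentBoxModel
from .scaling import TactoidPopulation

__all__ = [
    "FrapParams",
    "SceneParams",
    "BoxParams",
    "GeneratorConfig",
    "SceneGroundTruth",
    "gen_tactoid_population",
    "gen_frap_trace",
    "gen_scene",
    "gen_filament_box",
]

FRAP_INTERVAL_S = 1.62
FRAP_DURATION_S = 46.0


@dataclass(frozen=True)
class FrapParams:
    """Ground-truth recovery parameters for synthetic FRAP traces.

    Defaults emulate a Pf4-like tactoid: mobile fraction A = 0.544 (immobile
    45.6%), recovery time constant 8 s, the experimental 1.62 s frame
    interval and 46 s imaging window, bleach after 5 frames, and 2% additive
    Gaussian noise on the normalised scale.
    """

    amplitude: float = 1.0 - 0.456
    time_constant: float = 8.0
    interval: float = FRAP_INTERVAL_S
    duration: float = FRAP_DURATION_S
    noise_sd: float = 0.02  # on the 0-1 normalised scale
    n_prebleach: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.amplitude <= 1):
            raise ValueError("amplitude must be in (0, 1]")
        if self.time_constant <= 0 or self.interval <= 0:
            raise ValueError("time_constant and interval must be > 0")
        if self.duration < 3 * self.interval:
            raise ValueError("duration must cover >= 3 frames")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SceneParams:
    """Layout of a synthetic two-channel cell/tactoid scene.

    Cell geometry defaults to a typical rod bacterium (3 x 0.8 um); tactoid
    major axis is the cell's plus ``size_excess_um`` (Pf4-like ~1.3 um by
    default), the orientation offset SD emulates the measured cell-tactoid
    alignment scatter, and ``uptake_contrast`` is the intensity ratio of
    associated to non-associated cells in the antibiotic-uptake channel.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.1  # um / px
    n_cells: int = 8
    cell_length_um: float = 3.0
    cell_width_um: float = 0.8
    association_fraction: float = 0.7
    orientation_offset_sd_deg: float = 9.0
    size_excess_um: float = 1.3
    tactoid_minor_um: float = 1.6
    uptake_contrast: float = 0.5
    uptake_base_intensity: float = 120.0
    psf_sigma_px: float = 1.0
    noise_sd: float = 2.0  # Gaussian read noise, 8-bit-like intensity scale
    poisson_noise: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.association_fraction <= 1):
            raise ValueError("association_fraction must be in [0, 1]")
        for name in ("pixel_size", "cell_length_um", "cell_width_um",
                     "tactoid_minor_um", "uptake_contrast"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class BoxParams:
    """Filament-box geometry: cubic edge and filament radius in nm, driven
    by either a lattice spacing or a target random count."""

    edge: float = 89.72
    filament_radius: float = 3.1
    count: int | None = 69
    spacing: float | None = None


@dataclass(frozen=True)
class GeneratorConfig:
    """Bundle of all generator settings used by the simulate CLI."""

    seed: int = 0
    n: int = 150
    prefactor: float = 5.88
    volume_range: tuple[float, float] = (1.0, 50.0)
    sigma_log: float = 0.1
    frap: FrapParams = field(default_factory=FrapParams)
    scene: SceneParams = field(default_factory=SceneParams)
    box: BoxParams = field(default_factory=BoxParams)


def gen_tactoid_population(
    seed: int,
    n: int = 150,
    prefactor: float = 5.88,
    volume_range: tuple[float, float] = (1.0, 50.0),
    sigma_log: float = 0.1,
    exponent: float = -0.2,
    label: str = "synthetic",
) -> TactoidPopulation:
    """Population of tactoids following R/r = C * V**exponent with
    multiplicative log-normal scatter of SD ``sigma_log``.

    Volumes are log-uniform on ``volume_range`` (um^3).  Axes are
    back-derived from (V, R/r) through the prolate-spheroid rule
    V = (pi/6) R r**2, so morphometry and fitting see mutually consistent
    records.  Deterministic given ``seed``.
    """
    if sigma_log < 0:
        raise ValueError("sigma_log must be >= 0")
    if prefactor <= 0 or n < 1:
        raise ValueError("prefactor must be > 0 and n >= 1")
    lo, hi = volume_range
    if not (0 < lo <= hi):
        raise ValueError("volume_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    volumes = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    eps = rng.normal(0.0, sigma_log, size=n) if sigma_log > 0 else np.zeros(n)
    ratios = prefactor * volumes**exponent * np.exp(eps)
    ratios = np.maximum(ratios, 1.0)  # an aspect ratio below 1 is unphysical
    return TactoidPopulation(volumes=volumes, aspect_ratios=ratios, label=label)


def population_to_dataframe(pop: TactoidPopulation) -> pd.DataFrame:
    """Tabulate a population with spheroid-consistent axes (um)."""
    minor = (6.0 * pop.volumes / (np.pi * pop.aspect_ratios)) ** (1.0 / 3.0)
    major = pop.aspect_ratios * minor
    return pd.DataFrame(
        {
            "id": np.arange(1, len(pop) + 1),
            "label": pop.label,
            "major_um": major,
            "minor_um": minor,
            "volume_um3": pop.volumes,
        }
    )


def gen_frap_trace(seed: int, params: FrapParams = FrapParams()) -> FrapTrace:
    """One raw FRAP trace on the experimental time grid.

    ``params.n_prebleach`` frames at 100%, then
    I(t) = 100 * A * (1 - exp(-t/T)) at t = 0, dt, ..., with
    floor(duration/interval) + 1 post-bleach frames; Gaussian noise of SD
    ``100 * noise_sd`` added to every frame.
    """
    p = params
    rng = np.random.default_rng(seed)
    n_post = int(math.floor(p.duration / p.interval)) + 1
    t_pre = np.arange(-p.n_prebleach, 0) * p.interval
    t_post = np.arange(n_post) * p.interval
    times = np.concatenate([t_pre, t_post])
    ideal = np.concatenate(
        [
            np.full(p.n_prebleach, 100.0),
            100.0 * p.amplitude * (1.0 - np.exp(-t_post / p.time_constant)),
        ]
    )
    noisy = ideal + rng.normal(0.0, 100.0 * p.noise_sd, size=ideal.size)
    return FrapTrace(
        times=times, intensities=noisy, n_prebleach_frames=p.n_prebleach
    )


def capsule_moment_major(length_um: float, width_um: float) -> float:
    """Moment-ellipse major axis of a capsule (rounded rod) of the given
    overall length and width.

    Segmentation reports ellipse axes from second-order image moments, and
    for a capsule the moment-ellipse major exceeds the nominal rod length
    (a 3 x 0.8 um cell reads as ~3.28 um).  The scene generator therefore
    plants tactoid sizes relative to this value, so the planted size excess
    equals what the measurement's own definition (difference of fitted
    ellipse majors) recovers.
    """
    w = width_um
    r = w / 2.0
    body = length_um - w  # straight section
    if body < 0:
        raise ValueError("length must be >= width for a capsule")
    area_rect = body * w
    area_cap = math.pi * r**2 / 2.0
    m2_rect = w * body**3 / 12.0
    cap_centroid = 4.0 * r / (3.0 * math.pi)
    m2_cap = (
        (body / 2.0) ** 2 * area_cap
        + body * area_cap * cap_centroid
        + math.pi * r**4 / 8.0
    )
    var = (m2_rect + 2.0 * m2_cap) / (area_rect + 2.0 * area_cap)
    return 4.0 * math.sqrt(var)


@dataclass(frozen=True)
class SceneGroundTruth:
    """Planted parameters of one synthetic scene (per-cell table plus the
    channel images before blur and noise are applied)."""

    cells: pd.DataFrame  # x_um, y_um, orientation_deg, associated, tactoid_*


def _capsule_mask(
    shape: tuple[int, int],
    cx: float,
    cy: float,
    length_px: float,
    width_px: float,
    theta_deg: float,
) -> np.ndarray:
    """Capsule (rounded rod): points within width/2 of the central segment.

    Orientation follows the package convention: theta CCW on screen from +x,
    i.e. the axis direction is (cos t, -sin t) in (x, y-down) coordinates.
    """
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dx = xx - cx
    dy = cy - yy  # flip y so positive theta rotates CCW on screen
    t = math.radians(theta_deg)
    u = dx * math.cos(t) + dy * math.sin(t)
    v = -dx * math.sin(t) + dy * math.cos(t)
    half = max(length_px - width_px, 0.0) / 2.0
    du = np.abs(u) - half
    du = np.where(du > 0, du, 0.0)
    return du**2 + v**2 <= (width_px / 2.0) ** 2


def _ellipse_mask(
    shape: tuple[int, int],
    cx: float,
    cy: float,
    major_px: float,
    minor_px: float,
    theta_deg: float,
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dx = xx - cx
    dy = cy - yy
    t = math.radians(theta_deg)
    u = dx * math.cos(t) + dy * math.sin(t)
    v = -dx * math.sin(t) + dy * math.cos(t)
    return (u / (major_px / 2.0)) ** 2 + (v / (minor_px / 2.0)) ** 2 <= 1.0


def gen_scene(
    seed: int, params: SceneParams = SceneParams(), max_tries: int = 2000
) -> tuple[dict[str, np.ndarray], SceneGroundTruth]:
    """A two-channel (plus uptake) scene with known ground truth.

    Returns ``(channels, truth)`` where ``channels`` maps ``"cells"``,
    ``"tactoids"`` and ``"uptake"`` to float images.  Cells are placed
    without overlap (bounded rejection sampling; raises if the field cannot
    accommodate them); a planted fraction receives an enclosing ellipse
    tactoid whose orientation is the cell's plus N(0, offset SD).  In the
    uptake channel associated cells are dimmer by ``uptake_contrast``.
    """
    p = params
    rng = np.random.default_rng(seed)
    h, w = p.image_shape
    px = p.pixel_size
    cell_len_px = p.cell_length_um / px
    cell_wid_px = p.cell_width_um / px
    cell_moment_major = capsule_moment_major(p.cell_length_um, p.cell_width_um)
    tac_major_um = cell_moment_major + p.size_excess_um
    tac_major_px = tac_major_um / px
    tac_minor_px = p.tactoid_minor_um / px

    # conservative non-overlap: bounding circles of the larger (tactoid) shape
    sep_px = tac_major_px / 2.0 + 2.0
    margin = tac_major_px / 2.0 + 2.0
    if 2 * margin >= min(h, w):
        raise ValueError("field too small for the requested cell geometry")

    centers: list[tuple[float, float]] = []
    angles: list[float] = []
    tries = 0
    while len(centers) < p.n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {p.n_cells} cells without overlap "
                f"in {max_tries} tries"
            )
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        if all((cx - x) ** 2 + (cy - y) ** 2 >= (2 * sep_px) ** 2 for x, y in centers):
            centers.append((cx, cy))
            angles.append(rng.uniform(0.0, 180.0))

    n_assoc = int(round(p.association_fraction * p.n_cells))
    assoc = np.zeros(p.n_cells, dtype=bool)
    assoc[rng.permutation(p.n_cells)[:n_assoc]] = True
    offsets = rng.normal(0.0, p.orientation_offset_sd_deg, size=p.n_cells)

    cells_img = np.zeros((h, w))
    tact_img = np.zeros((h, w))
    uptake_img = np.zeros((h, w))
    rows = []
    for i, ((cx, cy), ang) in enumerate(zip(centers, angles)):
        cmask = _capsule_mask((h, w), cx, cy, cell_len_px, cell_wid_px, ang)
        cells_img[cmask] = 200.0
        tac_ang = (ang + offsets[i]) % 180.0 if assoc[i] else np.nan
        if assoc[i]:
            tmask = _ellipse_mask((h, w), cx, cy, tac_major_px, tac_minor_px, tac_ang)
            tact_img[tmask] = np.maximum(tact_img[tmask], 180.0)
        uptake = p.uptake_base_intensity * (p.uptake_contrast if assoc[i] else 1.0)
        uptake_img[cmask] = uptake
        rows.append(
            {
                "cell_id": i + 1,
                "x_um": cx * px,
                "y_um": cy * px,
                "orientation_deg": ang,
                "length_um": p.cell_length_um,
                "width_um": p.cell_width_um,
                "moment_major_um": cell_moment_major,
                "associated": bool(assoc[i]),
                "tactoid_orientation_deg": tac_ang,
                "tactoid_major_um": tac_major_um if assoc[i] else np.nan,
                "tactoid_minor_um": p.tactoid_minor_um if assoc[i] else np.nan,
                "uptake_intensity": uptake,
            }
        )

    channels = {"cells": cells_img, "tactoids": tact_img, "uptake": uptake_img}
    if p.psf_sigma_px > 0:
        from scipy.ndimage import gaussian_filter

        channels = {
            k: gaussian_filter(v, p.psf_sigma_px) for k, v in channels.items()
        }
    if p.poisson_noise:
        channels = {k: rng.poisson(v).astype(float) for k, v in channels.items()}
    if p.noise_sd > 0:
        channels = {
            k: v + rng.normal(0.0, p.noise_sd, size=v.shape)
            for k, v in channels.items()
        }
    return channels, SceneGroundTruth(cells=pd.DataFrame(rows))


def gen_filament_box(
    seed: int, params: BoxParams = BoxParams(), max_tries: int = 200000
) -> tuple[FilamentBoxModel, np.ndarray]:
    """A cubic box of parallel cylindrical filaments plus their centerlines.

    Lattice mode (``spacing`` set): square lattice at that spacing, count =
    (round(E/s))**2.  Random mode (``count`` set): centers rejection-sampled
    in the cross-section with pairwise distance >= 2 * filament_radius
    (hard, non-overlapping cylinders); raises if the requested count is not
    feasible within the try budget.  Returns the box model (count-driven, so
    packing arithmetic sees exactly these filaments) and an (n, 2) array of
    cross-section centers (nm); centerlines run parallel to the box axis.
    """
    p = params
    if (p.count is None) == (p.spacing is None):
        raise ValueError("exactly one of count or spacing must be set")
    rng = np.random.default_rng(seed)
    r = p.filament_radius
    if p.spacing is not None:
        per_edge = round(p.edge / p.spacing)
        if per_edge < 1:
            raise ValueError("spacing larger than the box edge")
        offsets = (np.arange(per_edge) + 0.5) * (p.edge / per_edge)
        xx, yy = np.meshgrid(offsets, offsets)
        centers = np.column_stack([xx.ravel(), yy.ravel()])
    else:
        n = p.count
        if n * math.pi * r**2 > 0.5 * p.edge**2:
            raise ValueError(
                "requested random count beyond non-overlap feasibility"
            )
        centers_list: list[np.ndarray] = []
        tries = 0
        while len(centers_list) < n:
            tries += 1
            if tries > max_tries:
                raise RuntimeError("rejection sampling exhausted its try budget")
            c = rng.uniform(r, p.edge - r, size=2)
            if all(np.sum((c - o) ** 2) >= (2 * r) ** 2 for o in centers_list):
                centers_list.append(c)
        centers = np.array(centers_list)
    box = FilamentBoxModel(
        edge=p.edge, filament_radius=r, filament_count=len(centers)
    )
    return box, centers
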