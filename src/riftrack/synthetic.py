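"""Synthetic two-channel time-lapse movies with known ground truth.

The generator emulates the statistical structure that the downstream analysis
stages assume for live MCF10A-like cells expressing a nuclear chromatin marker
(channel 0, "H2B") and a DNA-repair-protein marker (channel 1, "53BP1"):

* drifting, dividing elliptical nuclei with a persistent intranuclear texture;
* radiation-induced foci (RIF) in four size/intensity classes plus a diffuse
  nuclear protein background (class 0);
* foci confined to a small number of circular repair domains per nucleus,
  moving by reflected Brownian motion and occasionally merging on contact;
* exponentially decaying spontaneous foci plus a dose-dependent
  induction/resolution dome after irradiation at t = 0;
* the standard acquisition timeline for these experiments: one frame every
  15 min, shortened to 5 min for the first hour post-irradiation.

Everything is driven by a single integer seed: identical configurations and
seeds give bit-identical pixel arrays and ground-truth tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

NUCLEAR_CHANNEL = 0
REPAIR_CHANNEL = 1

# sample mean over the nominal focus footprint (disc of radius 2*sigma) of a
# unit-peak Gaussian: (1 - e^-2)/2
_GAUSS_FOOTPRINT_MEAN = (1.0 - math.exp(-2.0)) / 2.0


class PlacementError(ValueError):
    """Raised when nuclei or domains cannot be placed under the constraints."""


@dataclass(frozen=True)
class FociClassMixture:
    """Gaussian mixture over (log area [µm²], log mean intensity [a.u.]).

    The four default components run from small/dim (class 1) to large/bright
    (class 4). The subsample-and-select protocol must find K=4 non-trivially,
    so the defaults overlap; the exact numbers are fitted-by-eye stand-ins
    (no per-class brightness distributions are published for these cells).
    """

    means: np.ndarray
    sds: np.ndarray  # per-component diagonal standard deviations
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.means.shape != self.sds.shape or len(self.weights) != len(self.means):
            raise ValueError("mixture means/sds/weights shapes disagree")
        if not math.isclose(float(self.weights.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights < 0) or np.any(self.sds < 0):
            raise ValueError("mixture weights and sds must be non-negative")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def sample(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` (area_um2, mean_intensity) pairs; returns (values, labels 1..K)."""
        comp = rng.choice(self.n_components, size=n, p=self.weights)
        logx = self.means[comp] + rng.standard_normal((n, 2)) * self.sds[comp]
        return np.exp(logx), comp + 1


def default_foci_mixture() -> FociClassMixture:
    return FociClassMixture(
        means=np.log(
            [[0.35, 120.0], [0.45, 400.0], [1.6, 250.0], [4.5, 600.0]]
        ),
        sds=np.array(
            [[0.35, 0.30], [0.30, 0.25], [0.35, 0.30], [0.40, 0.30]]
        ),
        weights=np.array([0.40, 0.25, 0.20, 0.15]),
    )


@dataclass
class SyntheticConfig:
    """Generator settings; defaults mirror the study's acquisition conditions."""

    field_size_px: int = 256
    pixel_area_um2: float = 0.1           # Fig-4-style calibration: 1 px = 0.1 µm²
    frame_interval_pre_min: float = 15.0
    frame_interval_early_post_min: float = 5.0
    early_post_window_min: float = 60.0
    pre_hours: float = 24.0
    post_hours: float = 24.0
    dose_gy: float = 0.0
    n_cells: int = 5
    nuclear_area_um2: float = 150.0       # mean nuclear surface of these cells
    nuclear_area_sd_um2: float = 15.0
    nucleus_drift_sigma_um: float = 0.5   # per 15-min frame, per axis
    nucleus_rotation_sigma_deg: float = 0.0
    doubling_time_h: float | None = 20.0
    doubling_jitter_h: float = 3.0
    mitosis_block_dose_gy: float = 1.0    # 2 Gy arrests mitosis for ~20 h
    mitosis_block_h: float = 20.0
    division_times_min: tuple[tuple[int, float], ...] = ()
    death_times_min: tuple[tuple[int, float], ...] = ()
    n_domains_per_cell: int = 9           # plateau count per nucleus
    domain_radius_um: float = 1.545       # area pi*r^2 ~ 7.5 µm²
    domain_min_separation_um: float = 1.0  # margin beyond touching, if it fits
    diffusion_coefficient_um2_min: float = 0.005
    foci_class_mixture: FociClassMixture = field(default_factory=default_foci_mixture)
    spontaneous_amplitude: float = 20.0   # extra foci/cell at movie start
    spontaneous_decay_rate_per_h: float = 0.2
    spontaneous_plateau: float = 5.0      # settles to ~5 foci/cell
    rif_yield_per_gy: float = 15.0        # dose-dome amplitude, foci/cell/Gy
    induction_timescale_h: float = 0.5
    resolution_half_life_h: float = 7.0
    merge_probability: float = 0.1        # per contact event per frame
    nuclear_level: float = 100.0
    diffuse_level: float = 50.0
    background_level: float = 10.0
    background_noise_sd: float = 2.0
    texture_contrast: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.pixel_area_um2 <= 0:
            raise ValueError("pixel_area_um2 must be positive")
        rates = (
            self.spontaneous_decay_rate_per_h,
            self.rif_yield_per_gy,
            self.diffusion_coefficient_um2_min,
            self.merge_probability,
        )
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")

    @property
    def pixel_size_um(self) -> float:
        return math.sqrt(self.pixel_area_um2)

    @property
    def field_size_um(self) -> float:
        return self.field_size_px * self.pixel_size_um


@dataclass
class Movie:
    """Two-channel time-lapse stack, dimension order (T, C, Y, X)."""

    pixels: np.ndarray
    times_min: np.ndarray        # t = 0 at irradiation; negative pre-IR
    pixel_size_um: float
    dose_gy: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.times_min = np.asarray(self.times_min, dtype=float)
        if self.pixels.ndim != 4:
            raise ValueError("movie pixels must be (T, C, Y, X)")
        if len(self.times_min) != self.pixels.shape[0]:
            raise ValueError("times_min length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2

    def frame(self, t: int, channel: int) -> np.ndarray:
        return self.pixels[t, channel]


@dataclass
class GroundTruth:
    """Tables describing exactly what was rendered."""

    lineage: pd.DataFrame        # cell_id, parent_id, generation, start_frame, split_frame, death_frame
    cells: pd.DataFrame          # frame, cell_id, x_um, y_um, area_um2
    foci: pd.DataFrame           # frame, focus_id, cell_id, domain_id, x_um, y_um, class_label, area_um2, mean_intensity, total_intensity
    merges: pd.DataFrame         # frame, absorbed_id, absorber_id
    domains: pd.DataFrame        # cell_id, domain_id, x_um, y_um, radius_um, area_um2
    class_intensity: pd.DataFrame  # frame, time_min, I0..I4 (per-nucleus means)


def acquisition_timeline(config: SyntheticConfig) -> np.ndarray:
    """Frame timestamps in minutes, t = 0 at irradiation (no frame at 0).

    Pre-IR frames every ``frame_interval_pre_min``; post-IR every
    ``frame_interval_early_post_min`` for the first hour, then back to the
    pre-IR cadence.
    """
    pre = -np.arange(
        config.frame_interval_pre_min,
        config.pre_hours * 60.0 + 1e-9,
        config.frame_interval_pre_min,
    )[::-1]
    early = np.arange(
        config.frame_interval_early_post_min,
        config.early_post_window_min + 1e-9,
        config.frame_interval_early_post_min,
    )
    late = np.arange(
        config.early_post_window_min + config.frame_interval_pre_min,
        config.post_hours * 60.0 + 1e-9,
        config.frame_interval_pre_min,
    )
    times = np.concatenate([pre, early, late])
    if len(times) == 0:
        raise ValueError("timeline is empty; extend pre_hours/post_hours")
    return times


# --------------------------------------------------------------------------
# geometry helpers


def _place_centers(
    n: int,
    low: float,
    high: float,
    min_separation: float,
    rng: np.random.Generator,
    max_tries: int = 4000,
    what: str = "nuclei",
) -> np.ndarray:
    """Rejection-sample ``n`` centers in [low, high]² with a minimum spacing."""
    if n == 0:
        return np.zeros((0, 2))
    if high <= low:
        raise PlacementError(
            f"field too small to place {n} {what}: usable extent is non-positive"
        )
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n:
        cand = rng.uniform(low, high, size=2)
        if all(np.hypot(*(cand - c)) >= min_separation for c in centers):
            centers.append(cand)
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"field too small to place {n} {what} with minimum separation "
                f"{min_separation:.1f} µm in [{low:.1f}, {high:.1f}] µm"
            )
    return np.array(centers)


def _sunflower_points(n: int, rng: np.random.Generator) -> np.ndarray:
    """Evenly spread points in the unit disc (golden-angle spiral)."""
    i = np.arange(1, n + 1)
    r = np.sqrt((i - 0.5) / n)
    theta = i * (math.pi * (3.0 - math.sqrt(5.0))) + rng.uniform(0, 2 * math.pi)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _place_domains(
    n: int,
    semi_axes: tuple[float, float],
    radius: float,
    rng: np.random.Generator,
    min_separation: float = 0.0,
) -> np.ndarray:
    """Domain centers (cell-local µm) with discs inside the nucleus ellipse.

    Tries rejection sampling for non-overlapping discs first; if the packing is
    too tight, falls back to a deterministic sunflower layout (discs may touch
    or slightly overlap but always stay inside the ellipse).
    """
    a, b = semi_axes
    ai, bi = a - radius, b - radius
    if ai <= 0 or bi <= 0:
        raise PlacementError(
            f"domain radius {radius:.2f} µm does not fit inside nucleus "
            f"semi-axes ({a:.2f}, {b:.2f}) µm"
        )
    centers: list[np.ndarray] = []
    for _ in range(3000):
        u = rng.uniform(-1, 1, size=2)
        if u @ u > 1:
            continue
        cand = u * (ai, bi)
        if all(np.hypot(*(cand - c)) >= 2 * radius + min_separation for c in centers):
            centers.append(cand)
        if len(centers) == n:
            return np.array(centers)
    # dense packing: fall back to an even deterministic layout
    pts = _sunflower_points(n, rng)
    return pts * (ai * 0.97, bi * 0.97)


def _uniform_in_disc(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * math.pi, size=n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _reflect_into_disc(pos: np.ndarray, radius: float) -> np.ndarray:
    """Radially reflect points that stepped outside the disc back inside."""
    pos = pos.copy()
    r = np.hypot(pos[..., 0], pos[..., 1])
    out = r > radius
    if np.any(out):
        scale = (2 * radius - r[out]) / r[out]
        # a very long step could reflect past the centre; clip to the rim
        scale = np.clip(scale, -1.0, 1.0)
        pos[out] *= scale[:, None]
    return pos


# --------------------------------------------------------------------------
# focus population model


def expected_counts(
    times_min: np.ndarray, config: SyntheticConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Expected spontaneous and dose-induced foci per cell at each frame.

    Spontaneous pool: A·exp(−λ·(t − t_start)) + plateau, decaying from the
    start of acquisition as cells settle. Dose dome for t > 0:
    yield·dose·(exp(−k_res·t) − exp(−k_ind·t)) scaled to peak at yield·dose.
    """
    t = np.asarray(times_min, dtype=float)
    t_h = (t - t[0]) / 60.0
    spont = (
        config.spontaneous_amplitude
        * np.exp(-config.spontaneous_decay_rate_per_h * t_h)
        + config.spontaneous_plateau
    )
    dose = np.zeros_like(t)
    if config.dose_gy > 0:
        k_res = math.log(2.0) / config.resolution_half_life_h
        k_ind = math.log(2.0) / config.induction_timescale_h
        tp_h = np.clip(t / 60.0, 0.0, None)
        dome = np.exp(-k_res * tp_h) - np.exp(-k_ind * tp_h)
        peak = dome.max() if dome.max() > 0 else 1.0
        dose = config.rif_yield_per_gy * config.dose_gy * dome / peak
        dose[t <= 0] = 0.0
    return spont, dose


def generate_count_series(
    config: SyntheticConfig,
    noise: bool = True,
    n_replicates: int = 1,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-frame foci/cell counts for a control and a dosed well.

    Columns: time_min, control, dosed (+ control_rep{i}/dosed_rep{i} when
    ``n_replicates`` > 1). Control follows the settling exponential; the dosed
    well adds the induction/resolution dome. Counts are Poisson draws around
    the noiseless curves unless ``noise`` is off.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    times = acquisition_timeline(config)
    spont, dose = expected_counts(times, config)
    out = {"time_min": times, "control_true": spont, "dosed_true": spont + dose}
    for i in range(n_replicates):
        suffix = "" if n_replicates == 1 else f"_rep{i}"
        if noise:
            out[f"control{suffix}"] = rng.poisson(spont).astype(float)
            out[f"dosed{suffix}"] = rng.poisson(spont + dose).astype(float)
        else:
            out[f"control{suffix}"] = spont
            out[f"dosed{suffix}"] = spont + dose
    return pd.DataFrame(out)


def generate_feature_table(
    config: SyntheticConfig, n: int, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample ``n`` focus (area, mean intensity) feature rows from the mixture.

    Returns the feature table and the true component label (1..K) per row.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    values, labels = config.foci_class_mixture.sample(n, rng)
    df = pd.DataFrame(
        {"area_um2": values[:, 0], "mean_intensity": values[:, 1]}
    )
    return df, labels


def generate_trajectories(
    config: SyntheticConfig,
    n: int,
    confined: bool = False,
    n_frames: int | None = None,
    dt_min: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Brownian focus trajectories; returns (positions (n, T, 2) µm, times (T,)).

    Per-axis Gaussian increments with variance 2·D·δt per step. In confined
    mode the start points are uniform in the domain disc and displacements are
    reflected at the disc boundary. Without ``dt_min``/``n_frames`` the
    non-uniform post-IR acquisition timeline is used.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if dt_min is not None:
        if n_frames is None:
            raise ValueError("n_frames required when dt_min is given")
        times = np.arange(n_frames) * dt_min
    else:
        post = acquisition_timeline(config)
        post = post[post >= 0]
        times = post if n_frames is None else post[:n_frames]
    dts = np.diff(times)
    D = config.diffusion_coefficient_um2_min
    if confined:
        if config.domain_radius_um <= 0:
            raise ValueError("confined trajectories need domain_radius_um > 0")
        pos = np.empty((n, len(times), 2))
        pos[:, 0] = _uniform_in_disc(n, config.domain_radius_um, rng)
        for i, dt in enumerate(dts):
            sd = math.sqrt(2.0 * D * dt)
            step = rng.standard_normal((n, 2)) * sd
            pos[:, i + 1] = _reflect_into_disc(pos[:, i] + step, config.domain_radius_um)
    else:
        steps = rng.standard_normal((n, len(dts), 2)) * np.sqrt(2.0 * D * dts)[None, :, None]
        pos = np.concatenate(
            [np.zeros((n, 1, 2)), np.cumsum(steps, axis=1)], axis=1
        )
    return pos, times


def generate_intensity_series(
    rates: np.ndarray, I0: np.ndarray, n_steps: int
) -> np.ndarray:
    """Iterate the mass-balance update exactly; returns (n_steps + 1, K).

    ``rates[j, k]`` is the fraction of class j's intensity converting to class
    k per step (diagonal ignored). Total intensity is conserved exactly.
    """
    rates = np.asarray(rates, dtype=float)
    I0 = np.asarray(I0, dtype=float)
    K = len(I0)
    if rates.shape != (K, K):
        raise ValueError("rates must be square and match I0 length")
    if np.any(rates < 0) or np.any(I0 < 0):
        raise ValueError("rates and intensities must be non-negative")
    off = rates.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off.sum(axis=1) > 1.0 + 1e-12):
        raise ValueError("per-class outflow row sums must be <= 1")
    series = np.empty((n_steps + 1, K))
    series[0] = I0
    for t in range(n_steps):
        I = series[t]
        inflow = off.T @ I
        outflow = off.sum(axis=1) * I
        series[t + 1] = I + inflow - outflow
    return series


# --------------------------------------------------------------------------
# movie generation


@dataclass
class _Cell:
    cell_id: int
    parent_id: int
    generation: int
    start_frame: int
    area_um2: float
    angle: float
    center_um: np.ndarray
    texture: np.ndarray
    domain_centers: np.ndarray  # cell-local µm
    split_frame: int | None = None
    death_frame: int | None = None

    @property
    def semi_axes(self) -> tuple[float, float]:
        # fixed 1.4 aspect ratio: area = pi*a*b, a = 1.4*b
        b = math.sqrt(self.area_um2 / (math.pi * 1.4))
        return 1.4 * b, b


@dataclass
class _Focus:
    focus_id: int
    cell_id: int
    domain_id: int
    class_label: int
    area_um2: float
    mean_intensity: float
    pos_um: np.ndarray  # relative to domain centre
    spontaneous: bool


def _make_texture(rng: np.random.Generator, size: int, contrast: float) -> np.ndarray:
    noise = rng.standard_normal((size, size))
    smooth = ndimage.gaussian_filter(noise, 3.0)
    smooth /= max(np.abs(smooth).max(), 1e-9)
    return 1.0 + contrast * smooth


def _render_nucleus(
    canvas: np.ndarray, cell: _Cell, level: float, pixel_size: float
) -> None:
    """Add an ellipse with the cell's persistent texture to ``canvas``."""
    a, b = cell.semi_axes
    cx, cy = cell.center_um / pixel_size
    rmax = a / pixel_size + 2
    y0, y1 = int(max(0, cy - rmax)), int(min(canvas.shape[0], cy + rmax + 1))
    x0, x1 = int(max(0, cx - rmax)), int(min(canvas.shape[1], cx + rmax + 1))
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = (xx - cx) * pixel_size
    dy = (yy - cy) * pixel_size
    ca, sa = math.cos(cell.angle), math.sin(cell.angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    # sample the static texture in cell-local coordinates
    ts = cell.texture.shape[0]
    tu = np.clip((u / a + 1) * (ts - 1) / 2, 0, ts - 1)
    tv = np.clip((v / b + 1) * (ts - 1) / 2, 0, ts - 1)
    tex = ndimage.map_coordinates(cell.texture, [tv.ravel(), tu.ravel()], order=1)
    patch = level * tex.reshape(u.shape)
    canvas[y0:y1, x0:x1][inside] += patch[inside]


def _nucleus_mask_terms(cell: _Cell, pixel_size: float, shape: tuple[int, int]):
    a, b = cell.semi_axes
    cx, cy = cell.center_um / pixel_size
    rmax = a / pixel_size + 2
    y0, y1 = int(max(0, cy - rmax)), int(min(shape[0], cy + rmax + 1))
    x0, x1 = int(max(0, cx - rmax)), int(min(shape[1], cx + rmax + 1))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = (xx - cx) * pixel_size
    dy = (yy - cy) * pixel_size
    ca, sa = math.cos(cell.angle), math.sin(cell.angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return (y0, y1, x0, x1), inside


def _render_focus(
    canvas: np.ndarray, x_um: float, y_um: float, area_um2: float,
    mean_intensity: float, pixel_size: float,
) -> None:
    sigma_um = math.sqrt(area_um2 / math.pi) / 2.0  # area = pi*(2*sigma)^2
    sigma_px = max(sigma_um / pixel_size, 0.25)
    peak = mean_intensity / _GAUSS_FOOTPRINT_MEAN
    cx, cy = x_um / pixel_size, y_um / pixel_size
    r = max(int(4 * sigma_px) + 1, 2)
    y0, y1 = int(max(0, cy - r)), int(min(canvas.shape[0], cy + r + 1))
    x0, x1 = int(max(0, cx - r)), int(min(canvas.shape[1], cx + r + 1))
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    canvas[y0:y1, x0:x1] += peak * np.exp(-d2 / (2 * sigma_px**2))


def generate_movie(config: SyntheticConfig) -> tuple[Movie, GroundTruth]:
    """Render a full synthetic two-channel movie plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    times = acquisition_timeline(config)
    n_frames = len(times)
    size = config.field_size_px
    px = config.pixel_size_um

    # --- cells -------------------------------------------------------------
    mean_radius = math.sqrt(config.nuclear_area_um2 / math.pi)
    margin = 1.4 * mean_radius + 2.0
    centers = _place_centers(
        config.n_cells, margin, config.field_size_um - margin,
        min_separation=2.6 * mean_radius, rng=rng, what="nuclei",
    )
    cells: dict[int, _Cell] = {}
    next_cell_id = 1

    def new_cell(parent_id: int, generation: int, start_frame: int,
                 center: np.ndarray, area: float) -> _Cell:
        nonlocal next_cell_id
        semi_b = math.sqrt(area / (math.pi * 1.4))
        cell = _Cell(
            cell_id=next_cell_id,
            parent_id=parent_id,
            generation=generation,
            start_frame=start_frame,
            area_um2=area,
            angle=rng.uniform(0, math.pi),
            center_um=center.astype(float).copy(),
            texture=_make_texture(rng, 48, config.texture_contrast),
            domain_centers=_place_domains(
                config.n_domains_per_cell, (1.4 * semi_b, semi_b),
                config.domain_radius_um, rng,
                min_separation=config.domain_min_separation_um,
            ),
        )
        cells[next_cell_id] = cell
        next_cell_id += 1
        return cell

    for c in centers:
        area = max(
            rng.normal(config.nuclear_area_um2, config.nuclear_area_sd_um2), 60.0
        )
        new_cell(0, 1, 0, c, area)

    # division schedule: explicit list wins; otherwise exponential-ish timing
    division_at: dict[int, float] = {cid: t for cid, t in config.division_times_min}
    death_at: dict[int, float] = {cid: t for cid, t in config.death_times_min}

    def schedule_division(cell: _Cell, born_min: float) -> None:
        if cell.cell_id in division_at or config.doubling_time_h is None:
            return
        wait_h = config.doubling_time_h + rng.normal(0, config.doubling_jitter_h)
        t = born_min + max(wait_h, 2.0) * 60.0
        if config.dose_gy >= config.mitosis_block_dose_gy:
            if 0.0 <= t <= config.mitosis_block_h * 60.0:
                t = config.mitosis_block_h * 60.0 + rng.uniform(0, 120.0)
        division_at[cell.cell_id] = t

    for cell in list(cells.values()):
        schedule_division(cell, times[0] - rng.uniform(0, 0.5 * (config.doubling_time_h or 1) * 60))

    # --- foci bookkeeping ----------------------------------------------------
    foci: dict[int, _Focus] = {}
    next_focus_id = 1
    spont_curve, dose_curve = expected_counts(times, config)

    def spawn_focus(cell: _Cell, spontaneous: bool) -> None:
        nonlocal next_focus_id
        if len(cell.domain_centers) == 0:
            return
        vals, labels = config.foci_class_mixture.sample(1, rng)
        dom = int(rng.integers(len(cell.domain_centers)))
        foci[next_focus_id] = _Focus(
            focus_id=next_focus_id,
            cell_id=cell.cell_id,
            domain_id=dom,
            class_label=int(labels[0]),
            area_um2=float(vals[0, 0]),
            mean_intensity=float(vals[0, 1]),
            pos_um=_uniform_in_disc(1, config.domain_radius_um, rng)[0],
            spontaneous=spontaneous,
        )
        next_focus_id += 1

    movie = np.zeros((n_frames, 2, size, size), dtype=np.float32)
    cell_rows, foci_rows, merge_rows, lineage_extra = [], [], [], {}
    intensity_rows = []

    alive: set[int] = set(cells)
    for cell in cells.values():
        # seed initial foci population
        for _ in range(rng.poisson(spont_curve[0])):
            spawn_focus(cell, spontaneous=True)

    prev_t = times[0]
    for f in range(n_frames):
        t = times[f]
        dt = t - prev_t if f > 0 else 0.0

        # --- lifecycle ------------------------------------------------------
        for cid in sorted(alive):
            cell = cells[cid]
            if cid in death_at and t >= death_at[cid]:
                cell.death_frame = f
                alive.discard(cid)
                for fid in [k for k, fo in foci.items() if fo.cell_id == cid]:
                    del foci[fid]
                continue
            if cid in division_at and t >= division_at[cid] and f > 0:
                # growth arrest: auto-scheduled divisions falling in the
                # post-IR block window are pushed past it
                explicit = any(c == cid for c, _ in config.division_times_min)
                if (
                    not explicit
                    and config.dose_gy >= config.mitosis_block_dose_gy
                    and 0.0 < t <= config.mitosis_block_h * 60.0
                ):
                    division_at[cid] = (
                        config.mitosis_block_h * 60.0 + rng.uniform(0, 120.0)
                    )
                    continue
                cell.split_frame = f
                alive.discard(cid)
                for fid in [k for k, fo in foci.items() if fo.cell_id == cid]:
                    del foci[fid]
                axis = rng.uniform(0, 2 * math.pi)
                offset = np.array([math.cos(axis), math.sin(axis)])
                sep = 0.8 * cell.semi_axes[1]
                for s in (-1.0, 1.0):
                    child = new_cell(
                        cid, cell.generation + 1, f,
                        cell.center_um + s * sep * offset,
                        0.45 * cell.area_um2,
                    )
                    schedule_division(child, t)
                    alive.add(child.cell_id)
                    for _ in range(rng.poisson(max(spont_curve[f], 1.0))):
                        spawn_focus(child, spontaneous=True)

        # --- motion ---------------------------------------------------------
        if f > 0 and dt > 0:
            drift_sd = config.nucleus_drift_sigma_um * math.sqrt(dt / 15.0)
            for cid in alive:
                cells[cid].center_um = cells[cid].center_um + rng.normal(
                    0, drift_sd, size=2
                )
                if config.nucleus_rotation_sigma_deg:
                    cells[cid].angle += math.radians(
                        rng.normal(0, config.nucleus_rotation_sigma_deg)
                    )
            sd = math.sqrt(2 * config.diffusion_coefficient_um2_min * dt)
            for focus in foci.values():
                focus.pos_um = _reflect_into_disc(
                    (focus.pos_um + rng.normal(0, sd, size=2))[None, :],
                    config.domain_radius_um,
                )[0]

        # --- focus population dynamics -------------------------------------
        if f > 0:
            per_cell = {cid: [] for cid in alive}
            for fid, fo in foci.items():
                if fo.cell_id in per_cell:
                    per_cell[fo.cell_id].append(fid)
            target = spont_curve[f] + dose_curve[f]
            d_target = target - (spont_curve[f - 1] + dose_curve[f - 1])
            for cid in alive:
                if d_target > 0:
                    for _ in range(rng.poisson(d_target)):
                        spawn_focus(cells[cid], spontaneous=t <= 0)
                elif d_target < 0 and per_cell[cid]:
                    p = min(-d_target / max(len(per_cell[cid]), 1), 1.0)
                    for fid in per_cell[cid]:
                        if fid in foci and rng.uniform() < p:
                            del foci[fid]

        # --- merging --------------------------------------------------------
        by_domain: dict[tuple[int, int], list[int]] = {}
        for fid, fo in foci.items():
            by_domain.setdefault((fo.cell_id, fo.domain_id), []).append(fid)
        for group in by_domain.values():
            group = sorted(group)
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    fa, fb = foci.get(group[i]), foci.get(group[j])
                    if fa is None or fb is None:
                        continue
                    contact = 2.0 * (
                        math.sqrt(fa.area_um2 / math.pi) / 2
                        + math.sqrt(fb.area_um2 / math.pi) / 2
                    )
                    if (
                        np.hypot(*(fa.pos_um - fb.pos_um)) < contact
                        and rng.uniform() < config.merge_probability
                    ):
                        small, big = (fa, fb) if fa.area_um2 < fb.area_um2 else (fb, fa)
                        tot = (
                            big.mean_intensity * big.area_um2
                            + small.mean_intensity * small.area_um2
                        )
                        big.area_um2 += small.area_um2
                        big.mean_intensity = tot / big.area_um2
                        merge_rows.append(
                            {"frame": f, "absorbed_id": small.focus_id,
                             "absorber_id": big.focus_id}
                        )
                        del foci[small.focus_id]

        # --- render ---------------------------------------------------------
        nuc = movie[f, NUCLEAR_CHANNEL]
        rep = movie[f, REPAIR_CHANNEL]
        nuc += rng.normal(
            config.background_level, config.background_noise_sd, (size, size)
        ).astype(np.float32)
        rep += rng.normal(
            config.background_level, config.background_noise_sd, (size, size)
        ).astype(np.float32)

        per_cell_diffuse: dict[int, float] = {}
        for cid in sorted(alive):
            cell = cells[cid]
            mitotic = cell.split_frame is None and cid in division_at and (
                f + 1 < n_frames and times[f + 1] >= division_at[cid]
            )
            nuc_level = config.nuclear_level * (1.6 if mitotic else 1.0)
            rep_level = config.diffuse_level * (0.3 if mitotic else 1.0)
            _render_nucleus(nuc, cell, nuc_level, px)
            _render_nucleus(rep, cell, rep_level, px)
            n_px = cell.area_um2 / config.pixel_area_um2
            per_cell_diffuse[cid] = rep_level * n_px
            cell_rows.append(
                {"frame": f, "cell_id": cid, "x_um": cell.center_um[0],
                 "y_um": cell.center_um[1], "area_um2": cell.area_um2,
                 "mitotic": bool(mitotic)}
            )
            if not mitotic:
                ca, sa = math.cos(cell.angle), math.sin(cell.angle)
                rot = np.array([[ca, -sa], [sa, ca]])
                for fo in foci.values():
                    if fo.cell_id != cid:
                        continue
                    local = cell.domain_centers[fo.domain_id] + fo.pos_um
                    world = cell.center_um + rot @ local
                    _render_focus(
                        rep, world[0], world[1], fo.area_um2, fo.mean_intensity, px
                    )
                    foci_rows.append(
                        {"frame": f, "time_min": t, "focus_id": fo.focus_id,
                         "cell_id": cid, "domain_id": fo.domain_id,
                         "x_um": world[0], "y_um": world[1],
                         "class_label": fo.class_label,
                         "area_um2": fo.area_um2,
                         "mean_intensity": fo.mean_intensity,
                         "total_intensity": fo.mean_intensity * fo.area_um2
                         / config.pixel_area_um2}
                    )

        # --- true class-intensity series (per-nucleus means) ----------------
        n_alive = max(len(alive), 1)
        row = {"frame": f, "time_min": t}
        row["I0"] = sum(per_cell_diffuse.values()) / n_alive
        for k in range(1, 5):
            row[f"I{k}"] = sum(
                fo.mean_intensity * fo.area_um2 / config.pixel_area_um2
                for fo in foci.values()
                if fo.class_label == k and fo.cell_id in alive
            ) / n_alive
        intensity_rows.append(row)
        prev_t = t

    lineage = pd.DataFrame(
        [
            {"cell_id": c.cell_id, "parent_id": c.parent_id,
             "generation": c.generation, "start_frame": c.start_frame,
             "split_frame": c.split_frame, "death_frame": c.death_frame}
            for c in cells.values()
        ],
        columns=["cell_id", "parent_id", "generation", "start_frame",
                 "split_frame", "death_frame"],
    )
    domains = pd.DataFrame(
        [
            {"cell_id": c.cell_id, "domain_id": d,
             "x_um": c.domain_centers[d][0], "y_um": c.domain_centers[d][1],
             "radius_um": config.domain_radius_um,
             "area_um2": math.pi * config.domain_radius_um**2}
            for c in cells.values()
            for d in range(len(c.domain_centers))
        ],
        columns=["cell_id", "domain_id", "x_um", "y_um", "radius_um", "area_um2"],
    )
    foci_cols = ["frame", "time_min", "focus_id", "cell_id", "domain_id",
                 "x_um", "y_um", "class_label", "area_um2", "mean_intensity",
                 "total_intensity"]
    gt = GroundTruth(
        lineage=lineage,
        cells=pd.DataFrame(cell_rows, columns=["frame", "cell_id", "x_um",
                                               "y_um", "area_um2", "mitotic"]),
        foci=pd.DataFrame(foci_rows, columns=foci_cols),
        merges=pd.DataFrame(merge_rows, columns=["frame", "absorbed_id",
                                                 "absorber_id"]),
        domains=domains,
        class_intensity=pd.DataFrame(intensity_rows),
    )
    return Movie(movie, times, px, config.dose_gy), gt


def generate_registered_cell_movie(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[Movie, GroundTruth]:
    """Single-cell movie as produced by crop-and-register: one static centred
    nucleus with diffusing foci in its repair domains.

    Emulates the registered sub-movies used for temporal-MIP repair-domain
    analysis: no drift, no rotation, no division. The foci drawn here are
    biased to the small classes (many small RIF per domain), matching the
    '~60 RIF within 9 domains' regime the domain maps are computed from.
    """
    small_biased = FociClassMixture(
        means=config.foci_class_mixture.means,
        sds=config.foci_class_mixture.sds,
        weights=np.array([0.7, 0.3, 0.0, 0.0]),
    )
    cfg = replace(
        config,
        n_cells=1,
        nucleus_drift_sigma_um=0.0,
        nucleus_rotation_sigma_deg=0.0,
        doubling_time_h=None,
        division_times_min=(),
        death_times_min=(),
        foci_class_mixture=small_biased,
        merge_probability=0.0,
        seed=config.seed if rng is None else int(rng.integers(2**31 - 1)),
    )
    return generate_movie(cfg)
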