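"""Repair domains and foci motion: single-cell registration, temporal MIP
domain maps, and MSD-based diffusion / confinement estimation.

A registered single-cell movie collapses (maximum intensity projection over a
post-irradiation time window) into a domain map: the sub-nuclear regions that
foci visit repeatedly light up as compact blobs, the repair domains. Focus
trajectories give the mean square displacement relative to the first
post-irradiation frame; free diffusion shows MSD = 4 D t (2D convention,
D = slope / 4), while confinement inside a disc of radius r makes the MSD
plateau at r² (for uniform starting positions), so pi x plateau estimates the
domain area.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage import filters, morphology, transform
from skimage.registration import phase_cross_correlation

from .synthetic import Movie, NUCLEAR_CHANNEL, REPAIR_CHANNEL

log = logging.getLogger(__name__)


class RegistrationError(RuntimeError):
    """Registration failed or the registered overlap fell below the floor."""


class SchemaError(ValueError):
    """A track table is missing required columns or contains duplicates."""


@dataclass
class RegisteredCellMovie:
    pixels: np.ndarray        # (T, 2, H, W)
    times_min: np.ndarray
    pixel_size_um: float
    dose_gy: float
    transforms: pd.DataFrame  # frame, shift_y_px, shift_x_px, rotation_deg, iou

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]


@dataclass
class RepairDomainSummary:
    cell_id: int
    dose_gy: float
    n_domains: int
    areas_um2: np.ndarray

    @property
    def mean_area_um2(self) -> float:
        return float(np.mean(self.areas_um2)) if self.n_domains else float("nan")


@dataclass
class MSDCurve:
    lag_min: np.ndarray
    msd_um2: np.ndarray
    n_tracks: np.ndarray


@dataclass
class DiffusionFit:
    D_um2_min: float          # slope / 4 (2D convention)
    slope_um2_min: float      # raw MSD slope
    n_lags: int


@dataclass
class ConfinementResult:
    confined: bool
    area_um2: float           # pi x plateau; NaN when not confined
    plateau_um2: float


# --------------------------------------------------------------------------
# registration


def _otsu_mask(image: np.ndarray) -> np.ndarray:
    smooth = ndimage.gaussian_filter(np.asarray(image, dtype=float), 2.0)
    if np.ptp(smooth) < 1e-12:
        return np.zeros(image.shape, dtype=bool)
    return smooth > filters.threshold_otsu(smooth)


def _mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 0.0


def _estimate_rotation(ref: np.ndarray, img: np.ndarray, upsample: int) -> float:
    """Rotation (deg, ccw) of ``img`` relative to ``ref`` about the centre.

    Phase correlation of the polar-transformed log-magnitude Fourier spectra;
    the spectrum magnitude is translation-invariant, so rotation and shift
    decouple. Real images give a 180-deg-periodic spectrum, so the result is
    resolved into (-90, 90] — ample for frame-to-frame nuclear motion.
    """
    win = np.outer(np.hanning(ref.shape[0]), np.hanning(ref.shape[1]))
    f_ref = np.log1p(np.abs(np.fft.fftshift(np.fft.fft2(ref * win))))
    f_img = np.log1p(np.abs(np.fft.fftshift(np.fft.fft2(img * win))))
    radius = min(ref.shape) // 2 - 1
    n_angles = 720
    pol_ref = transform.warp_polar(f_ref, radius=radius, output_shape=(n_angles, radius))
    pol_img = transform.warp_polar(f_img, radius=radius, output_shape=(n_angles, radius))
    shift, _, _ = phase_cross_correlation(
        pol_ref, pol_img, upsample_factor=upsample, normalization=None
    )
    angle = shift[0] * 360.0 / n_angles
    angle = (angle + 90.0) % 180.0 - 90.0
    return float(angle)


def register_pair(
    reference: np.ndarray,
    image: np.ndarray,
    estimate_rotation: bool = True,
    upsample: int = 20,
) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Rigidly register ``image`` onto ``reference``.

    Rotation about the image centre is estimated first by phase correlation of
    the polar-transformed images, then translation by sub-pixel phase
    correlation. Returns (registered image, rotation deg, (dy, dx) px).
    """
    ref = np.asarray(reference, dtype=float)
    img = np.asarray(image, dtype=float)
    angle = 0.0
    if estimate_rotation:
        angle = _estimate_rotation(ref, img, upsample)
        if abs(angle) > 1e-9:
            img = transform.rotate(img, -angle, preserve_range=True)
    shift, _, _ = phase_cross_correlation(
        ref, img, upsample_factor=upsample, normalization=None
    )
    registered = ndimage.shift(img, shift, order=1, mode="nearest")
    return registered, float(angle), (float(shift[0]), float(shift[1]))


def crop_and_register(
    movie: Movie,
    track: pd.DataFrame,
    crop_size_px: int = 80,
    estimate_rotation: bool = True,
    min_overlap_iou: float = 0.6,
    reference_time_min: float | None = None,
) -> RegisteredCellMovie:
    """Crop fixed-size windows centred on a track and rigidly register them.

    The nuclear channel of each frame is registered to the reference frame
    (first post-IR frame by default) and the same transform is applied to the
    repair channel. Raises :class:`RegistrationError` when the track does not
    cover the window or the registered nuclear-mask overlap falls below the
    configured floor — callers drop such cells and log the reason.
    """
    track = track.sort_values("frame").reset_index(drop=True)
    if len(track) < 2:
        raise RegistrationError("track too short to register")
    frames = track.frame.to_numpy(dtype=int)
    times = movie.times_min[frames]
    if reference_time_min is None:
        post = np.nonzero(times >= 0)[0]
        ref_idx = int(post[0]) if len(post) else 0
    else:
        ref_idx = int(np.argmin(np.abs(times - reference_time_min)))
    half = crop_size_px // 2
    px = movie.pixel_size_um

    crops = np.zeros((len(track), 2, crop_size_px, crop_size_px), dtype=float)
    for i, row in track.iterrows():
        cy = int(round(row.y_um / px))
        cx = int(round(row.x_um / px))
        for ch in (NUCLEAR_CHANNEL, REPAIR_CHANNEL):
            frame = movie.pixels[int(row.frame), ch]
            y0, x0 = cy - half, cx - half
            ys = slice(max(y0, 0), min(y0 + crop_size_px, frame.shape[0]))
            xs = slice(max(x0, 0), min(x0 + crop_size_px, frame.shape[1]))
            crop = np.zeros((crop_size_px, crop_size_px))
            crop[ys.start - y0:ys.stop - y0, xs.start - x0:xs.stop - x0] = frame[ys, xs]
            crops[i, ch] = crop

    ref = crops[ref_idx, NUCLEAR_CHANNEL]
    ref_mask = _otsu_mask(ref)
    rows = []
    registered = np.empty_like(crops)
    for i in range(len(track)):
        if i == ref_idx:
            registered[i] = crops[i]
            angle, shift = 0.0, (0.0, 0.0)
        else:
            reg_nuc, angle, shift = register_pair(
                ref, crops[i, NUCLEAR_CHANNEL], estimate_rotation
            )
            registered[i, NUCLEAR_CHANNEL] = reg_nuc
            rep = crops[i, REPAIR_CHANNEL]
            if estimate_rotation and abs(angle) > 1e-9:
                rep = transform.rotate(rep, -angle, preserve_range=True)
            registered[i, REPAIR_CHANNEL] = ndimage.shift(
                rep, shift, order=1, mode="nearest"
            )
        iou = _mask_iou(ref_mask, _otsu_mask(registered[i, NUCLEAR_CHANNEL]))
        rows.append(
            {"frame": int(frames[i]), "shift_y_px": shift[0],
             "shift_x_px": shift[1], "rotation_deg": angle, "iou": iou}
        )
    transforms = pd.DataFrame(rows)
    if transforms.iou.min() < min_overlap_iou:
        raise RegistrationError(
            f"registered nuclear overlap fell to {transforms.iou.min():.2f} "
            f"(< {min_overlap_iou}); cell dropped"
        )
    return RegisteredCellMovie(registered, times, px, movie.dose_gy, transforms)


# --------------------------------------------------------------------------
# temporal MIP and domain segmentation


def temporal_mip(
    registered: RegisteredCellMovie,
    window_min: tuple[float, float] = (240.0, 1440.0),
    spacing_min: float = 15.0,
    channel: int = REPAIR_CHANNEL,
) -> np.ndarray:
    """Maximum intensity projection over time frames in the window.

    Defaults match the domain-map recipe: 4-24 h post-IR, frames spaced every
    15 min (the early 5-min frames are thinned to the spacing).
    """
    t = registered.times_min
    sel = []
    last = -math.inf
    for i, ti in enumerate(t):
        if window_min[0] <= ti <= window_min[1] and ti >= last + spacing_min - 1e-9:
            sel.append(i)
            last = ti
    if not sel:
        raise ValueError("no frames fall in the requested MIP window")
    return registered.pixels[sel, channel].max(axis=0)


def pre_ir_background(
    registered: RegisteredCellMovie, channel: int = REPAIR_CHANNEL
) -> np.ndarray:
    """Per-pixel temporal median over pre-IR frames (diffuse-signal estimate)."""
    pre = registered.times_min < 0
    if not pre.any():
        raise ValueError("movie has no pre-IR frames for background estimation")
    return np.median(registered.pixels[pre, channel], axis=0)


def segment_domains(
    mip: np.ndarray,
    nucleus_mask: np.ndarray,
    pixel_size_um: float,
    background: np.ndarray | None = None,
    min_domain_area_um2: float = 1.0,
    closing_radius_px: int = 1,
    cell_id: int = 0,
    dose_gy: float = 0.0,
) -> RepairDomainSummary:
    """Threshold the (background-subtracted) MIP inside the nucleus into
    repair domains; returns their count and areas in µm²."""
    img = np.asarray(mip, dtype=float)
    if background is not None:
        img = np.clip(img - np.asarray(background, dtype=float), 0, None)
    mask = np.asarray(nucleus_mask).astype(bool)
    inside = img[mask]
    if inside.size == 0 or np.ptp(inside) < 1e-12:
        return RepairDomainSummary(cell_id, dose_gy, 0, np.array([]))
    thr = filters.threshold_otsu(inside)
    domains = (img > thr) & mask
    if closing_radius_px > 0:
        domains = morphology.closing(
            domains, morphology.disk(closing_radius_px)
        ).astype(bool)
    domains = ndimage.binary_fill_holes(domains) & mask
    comp, n = ndimage.label(domains)
    pixel_area = pixel_size_um**2
    areas = []
    for ci in range(1, n + 1):
        a = float((comp == ci).sum()) * pixel_area
        if a >= min_domain_area_um2:
            areas.append(a)
    return RepairDomainSummary(cell_id, dose_gy, len(areas), np.array(areas))


def domain_dose_summary(
    summaries: list[RepairDomainSummary], fit_plateau: bool = True
) -> pd.DataFrame:
    """Mean domain count and area vs dose (± s.e.), with an optional
    saturating fit N(dose) = N_max * dose / (dose + d0).

    The fitted plateau N_max is attached as DataFrame attribute
    ``plateau_n_domains`` (NaN when the fit is skipped).
    """
    if not summaries:
        raise ValueError("no domain summaries")
    df = pd.DataFrame(
        [
            {"cell_id": s.cell_id, "dose_gy": s.dose_gy,
             "n_domains": s.n_domains, "mean_area_um2": s.mean_area_um2}
            for s in summaries
        ]
    )
    grouped = df.groupby("dose_gy").agg(
        n_cells=("cell_id", "size"),
        mean_n_domains=("n_domains", "mean"),
        se_n_domains=("n_domains", "sem"),
        mean_area_um2=("mean_area_um2", "mean"),
        se_area_um2=("mean_area_um2", "sem"),
    ).reset_index()
    plateau = float("nan")
    if fit_plateau and grouped.dose_gy.nunique() >= 3:
        try:
            popt, _ = curve_fit(
                lambda d, nmax, d0: nmax * d / (d + d0),
                df.dose_gy.to_numpy(), df.n_domains.to_numpy(dtype=float),
                p0=(df.n_domains.max(), 0.3), maxfev=10000,
            )
            plateau = float(popt[0])
        except RuntimeError:
            log.warning("saturating domain-count fit did not converge")
    grouped.attrs["plateau_n_domains"] = plateau
    return grouped


def predicted_domain_area(
    nuclear_area_um2: float = 150.0, domain_fraction: float = 0.06
) -> float:
    """Domain area implied by a domain occupying a fixed fraction of the
    nucleus (the prior theoretical estimate: 6% of ~150 µm² is ~9 µm²)."""
    return nuclear_area_um2 * domain_fraction


# --------------------------------------------------------------------------
# MSD, diffusion, confinement


def trajectories_to_table(positions: np.ndarray, times_min: np.ndarray) -> pd.DataFrame:
    """Convert an (n, T, 2) position array into a tidy track table."""
    n, T, _ = positions.shape
    return pd.DataFrame(
        {
            "track_id": np.repeat(np.arange(n), T),
            "frame": np.tile(np.arange(T), n),
            "time_min": np.tile(np.asarray(times_min, dtype=float), n),
            "x_um": positions[:, :, 0].ravel(),
            "y_um": positions[:, :, 1].ravel(),
        }
    )


def read_track_table(path, pixel_size_um: float | None = None) -> pd.DataFrame:
    """Read an externally produced track table (e.g. manual foci tracking).

    Requires columns track_id, frame and either (x_um, y_um) or pixel-unit
    (x, y) plus a calibration. Duplicate (track_id, frame) rows are an error.
    """
    df = pd.read_csv(path)
    for col in ("track_id", "frame"):
        if col not in df.columns:
            raise SchemaError(f"track table is missing required column '{col}'")
    if {"x_um", "y_um"} <= set(df.columns):
        pass
    elif {"x", "y"} <= set(df.columns):
        if pixel_size_um is None:
            raise SchemaError(
                "track table has pixel-unit x/y but no calibration was given"
            )
        df["x_um"] = df["x"] * pixel_size_um
        df["y_um"] = df["y"] * pixel_size_um
    else:
        missing = {"x_um", "y_um"} - set(df.columns)
        raise SchemaError(f"track table is missing position column(s) {sorted(missing)}")
    if df.duplicated(["track_id", "frame"]).any():
        raise SchemaError("track table contains duplicated (track_id, frame) rows")
    if "time_min" not in df.columns:
        df["time_min"] = df["frame"].astype(float)
    return df


def compute_msd(
    tracks: pd.DataFrame, reference_frame: int | None = None
) -> MSDCurve:
    """Ensemble MSD relative to a reference frame (first frame by default).

    MSD(t) = mean over tracks of |r(t) - r(t0)|², computed over tracks that
    cover both the reference frame and t. A time-averaged variant is provided
    by :func:`compute_msd_time_averaged`.
    """
    if tracks.groupby("track_id").size().max() < 2:
        raise ValueError("need at least one trajectory with >= 2 points")
    ref = int(tracks.frame.min()) if reference_frame is None else reference_frame
    piv_x = tracks.pivot(index="track_id", columns="frame", values="x_um")
    piv_y = tracks.pivot(index="track_id", columns="frame", values="y_um")
    times = tracks.groupby("frame")["time_min"].first()
    if ref not in piv_x.columns:
        raise ValueError(f"reference frame {ref} not covered by any track")
    dx = piv_x.sub(piv_x[ref], axis=0)
    dy = piv_y.sub(piv_y[ref], axis=0)
    sq = dx**2 + dy**2
    frames = [f for f in sq.columns if f >= ref]
    msd = sq[frames].mean(axis=0, skipna=True)
    n = sq[frames].notna().sum(axis=0)
    lag = times.loc[frames].to_numpy() - times.loc[ref]
    return MSDCurve(lag, msd.to_numpy(dtype=float), n.to_numpy())


def compute_msd_time_averaged(tracks: pd.DataFrame) -> MSDCurve:
    """Time-averaged MSD over all frame pairs at each lag (uniform sampling)."""
    piv_x = tracks.pivot(index="track_id", columns="frame", values="x_um").to_numpy()
    piv_y = tracks.pivot(index="track_id", columns="frame", values="y_um").to_numpy()
    times = tracks.groupby("frame")["time_min"].first().to_numpy()
    T = piv_x.shape[1]
    lags, msds, ns = [0.0], [0.0], [piv_x.shape[0]]
    for lag in range(1, T):
        dx = piv_x[:, lag:] - piv_x[:, :-lag]
        dy = piv_y[:, lag:] - piv_y[:, :-lag]
        sq = dx**2 + dy**2
        lags.append(float(np.mean(times[lag:] - times[:-lag])))
        msds.append(float(np.nanmean(sq)))
        ns.append(int(np.sum(~np.isnan(sq))))
    return MSDCurve(np.array(lags), np.array(msds), np.array(ns))


def fit_diffusion(msd: MSDCurve, n_lags: int = 12) -> DiffusionFit:
    """Diffusion coefficient from a line through the origin over early lags.

    D = slope / 4 in the 2D convention; a non-positive slope is clipped to
    zero with a warning.
    """
    sel = (msd.lag_min > 0)
    tau = msd.lag_min[sel][:n_lags]
    m = msd.msd_um2[sel][:n_lags]
    if len(tau) < 3:
        raise ValueError("need at least 3 positive lags to fit diffusion")
    slope = float(np.sum(tau * m) / np.sum(tau * tau))
    if slope <= 0:
        log.warning("non-positive MSD slope %.3g; clipping D at 0", slope)
        slope = 0.0
    return DiffusionFit(D_um2_min=slope / 4.0, slope_um2_min=slope, n_lags=len(tau))


def estimate_confinement_area(
    msd: MSDCurve,
    late_fraction: float = 1.0 / 3.0,
    rising_slope_ratio: float = 0.3,
) -> ConfinementResult:
    """Confinement area from the late-lag MSD plateau.

    For Brownian motion reflected in a disc of radius r with uniform starting
    positions, MSD relative to the start plateaus at r², so the domain area is
    pi x plateau. Returns a not-confined result when the late-lag slope is
    still a sizeable fraction of the early slope.
    """
    sel = msd.lag_min > 0
    tau = msd.lag_min[sel]
    m = msd.msd_um2[sel]
    if len(tau) < 6:
        raise ValueError("MSD curve too short to assess confinement")
    n_late = max(int(len(tau) * late_fraction), 2)
    early_n = max(min(3, len(tau) // 3), 2)
    early_slope = float(np.polyfit(tau[:early_n], m[:early_n], 1)[0])
    late_slope = float(np.polyfit(tau[-n_late:], m[-n_late:], 1)[0])
    plateau = float(np.mean(m[-n_late:]))
    if early_slope > 0 and late_slope > rising_slope_ratio * early_slope:
        return ConfinementResult(False, float("nan"), plateau)
    return ConfinementResult(True, math.pi * plateau, plateau)
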