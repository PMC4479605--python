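"""Nucleus segmentation: pixel classification plus a convexity-restricted
distance watershed.

The watershed exploits the observation that single epithelial nuclei are
convex while touching-nuclei conglomerates show concave contour angles: a
connected foreground component whose simplified outline has no concave vertex
is kept whole no matter what the distance transform suggests; only components
with at least one concavity are split.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature, filters, measure, morphology, segmentation

log = logging.getLogger(__name__)


@dataclass
class SegmentationParams:
    smooth_sigma_px: float = 2.0
    epsilon_px: float = 2.0              # Douglas-Peucker tolerance
    angle_tolerance_deg: float = 10.0    # concavity must exceed 180 deg + tol
    marker_smooth_sigma_px: float = 2.0
    min_marker_distance_px: int = 10     # ~ expected nucleus radius / 2
    min_area_um2: float = 20.0           # rejects debris
    invert: bool = False
    extra: dict = field(default_factory=dict)


def max_project(zstack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over the slices of a (Z, Y, X) stack."""
    zstack = np.asarray(zstack)
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise ValueError("zstack must be (Z, Y, X) with at least one slice")
    return zstack.max(axis=0)


def classify_pixels(
    image: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Foreground/background pixel classification.

    Default backend: Gaussian smoothing, Otsu threshold, hole filling. A
    constant image yields an empty mask (with a warning) rather than an error.
    """
    params = params or SegmentationParams()
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite-valued")
    if params.invert:
        image = image.max() - image
    smooth = ndimage.gaussian_filter(image, params.smooth_sigma_px)
    if math.isclose(float(smooth.max()), float(smooth.min()), abs_tol=1e-12):
        log.warning("constant image: returning empty foreground mask")
        return np.zeros(image.shape, dtype=bool)
    thr = filters.threshold_otsu(smooth)
    mask = smooth > thr
    return ndimage.binary_fill_holes(mask)


def _as_closed_ring(vertices: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    if len(v) >= 2 and np.allclose(v[0], v[-1]):
        v = v[:-1]
    if len(v) < 3:
        raise ValueError("contour must have at least 3 distinct vertices")
    return v


def simplify_contour(vertices: np.ndarray, epsilon_px: float) -> np.ndarray:
    """Douglas-Peucker simplification of a closed polygon.

    Vertices are (x, y) rows; the ring is rotated so the anchor is the vertex
    farthest from the centroid (an extreme point survives simplification).
    Every removed vertex lies within ``epsilon_px`` of the simplified outline.
    """
    if epsilon_px < 0:
        raise ValueError("epsilon must be >= 0")
    v = _as_closed_ring(vertices)
    if epsilon_px == 0:
        return v
    far = int(np.argmax(np.linalg.norm(v - v.mean(axis=0), axis=1)))
    ring = np.roll(v, -far, axis=0)
    closed = np.vstack([ring, ring[:1]])
    simplified = measure.approximate_polygon(closed, tolerance=epsilon_px)
    if len(simplified) >= 2 and np.allclose(simplified[0], simplified[-1]):
        simplified = simplified[:-1]
    if len(simplified) < 3:
        # over-simplified to a sliver; keep a triangle of extreme points
        idx = np.linspace(0, len(ring) - 1, 3).astype(int)
        simplified = ring[idx]
    return simplified


def count_concavities(
    vertices: np.ndarray, angle_tolerance_deg: float = 10.0
) -> int:
    """Number of concave vertices of a simple closed polygon.

    A vertex is concave when the turn there is opposite to the polygon's
    overall orientation and the interior angle exceeds 180 deg plus the
    tolerance.
    """
    v = _as_closed_ring(vertices)
    e_prev = v - np.roll(v, 1, axis=0)
    e_next = np.roll(v, -1, axis=0) - v
    cross = e_prev[:, 0] * e_next[:, 1] - e_prev[:, 1] * e_next[:, 0]
    signed_area = 0.5 * float(
        np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])
    )
    if math.isclose(signed_area, 0.0, abs_tol=1e-12):
        raise ValueError("degenerate polygon: zero signed area")
    orient = math.copysign(1.0, signed_area)
    dot = np.sum(e_prev * e_next, axis=1)
    # turn angle at each vertex; concave when turning against the orientation
    turn = np.arctan2(orient * cross, dot)
    tol = math.radians(angle_tolerance_deg)
    return int(np.sum(turn < -tol))


def component_contour(mask: np.ndarray) -> np.ndarray:
    """Outer contour of a binary component as (x, y) vertex rows."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("component has no contour")
    longest = max(contours, key=len)
    # find_contours yields (row, col); convert to (x, y) and undo padding
    return longest[:, ::-1] - 1.0


def convexity_restricted_watershed(
    mask: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Split touching nuclei while never splitting convex components.

    Each connected component's contour is simplified (Douglas-Peucker) and its
    concave vertices counted; components with zero concavities are kept whole,
    others are split by a smoothed-distance-transform watershed. Fragments
    below the minimum area are merged back into the largest-contact sibling.
    Returns an integer label image partitioning the foreground exactly.
    """
    params = params or SegmentationParams()
    mask = np.asarray(mask).astype(bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    comps, n_comp = ndimage.label(mask)
    next_label = 1
    for ci in range(1, n_comp + 1):
        comp = comps == ci
        try:
            contour = component_contour(comp)
            simple = simplify_contour(contour, params.epsilon_px)
            n_concave = count_concavities(simple, params.angle_tolerance_deg)
        except ValueError:
            n_concave = 0
        if n_concave == 0:
            labels[comp] = next_label
            next_label += 1
            continue
        sub = _split_component(comp, params)
        for v in np.unique(sub):
            if v == 0:
                continue
            labels[sub == v] = next_label
            next_label += 1
    return labels


def _split_component(comp: np.ndarray, params: SegmentationParams) -> np.ndarray:
    dist = ndimage.distance_transform_edt(comp)
    smooth = ndimage.gaussian_filter(dist, params.marker_smooth_sigma_px)
    peaks = feature.peak_local_max(
        smooth, min_distance=params.min_marker_distance_px, labels=comp,
        exclude_border=False,
    )
    markers = np.zeros(comp.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() <= 1:
        return comp.astype(np.int32)
    ws = segmentation.watershed(-smooth, markers, mask=comp)
    return _merge_small_fragments(ws, params)


def _merge_small_fragments(ws: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Merge fragments below the minimum area into their largest neighbour."""
    min_px = max(int(params.min_area_um2 / params.extra.get("pixel_area_um2", 0.1)), 1)
    ws = ws.copy()
    changed = True
    while changed:
        changed = False
        ids, counts = np.unique(ws[ws > 0], return_counts=True)
        if len(ids) <= 1:
            break
        for frag, cnt in zip(ids, counts):
            if cnt >= min_px:
                continue
            frag_mask = ws == frag
            dilated = ndimage.binary_dilation(frag_mask)
            neighbours = np.unique(ws[dilated & ~frag_mask])
            neighbours = neighbours[(neighbours != 0) & (neighbours != frag)]
            if len(neighbours) == 0:
                continue
            contact = [
                (np.sum(ws[dilated & ~frag_mask] == n), n) for n in neighbours
            ]
            ws[frag_mask] = max(contact)[1]
            changed = True
            break
    return ws


def measure_nuclei(
    labels: np.ndarray, pixel_size_um: float
) -> pd.DataFrame:
    """Per-nucleus centroid (µm), area (µm²) and perimeter (µm)."""
    pixel_area = pixel_size_um**2
    rows = []
    for rp in measure.regionprops(np.asarray(labels)):
        cy, cx = rp.centroid
        rows.append(
            {
                "label": rp.label,
                "x_um": cx * pixel_size_um,
                "y_um": cy * pixel_size_um,
                "area_um2": rp.area * pixel_area,
                "perimeter_um": rp.perimeter * pixel_size_um,
            }
        )
    return pd.DataFrame(
        rows, columns=["label", "x_um", "y_um", "area_um2", "perimeter_um"]
    )


def segment_frame(
    image: np.ndarray,
    pixel_size_um: float,
    params: SegmentationParams | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Classify pixels, split touching nuclei, drop debris; returns labels +
    feature table."""
    params = params or SegmentationParams()
    params.extra.setdefault("pixel_area_um2", pixel_size_um**2)
    mask = classify_pixels(image, params)
    labels = convexity_restricted_watershed(mask, params)
    feats = measure_nuclei(labels, pixel_size_um)
    keep = feats[feats.area_um2 >= params.min_area_um2]
    relabeled = np.zeros_like(labels)
    table = []
    for new_id, (_, row) in enumerate(keep.iterrows(), start=1):
        relabeled[labels == row.label] = new_id
        row = row.copy()
        row["label"] = new_id
        table.append(row)
    feats = pd.DataFrame(table).reset_index(drop=True) if table else keep
    return relabeled, feats
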