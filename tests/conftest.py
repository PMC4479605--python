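"""Shared fixtures: small synthetic movies and derived products.

Session-scoped so expensive renders and fits run once; every fixture is fully
seeded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import riftrack
from riftrack import foci as foci_mod
from riftrack import kinetics, segmentation, synthetic, tracking


@pytest.fixture(scope="session")
def seg_movie():
    """Four non-dividing, well-separated nuclei over ~6 h (dose 2 Gy)."""
    cfg = riftrack.SyntheticConfig(
        field_size_px=192, n_cells=4, pre_hours=1.0, post_hours=5.0,
        dose_gy=2.0, doubling_time_h=None, seed=23,
    )
    movie, gt = synthetic.generate_movie(cfg)
    return cfg, movie, gt


@pytest.fixture(scope="session")
def seg_movie_frames(seg_movie):
    """Per-frame (labels, features-with-intensities) for the movie above."""
    _, movie, _ = seg_movie
    labels_all, tables = [], []
    for f in range(movie.n_frames):
        labels, feats = segmentation.segment_frame(
            movie.frame(f, synthetic.NUCLEAR_CHANNEL), movie.pixel_size_um
        )
        if len(feats):
            nuc = movie.frame(f, synthetic.NUCLEAR_CHANNEL)
            rep = movie.frame(f, synthetic.REPAIR_CHANNEL)
            feats = feats.assign(
                mean_nuclear=[nuc[labels == l].mean() for l in feats.label],
                mean_repair=[rep[labels == l].mean() for l in feats.label],
            )
        labels_all.append(labels)
        tables.append(feats)
    return labels_all, tables


@pytest.fixture(scope="session")
def seg_tracks(seg_movie_frames):
    _, tables = seg_movie_frames
    return tracking.build_tracks(tables)


@pytest.fixture(scope="session")
def division_movie():
    """Three founders, each with one scheduled division, no dose effects."""
    cfg = riftrack.SyntheticConfig(
        field_size_px=256, n_cells=3, pre_hours=1.0, post_hours=2.5,
        dose_gy=0.0, doubling_time_h=None,
        division_times_min=((1, 30.0), (2, 50.0), (3, 80.0)), seed=31,
    )
    movie, gt = synthetic.generate_movie(cfg)
    return cfg, movie, gt


@pytest.fixture(scope="session")
def division_tracks(division_movie):
    _, movie, _ = division_movie
    tables = []
    for f in range(movie.n_frames):
        labels, feats = segmentation.segment_frame(
            movie.frame(f, synthetic.NUCLEAR_CHANNEL), movie.pixel_size_um
        )
        if len(feats):
            nuc = movie.frame(f, synthetic.NUCLEAR_CHANNEL)
            rep = movie.frame(f, synthetic.REPAIR_CHANNEL)
            feats = feats.assign(
                mean_nuclear=[nuc[labels == l].mean() for l in feats.label],
                mean_repair=[rep[labels == l].mean() for l in feats.label],
            )
        tables.append(feats)
    return tracking.build_tracks(tables)


@pytest.fixture(scope="session")
def default_features():
    """60k feature rows from the default four-class mixture + true labels."""
    cfg = riftrack.SyntheticConfig(seed=5)
    feats, labels = synthetic.generate_feature_table(cfg, 60_000)
    return feats, labels


@pytest.fixture(scope="session")
def fitted_class_model(default_features):
    feats, _ = default_features
    return kinetics.fit_foci_classes(feats, random_state=5)


def match_tracks_to_truth(tracks: pd.DataFrame, gt_cells: pd.DataFrame) -> pd.DataFrame:
    """Attach the nearest ground-truth cell id to every track observation."""
    rows = []
    for f, sub in tracks.groupby("frame"):
        g = gt_cells[gt_cells.frame == f]
        if not len(g):
            continue
        gxy = g[["x_um", "y_um"]].to_numpy()
        for _, r in sub.iterrows():
            d = np.hypot(gxy[:, 0] - r.x_um, gxy[:, 1] - r.y_um)
            rows.append({"frame": int(f), "track_id": int(r.track_id),
                         "gt_cell": int(g.cell_id.iloc[int(np.argmin(d))]),
                         "dist_um": float(d.min())})
    return pd.DataFrame(rows)
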