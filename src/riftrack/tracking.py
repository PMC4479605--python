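"""Frame-to-frame nucleus linking, mitosis/death detection, ancestry and
population metrics.

Linking solves a minimum-total-cost one-to-one assignment (Hungarian) with
distance and area-change gates. Mitotic events require a parent track that
ends, two new tracks starting nearby, loss of repair-channel signal and a rise
of nuclear-channel signal in the parent's final frames — the qualitative
criteria the field uses, with configurable thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment


@dataclass
class LinkingParams:
    max_displacement_um: float = 15.0     # per 15-min frame
    max_area_change: float = 0.5          # fraction of previous area
    r_mitosis_um: float = 20.0
    f_loss: float = 0.5                   # repair signal drop factor
    f_rise: float = 1.3                   # nuclear signal rise factor
    daughter_area_fraction: float = 0.9   # each daughter below this x parent
    mitosis_search_frames: int = 2
    edge_margin_um: float = 10.0


@dataclass
class LinkResult:
    matches: list[tuple[int, int]]
    unmatched_prev: list[int]
    unmatched_next: list[int]
    total_cost: float


def link_frames(
    obs_prev: pd.DataFrame,
    obs_next: pd.DataFrame,
    params: LinkingParams | None = None,
) -> LinkResult:
    """Optimal one-to-one assignment between two frames' nucleus observations.

    Cost per feasible pair = distance / gate + |Δarea| / (area_prev * gate).
    Pairs beyond either gate are forbidden. Returns positional indices into
    the two tables.
    """
    params = params or LinkingParams()
    n, m = len(obs_prev), len(obs_next)
    if n == 0 or m == 0:
        return LinkResult([], list(range(n)), list(range(m)), 0.0)
    p = obs_prev[["x_um", "y_um"]].to_numpy()
    q = obs_next[["x_um", "y_um"]].to_numpy()
    ap = obs_prev["area_um2"].to_numpy()
    aq = obs_next["area_um2"].to_numpy()
    dist = np.hypot(*(p[:, None, :] - q[None, :, :]).transpose(2, 0, 1))
    darea = np.abs(ap[:, None] - aq[None, :]) / np.maximum(ap[:, None], 1e-9)
    feasible = (dist <= params.max_displacement_um) & (darea <= params.max_area_change)
    BIG = 1e6
    cost = np.where(
        feasible,
        dist / params.max_displacement_um + darea / params.max_area_change,
        BIG,
    )
    ri, ci = linear_sum_assignment(cost)
    matches, total = [], 0.0
    matched_prev, matched_next = set(), set()
    for i, j in zip(ri, ci):
        if cost[i, j] < BIG:
            matches.append((int(i), int(j)))
            matched_prev.add(int(i))
            matched_next.add(int(j))
            total += float(cost[i, j])
    return LinkResult(
        matches,
        [i for i in range(n) if i not in matched_prev],
        [j for j in range(m) if j not in matched_next],
        total,
    )


def build_tracks(
    frame_tables: list[pd.DataFrame],
    params: LinkingParams | None = None,
) -> pd.DataFrame:
    """Chain per-frame feature tables into tracks.

    Each table needs columns label, x_um, y_um, area_um2 (plus any intensity
    columns, which are carried through). A lost nucleus terminates its track;
    unmatched observations start new tracks (no gap closing).
    """
    params = params or LinkingParams()
    rows: list[dict] = []
    next_track = 1
    active: dict[int, int] = {}  # positional index in previous frame -> track id
    prev = None
    for f, table in enumerate(frame_tables):
        table = table.reset_index(drop=True)
        assigned: dict[int, int] = {}
        if prev is not None and len(table):
            link = link_frames(prev, table, params)
            for i, j in link.matches:
                if i in active:
                    assigned[j] = active[i]
        for j in range(len(table)):
            if j not in assigned:
                assigned[j] = next_track
                next_track += 1
        for j, tid in assigned.items():
            row = {"frame": f, "track_id": tid}
            row.update(table.iloc[j].to_dict())
            rows.append(row)
        active = assigned
        prev = table
    return pd.DataFrame(rows)


def _track_bounds(tracks: pd.DataFrame) -> pd.DataFrame:
    g = tracks.groupby("track_id")["frame"]
    return pd.DataFrame({"start": g.min(), "end": g.max()})


def detect_mitosis(
    tracks: pd.DataFrame, params: LinkingParams | None = None
) -> pd.DataFrame:
    """Mitotic events: parent track ends, two new tracks appear nearby with
    small areas, repair signal drops and nuclear signal rises at the end of
    the parent track.

    Intensity criteria apply only when the tracks table carries
    mean_repair / mean_nuclear columns.
    """
    params = params or LinkingParams()
    bounds = _track_bounds(tracks)
    last_frame = int(tracks.frame.max())
    has_intensity = {"mean_repair", "mean_nuclear"} <= set(tracks.columns)
    events = []
    by_track = {tid: df.sort_values("frame") for tid, df in tracks.groupby("track_id")}
    for parent, b in bounds.iterrows():
        if b.end >= last_frame:
            continue
        pdf = by_track[parent]
        tail = pdf.iloc[-1]
        if has_intensity:
            med_rep = float(pdf.mean_repair.median())
            med_nuc = float(pdf.mean_nuclear.median())
            final = pdf[pdf.frame >= b.end - 1]
            if not (final.mean_repair.min() < params.f_loss * med_rep):
                continue
            if not (final.mean_nuclear.max() > params.f_rise * med_nuc):
                continue
        daughters = []
        for child, cb in bounds.iterrows():
            if child == parent:
                continue
            if not (b.end < cb.start <= b.end + params.mitosis_search_frames):
                continue
            head = by_track[child].iloc[0]
            d = math.hypot(head.x_um - tail.x_um, head.y_um - tail.y_um)
            if d > params.r_mitosis_um:
                continue
            if head.area_um2 > params.daughter_area_fraction * tail.area_um2:
                continue
            daughters.append((d, child, int(cb.start)))
        if len(daughters) >= 2:
            daughters.sort()
            (d1, c1, s1), (d2, c2, s2) = daughters[:2]
            events.append(
                {"parent": int(parent), "daughter1": int(c1),
                 "daughter2": int(c2), "frame": int(max(s1, s2))}
            )
    return pd.DataFrame(events, columns=["parent", "daughter1", "daughter2", "frame"])


def build_ancestry(
    tracks: pd.DataFrame, events: pd.DataFrame
) -> pd.DataFrame:
    """Ancestry table (cell_id, parent_id, start_frame, split_frame,
    generation); founders have parent 0 and generation 1."""
    bounds = _track_bounds(tracks)
    known = set(bounds.index)
    for col in ("parent", "daughter1", "daughter2"):
        unknown = set(events[col]) - known if len(events) else set()
        if unknown:
            raise ValueError(f"event references unknown track(s): {sorted(unknown)}")
    parent_of = {}
    split_of = {}
    for _, ev in events.iterrows():
        parent_of[ev.daughter1] = int(ev.parent)
        parent_of[ev.daughter2] = int(ev.parent)
        split_of[int(ev.parent)] = int(ev.frame)
    graph = nx.DiGraph()
    graph.add_nodes_from(bounds.index)
    graph.add_edges_from((p, c) for c, p in parent_of.items())
    if len(graph) and not nx.is_forest(graph.to_undirected()):
        raise ValueError("lineage is not a forest")
    rows = []
    for tid, b in bounds.iterrows():
        gen = 1
        node = tid
        while node in parent_of:
            node = parent_of[node]
            gen += 1
        rows.append(
            {
                "cell_id": int(tid),
                "parent_id": int(parent_of.get(tid, 0)),
                "start_frame": int(b.start),
                "split_frame": split_of.get(int(tid), pd.NA),
                "generation": gen,
            }
        )
    return pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)


def detect_death(
    tracks: pd.DataFrame,
    events: pd.DataFrame,
    field_size_um: tuple[float, float],
    params: LinkingParams | None = None,
) -> pd.DataFrame:
    """Death events: a track ending before the movie does, away from every
    border, that is not a mitosis parent."""
    params = params or LinkingParams()
    bounds = _track_bounds(tracks)
    last_frame = int(tracks.frame.max())
    parents = set(events.parent) if len(events) else set()
    w, hgt = field_size_um
    rows = []
    for tid, b in bounds.iterrows():
        if b.end >= last_frame or tid in parents:
            continue
        tail = tracks[(tracks.track_id == tid) & (tracks.frame == b.end)].iloc[0]
        margin = min(tail.x_um, tail.y_um, w - tail.x_um, hgt - tail.y_um)
        if margin > params.edge_margin_um:
            rows.append({"track_id": int(tid), "frame": int(b.end)})
    return pd.DataFrame(rows, columns=["track_id", "frame"])


def classify_giant_nuclei(
    areas_um2: np.ndarray, control_areas_um2: np.ndarray
) -> np.ndarray:
    """Flag nuclei larger than control mean + 2 x sample sd."""
    control = np.asarray(control_areas_um2, dtype=float)
    if control.size < 2:
        raise ValueError("need >= 2 control areas (sample sd undefined)")
    threshold = control.mean() + 2.0 * control.std(ddof=1)
    return np.asarray(areas_um2, dtype=float) > threshold


@dataclass
class PopulationMetrics:
    counts: pd.DataFrame          # time_h, n_nuclei
    mitotic_events: pd.DataFrame  # bin_start_h, n_events
    giant_fraction: pd.DataFrame  # time_h, fraction (empty without controls)
    deaths: pd.DataFrame          # time_h, cumulative_deaths


def population_curves(
    tracks: pd.DataFrame,
    events: pd.DataFrame,
    deaths: pd.DataFrame,
    times_min: np.ndarray,
    bin_hours: float = 2.0,
    control_areas_um2: np.ndarray | None = None,
) -> PopulationMetrics:
    """Per-frame counts, binned mitotic events, giant-nucleus fraction and
    cumulative deaths; times in hours relative to irradiation."""
    times_h = np.asarray(times_min, dtype=float) / 60.0
    counts = (
        tracks.groupby("frame")["track_id"].nunique()
        .reindex(range(len(times_h)), fill_value=0)
    )
    counts_df = pd.DataFrame({"time_h": times_h, "n_nuclei": counts.to_numpy()})

    if len(events):
        ev_h = times_h[events.frame.to_numpy()]
        lo = math.floor(times_h.min() / bin_hours) * bin_hours
        edges = np.arange(lo, times_h.max() + bin_hours, bin_hours)
        hist, _ = np.histogram(ev_h, bins=edges)
        mit_df = pd.DataFrame({"bin_start_h": edges[:-1], "n_events": hist})
    else:
        mit_df = pd.DataFrame(columns=["bin_start_h", "n_events"])

    if control_areas_um2 is not None:
        rows = []
        for f, sub in tracks.groupby("frame"):
            flags = classify_giant_nuclei(sub.area_um2.to_numpy(), control_areas_um2)
            rows.append({"time_h": times_h[int(f)], "fraction": float(flags.mean())})
        giant_df = pd.DataFrame(rows)
    else:
        giant_df = pd.DataFrame(columns=["time_h", "fraction"])

    death_cum = np.zeros(len(times_h))
    if len(deaths):
        for f in deaths.frame:
            death_cum[int(f):] += 1
    deaths_df = pd.DataFrame({"time_h": times_h, "cumulative_deaths": death_cum})
    return PopulationMetrics(counts_df, mit_df, giant_df, deaths_df)


def fit_doubling_time(times_h: np.ndarray, counts: np.ndarray) -> float:
    """Doubling time (h) from a log-linear fit to exponential growth."""
    times_h = np.asarray(times_h, dtype=float)
    counts = np.asarray(counts, dtype=float)
    ok = counts > 0
    slope = np.polyfit(times_h[ok], np.log(counts[ok]), 1)[0]
    if slope <= 0:
        raise ValueError("population is not growing")
    return math.log(2.0) / slope
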