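"""End-to-end orchestration: simulate (or load) a movie, segment, track,
detect and classify foci, estimate conversion rates, map repair domains and
quantify foci motion — all driven by one configuration and one seed.

Outputs are plain CSV/JSON files plus a run manifest listing every stage
output with a checksum, so re-running with the same configuration and seed
reproduces the outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import foci as foci_mod
from . import io as io_mod
from . import kinetics, motion, segmentation, synthetic, tracking

log = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "track", "foci", "classify", "rates",
          "domains", "msd", "report")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    output_dir: str = "riftrack_run"
    seed: int | None = None
    input_movie: str | None = None
    synthetic: dict = field(default_factory=dict)
    irradiation_time_min: float | None = 0.0
    dose_labels_cgy: tuple = ()
    segmentation: dict = field(default_factory=dict)
    tracking: dict = field(default_factory=dict)
    foci: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    domains: dict = field(default_factory=dict)
    msd: dict = field(default_factory=dict)

    def validate(self) -> None:
        has_movie = self.input_movie is not None
        has_synth = bool(self.synthetic) or not has_movie
        if has_movie and self.synthetic:
            raise ConfigError("config must set exactly one of input_movie / synthetic")
        if not has_movie and self.seed is None:
            raise ConfigError("seed is required for synthetic input")
        if self.irradiation_time_min is None:
            raise ConfigError("irradiation_time_min must be set")
        if len(set(self.dose_labels_cgy)) != len(self.dose_labels_cgy):
            raise ConfigError("dose labels must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage '{stage}' failed: {err}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seed": config.seed,
                      "config": dataclasses.asdict(config)}

    def record(stage: str, paths: list[Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "outputs": {p.name: _checksum(p) for p in paths},
            "seconds": round(time.perf_counter() - t0, 3),
        }

    # --- simulate / load ----------------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.input_movie:
            movie = io_mod.read_movie(config.input_movie)
            gt = None
            paths = []
        else:
            syn = synthetic.SyntheticConfig(seed=config.seed, **config.synthetic)
            movie, gt = synthetic.generate_movie(syn)
            mpath = io_mod.write_movie(out / "movie.tif", movie, seed=config.seed)
            gt.lineage.to_csv(out / "gt_lineage.csv", index=False)
            gt.foci.to_csv(out / "gt_foci.csv", index=False)
            gt.domains.to_csv(out / "gt_domains.csv", index=False)
            paths = [mpath, mpath.with_suffix(".json"), out / "gt_lineage.csv",
                     out / "gt_foci.csv", out / "gt_domains.csv"]
    except Exception as err:
        raise StageError("simulate", err) from err
    record("simulate", paths, t0)

    # --- segment ------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        seg_params = segmentation.SegmentationParams(**config.segmentation)
        labels_per_frame, frame_tables = [], []
        for f in range(movie.n_frames):
            labels, feats = segmentation.segment_frame(
                movie.frame(f, synthetic.NUCLEAR_CHANNEL), movie.pixel_size_um,
                seg_params,
            )
            labels_per_frame.append(labels)
            if len(feats):
                nuc = movie.frame(f, synthetic.NUCLEAR_CHANNEL)
                rep = movie.frame(f, synthetic.REPAIR_CHANNEL)
                feats = feats.assign(
                    mean_nuclear=[nuc[labels == l].mean() for l in feats.label],
                    mean_repair=[rep[labels == l].mean() for l in feats.label],
                )
            frame_tables.append(feats)
        nuclei = pd.concat(
            [t.assign(frame=f) for f, t in enumerate(frame_tables) if len(t)],
            ignore_index=True,
        ) if any(len(t) for t in frame_tables) else pd.DataFrame()
        nuclei.to_csv(out / "nuclei.csv", index=False)
    except Exception as err:
        raise StageError("segment", err) from err
    record("segment", [out / "nuclei.csv"], t0)

    # --- track --------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        link_params = tracking.LinkingParams(**config.tracking)
        tracks = tracking.build_tracks(frame_tables, link_params)
        events = tracking.detect_mitosis(tracks, link_params)
        ancestry = tracking.build_ancestry(tracks, events)
        field_um = (movie.pixels.shape[3] * movie.pixel_size_um,
                    movie.pixels.shape[2] * movie.pixel_size_um)
        deaths = tracking.detect_death(tracks, events, field_um, link_params)
        tracks = tracks.merge(
            ancestry[["cell_id", "generation"]].rename(
                columns={"cell_id": "track_id"}), on="track_id", how="left",
        )
        tracks.to_csv(out / "tracking.csv", index=False)
        ancestry.to_csv(out / "ancestry.csv", index=False)
        metrics = tracking.population_curves(
            tracks, events, deaths, movie.times_min
        )
        metrics.counts.to_csv(out / "population_counts.csv", index=False)
        metrics.mitotic_events.to_csv(out / "mitotic_events.csv", index=False)
    except Exception as err:
        raise StageError("track", err) from err
    record("track", [out / "tracking.csv", out / "ancestry.csv",
                     out / "population_counts.csv", out / "mitotic_events.csv"], t0)

    # --- foci ---------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        foci_params = foci_mod.FociParams(**config.foci)
        foci_rows, nuc_rows = [], []
        for f in range(movie.n_frames):
            rep = movie.frame(f, synthetic.REPAIR_CHANNEL)
            labels = labels_per_frame[f]
            det = foci_mod.detect_foci(rep, labels, movie.pixel_size_um, foci_params)
            mask = foci_mod.foci_mask(
                rep.shape, det, labels, movie.pixel_size_um, foci_params, rep
            )
            ni = foci_mod.nuclear_intensities(rep, labels, mask)
            foci_rows.append(det.assign(frame=f, time_min=movie.times_min[f]))
            nuc_rows.append(ni.assign(frame=f, time_min=movie.times_min[f]))
        foci_table = pd.concat(foci_rows, ignore_index=True)
        nuclear_table = pd.concat(nuc_rows, ignore_index=True)
        foci_table.to_csv(out / "foci.csv", index=False)
        nuclear_table.to_csv(out / "nuclear_intensity.csv", index=False)
    except Exception as err:
        raise StageError("foci", err) from err
    record("foci", [out / "foci.csv", out / "nuclear_intensity.csv"], t0)

    # --- classify -----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        if len(foci_table):
            model = kinetics.fit_foci_classes(
                foci_table, random_state=config.seed or 0, **config.classify
            )
            foci_table["class_label"] = kinetics.assign_class(foci_table, model)
            (out / "class_model.json").write_text(json.dumps(model.to_dict(), indent=1))
            foci_table.to_csv(out / "foci.csv", index=False)
        else:
            (out / "class_model.json").write_text(json.dumps({"n_classes": 0}))
    except Exception as err:
        raise StageError("classify", err) from err
    record("classify", [out / "class_model.json", out / "foci.csv"], t0)

    # --- rates --------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        series = kinetics.class_intensity_series(foci_table, nuclear_table)
        series["time_min"] = [movie.times_min[int(f)] for f in series.frame]
        series.to_csv(out / "class_intensity.csv", index=False)
        steps = kinetics.estimate_rate_series(series)
        rate_rows = []
        for s in steps:
            for j in range(len(s.I_prev)):
                for k in range(len(s.I_prev)):
                    if j != k and s.rates[j, k] > 1e-12:
                        rate_rows.append(
                            {"time_min": s.time_min, "dt_min": s.dt_min,
                             "from_class": j, "to_class": k,
                             "rate": s.rates[j, k],
                             "rate_per_min": s.rates[j, k] / s.dt_min,
                             "flow_au": s.flows[j, k],
                             "slack_au": s.slack[k]}
                        )
        pd.DataFrame(
            rate_rows, columns=["time_min", "dt_min", "from_class", "to_class",
                                "rate", "rate_per_min", "flow_au", "slack_au"],
        ).to_csv(out / "rates.csv", index=False)
        if steps:
            flows = kinetics.cumulative_flows(steps)
            for name in ("induction", "resolving", "merging"):
                getattr(flows, name).to_csv(out / f"flows_{name}.csv")
    except Exception as err:
        raise StageError("rates", err) from err
    record("rates", [out / "class_intensity.csv", out / "rates.csv"], t0)

    # --- domains ------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        dom_rows = []
        post_cover = movie.times_min[-1]
        window = tuple(config.domains.get("window_min", (240.0, min(1440.0, post_cover))))
        for tid, track in tracks.groupby("track_id"):
            if len(track) < max(5, movie.n_frames // 2):
                continue
            try:
                reg = motion.crop_and_register(
                    movie, track,
                    crop_size_px=int(config.domains.get("crop_size_px", 80)),
                    estimate_rotation=bool(config.domains.get("estimate_rotation", False)),
                )
            except motion.RegistrationError as err:
                log.info("cell %s dropped from domain analysis: %s", tid, err)
                continue
            try:
                mip = motion.temporal_mip(reg, window_min=window)
                background = (
                    motion.pre_ir_background(reg)
                    if (reg.times_min < 0).any() else None
                )
            except ValueError as err:
                log.info("cell %s dropped from domain analysis: %s", tid, err)
                continue
            nmask = motion._otsu_mask(reg.pixels[0, synthetic.NUCLEAR_CHANNEL])
            summary = motion.segment_domains(
                mip, nmask, movie.pixel_size_um, background=background,
                cell_id=int(tid), dose_gy=movie.dose_gy,
            )
            dom_rows.append(
                {"cell_id": summary.cell_id, "dose_cgy": movie.dose_gy * 100,
                 "n_domains": summary.n_domains,
                 "mean_area_um2": summary.mean_area_um2,
                 "areas": ";".join(f"{a:.3f}" for a in summary.areas_um2)}
            )
        pd.DataFrame(
            dom_rows, columns=["cell_id", "dose_cgy", "n_domains",
                               "mean_area_um2", "areas"],
        ).to_csv(out / "domains.csv", index=False)
    except Exception as err:
        raise StageError("domains", err) from err
    record("domains", [out / "domains.csv"], t0)

    # --- msd ----------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        if gt is not None and len(gt.foci):
            post = gt.foci[gt.foci.time_min >= 0]
            traj = post.rename(columns={"focus_id": "track_id"})[
                ["track_id", "frame", "time_min", "x_um", "y_um"]
            ]
            lengths = traj.groupby("track_id").size()
            traj = traj[traj.track_id.isin(lengths[lengths >= 5].index)]
        else:
            traj = pd.DataFrame(columns=["track_id", "frame", "time_min", "x_um", "y_um"])
        if len(traj):
            msd = motion.compute_msd(traj, reference_frame=int(traj.frame.min()))
            fit = motion.fit_diffusion(msd, n_lags=int(config.msd.get("n_lags", 12)))
            conf = motion.estimate_confinement_area(msd)
            pd.DataFrame(
                {"lag_min": msd.lag_min, "msd_um2": msd.msd_um2, "n": msd.n_tracks}
            ).to_csv(out / "msd.csv", index=False)
            (out / "msd_fit.json").write_text(json.dumps(
                {"D_um2_min": fit.D_um2_min, "slope_um2_min": fit.slope_um2_min,
                 "confined": conf.confined, "confinement_area_um2":
                 None if np.isnan(conf.area_um2) else conf.area_um2}, indent=1))
        else:
            pd.DataFrame(columns=["lag_min", "msd_um2", "n"]).to_csv(
                out / "msd.csv", index=False)
            (out / "msd_fit.json").write_text(json.dumps({"D_um2_min": None}))
    except Exception as err:
        raise StageError("msd", err) from err
    record("msd", [out / "msd.csv", out / "msd_fit.json"], t0)

    # --- report -------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        report_paths = make_report(out)
    except Exception as err:
        raise StageError("report", err) from err
    record("report", report_paths, t0)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def make_report(run_dir: str | Path) -> list[Path]:
    """Summary tables and plots from a completed run's CSV outputs only.

    Missing stage outputs are listed as absent; the report is still produced.
    Regeneration from the same CSVs is idempotent.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    report_dir = run_dir / "report"
    report_dir.mkdir(exist_ok=True)
    summary: dict = {"absent": []}
    paths: list[Path] = []

    def load(name: str) -> pd.DataFrame | None:
        p = run_dir / name
        if not p.exists():
            summary["absent"].append(name)
            return None
        return pd.read_csv(p)

    counts = load("population_counts.csv")
    if counts is not None and len(counts):
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.plot(counts.time_h, counts.n_nuclei)
        ax.set(xlabel="time post-IR (h)", ylabel="nuclei",
               title="population growth")
        fig.tight_layout()
        fig.savefig(report_dir / "population.png", dpi=100)
        plt.close(fig)
        paths.append(report_dir / "population.png")
        summary["final_nuclei"] = int(counts.n_nuclei.iloc[-1])

    ci = load("class_intensity.csv")
    if ci is not None and len(ci):
        fig, ax = plt.subplots(figsize=(5, 3))
        for col in [c for c in ci.columns if c.startswith("I")]:
            ax.plot(ci.time_min / 60.0, ci[col], label=col)
        ax.set(xlabel="time post-IR (h)", ylabel="intensity / nucleus (a.u.)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(report_dir / "class_intensity.png", dpi=100)
        plt.close(fig)
        paths.append(report_dir / "class_intensity.png")

    foci_table = load("foci.csv")
    if foci_table is None or not len(foci_table):
        summary["foci"] = "no data"
    else:
        summary["n_foci"] = int(len(foci_table))

    doms = load("domains.csv")
    if doms is not None and len(doms):
        summary["mean_domain_area_um2"] = float(doms.mean_area_um2.mean())
        summary["mean_n_domains"] = float(doms.n_domains.mean())

    msd = load("msd.csv")
    if msd is not None and len(msd):
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.plot(msd.lag_min, msd.msd_um2, marker="o", ms=2)
        ax.set(xlabel="lag (min)", ylabel="MSD (µm²)")
        fig.tight_layout()
        fig.savefig(report_dir / "msd.png", dpi=100)
        plt.close(fig)
        paths.append(report_dir / "msd.png")

    spath = report_dir / "summary.json"
    spath.write_text(json.dumps(summary, indent=1, sort_keys=True))
    paths.append(spath)
    return paths
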