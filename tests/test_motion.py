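"""Registration, temporal-MIP repair domains and MSD-based motion analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from skimage import draw, transform

import riftrack
from riftrack import motion
from riftrack import synthetic as syn


@pytest.fixture(scope="module")
def nucleus_frame():
    cfg = riftrack.SyntheticConfig(field_size_px=96, n_cells=1, pre_hours=0.5,
                                   post_hours=0.5, seed=9)
    movie, _ = syn.generate_movie(cfg)
    return movie.frame(0, syn.NUCLEAR_CHANNEL)


class TestRegistration:
    def test_known_rotation_recovered_within_one_degree(self, nucleus_frame):
        for angle in (2.5, 5.0, -7.0):
            img = transform.rotate(nucleus_frame, angle, preserve_range=True)
            _, est, _ = motion.register_pair(nucleus_frame, img)
            assert est == pytest.approx(angle, abs=1.0)

    def test_known_translation_recovered_within_half_pixel(self, nucleus_frame):
        img = ndimage.shift(nucleus_frame, (1.2, -2.3), order=1, mode="nearest")
        _, _, (dy, dx) = motion.register_pair(nucleus_frame, img,
                                              estimate_rotation=False)
        assert -dy == pytest.approx(1.2, abs=0.5)
        assert -dx == pytest.approx(-2.3, abs=0.5)

    def test_static_cell_identity_transforms(self):
        cfg = riftrack.SyntheticConfig(
            field_size_px=128, n_cells=1, pre_hours=0.5, post_hours=1.0,
            nucleus_drift_sigma_um=0.0, doubling_time_h=None, seed=13,
        )
        movie, gt = syn.generate_movie(cfg)
        track = gt.cells.rename(columns={"cell_id": "track_id"})
        reg = motion.crop_and_register(movie, track, crop_size_px=80)
        assert np.abs(reg.transforms.rotation_deg).max() < 1.0
        assert np.abs(reg.transforms[["shift_y_px", "shift_x_px"]]).to_numpy().max() < 1.0
        assert reg.transforms.iou.min() >= 0.9

    def test_translating_cell_registered_to_high_overlap(self):
        cfg = riftrack.SyntheticConfig(
            field_size_px=160, n_cells=1, pre_hours=0.5, post_hours=2.0,
            nucleus_drift_sigma_um=1.0, doubling_time_h=None, seed=14,
        )
        movie, gt = syn.generate_movie(cfg)
        track = gt.cells.rename(columns={"cell_id": "track_id"})
        reg = motion.crop_and_register(movie, track, crop_size_px=96)
        assert reg.transforms.iou.min() >= 0.95

    def test_short_track_rejected(self):
        cfg = riftrack.SyntheticConfig(field_size_px=96, n_cells=1,
                                       pre_hours=0.25, post_hours=0.25, seed=9)
        movie, gt = syn.generate_movie(cfg)
        track = gt.cells.rename(columns={"cell_id": "track_id"}).iloc[:1]
        with pytest.raises(motion.RegistrationError):
            motion.crop_and_register(movie, track)


def make_registered(pixels, times):
    return motion.RegisteredCellMovie(pixels, np.asarray(times, float),
                                      math.sqrt(0.1), 0.0, pd.DataFrame())


class TestTemporalMip:
    def test_single_frame_window_returns_frame(self):
        rng = np.random.default_rng(0)
        px = rng.uniform(size=(3, 2, 8, 8))
        reg = make_registered(px, [-15, 300, 600])
        out = motion.temporal_mip(reg, window_min=(250, 350))
        assert np.array_equal(out, px[1, syn.REPAIR_CHANNEL])

    def test_two_frames_elementwise_max(self):
        rng = np.random.default_rng(1)
        px = rng.uniform(size=(2, 2, 6, 6))
        reg = make_registered(px, [240, 255])
        out = motion.temporal_mip(reg, window_min=(240, 255))
        assert np.array_equal(out, px[:, syn.REPAIR_CHANNEL].max(axis=0))

    def test_superset_window_dominates_pixelwise(self):
        rng = np.random.default_rng(2)
        px = rng.uniform(size=(10, 2, 6, 6))
        reg = make_registered(px, np.arange(10) * 15.0 + 240)
        small = motion.temporal_mip(reg, window_min=(240, 300))
        big = motion.temporal_mip(reg, window_min=(240, 375))
        assert np.all(big >= small)

    def test_empty_window_rejected(self):
        reg = make_registered(np.zeros((2, 2, 4, 4)), [0, 15])
        with pytest.raises(ValueError):
            motion.temporal_mip(reg, window_min=(240, 300))


class TestSegmentDomains:
    @staticmethod
    def synthetic_mip(centers, radius_px, shape=(80, 80), level=200.0):
        mip = np.zeros(shape)
        for c in centers:
            rr, cc = draw.disk(c, radius_px, shape=shape)
            mip[rr, cc] = level
        return mip

    def test_nine_discs_recovered(self):
        # 9 discs of radius 1.545 µm (4.886 px at 0.3162 µm/px)
        px_size = math.sqrt(0.1)
        r_px = 1.545 / px_size
        centers = [(15 + 25 * i, 15 + 25 * j) for i in range(3) for j in range(3)]
        mip = self.synthetic_mip(centers, r_px)
        mask = np.ones(mip.shape, dtype=bool)
        out = motion.segment_domains(mip, mask, px_size)
        assert out.n_domains == 9
        assert out.mean_area_um2 == pytest.approx(7.50, rel=0.1)

    def test_uniform_nucleus_no_domains(self):
        mip = np.full((40, 40), 7.0)
        out = motion.segment_domains(mip, np.ones((40, 40), bool), 0.3162)
        assert out.n_domains == 0

    def test_discs_within_closing_distance_merge(self):
        px_size = math.sqrt(0.1)
        mip = self.synthetic_mip([(40, 36), (40, 47)], 5.0)
        out = motion.segment_domains(mip, np.ones(mip.shape, bool), px_size,
                                     closing_radius_px=2)
        assert out.n_domains == 1


class TestDomainDoseSummary:
    @staticmethod
    def summaries(dose_counts):
        out = []
        cid = 0
        for dose, counts in dose_counts.items():
            for n in counts:
                out.append(motion.RepairDomainSummary(
                    cid, dose, int(n), np.full(int(n), 7.5)))
                cid += 1
        return out

    def test_constant_summaries_reported_exactly(self):
        s = self.summaries({0.1: [9, 9], 2.0: [9, 9, 9]})
        df = motion.domain_dose_summary(s, fit_plateau=False)
        assert (df.mean_n_domains == 9).all()
        assert np.allclose(df.mean_area_um2, 7.5)

    def test_saturating_plateau_recovered(self):
        rng = np.random.default_rng(3)
        n_max, d0 = 9.3, 0.25
        dose_counts = {}
        for dose in (0.1, 0.2, 0.5, 1.0, 2.0, 4.0):
            mean = n_max * dose / (dose + d0)
            dose_counts[dose] = rng.poisson(mean, 40)
        df = motion.domain_dose_summary(self.summaries(dose_counts))
        assert df.attrs["plateau_n_domains"] == pytest.approx(n_max, rel=0.10)

    def test_single_dose_skips_fit(self):
        df = motion.domain_dose_summary(self.summaries({1.0: [9, 8]}))
        assert math.isnan(df.attrs["plateau_n_domains"])

    def test_theoretical_domain_size_consistency(self):
        # 6% of a ~150 µm² nucleus is ~9 µm²
        assert motion.predicted_domain_area(150.0, 0.06) == pytest.approx(9.0)


class TestMSD:
    def test_stationary_trajectories_zero(self):
        pos = np.zeros((5, 10, 2))
        msd = motion.compute_msd(motion.trajectories_to_table(pos, np.arange(10) * 5.0))
        assert np.allclose(msd.msd_um2, 0.0)
        assert msd.msd_um2[0] == 0.0

    def test_ballistic_motion_quadratic(self):
        t = np.arange(10) * 5.0
        v = 0.2
        pos = np.zeros((3, 10, 2))
        pos[:, :, 0] = v * t
        msd = motion.compute_msd(motion.trajectories_to_table(pos, t))
        assert np.allclose(msd.msd_um2, (v * msd.lag_min) ** 2)

    def test_free_diffusion_msd_matches_4dt(self):
        cfg = riftrack.SyntheticConfig(diffusion_coefficient_um2_min=0.014, seed=3)
        pos, times = syn.generate_trajectories(cfg, 500, n_frames=13, dt_min=5)
        msd = motion.compute_msd(motion.trajectories_to_table(pos, times))
        sel = msd.lag_min > 0
        expected = 4 * 0.014 * msd.lag_min[sel]
        assert np.abs(msd.msd_um2[sel] / expected - 1).mean() < 0.05

    def test_length_one_trajectories_rejected(self):
        df = pd.DataFrame({"track_id": [1], "frame": [0], "time_min": [0.0],
                           "x_um": [0.0], "y_um": [0.0]})
        with pytest.raises(ValueError):
            motion.compute_msd(df)


class TestFitDiffusion:
    def test_exact_slope_gives_exact_d(self):
        lag = np.arange(13) * 5.0
        msd = motion.MSDCurve(lag, 0.056 * lag, np.full(13, 100))
        fit = motion.fit_diffusion(msd)
        assert fit.D_um2_min == pytest.approx(0.014, abs=1e-12)
        assert fit.slope_um2_min == pytest.approx(0.056, abs=1e-12)

    def test_zero_msd_gives_zero_d(self):
        lag = np.arange(13) * 5.0
        fit = motion.fit_diffusion(motion.MSDCurve(lag, np.zeros(13), np.ones(13)))
        assert fit.D_um2_min == 0.0

    def test_unbiased_over_seeds(self):
        cfg = riftrack.SyntheticConfig(diffusion_coefficient_um2_min=0.01)
        ratios = []
        for seed in range(20):
            pos, times = syn.generate_trajectories(
                cfg, 500, n_frames=13, dt_min=5,
                rng=np.random.default_rng(900 + seed),
            )
            msd = motion.compute_msd(motion.trajectories_to_table(pos, times))
            ratios.append(motion.fit_diffusion(msd).D_um2_min / 0.01)
        assert 0.95 <= np.mean(ratios) <= 1.05


class TestConfinement:
    def test_constant_msd_maps_to_area(self):
        lag = np.arange(1, 20) * 15.0
        msd = motion.MSDCurve(lag, np.full(len(lag), 3.50), np.ones(len(lag)))
        out = motion.estimate_confinement_area(msd)
        assert out.confined
        assert out.area_um2 == pytest.approx(11.0, abs=0.05)

    def test_unconfined_walk_flagged(self):
        cfg = riftrack.SyntheticConfig(diffusion_coefficient_um2_min=0.014, seed=6)
        pos, times = syn.generate_trajectories(cfg, 400, n_frames=60, dt_min=5)
        msd = motion.compute_msd(motion.trajectories_to_table(pos, times))
        out = motion.estimate_confinement_area(msd)
        assert not out.confined
        assert math.isnan(out.area_um2)

    @pytest.mark.parametrize("radius,area", [(1.545, 7.5), (1.871, 11.0)])
    def test_reflected_disc_area_within_10pct(self, radius, area):
        cfg = riftrack.SyntheticConfig(
            diffusion_coefficient_um2_min=0.014, domain_radius_um=radius,
        )
        pos, times = syn.generate_trajectories(
            cfg, 300, confined=True, n_frames=288, dt_min=5,
            rng=np.random.default_rng(7),
        )
        msd = motion.compute_msd(motion.trajectories_to_table(pos, times))
        out = motion.estimate_confinement_area(msd)
        assert out.confined
        assert out.area_um2 == pytest.approx(area, rel=0.10)


class TestReadTrackTable:
    def test_two_point_track(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("track_id,frame,x_um,y_um\n1,0,0.0,0.0\n1,1,1.0,1.0\n")
        df = motion.read_track_table(p)
        assert len(df) == 2 and df.track_id.nunique() == 1

    def test_pixel_units_scaled_by_calibration(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("track_id,frame,x,y\n1,0,10,20\n1,1,12,22\n")
        df = motion.read_track_table(p, pixel_size_um=0.3162)
        assert df.x_um.iloc[0] == pytest.approx(3.162)
        assert df.y_um.iloc[1] == pytest.approx(6.9564)

    def test_duplicate_rows_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("track_id,frame,x_um,y_um\n1,0,0,0\n1,0,1,1\n")
        with pytest.raises(motion.SchemaError, match="duplicated"):
            motion.read_track_table(p)

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("track_id,x_um,y_um\n1,0,0\n")
        with pytest.raises(motion.SchemaError, match="frame"):
            motion.read_track_table(p)


class TestDomainRecoveryOnMovies:
    def test_mip_domains_match_rendered_discs(self):
        """Temporal MIP over diffusing foci recovers the domain discs."""
        rng = np.random.default_rng(61)
        areas, counts, true_counts = [], [], []
        for _ in range(4):
            cfg = riftrack.SyntheticConfig(
                field_size_px=96, n_cells=1, pre_hours=1.0, post_hours=24.0,
                n_domains_per_cell=5, domain_radius_um=1.545,
                diffusion_coefficient_um2_min=0.014, dose_gy=2.0,
                spontaneous_amplitude=0.0, spontaneous_plateau=8.0,
                rif_yield_per_gy=20.0, seed=int(rng.integers(2**31 - 1)),
            )
            movie, gt = syn.generate_registered_cell_movie(cfg)
            reg = make_registered(movie.pixels, movie.times_min)
            mip = motion.temporal_mip(reg, window_min=(240, 1440))
            bg = motion.pre_ir_background(reg)
            nmask = motion._otsu_mask(movie.frame(0, syn.NUCLEAR_CHANNEL))
            out = motion.segment_domains(mip, nmask, movie.pixel_size_um,
                                         background=bg)
            areas.extend(out.areas_um2)
            counts.append(out.n_domains)
            true_counts.append(len(gt.domains))
        assert np.mean(areas) == pytest.approx(7.50, rel=0.15)
        assert abs(np.mean(counts) - np.mean(true_counts)) <= 1.0
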