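"""Decay fits, GMM focus classification and the mass-balance LP estimator."""

import math

import numpy as np
import pandas as pd
import pytest

import riftrack
from riftrack import kinetics as kin
from riftrack import synthetic as syn


class TestControlDecay:
    def test_noiseless_parameters_recovered(self):
        t = np.arange(0, 48, 0.25)
        y = 20 * np.exp(-0.2 * t) + 5
        fit = kin.fit_control_decay(t, y)
        assert fit.amplitude == pytest.approx(20, abs=1e-6)
        assert fit.rate_per_h == pytest.approx(0.2, abs=1e-6)
        assert fit.plateau == pytest.approx(5, abs=1e-6)

    def test_constant_series_degenerate_branch(self):
        fit = kin.fit_control_decay(np.arange(10.0), np.full(10, 7.0))
        assert fit.rate_per_h == 0.0
        assert fit.plateau == pytest.approx(7.0)
        assert math.isinf(fit.half_life_h)

    def test_poisson_noise_median_rate_within_10pct(self):
        rng = np.random.default_rng(8)
        t = np.arange(0, 48, 0.25)
        truth = 20 * np.exp(-0.2 * t) + 5
        rates = []
        for _ in range(100):
            y = rng.poisson(truth)
            rates.append(kin.fit_control_decay(t, y).rate_per_h)
        assert np.median(rates) == pytest.approx(0.2, rel=0.10)


class TestSubtractControl:
    def test_dose_equal_to_control_gives_zero(self):
        t = np.arange(0, 20, 0.5)
        fit = kin.DecayFit(20, 0.2, 5)
        assert np.allclose(kin.subtract_control(t, fit.predict(t), fit), 0.0)

    def test_constant_offset_preserved(self):
        t = np.arange(0, 20, 0.5)
        fit = kin.DecayFit(20, 0.2, 5)
        out = kin.subtract_control(t, fit.predict(t) + 10, fit)
        assert np.allclose(out, 10.0)

    def test_timeline_mismatch_rejected(self):
        fit = kin.DecayFit(1, 0.1, 0)
        with pytest.raises(ValueError):
            kin.subtract_control(np.arange(5.0), np.arange(6.0), fit)

    def test_generator_dome_recovered_after_correction(self):
        cfg = riftrack.SyntheticConfig(
            field_size_px=128, n_cells=1, pre_hours=12.0, post_hours=20.0,
            dose_gy=2.0, seed=3,
        )
        df = syn.generate_count_series(cfg, noise=True)
        t_h = (df.time_min - df.time_min.iloc[0]) / 60.0
        # idealised control fitted over the whole time course
        fit = kin.fit_control_decay(t_h.to_numpy(), df.control.to_numpy())
        corrected = kin.subtract_control(t_h.to_numpy(), df.dosed.to_numpy(), fit)
        dome_true = (df.dosed_true - df.control_true).to_numpy()
        # corrected series tracks the true dome within Poisson noise
        resid = corrected - dome_true
        assert abs(np.mean(resid)) < 2.0
        assert np.max(np.abs(resid)) < 6 * np.sqrt(df.dosed_true.max())


class TestHalfLife:
    @pytest.mark.parametrize("rate,expected", [(0.0990, 7.00), (0.1733, 4.00)])
    def test_noiseless_half_life(self, rate, expected):
        t = np.arange(0, 20, 0.25)
        y = 30 * np.exp(-rate * t)
        assert kin.fit_half_life(t, y) == pytest.approx(expected, abs=0.01)

    def test_poisson_replicate_mean_within_10pct(self):
        rng = np.random.default_rng(12)
        t = np.arange(0, 20, 0.25)
        truth = 40 * np.exp(-0.0990 * t)
        values = [kin.fit_half_life(t, rng.poisson(truth)) for _ in range(100)]
        assert np.mean(values) == pytest.approx(7.0, rel=0.10)

    def test_non_decaying_series_rejected(self):
        t = np.arange(0, 20, 1.0)
        with pytest.raises(kin.FitError):
            kin.fit_half_life(t, np.linspace(1, 10, len(t)))


class TestFociClassSelection:
    def test_default_mixture_selects_four_classes(self, fitted_class_model):
        """The 10x10,000-subsample, max-5 protocol lands on K=4."""
        model = fitted_class_model
        assert model.n_classes == 4
        assert sum(k == 4 for k in model.rep_selections) >= 9

    def test_reproducible_given_seed(self, default_features):
        feats, _ = default_features
        sub = feats.iloc[:20_000]
        m1 = kin.fit_foci_classes(sub, n_reps=2, random_state=3)
        m2 = kin.fit_foci_classes(sub, n_reps=2, random_state=3)
        assert m1.n_classes == m2.n_classes
        assert np.allclose(m1.means, m2.means)

    def test_single_tight_gaussian_one_class(self):
        rng = np.random.default_rng(1)
        X = np.exp(rng.normal([0.0, 4.0], 0.1, (3000, 2)))
        model = kin.fit_foci_classes(X, n_reps=3, random_state=0)
        assert model.n_classes == 1

    def test_two_separated_gaussians_two_classes(self):
        rng = np.random.default_rng(2)
        a = rng.normal([-1.0, 3.0], 0.2, (2000, 2))
        b = rng.normal([2.0, 6.0], 0.2, (2000, 2))
        model = kin.fit_foci_classes(np.exp(np.vstack([a, b])), n_reps=3,
                                     random_state=0)
        assert model.n_classes == 2


class TestAssignClass:
    def test_component_mean_maps_to_its_class(self, fitted_class_model):
        model = fitted_class_model
        X = np.exp(model.means)
        labels = kin.assign_class(X, model)
        assert list(labels) == list(model.order)

    def test_agreement_with_ground_truth(self, default_features, fitted_class_model):
        feats, truth = default_features
        pred = kin.assign_class(feats, fitted_class_model)
        assert (pred == truth).mean() >= 0.9

    def test_class_order_increases_with_size_intensity(self, fitted_class_model):
        model = fitted_class_model
        key = model.means.sum(axis=1)
        by_class = {cls: k for cls, k in zip(model.order, key)}
        ordered = [by_class[c] for c in sorted(by_class)]
        assert all(a < b for a, b in zip(ordered, ordered[1:]))


class TestClassIntensitySeries:
    def test_no_foci_all_background(self):
        nuclear = pd.DataFrame(
            {"frame": [0, 0], "I_nuclear": [100.0, 200.0], "I_foci": [0.0, 0.0]}
        )
        foci = pd.DataFrame(columns=["frame", "total_intensity", "class_label"])
        out = kin.class_intensity_series(foci, nuclear)
        assert out.I0.iloc[0] == pytest.approx(150.0)
        assert all(out[f"I{k}"].iloc[0] == 0 for k in range(1, 5))

    def test_conservation_identity_per_frame(self):
        rng = np.random.default_rng(4)
        nuclear = pd.DataFrame({
            "frame": np.repeat([0, 1], 3),
            "I_nuclear": rng.uniform(100, 200, 6),
        })
        foci_rows = []
        ifoci = np.zeros(6)
        for i in range(6):
            for k in rng.integers(1, 5, size=2):
                amt = rng.uniform(5, 20)
                ifoci[i] += amt
                foci_rows.append({"frame": nuclear.frame[i],
                                  "total_intensity": amt, "class_label": int(k)})
        nuclear["I_foci"] = ifoci
        out = kin.class_intensity_series(pd.DataFrame(foci_rows), nuclear)
        for _, row in out.iterrows():
            total = sum(row[f"I{k}"] for k in range(5))
            nsub = nuclear[nuclear.frame == row.frame]
            assert total == pytest.approx(nsub.I_nuclear.mean())


def minimal_sparse_rates(rng, K=5):
    """Random sparse rate matrix that is the unique minimal-sum solution:
    either a single source class feeding several targets, or several sources
    feeding a single target."""
    rates = np.zeros((K, K))
    if rng.uniform() < 0.5:
        j = rng.integers(K)
        targets = rng.choice([k for k in range(K) if k != j],
                             size=rng.integers(1, 3), replace=False)
        budget = rng.uniform(0.1, 0.8)
        for k in targets:
            rates[j, k] = budget / len(targets)
    else:
        k = rng.integers(K)
        sources = rng.choice([j for j in range(K) if j != k],
                             size=rng.integers(1, 3), replace=False)
        for j in sources:
            rates[j, k] = rng.uniform(0.05, 0.6)
    return rates


class TestConversionRateLP:
    def test_identical_intensities_zero_rates(self):
        step = kin.estimate_conversion_rates([10, 20, 30, 0, 5],
                                             [10, 20, 30, 0, 5], 15)
        assert np.allclose(step.rates, 0) and np.allclose(step.slack, 0)

    def test_toy_example_c12_exact(self):
        step = kin.estimate_conversion_rates([100, 50, 0, 0, 0],
                                             [100, 30, 20, 0, 0], 15)
        assert step.rates[1, 2] == pytest.approx(0.4, abs=1e-9)
        other = step.rates.sum() - step.rates[1, 2]
        assert other == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(step.slack, 0, atol=1e-9)

    def test_unequal_totals_absorbed_by_slack(self):
        step = kin.estimate_conversion_rates([100, 50, 0, 0, 0],
                                             [100, 50, 10, 0, 0], 15)
        assert step.slack.sum() == pytest.approx(10.0, abs=1e-6)
        assert step.rates.sum() == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("trial", range(10))
    def test_forward_inverse_recovery_within_1e6(self, trial):
        rng = np.random.default_rng(200 + trial)
        rates = minimal_sparse_rates(rng)
        I0 = rng.uniform(10, 200, 5)
        series = syn.generate_intensity_series(rates, I0, 1)
        step = kin.estimate_conversion_rates(series[0], series[1], 15)
        assert np.abs(step.rates - rates).max() < 1e-6
        assert np.allclose(step.predicted_curr, series[1], atol=1e-8)

    @pytest.mark.parametrize("trial", range(5))
    def test_arbitrary_rates_reproduce_observations_zero_slack(self, trial):
        # the matrix may be non-unique, but flows must balance exactly
        rng = np.random.default_rng(300 + trial)
        rates = rng.uniform(0, 0.2, (5, 5))
        np.fill_diagonal(rates, 0)
        I0 = rng.uniform(5, 100, 5)
        series = syn.generate_intensity_series(rates, I0, 1)
        step = kin.estimate_conversion_rates(series[0], series[1], 15)
        assert np.allclose(step.slack, 0, atol=1e-6)
        assert np.allclose(step.predicted_curr, series[1], atol=1e-6)
        # minimal-sum objective never exceeds the generating matrix's sum
        assert step.rates.sum() <= rates.sum() + 1e-6

    def test_zero_prev_class_rates_fixed_to_zero(self):
        step = kin.estimate_conversion_rates([100, 0, 50, 0, 0],
                                             [120, 0, 30, 0, 0], 15)
        assert np.allclose(step.rates[1, :], 0)
        assert np.allclose(step.rates[3, :], 0)


class TestCumulativeFlows:
    @staticmethod
    def _steps_from_series(series, times=None):
        df = pd.DataFrame(series, columns=[f"I{k}" for k in range(5)])
        df["time_min"] = times if times is not None else np.arange(len(df)) * 15.0
        return kin.estimate_rate_series(df)

    def test_sham_equal_dose_all_zero(self):
        rng = np.random.default_rng(5)
        rates = minimal_sparse_rates(rng)
        series = syn.generate_intensity_series(rates, rng.uniform(10, 100, 5), 4)
        steps = self._steps_from_series(series)
        flows = kin.cumulative_flows(steps, sham_steps=steps)
        for table in (flows.induction, flows.resolving, flows.merging):
            assert np.allclose(table.to_numpy(), 0.0)

    def test_single_step_flow_arithmetic(self):
        rates = np.zeros((5, 5))
        rates[0, 3] = 0.25
        series = syn.generate_intensity_series(rates, [200, 10, 10, 0, 0], 1)
        steps = self._steps_from_series(series)
        flows = kin.cumulative_flows(steps)
        assert flows.induction["f0_t3"].iloc[0] == pytest.approx(0.25 * 200)

    def test_cumulative_curves_non_decreasing_and_sham_clipped(self):
        rng = np.random.default_rng(6)
        rates = np.zeros((5, 5))
        rates[0, 1], rates[1, 0], rates[1, 4] = 0.1, 0.05, 0.08
        series = syn.generate_intensity_series(rates, rng.uniform(20, 100, 5), 8)
        steps = self._steps_from_series(series)
        sham_rates = np.zeros((5, 5)); sham_rates[0, 1] = 0.02
        sham_series = syn.generate_intensity_series(sham_rates,
                                                    rng.uniform(20, 100, 5), 8)
        sham_steps = self._steps_from_series(sham_series)
        raw = kin.cumulative_flows(steps)
        normed = kin.cumulative_flows(steps, sham_steps=sham_steps)
        for table in (raw.induction, raw.resolving, raw.merging):
            assert (table.diff().fillna(0).to_numpy() >= -1e-9).all()
        for table in (normed.induction, normed.resolving, normed.merging):
            assert (table.to_numpy() >= -1e-12).all()

    def test_merging_only_generator_pattern(self):
        # classes 1 and 2 merge into 4; no induction or resolving
        rates = np.zeros((5, 5))
        rates[1, 4], rates[2, 4] = 0.2, 0.3
        series = syn.generate_intensity_series(rates, [50, 100, 100, 0, 0], 3)
        steps = self._steps_from_series(series)
        flows = kin.cumulative_flows(steps)
        assert np.allclose(flows.induction.to_numpy(), 0, atol=1e-8)
        assert np.allclose(flows.resolving.to_numpy(), 0, atol=1e-8)
        nonzero = {c for c in flows.merging.columns
                   if flows.merging[c].abs().max() > 1e-8}
        assert nonzero == {"f1_t4", "f2_t4"}
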