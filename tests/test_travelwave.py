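import numpy as np
import pytest

from somatotune import synthdata as sd
from somatotune import travelwave as tw
from somatotune.travelwave import (
    ROIMask,
    SinusoidFit,
    TaskDesign,
    TuningMaps,
    TuningProfile,
    build_reference_model,
    combine_runs,
    compute_tuning_profile,
    default_lag_grid,
    define_roi,
    fit_sinusoid,
    fit_sinusoid_map,
    press_metrics,
    tuning_metric,
)


class TestTaskDesign:
    def test_paper_design_timing(self, paper_design):
        assert paper_design.cycle_s == 32.0
        assert paper_design.run_s == 256.0
        assert paper_design.n_volumes == 170

    def test_cue_schedule_eight_repeats_per_digit(self, paper_design):
        sched = paper_design.cue_schedule()
        assert len(sched) == 32
        for digit in (2, 3, 4, 5):
            assert sum(b["digit"] == digit for b in sched) == 8

    def test_backward_reverses_digit_order(self):
        d = TaskDesign(tr=1.5, block_s=8.0, n_cycles=2, direction="backward")
        first_cycle = [b["digit"] for b in d.cue_schedule()[:4]]
        assert first_cycle == [5, 4, 3, 2]

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            TaskDesign(tr=0.0, block_s=8.0, n_cycles=8)
        with pytest.raises(ValueError):
            TaskDesign(tr=1.5, block_s=8.0, n_cycles=8, digits=(2,))

    def test_tr_off_fine_grid_rejected(self):
        with pytest.raises(ValueError, match="fine"):
            TaskDesign(tr=1.23, block_s=8.0, n_cycles=8).n_volumes


class TestReferenceModel:
    def test_boxcar_on_fraction(self, paper_design):
        _, box = tw._cycle_boxcar_fine(paper_design, 0.0)
        assert box.mean() == pytest.approx(0.25)

    def test_unit_variance_zero_mean(self, paper_design):
        m = build_reference_model(paper_design, 4.5)
        assert m.mean() == pytest.approx(0.0, abs=1e-12)
        assert m.std() == pytest.approx(1.0)

    def test_lag_out_of_range(self, paper_design):
        for lag in (-0.1, 32.0, 40.0):
            with pytest.raises(ValueError):
                build_reference_model(paper_design, lag)

    def test_circular_boundary(self, paper_design):
        m0 = build_reference_model(paper_design, 0.0)
        m_eps = build_reference_model(paper_design, 32.0 - 1e-6)
        assert np.allclose(m0, m_eps, atol=1e-3)

    def test_self_correlation_is_one(self, paper_design):
        for lag in (0.0, 7.5, 19.5):
            m = build_reference_model(paper_design, lag)
            assert np.corrcoef(m, m)[0, 1] == pytest.approx(1.0)


class TestTuningProfile:
    def test_plant_and_recover_on_grid(self, paper_design, lag_grid, model_bank):
        # invariant: argmax of the zero-noise profile is the planted lag
        for planted in (0.0, 7.5, 16.5, 30.0):
            ts = build_reference_model(paper_design, planted)
            prof = compute_tuning_profile(ts, paper_design, lag_grid, models=model_bank)
            assert lag_grid[np.argmax(prof.r)] == planted
            assert prof.r.max() == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip(self, paper_design, lag_grid, model_bank):
        ts = -build_reference_model(paper_design, 7.5)
        prof = compute_tuning_profile(ts, paper_design, lag_grid, models=model_bank)
        assert prof.r[lag_grid == 7.5][0] == pytest.approx(-1.0, abs=1e-12)

    def test_white_noise_null(self, paper_design, lag_grid, model_bank):
        # max |profile| r stays below 0.5 in >= 99% of 1000 replicates
        rng = np.random.default_rng(1234)
        below = sum(
            compute_tuning_profile(
                rng.standard_normal(170), paper_design, lag_grid, models=model_bank
            ).r.max() < 0.5
            for _ in range(1000)
        )
        assert below >= 990

    def test_constant_ts_flagged(self, paper_design, lag_grid, model_bank):
        prof = compute_tuning_profile(
            np.ones(170), paper_design, lag_grid, models=model_bank)
        assert not prof.valid
        assert np.all(np.isnan(prof.r))

    def test_wrong_length_rejected(self, paper_design, lag_grid):
        with pytest.raises(ValueError, match="volumes"):
            compute_tuning_profile(np.zeros(100), paper_design, lag_grid)

    def test_profile_invariants(self, paper_design, lag_grid, model_bank):
        rng = np.random.default_rng(0)
        prof = compute_tuning_profile(
            rng.standard_normal(170), paper_design, lag_grid, models=model_bank)
        assert np.all(np.abs(prof.r) <= 1.0)
        assert np.all(np.diff(prof.lags) > 0)


class TestFitSinusoid:
    def test_noiseless_identifiability(self, lag_grid):
        y = 1.0 * np.sin(2 * np.pi / 16.0 * lag_grid - 0.0) + 0.0
        fit = fit_sinusoid(TuningProfile(lags=lag_grid, r=y))
        assert fit.converged
        assert fit.period == pytest.approx(16.0, abs=1e-6)
        assert fit.a == pytest.approx(1.0, abs=1e-6)
        assert abs(fit.phi) < 1e-6
        assert abs(fit.offset) < 1e-6
        assert fit.rss < 1e-12

    def test_noiseless_with_cycle_centering(self, lag_grid):
        y = 0.8 * np.sin(2 * np.pi / 16.0 * lag_grid - 1.1) + 0.2
        fit = fit_sinusoid(TuningProfile(lags=lag_grid, r=y), cycle_s=32.0)
        assert fit.period == pytest.approx(16.0, abs=1e-6)
        assert fit.a == pytest.approx(0.8, abs=1e-6)
        x = np.linspace(0, 31.5, 100)
        assert np.allclose(fit.predict(x),
                           0.8 * np.sin(2 * np.pi / 16.0 * x - 1.1) + 0.2,
                           atol=1e-6)

    def test_constant_profile_degenerate(self, lag_grid):
        fit = fit_sinusoid(TuningProfile(lags=lag_grid, r=np.full(lag_grid.size, 0.3)))
        assert fit.a == pytest.approx(0.0)
        assert not fit.converged

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_sinusoid(TuningProfile(lags=np.arange(5.0), r=np.zeros(5)))

    def test_invalid_profile_not_converged(self, lag_grid):
        fit = fit_sinusoid(TuningProfile(lags=lag_grid,
                                         r=np.full(lag_grid.size, np.nan),
                                         valid=False))
        assert not fit.converged

    def test_fit_beats_coarse_grid(self, lag_grid):
        # optimality: rss never exceeds the best candidate of an
        # independent coarse 4-parameter grid
        rng = np.random.default_rng(7)
        periods = np.linspace(4.0, 64.0, 61)
        phis = np.linspace(-np.pi, np.pi, 16, endpoint=False)
        amps = np.linspace(0.1, 1.2, 12)
        offs = np.linspace(-0.4, 0.4, 9)
        S = np.sin(2 * np.pi / periods[:, None, None] * lag_grid[None, None, :]
                   - phis[None, :, None])
        for _ in range(5):
            y = (rng.uniform(0.3, 1.0)
                 * np.sin(2 * np.pi / rng.uniform(10, 50) * lag_grid
                          - rng.uniform(-np.pi, np.pi))
                 + rng.uniform(-0.2, 0.2)
                 + 0.08 * rng.standard_normal(lag_grid.size))
            fit = fit_sinusoid(TuningProfile(lags=lag_grid, r=y))
            best = min(
                float((((a * S + B) - y) ** 2).sum(axis=2).min())
                for a in amps for B in offs
            )
            assert fit.rss <= best + 1e-9


class TestCombineRuns:
    @staticmethod
    def _maps(amp, per, conv=None):
        amp = np.asarray(amp, float)
        conv = np.ones(amp.shape, bool) if conv is None else conv
        return TuningMaps(amplitude=amp, period=np.asarray(per, float),
                          phase=np.zeros(amp.shape), converged=conv)

    def test_idempotent_on_identical_maps(self):
        m = self._maps([[0.5, 0.7]], [[30.0, 33.0]])
        out = combine_runs(m, m)
        assert np.allclose(out.amplitude, m.amplitude)
        assert np.allclose(out.period, m.period)

    def test_mean_amplitude(self):
        out = combine_runs(self._maps([0.4], [30.0]), self._maps([0.6], [34.0]))
        assert out.amplitude[0] == pytest.approx(0.5)
        assert out.period[0] == pytest.approx(32.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            combine_runs(self._maps([0.4], [30.0]), self._maps([[0.4]], [[30.0]]))

    def test_non_converged_voxels_dropped(self):
        a = self._maps([0.4, 0.5], [30.0, 31.0], conv=np.array([True, False]))
        b = self._maps([0.6, 0.5], [34.0, 31.0], conv=np.array([True, True]))
        out = combine_runs(a, b)
        assert out.converged.tolist() == [True, False]
        assert np.isnan(out.period[1])

    def test_direction_average_reduces_period_error(self, paper_design, lag_grid):
        # combined period map beats either single run against noiseless truth
        def period_map(data, direction):
            des = TaskDesign(tr=1.5, block_s=8.0, n_cycles=8, direction=direction)
            bank = np.stack([build_reference_model(des, l) for l in lag_grid])
            flat = data.reshape(-1, 170)
            r = np.stack([compute_tuning_profile(v, des, lag_grid, models=bank).r
                          for v in flat])
            return fit_sinusoid_map(r.reshape(*data.shape[:-1], lag_grid.size),
                                    lag_grid, cycle_s=32.0)

        err_single, err_comb = [], []
        for seed in range(25):
            grid = sd.SimGrid.uniform((2, 2, 1), tuning_width=1.0,
                                      noise_sd=0.3, seed=seed)
            truth_grid = sd.SimGrid.uniform((2, 2, 1), tuning_width=1.0,
                                            noise_sd=0.0, seed=seed)
            fwd, _ = sd.simulate_fmri_run(grid, paper_design, "forward",
                                          seed=1000 + seed)
            bwd, _ = sd.simulate_fmri_run(grid, paper_design, "backward",
                                          seed=2000 + seed)
            clean, _ = sd.simulate_fmri_run(truth_grid, paper_design, "forward", seed=0)
            truth = period_map(clean, "forward").period
            mf, mb = period_map(fwd, "forward"), period_map(bwd, "backward")
            comb = combine_runs(mf, mb)
            err_single.append(np.nanmean((mf.period - truth) ** 2))
            err_comb.append(np.nanmean((comb.period - truth) ** 2))
        assert np.sqrt(np.mean(err_comb)) < np.sqrt(np.mean(err_single))


class TestDefineROI:
    def test_planted_strong_voxel_survives(self):
        amp = np.zeros((4, 4))
        amp[2, 2] = 0.99
        roi = define_roi(amp + 1e-6, n_timepoints=170, alpha=0.01)
        assert roi.mask[2, 2]
        assert roi.n_voxels == 1

    def test_default_alpha_is_one_percent(self):
        roi = define_roi(np.zeros((2, 2)) + 1e-6, n_timepoints=170)
        assert roi.alpha == 0.01

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            define_roi(np.zeros(4), n_timepoints=3)
        with pytest.raises(ValueError):
            define_roi(np.zeros(4), n_timepoints=170, alpha=1.5)

    def test_nan_voxels_never_selected(self):
        amp = np.array([np.nan, 0.99, np.nan])
        roi = define_roi(amp, n_timepoints=170, alpha=0.01)
        assert roi.mask.tolist() == [False, True, False]


class TestTuningMetric:
    def test_uniform_period(self):
        roi = ROIMask(mask=np.ones(5, bool), alpha=0.01)
        assert tuning_metric(np.full(5, 16.0), roi) == pytest.approx(0.0625)

    def test_single_voxel_roi(self):
        mask = np.zeros(4, bool)
        mask[1] = True
        metric = tuning_metric(np.array([10.0, 25.0, 40.0, 50.0]),
                               ROIMask(mask=mask, alpha=0.01))
        assert metric == pytest.approx(1.0 / 25.0)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            tuning_metric(np.full(4, 30.0), ROIMask(mask=np.zeros(4, bool), alpha=0.01))

    def test_aggregation_variants(self):
        roi = ROIMask(mask=np.ones(2, bool), alpha=0.01)
        periods = np.array([20.0, 40.0])
        assert tuning_metric(periods, roi) == pytest.approx(1.0 / 30.0)
        assert tuning_metric(periods, roi, aggregation="mean_of_inverse") == \
            pytest.approx(0.5 * (1 / 20 + 1 / 40))

    def test_invariance_to_ordering_and_padding(self):
        rng = np.random.default_rng(3)
        periods = rng.uniform(25, 40, 10)
        roi = ROIMask(mask=np.ones(10, bool), alpha=0.01)
        base = tuning_metric(periods, roi)
        perm = rng.permutation(10)
        assert tuning_metric(periods[perm], roi) == pytest.approx(base)
        padded = np.concatenate([periods, np.zeros(5)])
        roi_pad = ROIMask(mask=np.concatenate([np.ones(10, bool), np.zeros(5, bool)]),
                          alpha=0.01)
        assert tuning_metric(padded, roi_pad) == pytest.approx(base)


class TestPressMetrics:
    def test_perfect_presses(self):
        cues = np.arange(0.0, 20.0, 1.0)
        res = press_metrics(cues, cues)
        assert res.accuracy == 1.0
        assert res.rate_hz == pytest.approx(1.0)

    def test_press_401ms_late_is_inaccurate(self):
        res = press_metrics([0.401], [0.0])
        assert res.accuracy == 0.0

    def test_press_400ms_counts(self):
        res = press_metrics([0.400], [0.0])
        assert res.accuracy == 1.0

    def test_outlier_interval_excluded(self):
        # 20 intervals, one 10x the rest: the +/-2 SD rule drops exactly it
        presses = np.concatenate([np.arange(0.0, 20.0, 1.0), [29.0]])
        res = press_metrics(presses, [0.0])
        assert res.n_intervals_excluded == 1
        assert res.n_intervals_used == 19
        assert res.mean_interval_s == pytest.approx(1.0)

    def test_no_presses_flagged(self):
        res = press_metrics([], [0.0, 1.0])
        assert not res.valid
        assert res.accuracy == 0.0
        assert np.isnan(res.rate_hz)
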