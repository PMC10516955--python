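"""End-to-end estimation: fitting, confidence intervals, forecasting,
fit reports and contour grids."""

import numpy as np
import pytest

import snapgmm as sg
from snapgmm.moments import MomentLevel

from conftest import make_self_consistent


@pytest.fixture(scope="module")
def linear6_fit():
    """A moderate-budget fit on a generated linear6 dataset (shared across
    tests; the exact-propagation objective makes this cheap)."""
    net = sg.fixture_network("linear6")
    sd = sg.generate(sg.fixture_spec("linear6", seed=21,
                                     n_per_snapshot=[2000, 2000]))
    model = sg.SnapshotGMM(net, sd.dataset)
    res = model.fit(n_particles=200, n_steps=60, n_replicates=5, seed=17)
    return net, sd, model, res


class TestEstimate:
    def test_linear6_recovery_within_10pct(self, linear6_fit):
        net, sd, model, res = linear6_fit
        rel = np.abs(res.point_estimate - sd.truth_theta) / sd.truth_theta
        assert rel.max() < 0.10

    def test_ci_contains_point_estimate(self, linear6_fit):
        _, _, _, res = linear6_fit
        assert (res.ci_low <= res.point_estimate).all()
        assert (res.point_estimate <= res.ci_high).all()

    def test_best_cost_is_min_over_replicates(self, linear6_fit):
        _, _, model, res = linear6_fit
        assert res.best_cost == res.replicate_costs.min()
        assert res.best_cost == pytest.approx(model.cost(res.point_estimate),
                                              rel=1e-9)

    def test_best_cost_not_worse_than_truth(self, linear6_fit):
        net, sd, model, res = linear6_fit
        assert res.best_cost <= model.cost(net.free_values()) * (1 + 1e-9)

    def test_msn2_fixed_parameters_never_move(self, msn2):
        sd = sg.generate(sg.fixture_spec("msn2", seed=22,
                                         n_per_snapshot=[300, 300, 300]))
        model = sg.SnapshotGMM(msn2, sd.dataset, level=MomentLevel.MEANS_VARS)
        res = model.fit(n_particles=30, n_steps=10, n_replicates=2, seed=1)
        assert res.replicate_estimates.shape == (2, 4)
        assert res.free_names == ["kon", "koff", "ktr", "kdm"]
        theta = res.theta_full
        assert theta[msn2.parameter_index("pb")] == msn2.parameter("pb").value
        assert theta[msn2.parameter_index("pd")] == msn2.parameter("pd").value

    def test_single_replicate_has_no_ci(self, linear6):
        sd = sg.generate(sg.fixture_spec("linear6", seed=23,
                                         n_per_snapshot=[200, 200]))
        model = sg.SnapshotGMM(linear6, sd.dataset)
        res = model.fit(n_particles=20, n_steps=5, n_replicates=1, seed=0)
        assert res.ci_low is None
        with pytest.raises(ValueError, match="replicates"):
            res.conf_int()

    def test_column_mismatch_rejected(self, linear6):
        ds = sg.SnapshotDataset(x0=np.ones((5, 2)),
                                observations=[(1.0, np.ones((5, 2)))])
        with pytest.raises(ValueError, match="columns"):
            sg.SnapshotGMM(linear6, ds)


def test_ci_coverage_over_many_datasets():
    """Nominal 95% replicate-percentile intervals cover the generating
    rate for at least 80% of (dataset, parameter) pairs across 20
    independent 1000-cell linear6 datasets (10 replicates each)."""
    base = 2025
    covered, total = 0, 0
    for d in range(20):
        sd = sg.generate(sg.fixture_spec("linear6", seed=base + d,
                                         n_per_snapshot=[1000, 1000]))
        model = sg.SnapshotGMM(sg.fixture_network("linear6"), sd.dataset)
        res = model.fit(n_particles=100, n_steps=40, n_replicates=10,
                        seed=base + 1000 + d)
        hits = (res.ci_low <= sd.truth_theta) & (sd.truth_theta <= res.ci_high)
        covered += int(hits.sum())
        total += hits.size
    assert covered / total >= 0.80


class TestConfidenceIntervals:
    def test_identical_replicates_collapse(self):
        reps = np.full((8, 3), 2.5)
        lo, hi = sg.confidence_intervals(reps)
        np.testing.assert_array_equal(lo, [2.5] * 3)
        np.testing.assert_array_equal(hi, [2.5] * 3)

    def test_percentiles_match_sort_oracle(self):
        vals = np.arange(1.0, 101.0)
        rng = np.random.default_rng(0)
        rng.shuffle(vals)
        lo, hi = sg.confidence_intervals(vals[:, None], alpha=0.05)
        # sort-and-interpolate oracle: percentile q sits at index
        # q*(n-1) of the sorted sample
        srt = np.sort(vals)

        def oracle(q):
            pos = q * (len(srt) - 1)
            i = int(np.floor(pos))
            frac = pos - i
            return srt[i] * (1 - frac) + srt[min(i + 1, len(srt) - 1)] * frac

        assert lo[0] == pytest.approx(oracle(0.025))
        assert hi[0] == pytest.approx(oracle(0.975))

    @pytest.mark.parametrize("alpha", [0.0, 1.0, 1.5, -0.1])
    def test_invalid_alpha_rejected(self, alpha):
        with pytest.raises(ValueError, match="alpha"):
            sg.confidence_intervals(np.ones((3, 1)), alpha=alpha)

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(ValueError):
            sg.confidence_intervals(np.ones((1, 2)))


class TestForecast:
    def test_t0_returns_initial_moments(self, linear6, linear6_cells):
        out = sg.forecast(linear6, linear6.theta_file(), linear6_cells, [0.0])
        expected = sg.compute_moments(linear6_cells, MomentLevel.FULL,
                                      linear6.species)
        np.testing.assert_array_equal(out[0][1].values, expected.values)

    def test_means_match_expm_oracle(self, linear6, linear6_cells):
        from scipy.linalg import expm

        theta = 1.4 * linear6.theta_file()
        t = 2.5
        out = sg.forecast(linear6, theta, linear6_cells, [t],
                          level=MomentLevel.MEANS, method="rk45")
        A, _ = linear6.affine_dynamics(theta)
        expected = expm(A * t) @ linear6_cells.mean(axis=0)
        np.testing.assert_allclose(out[0][1].values, expected, rtol=1e-5)

    def test_forecast_at_fit_time_reproduces_predicted_moments(self, linear6_fit):
        _, _, model, res = linear6_fit
        t = model.dataset.times[0]
        fc = res.forecast([t])
        np.testing.assert_array_equal(fc[0][1].values,
                                      res.predicted_moments[0][1].values)

    def test_vav1_far_forecast_conserves_mass(self, vav1):
        sd = sg.generate(sg.fixture_spec("vav1", seed=24,
                                         n_per_snapshot=[100, 100, 100]))
        last_t = sd.dataset.times[-1]
        out = sg.forecast(vav1, sd.truth_theta, sd.dataset.x0, [5 * last_t])
        mv = out[0][1]
        assert np.isfinite(mv.values).all()
        total = sum(
            mv.values[mv.labels.index(f"mean:{s}")]
            for s in ("Vav1", "pVav1", "SykVav1", "SHP1pVav1")
        )
        x0_total = sum(
            sd.dataset.x0[:, vav1.species_index(s)].mean()
            for s in ("Vav1", "pVav1", "SykVav1", "SHP1pVav1")
        )
        assert total == pytest.approx(x0_total, rel=1e-5)


class TestFitReport:
    def test_perfect_fit_slopes_are_one(self, linear6, linear6_cells):
        ds = make_self_consistent(linear6, linear6_cells, [1.5])
        model = sg.SnapshotGMM(linear6, ds)
        # a "fit" whose point estimate is the truth itself
        res = model.fit(n_particles=1, n_steps=0, n_replicates=1, seed=0,
                        bounds=[(v * (1 - 1e-12), v * (1 + 1e-12))
                                for v in linear6.free_values()])
        rep = res.fit_report()
        np.testing.assert_allclose(rep["observed"], rep["predicted"], rtol=1e-6)
        slopes = res.fit_slopes()
        np.testing.assert_allclose(slopes.to_numpy(), 1.0, rtol=1e-6)

    def test_row_count(self, linear6_fit):
        _, _, model, res = linear6_fit
        rep = res.fit_report()
        expected = sg.moment_length(6, MomentLevel.FULL) * len(model.dataset.times)
        assert len(rep) == expected

    def test_moment_prediction_quality(self, linear6_fit):
        """Moment fits should be tight even where individual rates are
        less certain: per-class slopes near unity."""
        _, _, _, res = linear6_fit
        slopes = res.fit_slopes()
        assert ((slopes > 0.9) & (slopes < 1.1)).all()

    def test_summary_mentions_fixed_parameters(self, msn2):
        sd = sg.generate(sg.fixture_spec("msn2", seed=25,
                                         n_per_snapshot=[100, 100, 100]))
        model = sg.SnapshotGMM(msn2, sd.dataset, level=MomentLevel.MEANS)
        res = model.fit(n_particles=10, n_steps=3, n_replicates=2, seed=0)
        text = res.summary()
        assert "(fixed)" in text and "pb" in text and "pd" in text

    def test_plot_fit_writes_file(self, linear6_fit, tmp_path):
        _, _, _, res = linear6_fit
        out = tmp_path / "fit.png"
        res.plot_fit(out)
        assert out.stat().st_size > 0


class TestContour:
    def test_single_cell_grid(self, linear6, linear6_selfconsistent):
        model = sg.SnapshotGMM(linear6, linear6_selfconsistent)
        g = model.cost_contour("k1", "k2", (0.5, 2.0), (0.1, 0.9), n_grid=1)
        assert g.log_cost.shape == (1, 1)
        theta = linear6.theta_file()
        theta[0], theta[1] = 0.5, 0.1
        np.testing.assert_allclose(
            g.log_cost[0, 0],
            np.log10(max(model.cost_at_full_theta(theta), 1e-300)),
        )

    def test_argmin_cell_contains_truth_for_selfconsistent_data(
        self, linear6, linear6_selfconsistent
    ):
        model = sg.SnapshotGMM(linear6, linear6_selfconsistent)
        v1 = linear6.parameter("k1").value
        v2 = linear6.parameter("k2").value
        g = model.cost_contour("k1", "k2", (v1 / 10, v1 * 10),
                               (v2 / 10, v2 * 10), n_grid=11)
        iy, ix = g.argmin_cell()
        # 11 log-spaced points over +-1 decade put the truth at index 5
        assert (iy, ix) == (5, 5)

    def test_same_parameter_rejected(self, linear6, linear6_selfconsistent):
        model = sg.SnapshotGMM(linear6, linear6_selfconsistent)
        with pytest.raises(ValueError, match="differ"):
            model.cost_contour("k1", "k1", (0.1, 1), (0.1, 1))

    def test_frame_has_grid_squared_rows(self, linear6, linear6_selfconsistent):
        model = sg.SnapshotGMM(linear6, linear6_selfconsistent)
        g = model.cost_contour("k1", "k2", (0.1, 1.0), (0.1, 1.0), n_grid=5)
        assert len(g.to_frame()) == 25
        assert np.isfinite(g.log_cost).all()
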