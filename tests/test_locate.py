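"""Multilateration solvers, residual metric and estimate selection."""

import numpy as np
import pytest
from scipy import stats

from rumbleloc.geometry import StationGeometry
from rumbleloc.locate import (
    JointTdoaLocationModel,
    LocationEstimate,
    SolverConfig,
    TdoaLocationModel,
    best_estimate,
    compute_residual,
    localize_deterministic,
    predict_tdoas,
)
from rumbleloc.synth import simulate_tdoa_set
from rumbleloc.tdoa import TdoaSet


def tdoa_set_from(lags_by_station, reference="ETA", modality="seismic"):
    pairs = [(sid, lag, 1.0) for sid, lag in lags_by_station.items()]
    return TdoaSet(reference_station=reference, pairs=pairs, modality=modality,
                   event_id="t")


class TestPredictTdoas:
    def test_equidistant_source_has_zero_lag(self):
        sts = [StationGeometry("A", -50, 0), StationGeometry("B", 50, 0)]
        lags = predict_tdoas([0.0, 123.0], sts, "A", v=400.0)
        assert lags[0] == pytest.approx(0.0, abs=1e-12)

    def test_source_at_station_closed_form(self):
        sts = [StationGeometry("A", 0, 0), StationGeometry("B", 100, 0)]
        # source at B: travels 100 m further to A; lag_B = (0 - 100)/400
        lags = predict_tdoas([100.0, 0.0], sts, "A", v=400.0)
        assert lags[0] == pytest.approx(-0.25)

    @pytest.mark.parametrize("v, expected_ms", [(350.0, 2.86), (400.0, 2.50)])
    def test_interaural_geometry(self, v, expected_ms):
        """Two receivers 1 m apart, end-on source: published delay values."""
        sts = [StationGeometry("L", 0.0, 0.0), StationGeometry("R", 1.0, 0.0)]
        lags = predict_tdoas([-10.0, 0.0], sts, "L", v=v)
        assert abs(lags[0]) * 1e3 == pytest.approx(expected_ms, abs=0.005)

    def test_invalid_inputs(self):
        sts = [StationGeometry("A", 0, 0), StationGeometry("B", 1, 0)]
        with pytest.raises(ValueError):
            predict_tdoas([0, 0], sts, "A", v=-1.0)
        with pytest.raises(ValueError):
            predict_tdoas([0, 0], sts, "Z", v=400.0)


class TestComputeResidual:
    def test_perfect_fit_is_zero(self, stations):
        src = np.array([30.0, -20.0])
        ts = simulate_tdoa_set(stations, src, 400.0, 0.0, rng=0)
        assert compute_residual(src, 400.0, ts, stations) == pytest.approx(0.0, abs=1e-9)

    def test_single_pair_offset_arithmetic(self, stations):
        src = np.array([30.0, -20.0])
        ts = simulate_tdoa_set(stations, src, 400.0, 0.0, rng=0)
        pairs = list(ts.pairs)
        pairs[0] = (pairs[0][0], pairs[0][1] + 0.01, 1.0)
        bumped = TdoaSet(ts.reference_station, pairs, ts.modality, ts.event_id)
        # one of three lags off by 0.01 s at v = 400: (0.01 * 400) / 3
        assert compute_residual(src, 400.0, bumped, stations) == pytest.approx(
            4.0 / 3.0, abs=1e-6)


class TestDeterministic:
    def test_noiseless_inversion_recovers_truth(self, stations):
        src = np.array([-40.0, 55.0])
        ts = simulate_tdoa_set(stations, src, 400.0, 0.0, rng=1)
        estimates = localize_deterministic(ts, stations)
        by_v = {e.v: e for e in estimates}
        at_truth = by_v[400.0]
        assert np.linalg.norm(at_truth.x - src) < 0.5
        assert at_truth.residual < 0.01

    def test_zero_lags_square_array_centroid(self, square_stations):
        ts = tdoa_set_from({"B": 0.0, "C": 0.0, "D": 0.0}, reference="A")
        cfg = SolverConfig(wavespeed_grid={"seismic": [400.0], "acoustic": [350.0]})
        est = TdoaLocationModel(ts, square_stations, cfg).fit().best
        assert np.linalg.norm(est.x - [0.0, 0.0]) < 1e-3

    def test_grid_order_preserved(self, stations):
        ts = simulate_tdoa_set(stations, (10.0, 10.0), 400.0, 0.0, rng=2)
        ests = localize_deterministic(ts, stations)
        grid = SolverConfig().wavespeed_grid["seismic"]
        np.testing.assert_allclose([e.v for e in ests], grid)

    def test_perturbed_lags_bounded_by_residual_estimate(self, stations, rng):
        """One-bin lag perturbations: position shift <= 10x the residual.

        Checked at the true wavespeed's grid point: the bound concerns the
        sensitivity of the position fix itself, which a wavespeed search
        would confound (position trades off against wavespeed along a ridge).
        """
        src = np.array([20.0, -45.0])
        clean = simulate_tdoa_set(stations, src, 400.0, 0.0, rng=3)
        cfg = SolverConfig(wavespeed_grid={"seismic": [400.0], "acoustic": [350.0]})
        x_clean = TdoaLocationModel(clean, stations, cfg).fit().best.x
        for trial in range(5):
            delta = rng.choice([-0.05, 0.05], size=3)
            pairs = [(sid, lag + d, 1.0) for (sid, lag, _), d in zip(clean.pairs, delta)]
            noisy = TdoaSet(clean.reference_station, pairs, "seismic", "t")
            best = TdoaLocationModel(noisy, stations, cfg).fit().best
            assert best.residual > 0
            shift = np.linalg.norm(best.x - x_clean)
            assert shift <= 10.0 * best.residual

    def test_fewer_than_three_pairs_rejected(self, stations):
        ts = tdoa_set_from({"NTA": 0.1, "STA": 0.2})
        with pytest.raises(ValueError, match="3 station pairs"):
            TdoaLocationModel(ts, stations)

    def test_equivariance_under_rigid_motion(self, stations):
        """Rotating + translating stations and source moves the estimate identically."""
        src = np.array([33.0, -12.0])
        ts = simulate_tdoa_set(stations, src, 400.0, 0.0, rng=4)
        base = TdoaLocationModel(ts, stations).fit().best
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([500.0, -250.0])
        moved = [StationGeometry(s.station_id, *(R @ s.position + shift), s.modality)
                 for s in stations]
        moved_ts = simulate_tdoa_set(moved, R @ src + shift, 400.0, 0.0, rng=4)
        est = TdoaLocationModel(moved_ts, moved).fit().best
        np.testing.assert_allclose(est.x, R @ base.x + shift, atol=1e-3)
        assert est.v == base.v

    def test_scale_coupling_of_lags_and_wavespeed(self, stations):
        """Doubling all lags halves the best-fit wavespeed (v * lag geometry)."""
        src = np.array([-25.0, 40.0])
        ts = simulate_tdoa_set(stations, src, 400.0, 0.0, rng=5)
        scaled = TdoaSet(ts.reference_station,
                         [(sid, 2.0 * lag, 1.0) for sid, lag, _ in ts.pairs],
                         "seismic", "t")
        best = TdoaLocationModel(scaled, stations).fit().best
        assert best.v == pytest.approx(200.0, rel=0.07)
        assert np.linalg.norm(best.x - src) < 2.0


class TestProbabilistic:
    def test_posterior_concentrates_as_sigma_vanishes(self, stations):
        src = np.array([40.0, -30.0])
        ts = simulate_tdoa_set(stations, src, 400.0, 0.0, rng=0)
        cfg = SolverConfig(tdoa_sigma=1e-5, rng_seed=2)
        res = TdoaLocationModel(ts, stations, cfg).fit_probabilistic()
        assert np.linalg.norm(res.posterior_mean[:2] - src) < 1.0
        assert np.all(res.posterior_sd[:2] < 1.0)

    def test_flat_likelihood_returns_prior(self, stations):
        ts = simulate_tdoa_set(stations, (10.0, 5.0), 400.0, 0.0, rng=1)
        cfg = SolverConfig(tdoa_sigma=1e3, rng_seed=3)
        res = TdoaLocationModel(ts, stations, cfg).fit_probabilistic()
        pos = res.samples.samples
        xmin, xmax, ymin, ymax = cfg.prior_box(stations)
        ks_x = stats.kstest(pos[:, 0], stats.uniform(xmin, xmax - xmin).cdf).statistic
        ks_y = stats.kstest(pos[:, 1], stats.uniform(ymin, ymax - ymin).cdf).statistic
        assert ks_x < 0.1 and ks_y < 0.1

    def test_map_agrees_with_deterministic_best(self, stations):
        src = np.array([40.0, -30.0])
        ts = simulate_tdoa_set(stations, src, 400.0, 0.0, rng=0)
        cfg = SolverConfig(rng_seed=4)
        model = TdoaLocationModel(ts, stations, cfg)
        det_best = model.fit().best
        map_est = model.fit_probabilistic().map_estimate
        assert np.linalg.norm(det_best.x - map_est.x) < 2.0

    def test_posterior_best_close_to_grid_best(self, stations):
        src = np.array([-10.0, 60.0])
        ts = simulate_tdoa_set(stations, src, 400.0, 0.0, rng=6)
        cfg = SolverConfig(rng_seed=5)
        model = TdoaLocationModel(ts, stations, cfg)
        det_best = model.fit().best
        prob_best = model.fit_probabilistic().best
        assert prob_best.residual < det_best.residual + 0.5

    def test_posterior_scatter_export(self, stations, tmp_path):
        ts = simulate_tdoa_set(stations, (15.0, 25.0), 400.0, 0.0, rng=7)
        res = TdoaLocationModel(ts, stations, SolverConfig(rng_seed=9)) \
            .fit_probabilistic()
        out = tmp_path / "posterior.png"
        res.plot(out)
        assert out.exists() and out.stat().st_size > 0

    def test_reproducible_given_seed(self, stations):
        ts = simulate_tdoa_set(stations, (15.0, 25.0), 400.0, 0.0, rng=7)
        cfg = SolverConfig(rng_seed=11)
        a = TdoaLocationModel(ts, stations, cfg).fit_probabilistic()
        b = TdoaLocationModel(ts, stations, cfg).fit_probabilistic()
        np.testing.assert_array_equal(a.samples.samples, b.samples.samples)

    def test_empty_prior_support_rejected(self, stations):
        ts = simulate_tdoa_set(stations, (15.0, 25.0), 400.0, 0.0, rng=7)
        # a box a thousand kilometres away with an absurdly tight likelihood:
        # every drawn density overflows to -inf
        cfg = SolverConfig(position_prior=(1e6, 1e6 + 1.0, 1e6, 1e6 + 1.0),
                           wavespeed_prior={"seismic": (1.0, 1.5),
                                            "acoustic": (1.0, 1.5)},
                           tdoa_sigma=1e-300, rng_seed=0)
        with np.errstate(over="ignore"):
            with pytest.raises(ValueError, match="prior box excludes"):
                TdoaLocationModel(ts, stations, cfg).fit_probabilistic()


class TestJoint:
    def test_consistent_modalities_recover_truth(self, stations):
        src = np.array([12.0, 34.0])
        ts = simulate_tdoa_set(stations, src, 400.0, 0.0, rng=0, modality="seismic")
        ta = simulate_tdoa_set(stations, src, 350.0, 0.0, rng=0, modality="acoustic")
        cfg = SolverConfig(tdoa_sigma=1e-4, rng_seed=6)
        res = JointTdoaLocationModel(ts, ta, stations, cfg).fit()
        assert np.linalg.norm(res.posterior_mean[:2] - src) < 1.0

    def test_information_pooling_between_noise_levels(self, stations, rng):
        src = np.array([12.0, 34.0])
        clean = simulate_tdoa_set(stations, src, 400.0, 0.0, rng=0, modality="seismic")
        noisy_lags = [(sid, lag + rng.normal(0, 0.01), 1.0)
                      for sid, lag, _ in simulate_tdoa_set(
                          stations, src, 350.0, 0.0, rng=0, modality="acoustic").pairs]
        noisy = TdoaSet(clean.reference_station, noisy_lags, "acoustic",
                        clean.event_id)
        cfg = SolverConfig(tdoa_sigma=1e-3, rng_seed=7)
        sd_clean = TdoaLocationModel(clean, stations, cfg).fit_probabilistic() \
            .posterior_sd[:2].mean()
        sd_noisy = TdoaLocationModel(noisy, stations, cfg).fit_probabilistic() \
            .posterior_sd[:2].mean()
        sd_joint = JointTdoaLocationModel(clean, noisy, stations, cfg).fit() \
            .posterior_sd[:2].mean()
        assert sd_joint <= max(sd_clean, sd_noisy) * 1.5

    def test_duplicated_modality_matches_unimodal_map(self, stations):
        src = np.array([40.0, -30.0])
        ts = simulate_tdoa_set(stations, src, 400.0, 0.0, rng=0, modality="seismic")
        ta = TdoaSet(ts.reference_station, list(ts.pairs), "acoustic", ts.event_id)
        cfg = SolverConfig(rng_seed=8,
                           wavespeed_prior={"seismic": (150.0, 1600.0),
                                            "acoustic": (150.0, 1600.0)})
        uni = TdoaLocationModel(ts, stations, cfg).fit_probabilistic().map_estimate
        joint = JointTdoaLocationModel(ts, ta, stations, cfg).fit().map_estimate
        assert np.linalg.norm(uni.x - joint.x) < 2.0

    def test_mismatched_events_rejected(self, stations):
        a = simulate_tdoa_set(stations, (0, 0), 400.0, 0.0, rng=0, event_id="e1")
        b = simulate_tdoa_set(stations, (0, 0), 350.0, 0.0, rng=0, event_id="e2",
                              modality="acoustic")
        with pytest.raises(ValueError, match="different events"):
            JointTdoaLocationModel(a, b, stations)


class TestBestEstimate:
    def _est(self, residual):
        return LocationEstimate(x=[0.0, 0.0], v=400.0, residual=residual,
                                method="det", modality="seismic")

    def test_minimum_residual_wins(self):
        cands = [self._est(3.1), self._est(0.4), self._est(2.2)]
        assert best_estimate(cands) is cands[1]

    def test_ties_break_to_first(self):
        cands = [self._est(1.0), self._est(1.0), self._est(1.0)]
        assert best_estimate(cands) is cands[0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            best_estimate([])
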