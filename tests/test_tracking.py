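import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geltrap import (
    DimensionlessParameters,
    MOBILE_CUTOFF,
    TrajectorySet,
    analyze_tracks,
    classify_mobile,
    d_eff_at_lag,
    ensemble_geometric_msd,
    fit_anomalous_exponent,
    from_dimensionless,
    generate_tracks,
    msd_curve,
    msd_time_averaged,
)


def _track_df(tid, xy):
    return pd.DataFrame({"track_id": tid, "frame": np.arange(len(xy)),
                         "x_um": xy[:, 0], "y_um": xy[:, 1]})


class TestMSD:
    def test_stationary_track_has_zero_msd(self):
        xy = np.ones((50, 2))
        for lag in (1, 5, 20):
            assert msd_time_averaged(xy, lag) == 0.0

    def test_ballistic_track_quadratic_msd(self):
        dt, v = 0.0667, 0.8
        t = np.arange(100) * dt
        xy = np.column_stack([v * t, np.zeros_like(t)])
        for lag in (1, 3, 7):
            assert msd_time_averaged(xy, lag) == pytest.approx((v * lag * dt) ** 2, rel=1e-9)

    def test_brownian_ensemble_msd_is_4dt(self):
        rng = np.random.default_rng(0)
        D, dt, n_frames, n_tracks = 1.0, 0.0667, 300, 200
        msds = []
        for _ in range(n_tracks):
            steps = rng.standard_normal((n_frames, 2)) * np.sqrt(2 * D * dt)
            msds.append(msd_curve(np.cumsum(steps, axis=0), [1, 2, 4, 8]))
        mean = np.mean(msds, axis=0)
        expected = 4 * D * dt * np.array([1, 2, 4, 8])
        se = np.std(msds, axis=0, ddof=1) / np.sqrt(n_tracks)
        assert np.all(np.abs(mean - expected) < 3 * se)

    def test_lag_must_be_shorter_than_track(self):
        with pytest.raises(ValueError):
            msd_time_averaged(np.zeros((5, 2)), 5)


class TestEnsembleGeometricMSD:
    def test_identical_tracks_reduce_to_common_msd(self):
        rng = np.random.default_rng(1)
        xy = np.cumsum(rng.standard_normal((60, 2)) * 0.1, axis=0)
        ts = TrajectorySet(pd.concat([_track_df(0, xy), _track_df(1, xy)],
                                     ignore_index=True))
        ens = ensemble_geometric_msd(ts, [1, 2, 4])
        assert ens.msd_um2.to_numpy() == pytest.approx(msd_curve(xy, [1, 2, 4]), rel=1e-9)

    def test_log_mean_of_two_tracks(self):
        # tracks engineered to MSD = 0.01 and 1.0 -> geometric mean 0.1
        dt = 0.0667
        t = np.arange(40) * dt
        slow = np.column_stack([np.sqrt(0.01) / (dt * 1) * t * dt, np.zeros_like(t)])
        # ballistic with speed v so that (v*lag*dt)^2 = target at lag 1
        v_slow, v_fast = np.sqrt(0.01) / dt, np.sqrt(1.0) / dt
        slow = np.column_stack([v_slow * t, np.zeros_like(t)])
        fast = np.column_stack([v_fast * t, np.zeros_like(t)])
        ts = TrajectorySet(pd.concat([_track_df(0, slow), _track_df(1, fast)],
                                     ignore_index=True))
        ens = ensemble_geometric_msd(ts, [1])
        assert ens.msd_um2.iloc[0] == pytest.approx(0.1, rel=1e-6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_geometric_below_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        tracks = []
        for tid in range(4):
            xy = np.cumsum(rng.standard_normal((30, 2)) * rng.uniform(0.05, 0.5), axis=0)
            tracks.append(_track_df(tid, xy))
        ts = TrajectorySet(pd.concat(tracks, ignore_index=True))
        geo = ensemble_geometric_msd(ts, [2]).msd_um2.iloc[0]
        arith = np.mean([msd_time_averaged(xy, 2)
                         for _, xy in ts.tracks()])
        assert geo <= arith + 1e-12


class TestDeffAndMobility:
    def test_zero_msd_zero_diffusivity(self):
        assert d_eff_at_lag(0.0, 0.2667) == 0.0

    def test_cutoff_msd_value(self):
        # MSD(0.2667 s) = 0.0337 µm² sits exactly at the mobility boundary
        assert d_eff_at_lag(0.0337, 0.2667) == pytest.approx(10**-1.5, rel=2e-3)

    def test_boundary_is_inclusive(self):
        assert classify_mobile(MOBILE_CUTOFF)
        assert not classify_mobile(MOBILE_CUTOFF * 0.999)
        assert classify_mobile(0.25)   # typical freely diffusing particle
        assert not classify_mobile(1e-2)


class TestAnomalousExponent:
    def test_brownian_curve(self):
        taus = np.array([0.0667, 0.1334, 0.2668, 0.5336])
        d0, alpha = fit_anomalous_exponent(taus, 4 * 0.7 * taus)
        assert alpha == pytest.approx(1.0, abs=1e-9)
        assert d0 == pytest.approx(0.7, rel=1e-9)

    def test_ballistic_curve(self):
        taus = np.array([0.1, 0.2, 0.4, 0.8])
        _, alpha = fit_anomalous_exponent(taus, (2.0 * taus) ** 2)
        assert alpha == pytest.approx(2.0, abs=1e-9)

    def test_needs_positive_msd(self):
        with pytest.raises(ValueError):
            fit_anomalous_exponent([0.1, 0.2, 0.3], [0.0, 0.1, 0.2])


class TestGenerator:
    def test_default_video_has_300_frames(self):
        p = from_dimensionless(DimensionlessParameters(N=0))
        ts = generate_tracks(p, n_tracks=2, seed=0)
        assert all(len(xy) == 300 for _, xy in ts.tracks())

    def test_reproducible(self):
        p = from_dimensionless(DimensionlessParameters(N=0))
        a = generate_tracks(p, n_tracks=3, seed=5)
        b = generate_tracks(p, n_tracks=3, seed=5)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_brownian_pipeline_recovers_diffusivity(self):
        """No anchors: the MSD pipeline recovers D_P within 10%."""
        p = from_dimensionless(DimensionlessParameters(N=0), D_P_scale=1.0)
        ts = generate_tracks(p, n_tracks=200, seed=42)
        _, summary = analyze_tracks(ts)
        assert summary["mean_d_eff"] == pytest.approx(1.0, rel=0.10)
        assert summary["percent_mobile"] == 100.0
        assert summary["mean_exponent"] == pytest.approx(1.0, abs=0.1)

    def test_strong_trapping_immobilizes_tracks(self):
        """Permanent, concentrated anchors push the mobile fraction to ~0."""
        dp = DimensionlessParameters(d_ratio=20.0, N=15, tau_ratio=5.0,
                                     conc_dimless=10.0, phi=0.3)
        p = from_dimensionless(dp)
        ts = generate_tracks(p, n_tracks=60, seed=7)
        _, summary = analyze_tracks(ts)
        assert summary["percent_mobile"] < 5.0
        # arrested ensemble: MSD sits at the noise floor, exponent ~ 0
        assert summary["mean_exponent"] < 0.5

    def test_closure_with_model_prediction(self):
        """Mean track D_eff approaches D_P * stationary free fraction."""
        from geltrap import d_eff_exact

        dp = DimensionlessParameters(d_ratio=20.0, N=5, tau_ratio=20.0,
                                     conc_dimless=1.0, phi=0.5)
        p = from_dimensionless(dp, k_off_scale=5.0)
        ratio = d_eff_exact(p)
        assert 0.2 < ratio < 0.9  # mid-range so the noise floor is irrelevant
        ts = generate_tracks(p, n_tracks=200, seed=11)
        _, summary = analyze_tracks(ts)
        assert summary["mean_d_eff"] == pytest.approx(ratio * p.D_P, rel=0.20)


class TestTrajectoryIO:
    def test_csv_round_trip(self, tmp_path):
        p = from_dimensionless(DimensionlessParameters(N=0))
        ts = generate_tracks(p, n_tracks=3, seed=1)
        path = tmp_path / "tracks.csv"
        ts.to_csv(path)
        back = TrajectorySet.from_csv(path)
        pd.testing.assert_frame_equal(back.data, ts.data)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            TrajectorySet(pd.DataFrame({"track_id": [0], "frame": [0], "x_um": [0.0]}))

    def test_short_tracks_excluded_from_analysis(self):
        rng = np.random.default_rng(2)
        long_xy = np.cumsum(rng.standard_normal((30, 2)) * 0.3, axis=0)
        short_xy = np.zeros((3, 2))
        ts = TrajectorySet(pd.concat([_track_df(0, long_xy), _track_df(1, short_xy)],
                                     ignore_index=True))
        per_track, summary = analyze_tracks(ts)
        assert summary["n_excluded"] == 1
        assert len(per_track) == 1
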