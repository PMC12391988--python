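"""Track statistics and the mobile/immobilized population decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import geldiff as g
from geldiff.exceptions import ValidationError


def make_track(xy, dt=0.5, track_id="t0"):
    xy = np.asarray(xy, dtype=float)
    n = xy.shape[0]
    return g.Track(track_id=track_id, frames=np.arange(n),
                   times_s=np.arange(n) * dt, positions_um=xy)


class TestTrackStats:
    def test_stationary_track(self):
        s = g.track_stats(make_track(np.zeros((10, 2))))
        assert s.max_distance_to_start_um == 0.0
        assert s.path_length_um == 0.0
        assert np.all(s.msd_um2 == 0.0)

    def test_straight_track(self):
        xy = np.column_stack([np.arange(11.0), np.zeros(11)])
        s = g.track_stats(make_track(xy))
        assert s.max_distance_to_start_um == pytest.approx(10.0)
        assert s.path_length_um == pytest.approx(10.0)
        assert s.msd_um2[0] == pytest.approx(1.0)  # lag-1 MSD of unit steps

    def test_path_length_bounds_max_distance(self, rng):
        xy = np.cumsum(rng.standard_normal((50, 2)), axis=0)
        s = g.track_stats(make_track(xy))
        assert s.path_length_um >= s.max_distance_to_start_um >= 0.0

    def test_free_brownian_msd_matches_4_d_dt(self):
        # 1000 tracks at D = 1 um^2/s, dt = 0.1 s: lag-1 MSD expectation 0.4 um^2
        rng = np.random.default_rng(7)
        d, dt, n_steps, n_tracks = 1.0, 0.1, 20, 1000
        lag1 = []
        for _ in range(n_tracks):
            steps = rng.normal(0.0, np.sqrt(2 * d * dt), size=(n_steps, 2))
            xy = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
            lag1.append(g.track_stats(make_track(xy, dt=dt)).msd_um2[0])
        lag1 = np.asarray(lag1)
        se = lag1.std(ddof=1) / np.sqrt(n_tracks)
        assert abs(lag1.mean() - 0.4) <= 3 * se

    @given(angle=st.floats(0, 2 * np.pi), shift_x=st.floats(-50, 50),
           shift_y=st.floats(-50, 50))
    @settings(derandomize=True, max_examples=40)
    def test_max_distance_rigid_motion_invariant(self, angle, shift_x, shift_y):
        rng = np.random.default_rng(11)
        xy = np.cumsum(rng.standard_normal((30, 2)), axis=0)
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        moved = xy @ rot.T + np.array([shift_x, shift_y])
        a = g.track_stats(make_track(xy)).max_distance_to_start_um
        b = g.track_stats(make_track(moved)).max_distance_to_start_um
        assert b == pytest.approx(a, rel=1e-9, abs=1e-9)

    def test_single_point_track_rejected(self):
        with pytest.raises(ValidationError):
            make_track(np.zeros((1, 2)))


class TestConfinement:
    def test_confined_tracks_never_exceed_twice_radius(self):
        radius = 0.3
        tracks, truth = g.generate_tracks(g.TrackSimConfig(
            seed=5, n_tracks=60, mobile_fraction=0.0,
            confinement_radius_um=radius, localization_noise_um=0.0))
        for t in tracks:
            assert g.track_stats(t).max_distance_to_start_um <= 2 * radius + 1e-9

    def test_zero_radius_zero_noise_is_static(self):
        tracks, _ = g.generate_tracks(g.TrackSimConfig(
            seed=2, n_tracks=5, mobile_fraction=0.0,
            confinement_radius_um=0.0, localization_noise_um=0.0))
        for t in tracks:
            assert g.track_stats(t).max_distance_to_start_um == 0.0


class TestPopulationSummary:
    def test_two_point_masses_recovered_exactly(self):
        dists = [0.1] * 12 + [5.0] * 8
        stats = [g.TrackStats(f"t{i}", d, d, np.array([1.0]), np.array([0.0]))
                 for i, d in enumerate(dists)]
        summary = g.population_summary(stats, n_components=2)
        m = summary.mixture
        assert m.weights == pytest.approx([0.6, 0.4], abs=1e-9)
        assert m.means_um == pytest.approx([0.1, 5.0], rel=1e-9)
        assert m.separated

    def test_single_population_not_separated(self):
        # one log-normal cloud should not split into separated components
        flags = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            d = np.exp(rng.normal(0.0, 0.3, size=60))
            stats = [g.TrackStats(f"t{i}", x, x, np.array([1.0]), np.array([0.0]))
                     for i, x in enumerate(d)]
            m = g.population_summary(stats, n_components=2, seed=0).mixture
            flags.append(m.separated)
        assert np.mean(flags) <= 0.2

    def test_generator_default_mixture_weights_recovered(self):
        tracks, truth = g.generate_tracks(g.TrackSimConfig(seed=42))
        stats = [g.track_stats(t) for t in tracks]
        summary = g.population_summary(stats, n_components=2, seed=0)
        m = summary.mixture
        # components ordered by mean: immobile (0.6) first, mobile (0.4) second
        assert m.weights[0] == pytest.approx(0.6, abs=0.10)
        assert m.weights[1] == pytest.approx(0.4, abs=0.10)
        assert m.separated

    def test_em_log_likelihood_nondecreasing(self):
        tracks, _ = g.generate_tracks(g.TrackSimConfig(seed=9))
        stats = [g.track_stats(t) for t in tracks]
        m = g.population_summary(stats, n_components=2, seed=0).mixture
        assert np.all(np.diff(m.log_likelihood_trace) >= -1e-8)

    def test_agrees_with_sklearn_mixture(self):
        # independent EM implementation as cross-check on the same data
        sklearn = pytest.importorskip("sklearn.mixture")
        tracks, _ = g.generate_tracks(g.TrackSimConfig(seed=21))
        d = np.array([g.track_stats(t).max_distance_to_start_um for t in tracks])
        x = np.log(d[d > 0])
        ours = g.population_summary([g.TrackStats(str(i), v, v, np.array([1.0]),
                                                  np.array([0.0]))
                                     for i, v in enumerate(d)],
                                    n_components=2, seed=0).mixture
        gm = sklearn.GaussianMixture(n_components=2, n_init=5, random_state=0,
                                     tol=1e-8).fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        assert ours.means_log == pytest.approx(gm.means_.ravel()[order], abs=0.05)
        assert ours.weights == pytest.approx(gm.weights_[order], abs=0.05)

    def test_more_than_two_components_rejected(self):
        stats = [g.TrackStats(f"t{i}", 1.0, 1.0, np.array([1.0]), np.array([0.0]))
                 for i in range(20)]
        with pytest.raises(ValidationError):
            g.population_summary(stats, n_components=3)
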