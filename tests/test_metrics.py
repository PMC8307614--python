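"""Order parameters and distributional metrics on velocity fields."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import collmigr as cm
from collmigr.metrics import MAGNITUDE_FLOOR

from conftest import field_from, random_field


def brute_force_metrics(vectors):
    """Independent re-summation oracle over a plain list of (u, v) pairs."""
    arr = np.asarray(vectors, dtype=float)
    mags = np.hypot(arr[:, 0], arr[:, 1])
    nz = arr[mags > MAGNITUDE_FLOOR]
    nz_mags = np.hypot(nz[:, 0], nz[:, 1])
    unit = nz / nz_mags[:, None]
    return {
        "directionality": float(np.mean(unit[:, 0])),
        "coordination": float(np.hypot(unit[:, 0].mean(), unit[:, 1].mean())),
        "speed": float(mags.mean()),
        "x_velocity": float(arr[:, 0].mean()),
    }


class TestDirectionality:
    @pytest.mark.parametrize("vec,expected", [
        ((1.0, 0.0), 1.0),      # all motion rightward, parallel to field
        ((-1.0, 0.0), -1.0),    # all motion leftward, antiparallel
        ((0.0, 2.5), 0.0),      # perpendicular motion
    ])
    def test_uniform_fields(self, uniform_field, vec, expected):
        assert cm.directionality(uniform_field(*vec)) == pytest.approx(expected)

    def test_mixed_pair(self):
        fld = field_from([[1.0, 0.0]], [[0.0, 1.0]])
        assert cm.directionality(fld) == pytest.approx(0.5)

    def test_undefined_on_zero_field(self, uniform_field):
        with pytest.raises(cm.UndefinedMetricError):
            cm.directionality(uniform_field(0.0, 0.0))

    def test_rotation_by_pi_flips_sign(self, rng):
        fld = random_field(rng)
        flipped = field_from(-fld.u, -fld.v)
        assert cm.directionality(flipped) == pytest.approx(
            -cm.directionality(fld), abs=1e-12)


class TestCoordination:
    def test_parallel_any_magnitudes(self, rng):
        mags = rng.uniform(0.1, 5.0, size=(6, 6))
        theta = 0.83
        fld = field_from(mags * np.cos(theta), mags * np.sin(theta))
        assert cm.coordination(fld) == pytest.approx(1.0)

    def test_antiparallel_pair_cancels(self):
        fld = field_from([[1.0, -1.0]], [[0.0, 0.0]])
        assert cm.coordination(fld) == pytest.approx(0.0)

    def test_orthogonal_pair(self):
        fld = field_from([[1.0, 0.0]], [[0.0, 1.0]])
        assert cm.coordination(fld) == pytest.approx(np.sqrt(2) / 2)

    def test_rotation_invariance(self, rng):
        fld = random_field(rng)
        a = 1.1
        rot_u = fld.u * np.cos(a) - fld.v * np.sin(a)
        rot_v = fld.u * np.sin(a) + fld.v * np.cos(a)
        assert cm.coordination(field_from(rot_u, rot_v)) == pytest.approx(
            cm.coordination(fld), abs=1e-12)

    def test_axis_aligned_identity_with_directionality(self, rng):
        u = rng.choice([-1.0, 1.0], size=(8, 8)) * rng.uniform(0.5, 2, (8, 8))
        fld = field_from(u, np.zeros_like(u))
        assert cm.coordination(fld) == pytest.approx(
            abs(cm.directionality(fld)), abs=1e-12)


class TestScalarMeans:
    def test_mean_speed_345(self):
        assert cm.mean_speed(field_from([[3.0]], [[4.0]])) == pytest.approx(5.0)

    def test_speed_ignores_direction(self):
        fld = field_from([[1.0, -1.0]], [[0.0, 0.0]])
        assert cm.mean_speed(fld) == pytest.approx(1.0)
        assert cm.mean_x_velocity(fld) == pytest.approx(0.0)

    def test_mean_x_velocity_uniform(self, uniform_field):
        assert cm.mean_x_velocity(uniform_field(2.0, 7.0)) == pytest.approx(2.0)

    def test_brute_force_agreement_on_random_fields(self, rng):
        for _ in range(100):
            fld = random_field(rng)
            ref = brute_force_metrics(np.column_stack([fld.u.ravel(),
                                                       fld.v.ravel()]))
            assert cm.directionality(fld) == pytest.approx(ref["directionality"], abs=1e-12)
            assert cm.coordination(fld) == pytest.approx(ref["coordination"], abs=1e-12)
            assert cm.mean_speed(fld) == pytest.approx(ref["speed"], abs=1e-12)
            assert cm.mean_x_velocity(fld) == pytest.approx(ref["x_velocity"], abs=1e-12)

    def test_invalid_nodes_reduce_n(self, rng):
        u = rng.normal(size=(6, 6))
        v = rng.normal(size=(6, 6))
        valid = rng.random((6, 6)) > 0.4
        fld = field_from(u, v, valid=valid)
        ref = brute_force_metrics(np.column_stack([u[valid], v[valid]]))
        assert cm.mean_speed(fld) == pytest.approx(ref["speed"], abs=1e-12)
        assert cm.directionality(fld) == pytest.approx(ref["directionality"], abs=1e-12)


@settings(max_examples=50, deadline=None)
@given(arrays(float, (5, 5), elements=st.floats(-50, 50)),
       arrays(float, (5, 5), elements=st.floats(-50, 50)),
       st.floats(min_value=1e-3, max_value=1e3))
def test_bounds_and_scale_invariance(u, v, scale):
    """Directionality in [-1,1], coordination in [0,1], both magnitude-invariant."""
    # snap near-floor components to zero so the zero-magnitude cut keeps the
    # same vector set before and after scaling
    u = np.where(np.abs(u) < 1e-3, 0.0, u)
    v = np.where(np.abs(v) < 1e-3, 0.0, v)
    fld = field_from(u, v)
    try:
        d = cm.directionality(fld)
        c = cm.coordination(fld)
    except cm.UndefinedMetricError:
        return
    assert -1.0 <= d <= 1.0
    assert 0.0 <= c <= 1.0 + 1e-12
    scaled = field_from(scale * u, scale * v)
    assert cm.directionality(scaled) == pytest.approx(d, abs=1e-9)
    assert cm.coordination(scaled) == pytest.approx(c, abs=1e-9)


class TestNeighborCorrelation:
    def test_uniform_field(self, uniform_field):
        assert cm.neighbor_correlation(uniform_field(1.5, -0.5)) == pytest.approx(1.0)

    def test_checkerboard_antiparallel(self):
        sign = (-1.0) ** (np.add.outer(np.arange(8), np.arange(8)))
        fld = field_from(sign, np.zeros((8, 8)))
        assert cm.neighbor_correlation(fld) == pytest.approx(-1.0)

    def test_isotropic_null_near_zero(self):
        rng = np.random.default_rng(7)
        fld = random_field(rng, ny=64, nx=64)
        assert abs(cm.neighbor_correlation(fld)) < 0.05

    def test_undefined_without_neighbors(self):
        fld = field_from([[1.0, 1.0]], [[0.0, 0.0]],
                         valid=np.array([[True, False]]))
        with pytest.raises(cm.UndefinedMetricError):
            cm.neighbor_correlation(fld)


class TestAngleDistribution:
    def test_all_plus_x_single_bin(self, uniform_field):
        hist = cm.angle_distribution([uniform_field(3.0, 0.0)], n_bins=12)
        zero_bin = np.digitize(0.0, hist.bin_edges) - 1
        assert hist.frequency[zero_bin] == pytest.approx(1.0)
        assert hist.frequency.sum() == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_sample_flat(self):
        rng = np.random.default_rng(11)
        n_bins, m = 12, 40000
        theta = rng.uniform(-np.pi, np.pi, m)
        fld = field_from(np.cos(theta).reshape(200, 200),
                         np.sin(theta).reshape(200, 200))
        hist = cm.angle_distribution([fld], n_bins=n_bins)
        p = 1.0 / n_bins
        bound = 3.0 * np.sqrt(p * (1 - p) / m)
        assert np.max(np.abs(hist.frequency - p)) < bound

    def test_rejects_single_bin(self, uniform_field):
        with pytest.raises(cm.ConfigurationError):
            cm.angle_distribution([uniform_field(1, 0)], n_bins=1)


class TestMetricTimeseries:
    def test_constant_fields_give_constant_series(self, uniform_field):
        fields = [uniform_field(2.0, 1.0) for _ in range(5)]
        series = cm.metric_timeseries(fields, smoothing_window=3)
        single = cm.mean_speed(fields[0])
        assert np.allclose(series.speed, single)
        assert np.allclose(series.directionality,
                           cm.directionality(fields[0]))
        assert len(series) == 5

    def test_undefined_frames_become_nan_not_zero(self, uniform_field):
        good = uniform_field(1.0, 0.0)
        bad = field_from([[0.0]], [[0.0]])
        series = cm.metric_timeseries([good, bad, good], smoothing_window=0)
        assert np.isnan(series.directionality[1])
        assert series.directionality[0] == pytest.approx(1.0)

    def test_directionality_rises_after_bias_switch(self):
        base = cm.SimulationConfig(n_agents=200, n_frames=30, seed=21)
        off = cm.simulate_monolayer(base)
        on = cm.simulate_monolayer(base.with_(field_bias=3.0, seed=22))
        fields = ([cm.trajectory_to_field(off, f) for f in range(29)]
                  + [cm.trajectory_to_field(on, f) for f in range(29)])
        series = cm.metric_timeseries(fields)
        n = len(series)
        first = np.nanmean(series.directionality[: n // 4])
        last = np.nanmean(series.directionality[-n // 4:])
        assert last > first

    def test_max_speed_is_max_of_smoothed(self, rng):
        fields = [random_field(rng) for _ in range(7)]
        series = cm.metric_timeseries(fields, smoothing_window=3)
        assert cm.max_migration_speed(series) == pytest.approx(
            np.nanmax(series.speed))

    def test_value_at_time_picks_nearest_frame(self, uniform_field):
        fields = [uniform_field(float(i), 0.0, pixel_size=10.0,
                                frame_interval=10.0) for i in range(1, 6)]
        series = cm.metric_timeseries(fields, smoothing_window=0)
        assert cm.value_at_time(series, 21.0, "x_velocity") == pytest.approx(3.0)
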