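"""Kymographs, tissue segmentation, edge tracking, wound closure."""

import numpy as np
import pytest

import collmigr as cm

from conftest import field_from, random_field


def uniform_fields(u0, n=6, frame_interval=5.0, ny=8, nx=8):
    """Fields whose calibrated x-velocity is exactly u0 um/min."""
    return [field_from(np.full((ny, nx), float(u0) * frame_interval),
                       np.zeros((ny, nx)),
                       frame_interval=frame_interval, grid_spacing=10.0)
            for _ in range(n)]


class TestXvelocityKymograph:
    def test_uniform_fields_constant_cells(self):
        km = cm.xvelocity_kymograph(uniform_fields(2.0), row_duration=10.0,
                                    col_width=20.0)
        assert np.allclose(km.values[np.isfinite(km.values)], 2.0)

    def test_step_profile_reproduced(self):
        u = np.ones((8, 8)) * 10.0   # +1 um/min at 10 min/frame
        u[:, :4] = -10.0
        fld = field_from(u, np.zeros((8, 8)), grid_spacing=10.0,
                         frame_interval=10.0)
        km = cm.xvelocity_kymograph([fld], row_duration=10.0, col_width=10.0)
        row = km.values[0]
        assert np.allclose(row[:4], -1.0)
        assert np.allclose(row[4:8], 1.0)

    def test_nine_hours_of_ten_minute_rows(self):
        fields = uniform_fields(1.0, n=108, frame_interval=5.0)  # 9 h movie
        km = cm.xvelocity_kymograph(fields, row_duration=10.0, col_width=20.0)
        assert km.n_rows == 54

    def test_brute_force_binning_oracle(self, rng):
        fields = [random_field(rng, ny=8, nx=8, grid_spacing=10.0,
                               frame_interval=5.0) for _ in range(4)]
        km = cm.xvelocity_kymograph(fields, row_duration=10.0, col_width=25.0)
        # recompute one cell directly: rows pool 2 frames, cols pool x in bins
        for row, frames in [(0, fields[:2]), (1, fields[2:])]:
            for col in range(km.values.shape[1]):
                pooled = []
                for fld in frames:
                    sel = (fld.x_um // 25.0 == col) & fld.valid
                    pooled.extend(fld.u_um_min[sel])
                if pooled:
                    assert km.values[row, col] == pytest.approx(
                        np.mean(pooled), abs=1e-9)

    def test_row_shorter_than_interval_rejected(self):
        with pytest.raises(cm.ConfigurationError):
            cm.xvelocity_kymograph(uniform_fields(1.0, frame_interval=10.0),
                                   row_duration=5.0)


class TestSegmentTissue:
    def test_edge_scenario_boundary_within_tolerance(self):
        seq, truth = cm.make_edge_scenario("static", 0.0, (128, 256), 3, seed=1)
        mask = cm.segment_tissue(seq[0])
        measured = cm.edge_positions(mask, "leading")
        assert abs(measured - truth[0]) <= 5.0

    def test_blank_frame_empty_mask(self):
        with pytest.warns(UserWarning):
            mask = cm.segment_tissue(np.zeros((64, 64)))
        assert not mask.any()

    def test_pure_noise_frame_empty_mask(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="no tissue"):
            mask = cm.segment_tissue(0.05 * rng.standard_normal((64, 64)))
        assert not mask.any()

    def test_full_texture_frame_full_mask(self):
        from collmigr.simulate import _speckle_texture
        rng = np.random.default_rng(4)
        tex = _speckle_texture((96, 96), rng, 0.05, 1.5)
        mask = cm.segment_tissue(tex)
        assert mask.all()

    def test_translation_equivariance_on_masks(self):
        seq, _ = cm.make_edge_scenario("static", 0.0, (64, 200), 2, seed=2)
        frame = seq[0]
        shifted = np.roll(frame, 30, axis=1)
        m0 = cm.segment_tissue(frame)
        m1 = cm.segment_tissue(shifted)
        assert (cm.edge_positions(m1, "leading")
                - cm.edge_positions(m0, "leading")) == pytest.approx(30.0, abs=2.0)


class TestEdgePositions:
    def test_rectangular_mask_calibrated(self):
        mask = np.zeros((32, 512), dtype=bool)
        mask[:, :400] = True    # tissue fills columns 0..399, ends at x=400 px
        assert cm.edge_positions(mask, "leading", pixel_size=1.3) == pytest.approx(520.0)

    def test_trailing_of_full_width_mask_is_zero(self):
        mask = np.ones((16, 64), dtype=bool)
        assert cm.edge_positions(mask, "trailing") == 0.0

    def test_median_robust_to_minority_finger(self):
        mask = np.zeros((40, 300), dtype=bool)
        mask[:, :200] = True
        base = cm.edge_positions(mask, "leading")
        fingered = mask.copy()
        fingered[:10, :250] = True   # 50-px finger on 25% of rows
        assert cm.edge_positions(fingered, "leading") == base

    def test_matches_brute_force_median(self, rng):
        mask = np.zeros((20, 100), dtype=bool)
        ends = rng.integers(30, 90, size=20)
        for r, e in enumerate(ends):
            mask[r, :e] = True
        expected = float(np.median(ends))
        assert cm.edge_positions(mask, "leading") == pytest.approx(expected)

    def test_empty_mask_undefined(self):
        with pytest.raises(cm.UndefinedEdgeError):
            cm.edge_positions(np.zeros((8, 8), dtype=bool))


class TestEdgeDisplacementSeries:
    @pytest.mark.parametrize("mode,rate,sign", [
        ("advance", 3.0, 1), ("static", 0.0, 0), ("retract", 2.0, -1)])
    def test_sign_and_magnitude(self, mode, rate, sign):
        seq, truth = cm.make_edge_scenario(mode, rate, (128, 256), 11, seed=7)
        trace = cm.edge_displacement_series(seq)
        final = trace.displacement[-1]
        expected = sign * rate * 10
        if sign == 0:
            assert abs(final) < 5.0
        else:
            assert np.sign(final) == sign
            assert final == pytest.approx(expected, rel=0.2)

    def test_displacement_zero_at_first_frame(self):
        seq, _ = cm.make_edge_scenario("advance", 2.0, (64, 256), 5, seed=0)
        trace = cm.edge_displacement_series(seq)
        assert trace.displacement[0] == 0.0
        assert len(trace) == 5


class TestWoundClosure:
    @staticmethod
    def _trace(time, leading=None, trailing=None):
        n = len(time)
        lead = np.asarray(leading if leading is not None else np.zeros(n), float)
        trail = np.asarray(trailing if trailing is not None else np.zeros(n), float)
        return cm.EdgeTrace(np.asarray(time, float), lead, trail,
                            lead - lead[0], trail - trail[0])

    def test_two_edges_approaching(self):
        t = np.arange(0.0, 60.0, 5.0)
        left = self._trace(t, leading=100.0 + 1.0 * t)
        right = self._trace(t, trailing=400.0 - 1.0 * t)
        res = cm.wound_closure_rate(left, right)
        assert res.rate_um_min == pytest.approx(2.0)
        assert res.closure_time_min is None

    def test_static_edges_zero_rate(self):
        t = np.arange(0.0, 30.0, 5.0)
        res = cm.wound_closure_rate(self._trace(t, leading=np.full(6, 100.0)),
                                    self._trace(t, trailing=np.full(6, 300.0)))
        assert res.rate_um_min == pytest.approx(0.0)
        assert res.closure_time_min is None

    def test_closure_time_detected(self):
        t = np.arange(0.0, 110.0, 10.0)
        left = self._trace(t, leading=0.0 + 1.0 * t)
        right = self._trace(t, trailing=100.0 - 1.0 * t)
        res = cm.wound_closure_rate(left, right)
        assert res.closure_time_min == pytest.approx(50.0)

    def test_noisy_synthetic_rate_within_ten_percent(self, rng):
        t = np.arange(0.0, 300.0, 5.0)
        approach = 0.8  # um/min total
        gap0 = 400.0
        left = self._trace(t, leading=50.0 + 0.4 * t + rng.normal(0, 3, len(t)))
        right = self._trace(t, trailing=50.0 + gap0 - 0.4 * t
                            + rng.normal(0, 3, len(t)))
        res = cm.wound_closure_rate(left, right)
        assert res.rate_um_min == pytest.approx(approach, rel=0.1)

    def test_mismatched_time_bases_rejected(self):
        a = self._trace(np.arange(0.0, 30.0, 5.0), trailing=np.full(6, 300.0))
        b = self._trace(np.arange(0.0, 60.0, 10.0), leading=np.zeros(6))
        with pytest.raises(cm.InputError):
            cm.wound_closure_rate(b, a)

    def test_end_to_end_two_tissue_scenario(self):
        """Gap between a rendered advancing tissue and its mirror image."""
        rate = 2.0  # px/frame each side
        seq, _ = cm.make_edge_scenario("advance", rate, (128, 256), 11, seed=3)
        left = cm.edge_displacement_series(seq)
        mirrored = cm.ImageSequence(seq.frames[:, :, ::-1].copy(),
                                    seq.pixel_size, seq.frame_interval)
        right = cm.edge_displacement_series(mirrored)
        res = cm.wound_closure_rate(left, right)
        # both edges advance at `rate` px/frame; frame_interval = 1 min
        assert res.rate_um_min == pytest.approx(2 * rate, rel=0.1)
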