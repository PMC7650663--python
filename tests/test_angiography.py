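"""Angiography preprocessing, compartment curves, and both PI variants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from bbbkit import angiography as an
from bbbkit import stats
from bbbkit.exceptions import (
    DivisionGuardError,
    InvalidInputError,
    RegistrationError,
    RegistrationFallbackWarning,
    SegmentationError,
    WindowNotFoundError,
)
from conftest import rank_oracle, weighted_vector_oracle


class TestResizeFrames:
    def test_constant_frame_preserved(self, make_series):
        s = make_series(np.full((3, 512, 512), 7.0))
        out = an.resize_frames(s, 128)
        assert out.frames.shape == (3, 128, 128)
        np.testing.assert_allclose(out.frames, 7.0)
        np.testing.assert_allclose(out.times, s.times)

    def test_checkerboard_block_mean(self, make_series):
        board = np.indices((4, 4)).sum(axis=0) % 2
        out = an.resize_frames(make_series(board[None].astype(float)), 2)
        np.testing.assert_allclose(out.frames[0], 0.5)

    def test_matches_block_mean_loop_oracle(self, make_series, rng):
        frame = rng.random((128, 128))
        out = an.resize_frames(make_series(frame[None]), 32)
        oracle = np.empty((32, 32))
        f = 128 // 32
        for i in range(32):
            for j in range(32):
                oracle[i, j] = frame[i * f:(i + 1) * f, j * f:(j + 1) * f].mean()
        np.testing.assert_allclose(out.frames[0], oracle, atol=1e-12)

    def test_upsampling_rejected(self, make_series):
        with pytest.raises(InvalidInputError):
            an.resize_frames(make_series(np.ones((1, 64, 64))), 128)


@pytest.fixture
def structured_frame(rng):
    img = np.zeros((64, 64))
    img[20:24, 5:60] = 100.0
    img[30:55, 30:33] = 80.0
    return ndimage.gaussian_filter(img, 1.0) + rng.normal(0, 1, (64, 64)) ** 2


class TestRegisterSeries:
    def test_aligned_series_gets_identity_transforms(self, make_series,
                                                     structured_frame):
        s = make_series(np.stack([structured_frame] * 3))
        _, shifts = an.register_series(s, reference_index=0)
        np.testing.assert_allclose(shifts, 0.0, atol=0.3)

    def test_known_shift_recovered(self, make_series, structured_frame):
        moved = ndimage.shift(structured_frame, (3, -2), order=1, mode="nearest")
        s = make_series(np.stack([structured_frame, moved]))
        registered, shifts = an.register_series(s, reference_index=0)
        np.testing.assert_allclose(shifts[1], (-3, 2), atol=0.5)
        core = np.s_[8:-8, 8:-8]
        resid = registered.frames[1][core] - structured_frame[core]
        assert np.abs(resid).mean() < 2.0

    def test_pure_noise_falls_back_to_identity(self, make_series,
                                               structured_frame, rng):
        noise = rng.normal(10, 1, structured_frame.shape) ** 2
        s = make_series(np.stack([structured_frame, noise]))
        with pytest.warns(RegistrationFallbackWarning):
            _, shifts = an.register_series(s, reference_index=0)
        np.testing.assert_allclose(shifts[1], 0.0)

    def test_all_zero_frame_raises_with_frame_index(self, make_series,
                                                    structured_frame):
        s = make_series(np.stack([structured_frame, np.zeros((64, 64))]))
        with pytest.raises(RegistrationError, match="frame 1"):
            an.register_series(s, reference_index=0)


class TestSegmentVessels:
    def test_line_phantom_recovered(self, make_series, rng):
        truth = np.zeros((64, 64), dtype=bool)
        truth[30:33, 4:60] = True
        img = np.where(truth, 200.0, 6.0) + rng.normal(0, 2, (64, 64))
        masks = an.segment_vessels(make_series(img[None].clip(0)))
        inter = (masks.vessel & truth).sum()
        dice = 2 * inter / (masks.vessel.sum() + truth.sum())
        assert dice >= 0.9

    def test_uniform_frame_rejected(self, make_series):
        with pytest.raises(SegmentationError):
            an.segment_vessels(make_series(np.full((1, 64, 64), 3.0)))

    def test_single_pixel_hole_filled(self, make_series, rng):
        truth = np.zeros((64, 64), dtype=bool)
        truth[28:36, 4:60] = True
        img = np.where(truth, 200.0, 6.0)
        img[31, 30] = 6.0  # dropout inside the vessel
        img += rng.normal(0, 1, (64, 64))
        masks = an.segment_vessels(make_series(img[None].clip(0)))
        assert masks.vessel[31, 30]

    def test_guard_band_separates_compartments(self, make_series, rng):
        truth = np.zeros((64, 64), dtype=bool)
        truth[30:33, 4:60] = True
        img = np.where(truth, 200.0, 6.0) + rng.normal(0, 2, (64, 64))
        masks = an.segment_vessels(make_series(img[None].clip(0)), guard_px=2)
        assert not (masks.vessel & masks.extravascular).any()
        boundary = ndimage.binary_dilation(masks.vessel) & ~masks.vessel
        assert not (boundary & masks.extravascular).any()


class TestSelectPrimaryVessel:
    @pytest.fixture
    def two_component_masks(self):
        vessel = np.zeros((32, 32), dtype=bool)
        vessel[5:15, 5:15] = True       # 100 px component
        vessel[20:28, 20:25] = True     # 40 px component
        return an.CompartmentMasks(vessel=vessel, extravascular=~vessel)

    def test_roi_selects_branch(self, two_component_masks):
        roi = np.zeros((32, 32), dtype=bool)
        roi[20:28, 20:25] = True
        out = an.select_primary_vessel(two_component_masks, roi=roi,
                                       erode_px=0)
        assert out.primary_vessel.sum() == 40

    def test_largest_component_wins_without_roi(self, two_component_masks):
        out = an.select_primary_vessel(two_component_masks, erode_px=0)
        assert out.primary_vessel.sum() == 100
        assert out.primary_vessel[6, 6]

    def test_disjoint_roi_rejected(self, two_component_masks):
        roi = np.zeros((32, 32), dtype=bool)
        roi[0:3, 0:3] = True
        with pytest.raises(InvalidInputError):
            an.select_primary_vessel(two_component_masks, roi=roi)


class TestCompartmentCurves:
    def test_constant_frames(self, make_series):
        masks = an.CompartmentMasks(
            vessel=np.eye(8, dtype=bool), extravascular=~np.eye(8, dtype=bool)
        )
        vif, ev = an.compartment_curves(make_series(np.full((4, 8, 8), 3.0)),
                                        masks)
        np.testing.assert_allclose(vif.intensity, 3.0)
        np.testing.assert_allclose(ev.intensity, 3.0)

    def test_single_pixel_masks_trace_that_pixel(self, make_series, rng):
        frames = rng.random((6, 8, 8))
        vessel = np.zeros((8, 8), dtype=bool)
        vessel[2, 3] = True
        ev = np.zeros((8, 8), dtype=bool)
        ev[5, 5] = True
        masks = an.CompartmentMasks(vessel=vessel, extravascular=ev)
        vif, evc = an.compartment_curves(make_series(frames), masks)
        np.testing.assert_allclose(vif.intensity, frames[:, 2, 3], atol=1e-12)
        np.testing.assert_allclose(evc.intensity, frames[:, 5, 5], atol=1e-12)

    def test_matches_loop_oracle(self, make_series, rng):
        frames = rng.random((10, 16, 16))
        vessel = rng.random((16, 16)) > 0.7
        masks = an.CompartmentMasks(vessel=vessel, extravascular=~vessel)
        vif, ev = an.compartment_curves(make_series(frames), masks)
        for i in range(10):
            assert vif.intensity[i] == pytest.approx(frames[i][vessel].mean(),
                                                     abs=1e-12)
            assert ev.intensity[i] == pytest.approx(frames[i][~vessel].mean(),
                                                    abs=1e-12)

    def test_empty_mask_rejected(self, make_series):
        empty = np.zeros((8, 8), dtype=bool)
        masks = an.CompartmentMasks(vessel=empty, extravascular=~empty)
        with pytest.raises(InvalidInputError):
            an.compartment_curves(make_series(np.ones((2, 8, 8))), masks)


class TestFindClearanceWindow:
    def test_exponential_decay_band_entry(self):
        # rise to A=100 then decay exp(-t/tau), tau=20: initial slope -5,
        # flattening; |slope| = 1 at tau*ln(5) = 32.19 s after the peak
        t = np.arange(0.0, 120.0, 0.2)
        y = np.where(t < 10, 10 * t, 100 * np.exp(-(t - 10) / 20.0))
        w = an.find_clearance_window(an.ITCurve(t=t, intensity=y),
                                     smooth_width=1)
        assert w.t_cr == pytest.approx(10 + 20 * np.log(5), abs=1.0)
        assert w.t_end == pytest.approx(t[-1])

    def test_monotone_rise_has_no_window(self):
        t = np.arange(0.0, 10.0, 0.5)
        with pytest.raises(WindowNotFoundError):
            an.find_clearance_window(an.ITCurve(t=t, intensity=t**2))

    def test_flat_after_peak_starts_immediately(self):
        t = np.arange(0.0, 20.0, 1.0)
        y = np.where(t < 5, t, 5.0)
        w = an.find_clearance_window(an.ITCurve(t=t, intensity=y),
                                     smooth_width=1)
        assert w.t_cr <= 7.0  # first samples after the peak (derivative 0)


class TestPiClearance:
    @staticmethod
    def _curves(ratio=0.5):
        t = np.arange(0.0, 100.0, 1.0)
        vif = 10.0 * np.exp(-t / 50.0)
        return (an.ITCurve(t=t, intensity=ratio * vif),
                an.ITCurve(t=t, intensity=vif))

    def test_proportional_curves(self):
        ev, vif = self._curves(0.5)
        w = an.ClearanceWindow(t_cr=10.0, t_end=99.0)
        assert an.pi_clearance(ev, vif, w).pi == pytest.approx(0.5, rel=1e-12)

    def test_identity_curves(self):
        ev, vif = self._curves(1.0)
        w = an.ClearanceWindow(t_cr=5.0, t_end=99.0)
        assert an.pi_clearance(ev, vif, w).pi == pytest.approx(1.0, rel=1e-12)

    def test_against_closed_form_integral(self):
        # EV constant 2, VIF = 4 exp(-t/100): integrand 0.5 exp(t/100), whose
        # window average has the closed form 50*(e^(b/100)-e^(a/100))/(b-a)
        t = np.arange(0.0, 301.0, 1.0)  # 1 Hz sampling
        ev = an.ITCurve(t=t, intensity=np.full_like(t, 2.0))
        vif = an.ITCurve(t=t, intensity=4.0 * np.exp(-t / 100.0))
        a, b = 50.0, 300.0
        w = an.ClearanceWindow(t_cr=a, t_end=b)
        exact = 50.0 * (np.exp(b / 100) - np.exp(a / 100)) / (b - a)
        assert an.pi_clearance(ev, vif, w).pi == pytest.approx(exact, abs=1e-3)

    def test_quadrature_error_shrinks_quadratically(self):
        errs = []
        for dt in (1.0, 0.5):
            t = np.arange(0.0, 300.0 + dt / 2, dt)
            ev = an.ITCurve(t=t, intensity=np.full_like(t, 2.0))
            vif = an.ITCurve(t=t, intensity=4.0 * np.exp(-t / 100.0))
            w = an.ClearanceWindow(t_cr=50.0, t_end=300.0)
            exact = 50.0 * (np.exp(3.0) - np.exp(0.5)) / 250.0
            errs.append(abs(an.pi_clearance(ev, vif, w).pi - exact))
        assert errs[1] == pytest.approx(errs[0] / 4, rel=0.2)

    def test_nonpositive_vif_guarded(self):
        t = np.arange(0.0, 10.0, 1.0)
        vif = an.ITCurve(t=t, intensity=np.linspace(1, -1, t.size))
        ev = an.ITCurve(t=t, intensity=np.ones_like(t))
        with pytest.raises(DivisionGuardError):
            an.pi_clearance(ev, vif, an.ClearanceWindow(t_cr=1.0, t_end=9.0))

    @given(c=st.floats(0.1, 10.0))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_scale_invariance(self, c):
        """Joint rescaling leaves PI unchanged; EV-only rescaling is linear."""
        ev, vif = self._curves(0.5)
        w = an.ClearanceWindow(t_cr=10.0, t_end=99.0)
        base = an.pi_clearance(ev, vif, w).pi
        joint = an.pi_clearance(
            an.ITCurve(t=ev.t, intensity=c * ev.intensity),
            an.ITCurve(t=vif.t, intensity=c * vif.intensity), w).pi
        ev_only = an.pi_clearance(
            an.ITCurve(t=ev.t, intensity=c * ev.intensity), vif, w).pi
        assert joint == pytest.approx(base, rel=1e-9)
        assert ev_only == pytest.approx(c * base, rel=1e-9)


def _two_compartment_image(ev_values, vessel_values):
    """Rectangular image whose first rows are EV pixels, last rows vessel."""
    ev_values = np.asarray(ev_values, dtype=float)
    vessel_values = np.asarray(vessel_values, dtype=float)
    width = np.gcd(ev_values.size, vessel_values.size)
    ev_img = ev_values.reshape(-1, width)
    v_img = vessel_values.reshape(-1, width)
    img = np.vstack([ev_img, v_img])
    vessel = np.zeros(img.shape, dtype=bool)
    vessel[ev_img.shape[0]:, :] = True
    return img, an.CompartmentMasks(vessel=vessel, extravascular=~vessel,
                                    primary_vessel=vessel)


class TestPiHistogram:
    @staticmethod
    def _series(img, make):
        return an.AngioSeries(frames=img[None], times=np.array([0.0]),
                              frame_rate=1.0, tracer_mode="accumulating")

    def test_identical_distributions_near_unity(self, rng):
        values = rng.normal(50, 10, size=4096)
        img, masks = _two_compartment_image(values[:2048], values[2048:])
        res = an.pi_histogram(self._series(img, None), masks, bins=64)
        assert res.pi == pytest.approx(1.0, abs=0.15)

    def test_direction_for_separated_compartments(self, rng):
        dim = rng.uniform(0, 30, 2048)
        bright = rng.uniform(60, 100, 2048)
        img_up, masks = _two_compartment_image(bright, dim)   # EV brighter
        up = an.pi_histogram(self._series(img_up, None), masks, bins=64)
        img_dn, masks_dn = _two_compartment_image(dim, bright)
        down = an.pi_histogram(self._series(img_dn, None), masks_dn, bins=64)
        assert up.pi > 1.0 > down.pi

    def test_matches_bruteforce_rank_oracle(self, rng):
        """Histogram PI equals mean-rank ratio of loop-built weighted vectors."""
        for trial in range(10):
            ev = np.repeat(rng.integers(0, 20, size=8), 100).astype(float)
            vessel = np.repeat(rng.integers(0, 20, size=6), 100).astype(float)
            img, masks = _two_compartment_image(ev, vessel)
            bins = 20
            res = an.pi_histogram(self._series(img, None), masks, bins=bins)
            pooled = np.concatenate([ev, vessel])
            lo, hi = np.percentile(pooled, [0.5, 99.5])
            edges = np.linspace(lo, hi, bins + 1)
            w_ev = weighted_vector_oracle(np.clip(ev, lo, hi), edges)
            w_v = weighted_vector_oracle(np.clip(vessel, lo, hi), edges)
            ranks = rank_oracle(np.concatenate([w_ev, w_v]))
            expected = (ranks[: w_ev.size].mean() / ranks[w_ev.size:].mean())
            assert res.pi == pytest.approx(expected, rel=1e-12)

    def test_intensity_rescaling_invariance(self, rng):
        """Joint positive rescaling preserves weighted-vector rank order,
        hence the rank-ratio PI."""
        ev = rng.uniform(0, 40, 2048)
        vessel = rng.uniform(20, 100, 2048)
        img, masks = _two_compartment_image(ev, vessel)
        base = an.pi_histogram(self._series(img, None), masks).pi
        img2, masks2 = _two_compartment_image(3 * ev, 3 * vessel)
        scaled = an.pi_histogram(self._series(img2, None), masks2).pi
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_wrong_tracer_mode_rejected(self, rng):
        img, masks = _two_compartment_image(rng.random(64), rng.random(64))
        series = an.AngioSeries(frames=img[None], times=np.array([0.0]),
                                frame_rate=5.0, tracer_mode="clearing")
        with pytest.raises(InvalidInputError):
            an.pi_histogram(series, masks)


class TestPiShiftAndCall:
    def test_shift_examples(self):
        mk = lambda pi: an.PIResult(pi=pi, mode="histogram")
        assert an.pi_shift(mk(1.0), mk(1.0)) == 0.0
        assert an.pi_shift(mk(1.179), mk(1.0)) == pytest.approx(17.9)
        assert an.pi_shift(mk(1.0), mk(2.0)) == pytest.approx(-50.0)

    def test_zero_baseline_rejected(self):
        mk = lambda pi: an.PIResult(pi=pi, mode="histogram")
        with pytest.raises(InvalidInputError):
            an.pi_shift(mk(1.0), mk(0.0))

    def test_mode_mismatch_rejected(self):
        a = an.PIResult(pi=1.0, mode="histogram")
        b = an.PIResult(pi=1.0, mode="clearance",
                        window=an.ClearanceWindow(0.0, 1.0))
        with pytest.raises(InvalidInputError):
            an.pi_shift(a, b)

    def test_zero_shift_never_flagged(self):
        null = stats.ShamNull(sham_shifts=np.zeros(2), mean=0.0, sd=2.0)
        assert an.call_bbbd(0.0, null) is False


class TestPixelMaps:
    def test_proportional_pixels_recover_their_ratio(self, make_series, rng):
        t = np.arange(0.0, 50.0, 1.0)
        vif_curve = 10.0 * np.exp(-t / 40.0)
        coeff = rng.random((8, 8)) + 0.1
        frames = vif_curve[:, None, None] * coeff[None]
        series = make_series(frames, frame_rate=1.0)
        vif = an.ITCurve(t=series.times, intensity=vif_curve)
        w = an.ClearanceWindow(t_cr=5.0, t_end=49.0)
        pi_map = an.pixel_pi_map(series, vif, w)
        np.testing.assert_allclose(pi_map, coeff, rtol=1e-10)

    def test_pixel_bbbd_map_threshold(self):
        shifts = np.array([[0.0, 10.0], [5.0, 20.0]])
        flagged = an.pixel_bbbd_map(shifts, null_mean=0.0, null_sd=2.0)
        np.testing.assert_array_equal(flagged,
                                      [[False, True], [False, True]])
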