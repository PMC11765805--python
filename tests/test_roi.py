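"""ROI photometry: segmentation, registration, formulas (1)-(4)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forkdyn.movie import Movie
from forkdyn.pipeline import quantify_movie
from forkdyn.roi import (
    ROISet,
    RawTraces,
    aggregate_cells,
    bound_trace,
    disk_mask,
    ellipse_mask,
    measure_raw,
    rect_mask,
    register_translation,
    segment_nuclei,
)
from forkdyn.simulate import OpticsNoise, random_geometry, render_movie

CHANNEL_KINDS = {"pcna": "decay", "rpa1": "accumulation"}


def synthetic_raw(times, d_t, background=0.0):
    """RawTraces whose B regions already carry the diffuse trace d_t."""
    d_t = np.asarray(d_t, dtype=float)
    bg = np.full_like(d_t, background)
    return RawTraces(times=np.asarray(times, dtype=float), nucleus=d_t + bg,
                     foci_free=np.stack([d_t + bg] * 3), background=bg)


class TestSegmentation:
    def test_single_bright_ellipse_yields_one_covering_label(self):
        img = np.zeros((100, 100)) + 5.0
        truth = ellipse_mask((100, 100), (50, 50), (25, 30))
        img[truth] = 100.0
        labels = segment_nuclei(img)
        assert labels.max() == 1
        covered = (labels == 1) & truth
        assert covered.sum() >= 0.9 * truth.sum()

    def test_two_disjoint_ellipses_yield_two_labels(self):
        img = np.zeros((120, 120)) + 5.0
        img[ellipse_mask((120, 120), (30, 30), (15, 15))] = 100.0
        img[ellipse_mask((120, 120), (85, 85), (15, 18))] = 100.0
        assert segment_nuclei(img).max() == 2

    def test_constant_image_yields_no_labels_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            labels = segment_nuclei(np.ones((50, 50)))
        assert labels.max() == 0


class TestRegistration:
    def test_known_synthetic_drift_is_recovered(self, stall_schedule):
        geom = random_geometry(4, shape=(96, 96), n_foci=6, drift=(1.0, 0.5))
        optics = OpticsNoise(seed=0, photon_scale=0.0, read_sigma=0.0)
        sched = type(stall_schedule)(
            t_start=0.0, t_hu=1.0, t_w=5.0, t_end=5.0,
            channels={"pcna": stall_schedule.channels["pcna"]},
        )
        movie, _ = render_movie(sched, geom, optics, frame_interval_min=1.0)
        _, shifts = register_translation(movie.channels["pcna"])
        expected = np.outer(np.arange(movie.n_frames), (1.0, 0.5))
        assert np.abs(shifts - expected).max() < 0.1

    def test_identical_frames_give_zero_shifts(self):
        rng = np.random.default_rng(0)
        frame = rng.random((40, 40))
        stack = np.stack([frame] * 4)
        corrected, shifts = register_translation(stack)
        assert np.array_equal(shifts, np.zeros((4, 2)))
        assert np.allclose(corrected, stack)

    def test_single_frame_is_a_no_op(self):
        stack = np.random.default_rng(1).random((1, 30, 30))
        corrected, shifts = register_translation(stack)
        assert shifts.shape == (1, 2)
        assert np.allclose(corrected, stack)

    def test_flat_stack_warns_and_assumes_no_drift(self):
        with pytest.warns(UserWarning, match="flat"):
            _, shifts = register_translation(np.ones((3, 20, 20)))
        assert not shifts.any()


class TestMeasureRaw:
    def make_rois(self, shape=(96, 96)):
        nucleus = ellipse_mask(shape, (48, 48), (30, 36))
        return ROISet(
            nucleus=nucleus,
            foci_free=[disk_mask(shape, (48, 48), 4.0)],
            background=rect_mask(shape, (2, 2), (10, 10)),
        )

    def test_uniform_image_measures_its_value_everywhere(self):
        rois = self.make_rois()
        stack = np.full((4, 96, 96), 7.5)
        movie = Movie(channels={"c": stack}, frame_interval=1.0)
        raw = measure_raw(movie, rois)["c"]
        for arr in (raw.nucleus, raw.background, raw.foci_free[0]):
            assert np.allclose(arr, 7.5)

    def test_background_roi_reads_the_camera_offset(self, noise_free_movie):
        movie, truth = noise_free_movie
        rois = self.make_rois(movie.frame_shape)
        raw = measure_raw(movie, rois)["pcna"]
        assert np.allclose(raw.background, 10.0)  # simulator offset

    def test_roi_shape_mismatch_raises(self, noise_free_movie):
        movie, _ = noise_free_movie
        with pytest.raises(ValueError, match="shape"):
            measure_raw(movie, self.make_rois((64, 64)))


class TestBoundTrace:
    def test_constant_diffuse_gives_zero_bound_everywhere(self):
        t = np.arange(0.0, 20.0, 0.5)
        raw = synthetic_raw(t, np.full_like(t, 30.0), background=5.0)
        tr = bound_trace(raw, (0.0, 19.5))
        assert np.allclose(tr.bound, 0.0)
        assert np.allclose(tr.fraction, 0.0)

    def test_formula_identity_closes(self, noisy_movie):
        movie, _ = noisy_movie
        res = quantify_movie(movie, CHANNEL_KINDS, register=False)
        for tr in res["traces"].values():
            assert np.allclose(tr.fraction * tr.total_ref + tr.diffuse, tr.total_ref)

    def test_noise_free_fraction_matches_ground_truth(self, noise_free_movie):
        """Oracle equivalence: formula (4) recovers the simulator's fraction."""
        movie, truth = noise_free_movie
        res = quantify_movie(movie, CHANNEL_KINDS)
        for ch in CHANNEL_KINDS:
            err = np.abs(res["traces"][ch].fraction - truth.fractions[ch])
            assert err.max() < 0.01

    def test_fraction_invariant_to_detector_gain(self):
        t = np.arange(0.0, 30.0, 0.5)
        d = 30.0 - 8.0 * np.exp(-t / 4.0)
        raw1 = synthetic_raw(t, d, background=5.0)
        raw3 = synthetic_raw(t, 3.0 * d, background=15.0)
        f1 = bound_trace(raw1, (20.0, 29.5)).fraction
        f3 = bound_trace(raw3, (20.0, 29.5)).fraction
        assert np.allclose(f1, f3)

    def test_short_reference_window_raises(self):
        t = np.arange(0.0, 10.0, 1.0)
        raw = synthetic_raw(t, np.full_like(t, 20.0))
        with pytest.raises(ValueError, match="reference window"):
            bound_trace(raw, (0.0, 1.0))

    def test_negative_reference_intensity_raises(self):
        t = np.arange(0.0, 10.0, 1.0)
        low = np.full_like(t, 2.0)
        raw = RawTraces(times=t, nucleus=low, foci_free=np.stack([low] * 2),
                        background=np.full_like(t, 5.0))
        with pytest.raises(ValueError, match="background exceeds"):
            bound_trace(raw, (0.0, 9.0))

    def test_peak_normalized_trace_tops_at_one_on_flat_plateau(self):
        # flat peak -> smoothing and raw max coincide, peak is exactly 1
        t = np.arange(0.0, 40.0, 0.5)
        d = np.where(t < 20, 30.0, 20.0)
        raw = synthetic_raw(t, d)
        tr = bound_trace(raw, (0.0, 19.5))
        assert tr.bound_norm.max() == pytest.approx(1.0, abs=1e-12)


@settings(derandomize=True, max_examples=25)
@given(gain=st.floats(0.2, 5.0), offset=st.floats(0.0, 50.0))
def test_normalized_bound_invariant_to_affine_intensity_changes(gain, offset):
    """nE_t survives any gain and any shared offset on B and C regions."""
    t = np.arange(0.0, 30.0, 0.5)
    d = 30.0 - 8.0 * np.exp(-t / 4.0)
    base = synthetic_raw(t, d, background=5.0)
    scaled = RawTraces(
        times=t,
        nucleus=gain * base.nucleus + offset,
        foci_free=gain * base.foci_free + offset,
        background=gain * base.background + offset,
    )
    ne0 = bound_trace(base, (20.0, 29.5)).bound_norm
    ne1 = bound_trace(scaled, (20.0, 29.5)).bound_norm
    assert np.allclose(ne0, ne1, atol=1e-9)


class TestAggregate:
    def make_trace(self, f):
        t = np.arange(len(f), dtype=float)
        f = np.asarray(f, dtype=float)
        from forkdyn.roi import BoundTrace

        return BoundTrace(times=t, diffuse=1 - f, total_ref=1.0, bound=f,
                          bound_norm=f, fraction=f, reference_window=(0, 1))

    def test_single_trace_aggregates_to_itself_with_zero_sd(self):
        tr = self.make_trace([0.1, 0.2, 0.3])
        agg = aggregate_cells([tr])
        assert np.allclose(agg["mean"], tr.fraction)
        assert np.allclose(agg["sd"], 0.0)
        assert (agg["n"] == 1).all()

    def test_mirrored_traces_average_to_zero(self):
        x = np.array([0.5, -0.2, 0.3])
        agg = aggregate_cells([self.make_trace(x), self.make_trace(-x)])
        assert np.allclose(agg["mean"], 0.0)

    def test_unequal_lengths_reported_per_frame(self):
        agg = aggregate_cells([self.make_trace([1.0, 1.0]), self.make_trace([3.0, 3.0, 3.0])])
        assert list(agg["n"]) == [2, 2, 1]
        assert np.allclose(agg["mean"], [2.0, 2.0, 3.0])

    def test_empty_list_raises(self):
        with pytest.raises(ValueError, match="no traces"):
            aggregate_cells([])


class TestRoiSetValidation:
    def test_region_outside_nucleus_rejected(self):
        shape = (64, 64)
        nucleus = ellipse_mask(shape, (32, 32), (15, 15))
        with pytest.raises(ValueError, match="leaves the nucleus"):
            ROISet(nucleus=nucleus, foci_free=[disk_mask(shape, (5, 5), 4.0)],
                   background=rect_mask(shape, (55, 55), (8, 8)))

    def test_background_overlapping_nucleus_rejected(self):
        shape = (64, 64)
        nucleus = ellipse_mask(shape, (32, 32), (15, 15))
        with pytest.raises(ValueError, match="overlaps"):
            ROISet(nucleus=nucleus, foci_free=[disk_mask(shape, (32, 32), 4.0)],
                   background=rect_mask(shape, (28, 28), (8, 8)))


class TestRoiFile:
    def test_json_round_trip_builds_equivalent_masks(self, tmp_path):
        from forkdyn.roi import load_rois, save_rois

        spec = {
            "nucleus": {"type": "ellipse", "center": [32, 32], "axes": [20, 24]},
            "foci_free": [
                {"type": "ellipse", "center": [32, 32], "axes": [4, 4]},
                {"type": "polygon",
                 "vertices": [[24, 20], [24, 30], [30, 30], [30, 20]]},
            ],
            "background": {"type": "rect", "top_left": [2, 2], "size": [8, 8]},
        }
        p = tmp_path / "rois.json"
        save_rois(spec, p)
        rois = load_rois(p, (64, 64))
        assert rois.nucleus.sum() == ellipse_mask((64, 64), (32, 32), (20, 24)).sum()
        assert len(rois.foci_free) == 2
        assert rois.foci_free[1].sum() >= 25  # polygon region rasterized
        assert rois.background.sum() == 64
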