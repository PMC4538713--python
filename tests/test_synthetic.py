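"""Phantom construction, motion scripts, and session simulation ground truth."""

import numpy as np
import pytest

from navmc.geometry import FRONTAL_CORTEX, motion_magnitude
from navmc.suvr import erode_mask, region_mean
from navmc.synthetic import (
    MotionScript,
    PhantomSpec,
    nod_slide_script,
    preset_session,
    simulate_session,
)


class TestPhantom:
    def test_masks_disjoint_and_nonempty(self, phantom):
        _, _, _, masks = phantom
        cortex, cereb = masks["cortex"], masks["cerebellum"]
        assert cortex.voxel_count > 0 and cereb.voxel_count > 0
        assert not (cortex.mask & cereb.mask).any()

    def test_activity_ratio_by_construction(self, phantom):
        # noise-free, unblurred phantom: region means are the set levels
        spec, pet, _, masks = phantom
        cx = region_mean(pet, erode_mask(masks["cortex"], 1))
        cb = region_mean(pet, erode_mask(masks["cerebellum"], 1))
        assert cx / cb == pytest.approx(2.6, rel=0.01)

    def test_mr_contrast_independent_of_activity(self, phantom):
        _, pet, mr, _ = phantom
        assert not np.allclose(pet.data, mr.data)

    def test_compartment_outside_head_rejected(self):
        with pytest.raises(ValueError, match="outside the head"):
            PhantomSpec(cerebellum_center=(0.0, -75.0, -40.0))

    def test_thin_shell_rejected(self):
        with pytest.raises(ValueError, match="shell thickness"):
            PhantomSpec(shell_thickness_mm=1.0)


class TestMotionScript:
    def test_identity_before_first_event(self):
        s = MotionScript(((100.0, [1, 0, 0, 0, 0, -2]),))
        assert np.allclose(s.params_at(50.0), 0.0)
        assert np.allclose(s.params_at(100.0), [1, 0, 0, 0, 0, -2])
        assert np.allclose(s.params_at(500.0), [1, 0, 0, 0, 0, -2])

    def test_linear_drift_interpolates(self):
        s = MotionScript(
            ((100.0, np.zeros(6)), (200.0, [0, 0, 0, 0, 0, -4.0])), interp="linear"
        )
        assert s.params_at(150.0)[5] == pytest.approx(-2.0)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            MotionScript(((100.0, np.zeros(6)), (100.0, np.zeros(6))))

    def test_nod_slide_scaled_to_requested_magnitude(self):
        for target in (4.0, 8.0, 11.0):
            script = nod_slide_script(target)
            assert script.max_magnitude() == pytest.approx(target, abs=0.01)

    def test_zero_magnitude_script_is_empty(self):
        assert nod_slide_script(0.0).events == ()
        assert nod_slide_script(0.0).max_magnitude() == 0.0


@pytest.fixture(scope="module")
def small_kwargs():
    # desk-size session: navigators only, two bursts of three
    return dict(
        nav_times_s=[73.0, 441.0],
        nav_count_per_burst=3,
        scan_start_s=0.0,
        scan_end_s=600.0,
        render_pet=False,
    )


class TestSimulateSession:
    def test_zero_motion_truth_is_identity(self, small_kwargs):
        sess = simulate_session(PhantomSpec(), MotionScript(()), seed=5, **small_kwargs)
        for burst in sess.true_nav_transforms:
            for t in burst:
                assert t.is_identity(tol=1e-12)

    def test_same_seed_bit_identical(self, small_kwargs):
        a = simulate_session(PhantomSpec(), MotionScript(()), seed=6, **small_kwargs)
        b = simulate_session(PhantomSpec(), MotionScript(()), seed=6, **small_kwargs)
        for va, vb in zip(a.all_navigators, b.all_navigators):
            assert np.array_equal(va.data, vb.data)

    def test_different_seed_differs(self, small_kwargs):
        a = simulate_session(PhantomSpec(), MotionScript(()), seed=6, **small_kwargs)
        b = simulate_session(PhantomSpec(), MotionScript(()), seed=7, **small_kwargs)
        assert not np.array_equal(a.navigators[0][0].data, b.navigators[0][0].data)

    def test_nav_outside_scan_rejected(self, small_kwargs):
        kw = dict(small_kwargs, nav_times_s=[73.0, 590.0])
        with pytest.raises(ValueError, match="scan window"):
            simulate_session(PhantomSpec(), MotionScript(()), seed=0, **kw)

    def test_single_step_pose_bookkeeping(self):
        """One 8 mm tz step between frames 3 and 4: poses split exactly."""
        step = MotionScript(((800.0, [0, 0, 0, 0, 0, -8.0]),))
        sess = simulate_session(
            PhantomSpec(),
            step,
            nav_times_s=[73, 441, 698, 876, 1412, 1947],
            nav_count_per_burst=1,
            scan_end_s=1980.0,
            render_pet=False,
            seed=1,
        )
        flat = [b[0] for b in sess.true_nav_transforms]
        for t in flat[:3]:
            assert t.is_identity(tol=1e-12)
        for t in flat[3:]:
            assert np.allclose(t.params, [0, 0, 0, 0, 0, -8.0], atol=1e-12)

    def test_event_at_scan_start_rejected(self, small_kwargs):
        s = MotionScript(((0.0, [0, 0, 0, 1, 0, 0]),))
        with pytest.raises(ValueError, match="identity"):
            simulate_session(PhantomSpec(), s, seed=0, **small_kwargs)


class TestPresetSession:
    def test_counts_and_structure(self, session_8mm):
        sess = session_8mm
        assert len(sess.all_navigators) == 60  # 6 bursts x 10
        assert len(sess.pet_frames) == 6
        assert len(sess.schedule.frames) == 6
        assert sess.motion_free_reference is not None

    def test_max_true_motion_matches_request(self, session_8mm):
        mags = [
            motion_magnitude(t, FRONTAL_CORTEX)
            for burst in session_8mm.true_nav_transforms
            for t in burst
        ]
        assert max(mags) == pytest.approx(8.0, abs=0.01)

    def test_frame_durations_match_midpoint_rule(self, session_8mm):
        assert list(session_8mm.schedule.durations_s) == [
            257.0, 312.5, 217.5, 357.0, 535.5, 300.5,
        ]

    def test_zero_motion_preset_has_identity_truth(self):
        sess = preset_session(seed=2, max_motion_mm=0.0, render_pet=False)
        for burst in sess.true_nav_transforms:
            for t in burst:
                assert t.is_identity(tol=1e-12)


def test_poisson_noise_variance_tracks_mean_over_duration():
    """Frame noise: var ~= mean / (duration * counts_scale), within 10%."""
    spec = PhantomSpec(shape=(32, 32, 16), voxel_mm=4.0)
    reps = []
    for seed in range(50):
        sess = simulate_session(
            spec,
            MotionScript(()),
            nav_times_s=[73.0],
            nav_count_per_burst=1,
            scan_end_s=300.0,
            nav_shape=(16, 16, 16),
            pet_counts_scale=0.5,
            seed=seed,
        )
        reps.append(sess.pet_frames[0].data)
    reps = np.array(reps)
    mean = reps.mean(axis=0)
    var = reps.var(axis=0)
    sel = mean > 0.5  # voxels with solid signal
    duration = sess.schedule.frames[0].duration_s
    expected = mean[sel] / (duration * 0.5)
    ratio = var[sel].sum() / expected.sum()
    assert ratio == pytest.approx(1.0, abs=0.10)
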