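"""Digital phantom and simulated navigator + PET sessions with ground truth.

The simulator stands in for patient data: it builds a piecewise-constant
ellipsoidal head phantom (cortical shell, white matter, cerebellum,
ventricle, scalp) with independent PET-activity and MR-contrast levels, and
renders a full acquisition session from it:

* **Navigators** — low-resolution MR volumes (default 64x64x36 grid at 3 mm
  isotropic) sampled in bursts at sparse time points, with additive Gaussian
  noise at a specified SNR and a small Gaussian blur emulating the finite
  EPI resolution.
* **PET frames** — the activity distribution under the frame's head pose,
  blurred by an isotropic Gaussian PSF (default 5 mm FWHM, the effective
  scanner + reconstruction-filter resolution), Poisson-sampled at a count
  level proportional to frame duration, and returned in activity units
  (decay-corrected frames: constant-activity ground truth).

Head pose over time follows a :class:`MotionScript` — piecewise-constant by
default, with an optional linear-drift interpolation mode — and every
rendered volume's true rigid transform is recorded, enabling
parameter-recovery tests of registration and correction.  Moved volumes are
sampled *analytically*: the image of the moved head at world point ``p`` is
the phantom evaluated at ``M^{-1}(p)``, so no interpolation error enters the
ground truth.  All randomness flows from a single seed; regenerating with
the same seed and spec is bit-identical.

The bundled preset emulates the study conditions of a 30-min amyloid
(PiB-like) PET/MR scan: six navigator bursts of ten volumes (30 s per
burst) at mean times 73, 441, 698, 876, 1412 and 1947 s, and a nod + slide
motion script (pitch steps plus inferior drift, the dominant head-motion
pattern in brain imaging) scaled to a requested maximum magnitude at the
frontal-cortex QC point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from . import geometry
from .framing import FrameSchedule, compute_frames
from .geometry import FRONTAL_CORTEX, RigidTransform, identity, make_rigid
from .io import TimingTable, Volume, grid_world_coords
from .suvr import RegionMask

__all__ = [
    "PhantomSpec",
    "MotionScript",
    "SessionTruth",
    "generate_phantom",
    "simulate_session",
    "navigator_pair",
    "nod_slide_script",
    "preset_session",
    "NAV_BURST_TIMES_S",
]

#: Mean navigator-burst start times (s after PET scan start) of the emulated
#: 30-min protocol.
NAV_BURST_TIMES_S = (73.0, 441.0, 698.0, 876.0, 1412.0, 1947.0)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

_COMPARTMENTS = ("ventricle", "cerebellum", "cortex", "white", "scalp", "background")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity levels of the ellipsoidal head phantom.

    All lengths in mm; activities in arbitrary kBq/mL-like units; MR levels
    in arbitrary signal units, independent of activity.  The default
    activities describe an amyloid-positive pattern with a cortex:cerebellum
    ratio of 2.6.
    """

    shape: tuple[int, int, int] = (128, 128, 63)
    voxel_mm: float = 2.0
    head_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    head_semiaxes: tuple[float, float, float] = (65.0, 80.0, 50.0)
    brain_semiaxes: tuple[float, float, float] = (58.0, 72.0, 46.0)
    shell_thickness_mm: float = 12.0
    cerebellum_center: tuple[float, float, float] = (0.0, -45.0, -22.0)
    cerebellum_semiaxes: tuple[float, float, float] = (22.0, 18.0, 14.0)
    ventricle_center: tuple[float, float, float] = (0.0, 10.0, 5.0)
    ventricle_semiaxes: tuple[float, float, float] = (15.0, 20.0, 10.0)
    activity: dict = field(
        default_factory=lambda: {
            "cortex": 2.6,
            "white": 1.5,
            "cerebellum": 1.0,
            "ventricle": 0.3,
            "scalp": 0.2,
            "background": 0.0,
        }
    )
    mr_contrast: dict = field(
        default_factory=lambda: {
            "cortex": 0.8,
            "white": 1.0,
            "cerebellum": 0.85,
            "ventricle": 0.3,
            "scalp": 0.6,
            "background": 0.0,
        }
    )

    def __post_init__(self) -> None:
        if self.shell_thickness_mm <= self.voxel_mm:
            raise ValueError("shell thickness must exceed the voxel size")
        if any(v < 0 for v in self.activity.values()):
            raise ValueError("activities must be non-negative")
        inner = np.asarray(self.brain_semiaxes) - self.shell_thickness_mm
        if np.any(inner <= 0):
            raise ValueError("shell thickness exceeds brain semi-axes")
        for name in ("brain", "cerebellum", "ventricle"):
            center, semi = self._ellipsoid(name)
            if not _ellipsoid_inside(
                center, semi, np.asarray(self.head_center), np.asarray(self.head_semiaxes)
            ):
                raise ValueError(f"{name} compartment extends outside the head")

    def _ellipsoid(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        if name == "head":
            return np.asarray(self.head_center), np.asarray(self.head_semiaxes)
        if name == "brain":
            return np.asarray(self.head_center), np.asarray(self.brain_semiaxes)
        if name == "brain_inner":
            return (
                np.asarray(self.head_center),
                np.asarray(self.brain_semiaxes) - self.shell_thickness_mm,
            )
        if name == "cerebellum":
            return np.asarray(self.cerebellum_center), np.asarray(self.cerebellum_semiaxes)
        if name == "ventricle":
            return np.asarray(self.ventricle_center), np.asarray(self.ventricle_semiaxes)
        raise KeyError(name)

    def labels_at(self, points: np.ndarray) -> np.ndarray:
        """Compartment index (into ``_COMPARTMENTS``) at ``(N, 3)`` world mm."""
        points = np.asarray(points, dtype=np.float32)
        out = np.full(points.shape[0], _COMPARTMENTS.index("background"), dtype=np.int8)
        head_idx = np.flatnonzero(_in_ellipsoid(points, *self._ellipsoid("head")))
        out[head_idx] = _COMPARTMENTS.index("scalp")
        # inner compartments only need evaluating on in-head points (~1/3 of grid)
        pts = points[head_idx]
        label = np.zeros(len(head_idx), dtype=np.int8)
        in_brain = _in_ellipsoid(pts, *self._ellipsoid("brain"))
        label[in_brain] = 1
        label[_in_ellipsoid(pts, *self._ellipsoid("brain_inner"))] = 2
        label[_in_ellipsoid(pts, *self._ellipsoid("cerebellum"))] = 3
        label[_in_ellipsoid(pts, *self._ellipsoid("ventricle"))] = 4
        lut = np.array(
            [
                _COMPARTMENTS.index("scalp"),
                _COMPARTMENTS.index("cortex"),
                _COMPARTMENTS.index("white"),
                _COMPARTMENTS.index("cerebellum"),
                _COMPARTMENTS.index("ventricle"),
            ],
            dtype=np.int8,
        )
        out[head_idx] = lut[label]
        return out

    def sample(self, points: np.ndarray, levels: dict) -> np.ndarray:
        """Piecewise-constant intensity at ``(N, 3)`` world points."""
        lut = np.array([levels[c] for c in _COMPARTMENTS], dtype=float)
        return lut[self.labels_at(points)]

    def grid_affine(self, shape=None, voxel_mm=None) -> np.ndarray:
        """Voxel->world affine for a grid centred on the world origin."""
        shape = np.asarray(self.shape if shape is None else shape)
        voxel = self.voxel_mm if voxel_mm is None else voxel_mm
        affine = np.diag([voxel, voxel, voxel, 1.0])
        affine[:3, 3] = -voxel * (shape - 1) / 2.0
        return affine


def _in_ellipsoid(points: np.ndarray, center: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    # column-wise accumulation avoids (N, 3) temporaries on million-point grids
    q = np.square((points[:, 0] - center[0]) / semiaxes[0])
    q += np.square((points[:, 1] - center[1]) / semiaxes[1])
    q += np.square((points[:, 2] - center[2]) / semiaxes[2])
    return q <= 1.0


def _ellipsoid_inside(center, semiaxes, out_center, out_semiaxes, n: int = 512) -> bool:
    """Every surface point of the inner ellipsoid lies inside the outer one."""
    rng = np.random.default_rng(0)  # fixed probe directions; pure geometry check
    dirs = rng.standard_normal((n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    surface = center + dirs * semiaxes
    rel = (surface - out_center) / out_semiaxes
    return bool(np.all(np.einsum("ij,ij->i", rel, rel) <= 1.0 + 1e-12))


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, Volume, dict[str, RegionMask]]:
    """Render the phantom on its grid.

    Returns ``(pet_truth, mr_truth, masks)`` where the masks cover cortex,
    cerebellum, ventricle, white matter and background on the same grid.
    """
    affine = spec.grid_affine()
    probe = Volume(np.zeros(spec.shape, dtype=np.float32), affine)
    pts = probe.grid_world_coords()
    labels = spec.labels_at(pts).reshape(spec.shape)
    act_lut = np.array([spec.activity[c] for c in _COMPARTMENTS], dtype=np.float32)
    mr_lut = np.array([spec.mr_contrast[c] for c in _COMPARTMENTS], dtype=np.float32)
    pet = Volume(act_lut[labels], affine, label="pet_truth")
    mr = Volume(mr_lut[labels], affine, label="mr_truth")
    masks = {
        name: RegionMask(labels == _COMPARTMENTS.index(name), name)
        for name in ("cortex", "cerebellum", "ventricle", "white", "background")
    }
    return pet, mr, masks


@dataclass(frozen=True)
class MotionScript:
    """Head pose over time: piecewise-constant steps or linear drift.

    ``events`` is a list of ``(time_s, params)`` with strictly increasing
    times; the pose before the first event is identity.  With
    ``interp="step"`` the pose jumps to each event's parameters at its time;
    with ``interp="linear"`` parameters ramp linearly between events
    (drift), staying at the last event's pose afterwards.
    """

    events: tuple = ()
    interp: str = "step"

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if self.interp not in ("step", "linear"):
            raise ValueError("interp must be 'step' or 'linear'")
        events = tuple((float(t), np.asarray(p, dtype=float)) for t, p in self.events)
        for _, p in events:
            if p.shape != (6,) or not np.all(np.isfinite(p)):
                raise ValueError("each event needs 6 finite parameters")
        object.__setattr__(self, "events", events)

    def params_at(self, time_s: float) -> np.ndarray:
        if not self.events:
            return np.zeros(6)
        times = np.array([t for t, _ in self.events])
        if time_s < times[0]:
            return np.zeros(6)
        if self.interp == "step" or time_s >= times[-1]:
            idx = int(np.searchsorted(times, time_s, side="right")) - 1
            return self.events[idx][1].copy()
        idx = int(np.searchsorted(times, time_s, side="right")) - 1
        t0, p0 = self.events[idx]
        t1, p1 = self.events[idx + 1]
        w = (time_s - t0) / (t1 - t0)
        return (1 - w) * p0 + w * p1

    def pose_at(self, time_s: float) -> RigidTransform:
        """Rigid transform (reference -> moved coordinates) at ``time_s``."""
        return make_rigid(self.params_at(time_s))

    def max_magnitude(self, ref=FRONTAL_CORTEX) -> float:
        """Largest event-pose motion magnitude at ``ref``."""
        if not self.events:
            return 0.0
        return max(geometry.motion_magnitude(make_rigid(p), ref) for _, p in self.events)


@dataclass
class SessionTruth:
    """A simulated session with full ground truth.

    ``navigators`` is a list of bursts, each a list of navigator
    :class:`Volume` objects with acquisition times; ``true_nav_transforms``
    mirrors that structure and gives each navigator's pose *relative to the
    first navigator of the session* (the registration reference), so the
    first entry is identity.  ``true_frame_transforms`` gives each PET
    frame's pose relative to frame 1.
    """

    navigators: list[list[Volume]]
    nav_times_s: list[list[float]]
    pet_frames: list[Volume]
    schedule: FrameSchedule
    timing: TimingTable
    true_nav_transforms: list[list[RigidTransform]]
    true_frame_transforms: list[RigidTransform]
    motion_free_reference: Volume | None
    masks: dict[str, RegionMask]
    phantom_spec: PhantomSpec
    script: MotionScript
    seed: int

    @property
    def all_navigators(self) -> list[Volume]:
        return [v for burst in self.navigators for v in burst]


def _render_moved(
    spec: PhantomSpec,
    levels: dict,
    pose: RigidTransform,
    shape,
    blur_sigma_mm: float,
    voxel_mm: float,
    grid_pts: np.ndarray,
) -> np.ndarray:
    """Image of the phantom moved by ``pose``, on the given grid, blurred.

    The moved image at world point p equals the reference phantom at
    ``pose^{-1}(p)``; the phantom is evaluated analytically there, so no
    interpolation error enters the ground truth.  ``grid_pts`` are the
    grid's voxel-centre world coordinates (precomputed once per grid).
    """
    inv = geometry.invert(pose)
    rot32 = inv.rotation.astype(np.float32)
    back = np.asarray(grid_pts, dtype=np.float32) @ rot32.T
    back += inv.translation.astype(np.float32)
    img = spec.sample(back, levels).reshape(shape).astype(np.float32)
    if blur_sigma_mm > 0:
        img = ndimage.gaussian_filter(img, blur_sigma_mm / voxel_mm)
    return img


def simulate_session(
    spec: PhantomSpec,
    script: MotionScript,
    nav_times_s=NAV_BURST_TIMES_S,
    nav_count_per_burst: int = 10,
    burst_duration_s: float = 30.0,
    scan_start_s: float = 0.0,
    scan_end_s: float = 1980.0,
    nav_shape: tuple[int, int, int] = (64, 64, 36),
    nav_voxel_mm: float = 3.0,
    nav_snr: float = 20.0,
    nav_blur_fwhm_mm: float = 4.0,
    pet_counts_scale: float = 0.5,
    psf_fwhm_mm: float = 5.0,
    intra_frame_poses: int = 1,
    render_pet: bool = True,
    seed: int = 0,
) -> SessionTruth:
    """Simulate a full navigator + PET session.

    Parameters
    ----------
    nav_times_s:
        Burst start times (s); every burst must lie inside the scan window.
    nav_snr:
        Mean in-head navigator signal divided by the Gaussian noise sigma.
    pet_counts_scale:
        Expected counts per voxel per second per activity unit; sets the
        Poisson noise level of the frames (~5% relative noise in cortex for
        a 5-min frame at the default).
    intra_frame_poses:
        1 (default) renders each frame at the single pose holding at its
        navigator's start time (the negligible-intra-frame-motion
        assumption); >1 averages that many sub-poses across the frame,
        deliberately violating the assumption for robustness tests.
    render_pet:
        False skips PET frames and the motion-free reference (navigator-only
        sessions, e.g. for registration and burst-noise studies).
    """
    nav_times_s = np.asarray(nav_times_s, dtype=float)
    if nav_times_s.size == 0:
        raise ValueError("at least one navigator burst is required")
    if np.any(nav_times_s < scan_start_s) or np.any(
        nav_times_s + burst_duration_s > scan_end_s
    ):
        raise ValueError("navigator bursts must lie inside the scan window")
    if nav_count_per_burst < 1:
        raise ValueError("nav_count_per_burst must be >= 1")
    if script.events and script.events[0][0] <= scan_start_s:
        raise ValueError("pose at scan start must be identity (no event at/before start)")

    rng = np.random.default_rng(seed)
    schedule = compute_frames(nav_times_s, scan_start_s, scan_end_s)
    nav_affine = spec.grid_affine(nav_shape, nav_voxel_mm)
    pet_affine = spec.grid_affine()
    nav_pts = grid_world_coords(nav_shape, nav_affine).astype(np.float32)
    pet_pts = grid_world_coords(spec.shape, pet_affine).astype(np.float32)
    nav_sigma_mm = nav_blur_fwhm_mm * FWHM_TO_SIGMA
    psf_sigma_mm = psf_fwhm_mm * FWHM_TO_SIGMA

    # Piecewise-constant motion means few unique poses; render each once and
    # only the noise differs between repeats (e.g. the 10 navigators of a burst).
    render_cache: dict[tuple, np.ndarray] = {}

    def render(levels_key: str, pose: RigidTransform, grid: str) -> np.ndarray:
        key = (levels_key, grid, pose.params.tobytes())
        if key not in render_cache:
            if grid == "nav":
                render_cache[key] = _render_moved(
                    spec, spec.mr_contrast, pose, nav_shape, nav_sigma_mm,
                    nav_voxel_mm, nav_pts,
                )
            else:
                render_cache[key] = _render_moved(
                    spec, spec.activity, pose, spec.shape, psf_sigma_mm,
                    spec.voxel_mm, pet_pts,
                )
        return render_cache[key]

    # Noise sigma from the noise-free reference navigator's in-head mean.
    ref_nav = render("mr", identity(), "nav")
    head_mask = ref_nav > 0.1 * ref_nav.max()
    noise_sigma = float(ref_nav[head_mask].mean()) / nav_snr

    first_pose: RigidTransform | None = None
    navigators: list[list[Volume]] = []
    nav_times_out: list[list[float]] = []
    true_nav: list[list[RigidTransform]] = []
    spacing = burst_duration_s / nav_count_per_burst
    for b, t0 in enumerate(nav_times_s):
        burst: list[Volume] = []
        times: list[float] = []
        transforms: list[RigidTransform] = []
        for j in range(nav_count_per_burst):
            t = float(t0 + j * spacing)
            pose = script.pose_at(t)
            if first_pose is None:
                first_pose = pose
            img = render("mr", pose, "nav")
            img = img + rng.normal(0.0, noise_sigma, size=img.shape).astype(np.float32)
            burst.append(
                Volume(img.astype(np.float32), nav_affine, frame_start=t,
                       frame_duration=spacing, label=f"nav{b + 1}_{j + 1}")
            )
            times.append(t)
            transforms.append(
                geometry.compose(pose, geometry.invert(first_pose))
            )
        navigators.append(burst)
        nav_times_out.append(times)
        true_nav.append(transforms)

    frame_ref_pose: RigidTransform | None = None
    pet_frames: list[Volume] = []
    true_frames: list[RigidTransform] = []
    frames_iter = schedule.frames if render_pet else ()
    for i, frame in enumerate(frames_iter):
        nav_t = float(nav_times_s[i])
        if intra_frame_poses <= 1:
            pose = script.pose_at(nav_t)
            lam = render("pet", pose, "pet")
        else:
            sub = np.linspace(frame.start_s, frame.end_s, intra_frame_poses + 2)[1:-1]
            lam = np.mean(
                [render("pet", script.pose_at(t), "pet") for t in sub], axis=0
            ).astype(np.float32)
            pose = script.pose_at(nav_t)
        if frame_ref_pose is None:
            frame_ref_pose = pose
        scale = frame.duration_s * pet_counts_scale
        counts = rng.poisson(np.clip(lam, 0, None) * scale)
        data = (counts / scale).astype(np.float32)
        pet_frames.append(
            Volume(data, pet_affine, frame_start=frame.start_s,
                   frame_duration=frame.duration_s, label=f"frame{i + 1}")
        )
        true_frames.append(geometry.compose(pose, geometry.invert(frame_ref_pose)))

    motion_free = None
    if render_pet:
        motion_free = Volume(
            render("pet", identity(), "pet").copy(),
            pet_affine,
            label="motion_free_reference",
        )
    _, _, masks = generate_phantom(spec)

    rows = [("scan", "scan", scan_start_s, scan_end_s - scan_start_s)]
    rows += [
        (f"nav{b + 1}", "navigator_burst", float(t), burst_duration_s)
        for b, t in enumerate(nav_times_s)
    ]
    rows += [
        (f"frame{i + 1}", "pet_frame", f.start_s, f.duration_s)
        for i, f in enumerate(schedule.frames)
    ]
    timing = TimingTable(
        pd.DataFrame(rows, columns=["label", "kind", "start_s", "duration_s"])
    )

    return SessionTruth(
        navigators=navigators,
        nav_times_s=nav_times_out,
        pet_frames=pet_frames,
        schedule=schedule,
        timing=timing,
        true_nav_transforms=true_nav,
        true_frame_transforms=true_frames,
        motion_free_reference=motion_free,
        masks=masks,
        phantom_spec=spec,
        script=script,
        seed=seed,
    )


def navigator_pair(
    params,
    spec: PhantomSpec | None = None,
    nav_shape: tuple[int, int, int] = (64, 64, 36),
    nav_voxel_mm: float = 3.0,
    nav_snr: float = 20.0,
    nav_blur_fwhm_mm: float = 4.0,
    seed: int = 0,
) -> tuple[Volume, Volume, RigidTransform]:
    """One fixed/moving navigator pair with a known rigid pose.

    Returns ``(fixed, moving, truth)`` where ``fixed`` is the phantom at the
    reference pose, ``moving`` the phantom moved by ``make_rigid(params)``,
    both with independent Gaussian noise at ``nav_snr``.  Registration of
    ``moving`` to ``fixed`` should recover ``truth``.
    """
    spec = spec or PhantomSpec()
    pose = make_rigid(params)
    affine = spec.grid_affine(nav_shape, nav_voxel_mm)
    pts = grid_world_coords(nav_shape, affine).astype(np.float32)
    sigma_mm = nav_blur_fwhm_mm * FWHM_TO_SIGMA
    rng = np.random.default_rng(seed)
    ref = _render_moved(spec, spec.mr_contrast, identity(), nav_shape, sigma_mm,
                        nav_voxel_mm, pts)
    mov = _render_moved(spec, spec.mr_contrast, pose, nav_shape, sigma_mm,
                        nav_voxel_mm, pts)
    noise = float(ref[ref > 0.1 * ref.max()].mean()) / nav_snr
    fixed = Volume(
        (ref + rng.normal(0, noise, ref.shape)).astype(np.float32), affine, label="fixed"
    )
    moving = Volume(
        (mov + rng.normal(0, noise, mov.shape)).astype(np.float32), affine, label="moving"
    )
    return fixed, moving, pose


def nod_slide_script(max_magnitude_mm: float, ref=FRONTAL_CORTEX) -> MotionScript:
    """Nod + inferior-slide motion script scaled to a target magnitude.

    The script steps through four poses between navigator bursts, each a
    combination of negative pitch (chin-down nod, which displaces the
    frontal-cortex point inferiorly) and negative-z translation (sliding
    down out of the scanner), growing to a final pose whose motion magnitude
    at ``ref`` equals ``max_magnitude_mm``.
    """
    if max_magnitude_mm < 0:
        raise ValueError("max_magnitude_mm must be >= 0")
    if max_magnitude_mm == 0:
        return MotionScript(())
    shape = np.array([-1.0, 0.0, 0.0, 0.0, 0.0, -1.0])  # unit nod + unit slide
    times = (300.0, 600.0, 1000.0, 1500.0)
    fractions = (0.25, 0.5, 0.75, 1.0)

    def mag(s: float) -> float:
        return geometry.motion_magnitude(make_rigid(shape * s), ref)

    hi = max_magnitude_mm  # mag(s) >= s for this shape, so the root is below
    scale = optimize.brentq(lambda s: mag(s) - max_magnitude_mm, 0.0, hi, xtol=1e-10)
    events = tuple((t, shape * scale * f) for t, f in zip(times, fractions))
    return MotionScript(events)


def preset_session(seed: int, max_motion_mm: float = 8.0, **overrides) -> SessionTruth:
    """Convenience preset emulating the 30-min sparse-navigator protocol.

    Six bursts of ten navigators at the mean burst times, a 1980 s scan
    window (extended past 30 min so the late sixth burst lies inside), and a
    nod + slide script with the requested maximum motion magnitude at the
    frontal-cortex point (default 8 mm).  ``overrides`` are forwarded to
    :func:`simulate_session`.
    """
    spec = overrides.pop("spec", PhantomSpec())
    script = nod_slide_script(max_motion_mm)
    return simulate_session(spec, script, seed=seed, **overrides)
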