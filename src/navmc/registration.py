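"""Rigid registration of navigator volumes to a reference navigator.

Each navigator is registered to the first navigator of the session with a
6-parameter rigid transform.  The returned transform maps fixed-space world
points to moving-space sample locations — which, for a moving head imaged at
a later time, equals the head-motion transform itself (reference pose ->
moved pose), so its motion magnitude at a reference point is the measured
displacement of that anatomical point.

Method
------
* Similarity metric: normalised cross-correlation (NCC, default; invariant
  to global intensity scaling between EPI volumes) or SSD, evaluated by
  trilinear interpolation of the moving image at transformed fixed-voxel
  positions.  Voxels falling outside the moving FOV are excluded from the
  metric, and a candidate transform is rejected outright if less than a
  quarter of the fixed voxels remain in overlap.
* Multi-resolution: a Gaussian pyramid (default subsampling factors 4, 2,
  1) for capture range and speed.
* Optimiser: deterministic coordinate search over the six parameters with
  shrinking steps (no gradients, no randomness by default).  At each step
  size the six axes are swept in fixed order, accepting only improvements,
  until a sweep yields none; the step is then halved down to the
  convergence tolerance.  The optimiser never returns a transform with a
  worse metric than its initialisation, and the identity is always kept as
  a candidate.
* Both images are pre-smoothed slightly before metric evaluation (at the
  finest level as well): estimating on raw noisy images biases intensity
  metrics toward off-grid poses, because sub-voxel trilinear interpolation
  averages the moving image's noise and spuriously improves the metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import RigidTransform, make_rigid
from .io import Volume

__all__ = ["RegistrationConfig", "RegistrationResult", "register_rigid", "register_burst"]


@dataclass(frozen=True)
class RegistrationConfig:
    """Settings for :func:`register_rigid`.

    ``param_scales`` multiplies the common step size per parameter; with the
    default of ones a 1-unit step means 1 degree on rotations and 1 mm on
    translations, which are comparable displacements at the ~60 mm head
    radius.  ``seed`` only matters when ``n_perturbations > 0`` (optional
    random restarts around the identity).
    """

    metric: str = "ncc"
    pyramid_levels: int = 3
    max_iter: int = 100
    convergence_tol: float = 0.01
    initial_step: float = 2.0
    param_scales: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    min_overlap: float = 0.25
    max_metric_points: int = 20000
    seed: int | None = None
    n_perturbations: int = 0

    def __post_init__(self) -> None:
        if self.metric not in ("ncc", "ssd"):
            raise ValueError("metric must be 'ncc' or 'ssd'")
        if self.pyramid_levels < 1 or self.max_iter < 1:
            raise ValueError("pyramid_levels and max_iter must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")


@dataclass
class RegistrationResult:
    """Outcome of a rigid registration."""

    transform: RigidTransform
    final_metric: float
    converged: bool
    iterations: list[int]

    @property
    def params(self) -> np.ndarray:
        return self.transform.params


def _check_volume(v: Volume, role: str) -> None:
    if min(v.shape) < 16:
        raise ValueError(f"{role} volume needs >= 16 voxels per axis, got {v.shape}")
    data = v.data
    if float(data.max()) == float(data.min()):
        raise ValueError(f"{role} volume is constant-intensity; metric undefined")


def _pyramid_level(
    vol: Volume, factor: int, base_sigma: float = 0.8
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth-and-subsample one pyramid level; returns (data, affine).

    Every level — including the finest — is smoothed slightly
    (``base_sigma`` voxels).  Estimating on smoothed images suppresses the
    interpolation-noise bias of intensity metrics, where sub-voxel sample
    positions average away moving-image noise and spuriously improve the
    metric at slightly rotated poses.
    """
    sigma = base_sigma if factor == 1 else factor / 2.0
    data = ndimage.gaussian_filter(np.asarray(vol.data, dtype=np.float32), sigma=sigma)
    if factor == 1:
        return data, vol.affine
    data = data[::factor, ::factor, ::factor]
    scale = np.diag([factor, factor, factor, 1.0]).astype(float)
    return data, vol.affine @ scale


class _MetricEvaluator:
    """NCC/SSD between a fixed level and the moving level under a transform.

    The metric is evaluated only at fixed voxels carrying signal (above a
    low intensity threshold, slightly dilated): background voxels contain
    pure noise and would both dilute the metric and triple its cost.
    """

    def __init__(self, fixed: np.ndarray, fixed_affine: np.ndarray,
                 moving: np.ndarray, moving_affine: np.ndarray,
                 metric: str, min_overlap: float,
                 max_points: int | None = None) -> None:
        hi = float(np.percentile(fixed, 99.5))
        sel = fixed > 0.25 * hi
        sel = ndimage.binary_dilation(sel, iterations=2)
        if sel.sum() < 0.05 * sel.size or hi <= 0:  # near-uniform image
            sel = np.ones(fixed.shape, dtype=bool)
        idx = np.argwhere(sel).T.astype(np.float64)
        pts = np.ascontiguousarray((fixed_affine[:3, :3] @ idx).T + fixed_affine[:3, 3])
        vals = fixed[sel].astype(np.float64)
        if max_points is not None and len(vals) > max_points:
            stride = int(np.ceil(len(vals) / max_points))
            pts, vals = pts[::stride].copy(), vals[::stride].copy()
        self.fixed_pts = pts
        self.fixed_vals = vals
        self.moving = np.asarray(moving, dtype=np.float32)
        self.inv_moving = np.linalg.inv(moving_affine)
        self.metric = metric
        self.min_overlap = min_overlap
        self.shape = np.array(moving.shape, dtype=float)
        self.n_evals = 0

    def __call__(self, params: np.ndarray) -> float:
        self.n_evals += 1
        t = make_rigid(params)
        pts = self.fixed_pts @ t.rotation.T + t.translation
        vox = pts @ self.inv_moving[:3, :3].T + self.inv_moving[:3, 3]
        valid = np.all((vox >= 0) & (vox <= self.shape - 1), axis=1)
        if valid.sum() < self.min_overlap * valid.size:
            return np.inf
        sampled = ndimage.map_coordinates(
            self.moving, vox[valid].T, order=1, mode="constant", cval=0.0, prefilter=False
        )
        f = self.fixed_vals[valid]
        if self.metric == "ssd":
            return float(np.mean((sampled - f) ** 2))
        fs = f - f.mean()
        ms = sampled - sampled.mean()
        denom = np.sqrt((fs @ fs) * (ms @ ms))
        if denom == 0:
            return np.inf
        return 1.0 - float((fs @ ms) / denom)


def _coordinate_search(
    fun, params: np.ndarray, initial_step: float, tol: float,
    scales: np.ndarray, max_iter: int,
) -> tuple[np.ndarray, float, int, bool]:
    """Shrinking-step coordinate descent; deterministic axis order."""
    best = fun(params)
    step = initial_step
    sweeps = 0
    converged = True
    while step >= tol:
        improved = True
        while improved:
            if sweeps >= max_iter:
                converged = False
                break
            improved = False
            sweeps += 1
            for axis in range(6):
                for sign in (1.0, -1.0):
                    cand = params.copy()
                    cand[axis] += sign * step * scales[axis]
                    val = fun(cand)
                    if val < best:
                        best, params = val, cand
                        improved = True
                        break  # take the first improving direction on this axis
        if not converged:
            break
        step /= 2.0
    return params, best, sweeps, converged


def register_rigid(moving: Volume, fixed: Volume, cfg: RegistrationConfig | None = None
                   ) -> RegistrationResult:
    """Estimate the rigid transform aligning ``moving`` to ``fixed``.

    The result's transform maps fixed-space world coordinates to the
    corresponding sample location in the moving volume; resampling the
    moving volume through it reproduces the fixed view.  The final metric is
    never worse than the metric of the identity transform.
    """
    cfg = cfg or RegistrationConfig()
    _check_volume(fixed, "fixed")
    _check_volume(moving, "moving")

    factors = [2 ** (cfg.pyramid_levels - 1 - i) for i in range(cfg.pyramid_levels)]
    scales = np.asarray(cfg.param_scales, dtype=float)
    params = np.zeros(6)
    rng = np.random.default_rng(cfg.seed) if cfg.n_perturbations else None

    final_metric = np.inf
    iterations: list[int] = []
    converged = True
    for li, factor in enumerate(factors):
        fdata, faff = _pyramid_level(fixed, factor)
        mdata, maff = _pyramid_level(moving, factor)
        if min(fdata.shape) < 4:
            iterations.append(0)
            continue
        ev = _MetricEvaluator(fdata, faff, mdata, maff, cfg.metric, cfg.min_overlap,
                              cfg.max_metric_points)
        if not np.isfinite(ev(np.zeros(6))):
            raise ValueError("fixed and moving volumes do not overlap in world space")
        # keep identity as a candidate so the final metric never beats it backwards
        if ev(params) > ev(np.zeros(6)):
            params = np.zeros(6)
        starts = [params]
        if rng is not None and li == 0:
            starts += [params + rng.normal(0, 2.0, 6) for _ in range(cfg.n_perturbations)]
        step0 = cfg.initial_step * factor
        # coarse levels stop at a quarter-unit step; the finest level
        # shrinks the step down to the convergence tolerance
        tol = cfg.convergence_tol if factor == 1 else max(0.25 * factor,
                                                          cfg.convergence_tol)
        best_p, best_v, n_sw = params, np.inf, 0
        for s0 in starts:
            p, v, sw, conv = _coordinate_search(ev, np.asarray(s0, float), step0,
                                                tol, scales, cfg.max_iter)
            n_sw += sw
            if v < best_v:
                best_p, best_v = p, v
                converged = converged and conv
        params, final_metric = best_p, best_v
        iterations.append(n_sw)

    return RegistrationResult(
        transform=make_rigid(params),
        final_metric=float(final_metric),
        converged=converged,
        iterations=iterations,
    )


def register_burst(burst: list[Volume], fixed: Volume,
                   cfg: RegistrationConfig | None = None) -> list[RegistrationResult]:
    """Register every volume of a navigator burst to the same fixed reference.

    Volumes are registered independently; a failure on one volume is
    re-raised with its burst index.
    """
    if not burst:
        raise ValueError("burst must contain at least one volume")
    results = []
    for i, vol in enumerate(burst):
        try:
            results.append(register_rigid(vol, fixed, cfg))
        except ValueError as exc:
            raise ValueError(f"burst volume {i}: {exc}") from exc
    return results
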