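"""Motion QC: traces, intra-burst noise spread, and the MC-trigger decision.

The QC products mirror clinical practice with sparse navigators: plot the
motion magnitude of each navigator (relative to the first) at the
frontal-cortex point and at the scanner centre of FOV, check that the ten
navigators within each 30-s burst agree to well under a millimetre (any
larger intra-burst spread indicates registration noise rather than motion),
and recommend frame-based motion correction when the maximum magnitude at
the frontal-cortex point strictly exceeds 4 mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .geometry import CFOV, FRONTAL_CORTEX, ReferencePoint, RigidTransform, identity
from .registration import RegistrationResult

__all__ = [
    "TraceEntry",
    "MotionTrace",
    "QCReport",
    "build_trace",
    "burst_spread",
    "decide_mc",
    "plot_trace",
    "MC_THRESHOLD_MM",
]

#: Maximum motion magnitude (mm, frontal-cortex point) above which
#: frame-based motion correction is recommended.
MC_THRESHOLD_MM = 4.0

DEFAULT_POINTS = (FRONTAL_CORTEX, CFOV)


@dataclass(frozen=True)
class TraceEntry:
    time_s: float
    transform: RigidTransform
    magnitudes_mm: dict


@dataclass(frozen=True)
class MotionTrace:
    """Per-navigator transforms and motion magnitudes at named points.

    The first entry is the reference navigator: identity transform, zero
    magnitudes.  Times are non-decreasing.
    """

    entries: tuple[TraceEntry, ...]
    reference_label: str = "nav1"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("trace must contain at least the reference entry")
        times = [e.time_s for e in self.entries]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("trace times must be non-decreasing")
        first = self.entries[0]
        if not first.transform.is_identity(tol=1e-9):
            raise ValueError("first trace entry must be the identity reference")

    def magnitudes(self, point_name: str) -> np.ndarray:
        return np.array([e.magnitudes_mm[point_name] for e in self.entries])

    def max_magnitude(self, point_name: str = FRONTAL_CORTEX.name) -> float:
        return float(self.magnitudes(point_name).max())

    @property
    def times_s(self) -> np.ndarray:
        return np.array([e.time_s for e in self.entries])


@dataclass(frozen=True)
class QCReport:
    """Motion QC summary for one session."""

    max_magnitude_mm: dict
    mc_recommended: bool
    threshold_mm: float = MC_THRESHOLD_MM
    burst_spread_mm: list | None = None
    notes: str = ""


def build_trace(
    results: list[RegistrationResult],
    times_s,
    points: tuple[ReferencePoint, ...] = DEFAULT_POINTS,
    reference_time_s: float | None = None,
    reference_label: str = "nav1",
) -> MotionTrace:
    """Assemble a motion trace from registration results.

    An identity entry for the reference navigator is prepended at
    ``reference_time_s`` (default: the first result's time, or 0 when there
    are no results).  ``results`` and ``times_s`` must have equal lengths
    and sorted times.
    """
    times_s = [float(t) for t in np.atleast_1d(np.asarray(times_s, dtype=float))]
    if len(results) != len(times_s):
        raise ValueError(f"{len(results)} results but {len(times_s)} times")
    if reference_time_s is None:
        reference_time_s = times_s[0] if times_s else 0.0
    if times_s and reference_time_s > times_s[0]:
        raise ValueError("reference time must not exceed the first result time")

    def mags(t: RigidTransform) -> dict:
        return {p.name: geometry.motion_magnitude(t, p) for p in points}

    entries = [TraceEntry(float(reference_time_s), identity(), mags(identity()))]
    for res, t in zip(results, times_s):
        entries.append(TraceEntry(t, res.transform, mags(res.transform)))
    return MotionTrace(tuple(entries), reference_label)


def burst_spread(
    burst_results: list[RegistrationResult],
    point: ReferencePoint = FRONTAL_CORTEX,
) -> float:
    """Registration-noise spread within one navigator burst (mm).

    Each burst transform is referred to the burst's own first navigator
    (``invert(T_first) ∘ ... `` composed with ``T_k``), isolating
    navigator-to-navigator registration noise from real inter-burst motion;
    the spread is the largest resulting motion magnitude at ``point``.
    """
    if len(burst_results) < 2:
        raise ValueError("burst spread needs at least 2 registration results")
    first_inv = geometry.invert(burst_results[0].transform)
    return max(
        geometry.motion_magnitude(geometry.compose(r.transform, first_inv), point)
        for r in burst_results
    )


def decide_mc(
    trace: MotionTrace,
    threshold_mm: float = MC_THRESHOLD_MM,
    burst_spread_mm: list | None = None,
    notes: str = "",
) -> QCReport:
    """Recommend motion correction iff the maximum motion magnitude at the
    frontal-cortex point strictly exceeds ``threshold_mm``."""
    point_names = trace.entries[0].magnitudes_mm.keys()
    max_mag = {name: trace.max_magnitude(name) for name in point_names}
    recommended = max_mag[FRONTAL_CORTEX.name] > threshold_mm
    return QCReport(
        max_magnitude_mm=max_mag,
        mc_recommended=bool(recommended),
        threshold_mm=float(threshold_mm),
        burst_spread_mm=burst_spread_mm,
        notes=notes,
    )


def plot_trace(trace: MotionTrace, path=None, title: str = "Motion magnitude"):
    """Plot motion magnitude over time per reference point.

    The frontal-cortex curve is drawn red and the cFOV curve purple (cortex
    motion vs centre-of-FOV motion); other points cycle default colors.
    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {FRONTAL_CORTEX.name: "red", CFOV.name: "purple"}
    fig, ax = plt.subplots(figsize=(7, 3.5))
    for name in trace.entries[0].magnitudes_mm:
        ax.plot(
            trace.times_s,
            trace.magnitudes(name),
            marker=".",
            color=colors.get(name),
            label=name,
        )
    ax.axhline(MC_THRESHOLD_MM, ls="--", lw=0.8, color="gray")
    ax.set_xlabel("time after scan start (s)")
    ax.set_ylabel("motion magnitude (mm)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
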