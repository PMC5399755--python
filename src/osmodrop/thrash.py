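"""Thrash counting: the swimming-speed measure of the droplet assay.

One thrash is one curving of the worm body toward either side.  The
per-frame *bend signal* operationalizes "curving": the signed angle
between the equivalent-ellipse major axis of the anterior half of the
silhouette and that of the posterior half, the halves split at the
centroid along the whole-body major axis.  Thrashes are counted as
hysteretic sign alternations of that signal (Schmitt trigger), i.e. two
counts per full undulation cycle, binned per minute like turns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import FrameStack
from .shape import (DegenerateShapeError, EmptyMaskError,
                    fit_equivalent_ellipse, segment_frame)

DEFAULT_HYSTERESIS_RAD = 0.2


@dataclass
class BendSignal:
    """Signed per-frame body-bend angle (radians); NaN where flagged."""

    time_s: np.ndarray
    bend: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.bend = np.asarray(self.bend, dtype=float)
        if self.time_s.shape != self.bend.shape:
            raise ValueError("time_s and bend must have equal length")


def _axis_angle_diff(a: float, b: float) -> float:
    """Signed difference between two axial angles, wrapped to (−π/2, π/2]."""
    d = a - b
    while d <= -np.pi / 2:
        d += np.pi
    while d > np.pi / 2:
        d -= np.pi
    return d


def bending_signal(stack: FrameStack, policy: str = "otsu",
                   threshold: float | None = None,
                   min_area: int = 10) -> BendSignal:
    """Signed body-bend angle per frame of a recording.

    For each frame the silhouette is split at its centroid along the
    whole-body principal axis into an anterior and a posterior half
    (projection sign onto the axis), an ellipse is fitted to each half,
    and the bend is the signed angle from the posterior to the anterior
    half's major axis.  The projection axis direction is kept continuous
    across frames (no spurious sign flips from the π ambiguity of the
    principal axis).  Degenerate or lost frames yield NaN, never zero.
    """
    n = len(stack)
    bend = np.full(n, np.nan)
    prev_axis: np.ndarray | None = None
    for i, frame in enumerate(stack):
        try:
            mask = segment_frame(frame, policy=policy, threshold=threshold,
                                 min_area=min_area)
            whole = fit_equivalent_ellipse(mask)
        except (EmptyMaskError, DegenerateShapeError):
            continue
        axis = np.array([np.cos(whole.orientation),
                         np.sin(whole.orientation)])
        if prev_axis is not None and float(axis @ prev_axis) < 0:
            axis = -axis
        prev_axis = axis
        rows, cols = np.nonzero(mask)
        proj = ((rows - whole.centroid[0]) * axis[0]
                + (cols - whole.centroid[1]) * axis[1])
        half_masks = []
        ok = True
        for sel in (proj >= 0, proj < 0):
            hm = np.zeros_like(mask)
            hm[rows[sel], cols[sel]] = True
            if hm.sum() < 3:
                ok = False
                break
            half_masks.append(hm)
        if not ok:
            continue
        try:
            ang_a = fit_equivalent_ellipse(half_masks[0]).orientation
            ang_p = fit_equivalent_ellipse(half_masks[1]).orientation
        except DegenerateShapeError:
            continue
        bend[i] = _axis_angle_diff(ang_a, ang_p)
    return BendSignal(time_s=stack.times_s, bend=bend)


def count_thrashes(signal: BendSignal,
                   hysteresis: float = DEFAULT_HYSTERESIS_RAD,
                   ) -> tuple[np.ndarray, list[float]]:
    """Schmitt-trigger half-cycle thrash counts per minute.

    A thrash is registered each time the bend signal enters the
    ``> +hysteresis`` band coming from the opposite (or unknown) state,
    or symmetrically the ``< −hysteresis`` band, so a clean sinusoid of
    frequency f yields 2f counts per second.  NaN samples are skipped
    without resetting the trigger state.  Counts are invariant to a
    global sign flip of the signal.

    Returns (thrashes per whole minute, crossing times in seconds).
    """
    if hysteresis <= 0:
        raise ValueError("hysteresis must be positive")
    state = 0  # 0 unknown, +1, -1
    times: list[float] = []
    for t, b in zip(signal.time_s, signal.bend):
        if np.isnan(b):
            continue
        if b > hysteresis and state != 1:
            times.append(float(t))
            state = 1
        elif b < -hysteresis and state != -1:
            times.append(float(t))
            state = -1
    duration = float(signal.time_s[-1] + (signal.time_s[1] - signal.time_s[0])
                     if len(signal.time_s) > 1 else 0.0)
    return _bin_per_minute(times, duration), times


def thrashes_from_annotations(annotated_times_s, duration_s: float) -> np.ndarray:
    """Per-minute thrash counts from manually annotated thrash times.

    Import path for recordings scored by hand rather than by the
    bend-signal trigger; binning matches :func:`count_thrashes`.
    """
    return _bin_per_minute([float(t) for t in annotated_times_s], duration_s)


def _bin_per_minute(times: list[float], duration_s: float) -> np.ndarray:
    n_bins = int(duration_s // 60)
    counts = np.zeros(max(n_bins, 0))
    for t in times:
        m = int(t // 60)
        if 0 <= m < n_bins:
            counts[m] += 1
    return counts
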