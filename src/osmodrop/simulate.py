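"""Synthetic droplet-assay recordings with known ground truth.

Every downstream stage of the pipeline (segmentation, equivalent-ellipse
eccentricity, turn calling, thrash counting, dehydration area, ΔF/F) is
validated against data produced here, because the assay's raw inputs are
video of single worms swimming in 6 µl droplets and no public recordings
exist.  The generator emulates the phenomenology of those recordings:

* a single worm per field, rendered as a constant-arclength midline
  dilated to a half-width, undulating sinusoidally at the thrash
  frequency;
* turn events — Ω-shaped body bends or deep reversal folds — during which
  the sinusoidal curvature is replaced by a high uniform (or focal)
  curvature that collapses the silhouette's eccentricity;
* turn onsets from a refractory, rate-compensated point process whose
  instantaneous episode rate equals ``turn_rate_fn`` (turns/min), so the
  logged ground truth matches the rate parameter exactly in expectation;
* whole-body shrinkage via ``area_scale`` (linear dimensions scale with
  sqrt(area_scale)), emulating dehydration under hyperosmotic solutions;
* fluorescence traces with mono-exponential photobleaching, an optional
  step response at the solution switch, and additive Gaussian noise.

All randomness flows from a single integer seed; identical parameters and
seed give bit-identical stacks and logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .frames import FrameStack


class SimulationParameterError(ValueError):
    """Physically or numerically inadmissible generator parameters."""


# ---------------------------------------------------------------------------
# Turn-rate profiles (turns per minute as a function of assay time)


def constant_rate(rate_per_min: float) -> Callable[[float], float]:
    """Constant turning-rate profile, turns/min."""
    if rate_per_min < 0:
        raise SimulationParameterError("rate must be non-negative")

    def fn(t: float) -> float:
        return rate_per_min

    fn.max_rate = rate_per_min  # type: ignore[attr-defined]
    return fn


def linear_ramp(rate0_per_min: float, rate_end_per_min: float,
                ramp_end_s: float = 240.0) -> Callable[[float], float]:
    """Linearly ramping turning rate, plateauing at ``rate_end_per_min``.

    The default ramp end of 240 s makes the expected rate over the whole
    5th minute ([240, 300) s) equal to ``rate_end_per_min``, so a cohort's
    minute-5 ground truth is exactly the plateau value — the quantity the
    assay's summary tables report.
    """
    if min(rate0_per_min, rate_end_per_min) < 0:
        raise SimulationParameterError("rates must be non-negative")
    if ramp_end_s <= 0:
        raise SimulationParameterError("ramp_end_s must be positive")

    def fn(t: float) -> float:
        u = min(max(t, 0.0) / ramp_end_s, 1.0)
        return rate0_per_min + (rate_end_per_min - rate0_per_min) * u

    fn.max_rate = max(rate0_per_min, rate_end_per_min)  # type: ignore[attr-defined]
    return fn


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class SwimSimParams:
    """Parameters of a synthetic single-worm droplet swim recording.

    Defaults correspond to the assay conditions the pipeline targets:
    5-minute recordings at 10 Hz, one adult worm per droplet, rendered at
    a reduced single-droplet crop resolution chosen for segmentability.
    """

    duration_s: float = 300.0
    frame_rate_hz: float = 10.0
    canvas_px: tuple[int, int] = (96, 96)
    worm_length_px: float = 56.0
    worm_halfwidth_px: float = 2.5
    thrash_freq_hz: float = 1.0
    turn_rate_fn: Callable[[float], float] = field(
        default_factory=lambda: constant_rate(0.0))
    turn_duration_s: float = 0.8
    turn_refractory_s: float = 0.6
    turn_shape: str = "omega"  # or "reversal-bend"
    area_scale: float = 1.0
    swim_amplitude_rad: float = 4.0   # peak dimensionless curvature κ·L
    omega_angle_rad: float = 5.2      # ≈ 300°: total bend of the Ω arc
    fold_angle_rad: float = 5.8       # total bend of the reversal fold
    background_level: float = 20.0
    worm_level: float = 200.0
    noise_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise SimulationParameterError("duration_s must be positive")
        if self.frame_rate_hz <= 0:
            raise SimulationParameterError("frame_rate_hz must be positive")
        if not 0 < self.area_scale <= 1:
            raise SimulationParameterError("area_scale must be in (0, 1]")
        if self.worm_halfwidth_px <= 0 or self.worm_length_px <= 0:
            raise SimulationParameterError("worm dimensions must be positive")
        diag = float(np.hypot(*self.canvas_px))
        if self.worm_length_px > diag:
            raise SimulationParameterError(
                f"worm ({self.worm_length_px} px) longer than canvas "
                f"diagonal ({diag:.1f} px)")
        if self.turn_shape not in {"omega", "reversal-bend"}:
            raise SimulationParameterError(
                f"unknown turn_shape {self.turn_shape!r}")
        lam_max = _max_rate_per_s(self.turn_rate_fn, self.duration_s)
        dead = self.turn_duration_s + self.turn_refractory_s
        if lam_max > 0 and dead >= 1.0 / lam_max:
            raise SimulationParameterError(
                "turn_duration_s + refractory exceeds the mean inter-turn "
                f"gap implied by the maximum rate ({lam_max * 60:.1f}/min): "
                "unphysical parameters")


@dataclass
class GroundTruthLog:
    """True event times and areas produced alongside a synthetic video."""

    turn_intervals: list[tuple[float, float]]
    thrash_halfcycle_times: list[float]
    true_area_px: np.ndarray
    duration_s: float = 0.0

    def validate(self) -> None:
        prev_end = -np.inf
        for s, e in self.turn_intervals:
            if not (0 <= s < e <= self.duration_s + 1e-9):
                raise ValueError("turn interval outside recording")
            if s < prev_end:
                raise ValueError("turn intervals overlap or are unsorted")
            prev_end = e


@dataclass
class CalciumSimParams:
    """Parameters of a synthetic single-neuron fluorescence recording.

    ``step_amplitude_frac`` is the fractional fluorescence increase at the
    solution switch (0.2 ⇒ a 20% ΔF/F step under perfect correction).
    """

    duration_s: float = 120.0
    sample_rate_hz: float = 10.0
    f0: float = 100.0
    bleach_rate: float = 0.002
    step_time_s: float = 60.0
    step_amplitude_frac: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.f0 <= 0:
            raise SimulationParameterError("f0 must be positive")
        if self.bleach_rate < 0:
            raise SimulationParameterError("bleach_rate must be >= 0")
        if not 0 <= self.step_time_s <= self.duration_s:
            raise SimulationParameterError(
                "step_time_s must lie within the recording")
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise SimulationParameterError("duration and rate must be positive")


# ---------------------------------------------------------------------------
# Turn-onset point process


def _max_rate_per_s(rate_fn: Callable[[float], float], duration_s: float) -> float:
    if hasattr(rate_fn, "max_rate"):
        return float(rate_fn.max_rate) / 60.0
    grid = np.linspace(0.0, duration_s, 512)
    return float(max(rate_fn(t) for t in grid)) / 60.0


def draw_turn_intervals(rate_fn: Callable[[float], float], duration_s: float,
                        turn_duration_s: float, refractory_s: float,
                        rng: np.random.Generator) -> list[tuple[float, float]]:
    """Sample turn episodes whose instantaneous rate is ``rate_fn``.

    Episodes occupy ``turn_duration_s`` and are followed by a refractory
    gap of ``refractory_s`` during which no new turn can start (a worm
    cannot initiate a reorientation while still executing one).  The
    waiting time after the dead time is exponential with a compensated
    intensity μ(t) = λ(t) / (1 − λ(t)·D), D the total dead time, which
    makes the long-run episode rate equal λ(t) — so ``rate_fn`` is
    directly the expected turns/min a downstream counter should recover.
    Sampling uses Ogata thinning against the global maximum intensity.

    Requires λ_max · D < 1 (enforced by :meth:`SwimSimParams.validate`).
    """
    lam_max = _max_rate_per_s(rate_fn, duration_s)
    if lam_max <= 0:
        return []
    dead = turn_duration_s + refractory_s
    if dead >= 1.0 / lam_max:
        raise SimulationParameterError(
            "turn duration + refractory exceeds mean inter-turn gap at the "
            "maximum rate")
    mu_max = lam_max / (1.0 - lam_max * dead)
    intervals: list[tuple[float, float]] = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / mu_max)
        if t >= duration_s:
            break
        lam = rate_fn(t) / 60.0
        mu = lam / (1.0 - lam * dead) if lam > 0 else 0.0
        if rng.random() < mu / mu_max:
            end = min(t + turn_duration_s, duration_s)
            intervals.append((t, end))
            t = end + refractory_s
            if t >= duration_s:
                break
    return intervals


# ---------------------------------------------------------------------------
# Worm rendering


def _midline(curvature: np.ndarray, ds: float, theta0: float) -> np.ndarray:
    """Integrate a curvature profile into (row, col) midline coordinates."""
    theta = theta0 + np.concatenate(([0.0], np.cumsum(
        0.5 * (curvature[1:] + curvature[:-1]) * ds)))
    dr = np.cos(theta)
    dc = np.sin(theta)
    r = np.concatenate(([0.0], np.cumsum(0.5 * (dr[1:] + dr[:-1]) * ds)))
    c = np.concatenate(([0.0], np.cumsum(0.5 * (dc[1:] + dc[:-1]) * ds)))
    return np.column_stack([r, c])


def render_worm_mask(canvas_px: tuple[int, int], curvature: np.ndarray,
                     length_px: float, halfwidth_px: float,
                     theta0: float = 0.0) -> np.ndarray:
    """Rasterize a worm body: midline dilated to ``halfwidth_px``.

    ``curvature`` is sampled uniformly along arclength (units 1/px).  The
    midline is centered on the canvas; a pixel belongs to the body when
    its center lies within the half-width of the midline polyline.
    """
    pts = _midline(curvature, length_px / (len(curvature) - 1), theta0)
    # center the bounding box of the midline on the canvas
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    center = np.array([(canvas_px[0] - 1) / 2.0, (canvas_px[1] - 1) / 2.0])
    pts = pts - (lo + hi) / 2.0 + center
    pad = halfwidth_px + 1.5
    r0 = max(int(np.floor(pts[:, 0].min() - pad)), 0)
    r1 = min(int(np.ceil(pts[:, 0].max() + pad)) + 1, canvas_px[0])
    c0 = max(int(np.floor(pts[:, 1].min() - pad)), 0)
    c1 = min(int(np.ceil(pts[:, 1].max() + pad)) + 1, canvas_px[1])
    mask = np.zeros(canvas_px, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return mask
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist, _ = cKDTree(pts).query(grid, k=1)
    mask[r0:r1, c0:c1] = (dist <= halfwidth_px).reshape(rr.shape)
    return mask


def _turn_weight(t: float, intervals: Sequence[tuple[float, float]],
                 ramp_frac: float = 0.2) -> tuple[float, int]:
    """Blend weight in [0, 1] toward the turn posture, and interval index."""
    for i, (s, e) in enumerate(intervals):
        if s <= t < e:
            u = (t - s) / (e - s)
            w = min(u / ramp_frac, (1.0 - u) / ramp_frac, 1.0)
            return max(w, 0.0), i
    return 0.0, -1


def _swim_curvature(s: np.ndarray, phase: float, length: float,
                    amplitude: float) -> np.ndarray:
    # one undulation wavelength along the body -> S-shaped posture whose
    # net bend is ~0, keeping swim eccentricity high
    return (amplitude / length) * np.sin(phase - 2.0 * np.pi * s / length)


def _turn_curvature(s: np.ndarray, shape: str, sign: float, length: float,
                    omega_angle: float, fold_angle: float) -> np.ndarray:
    if shape == "omega":
        return np.full_like(s, sign * omega_angle / length)
    # reversal-bend: deep focal fold at mid-body
    sigma = length / 6.0
    bump = np.exp(-0.5 * ((s - length / 2.0) / sigma) ** 2)
    bump *= fold_angle / np.trapezoid(bump, s)
    return sign * bump


def simulate_swim_video(params: SwimSimParams) -> tuple[FrameStack, GroundTruthLog]:
    """Generate one synthetic droplet swim recording plus its ground truth.

    Returns the rendered grayscale stack (uint8, worm bright on dark
    background, additive Gaussian noise) and a :class:`GroundTruthLog`
    holding every turn interval, every thrash half-cycle boundary outside
    turns, and the exact rendered body area per frame.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    scale = float(np.sqrt(params.area_scale))
    length = params.worm_length_px * scale
    halfwidth = params.worm_halfwidth_px * scale
    n_frames = int(round(params.duration_s * params.frame_rate_hz))

    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    intervals = draw_turn_intervals(params.turn_rate_fn, params.duration_s,
                                    params.turn_duration_s,
                                    params.turn_refractory_s, rng)
    turn_signs = rng.choice([-1.0, 1.0], size=len(intervals))

    ds_n = max(int(round(length / 0.5)), 8)
    s = np.linspace(0.0, length, ds_n + 1)
    frames = np.empty((n_frames, *params.canvas_px), dtype=np.uint8)
    true_area = np.empty(n_frames, dtype=np.int64)
    span = params.worm_level - params.background_level
    for i in range(n_frames):
        t = i / params.frame_rate_hz
        phase = phase0 + 2.0 * np.pi * params.thrash_freq_hz * t
        kappa = _swim_curvature(s, phase, length, params.swim_amplitude_rad)
        w, idx = _turn_weight(t, intervals)
        if w > 0.0:
            kturn = _turn_curvature(s, params.turn_shape, turn_signs[idx],
                                    length, params.omega_angle_rad,
                                    params.fold_angle_rad)
            kappa = (1.0 - w) * kappa + w * kturn
        mask = render_worm_mask(params.canvas_px, kappa, length, halfwidth,
                                theta0)
        true_area[i] = int(mask.sum())
        img = params.background_level + span * mask
        img = img + rng.normal(0.0, params.noise_sd, size=mask.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)

    # thrash half-cycle boundaries: phase crossings of multiples of π,
    # logged only while the worm is actually swimming (outside turns)
    k0 = int(np.ceil(-phase0 / np.pi))
    times = []
    k = k0
    while True:
        tk = (k * np.pi - phase0) / (2.0 * np.pi * params.thrash_freq_hz)
        if tk >= params.duration_s:
            break
        if tk >= 0 and _turn_weight(tk, intervals)[1] == -1:
            times.append(tk)
        k += 1

    stack = FrameStack(frames=frames, frame_rate_hz=params.frame_rate_hz)
    log = GroundTruthLog(turn_intervals=intervals,
                         thrash_halfcycle_times=times,
                         true_area_px=true_area,
                         duration_s=params.duration_s)
    log.validate()
    return stack, log


# ---------------------------------------------------------------------------
# Dehydration image pairs


def simulate_dehydration_pair(area_ratio: float, n_images: int, seed: int,
                              worm_length_px: float = 150.0,
                              worm_halfwidth_px: float = 6.0,
                              canvas_px: tuple[int, int] = (256, 256),
                              background_level: float = 20.0,
                              worm_level: float = 200.0,
                              noise_sd: float = 5.0,
                              ) -> tuple[FrameStack, FrameStack, dict]:
    """Pre/post micrograph pairs of one worm before and after soaking.

    The post-soak worm's linear dimensions are scaled by sqrt(area_ratio),
    so its silhouette area is ``area_ratio`` times the pre-soak area.
    Pose (orientation and body-wave phase) varies across the ``n_images``
    replicates, emulating repeated photographs of a crawling worm.

    Returns (pre stack, post stack, truth) where ``truth`` holds the exact
    rendered pixel areas of each image.
    """
    if not 0 < area_ratio <= 1:
        raise SimulationParameterError("area_ratio must be in (0, 1]")
    if n_images < 1:
        raise SimulationParameterError("n_images must be >= 1")
    rng = np.random.default_rng(seed)
    lin = float(np.sqrt(area_ratio))
    pre_frames, post_frames = [], []
    pre_area, post_area = [], []
    span = worm_level - background_level
    for _ in range(n_images):
        for which, sc in (("pre", 1.0), ("post", lin)):
            length = worm_length_px * sc
            ds_n = max(int(round(length / 0.5)), 8)
            s = np.linspace(0.0, length, ds_n + 1)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            theta0 = rng.uniform(0.0, 2.0 * np.pi)
            # gentle crawling posture: shallow sinusoid
            kappa = (2.5 / length) * np.sin(phase - 2.0 * np.pi * s / length)
            mask = render_worm_mask(canvas_px, kappa, length,
                                    worm_halfwidth_px * sc, theta0)
            img = background_level + span * mask
            img = img + rng.normal(0.0, noise_sd, size=mask.shape)
            img = np.clip(img, 0, 255).astype(np.uint8)
            if which == "pre":
                pre_frames.append(img)
                pre_area.append(int(mask.sum()))
            else:
                post_frames.append(img)
                post_area.append(int(mask.sum()))
    truth = {"area_ratio": area_ratio,
             "pre_area_px": np.array(pre_area),
             "post_area_px": np.array(post_area)}
    return (FrameStack(np.stack(pre_frames), frame_rate_hz=1.0),
            FrameStack(np.stack(post_frames), frame_rate_hz=1.0), truth)


# ---------------------------------------------------------------------------
# Calcium traces


def simulate_calcium_trace(params: CalciumSimParams):
    """Synthetic single-ROI fluorescence trace with bleaching and a step.

    F(t) = f0·exp(−bleach_rate·t) · (1 + step·1[t ≥ step_time]) + noise.
    Returns (CalciumTrace with raw F only, truth dict of the noiseless
    components).
    """
    from .calcium import CalciumTrace

    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.sample_rate_hz))
    t = np.arange(n) / params.sample_rate_hz
    decay = params.f0 * np.exp(-params.bleach_rate * t)
    step = 1.0 + params.step_amplitude_frac * (t >= params.step_time_s)
    clean = decay * step
    noise = rng.normal(0.0, params.noise_sd, size=n) if params.noise_sd > 0 else 0.0
    f = clean + noise
    trace = CalciumTrace(time_s=t, F=f)
    truth = {"clean": clean, "decay": decay,
             "step_amplitude_frac": params.step_amplitude_frac,
             "step_time_s": params.step_time_s}
    return trace, truth
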