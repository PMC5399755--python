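"""Turn calling from the eccentricity time series, and per-minute rates.

A turn — a reversal or a large Ω-shaped body bend; the assay pools both —
is called wherever the worm's equivalent-ellipse eccentricity stays below
a threshold for long enough.  The threshold is an empirical constant,
determined by calibration against annotated (manually detected or
simulator ground-truth) turns; 0.85 is the default obtained by
calibrating on the synthetic generator at its default appearance.

The headline statistic is the number of turns per minute, with events
assigned to half-open minute bins [60(m−1), 60m) by their start time, and
the 5th-minute rate ([240, 300) s) as the primary group comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_THRESHOLD = 0.85
DEFAULT_MIN_DURATION_S = 0.2
DEFAULT_MERGE_GAP_S = 0.3


@dataclass
class TurnEventSeries:
    """Called turn intervals and binned per-minute turning rates."""

    events: list[tuple[float, float]]
    threshold_used: float
    per_minute_rates: np.ndarray
    minute_bins: list[tuple[float, float]]

    @property
    def n_events(self) -> int:
        return len(self.events)


def _runs_below(ecc: np.ndarray, threshold: float,
                flagged: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of sub-threshold frames; flagged frames are neutral.

    A flagged (lost-worm) frame neither belongs to a run nor terminates
    it: runs may span interior flagged frames.  Returns half-open frame
    index intervals [first, last+1) of the below-threshold members.
    """
    runs = []
    start = None
    last_below = None
    for i, (e, fl) in enumerate(zip(ecc, flagged)):
        if fl or np.isnan(e):
            continue
        if e < threshold:
            if start is None:
                start = i
            last_below = i
        else:
            if start is not None:
                runs.append((start, last_below + 1))
                start = None
    if start is not None:
        runs.append((start, last_below + 1))
    return runs


def merge_events(events: list[tuple[float, float]],
                 merge_gap_s: float) -> list[tuple[float, float]]:
    """Fuse events separated by less than ``merge_gap_s``.  Idempotent."""
    if not events:
        return []
    events = sorted(events)
    merged = [events[0]]
    for s, e in events[1:]:
        ps, pe = merged[-1]
        if s - pe < merge_gap_s:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def call_turns(ecc_series: np.ndarray, frame_rate_hz: float,
               threshold: float = DEFAULT_THRESHOLD,
               min_duration_s: float = DEFAULT_MIN_DURATION_S,
               merge_gap_s: float = DEFAULT_MERGE_GAP_S,
               flagged: np.ndarray | None = None,
               median_filter: bool = False) -> TurnEventSeries:
    """Call turn events from a per-frame eccentricity series.

    Maximal runs of frames with e < ``threshold`` lasting at least
    ``min_duration_s`` become events; events separated by less than
    ``merge_gap_s`` are merged.  Flagged frames (lost worm) are treated
    as missing: they neither join nor interrupt runs or merging.

    Parameters
    ----------
    ecc_series
        Eccentricity per frame (NaN allowed; treated as flagged).
    frame_rate_hz
        Sampling rate of the series.
    median_filter
        Optional 3-frame median prefilter; off by default to keep the
        operational turn definition minimal.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    ecc = np.asarray(ecc_series, dtype=float)
    if flagged is None:
        flagged = np.zeros(ecc.shape, dtype=bool)
    else:
        flagged = np.asarray(flagged, dtype=bool)
    if median_filter:
        from scipy.signal import medfilt
        valid = ~(flagged | np.isnan(ecc))
        sm = ecc.copy()
        sm[valid] = medfilt(ecc[valid], kernel_size=3)
        ecc = sm

    dt = 1.0 / frame_rate_hz
    runs = _runs_below(ecc, threshold, flagged)
    events = [(s * dt, e * dt) for s, e in runs
              if (e - s) * dt >= min_duration_s - 1e-12]
    events = merge_events(events, merge_gap_s)
    duration_s = len(ecc) * dt
    rates, bins = turns_per_minute(events, duration_s)
    return TurnEventSeries(events=events, threshold_used=threshold,
                           per_minute_rates=rates, minute_bins=bins)


def turns_per_minute(events: list[tuple[float, float]], duration_s: float,
                     ) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Count event starts per half-open minute bin [60(m−1), 60m).

    Only whole minutes are binned; a recording shorter than 60 s yields
    an empty rate vector with a warning (the events themselves are still
    available to the caller).
    """
    n_bins = int(duration_s // 60)
    if n_bins == 0:
        warnings.warn("recording shorter than one minute: no per-minute "
                      "rates", RuntimeWarning)
        return np.array([]), []
    starts = np.array([s for s, _ in events])
    rates = np.zeros(n_bins)
    bins = []
    for m in range(n_bins):
        lo, hi = 60.0 * m, 60.0 * (m + 1)
        bins.append((lo, hi))
        if starts.size:
            rates[m] = int(((starts >= lo) & (starts < hi)).sum())
    return rates, bins


def minute_rate(series: TurnEventSeries, minute: int = 5) -> float:
    """Turns/min in a given whole minute (1-based; minute 5 = [240, 300) s)."""
    if minute < 1 or minute > len(series.per_minute_rates):
        raise ValueError(f"minute {minute} not covered by the recording")
    return float(series.per_minute_rates[minute - 1])


def _event_f1(events: list[tuple[float, float]],
              annotations: list[tuple[float, float]]) -> float:
    """Event-level F1 with one-to-one matching by interval overlap.

    Each called event can satisfy at most one annotation (greedy in time
    order), so a single over-merged event spanning many annotations is
    penalized as misses rather than scored as a hit for each.
    """
    def overlaps(a, b):
        return a[0] < b[1] and b[0] < a[1]

    used = [False] * len(events)
    tp = 0
    for ann in sorted(annotations):
        for j, ev in enumerate(sorted(events)):
            if not used[j] and overlaps(ann, ev):
                used[j] = True
                tp += 1
                break
    fp = used.count(False)
    fn = len(annotations) - tp
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def calibrate_threshold(ecc_series: np.ndarray, frame_rate_hz: float,
                        annotated_turn_intervals: list[tuple[float, float]],
                        grid: np.ndarray | None = None,
                        min_duration_s: float = DEFAULT_MIN_DURATION_S,
                        merge_gap_s: float = DEFAULT_MERGE_GAP_S,
                        flagged: np.ndarray | None = None) -> float:
    """Pick the eccentricity threshold maximizing event-level F1.

    Scans a grid (default step 0.01 over [0.5, 0.99]) of thresholds,
    calling turns at each and scoring against the annotated intervals
    (manual annotations or simulator ground truth); ties break toward the
    higher threshold.  Raises if there are no positive annotations.
    """
    if not annotated_turn_intervals:
        raise ValueError("calibration requires at least one annotated turn")
    if grid is None:
        grid = np.arange(0.50, 0.99 + 1e-9, 0.01)
    best_thr, best_f1 = None, -1.0
    for thr in grid:
        series = call_turns(ecc_series, frame_rate_hz, threshold=float(thr),
                            min_duration_s=min_duration_s,
                            merge_gap_s=merge_gap_s, flagged=flagged)
        f1 = _event_f1(series.events, annotated_turn_intervals)
        if f1 >= best_f1:  # >= : ties go to the higher threshold
            best_f1, best_thr = f1, float(thr)
    return best_thr
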