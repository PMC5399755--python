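"""GCaMP fluorescence analysis: bleach correction, ΔF/F, response summaries.

The analysis follows the standard single-ROI protocol: the mean of the
(bleach-corrected) fluorescence over the first 60 s of a recording is the
baseline F_base, and ΔF/F(t) = (F(t) − F_base)/F_base × 100% is computed
for every frame of the first 120 s.  Photobleaching is removed beforehand
by fitting a mono-exponential a·exp(−b·t) + c and dividing it out,
renormalized to its t = 0 value, so fractional responses are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy import stats as sps


class BaselineError(ValueError):
    """Baseline fluorescence is non-positive or undefined."""


@dataclass
class CalciumTrace:
    """One animal's ROI-mean fluorescence recording and derived series.

    ``dff`` is in percent and is defined only inside the analysis window
    (NaN elsewhere); ``F_base`` is computed strictly from the baseline
    window of the corrected trace.
    """

    time_s: np.ndarray
    F: np.ndarray
    F_corrected: np.ndarray | None = None
    F_base: float | None = None
    dff: np.ndarray | None = None
    animal_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.time_s.shape != self.F.shape:
            raise ValueError("time_s and F must have the same length")


def _exp_model(t, a, b, c):
    return a * np.exp(-b * t) + c


def bleach_correct(trace: CalciumTrace, method: str = "exponential_fit",
                   fit_window: str = "baseline", baseline_s: float = 60.0,
                   ) -> CalciumTrace:
    """Remove mono-exponential photobleaching from a raw trace.

    A decaying exponential F̂(t) = a·exp(−b·t) + c (b ≥ 0) is fitted by
    least squares and divided out, renormalized to F̂(0):
    corrected(t) = F(t) / F̂(t) × F̂(0).  Division (rather than
    subtraction) keeps ΔF/F — a ratio statistic — invariant to the
    correction for an unbleached trace.

    Parameters
    ----------
    fit_window
        ``"baseline"`` (default) fits only the first ``baseline_s``
        seconds and extrapolates the decay over the rest of the trace, so
        a genuine response after the baseline cannot bias the decay
        estimate; ``"full"`` fits the whole trace (the behaviour of
        common whole-trace bleach-correction tools), which partially
        absorbs sustained responses into the fitted decay.  See the
        methods note for the trade-off.
    method
        Only ``"exponential_fit"`` is implemented; a non-convergent fit
        falls back to a linear detrend with a logged warning.
    """
    if method != "exponential_fit":
        raise ValueError(f"unknown bleach-correction method {method!r}")
    t = trace.time_s
    f = trace.F
    if len(f) < 10:
        raise ValueError("trace too short for bleach correction (need >= 10)")
    if np.any(f <= 0):
        raise ValueError("bleach correction requires positive fluorescence")
    if fit_window == "baseline":
        sel = t < baseline_s
        if sel.sum() < 10:
            raise ValueError("baseline window too short for the fit")
    elif fit_window == "full":
        sel = np.ones_like(t, dtype=bool)
    else:
        raise ValueError(f"unknown fit_window {fit_window!r}")
    tf, ff = t[sel], f[sel]
    span = max(tf[-1] - tf[0], 1e-9)
    p0 = (max(ff[0] - ff[-1], 1e-3 * ff[0]), 1.0 / span, min(ff))
    try:
        popt, _ = curve_fit(_exp_model, tf, ff, p0=p0,
                            bounds=([0.0, 0.0, -np.inf],
                                    [np.inf, np.inf, np.inf]),
                            maxfev=20000)
        fitted = _exp_model(t, *popt)
        if np.any(fitted <= 0):
            raise RuntimeError("fitted decay crosses zero")
    except (RuntimeError, ValueError):
        warnings.warn("exponential bleach fit did not converge; "
                      "falling back to linear detrend", RuntimeWarning)
        slope, intercept = np.polyfit(tf, ff, 1)
        fitted = slope * t + intercept
        if np.any(fitted <= 0):
            fitted = np.full_like(t, ff.mean())
    corrected = f / fitted * fitted[0]
    return CalciumTrace(time_s=t, F=f, F_corrected=corrected,
                        animal_id=trace.animal_id, condition=trace.condition)


def compute_dff(trace: CalciumTrace,
                baseline_window: tuple[float, float] = (0.0, 60.0),
                analysis_window: tuple[float, float] = (0.0, 120.0),
                ) -> CalciumTrace:
    """ΔF/F in percent over the analysis window, baseline-referenced.

    F_base is the mean corrected fluorescence over the half-open baseline
    window; dff(t) = (F_corrected(t) − F_base)/F_base × 100 for t in the
    analysis window and NaN outside it.  If the trace was never
    bleach-corrected the raw F is used as-is.
    """
    t = trace.time_s
    f = trace.F_corrected if trace.F_corrected is not None else trace.F
    if t[-1] + 1e-9 < analysis_window[1] - (t[1] - t[0]):
        raise ValueError("trace does not cover the analysis window")
    base_sel = (t >= baseline_window[0]) & (t < baseline_window[1])
    if not base_sel.any():
        raise BaselineError("baseline window contains no samples")
    f_base = float(f[base_sel].mean())
    if f_base <= 0:
        raise BaselineError(f"non-positive baseline fluorescence {f_base}")
    dff = np.full_like(f, np.nan)
    ana = (t >= analysis_window[0]) & (t < analysis_window[1])
    dff[ana] = (f[ana] - f_base) / f_base * 100.0
    return CalciumTrace(time_s=t, F=trace.F, F_corrected=f, F_base=f_base,
                        dff=dff, animal_id=trace.animal_id,
                        condition=trace.condition)


def response_summary(trace: CalciumTrace,
                     response_window: tuple[float, float] = (60.0, 120.0),
                     ) -> float:
    """Per-animal mean ΔF/F (%) over the response window."""
    if trace.dff is None:
        raise ValueError("compute_dff must run before response_summary")
    sel = ((trace.time_s >= response_window[0])
           & (trace.time_s < response_window[1]))
    vals = trace.dff[sel]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("response window contains no defined dff samples")
    return float(vals.mean())


def normality_check(samples) -> dict:
    """Kolmogorov–Smirnov and Shapiro–Wilk normality tests of a sample.

    The KS test is run against a normal with the sample's own mean and SD
    (so its p value is approximate in the Lilliefors sense); Shapiro–Wilk
    is reported alongside.  Requires n ≥ 3 and a non-constant sample.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise ValueError("normality tests require at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality tests undefined")
    ks = sps.kstest(x, "norm", args=(x.mean(), sd))
    sw = sps.shapiro(x)
    return {"ks_statistic": float(ks.statistic), "ks_p": float(ks.pvalue),
            "shapiro_statistic": float(sw.statistic),
            "shapiro_p": float(sw.pvalue)}


def dff_matrix(traces: list[CalciumTrace]):
    """Per-animal ΔF/F rows as a DataFrame (heat-map matrix; animals × time).

    Columns are sample times in seconds; the index is animal_id.  The
    matrix round-trips losslessly through ``to_csv``/``read_csv``.
    """
    import pandas as pd

    if not traces:
        raise ValueError("no traces")
    t = traces[0].time_s
    rows = {}
    for tr in traces:
        if tr.dff is None:
            raise ValueError("all traces need dff computed")
        rows[tr.animal_id or f"animal{len(rows)}"] = tr.dff
    return pd.DataFrame(rows, index=t).T


def save_heatmap(matrix, path, vmin=None, vmax=None) -> None:
    """Write a PNG heat map of per-animal ΔF/F rows (animals × time)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.25 * max(len(matrix), 8) + 1))
    im = ax.imshow(matrix.values, aspect="auto", cmap="viridis",
                   vmin=vmin, vmax=vmax,
                   extent=(float(matrix.columns[0]), float(matrix.columns[-1]),
                           len(matrix), 0))
    ax.set_xlabel("time (s)")
    ax.set_ylabel("animal")
    fig.colorbar(im, ax=ax, label="ΔF/F (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
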