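"""End-to-end droplet-assay orchestration.

Chains the stages segment → equivalent ellipse → turn calling → thrash
counting for one recording (real or simulated), and runs whole simulated
cohorts into the long-format rate tables the statistics layer consumes.
Runs are reproducible from configuration + seed; every persisted table
carries the configuration hash.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import FrameStack, read_stack, write_tiff
from .ioutils import PipelineConfig, write_table, write_truth_csv
from .shape import metrics_table
from .simulate import (GroundTruthLog, SwimSimParams, constant_rate,
                       linear_ramp, simulate_swim_video)
from .thrash import bending_signal, count_thrashes
from .turns import call_turns


class PipelineStageError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


def _rate_fn_from_spec(spec) -> callable:
    """Build a turn-rate profile from a serializable config spec.

    ``{"constant": r}`` or ``{"ramp": [r0, r_end]}`` or
    ``{"ramp": [r0, r_end, ramp_end_s]}``; numbers are turns/min.
    """
    if callable(spec):
        return spec
    if isinstance(spec, (int, float)):
        return constant_rate(float(spec))
    if isinstance(spec, dict):
        if "constant" in spec:
            return constant_rate(float(spec["constant"]))
        if "ramp" in spec:
            return linear_ramp(*[float(x) for x in spec["ramp"]])
    raise ValueError(f"cannot interpret turn-rate spec {spec!r}")


def swim_params_from_config(config: PipelineConfig,
                            seed: int | None = None) -> SwimSimParams:
    """Materialize :class:`SwimSimParams` from a config's simulation section."""
    kwargs = dict(config.simulation)
    if "turn_rate" in kwargs:
        kwargs["turn_rate_fn"] = _rate_fn_from_spec(kwargs.pop("turn_rate"))
    if "canvas_px" in kwargs:
        kwargs["canvas_px"] = tuple(kwargs["canvas_px"])
    kwargs.setdefault("seed", config.seed)
    if seed is not None:
        kwargs["seed"] = seed
    return SwimSimParams(**kwargs)


def analyze_stack(stack: FrameStack, config: PipelineConfig | None = None,
                  with_thrash: bool = True) -> dict:
    """Segment → ellipse → turns → thrash for one recording.

    Returns a dict with the per-frame ``metrics`` DataFrame, the called
    ``turns`` (:class:`TurnEventSeries`), a long-format ``rates``
    DataFrame (minute, turns_per_min), and per-minute ``thrash`` counts
    (``with_thrash=False`` skips the bend-signal pass when only turning
    rates are needed).  Stage failures are re-raised tagged with the
    stage name.
    """
    config = config or PipelineConfig()
    try:
        metrics = metrics_table(stack, **config.segmentation)
    except Exception as exc:
        raise PipelineStageError(f"segmentation: {exc}") from exc
    try:
        turn_series = call_turns(
            metrics["eccentricity"].to_numpy(), stack.frame_rate_hz,
            flagged=metrics["flagged"].to_numpy(), **config.turns)
    except Exception as exc:
        raise PipelineStageError(f"turn calling: {exc}") from exc
    thrash_counts = np.array([])
    if with_thrash:
        try:
            bend = bending_signal(stack, **config.segmentation)
            thrash_counts, _ = count_thrashes(bend, **config.thrash)
        except Exception as exc:
            raise PipelineStageError(f"thrash counting: {exc}") from exc
    rates = pd.DataFrame({
        "minute": np.arange(1, len(turn_series.per_minute_rates) + 1),
        "turns_per_min": turn_series.per_minute_rates,
    })
    return {"metrics": metrics, "turns": turn_series, "rates": rates,
            "thrash_per_min": thrash_counts}


def run_droplet_pipeline(config: PipelineConfig,
                         video: str | Path | FrameStack | None = None,
                         out_dir: str | Path | None = None) -> dict:
    """Run the full droplet pipeline on a video or a fresh simulation.

    With ``video=None`` a recording is simulated from the config's
    ``simulation`` section and its ground truth is persisted alongside
    the analysis outputs.  With ``out_dir`` set, all intermediates
    (metrics, events, rates, thrash tables, and simulated TIFF + truth)
    are written with provenance headers; identical config + seed gives
    byte-identical tables.
    """
    truth: GroundTruthLog | None = None
    if video is None:
        params = swim_params_from_config(config)
        stack, truth = simulate_swim_video(params)
    elif isinstance(video, FrameStack):
        stack = video
    else:
        stack = read_stack(video)
    result = analyze_stack(stack, config)
    result["truth"] = truth
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(result["metrics"], out / "metrics.csv", config=config)
        events = pd.DataFrame(result["turns"].events,
                              columns=["start_s", "end_s"])
        write_table(events, out / "events.csv", config=config)
        write_table(result["rates"], out / "rates.csv", config=config)
        thr = pd.DataFrame({
            "minute": np.arange(1, len(result["thrash_per_min"]) + 1),
            "thrashes_per_min": result["thrash_per_min"]})
        write_table(thr, out / "thrash.csv", config=config)
        if truth is not None:
            write_tiff(stack, out / "video.tif")
            write_truth_csv(truth, out / "truth.csv", config=config)
    return result


def cohort_rates(base_params: SwimSimParams, n_animals: int, base_seed: int,
                 config: PipelineConfig | None = None,
                 label: str | None = None,
                 with_truth: bool = False) -> pd.DataFrame:
    """Simulate and analyze a cohort; return a long-format rate table.

    Each animal gets an independent seed derived from ``base_seed``.
    Columns: animal_id, minute, turns_per_min (plus true_turns_per_min
    when ``with_truth``), and a ``condition`` label if given — the
    AssayTable layout the statistics layer consumes.
    """
    rng = np.random.default_rng(base_seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_animals)
    config = config or PipelineConfig()
    rows = []
    for i, seed in enumerate(seeds):
        params = dataclasses.replace(base_params, seed=int(seed))
        stack, truth = simulate_swim_video(params)
        res = analyze_stack(stack, config, with_thrash=False)
        true_rates, _ = _true_minute_rates(truth)
        for _, rec in res["rates"].iterrows():
            m = int(rec["minute"])
            row = {"animal_id": f"{label or 'animal'}_{i:03d}",
                   "minute": m, "turns_per_min": rec["turns_per_min"]}
            if with_truth:
                row["true_turns_per_min"] = true_rates[m - 1]
            if label is not None:
                row["condition"] = label
            rows.append(row)
    return pd.DataFrame(rows)


def _true_minute_rates(truth: GroundTruthLog) -> tuple[np.ndarray, list]:
    from .turns import turns_per_minute

    return turns_per_minute(truth.turn_intervals, truth.duration_s)
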