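"""Ground-truth matching utilities for validating the analysis chain.

Only meaningful for simulated datasets, where the true event list is
known: computes the pixel footprint each event should occupy, matches
detected components to ground truth by time-position overlap, and pools
measured quantities for parameter-recovery checks.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .kymo_analysis import AnalysisResult, DISCARDED, EventTrace
from .params import ImagingParams, MicrotubuleSpec
from .simulate import GroundTruthEvent


def ground_truth_pixels(
    ev: GroundTruthEvent, mt: MicrotubuleSpec, imaging: ImagingParams
) -> set[tuple[int, int]]:
    """(frame, column) pixels the motor centre occupies while bound."""
    midtimes = (np.arange(imaging.n_frames) + 0.5) * imaging.frame_interval
    frames = np.nonzero(ev.bound_at(midtimes))[0]
    out = set()
    for f in frames:
        pos = float(ev.position_at(midtimes[f]))
        col = int(np.floor(mt.position_to_column(pos, imaging.pixel_size) + 0.5))
        out.add((int(f), col))
    return out


def match_events(
    gt_events: Sequence[GroundTruthEvent],
    result: AnalysisResult,
    mt: MicrotubuleSpec,
    imaging: ImagingParams,
    min_overlap: float = 0.5,
) -> dict:
    """Match ground-truth events to detected traces by pixel overlap.

    A ground-truth event is *recovered* when exactly one detected,
    non-discarded trace covers at least ``min_overlap`` of its footprint.
    Returns per-event matches plus recovery and pixel-recall summaries;
    events with an empty footprint (bound for less than one frame) are
    undetectable and excluded from the denominator.
    """
    trace_pixels = [set(map(tuple, tr.pixels.tolist())) for tr in result.traces]
    matches: list[int | None] = []
    recalls: list[float] = []
    n_detectable = 0
    n_recovered = 0
    for ev in gt_events:
        gt_px = ground_truth_pixels(ev, mt, imaging)
        if not gt_px:
            matches.append(None)
            continue
        n_detectable += 1
        overlaps = [
            (i, len(gt_px & tp) / len(gt_px)) for i, tp in enumerate(trace_pixels)
        ]
        hits = [(i, ov) for i, ov in overlaps if ov >= min_overlap]
        recalls.append(max((ov for _, ov in overlaps), default=0.0))
        if len(hits) == 1 and result.traces[hits[0][0]].cls != DISCARDED:
            matches.append(hits[0][0])
            n_recovered += 1
        else:
            matches.append(None)
    return {
        "matches": matches,
        "n_detectable": n_detectable,
        "n_recovered": n_recovered,
        "recovery_rate": n_recovered / n_detectable if n_detectable else float("nan"),
        "mean_pixel_recall": float(np.mean(recalls)) if recalls else float("nan"),
    }


def plus_end_side(mt: MicrotubuleSpec) -> str:
    return mt.plus_end


def collect_end_residences(
    results: Sequence[AnalysisResult],
    mts: Sequence[MicrotubuleSpec],
    plus_end_only: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool uncensored end-residence times (s) and frame counts.

    With ``plus_end_only`` (the default for simulated data, where polarity
    is known), only events at the plus-end column are used.
    """
    durations, counts = [], []
    for res, mt in zip(results, mts):
        side = plus_end_side(mt)
        for tr in res.traces:
            if not tr.is_end_resident or tr.end_censored or tr.censored:
                continue
            if plus_end_only and tr.end_side != side:
                continue
            durations.append(tr.end_residence)
            counts.append(tr.end_frames)
    return np.asarray(durations, float), np.asarray(counts, int)


def collect_velocities(results: Sequence[AnalysisResult]) -> np.ndarray:
    """Pool velocities of uncensored translocating events (nm/s)."""
    out = [
        tr.velocity
        for res in results
        for tr in res.traces
        if tr.velocity is not None and not tr.censored
    ]
    return np.asarray(out, float)


def collect_run_lengths(results: Sequence[AnalysisResult]) -> np.ndarray:
    """Pool run lengths (μm) of uncensored runs that end on the lattice."""
    out = [
        tr.run_length
        for res in results
        for tr in res.traces
        if tr.run_length is not None and not tr.run_censored
    ]
    return np.asarray(out, float)
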