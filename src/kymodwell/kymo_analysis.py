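"""Measurement of single-motor events on two-channel kymographs.

The procedure mirrors manual single-molecule kymograph scoring: threshold
both channels against background, define the microtubule ends as the
outermost above-threshold columns of the time-averaged rhodamine profile,
segment discrete fluorescence events in the GFP channel as 8-connected
components (events are discrete when separated by at least one non-event
pixel in time or space), classify each component, and measure microtubule
end residence, translocation velocity and run length.

Event classes
-------------
``translocating``
    Unidirectional motion over >= ``min_transloc_frames`` frames with net
    displacement >= ``min_net_displacement_px`` pixels.
``lattice``
    Any other well-formed (non-crossing) event; statically bound.
``discarded-crossing``
    Components in which two molecules cross or merge so that individual
    events cannot be identified; excluded from all measurements.

Any non-discarded event whose per-frame centroid occupies a microtubule
end column is additionally *end-resident*; the maximal consecutive run of
end-occupied frames yields the end-residence time.

Durations from frame counts
---------------------------
A motor bound for a time ``t`` is seen in ``k`` frames, where ``k`` counts
frame midpoints covered by the binding interval. For exponentially
distributed ``t``, ``E[k | k >= 1] = 1/(1 - exp(-dt/t_mean))``, so the
naive ``k * dt`` duration overestimates short dwells by up to ~dt/2 plus a
detection-conditioning term. The default convention ``k_minus_half``
((k - 1/2) * dt) is nearly unbiased down to dwells of ~one frame;
``k`` and ``k_minus_1`` are available for comparison with other software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.measure import label as sk_label

DISCARDED = "discarded-crossing"
LATTICE = "lattice"
TRANSLOCATING = "translocating"

DURATION_CONVENTIONS = {"k": 0.0, "k_minus_half": 0.5, "k_minus_1": 1.0}

EVENT_CSV_COLUMNS = [
    "mt_id",
    "event_id",
    "class",
    "first_frame",
    "last_frame",
    "end_side",
    "end_frames",
    "end_residence_s",
    "velocity_nm_s",
    "run_length_um",
    "censored",
    "end_censored",
    "run_censored",
    "discard_reason",
]


class AnalysisError(RuntimeError):
    pass


@dataclass(frozen=True)
class Kymograph:
    """Two-channel time x position image with imaging geometry."""

    rhodamine: np.ndarray  # (frames, pixels)
    gfp: np.ndarray        # same shape
    frame_interval: float  # s
    pixel_size: float      # nm

    def __post_init__(self) -> None:
        if self.rhodamine.shape != self.gfp.shape:
            raise ValueError("channel shapes differ")
        if self.rhodamine.ndim != 2:
            raise ValueError("channels must be 2-D (frames x pixels)")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be > 0")

    @property
    def n_frames(self) -> int:
        return self.rhodamine.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.rhodamine.shape[1]

    def mirrored(self) -> "Kymograph":
        """Horizontally mirrored copy (plus/minus end swap)."""
        return Kymograph(
            self.rhodamine[:, ::-1].copy(), self.gfp[:, ::-1].copy(),
            self.frame_interval, self.pixel_size,
        )


@dataclass(frozen=True)
class MicrotubuleExtent:
    """Microtubule span in image columns.

    ``left_end``/``right_end`` are the outermost above-threshold columns.
    ``left_tip``/``right_tip`` are sub-pixel end positions (column units)
    recovered from the partial-pixel intensity of the end columns; they
    default to the column centres when unknown (hand-built fixtures).
    """

    left_end: int
    right_end: int
    threshold_rho: float
    left_tip: Optional[float] = None
    right_tip: Optional[float] = None

    def __post_init__(self) -> None:
        if self.left_end >= self.right_end:
            raise ValueError("left_end must be < right_end")

    @property
    def left_tip_col(self) -> float:
        return self.left_end if self.left_tip is None else self.left_tip

    @property
    def right_tip_col(self) -> float:
        return self.right_end if self.right_tip is None else self.right_tip


@dataclass
class AnalysisConfig:
    """Tunable measurement options (defaults follow the assay conventions)."""

    k_threshold: float = 3.0
    duration_convention: str = "k_minus_half"
    end_window: int = 0          # widen end occupancy by this many columns
    end_margin_px: float = 0.4   # centroid-to-tip distance scored as "at the end"
    end_gap_frames: int = 1      # bridge this many off-frames inside an end run
    centroid_halfwidth: int = 2  # fixed centroid window half-width (px)
    min_transloc_frames: int = 3
    min_net_displacement_px: float = 2.0
    jitter_tol_px: float = 0.5   # |step| below this counts as a pause
    min_event_pixels: int = 2    # smaller components are treated as noise

    def __post_init__(self) -> None:
        if self.duration_convention not in DURATION_CONVENTIONS:
            raise ValueError(
                f"duration_convention must be one of {sorted(DURATION_CONVENTIONS)}"
            )


@dataclass
class EventTrace:
    """One segmented fluorescence event and its measurements."""

    pixels: np.ndarray                    # (N, 2) int array of (frame, column)
    cls: str
    first_frame: int
    last_frame: int
    frames: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    centroids: np.ndarray = field(default_factory=lambda: np.empty(0))
    end_side: Optional[str] = None        # 'left' / 'right'
    end_frames: int = 0                   # maximal consecutive end-occupied frames
    end_residence: Optional[float] = None  # s
    velocity: Optional[float] = None      # nm/s
    run_length: Optional[float] = None    # μm
    censored: bool = False                # touches first or last movie frame
    end_censored: bool = False            # end run touches a movie boundary
    run_censored: bool = False            # run terminates at an end / boundary
    discard_reason: str = ""

    @property
    def is_end_resident(self) -> bool:
        return self.end_frames >= 1 and self.cls != DISCARDED


def estimate_threshold(channel: np.ndarray, k: float = 3.0) -> float:
    """Background-subtracted intensity threshold: median + k * robust SD.

    The robust SD is 1.4826 * MAD, insensitive to the sparse bright
    pixels that carry signal. A constant image yields its own value (with
    a warning): no signal is separable from background.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("empty channel")
    if k <= 0:
        raise ValueError("k must be > 0")
    med = float(np.median(channel))
    mad = float(np.median(np.abs(channel - med)))
    if mad == 0.0:
        warnings.warn(
            "channel has zero median absolute deviation; no signal separable",
            stacklevel=2,
        )
    return med + k * 1.4826 * mad


def locate_microtubule(kymo: Kymograph, k: float = 3.0) -> MicrotubuleExtent:
    """Find the microtubule end columns on the time-averaged rhodamine profile.

    The end is the final above-threshold column at either side of the
    longest above-threshold run (stabilised microtubules are static, so
    averaging over frames is appropriate). The end columns are usually
    only partially covered by the microtubule; their intensity relative
    to the interior recovers the sub-pixel tip position.
    """
    profile = np.asarray(kymo.rhodamine, dtype=float).mean(axis=0)
    thr = estimate_threshold(profile, k)
    above = profile > thr
    if not above.any():
        raise AnalysisError("no microtubule detected in the rhodamine channel")
    best_start, best_len = _longest_run(above)
    left, right = best_start, best_start + best_len - 1

    left_tip = right_tip = None
    if best_len >= 4:
        interior = float(np.median(profile[left + 1 : right]))
        outside = np.ones(profile.size, bool)
        outside[left : right + 1] = False
        bg = float(np.median(profile[outside])) if outside.any() else 0.0
        span = interior - bg
        if span > 0:
            cov_l = float(np.clip((profile[left] - bg) / span, 0.0, 1.0))
            cov_r = float(np.clip((profile[right] - bg) / span, 0.0, 1.0))
            left_tip = left + 0.5 - cov_l
            right_tip = right - 0.5 + cov_r
    return MicrotubuleExtent(left, right, thr, left_tip, right_tip)


def _longest_run(above: np.ndarray) -> tuple[int, int]:
    """Start and length of the longest run of True values."""
    best_start = best_len = 0
    start = None
    for i, v in enumerate(np.append(above, False)):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    return best_start, best_len


def detect_event_pixels(
    kymo: Kymograph, extent: MicrotubuleExtent, k: float = 3.0
) -> np.ndarray:
    """Binary mask of GFP event pixels, restricted to the microtubule span."""
    thr = estimate_threshold(kymo.gfp, k)
    mask = np.asarray(kymo.gfp, dtype=float) > thr
    mask[:, : extent.left_end] = False
    mask[:, extent.right_end + 1 :] = False
    return mask


def segment_events(mask: np.ndarray) -> list[np.ndarray]:
    """Split an event mask into discrete events (8-connected components).

    Diagonal contact does not separate events; components are returned as
    (N, 2) arrays of (frame, column) indices, ordered by first appearance.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = sk_label(mask, connectivity=2)
    out = []
    for lab in range(1, labels.max() + 1):
        rows, cols = np.nonzero(labels == lab)
        out.append(np.column_stack([rows, cols]))
    out.sort(key=lambda px: (int(px[:, 0].min()), int(px[:, 1].min())))
    return out


def duration_from_frames(
    k_frames: int, frame_interval: float, convention: str = "k_minus_half"
) -> float:
    """Convert a frame count to a duration under the given convention."""
    offset = DURATION_CONVENTIONS[convention]
    return max(k_frames - offset, 0.0) * frame_interval


def _row_runs(cols: np.ndarray) -> int:
    """Number of disjoint horizontal runs in a sorted column list."""
    if cols.size == 0:
        return 0
    return int(1 + np.sum(np.diff(np.sort(cols)) > 1))


def _close_gaps(occ: np.ndarray, max_gap: int) -> np.ndarray:
    """Fill runs of up to ``max_gap`` False values flanked by True."""
    if max_gap <= 0 or occ.size < 3:
        return occ
    occ = occ.copy()
    idx = np.nonzero(occ)[0]
    for a, b in zip(idx[:-1], idx[1:]):
        if 1 < b - a <= max_gap + 1:
            occ[a:b] = True
    return occ


def _max_consecutive(values: np.ndarray) -> tuple[int, int, int]:
    """Longest run of consecutive integers: (length, start, end)."""
    if values.size == 0:
        return 0, -1, -1
    values = np.sort(values)
    best_len = cur_len = 1
    best_start = cur_start = values[0]
    best_end = values[0]
    for prev, cur in zip(values[:-1], values[1:]):
        if cur == prev + 1:
            cur_len += 1
        else:
            cur_start, cur_len = cur, 1
        if cur_len > best_len:
            best_len, best_start, best_end = cur_len, cur_start, cur
    return int(best_len), int(best_start), int(best_end)


def classify_event(
    pixels: np.ndarray,
    extent: MicrotubuleExtent,
    kymo: Kymograph,
    config: AnalysisConfig | None = None,
    gfp_threshold: Optional[float] = None,
    gfp_background: Optional[float] = None,
) -> EventTrace:
    """Classify one segmented component and measure it.

    Crossing test first: a frame-row containing two or more disjoint pixel
    runs means two molecules could not be separated, and the event is
    discarded without measurements. Otherwise the per-frame
    intensity-weighted centroid column drives the translocation test, end
    occupancy, velocity and run length.
    """
    if config is None:
        config = AnalysisConfig()
    pixels = np.asarray(pixels, dtype=int)
    if pixels.size == 0:
        raise ValueError("empty pixel set")
    gfp = np.asarray(kymo.gfp, dtype=float)
    if gfp_threshold is None:
        gfp_threshold = estimate_threshold(gfp, config.k_threshold)
    if gfp_background is None:
        gfp_background = float(np.median(gfp))
    frames_all = pixels[:, 0]
    first, last = int(frames_all.min()), int(frames_all.max())
    censored = first == 0 or last == kymo.n_frames - 1

    rows = np.unique(frames_all)
    for r in rows:
        if _row_runs(pixels[frames_all == r, 1]) >= 2:
            return EventTrace(
                pixels, DISCARDED, first, last,
                censored=censored, discard_reason="crossing",
            )

    # Intensity-weighted centroid per frame, over a fixed window around
    # the brightest component pixel in that row. A fixed window (rather
    # than the above-threshold footprint) avoids both the selection
    # jitter of dim edge pixels toggling across the threshold and the
    # inward bias from the event mask being clipped at the microtubule
    # span (a spot at the very end spills its PSF tail past the final
    # column).
    hw = config.centroid_halfwidth
    centroids = np.empty(rows.size)
    for i, r in enumerate(rows):
        cols = np.sort(pixels[frames_all == r, 1])
        c_peak = int(cols[np.argmax(gfp[r, cols])])
        lo = max(0, c_peak - hw)
        hi = min(kymo.n_pixels, c_peak + hw + 1)
        window = np.arange(lo, hi)
        w = np.clip(gfp[r, window] - gfp_background, 0.0, None)
        if w.sum() <= 0:
            centroids[i] = float(cols.mean())
        else:
            centroids[i] = float(np.sum(w * window) / np.sum(w))

    # End occupancy: the centroid lies within a small margin of the
    # (sub-pixel) microtubule end. One-sided, since nothing lies beyond
    # the end; ``end_window`` widens the zone by whole columns. Because
    # one discrete trace is one molecule, a single off-frame inside an
    # end run is centroid noise, not a departure; such gaps are bridged.
    margin = config.end_margin_px + config.end_window
    occ_left = _close_gaps(centroids <= extent.left_tip_col + margin,
                           config.end_gap_frames)
    occ_right = _close_gaps(centroids >= extent.right_tip_col - margin,
                            config.end_gap_frames)
    occ_any = occ_left | occ_right

    left_len, *_ = _max_consecutive(rows[occ_left])
    right_len, r_start, r_end = _max_consecutive(rows[occ_right])
    if right_len >= left_len and right_len > 0:
        end_side, end_frames, run_rows = "right", right_len, (r_start, r_end)
    elif left_len > 0:
        l_len, l_start, l_end = _max_consecutive(rows[occ_left])
        end_side, end_frames, run_rows = "left", l_len, (l_start, l_end)
    else:
        end_side, end_frames, run_rows = None, 0, (-1, -1)
    end_censored = end_frames > 0 and (
        run_rows[0] == 0 or run_rows[1] == kymo.n_frames - 1
    )

    # translocation test on centroid steps
    steps = np.diff(centroids)
    signif = steps[np.abs(steps) > config.jitter_tol_px]
    unidirectional = signif.size == 0 or np.all(signif > 0) or np.all(signif < 0)
    net = abs(centroids[-1] - centroids[0]) if centroids.size > 1 else 0.0
    is_transloc = (
        rows.size >= config.min_transloc_frames
        and unidirectional
        and signif.size > 0
        and net >= config.min_net_displacement_px
    )
    cls = TRANSLOCATING if is_transloc else LATTICE

    trace = EventTrace(
        pixels, cls, first, last, frames=rows, centroids=centroids,
        end_side=end_side, end_frames=end_frames,
        censored=censored, end_censored=end_censored,
    )
    if end_frames >= 1:
        trace.end_residence = duration_from_frames(
            end_frames, kymo.frame_interval, config.duration_convention
        )
    if is_transloc:
        lattice_rows = ~occ_any
        use = lattice_rows if lattice_rows.sum() >= 2 else np.ones(rows.size, bool)
        t = rows[use] * kymo.frame_interval
        x = centroids[use] * kymo.pixel_size
        slope = np.polyfit(t, x, 1)[0]
        trace.velocity = abs(float(slope))
        trace.run_length = abs(x[-1] - x[0]) / 1000.0
        trace.run_censored = censored or end_frames > 0
    return trace


def measure_end_residence(
    trace: EventTrace,
    frame_interval: float,
    convention: str = "k_minus_half",
) -> float:
    """End-residence time (s) of an end-resident trace."""
    if trace.cls == DISCARDED:
        raise ValueError("discarded (crossing) events carry no measurements")
    if trace.end_frames < 1:
        raise ValueError("trace never occupies an end column")
    return duration_from_frames(trace.end_frames, frame_interval, convention)


def measure_velocity(
    trace: EventTrace, pixel_size: float, frame_interval: float
) -> float:
    """Translocation speed (nm/s): |OLS slope| of centroid position vs time."""
    if trace.cls != TRANSLOCATING:
        raise ValueError("velocity is defined for translocating events only")
    if trace.frames.size < 2:
        raise ValueError("need at least 2 frames to fit a velocity")
    t = trace.frames * frame_interval
    x = trace.centroids * pixel_size
    return abs(float(np.polyfit(t, x, 1)[0]))


def measure_run_length(trace: EventTrace, pixel_size: float) -> float:
    """Run length (μm): net centroid displacement over the trace."""
    if trace.cls != TRANSLOCATING:
        raise ValueError("run length is defined for translocating events only")
    if trace.centroids.size < 2:
        raise ValueError("need at least 2 frames")
    return abs(float(trace.centroids[-1] - trace.centroids[0])) * pixel_size / 1000.0


@dataclass
class AnalysisResult:
    traces: list[EventTrace]
    extent: MicrotubuleExtent
    gfp_threshold: float


def analyse_kymograph(
    kymo: Kymograph, config: AnalysisConfig | None = None
) -> AnalysisResult:
    """Full measurement chain for one kymograph.

    Locates the microtubule, thresholds the GFP channel, segments discrete
    events and classifies/measures each. Discarded (crossing) events are
    retained in the output without measurements. The analysis contains no
    randomness: identical input gives identical output.
    """
    if config is None:
        config = AnalysisConfig()
    extent = locate_microtubule(kymo, config.k_threshold)
    mask = detect_event_pixels(kymo, extent, config.k_threshold)
    gfp_thr = estimate_threshold(kymo.gfp, config.k_threshold)
    gfp_bg = float(np.median(np.asarray(kymo.gfp, dtype=float)))
    traces = []
    for pixels in segment_events(mask):
        if len(pixels) < config.min_event_pixels:
            continue
        traces.append(
            classify_event(pixels, extent, kymo, config, gfp_thr, gfp_bg)
        )
    return AnalysisResult(traces, extent, gfp_thr)


def traces_to_records(
    traces: Sequence[EventTrace], mt_id: int = 0
) -> list[dict]:
    """Flatten traces into per-event records (one row per event)."""
    records = []
    for j, tr in enumerate(traces):
        records.append(
            {
                "mt_id": mt_id,
                "event_id": j,
                "class": tr.cls,
                "first_frame": tr.first_frame,
                "last_frame": tr.last_frame,
                "end_side": tr.end_side or "",
                "end_frames": tr.end_frames,
                "end_residence_s": tr.end_residence,
                "velocity_nm_s": tr.velocity,
                "run_length_um": tr.run_length,
                "censored": tr.censored,
                "end_censored": tr.end_censored,
                "run_censored": tr.run_censored,
                "discard_reason": tr.discard_reason,
            }
        )
    return records
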