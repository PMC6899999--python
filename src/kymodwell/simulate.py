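"""Stochastic simulation of single-motor events and kymograph rendering.

Events are generated from the kinetic model in :mod:`kymodwell.params`
(Poisson landings, constant-speed translocation with exponential run
length, exponential end/lattice dwells) and rendered into noisy
two-channel kymographs (rhodamine microtubule channel + GFP motor
channel) as acquired in single-molecule TIRF assays on immobilised,
stabilised microtubules.

Conventions
-----------
* Positions are μm from the microtubule minus end.
* A motor contributes signal to frame ``k`` iff it is bound at the frame
  midpoint time ``(k + 1/2) * frame_interval``; there is no motion blur.
* A translocating motor that reaches the plus end stops at the tip
  position (microtubule length) and dwells there before detaching.
* Spots of simultaneously bound motors are additive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .kymo_analysis import Kymograph
from .params import ImagingParams, MicrotubuleSpec, MotorParams, ParameterError

TRANSLOCATING = "translocating"
STATIC = "static-lattice"

GROUND_TRUTH_COLUMNS = [
    "mt_id",
    "event_id",
    "kind",
    "landing_time_s",
    "landing_pos_um",
    "detach_time_s",
    "reached_end",
    "end_arrival_time_s",
    "censored",
]


class RenderError(RuntimeError):
    """Raised when an event cannot be placed inside the image."""


@dataclass
class GroundTruthEvent:
    """One realised motor–microtubule interaction with known truth.

    ``reached_end`` marks events that bind or arrive at the plus-end tip;
    for those, ``end_departure_time == detach_time``. ``censored`` marks
    events still bound when the movie ends.
    """

    event_id: int
    kind: str
    landing_time: float
    landing_position: float
    detach_time: float
    reached_end: bool
    end_arrival_time: Optional[float] = None
    velocity: float = 0.0
    mt_length: float = 0.0
    censored: bool = False

    @property
    def end_departure_time(self) -> Optional[float]:
        return self.detach_time if self.reached_end else None

    def position_at(self, t: float | np.ndarray) -> np.ndarray:
        """Motor position (μm from minus end) at time(s) ``t`` while bound.

        A motor that has captured the end (``reached_end``) sits at the
        tip from ``end_arrival_time`` onward; before that it translocates
        at constant speed.
        """
        t = np.asarray(t, dtype=float)
        if self.kind == STATIC:
            return np.full_like(t, self.landing_position)
        pos = self.landing_position + self.velocity * 1e-3 * (t - self.landing_time)
        if self.reached_end and self.end_arrival_time is not None:
            pos = np.where(t >= self.end_arrival_time, self.mt_length, pos)
        return np.minimum(pos, self.mt_length)

    def bound_at(self, t: float | np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (t >= self.landing_time) & (t < self.detach_time)

    def trajectory(self, times: Sequence[float]) -> np.ndarray:
        """Positions at the given times; NaN where the motor is unbound."""
        times = np.asarray(times, dtype=float)
        pos = self.position_at(times)
        return np.where(self.bound_at(times), pos, np.nan)


def _end_capture_distance(
    mt: MicrotubuleSpec, imaging: Optional[ImagingParams]
) -> float:
    """Distance (μm) before the tip at which the end dwell begins.

    With imaging geometry known, the end dwell starts when the motor
    enters the plus-end pixel column (the terminal tubulin site is not
    resolved below pixel size); without geometry it starts at the tip.
    """
    if imaging is None:
        return 0.0
    tip_col = mt.length_px(imaging.pixel_size)  # tip offset in px from MT start
    frac = tip_col - (np.floor(tip_col + 0.5) - 0.5)  # tip depth into its column
    return float(frac) * imaging.pixel_size / 1000.0


def simulate_events(
    motor: MotorParams,
    mt: MicrotubuleSpec,
    duration: float,
    seed: int | np.random.Generator = 0,
    imaging: Optional[ImagingParams] = None,
) -> list[GroundTruthEvent]:
    """Draw one movie's worth of ground-truth events.

    Landings form a Poisson process of rate ``landing_rate * length`` with
    uniform landing positions. Translocating events run plus-ward at
    ``velocity`` under a constant detachment hazard ``velocity /
    mean_run_length``; on capturing the plus end they stop at the tip and
    dwell exponentially with mean ``mean_end_dwell``. Static events dwell
    in place; static landings within ``end_zone_um`` of the plus end bind
    the terminal site and draw from the end dwell instead.

    When ``imaging`` is given, end capture happens on entry into the
    plus-end pixel column (matching how end residence is scored on the
    rendered kymograph); otherwise at the tip itself.

    Identical seed gives identical output.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if motor.fraction_static > 0 and motor.mean_lattice_dwell is None:
        raise ParameterError(
            f"{motor.name}: static events requested (fraction_static="
            f"{motor.fraction_static}) but mean_lattice_dwell is not set"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    capture = _end_capture_distance(mt, imaging)

    n = rng.poisson(motor.landing_rate * mt.length * duration)
    times = np.sort(rng.uniform(0.0, duration, n))
    positions = rng.uniform(0.0, mt.length, n)

    events: list[GroundTruthEvent] = []
    for i in range(n):
        t0, x0 = float(times[i]), float(positions[i])
        is_static = rng.uniform() < motor.fraction_static
        if is_static:
            at_end = (mt.length - x0) <= motor.end_zone_um
            if at_end:
                dwell = rng.exponential(motor.mean_end_dwell)
                ev = GroundTruthEvent(
                    i, STATIC, t0, mt.length, t0 + dwell, True,
                    end_arrival_time=t0, mt_length=mt.length,
                )
            else:
                dwell = rng.exponential(motor.mean_lattice_dwell)
                ev = GroundTruthEvent(
                    i, STATIC, t0, x0, t0 + dwell, False, mt_length=mt.length
                )
        else:
            run = rng.exponential(motor.mean_run_length)
            dist_to_capture = max(mt.length - capture - x0, 0.0)
            v_um = motor.velocity * 1e-3  # μm/s
            if run < dist_to_capture:
                ev = GroundTruthEvent(
                    i, TRANSLOCATING, t0, x0, t0 + run / v_um, False,
                    velocity=motor.velocity, mt_length=mt.length,
                )
            else:
                t_arr = t0 + dist_to_capture / v_um
                dwell = rng.exponential(motor.mean_end_dwell)
                ev = GroundTruthEvent(
                    i, TRANSLOCATING, t0, x0, t_arr + dwell, True,
                    end_arrival_time=t_arr, velocity=motor.velocity,
                    mt_length=mt.length,
                )
        ev.censored = ev.detach_time >= duration
        events.append(ev)
    return events


def render_kymograph(
    events: Sequence[GroundTruthEvent],
    mt: MicrotubuleSpec,
    imaging: ImagingParams,
    rng: Optional[np.random.Generator] = None,
) -> Kymograph:
    """Render ground-truth events into a noisy two-channel kymograph.

    Rows are frames (time ascending), columns are position pixels.
    The rhodamine channel carries the microtubule (uniform intensity over
    its span, partial coverage at the tip columns); the GFP channel a
    Gaussian spot of width ``psf_sigma`` per bound motor per frame.
    """
    T, X = imaging.n_frames, imaging.n_pixels
    if rng is None:
        rng = np.random.default_rng(imaging.seed)

    mt_lo = float(mt.start_pixel)
    mt_hi = mt_lo + mt.length_px(imaging.pixel_size)
    if mt_lo < 0 or mt_hi > X - 1:
        raise ParameterError(
            f"microtubule span [{mt_lo:.1f}, {mt_hi:.1f}] px exceeds image width {X}"
        )

    cols = np.arange(X, dtype=float)
    # column c spans [c - 0.5, c + 0.5]; coverage fraction of the MT span
    coverage = np.clip(np.minimum(cols + 0.5, mt_hi) - np.maximum(cols - 0.5, mt_lo), 0.0, 1.0)
    rho = np.tile(imaging.background_mean + imaging.mt_amplitude * coverage, (T, 1))

    gfp = np.full((T, X), imaging.background_mean)
    midtimes = (np.arange(T) + 0.5) * imaging.frame_interval
    half_win = max(1, int(np.ceil(4 * imaging.psf_sigma)))
    for ev in events:
        if ev.landing_time >= imaging.duration:
            raise RenderError(
                f"event {ev.event_id} lands at {ev.landing_time:.2f}s, after movie end"
            )
        frames = np.nonzero(ev.bound_at(midtimes))[0]
        if frames.size == 0:
            continue
        pos = ev.position_at(midtimes[frames])
        if np.any(pos < -1e-9) or np.any(pos > ev.mt_length + 1e-9):
            raise RenderError(f"event {ev.event_id} position outside the microtubule")
        centre = np.array(
            [mt.position_to_column(p, imaging.pixel_size) for p in pos]
        )
        if np.any(centre < 0) or np.any(centre > X - 1):
            raise RenderError(f"event {ev.event_id} falls outside the image")
        for f, c in zip(frames, centre):
            lo = max(0, int(np.floor(c)) - half_win)
            hi = min(X, int(np.ceil(c)) + half_win + 1)
            window = np.arange(lo, hi)
            gfp[f, lo:hi] += imaging.signal_amplitude * np.exp(
                -0.5 * ((window - c) / imaging.psf_sigma) ** 2
            )

    if imaging.background_sd > 0:
        rho = rho + rng.normal(0.0, imaging.background_sd, (T, X))
        gfp = gfp + rng.normal(0.0, imaging.background_sd, (T, X))
    return Kymograph(
        rhodamine=rho, gfp=gfp,
        frame_interval=imaging.frame_interval, pixel_size=imaging.pixel_size,
    )


@dataclass
class SimulatedDataset:
    """Paired kymographs and ground truth for one motor variant."""

    motor: MotorParams
    imaging: ImagingParams
    microtubules: list[MicrotubuleSpec]
    kymographs: list[Kymograph]
    events: list[list[GroundTruthEvent]]
    tiff_paths: list[Path] = field(default_factory=list)
    csv_path: Optional[Path] = None

    @property
    def n_events(self) -> int:
        return sum(len(e) for e in self.events)


def generate_dataset(
    motor: MotorParams,
    imaging: ImagingParams,
    n_microtubules: int,
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
    mt_length_range: tuple[float, float] = (4.0, 8.0),
) -> SimulatedDataset:
    """Simulate and render a dataset of kymographs with ground truth.

    Microtubule lengths are uniform over ``mt_length_range`` (μm) and each
    microtubule is centred in the image. When ``out_dir`` is given, writes
    one two-channel TIFF per microtubule plus ``ground_truth.csv`` and
    ``microtubules.csv``; the same seed produces byte-identical output.
    """
    if n_microtubules < 1:
        raise ValueError("n_microtubules must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_microtubules)

    mts, kymos, all_events = [], [], []
    for child in children:
        rng = np.random.default_rng(child)
        length = float(rng.uniform(*mt_length_range))
        length_px = length * 1000.0 / imaging.pixel_size
        start = int((imaging.n_pixels - length_px) // 2)
        if start < 1:
            raise ParameterError(
                f"microtubule of {length:.1f} μm does not fit in {imaging.n_pixels} px"
            )
        mt = MicrotubuleSpec(length=length, start_pixel=start)
        events = simulate_events(motor, mt, imaging.duration, rng, imaging=imaging)
        kymo = render_kymograph(events, mt, imaging, rng)
        mts.append(mt)
        kymos.append(kymo)
        all_events.append(events)

    ds = SimulatedDataset(motor, imaging, mts, kymos, all_events)
    if out_dir is not None:
        _write_dataset(ds, Path(out_dir))
    return ds


def _write_dataset(ds: SimulatedDataset, out_dir: Path) -> None:
    from .io import write_kymograph_tiff

    out_dir.mkdir(parents=True, exist_ok=True)
    for i, kymo in enumerate(ds.kymographs):
        path = out_dir / f"mt_{i:03d}.tif"
        write_kymograph_tiff(path, kymo)
        ds.tiff_paths.append(path)

    ds.csv_path = out_dir / "ground_truth.csv"
    with open(ds.csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(GROUND_TRUTH_COLUMNS)
        for i, events in enumerate(ds.events):
            for ev in events:
                writer.writerow(
                    [
                        i,
                        ev.event_id,
                        ev.kind,
                        f"{ev.landing_time:.6f}",
                        f"{ev.landing_position:.6f}",
                        f"{ev.detach_time:.6f}",
                        int(ev.reached_end),
                        "" if ev.end_arrival_time is None else f"{ev.end_arrival_time:.6f}",
                        int(ev.censored),
                    ]
                )

    with open(out_dir / "microtubules.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mt_id", "length_um", "start_pixel", "plus_end"])
        for i, mt in enumerate(ds.microtubules):
            writer.writerow([i, f"{mt.length:.6f}", mt.start_pixel, mt.plus_end])
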