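"""Kinetic and imaging parameter containers.

The generative model of a single kinesin motor is deliberately minimal:
landings are a Poisson process along the microtubule, translocation is at
constant speed with an exponential run length, residence at the microtubule
end (and, for non-translocating motors, on the lattice) is exponential.
These are the standard single-molecule motility assumptions for processive
kinesins on stabilised (non-dynamic) microtubules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional


class ParameterError(ValueError):
    """Raised when a kinetic or imaging parameterisation is inconsistent."""


@dataclass(frozen=True)
class MotorParams:
    """Generative kinetic parameters of one kinesin variant.

    Parameters
    ----------
    name : str
        Variant label (e.g. ``"WT"``, ``"S266R"``).
    velocity : float
        Mean translocation speed, nm/s. Zero for non-translocating motors.
    mean_run_length : float or None
        Exponential mean distance (μm) travelled before detaching from the
        lattice. Required when ``velocity > 0``.
    mean_end_dwell : float
        Exponential mean residence time (s) at the microtubule plus end.
    mean_lattice_dwell : float or None
        Exponential mean duration (s) of statically bound lattice events.
        Required when ``fraction_static > 0``.
    landing_rate : float
        Landing rate, events per μm of microtubule per second.
    fraction_static : float
        Proportion of landings that bind without translocating, in [0, 1].
    end_zone_um : float
        Distance (μm) from the plus end within which a static landing binds
        the terminal site (and draws its dwell from ``mean_end_dwell``).
        Default is one pixel-width of typical TIRF sampling (0.16 μm).
    """

    name: str
    velocity: float
    mean_run_length: Optional[float]
    mean_end_dwell: float
    mean_lattice_dwell: Optional[float] = None
    landing_rate: float = 0.005
    fraction_static: float = 0.0
    end_zone_um: float = 0.16

    def __post_init__(self) -> None:
        if self.velocity < 0:
            raise ParameterError(f"{self.name}: velocity must be >= 0")
        if self.velocity > 0 and (
            self.mean_run_length is None or self.mean_run_length <= 0
        ):
            raise ParameterError(
                f"{self.name}: mean_run_length must be > 0 for a translocating motor"
            )
        if self.mean_end_dwell <= 0:
            raise ParameterError(f"{self.name}: mean_end_dwell must be > 0")
        if self.landing_rate < 0:
            raise ParameterError(f"{self.name}: landing_rate must be >= 0")
        if not 0.0 <= self.fraction_static <= 1.0:
            raise ParameterError(f"{self.name}: fraction_static must lie in [0, 1]")
        if self.fraction_static > 0 and self.velocity == 0 and (
            self.mean_lattice_dwell is None and self.fraction_static < 1
        ):
            raise ParameterError(f"{self.name}: inconsistent static parameterisation")
        if self.mean_lattice_dwell is not None and self.mean_lattice_dwell <= 0:
            raise ParameterError(f"{self.name}: mean_lattice_dwell must be > 0")

    def with_(self, **kwargs) -> "MotorParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ImagingParams:
    """TIRF imaging geometry and noise model for kymograph rendering.

    ``frame_interval`` defaults to 1/2.7 s (2.7 Hz acquisition) and
    ``pixel_size`` to 160 nm/pixel (EMCCD at 100x magnification).
    ``signal_amplitude`` is the peak intensity of a single GFP spot above
    background; ``mt_amplitude`` the rhodamine microtubule intensity above
    background. Both channels receive additive Gaussian background noise.
    """

    frame_interval: float = 1.0 / 2.7
    pixel_size: float = 160.0
    n_frames: int = 500
    n_pixels: int = 120
    psf_sigma: float = 1.0
    signal_amplitude: float = 160.0
    mt_amplitude: float = 600.0
    background_mean: float = 200.0
    background_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be > 0")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if self.n_pixels < 2:
            raise ParameterError("n_pixels must be >= 2")
        if self.background_sd < 0:
            raise ParameterError("background_sd must be >= 0")

    @property
    def duration(self) -> float:
        """Movie length in seconds."""
        return self.n_frames * self.frame_interval

    def with_(self, **kwargs) -> "ImagingParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MicrotubuleSpec:
    """A static (GMPCPP-stabilised) microtubule within the image.

    ``start_pixel`` is the column of the left-most covered pixel edge;
    ``plus_end`` says on which image side the plus end lies. Positions of
    events are measured in μm from the minus end.
    """

    length: float
    start_pixel: int = 10
    plus_end: str = "right"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ParameterError("microtubule length must be > 0")
        if self.plus_end not in ("right", "left"):
            raise ParameterError("plus_end must be 'right' or 'left'")

    def length_px(self, pixel_size_nm: float) -> float:
        return self.length * 1000.0 / pixel_size_nm

    def position_to_column(self, pos_um: float, pixel_size_nm: float) -> float:
        """Fractional image column of a position (μm from the minus end)."""
        px = pos_um * 1000.0 / pixel_size_nm
        if self.plus_end == "right":
            return self.start_pixel + px
        return self.start_pixel + self.length_px(pixel_size_nm) - px


# Reference panel: published single-molecule TIRF measurements for the rat
# kinesin-1 motor-domain construct rkin430-GFP, its alpha4-helix point
# mutants, and the kinesin-13 depolymerase MCAK, used here as generative
# inputs. Velocities in nm/s, run lengths in μm, dwells in s.
DEFAULT_PANEL: dict[str, MotorParams] = {
    "WT": MotorParams("WT", 810.0, 3.06, 0.46),
    "G262K": MotorParams("G262K", 522.0, 1.29, 0.78),
    "N263E": MotorParams("N263E", 686.0, 1.05, 0.95),
    "S266R": MotorParams("S266R", 676.0, 1.54, 1.41),
    "Triple": MotorParams("Triple", 646.0, 0.92, 1.09),
    "S266A": MotorParams("S266A", 548.0, 1.48, 0.92),
    # MCAK does not translocate: all landings are static binders; landings
    # within the end zone recognise the terminal site (long end residence).
    "MCAK": MotorParams(
        "MCAK",
        velocity=0.0,
        mean_run_length=None,
        mean_end_dwell=2.03,
        mean_lattice_dwell=0.68,
        fraction_static=1.0,
    ),
}

# Sample sizes (end-residence events) from the same published dataset;
# used when emulating the study's per-variant statistics.
END_RESIDENCE_N: dict[str, int] = {
    "WT": 273,
    "G262K": 285,
    "N263E": 272,
    "S266R": 284,
    "Triple": 296,
    "S266A": 252,
    "MCAK": 238,
}

# Basal ATP turnover rates (s^-1) for the same panel.
BASAL_ATPASE_RATES: dict[str, float] = {
    "WT": 0.14,
    "G262K": 0.11,
    "N263E": 0.18,
    "S266R": 0.11,
    "Triple": 0.23,
    "S266A": 0.24,
    "MCAK": 0.0021,
}
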