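"""Basal ATP turnover rates from ADP-production timecourses.

At saturating ATP (2 mM) over tens of minutes, basal hydrolysis by a
kinesin motor domain is zeroth-order in ATP, so [ADP](t) is linear and
the turnover rate is the slope divided by the enzyme concentration.
The standard assay adds 1 μM kinesin to buffer with 2 mM ATP and samples
every 5 min; no Michaelis-Menten fitting is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats


class LinearityError(ValueError):
    """ADP production too close to ATP exhaustion for a linear fit."""


@dataclass
class ATPaseTimecourse:
    """(time, [ADP]) series with enzyme concentration.

    times in s, adp in μM; ``kinesin_conc`` (μM) scales slope to per-enzyme
    turnover; ``atp0`` (μM) is the starting ATP concentration.
    """

    times: np.ndarray
    adp: np.ndarray
    kinesin_conc: float = 1.0
    atp0: float = 2000.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.adp = np.asarray(self.adp, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.adp.shape:
            raise ValueError("times and adp must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.adp < 0) or np.any(self.adp > self.atp0):
            raise ValueError("adp must lie within [0, atp0]")
        if self.kinesin_conc <= 0:
            raise ValueError("kinesin_conc must be > 0")

    @classmethod
    def default_template(
        cls,
        n_points: int = 7,
        spacing_s: float = 300.0,
        kinesin_conc: float = 1.0,
        atp0: float = 2000.0,
    ) -> "ATPaseTimecourse":
        """Assay-like template: samples every 5 min, zero ADP."""
        t = np.arange(n_points) * spacing_s
        return cls(t, np.zeros(n_points), kinesin_conc, atp0)


@dataclass(frozen=True)
class TurnoverFit:
    rate: float        # s^-1
    stderr: float      # s^-1
    slope: float       # μM/s
    intercept: float   # μM


def fit_turnover(tc: ATPaseTimecourse) -> TurnoverFit:
    """Turnover rate (s^-1): OLS slope of [ADP] vs time / [kinesin].

    Requires >= 3 timepoints and ADP consumption below 50% of the initial
    ATP, outside of which the zeroth-order (linear) assumption fails.
    """
    if tc.times.size < 3:
        raise ValueError("need at least 3 timepoints")
    if tc.adp.max() >= 0.5 * tc.atp0:
        raise LinearityError(
            "ADP exceeds 50% of initial ATP; truncate the timecourse to its "
            "linear range before fitting"
        )
    res = stats.linregress(tc.times, tc.adp)
    return TurnoverFit(
        rate=res.slope / tc.kinesin_conc,
        stderr=(0.0 if np.isnan(res.stderr) else res.stderr) / tc.kinesin_conc,
        slope=res.slope,
        intercept=res.intercept,
    )


def simulate_timecourse(
    rate: float,
    template: Optional[ATPaseTimecourse] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ATPaseTimecourse:
    """Synthetic ADP timecourse: rate * [kinesin] * t plus Gaussian noise,
    clipped to [0, atp0]. Seeded and deterministic."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if template is None:
        template = ATPaseTimecourse.default_template()
    rng = np.random.default_rng(seed)
    adp = rate * template.kinesin_conc * template.times
    if noise_sd > 0:
        adp = adp + rng.normal(0.0, noise_sd, adp.shape)
    adp = np.clip(adp, 0.0, template.atp0)
    return ATPaseTimecourse(
        template.times.copy(), adp, template.kinesin_conc, template.atp0
    )


def read_timecourse_csv(
    path, kinesin_conc: float = 1.0, atp0: float = 2000.0
) -> ATPaseTimecourse:
    """Read a `time_s,adp_uM` CSV into a timecourse."""
    import pandas as pd

    df = pd.read_csv(path)
    return ATPaseTimecourse(
        df["time_s"].to_numpy(), df["adp_uM"].to_numpy(), kinesin_conc, atp0
    )
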