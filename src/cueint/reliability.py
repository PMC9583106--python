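"""Map cue conditions (light elevation, wind speed) to mean vector lengths
and von Mises concentrations.

The empirical precision fits are linear in wind speed and split-linear in
light elevation (elevation in *radians*; the printed coefficients are only
dimensionally sensible that way). Small additive constants augment the
fitted R before kappa estimation so that simulated populations match the
observed ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .circstats import kappa_fisher

__all__ = [
    "ReliabilityParams",
    "CueCondition",
    "wind_R",
    "light_R",
    "condition_kappas",
]

# keep R strictly below 1 so kappa estimation stays finite
_R_CEILING = 1.0 - 1e-9


@dataclass(frozen=True)
class ReliabilityParams:
    """Constants of the precision fits and the kappa-stage augmentation."""

    wind_slope: float = 0.11  # R per (m/s)
    wind_intercept: float = 0.43
    light_slope_low: float = -0.07  # R per radian of elevation
    light_intercept_low: float = 0.80
    light_slope_high: float = -1.26
    light_intercept_high: float = 2.31
    breakpoint_deg: float = 75.0
    c_wind: float = 0.133
    c_light: float = 0.135

    def __post_init__(self) -> None:
        if self.c_wind < 0 or self.c_light < 0:
            raise ValueError("additive constants must be >= 0")
        if not 0.0 < self.breakpoint_deg < 90.0:
            raise ValueError("breakpoint must lie in (0, 90) degrees")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ReliabilityParams":
        return cls(**d)


@dataclass(frozen=True)
class CueCondition:
    """One experimental condition of the two-cue paradigm.

    ``conflict_deg`` is the azimuthal shift applied to the wind cue while
    the light cue stays put (0 for the congruent control).
    """

    light_elevation_deg: float
    wind_speed_ms: float
    light_azimuth_deg: float = 0.0
    wind_azimuth_deg: float = 0.0
    conflict_deg: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.light_elevation_deg <= 90.0:
            raise ValueError("light elevation must lie in [0, 90] degrees")
        if self.wind_speed_ms < 0:
            raise ValueError("wind speed must be >= 0")
        object.__setattr__(self, "light_azimuth_deg", self.light_azimuth_deg % 360.0)
        object.__setattr__(self, "wind_azimuth_deg", self.wind_azimuth_deg % 360.0)

    @property
    def label(self) -> str:
        """Stable identifier, e.g. ``e60_w2.5_c120``."""
        return (
            f"e{self.light_elevation_deg:g}_w{self.wind_speed_ms:g}"
            f"_c{self.conflict_deg:g}"
        )

    @property
    def setting(self) -> tuple[float, float]:
        """(elevation, wind speed) pair ignoring the conflict angle."""
        return (self.light_elevation_deg, self.wind_speed_ms)


def wind_R(
    speed_ms: float,
    params: ReliabilityParams | None = None,
    augmented: bool = True,
) -> float:
    """Fitted mean vector length of the wind cue at ``speed_ms`` m/s."""
    if speed_ms < 0:
        raise ValueError("wind speed must be >= 0")
    p = params or ReliabilityParams()
    r = p.wind_slope * speed_ms + p.wind_intercept
    if augmented:
        r += p.c_wind
    return min(max(r, 0.0), _R_CEILING)


def light_R(
    elevation_deg: float,
    params: ReliabilityParams | None = None,
    augmented: bool = True,
) -> float:
    """Fitted mean vector length of the light cue at ``elevation_deg``.

    The split-linear fit takes elevation in radians; the breakpoint
    (default 75 degrees) belongs to the low-elevation branch.
    """
    if not 0.0 <= elevation_deg <= 90.0:
        raise ValueError("light elevation must lie in [0, 90] degrees")
    p = params or ReliabilityParams()
    phi = math.radians(elevation_deg)
    if elevation_deg <= p.breakpoint_deg:
        r = p.light_slope_low * phi + p.light_intercept_low
    else:
        r = p.light_slope_high * phi + p.light_intercept_high
    if augmented:
        r += p.c_light
    return min(max(r, 0.0), _R_CEILING)


def condition_kappas(
    cond: CueCondition, params: ReliabilityParams | None = None
) -> tuple[float, float]:
    """(kappa_wind, kappa_light) for a condition, via the augmented R fits."""
    p = params or ReliabilityParams()
    k_wind = kappa_fisher(wind_R(cond.wind_speed_ms, p, augmented=True))
    k_light = kappa_fisher(light_R(cond.light_elevation_deg, p, augmented=True))
    return k_wind, k_light
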