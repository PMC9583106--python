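"""The five directional cue-integration models.

Each model maps two cue beliefs (a sampled direction theta plus a
concentration kappa per cue) to a single integrated heading:

* ``WTA``  winner-take-all: follow the cue with the larger kappa.
* ``WAM``  weighted arithmetic mean of the raw angle values (kept for
  comparison despite being inappropriate for circular data; the 0/360
  pathology is preserved on purpose).
* ``WVS``  weighted vector sum with normalised kappa weights - the
  statistically optimal circular combination.
* ``NVS``  vector sum with the normalised weights pushed through a steep
  sigmoid, so the stronger cue usually dominates but both contribute.
* ``BVS``  as NVS, but each individual carries a small Gaussian weight
  bias toward one cue, reused across the exits of that individual.

All integrators accept scalar or ndarray ``theta`` fields (kappas are
scalars per condition) and are vectorised over individuals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .circstats import wrap_angle

__all__ = [
    "MODEL_NAMES",
    "MODEL_N_PARAMS",
    "DEFAULT_SIGMOID_STEEPNESS",
    "DEFAULT_SIGMA_BIAS",
    "CueBelief",
    "Weights",
    "ModelConfig",
    "normalized_weights",
    "sigmoid_adjust",
    "integrate_wta",
    "integrate_wam",
    "integrate_wvs",
    "integrate_nvs",
    "integrate_bvs",
    "integrate",
]

logger = logging.getLogger(__name__)

MODEL_NAMES = ("WTA", "WAM", "WVS", "NVS", "BVS")

#: free-parameter counts used by the information criteria
MODEL_N_PARAMS = {"WTA": 0, "WAM": 0, "WVS": 0, "NVS": 1, "BVS": 2}

DEFAULT_SIGMOID_STEEPNESS = 53.0
DEFAULT_SIGMA_BIAS = math.sqrt(0.000303)  # ~0.0174


@dataclass(frozen=True)
class CueBelief:
    """A sampled cue direction paired with that cue's concentration.

    ``theta`` is stored as given: expressing inputs in the canonical frame
    (light azimuth = 0, angles in (-pi, pi]) is the caller's contract. The
    value is deliberately not auto-wrapped so that WAM's raw-value pathology
    (the average of 0 and 2*pi is pi) remains expressible.
    """

    theta: float | np.ndarray
    kappa: float

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not np.all(np.isfinite(np.asarray(self.theta, dtype=float))):
            raise ValueError("theta must be finite")


@dataclass(frozen=True)
class Weights:
    w_wind: float
    w_light: float


@dataclass(frozen=True)
class ModelConfig:
    """Name plus the (few) tunable constants of the model family."""

    name: str
    a: float = DEFAULT_SIGMOID_STEEPNESS
    sigma_bias: float = DEFAULT_SIGMA_BIAS
    n_params: int = field(init=False)

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")
        if self.a <= 0:
            raise ValueError("sigmoid steepness a must be > 0")
        if self.sigma_bias < 0:
            raise ValueError("sigma_bias must be >= 0")
        object.__setattr__(self, "n_params", MODEL_N_PARAMS[self.name])


def normalized_weights(k_wind: float, k_light: float) -> Weights:
    """Each kappa divided by their sum; degenerate if both are zero."""
    total = k_wind + k_light
    if total <= 0:
        raise ValueError("degenerate weights: kappa_wind + kappa_light must be > 0")
    return Weights(w_wind=k_wind / total, w_light=k_light / total)


def sigmoid_adjust(x, a: float = DEFAULT_SIGMOID_STEEPNESS):
    """g(x; a) = 1 / (1 + exp(-a (x - 0.5))): steep gate around 0.5."""
    if a <= 0:
        raise ValueError("sigmoid steepness a must be > 0")
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):  # saturates cleanly to 0
        out = 1.0 / (1.0 + np.exp(-a * (x - 0.5)))
    if out.ndim == 0:
        return float(out)
    return out


def _vector_sum_heading(theta_wind, theta_light, w_wind, w_light):
    """Angular component of the sum of polar vectors (theta, W).

    Computed as theta_wind + atan2(sin(d), (w_wind/w_light) + cos(d)) with
    d = theta_light - theta_wind. Degenerate cases: w_light == 0 returns
    theta_wind (the vector-sum limit); atan2(0, 0) (equal weights at exactly
    180 degrees of separation) is defined as a 0 offset and logged.
    """
    theta_wind = np.asarray(theta_wind, dtype=float)
    theta_light = np.asarray(theta_light, dtype=float)
    w_wind = np.asarray(w_wind, dtype=float)
    w_light = np.asarray(w_light, dtype=float)

    d = theta_light - theta_wind
    s = np.sin(d)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(w_light > 0, w_wind / np.where(w_light > 0, w_light, 1.0), np.inf)
    c = ratio + np.cos(d)
    degenerate = (s == 0.0) & (c == 0.0)
    if np.any(degenerate):
        logger.debug(
            "vector sum hit atan2(0, 0) for %d input(s); returning theta_wind",
            int(np.count_nonzero(degenerate)),
        )
    offset = np.where(np.isinf(ratio), 0.0, np.arctan2(s, c))
    out = wrap_angle(theta_wind + offset)
    return out


def integrate_wta(
    wind: CueBelief, light: CueBelief, rng: np.random.Generator | None = None
):
    """Winner-take-all: the cue with the larger kappa wins outright.

    Exact ties are broken by a fair coin per output element; ``rng`` is only
    required in that (measure-zero) case.
    """
    if wind.kappa > light.kappa:
        return wind.theta
    if light.kappa > wind.kappa:
        return light.theta
    if rng is None:
        raise ValueError("tied weights: an rng is required to break the tie")
    tw = np.asarray(wind.theta, dtype=float)
    tl = np.asarray(light.theta, dtype=float)
    tw, tl = np.broadcast_arrays(tw, tl)
    pick_wind = rng.random(size=tw.shape) < 0.5
    out = np.where(pick_wind, tw, tl)
    if out.ndim == 0:
        return float(out)
    return out


def integrate_wam(wind: CueBelief, light: CueBelief):
    """Weighted arithmetic mean of the raw angle values.

    The average is taken on the numeric values *without* wrapping first, so
    the classic circular pathology (mean of 0 and 360 degrees is 180) is
    preserved; the result is frame-dependent by construction. Callers should
    express inputs in the canonical frame (light azimuth = 0) first.
    """
    w = normalized_weights(wind.kappa, light.kappa)
    raw = w.w_wind * np.asarray(wind.theta, dtype=float) + w.w_light * np.asarray(
        light.theta, dtype=float
    )
    if raw.ndim == 0:
        return float(raw)
    return raw


def integrate_wvs(wind: CueBelief, light: CueBelief, weights: Weights | None = None):
    """Optimal weighted vector sum with normalised kappa weights."""
    w = weights or normalized_weights(wind.kappa, light.kappa)
    return _vector_sum_heading(wind.theta, light.theta, w.w_wind, w.w_light)


def integrate_nvs(
    wind: CueBelief, light: CueBelief, a: float = DEFAULT_SIGMOID_STEEPNESS
):
    """Non-optimal vector sum: sigmoid-adjusted weights, then the vector sum."""
    w = normalized_weights(wind.kappa, light.kappa)
    gw = sigmoid_adjust(w.w_wind, a)
    gl = sigmoid_adjust(w.w_light, a)
    return _vector_sum_heading(wind.theta, light.theta, gw, gl)


def integrate_bvs(
    wind: CueBelief,
    light: CueBelief,
    a: float = DEFAULT_SIGMOID_STEEPNESS,
    bias_b: float | np.ndarray = 0.0,
):
    """Biased non-optimal vector sum.

    The normalised wind weight is shifted by -b and the light weight by +b
    before the sigmoid (so positive b favours the light cue). The shifted
    weights are passed to g unclamped; g maps all reals into (0, 1).
    ``bias_b`` is sampled once per individual by the caller and must be
    reused across that individual's integrations.
    """
    w = normalized_weights(wind.kappa, light.kappa)
    b = np.asarray(bias_b, dtype=float)
    gw = sigmoid_adjust(w.w_wind - b, a)
    gl = sigmoid_adjust(w.w_light + b, a)
    return _vector_sum_heading(wind.theta, light.theta, gw, gl)


def integrate(
    name: str,
    wind: CueBelief,
    light: CueBelief,
    rng: np.random.Generator | None = None,
    a: float = DEFAULT_SIGMOID_STEEPNESS,
    bias_b: float | np.ndarray = 0.0,
):
    """Dispatch to an integrator by model name."""
    if name == "WTA":
        return integrate_wta(wind, light, rng=rng)
    if name == "WAM":
        return integrate_wam(wind, light)
    if name == "WVS":
        return integrate_wvs(wind, light)
    if name == "NVS":
        return integrate_nvs(wind, light, a=a)
    if name == "BVS":
        return integrate_bvs(wind, light, a=a, bias_b=bias_b)
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
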