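"""Monte-Carlo simulation of the cue-conflict paradigm.

For each simulated individual the chosen model integrates two noisy cue
samples twice - once with the cue means aligned (initial) and once with the
wind mean shifted by the conflict angle - and the wrapped difference of the
two integrated headings is that individual's change in heading. Populations
of changes are binned into 5-degree probability mass functions which serve
as the model likelihood downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .circstats import wrap_angle
from .models import (
    DEFAULT_SIGMOID_STEEPNESS,
    DEFAULT_SIGMA_BIAS,
    MODEL_NAMES,
    CueBelief,
    ModelConfig,
    integrate,
)
from .reliability import CueCondition, ReliabilityParams, condition_kappas

__all__ = [
    "SimulationConfig",
    "PopulationPMF",
    "ConditionSamples",
    "conflict_condition_grid",
    "draw_condition_samples",
    "simulate_individual_change",
    "simulate_population",
    "bin_to_pmf",
    "bin_index",
    "run_condition_grid",
]

#: elevations (deg) crossed with conflicts at each wind speed (m/s)
GRID_ELEVATIONS = {2.5: (45.0, 60.0, 75.0, 86.0), 1.25: (60.0, 75.0, 86.0)}
GRID_CONFLICTS = (0.0, 60.0, 120.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Population size, binning and seeding of the Monte-Carlo runs."""

    n_sim: int = 1_000_000
    bin_width_deg: float = 5.0
    seed: int | None = None
    share_samples_across_models: bool = True
    pseudocount: float = 1.0  # Laplace floor applied before likelihood use

    def __post_init__(self) -> None:
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if 360.0 % self.bin_width_deg != 0.0:
            raise ValueError("360 must be divisible by bin_width_deg")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    @property
    def n_bins(self) -> int:
        return int(round(360.0 / self.bin_width_deg))


@dataclass(frozen=True)
class PopulationPMF:
    """Normalised probability mass over change-in-heading bins.

    Bins are half-open right-inclusive, covering (-180, 180] degrees.
    """

    model: str
    condition_label: str
    bin_edges_deg: np.ndarray  # n_bins + 1 edges
    mass: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.mass < 0):
            raise ValueError("PMF mass must be non-negative")
        if abs(float(self.mass.sum()) - 1.0) > 1e-9:
            raise ValueError("PMF mass must sum to 1")


def conflict_condition_grid(
    speeds_elevations: dict[float, tuple[float, ...]] | None = None,
    conflicts: tuple[float, ...] = GRID_CONFLICTS,
) -> list[CueCondition]:
    """The default 21-condition grid: {45,60,75,86} deg x 3 conflicts at
    2.5 m/s plus {60,75,86} deg x 3 conflicts at 1.25 m/s."""
    grid = speeds_elevations or GRID_ELEVATIONS
    conditions = []
    for speed, elevations in grid.items():
        for elev in elevations:
            for conf in conflicts:
                conditions.append(
                    CueCondition(
                        light_elevation_deg=elev,
                        wind_speed_ms=speed,
                        conflict_deg=conf,
                    )
                )
    return conditions


@dataclass(frozen=True)
class ConditionSamples:
    """The random draws for one condition, shared across models.

    Cue samples are expressed in the canonical frame (light azimuth = 0);
    the wind means are 0 (initial) and the conflict angle (conflict step).
    ``bias`` is consumed by BVS only and ``tie_coin`` by WTA ties only, so
    that every model sees identical von Mises draws.
    """

    wind_initial: np.ndarray
    light_initial: np.ndarray
    wind_conflict: np.ndarray
    light_conflict: np.ndarray
    bias: np.ndarray
    tie_coin: np.ndarray


def draw_condition_samples(
    cond: CueCondition,
    kappas: tuple[float, float],
    n: int,
    rng: np.random.Generator,
    sigma_bias: float = DEFAULT_SIGMA_BIAS,
) -> ConditionSamples:
    """Draw all per-individual randomness for one condition."""
    k_wind, k_light = kappas
    conflict = math.radians(cond.conflict_deg)
    return ConditionSamples(
        wind_initial=wrap_angle(rng.vonmises(0.0, k_wind, size=n)),
        light_initial=wrap_angle(rng.vonmises(0.0, k_light, size=n)),
        wind_conflict=wrap_angle(rng.vonmises(conflict, k_wind, size=n)),
        light_conflict=wrap_angle(rng.vonmises(0.0, k_light, size=n)),
        bias=rng.normal(0.0, sigma_bias, size=n),
        tie_coin=rng.random(size=n),
    )


def _integrate_step(
    model: str,
    theta_wind: np.ndarray,
    theta_light: np.ndarray,
    kappas: tuple[float, float],
    a: float,
    bias: np.ndarray,
    tie_coin: np.ndarray,
) -> np.ndarray:
    k_wind, k_light = kappas
    wind = CueBelief(theta=theta_wind, kappa=k_wind)
    light = CueBelief(theta=theta_light, kappa=k_light)
    if model == "WTA" and k_wind == k_light:
        # break the (measure-zero) tie with the shared per-individual coin
        return np.where(tie_coin < 0.5, theta_wind, theta_light)
    if model == "BVS":
        return integrate("BVS", wind, light, a=a, bias_b=bias)
    if model == "NVS":
        return integrate("NVS", wind, light, a=a)
    return integrate(model, wind, light)


def _population_changes(
    model: str, kappas: tuple[float, float], samples: ConditionSamples, a: float
) -> np.ndarray:
    initial = _integrate_step(
        model,
        samples.wind_initial,
        samples.light_initial,
        kappas,
        a,
        samples.bias,
        samples.tie_coin,
    )
    conflict = _integrate_step(
        model,
        samples.wind_conflict,
        samples.light_conflict,
        kappas,
        a,
        samples.bias,  # same individual bias on both steps
        samples.tie_coin,
    )
    return wrap_angle(np.asarray(conflict) - np.asarray(initial))


def simulate_individual_change(
    model: str,
    cond: CueCondition,
    kappas: tuple[float, float],
    rng: np.random.Generator,
    model_config: ModelConfig | None = None,
) -> float:
    """Change in integrated heading for one simulated individual (radians)."""
    mc = model_config or ModelConfig(model)
    samples = draw_condition_samples(cond, kappas, 1, rng, sigma_bias=mc.sigma_bias)
    return float(_population_changes(model, kappas, samples, mc.a)[0])


def simulate_population(
    model: str,
    cond: CueCondition,
    config: SimulationConfig,
    params: ReliabilityParams | None = None,
    model_config: ModelConfig | None = None,
    samples: ConditionSamples | None = None,
) -> np.ndarray:
    """Changes in heading for ``config.n_sim`` independent individuals.

    Deterministic for a fixed ``config.seed``. Pre-drawn ``samples`` may be
    supplied to share the underlying von Mises draws across models.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}")
    mc = model_config or ModelConfig(model)
    kappas = condition_kappas(cond, params)
    if samples is None:
        rng = np.random.default_rng(config.seed)
        samples = draw_condition_samples(
            cond, kappas, config.n_sim, rng, sigma_bias=mc.sigma_bias
        )
    return _population_changes(model, kappas, samples, mc.a)


def bin_index(angles_rad, bin_width_deg: float = 5.0) -> np.ndarray:
    """Index of the half-open right-inclusive bin containing each angle.

    Bin k covers (-180 + k*w, -180 + (k+1)*w] degrees.
    """
    deg = np.degrees(wrap_angle(np.asarray(angles_rad, dtype=float)))
    n_bins = int(round(360.0 / bin_width_deg))
    # right-inclusive: ceil((x + 180)/w) - 1, robust to float edge noise
    idx = np.ceil((deg + 180.0) / bin_width_deg - 1e-9).astype(int) - 1
    return np.clip(idx, 0, n_bins - 1)


def bin_to_pmf(
    changes_rad,
    model: str = "",
    condition_label: str = "",
    bin_width_deg: float = 5.0,
    pseudocount: float = 0.0,
) -> PopulationPMF:
    """Histogram changes into (-180, 180] bins and normalise to a PMF.

    ``pseudocount`` adds that many counts to every bin before normalising
    (Laplace floor), preventing -inf log likelihoods downstream.
    """
    changes = np.atleast_1d(np.asarray(changes_rad, dtype=float))
    if changes.size == 0:
        raise ValueError("no data: cannot bin an empty sample")
    n_bins = int(round(360.0 / bin_width_deg))
    counts = np.bincount(bin_index(changes, bin_width_deg), minlength=n_bins).astype(
        float
    )
    counts += pseudocount
    edges = -180.0 + bin_width_deg * np.arange(n_bins + 1)
    return PopulationPMF(
        model=model,
        condition_label=condition_label,
        bin_edges_deg=edges,
        mass=counts / counts.sum(),
    )


def run_condition_grid(
    models: list[str],
    conditions: list[CueCondition],
    config: SimulationConfig,
    params: ReliabilityParams | None = None,
    model_configs: dict[str, ModelConfig] | None = None,
) -> dict[tuple[str, str], PopulationPMF]:
    """One PMF per (model, condition).

    When ``config.share_samples_across_models`` is on, the von Mises draws
    for each condition are generated once and reused by every model; each
    condition gets an independent child seed so results do not depend on
    model order.
    """
    if not conditions:
        raise ValueError("condition list must be non-empty")
    mcs = model_configs or {m: ModelConfig(m) for m in models}
    seed_seq = np.random.SeedSequence(config.seed)
    children = seed_seq.spawn(len(conditions))
    sigma_bias = max(mc.sigma_bias for mc in mcs.values())
    out: dict[tuple[str, str], PopulationPMF] = {}
    for cond, child in zip(conditions, children):
        kappas = condition_kappas(cond, params)
        rng = np.random.default_rng(child)
        shared = (
            draw_condition_samples(cond, kappas, config.n_sim, rng, sigma_bias)
            if config.share_samples_across_models
            else None
        )
        for model in models:
            samples = shared
            if samples is None:
                rng_m = np.random.default_rng(child.spawn(1)[0])
                samples = draw_condition_samples(
                    cond, kappas, config.n_sim, rng_m, mcs[model].sigma_bias
                )
            changes = _population_changes(model, kappas, samples, mcs[model].a)
            out[(model, cond.label)] = bin_to_pmf(
                changes,
                model=model,
                condition_label=cond.label,
                bin_width_deg=config.bin_width_deg,
                pseudocount=config.pseudocount,
            )
    return out
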