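"""Synthetic exit-bearing datasets with known-truth manifests.

Two generators emulate the experimental protocols: the single-cue
reliability series (five exits, a 180-degree cue shift, five more exits)
and the two-cue conflict assay (congruent x3 - conflict - congruent -
conflict - congruent x2). Exits are produced by sampling cue beliefs and
re-integrating per exit with a chosen generating model, so the simulated
populations carry the conflict-dependent variance the models predict.

Truth manifests (generating model, per-beetle bearings and biases, kappas)
are returned separately and must never be read by analysis stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circstats import wrap_angle
from .models import (
    DEFAULT_SIGMA_BIAS,
    DEFAULT_SIGMOID_STEEPNESS,
    MODEL_NAMES,
    CueBelief,
    integrate,
)
from .reliability import (
    CueCondition,
    ReliabilityParams,
    condition_kappas,
    kappa_fisher,
    light_R,
    wind_R,
)

__all__ = [
    "SynthConfig",
    "generate_reliability_dataset",
    "generate_conflict_dataset",
]

#: wind-azimuth offsets (degrees, relative to congruent) of the 8-exit
#: conflict protocol; c1/c2 are filled with the pseudo-randomised order
_PROTOCOL_SLOTS = ("cong", "cong", "cong", "c1", "cong", "c2", "cong", "cong")


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic generators."""

    generating_model: str = "BVS"
    n_beetles: int = 20
    seed: int | None = 0
    a: float = DEFAULT_SIGMOID_STEEPNESS
    sigma_bias: float = DEFAULT_SIGMA_BIAS
    params: ReliabilityParams = field(default_factory=ReliabilityParams)

    def __post_init__(self) -> None:
        if self.generating_model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.generating_model!r}")
        if self.n_beetles < 1:
            raise ValueError("n_beetles must be >= 1")


def _bearing360(x_rad) -> np.ndarray:
    return np.asarray(np.degrees(wrap_angle(x_rad)) % 360.0)


def generate_reliability_dataset(
    conditions: list[CueCondition],
    config: SynthConfig,
    augmented: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Single-cue precision series: 5 exits, 180-degree cue shift, 5 exits.

    Each beetle holds a uniform-random menotactic bearing relative to the
    cue; every exit is that bearing plus the current cue azimuth plus a
    fresh von Mises cue-sample error. The tested cue is the wind when the
    condition has a positive wind speed, else the light.

    By default kappa comes from the *non-augmented* precision fit, so the
    median per-beetle R of the generated population lands on the fit line
    (matching real beetles). The additive augmentation constants compensate
    for the doubled snapshot noise of the change-in-heading paradigm and
    belong to the conflict simulation, not to single-draw precision exits;
    set ``augmented=True`` to use the augmented kappas anyway.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    manifest: dict = {
        "kind": "reliability",
        "seed": config.seed,
        "augmented": augmented,
        "conditions": [],
    }
    for cond in conditions:
        cue = "wind" if cond.wind_speed_ms > 0 else "light"
        if cue == "wind":
            kappa = kappa_fisher(
                wind_R(cond.wind_speed_ms, config.params, augmented=augmented)
            )
            base_az = cond.wind_azimuth_deg
        else:
            kappa = kappa_fisher(
                light_R(cond.light_elevation_deg, config.params, augmented=augmented)
            )
            base_az = cond.light_azimuth_deg
        bearings = rng.uniform(-math.pi, math.pi, size=config.n_beetles)
        noise = rng.vonmises(0.0, kappa, size=(config.n_beetles, 10))
        cond_manifest = {
            "label": cond.label,
            "cue": cue,
            "kappa": kappa,
            "beetles": {},
        }
        for b in range(config.n_beetles):
            beetle_id = f"{cond.label}_b{b:03d}"
            cond_manifest["beetles"][beetle_id] = math.degrees(bearings[b])
            for exit_index in range(1, 11):
                cue_az = (base_az + (180.0 if exit_index > 5 else 0.0)) % 360.0
                exit_deg = float(
                    _bearing360(bearings[b] + math.radians(cue_az) + noise[b, exit_index - 1])
                )
                rows.append(
                    {
                        "beetle_id": beetle_id,
                        "day": 1,
                        "exit_index": exit_index,
                        "phase": "congruent",
                        "light_elevation_deg": cond.light_elevation_deg,
                        "wind_speed_ms": cond.wind_speed_ms,
                        "light_azimuth_deg": cue_az if cue == "light" else cond.light_azimuth_deg,
                        "wind_azimuth_deg": cue_az if cue == "wind" else cond.wind_azimuth_deg,
                        "conflict_deg": 0.0,
                        "exit_bearing_deg": exit_deg,
                    }
                )
        manifest["conditions"].append(cond_manifest)
    return pd.DataFrame(rows), manifest


def generate_conflict_dataset(
    conditions: list[CueCondition],
    config: SynthConfig,
    conflict_pair: tuple[float, float] = (60.0, 120.0),
) -> tuple[pd.DataFrame, dict]:
    """Conflict-assay sessions generated by a chosen integration model.

    ``conditions`` may be the full conflict grid; sessions are generated per
    unique (elevation, wind speed) setting, since one 8-exit session covers
    all three conflict levels. Per beetle: a persistent uniform-random
    intended bearing, a persistent weight bias (used by BVS), and a
    pseudo-randomised conflict order. Every exit re-samples both cue beliefs
    and re-integrates with the generating model.
    """
    settings: list[CueCondition] = []
    seen = set()
    for cond in conditions:
        if cond.setting not in seen:
            seen.add(cond.setting)
            settings.append(
                CueCondition(
                    light_elevation_deg=cond.light_elevation_deg,
                    wind_speed_ms=cond.wind_speed_ms,
                    light_azimuth_deg=cond.light_azimuth_deg,
                    wind_azimuth_deg=cond.wind_azimuth_deg,
                )
            )
    rng = np.random.default_rng(config.seed)
    model = config.generating_model
    rows = []
    manifest: dict = {
        "kind": "conflict",
        "seed": config.seed,
        "model": model,
        "a": config.a,
        "sigma_bias": config.sigma_bias if model == "BVS" else 0.0,
        "settings": [],
    }
    n = config.n_beetles
    n_exits = len(_PROTOCOL_SLOTS)
    for cond in settings:
        k_wind, k_light = condition_kappas(cond, config.params)
        bearings = rng.uniform(-math.pi, math.pi, size=n)
        bias = (
            rng.normal(0.0, config.sigma_bias, size=n)
            if model == "BVS"
            else np.zeros(n)
        )
        swap = rng.random(size=n) < 0.5  # conflict order per beetle
        offsets = np.zeros((n, n_exits))
        offsets[:, 3] = np.where(swap, conflict_pair[1], conflict_pair[0])
        offsets[:, 5] = np.where(swap, conflict_pair[0], conflict_pair[1])

        theta_wind = wrap_angle(
            rng.vonmises(np.radians(offsets), k_wind, size=(n, n_exits))
        )
        theta_light = wrap_angle(rng.vonmises(0.0, k_light, size=(n, n_exits)))
        headings = integrate(
            model,
            CueBelief(theta=theta_wind, kappa=k_wind),
            CueBelief(theta=theta_light, kappa=k_light),
            rng=rng,
            a=config.a,
            bias_b=bias[:, None],
        )
        exits = _bearing360(
            bearings[:, None] + math.radians(cond.light_azimuth_deg) + headings
        )

        setting_manifest = {
            "setting": {"light_elevation_deg": cond.light_elevation_deg,
                        "wind_speed_ms": cond.wind_speed_ms},
            "kappa_wind": k_wind,
            "kappa_light": k_light,
            "beetles": {},
        }
        tag = f"e{cond.light_elevation_deg:g}w{cond.wind_speed_ms:g}"
        for b in range(n):
            beetle_id = f"{tag}_b{b:03d}"
            setting_manifest["beetles"][beetle_id] = {
                "bearing_deg": math.degrees(bearings[b]),
                "bias": float(bias[b]),
                "order": [float(offsets[b, 3]), float(offsets[b, 5])],
            }
            for j in range(n_exits):
                conflict = float(offsets[b, j])
                phase = "congruent" if conflict == 0 else f"conflict{conflict:g}"
                rows.append(
                    {
                        "beetle_id": beetle_id,
                        "day": 1,
                        "exit_index": j + 1,
                        "phase": phase,
                        "light_elevation_deg": cond.light_elevation_deg,
                        "wind_speed_ms": cond.wind_speed_ms,
                        "light_azimuth_deg": cond.light_azimuth_deg,
                        "wind_azimuth_deg": (cond.light_azimuth_deg + conflict) % 360.0,
                        "conflict_deg": conflict,
                        "exit_bearing_deg": float(exits[b, j]),
                    }
                )
        manifest["settings"].append(setting_manifest)
    return pd.DataFrame(rows), manifest
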