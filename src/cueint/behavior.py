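"""Empirical pipeline for exit-bearing tables.

Covers cue normalisation, the orientation and conflict exclusion screens,
menotaxis classification, per-beetle precision, and change-in-heading
statistics. Functions operate on pandas DataFrames using the exit-table
schema defined in :mod:`cueint.io_cli` (angles in degrees at this boundary;
circular math happens in radians via :mod:`cueint.circstats`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circstats import ResultantSummary, mean_resultant, rayleigh_test, wrap_angle

__all__ = [
    "BeetleSeries",
    "wrap_deg",
    "normalize_exits",
    "beetle_series",
    "reliability_screen",
    "menotaxis_test",
    "conflict_screen",
    "change_in_heading",
    "extract_conflict_changes",
    "summarize_condition",
    "summarize_reliability",
    "per_beetle_R",
]

SESSION_KEYS = ["beetle_id", "day", "light_elevation_deg", "wind_speed_ms"]

#: exit protocol of one conflict session: positions (1-based) of the two
#: conflict exits among the eight exits
CONFLICT_POSITIONS = (4, 6)
SESSION_EXITS = 8
N_CONGRUENT = 6


def wrap_deg(x):
    """Wrap degree-valued angle(s) to (-180, 180]."""
    return np.degrees(wrap_angle(np.radians(x)))


@dataclass(frozen=True)
class BeetleSeries:
    """One beetle's cue-normalised exits plus their resultant summary."""

    beetle_id: str
    normalized_deg: np.ndarray
    summary: ResultantSummary


def normalize_exits(df: pd.DataFrame, cue: str = "light") -> pd.DataFrame:
    """Add a ``normalized_deg`` column: exit bearing relative to the cue.

    ``cue`` selects which azimuth column (light or wind) is subtracted; each
    row must carry the azimuth in force at that exit, so the mid-session
    180-degree cue shift is handled by construction.
    """
    col = {"light": "light_azimuth_deg", "wind": "wind_azimuth_deg"}.get(cue)
    if col is None:
        raise ValueError("cue must be 'light' or 'wind'")
    if col not in df.columns:
        raise ValueError(f"incomplete record: missing column {col!r}")
    if df[col].isna().any():
        raise ValueError(f"incomplete record: missing {cue} azimuth values")
    out = df.copy()
    out["normalized_deg"] = wrap_deg(df["exit_bearing_deg"] - df[col])
    return out


def beetle_series(df: pd.DataFrame, cue: str = "light") -> list[BeetleSeries]:
    """Group a single-condition table into per-beetle normalised series."""
    norm = normalize_exits(df, cue=cue)
    series = []
    for beetle_id, grp in norm.groupby("beetle_id", sort=True):
        angles = np.radians(grp.sort_values("exit_index")["normalized_deg"].to_numpy())
        series.append(
            BeetleSeries(
                beetle_id=str(beetle_id),
                normalized_deg=np.degrees(angles),
                summary=mean_resultant(angles),
            )
        )
    return series


def reliability_screen(
    series: BeetleSeries, alpha: float = 0.05, expected_exits: int = 10
) -> bool:
    """True when the beetle is oriented (Rayleigh rejects uniformity).

    Beetles whose normalised exits cannot be distinguished from uniform at
    ``alpha`` are deemed unable to orient (excluded from tactic analysis).
    """
    n = series.normalized_deg.size
    if n != expected_exits:
        raise ValueError(
            f"protocol violation: beetle {series.beetle_id} has {n} exits, "
            f"expected {expected_exits}"
        )
    _, p = rayleigh_test(np.radians(series.normalized_deg))
    return p <= alpha


def menotaxis_test(mean_bearings_deg, alpha: float = 0.05) -> str:
    """Classify a population of per-beetle mean bearings.

    A uniform distribution of means (Rayleigh p > alpha) is menotaxis -
    arbitrary bearings with respect to the cue; a directed population is
    taxis.
    """
    bearings = np.atleast_1d(np.asarray(mean_bearings_deg, dtype=float))
    if bearings.size < 2:
        raise ValueError("need at least 2 beetle means")
    _, p = rayleigh_test(np.radians(bearings))
    return "taxis" if p <= alpha else "menotaxis"


def _session_frame(session: pd.DataFrame) -> pd.DataFrame:
    s = session.sort_values("exit_index")
    if len(s) != SESSION_EXITS:
        raise ValueError(
            f"protocol violation: session has {len(s)} exits, expected {SESSION_EXITS}"
        )
    congruent = s[s["conflict_deg"] == 0]
    if len(congruent) != N_CONGRUENT:
        raise ValueError(
            f"protocol violation: {len(congruent)} congruent exits, expected {N_CONGRUENT}"
        )
    positions = np.flatnonzero((s["conflict_deg"] != 0).to_numpy()) + 1
    if tuple(positions) != CONFLICT_POSITIONS:
        raise ValueError(
            f"protocol violation: conflict exits at positions {tuple(positions)}, "
            f"expected {CONFLICT_POSITIONS}"
        )
    return s


def conflict_screen(session: pd.DataFrame, alpha: float = 0.1) -> bool:
    """True (keep) when the six congruent headings are directed.

    Sessions whose congruent exits are not significantly different from
    uniform (Rayleigh p >= alpha) are dropped: such beetles did not recover
    a consistent bearing between conflicts.
    """
    s = _session_frame(session)
    congruent = s[s["conflict_deg"] == 0]["exit_bearing_deg"].to_numpy()
    _, p = rayleigh_test(np.radians(congruent))
    return p < alpha


def change_in_heading(exit_before_deg: float, exit_after_deg: float) -> float:
    """Signed angular difference wrap(after - before) in (-180, 180]."""
    return float(wrap_deg(exit_after_deg - exit_before_deg))


def _shift_sign(wind_az_before: float, wind_az_after: float) -> float:
    """+1 when the wind azimuth was shifted counterclockwise (or not at
    all), -1 for a clockwise shift; changes are reported positive in the
    direction of the applied shift."""
    shift = wrap_deg(wind_az_after - wind_az_before)
    return -1.0 if shift < 0 else 1.0


def extract_conflict_changes(
    df: pd.DataFrame, alpha: float = 0.1, apply_screen: bool = True
) -> pd.DataFrame:
    """Per-beetle changes in heading from conflict-assay sessions.

    Sessions (keyed by beetle, day and cue setting) are screened on their
    six congruent exits, then yield one change per conflict level: first to
    second congruent exit for the 0-degree control, and the exit preceding
    each conflict exit to that conflict exit for 60/120 degrees. Changes are
    signed positive in the direction of the wind shift.
    """
    rows = []
    for keys, session in df.groupby(SESSION_KEYS, sort=True):
        s = _session_frame(session)
        if apply_screen and not conflict_screen(s, alpha=alpha):
            continue
        bearings = s["exit_bearing_deg"].to_numpy()
        wind_az = s["wind_azimuth_deg"].to_numpy()
        conflicts = s["conflict_deg"].to_numpy()
        keyd = dict(zip(SESSION_KEYS, keys))
        # 0-degree control: first and second exits, cues unchanged
        rows.append(
            {**keyd, "conflict_deg": 0.0,
             "change_deg": change_in_heading(bearings[0], bearings[1])}
        )
        for pos in CONFLICT_POSITIONS:
            i = pos - 1
            sign = _shift_sign(wind_az[i - 1], wind_az[i])
            rows.append(
                {**keyd, "conflict_deg": float(conflicts[i]),
                 "change_deg": sign * change_in_heading(bearings[i - 1], bearings[i])}
            )
    return pd.DataFrame(
        rows,
        columns=SESSION_KEYS + ["conflict_deg", "change_deg"],
    )


def summarize_condition(changes_deg) -> dict:
    """Circular mean, circular SD (degrees), Rayleigh p and n of changes."""
    changes = np.atleast_1d(np.asarray(changes_deg, dtype=float))
    if changes.size < 2:
        raise ValueError("need at least 2 changes to summarise")
    summary = mean_resultant(np.radians(changes))
    _, p = rayleigh_test(np.radians(changes))
    return {
        "mean_deg": math.degrees(summary.mean_angle),
        "circ_sd_deg": math.degrees(summary.circ_sd)
        if math.isfinite(summary.circ_sd)
        else math.inf,
        "rayleigh_p": p,
        "n": int(changes.size),
    }


def per_beetle_R(
    df: pd.DataFrame,
    bearing_col: str = "exit_bearing_deg",
    group_col: str = "beetle_id",
) -> pd.Series:
    """Mean vector length per beetle from the given bearing column."""
    return df.groupby(group_col, sort=True)[bearing_col].apply(
        lambda b: mean_resultant(np.radians(b.to_numpy())).R
    )


def summarize_reliability(
    df: pd.DataFrame, cue: str = "light", alpha: float = 0.05
) -> pd.DataFrame:
    """Per-condition precision summary of a single-cue reliability table.

    For each cue setting: per-beetle R (all beetles, including those failing
    the orientation screen, as precision includes them), the median R and
    IQR (linear interpolation between order statistics), and the menotaxis
    classification from the oriented beetles' mean bearings.
    """
    setting_col = "light_elevation_deg" if cue == "light" else "wind_speed_ms"
    rows = []
    for setting, grp in df.groupby(setting_col, sort=True):
        series = beetle_series(grp, cue=cue)
        r_values = np.array([s.summary.R for s in series])
        oriented = [s for s in series if reliability_screen(s, alpha=alpha)]
        if len(oriented) >= 2:
            means = [math.degrees(s.summary.mean_angle) for s in oriented]
            _, p = rayleigh_test(np.radians(means))
            tactic = menotaxis_test(means, alpha=alpha)
        else:
            p, tactic = math.nan, "n/a"
        q25, q50, q75 = np.percentile(r_values, [25, 50, 75])
        rows.append(
            {
                setting_col: setting,
                "n": len(series),
                "n_oriented": len(oriented),
                "median_R": q50,
                "iqr_low": q25,
                "iqr_high": q75,
                "population_rayleigh_p": p,
                "tactic": tactic,
                "note": "",
            }
        )
    return pd.DataFrame(rows)
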