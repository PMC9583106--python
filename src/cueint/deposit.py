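"""Loader for a locally provided copy of the deposited behavioural data.

The published exit-angle dataset is not redistributed with this package; to
run the data-dependent benchmarks, convert it to the exit-table schema (see
:mod:`cueint.io_cli`) and place the files under ``data/zenodo/`` (or point
the ``CUEINT_DATA_DIR`` environment variable at them):

* ``reliability_light.csv`` - sun-reliability exits (10 per beetle)
* ``reliability_wind.csv``  - wind-reliability exits (10 per beetle)
* ``conflict.csv``          - 8-exit conflict-assay sessions
* ``precision.csv``         - 36-exit individual-precision sessions

An optional ``mapping.json`` ({filename: {source column: schema column}})
adapts files whose headers differ from the schema.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import pandas as pd

from .io_cli import read_exit_csv

__all__ = ["find_data_dir", "load_deposited", "DEPOSIT_FILES"]

DEPOSIT_FILES = (
    "reliability_light.csv",
    "reliability_wind.csv",
    "conflict.csv",
    "precision.csv",
)


def find_data_dir(repo_root: Path | None = None) -> Path | None:
    """Locate the local deposit copy; None when unavailable."""
    env = os.environ.get("CUEINT_DATA_DIR")
    candidates = [Path(env)] if env else []
    root = repo_root or Path(__file__).resolve().parents[2]
    candidates.append(root / "data" / "zenodo")
    for c in candidates:
        if c.is_dir() and any(c.glob("*.csv")):
            return c
    return None


def load_deposited(data_dir: Path, name: str) -> pd.DataFrame:
    """Read one deposit file through the schema validator."""
    path = Path(data_dir) / name
    if not path.exists():
        raise FileNotFoundError(
            f"{name} not found in {data_dir}; see cueint.deposit docs for the "
            "expected layout"
        )
    mapping = None
    mapping_path = Path(data_dir) / "mapping.json"
    if mapping_path.exists():
        mapping = json.loads(mapping_path.read_text()).get(name)
    return read_exit_csv(path, mapping=mapping)
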