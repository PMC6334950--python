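"""CSV/YAML plumbing shared by the CLI: schema checks and config loading.

The cohort lives in a single flat CSV, one row per animal, decimal point
".", comma delimiter, units fixed by the schema (see the column constants of
the blood, urine and synthetic modules). Derived-variable output is written
with 4 decimal places.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

__all__ = ["read_table", "write_derived", "require_columns", "load_config",
           "config_hash", "BLOOD_INPUT_COLUMNS", "URINE_INPUT_COLUMNS"]

BLOOD_INPUT_COLUMNS = [
    "pH_v", "pCO2_v", "ctHb", "body_temp", "cNa", "cK", "cCa_ion", "cCl",
    "cLactate", "cPi", "cMg_total", "cAlbumin", "cTotalProtein",
]
URINE_INPUT_COLUMNS = ["cBE_u", "cAE_u", "cAmm_u"]


def require_columns(df: pd.DataFrame, columns, what: str = "input") -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


def read_table(path) -> pd.DataFrame:
    """Read a delimited cohort table, surfacing the offending location on
    malformed rows."""
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"input file not found: {path}") from exc


def write_derived(df: pd.DataFrame, path) -> None:
    """Write derived-variable output with fixed 4-decimal formatting."""
    df.to_csv(path, index=False, float_format="%.4f")


def load_config(path) -> dict:
    """Load a YAML (or JSON) pipeline configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(data).__name__}")
    return data


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for run logs."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
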