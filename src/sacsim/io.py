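"""Tidy CSV / JSON output helpers shared by the CLI and scripts."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def write_tidy_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=_jsonify) + "\n")
    return path


def _jsonify(x):
    import numpy as np
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def trajectory_long_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Wide time x species table -> tidy (time, species, value)."""
    return df.melt(id_vars=["time"], var_name="species", value_name="value")
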