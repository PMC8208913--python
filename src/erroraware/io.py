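"""Plain-text / HDF5 persistence for pipeline artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_trial_table", "read_trial_table", "write_json"]


def write_trial_table(trials: pd.DataFrame, path) -> None:
    """Tab-separated trial table with a header row."""
    trials.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_trial_table(path) -> pd.DataFrame:
    # keep literal "n/a" category labels; only "NA" marks missing values
    df = pd.read_csv(path, sep="\t", na_values=["NA"],
                     keep_default_na=False)
    df["trial_nr"] = df["trial_nr"].astype(int)
    return df


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder))
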