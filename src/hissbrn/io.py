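"""CSV schemas and readers/writers for the pipeline artifacts."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

TRIALS_COLUMNS = [
    "female_id",
    "day_centred",
    "stage",
    "julian_date",
    "time_mean",
    "time_dev",
    "age_class",
    "hiss_count",
    "hiss_std",
]

FEMALES_COLUMNS = [
    "female_id",
    "lay_date",
    "clutch_size",
    "nest_success",
    "n_fledged",
    "mean_fledgling_mass",
]


class SchemaError(ValueError):
    """A table is missing required columns."""


def _require(df: pd.DataFrame, columns: list[str], what: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing columns {missing}")
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    _require(df, TRIALS_COLUMNS, "trials table")
    df[TRIALS_COLUMNS].to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    return _require(pd.read_csv(path), TRIALS_COLUMNS, str(path))


def write_females(df: pd.DataFrame, path: str | Path) -> None:
    _require(df, FEMALES_COLUMNS, "females table")
    df[FEMALES_COLUMNS].to_csv(path, index=False)


def read_females(path: str | Path) -> pd.DataFrame:
    return _require(pd.read_csv(path), FEMALES_COLUMNS, str(path))


def write_id_samples_long(id_samples, trait_order, path: str | Path) -> None:
    """Long-format dump of posterior ID-matrix samples."""
    rows = []
    for s, mat in enumerate(id_samples):
        for i, ta in enumerate(trait_order):
            for j, tb in enumerate(trait_order):
                if j < i:
                    continue
                rows.append((s, ta, tb, mat[i, j]))
    pd.DataFrame(
        rows, columns=["sample_index", "trait_row", "trait_col", "value"]
    ).to_csv(path, index=False)


def read_id_samples_long(path: str | Path, trait_order) -> "np.ndarray":
    import numpy as np

    df = pd.read_csv(path)
    idx = {t: i for i, t in enumerate(trait_order)}
    n = int(df["sample_index"].max()) + 1
    k = len(trait_order)
    out = np.zeros((n, k, k))
    i = df["trait_row"].map(idx).to_numpy()
    j = df["trait_col"].map(idx).to_numpy()
    s = df["sample_index"].to_numpy()
    v = df["value"].to_numpy()
    out[s, i, j] = v
    out[s, j, i] = v
    return out
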