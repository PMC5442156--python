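"""Readers and writers for the pipeline's on-disk artifacts.

All tables are tab-separated text with a schema comment line
(``# mitoscreen-table v1 name=<name>``) followed by a header row; movies
are multi-frame grayscale TIFF stacks, one file per channel.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

SCHEMA_PREFIX = "# mitoscreen-table"
SCHEMA_VERSION = "v1"


def write_table(df: pd.DataFrame, path: str | Path, name: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"{SCHEMA_PREFIX} {SCHEMA_VERSION} name={name}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(SCHEMA_PREFIX):
            raise ValueError(f"{path} is not a mitoscreen table (missing schema line)")
        parts = first.strip().split()
        if parts[2] != SCHEMA_VERSION:
            raise ValueError(f"unsupported table schema {parts[2]}")
        df = pd.read_csv(fh, sep="\t")
    df.attrs["name"] = first.strip().split("name=", 1)[1]
    return df


def write_movie(stacks: dict[str, np.ndarray], directory: str | Path, prefix: str = "movie") -> list[Path]:
    """One multi-frame TIFF per channel: ``<prefix>_<channel>.tif``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for channel, stack in stacks.items():
        p = directory / f"{prefix}_{channel}.tif"
        tifffile.imwrite(p, stack)
        paths.append(p)
    return paths


def read_movie(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)
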