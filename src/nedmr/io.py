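"""Readers and writers for the plain-text formats used by the pipeline.

BED intervals (0-based, half-open), TSV matrices with a header row and the
row identifier in the first column, TSV label tables, and JSON manifests.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_bed",
    "write_bed",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "write_json",
    "read_json",
]


def read_bed(path, one_based: bool = False) -> pd.DataFrame:
    """Read a BED file into chrom/start/end (+ extra columns preserved).

    ``one_based=True`` shifts starts by -1 to convert inclusive 1-based
    input to the internal 0-based half-open convention.  Malformed lines
    raise with their line number.
    """
    rows = []
    extra_names: list[str] | None = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 tab-separated columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            if one_based:
                start -= 1
            if end < start:
                raise ValueError(f"{path}:{ln}: end < start ({end} < {start})")
            if extra_names is None:
                extra_names = [f"col{i + 4}" for i in range(len(parts) - 3)]
            rows.append([parts[0], start, end, *parts[3:]])
    cols = ["chrom", "start", "end", *(extra_names or [])]
    df = pd.DataFrame(rows, columns=cols)
    # conventional BED extras: name, score
    if "col4" in df.columns:
        df = df.rename(columns={"col4": "name"})
    if "col5" in df.columns:
        df = df.rename(columns={"col5": "score"})
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    """Write chrom/start/end plus any extra columns as a headerless BED."""
    cols = ["chrom", "start", "end"] + [
        c for c in df.columns if c not in ("chrom", "start", "end")
    ]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_matrix(path) -> pd.DataFrame:
    """TSV matrix with a header row; first column is the row identifier."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_labels(s: pd.Series, path, index_label: str = "sample") -> None:
    s.to_frame().to_csv(path, sep="\t", index_label=index_label)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=str)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
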