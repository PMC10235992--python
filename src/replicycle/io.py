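"""Plain-text table I/O for the pipeline's interchange files.

All stages exchange TSV tables (cells.tsv, detections.tsv, truth_events.tsv,
supercells.tsv, tracks.tsv, events.tsv) plus small JSON sidecars, so every
artifact stays inspectable with standard shell tools.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["write_tsv", "read_tsv", "write_json", "read_json"]

_FLOAT_FMT = "%.10g"


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
    return path


def read_json(path):
    return json.loads(Path(path).read_text())
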