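"""File I/O: multi-page TIFF fields, CSV tables, atomic writes."""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

DNA_PAGE = 0
REPORTER_PAGE = 1


def write_field_tiff(path: str | Path, dna: np.ndarray, reporter: np.ndarray) -> None:
    """Write one field as a two-page TIFF (page 0 = DNA, page 1 = reporter)."""
    stack = np.stack([dna, reporter]).astype(np.float32)
    tifffile.imwrite(str(path), stack)


def read_field_tiff(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    stack = tifffile.imread(str(path))
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError(f"{path}: expected a 2-page TIFF stack")
    return stack[DNA_PAGE].astype(float), stack[REPORTER_PAGE].astype(float)


def write_label_tiff(path: str | Path, labels: np.ndarray) -> None:
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    atomic_write_text(path, df.to_csv(index=False))


def write_json(obj, path: str | Path) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
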