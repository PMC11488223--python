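"""File I/O: tables (CSV/TSV), GMT gene sets, label masks, manifests.

Tables are UTF-8 CSV/TSV with a header row and '.' decimal separator.  Masks
are 16-bit single-channel TIFF or PNG label images (0 = background).  GMT
lines are ``name<TAB>description<TAB>gene...``.  Every writer has a matching
reader such that read(write(x)) round-trips.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "read_table", "write_table", "read_gmt", "write_gmt",
    "read_mask", "write_mask", "write_manifest",
]


class MalformedFileError(ValueError):
    pass


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_table(path, index_col=None) -> pd.DataFrame:
    """Read a CSV/TSV table with a header row; errors carry line numbers."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table: {path}")
    try:
        return pd.read_csv(path, sep=_sep_for(path), index_col=index_col)
    except pd.errors.ParserError as exc:  # pandas reports the offending line
        raise MalformedFileError(f"{path}: {exc}") from exc


def write_table(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), index=index)
    return path


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name, description, then member genes."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MalformedFileError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path,
              descriptions: dict[str, str] | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in gene_sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")
    return path


def read_mask(path) -> np.ndarray:
    """Read a 16-bit label image (TIFF or PNG); background is label 0."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim != 2:
        raise MalformedFileError(f"{path}: expected a single-channel label image")
    return arr.astype(np.uint16)


def write_mask(mask: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(mask)
    if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels out of uint16 range")
    arr = arr.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)
    return path


def write_manifest(path, config: dict, seed: int | None = None) -> Path:
    """Record the run configuration, seed and versions for reproducibility."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "evmorph_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "config": config,
    }
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
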