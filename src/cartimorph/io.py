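"""Standard-format I/O: TIFF/PNG images in, CSV/JSON/YAML out.

CSV floats are serialized with 12 significant digits and stable column
order; images round-trip bit-identically (lossless TIFF and PNG only).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

FLOAT_FORMAT = "%.12g"


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF or PNG raster image."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            return tifffile.imread(path)
        return iio.imread(path)
    except Exception as exc:  # corrupt file
        raise ValueError(f"unreadable image {path}: {exc}") from exc


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a raster image losslessly (TIFF for grayscale stacks, PNG
    for 8-bit masks)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    """Write a CSV with stable column order and >= 10 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a CSV, checking that required columns are present."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    df = pd.read_csv(path)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path} missing required columns: {sorted(missing)}")
    return df


def write_json(path: str | Path, obj: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_config(path: str | Path, config: dict) -> None:
    """Serialize a configuration mapping to YAML (round-trip stable)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config, sort_keys=True))


def read_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    return yaml.safe_load(path.read_text())
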