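"""TIFF input/output carrying physical pixel-size metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile


def write_tiff(path: str | Path, image: np.ndarray, pixel_size_um: float) -> None:
    """Write ``image`` as TIFF with pixel size recorded in the description tag."""
    meta = {"pixel_size_um": float(pixel_size_um)}
    tifffile.imwrite(str(path), image, description=json.dumps(meta))


def read_tiff(path: str | Path) -> tuple[np.ndarray, float | None]:
    """Read a TIFF, returning (array, pixel_size_um or None if absent)."""
    with tifffile.TiffFile(str(path)) as tif:
        image = tif.asarray()
        desc = tif.pages[0].description
    pixel_size = None
    if desc:
        try:
            meta = json.loads(desc)
            pixel_size = float(meta["pixel_size_um"])
        except (ValueError, KeyError, TypeError):
            pixel_size = None
    return image, pixel_size
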