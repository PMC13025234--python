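"""File conventions: multi-page TIFF + JSON sidecar, CSV tables.

Images are written as multi-page TIFF with one page per channel in the
fixed order (nuclear stain, nucleolin, fibrillarin, SC-35); physical
spacing, channel names and the generator seed live in an adjacent JSON
sidecar.  All tables are UTF-8 CSV with header rows and a fixed float
format, so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import GeometryError
from .geometry import ImageGeometry
from .synthdata.imaging import SyntheticImage



def sidecar_path(image_path: str | Path) -> Path:
    p = Path(image_path)
    return p.with_suffix(p.suffix + ".json")


def write_image(path: str | Path, image: SyntheticImage) -> Path:
    """Write channels as multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    stack = np.stack([image.channels[name] for name in image.channel_order])
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {
        "spacing_um": list(image.geometry.spacing),
        "channel_names": list(image.channel_order),
        "seed": image.seed,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_image(path: str | Path) -> tuple[dict[str, np.ndarray], ImageGeometry, int]:
    """Read a TIFF written by :func:`write_image`; returns channel
    arrays keyed by name, the geometry, and the generator seed."""
    path = Path(path)
    stack = tifffile.imread(path)
    meta = json.loads(sidecar_path(path).read_text())
    names = meta["channel_names"]
    if stack.shape[0] != len(names):
        raise GeometryError(
            f"TIFF has {stack.shape[0]} pages but sidecar names {len(names)} channels"
        )
    geometry = ImageGeometry(tuple(stack.shape[1:]), tuple(meta["spacing_um"]))
    channels = {name: stack[i] for i, name in enumerate(names)}
    return channels, geometry, int(meta.get("seed", 0))


def write_labels(path: str | Path, label_mask: np.ndarray, geometry: ImageGeometry,
                 channel: str = "") -> Path:
    """Write a label mask as TIFF with a sidecar carrying the spacing."""
    path = Path(path)
    tifffile.imwrite(path, label_mask.astype(np.int32), photometric="minisblack")
    meta = {"spacing_um": list(geometry.spacing), "channel_names": [channel],
            "kind": "labels"}
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_labels(path: str | Path) -> tuple[np.ndarray, ImageGeometry, str]:
    path = Path(path)
    mask = tifffile.imread(path)
    meta = json.loads(sidecar_path(path).read_text())
    geometry = ImageGeometry(tuple(mask.shape), tuple(meta["spacing_um"]))
    channel = (meta.get("channel_names") or [""])[0]
    return np.asarray(mask), geometry, channel


def write_table(path: str | Path, table: pd.DataFrame) -> Path:
    """Deterministic CSV output: floats use the shortest representation
    that round-trips exactly, so a table can be re-read and re-derived
    byte-identically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    # the default float parser can be one ulp off; exact round-tripping
    # is what makes re-derived reports byte-identical
    return pd.read_csv(path, float_precision="round_trip")


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
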