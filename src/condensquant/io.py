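"""File I/O: multi-channel TIFF, truth sidecars, profile/trace CSV, configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .dropletquant import MultiChannelField

__all__ = [
    "write_field_tiff",
    "read_field_tiff",
    "write_truth_json",
    "read_truth_json",
    "write_profile_csv",
    "read_profile_csv",
    "write_frap_csv",
    "read_frap_csv",
    "read_polylines",
    "load_config",
]

CSV_FLOAT_FORMAT = "%.10g"


def write_field_tiff(path, field: MultiChannelField) -> None:
    """Write one TIFF page per channel; channel names go to the description."""
    pages = np.stack([field.channel(n) for n in field.channel_names]).astype(np.float32)
    meta = {"channels": list(field.channel_names), "pixel_size_nm": field.pixel_size_nm}
    tifffile.imwrite(path, pages, description=json.dumps(meta))


def read_field_tiff(
    path, channel_names=None, pixel_size_nm: float | None = None
) -> MultiChannelField:
    """Read a multi-page TIFF into a MultiChannelField.

    Channel names / pixel size are taken from the embedded description
    written by :func:`write_field_tiff` unless overridden.
    """
    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if pages.ndim == 2:
        pages = pages[None]
    names = channel_names or meta.get("channels") or [f"ch{i}" for i in range(len(pages))]
    px = pixel_size_nm or meta.get("pixel_size_nm") or 120.0
    channels = {name: pages[i].astype(float) for i, name in enumerate(names)}
    return MultiChannelField(channels, float(px))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_truth_json(path, truth) -> None:
    """Write a generative truth dataclass as a JSON sidecar."""
    from dataclasses import asdict, is_dataclass

    data = asdict(truth) if is_dataclass(truth) else dict(truth)
    Path(path).write_text(json.dumps(_jsonable(data), indent=2, sort_keys=True))


def read_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_profile_csv(path, positions_px, pixel_size_nm, **channels) -> None:
    """Profile CSV with position_px, position_um and one column per channel."""
    frame = pd.DataFrame({"position_px": positions_px})
    frame["position_um"] = frame["position_px"] * pixel_size_nm / 1000.0
    for name, values in channels.items():
        frame[name] = values
    frame.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def read_profile_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_frap_csv(path, frame: pd.DataFrame) -> None:
    """FRAP trace CSV (time_s, roi, reference, background); bleach frame in a header comment."""
    bleach = frame.attrs.get("bleach_frame")
    with open(path, "w") as fh:
        if bleach is not None:
            fh.write(f"# bleach_frame={int(bleach)}\n")
        frame.to_csv(fh, index=False, float_format=CSV_FLOAT_FORMAT)


def read_frap_csv(path) -> pd.DataFrame:
    bleach = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# bleach_frame="):
            bleach = int(first.strip().split("=", 1)[1])
            frame = pd.read_csv(fh)
        else:
            fh.seek(0)
            frame = pd.read_csv(fh)
    if bleach is not None:
        frame.attrs["bleach_frame"] = bleach
    return frame


def read_polylines(path) -> dict[str, np.ndarray]:
    """Read junction polylines from JSON or CSV.

    JSON: ``{"name": [[row, col], ...], ...}``.  CSV: columns
    ``polyline,row,col`` (0-based pixel coordinates, origin top-left),
    vertices in row order.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        return {k: np.asarray(v, dtype=float) for k, v in raw.items()}
    frame = pd.read_csv(path)
    required = {"polyline", "row", "col"}
    if not required.issubset(frame.columns):
        raise ValueError(f"polyline CSV needs columns {sorted(required)}")
    return {
        str(name): grp[["row", "col"]].to_numpy(dtype=float)
        for name, grp in frame.groupby("polyline", sort=True)
    }


def load_config(path) -> dict:
    """Load a YAML (or JSON) config file."""
    text = Path(path).read_text()
    return yaml.safe_load(text)
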