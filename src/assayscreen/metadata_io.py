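"""Plate-map metadata, image loading and table I/O.

An *experiment* is an ordered collection of image sets.  Each image set is
one microscope field with one file per channel plus the sample metadata a
screen needs: plate, well, compound, dose and control status.  Images are
loaded as float rasters scaled into [0, 1] by the dtype maximum so that
intensities are comparable across images and bit depths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CONTROL_ALIASES",
    "Experiment",
    "ImageSetRecord",
    "load_experiment",
    "read_image",
    "write_feature_table",
    "write_report",
]

#: Case-insensitive aliases for the control column.  Anything not listed is
#: treated as a regular (non-control) sample.
CONTROL_ALIASES: Mapping[str, str] = {
    "positive": "positive",
    "pos": "positive",
    "p": "positive",
    "negative": "negative",
    "neg": "negative",
    "n": "negative",
}

#: Number of significant digits used when writing float tables; chosen so a
#: write/read round trip reproduces IEEE doubles bit for bit.
FLOAT_FORMAT = "%.17g"


class MetadataError(ValueError):
    """Raised for malformed plate maps, with row/column context."""


@dataclass(frozen=True)
class ImageSetRecord:
    """One image set: channel files plus sample metadata."""

    set_id: str
    channel_paths: dict[str, str]
    plate: str = ""
    well: str = ""
    compound: str = ""
    dose: float = 0.0
    control: str = "sample"
    cell_type: str = ""
    dose_defaulted: bool = False

    def __post_init__(self):
        if self.control not in ("positive", "negative", "sample"):
            raise MetadataError(
                f"set {self.set_id!r}: control must be positive/negative/sample, "
                f"got {self.control!r}"
            )
        if not (self.dose >= 0):
            raise MetadataError(f"set {self.set_id!r}: dose must be >= 0, got {self.dose}")


@dataclass
class Experiment:
    """Ordered image-set records sharing a channel naming scheme."""

    records: list[ImageSetRecord]
    channel_names: list[str]

    def __post_init__(self):
        if not self.records:
            raise MetadataError("an experiment needs at least one image set")
        if not self.channel_names:
            raise MetadataError("channel_names must be non-empty")
        ids = [r.set_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise MetadataError(f"duplicate set_id(s): {dup}")

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def record(self, set_id: str) -> ImageSetRecord:
        for r in self.records:
            if r.set_id == set_id:
                return r
        raise KeyError(set_id)


def normalize_control(value: object) -> str:
    """Map a raw control label to positive/negative/sample (case-insensitive)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "sample"
    return CONTROL_ALIASES.get(str(value).strip().lower(), "sample")


def _channel_column(df: pd.DataFrame, channel: str) -> str:
    for cand in (f"path_{channel}", channel):
        if cand in df.columns:
            return cand
    raise MetadataError(
        f"missing channel path column for {channel!r} "
        f"(expected 'path_{channel}' or '{channel}')"
    )


def load_experiment(path: str | Path, channel_names: Sequence[str]) -> Experiment:
    """Read a CSV plate map into a validated :class:`Experiment`.

    The table needs one row per image set with columns ``set_id``, one path
    column per channel (``path_<channel>`` or the bare channel name), and
    ``plate``, ``well``, ``compound``, ``dose``, ``control`` (``cell_type``
    optional).  Control labels are normalized case-insensitively; missing
    control doses default to 0 (negative) or the maximum observed dose
    (positive), flagged via ``dose_defaulted``, so dose-series grouping
    always has endpoints.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"set_id": str, "plate": str, "well": str})
    if df.empty:
        raise MetadataError(f"{path}: plate map is empty")
    for col in ("set_id", "plate", "well", "compound", "dose", "control"):
        if col not in df.columns:
            raise MetadataError(f"{path}: missing required column {col!r}")
    chan_cols = {c: _channel_column(df, c) for c in channel_names}

    doses: list[float | None] = []
    controls: list[str] = []
    for i, row in df.iterrows():
        controls.append(normalize_control(row["control"]))
        raw = row["dose"]
        if pd.isna(raw) or (isinstance(raw, str) and not raw.strip()):
            doses.append(None)
            continue
        try:
            doses.append(float(raw))
        except (TypeError, ValueError):
            raise MetadataError(
                f"{path}: row {i}: unparseable dose {raw!r}"
            ) from None

    known = [d for d in doses if d is not None]
    max_dose = max(known) if known else 1.0

    records = []
    for i, row in df.iterrows():
        dose, defaulted = doses[i], False
        if dose is None:
            defaulted = True
            if controls[i] == "negative":
                dose = 0.0
            elif controls[i] == "positive":
                dose = max_dose
            else:
                raise MetadataError(f"{path}: row {i}: sample well without a dose")
        records.append(
            ImageSetRecord(
                set_id=str(row["set_id"]),
                channel_paths={c: str(row[chan_cols[c]]) for c in channel_names},
                plate=str(row["plate"]),
                well=str(row["well"]),
                compound="" if pd.isna(row["compound"]) else str(row["compound"]),
                dose=dose,
                control=controls[i],
                cell_type=str(row.get("cell_type", "")) if "cell_type" in df.columns else "",
                dose_defaulted=defaulted,
            )
        )
    return Experiment(records=records, channel_names=list(channel_names))


def read_image(path: str | Path) -> np.ndarray:
    """Load an 8- or 16-bit grayscale image as a float64 raster in [0, 1].

    Integer pixel values are divided by the dtype maximum (255 or 65535),
    never by the observed maximum, so intensities compare across images.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected single-plane grayscale, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        raise ValueError(f"{path}: unsupported bit depth / dtype {arr.dtype}")
    return arr.astype(np.float64) / scale


def check_raster(pixels: np.ndarray) -> np.ndarray:
    """Validate an intensity raster: 2-D, finite, within [0, 1]."""
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError(f"raster must be 2-D and non-empty, got shape {pixels.shape}")
    if not np.isfinite(pixels).all():
        raise ValueError("raster contains non-finite pixels")
    if pixels.min() < 0 or pixels.max() > 1:
        raise ValueError("raster values must lie in [0, 1]")
    return pixels


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table to CSV (17 significant digits; NaN -> empty cell)."""
    if table.empty:
        raise ValueError("refusing to write an empty feature table")
    table.to_csv(path, float_format=FLOAT_FORMAT, index=True)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read back a feature table written by :func:`write_feature_table`."""
    return pd.read_csv(path, index_col=0, float_precision="round_trip")


def write_report(report, path: str | Path) -> None:
    """Write a ranked screening report to CSV.

    Columns: feature, category, zprime, vfactor, band, rank — rows already
    in rank order.
    """
    report.to_frame().to_csv(path, float_format=FLOAT_FORMAT, index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
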