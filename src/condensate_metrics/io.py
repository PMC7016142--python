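"""Readers and writers shared by all pipeline stages.

Formats are deliberately plain: single-channel TIFF for images (pixel size
recorded both in the TIFF resolution tags and in a sidecar JSON), CSV for
tabular data and TSV for peak lists (spectroscopy convention).  The CSV
dialect is pinned — UTF-8, comma separator, dot decimal, LF endings — and
units are carried in column names (``…_nm``, ``…_uM``, ``…_s``); a table
whose unit suffixes do not match the expected schema is rejected outright
rather than converted, which prevents silent nm/µm confusion.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging import FluorescenceImage

logger = logging.getLogger("condensate_metrics")

__all__ = [
    "SchemaError",
    "read_image",
    "write_image",
    "read_table",
    "write_table",
    "VESICLE_COLUMNS",
    "PEAK_COLUMNS",
    "DECAY_COLUMNS",
]

VESICLE_COLUMNS = ["x_nm", "y_nm", "z_nm", "radius_nm"]
PEAK_COLUMNS = ["residue_id", "intensity", "noise"]
DECAY_COLUMNS = ["residue_id", "delay_s", "intensity"]


class SchemaError(ValueError):
    """A table does not match the expected column/unit schema."""


def write_image(
    path: str | Path, image: FluorescenceImage, dtype: str = "float32"
) -> Path:
    """Write a single-channel TIFF plus a sidecar JSON with the pixel size.

    ``dtype`` may be ``"float32"`` or ``"uint16"``; the resolution tag
    records pixels per centimetre.
    """
    path = Path(path)
    if dtype == "uint16":
        data = np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        data = image.pixels.astype(np.float32)
    else:
        raise ValueError("dtype must be 'float32' or 'uint16'")
    px_per_cm = 1e7 / image.pixel_size_nm
    tifffile.imwrite(
        path, data, resolution=(px_per_cm, px_per_cm), resolutionunit="CENTIMETER"
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"pixel_size_nm": image.pixel_size_nm,
             "channel_label": image.channel_label},
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    return path


def read_image(path: str | Path, pixel_size_nm: float | None = None) -> FluorescenceImage:
    """Read a single-channel TIFF into a :class:`FluorescenceImage`.

    Pixel size priority: explicit ``pixel_size_nm`` argument, then sidecar
    JSON (``<file>.json``), then the TIFF resolution tags; conflicting
    sources log a warning and the higher-priority one wins.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        pixels = page.asarray().astype(float)
        tag_px = None
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is not None and res.value[0] > 0:
            per_unit = res.value[0] / res.value[1]
            unit_nm = {2: 2.54e7, 3: 1e7}.get(getattr(unit.value, "value", unit.value) if unit else 2)
            if unit_nm:
                tag_px = unit_nm / per_unit

    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar_px, label = None, ""
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
        sidecar_px = meta.get("pixel_size_nm")
        label = meta.get("channel_label", "")

    candidates = [("argument", pixel_size_nm), ("sidecar", sidecar_px), ("TIFF tags", tag_px)]
    known = [(src, v) for src, v in candidates if v is not None]
    if not known:
        raise ValueError(f"no pixel size available for {path}; pass pixel_size_nm")
    src, chosen = known[0]
    for other_src, v in known[1:]:
        if abs(v - chosen) / chosen > 1e-3:
            logger.warning(
                "pixel size conflict for %s: %s=%.4g nm vs %s=%.4g nm; using %s",
                path, src, chosen, other_src, v, src,
            )
    return FluorescenceImage(pixels=pixels, pixel_size_nm=float(chosen), channel_label=label)


def _check_schema(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if not missing:
        return
    # a missing unit-suffixed column whose stem exists under another suffix
    # is a unit mismatch, reported as such
    for col in missing:
        stem = col.rsplit("_", 1)[0]
        wrong = [c for c in df.columns if c.rsplit("_", 1)[0] == stem and c != col]
        if wrong:
            raise SchemaError(
                f"{path}: column {wrong[0]!r} has the wrong unit suffix; "
                f"expected {col!r} (no implicit unit conversion)"
            )
    raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_table(
    path: str | Path,
    required: list[str] | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Read a CSV/TSV with the pinned dialect and optional schema check."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep, decimal=".", encoding="utf-8", comment="#")
    if required:
        _check_schema(df, required, path)
    return df


def write_table(path: str | Path, df: pd.DataFrame, sep: str = ",") -> Path:
    """Write a CSV/TSV with the pinned dialect (UTF-8, dot decimal, LF)."""
    path = Path(path)
    df.to_csv(path, sep=sep, index=False, encoding="utf-8", lineterminator="\n")
    return path
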