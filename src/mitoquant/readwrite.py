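"""TIFF/CSV/JSON input and output.

Integer TIFFs round-trip bit-exactly. The physical pixel size is resolved
in this order: TIFF resolution tags (X/YResolution + ResolutionUnit,
written here as pixels per centimetre), then the config value, else an
error naming the missing field. Region tables are written as CSV in the
fixed column order of :data:`mitoquant.images.REGION_TABLE_COLUMNS`.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import AnalysisConfig
from .images import BinaryMask, ChannelRole, Image, ZStack

logger = logging.getLogger("mitoquant")

__all__ = ["read_image", "write_image", "write_mask", "write_results"]

_UM_PER_CM = 1.0e4


class MissingPixelSizeError(ValueError):
    """Raised when no pixel size is available from metadata or config."""


def _pixel_size_from_tags(page: "tifffile.TiffPage") -> float | None:
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0 or den == 0:
        return None
    px_per_unit = num / den
    unit = int(tags["ResolutionUnit"].value)
    if unit == 3:  # centimetre
        return _UM_PER_CM / px_per_unit
    if unit == 2:  # inch
        return 25400.0 / px_per_unit
    return None


def _bit_origin(dtype: np.dtype) -> str:
    if dtype == np.uint8:
        return "u8"
    if dtype == np.uint16:
        return "u16"
    return "float"


def read_image(
    path: str | Path,
    config: AnalysisConfig | None = None,
    channel_role: str | ChannelRole = ChannelRole.OTHER,
) -> Image | ZStack:
    """Read a single- or multi-page TIFF into an Image or ZStack.

    Intensities are preserved bit-exactly (integer data is widened to
    float64, which is lossless for 8/16-bit). Pixel size resolves
    metadata -> config -> :class:`MissingPixelSizeError`.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.pages
        ps = _pixel_size_from_tags(pages[0])
        if ps is None and config is not None:
            ps = config.pixel_size_um
        if ps is None:
            raise MissingPixelSizeError(
                f"{path}: no resolution tags and no pixel_size_um in config"
            )
        planes = []
        for page in pages:
            data = page.asarray()
            planes.append(Image(data, ps, channel_role, _bit_origin(data.dtype)))
    if len(planes) == 1:
        return planes[0]
    z = config.z_step_um if config is not None else 1.0
    return ZStack(planes, z_step_um=z)


def write_image(path: str | Path, img: Image, dtype: str | None = None) -> None:
    """Write an Image as TIFF with resolution tags encoding the pixel size."""
    data = img.pixels
    if dtype is None:
        dtype = {"u8": "uint8", "u16": "uint16"}.get(img.bit_origin, "float32")
    if dtype in ("uint8", "uint16"):
        info = np.iinfo(dtype)
        data = np.clip(np.rint(data), info.min, info.max)
    data = data.astype(dtype)
    px_per_cm = _UM_PER_CM / img.pixel_size_um
    tifffile.imwrite(
        path,
        data,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def write_stack(path: str | Path, stack: ZStack, dtype: str = "float32") -> None:
    data = np.stack([p.pixels for p in stack.planes]).astype(dtype)
    px_per_cm = _UM_PER_CM / stack.planes[0].pixel_size_um
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def write_mask(path: str | Path, mask: BinaryMask, pixel_size_um: float) -> None:
    """Write a binary mask as an 8-bit 0/255 TIFF."""
    img = Image(mask.pixels.astype(np.float64) * 255.0, pixel_size_um, "other", "u8")
    write_image(path, img, dtype="uint8")


def write_results(
    tables: dict[str, pd.DataFrame],
    masks: dict[str, BinaryMask],
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    inputs: list[str] | None = None,
) -> dict:
    """Write result tables (CSV), masks (8-bit TIFF) and a JSON manifest.

    Returns the manifest, which lists every file written, the input paths,
    the config hash, and the package version. Re-running with identical
    inputs and config produces byte-identical CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or AnalysisConfig()
    written: list[str] = []
    for name, table in tables.items():
        p = out / f"{name}.csv"
        table.to_csv(p, index=False, lineterminator="\n")
        written.append(p.name)
        logger.info("wrote table %s (%d rows)", p, len(table))
    ps = config.pixel_size_um or 1.0
    for name, mask in masks.items():
        p = out / f"{name}.tif"
        write_mask(p, mask, ps)
        written.append(p.name)
        logger.info("wrote mask %s (%d foreground px)", p, mask.n_foreground)
    manifest = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "config": config.to_dict(),
        "inputs": inputs or [],
        "files": sorted(written),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
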