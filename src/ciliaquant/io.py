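"""Image and table I/O: per-channel grayscale TIFFs and long-format CSVs.

Each field of view is stored as one single-plane grayscale TIFF per channel,
named ``<donor>__<condition_alias>__<antibody>__img<NNN>__<color>.tif``.
Channel role (test / marker / nuclei) is carried by the filename colour token
plus an explicit role->colour mapping, never inferred from pixel statistics,
so fluorochrome colour switches are a pure configuration change.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .vocab import (
    DEFAULT_PIXEL_SIZE_UM,
    DEFAULT_ROLE_TO_COLOR,
    is_known_antibody,
    is_known_condition,
    normalize_condition,
)

logger = logging.getLogger(__name__)

_IMG_RE = re.compile(r"^img(\d+)$")


def parse_image_filename(name: str) -> dict[str, str] | None:
    """Parse ``<donor>__<condition>__<antibody>__img<NNN>__<color>.tif``.

    Fields are separated by double underscores; single underscores inside a
    field (condition aliases like ``RT_RT_m80``) are preserved.  Returns None
    for names outside the convention.
    """
    stem, dot, ext = name.rpartition(".")
    if ext.lower() not in ("tif", "tiff") or not dot:
        return None
    parts = stem.split("__")
    if len(parts) != 5:
        return None
    donor, condition, antibody, img, color = parts
    m = _IMG_RE.match(img)
    if m is None or not (donor and condition and antibody and color.isalpha()):
        return None
    return {
        "donor": donor,
        "condition": condition,
        "antibody": antibody,
        "index": m.group(1),
        "color": color,
    }


@dataclass(frozen=True)
class ChannelImage:
    """One 2-D grayscale intensity grid with its role and pixel size."""

    pixels: np.ndarray
    role: str
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(
                f"ChannelImage requires a 2-D grid, got shape {px.shape}; "
                "export each channel as a separate single-plane grayscale file"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("ChannelImage pixels must be finite")
        if px.size and px.min() < 0:
            raise ValueError("ChannelImage pixels must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class ImageSet:
    """All channel files for one field of view, keyed by colour token."""

    image_id: str
    paths: dict[str, Path] = field(default_factory=dict)

    def channel(
        self,
        role: str,
        role_to_color: Mapping[str, str] = DEFAULT_ROLE_TO_COLOR,
        pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    ) -> ChannelImage:
        color = role_to_color[role]
        return read_channel(self.paths[color], role, pixel_size_um)


@dataclass
class SlideRecord:
    """One stained slide: metadata triple plus its field-of-view image sets."""

    donor: str
    condition: str
    antibody: str
    images: list[ImageSet] = field(default_factory=list)
    delta: float | None = None
    seed: int | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.donor, self.condition, self.antibody)


def read_channel(
    path: str | Path,
    role: str,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> ChannelImage:
    """Read one single-plane grayscale TIFF as a :class:`ChannelImage`.

    8- and 16-bit integer inputs are accepted and preserved losslessly.
    Multi-plane or RGB files are rejected with a message asking for
    per-channel export.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single-plane grayscale image, got shape "
            f"{arr.shape}; export each channel as a separate grayscale TIFF"
        )
    return ChannelImage(pixels=arr, role=role, pixel_size_um=pixel_size_um)


def write_channel(path: str | Path, pixels: np.ndarray) -> Path:
    """Write a 2-D array as an uncompressed grayscale TIFF.

    Float inputs are quantized to 16-bit (values clipped to [0, 65535]);
    integer inputs are written as-is.  No timestamp is embedded so identical
    arrays produce byte-identical files.
    """
    path = Path(path)
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D pixel grid, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr, photometric="minisblack")
    return path


def discover_slides(
    root: str | Path,
    role_to_color: Mapping[str, str] = DEFAULT_ROLE_TO_COLOR,
) -> tuple[list[SlideRecord], list[str]]:
    """Group channel files under ``root`` into validated :class:`SlideRecord`s.

    Returns ``(records, warnings)``.  Image sets missing the test or marker
    channel are excluded and listed in the warnings; unknown condition or
    antibody tokens are flagged on the record but kept, so vocabularies beyond
    the 7x8 study design remain processable.  Discovery is order-independent:
    files are grouped by parsed key and sorted, so the directory listing order
    never matters.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"slide directory not found: {root}")

    groups: dict[tuple[str, str, str], dict[str, dict[str, Path]]] = {}
    warnings: list[str] = []
    for path in sorted(root.rglob("*.tif")) + sorted(root.rglob("*.tiff")):
        m = parse_image_filename(path.name)
        if m is None:
            warnings.append(f"unrecognized filename skipped: {path.name}")
            continue
        donor = m["donor"]
        condition = normalize_condition(m["condition"])
        antibody = m["antibody"]
        image_id = f"img{m['index']}"
        slide = groups.setdefault((donor, condition, antibody), {})
        slide.setdefault(image_id, {})[m["color"].lower()] = path

    required = {role_to_color["test"], role_to_color["marker"]}
    records: list[SlideRecord] = []
    for (donor, condition, antibody) in sorted(groups):
        image_sets: list[ImageSet] = []
        flags: list[str] = []
        if not is_known_condition(condition):
            flags.append(f"unknown condition token: {condition}")
        if not is_known_antibody(antibody):
            flags.append(f"unknown antibody token: {antibody}")
        for image_id in sorted(groups[(donor, condition, antibody)]):
            channels = groups[(donor, condition, antibody)][image_id]
            missing = required - channels.keys()
            if missing:
                warnings.append(
                    f"{donor}/{condition}/{antibody}/{image_id}: missing "
                    f"channel(s) {sorted(missing)}; image set excluded"
                )
                continue
            image_sets.append(ImageSet(image_id=image_id, paths=dict(channels)))
        if image_sets:
            records.append(
                SlideRecord(donor, condition, antibody, image_sets, flags=flags)
            )
    for w in warnings:
        logger.warning(w)
    return records, warnings


def write_table(rows: pd.DataFrame | Iterable[Mapping], path: str | Path,
                columns: Sequence[str] | None = None) -> Path:
    """Write a table as CSV with full float precision (round-trip safe to at
    least 12 significant digits)."""
    path = Path(path)
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if columns is not None:
        if df.empty and len(df.columns) == 0:
            df = pd.DataFrame(columns=list(columns))
        else:
            df = df.reindex(columns=list(columns))
    df.to_csv(path, index=False, float_format="%.15g")
    return path


def read_table(path: str | Path, required: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, optionally validating that required columns exist."""
    df = pd.read_csv(path)
    if required is not None:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{Path(path).name}: missing column(s) {missing}")
    return df
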