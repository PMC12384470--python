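"""Primary-object identification, run independently per channel.

Smoothing -> global threshold -> 8-connected components -> hole filling ->
size filter, with every knob exposed in :class:`SegmentationConfig`.  Objects
touching the image border are kept: tufts of partially imaged cells still
carry signal and no exclusion rule is imposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

from .io import ChannelImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationConfig:
    """Settings for one channel's object identification.

    smoothing_sigma
        Gaussian pre-smoothing in px (0 disables).
    threshold_method
        "otsu_log" (default: two-class Otsu on log1p intensities — with a few
        very bright objects over a dim extended signal, raw-intensity Otsu
        lands halfway up the bright class and misses the dim one entirely),
        "otsu" (two-class on raw intensities), or "fixed"
        (use ``fixed_threshold``).
    threshold_correction
        Multiplicative factor applied to the computed threshold.
    min_area / max_area
        Object size window in px; components outside it are dropped.
    fill_holes
        Fill enclosed background holes inside each object.
    """

    smoothing_sigma: float = 1.0
    threshold_method: str = "otsu_log"
    threshold_correction: float = 1.0
    fixed_threshold: float = 0.0
    min_area: int = 40
    max_area: int = 1_000_000
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if not 0 < self.min_area < self.max_area:
            raise ValueError("need 0 < min_area < max_area")
        if self.threshold_correction <= 0:
            raise ValueError("threshold_correction must be > 0")
        if self.threshold_method not in ("otsu", "otsu_log", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")


class LabeledObjects:
    """Integer label map (0 = background) with consecutive labels 1..n."""

    def __init__(self, label_map: np.ndarray):
        label_map = np.asarray(label_map)
        if label_map.ndim != 2:
            raise ValueError("label map must be 2-D")
        self.label_map = label_map.astype(np.int32)
        self.n_objects = int(label_map.max())
        # precomputed per-object pixel coordinates
        self._slices = ndimage.find_objects(self.label_map)

    def object_mask(self, object_id: int) -> np.ndarray:
        """Binary mask of one object; raises KeyError for unknown ids."""
        if not 1 <= object_id <= self.n_objects:
            raise KeyError(
                f"object id {object_id} outside 1..{self.n_objects}"
            )
        return self.label_map == object_id

    def areas(self) -> np.ndarray:
        """Pixel count per object, index i -> object i+1."""
        if self.n_objects == 0:
            return np.zeros(0, dtype=np.int64)
        return np.bincount(self.label_map.ravel(), minlength=self.n_objects + 1)[1:]

    def __len__(self) -> int:
        return self.n_objects


def object_mask(objs: LabeledObjects, object_id: int) -> np.ndarray:
    return objs.object_mask(object_id)


def segment_channel(img: ChannelImage | np.ndarray,
                    cfg: SegmentationConfig = SegmentationConfig()) -> LabeledObjects:
    """Identify objects in one channel.

    Deterministic for fixed input and config.  A constant image (threshold
    undefined) yields zero objects with a logged warning.  Components whose
    area falls outside [min_area, max_area] are removed and the survivors
    relabelled consecutively.
    """
    pixels = img.pixels if isinstance(img, ChannelImage) else np.asarray(img, dtype=float)
    if not np.all(np.isfinite(pixels)):
        raise ValueError("image contains non-finite pixels")
    work = pixels.astype(float)
    if cfg.smoothing_sigma > 0:
        work = ndimage.gaussian_filter(work, sigma=cfg.smoothing_sigma)

    if cfg.threshold_method == "fixed":
        thr = cfg.fixed_threshold
    else:
        data = np.log1p(work) if cfg.threshold_method == "otsu_log" else work
        if np.ptp(data) == 0:
            logger.warning("constant image: threshold undefined, zero objects")
            return LabeledObjects(np.zeros_like(pixels, dtype=np.int32))
        t = threshold_otsu(data)
        thr = float(np.expm1(t)) if cfg.threshold_method == "otsu_log" else float(t)
    thr *= cfg.threshold_correction

    mask = work > thr
    if cfg.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    labels = sk_label(mask, connectivity=2)  # 8-connectivity
    if labels.max() == 0:
        return LabeledObjects(labels)

    areas = np.bincount(labels.ravel())
    keep = np.zeros(areas.size, dtype=bool)
    keep[1:] = (areas[1:] >= cfg.min_area) & (areas[1:] <= cfg.max_area)
    # relabel survivors consecutively, preserving scan order
    remap = np.zeros(areas.size, dtype=np.int32)
    remap[keep] = np.arange(1, int(keep.sum()) + 1)
    return LabeledObjects(remap[labels])
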