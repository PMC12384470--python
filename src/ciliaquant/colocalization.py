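"""Image-level two-channel relationship measures.

The rank-weighted colocalization coefficient (RWC) is directional: within an
analysis mask, both channels' intensities are ranked (midranks for ties); a
pixel's weight is ``(Rmax - D_i) / Rmax`` with ``D_i`` the absolute rank
difference and ``Rmax`` the largest ``D_i`` in the mask, so pixels whose two
ranks agree count fully and maximally discordant pixels not at all.  The
coefficient is the weight-discounted share of the primary channel's intensity
carried by colocalized pixels (both channels strictly above threshold):

    RWC(primary -> secondary) = sum_coloc I_primary * W / sum_mask I_primary

It lies in [0, 1] and is generally asymmetric in its arguments — the red->
green direction collapses when antibody signal leaves the cilium while the
green->red direction barely moves, which is exactly the asymmetry a stable
marker channel affords.  Pearson correlation over the same mask is reported
alongside (symmetric, range [-1, 1]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from skimage.filters import threshold_otsu

from .io import ChannelImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColocConfig:
    """Thresholding for the colocalization analysis mask.

    ``otsu_log`` (the default) applies two-class Otsu to log1p intensities,
    which places the foreground cut between background and the faint diffuse
    signal rather than halfway up to the brightest tuft — without it, early
    degradation is invisible to the threshold.  ``otsu`` operates on raw
    intensities; ``fixed`` uses the configured values.
    """

    threshold_method: str = "otsu_log"  # "otsu_log", "otsu" or "fixed"
    fixed_threshold_red: float = 0.0
    fixed_threshold_green: float = 0.0
    mask_mode: str = "union"            # "union" of foregrounds or "image"

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "otsu_log", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.mask_mode not in ("union", "image"):
            raise ValueError(f"unknown mask_mode {self.mask_mode!r}")


@dataclass(frozen=True)
class ColocResult:
    rwc_red_green: float
    rwc_green_red: float
    pearson: float
    threshold_red: float
    threshold_green: float
    n_coloc_pixels: int
    n_mask_pixels: int


def coloc_thresholds(
    red: np.ndarray,
    green: np.ndarray,
    cfg: ColocConfig = ColocConfig(),
) -> tuple[float, float]:
    """Per-channel foreground thresholds for colocalization.

    A constant channel has no Otsu threshold; its own value is returned (so
    nothing is strictly above it and the colocalized set is empty) with a
    warning.
    """
    if red.shape != green.shape:
        raise ValueError(f"channel shapes differ: {red.shape} vs {green.shape}")
    if cfg.threshold_method == "fixed":
        return cfg.fixed_threshold_red, cfg.fixed_threshold_green
    out = []
    for name, chan in (("red", red), ("green", green)):
        if np.ptp(chan) == 0:
            logger.warning("constant %s channel: no foreground, empty colocalization",
                           name)
            out.append(float(chan.flat[0]) if chan.size else 0.0)
        elif cfg.threshold_method == "otsu_log":
            out.append(float(np.expm1(threshold_otsu(np.log1p(chan.astype(float))))))
        else:
            out.append(float(threshold_otsu(chan.astype(float))))
    return out[0], out[1]


def rwc(
    primary: np.ndarray,
    secondary: np.ndarray,
    thr_primary: float,
    thr_secondary: float,
    mask: np.ndarray | None = None,
) -> float:
    """Directional rank-weighted colocalization of ``primary`` with
    ``secondary`` (see module docstring).  Returns 0 (with a warning) when
    the primary channel carries no intensity in the mask."""
    primary = np.asarray(primary, dtype=float)
    secondary = np.asarray(secondary, dtype=float)
    if primary.shape != secondary.shape:
        raise ValueError("channel shapes differ")
    if mask is None:
        mask = np.ones(primary.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty analysis mask")

    p = primary[mask]
    s = secondary[mask]
    total = p.sum()
    if total <= 0:
        logger.warning("zero primary intensity in mask: RWC 0 by convention")
        return 0.0
    rank_p = rankdata(p, method="average")
    rank_s = rankdata(s, method="average")
    d = np.abs(rank_p - rank_s)
    rmax = d.max()
    weights = np.ones_like(d) if rmax == 0 else (rmax - d) / rmax
    coloc = (p > thr_primary) & (s > thr_secondary)
    return float(np.sum(p[coloc] * weights[coloc]) / total)


def pearson(
    red: np.ndarray,
    green: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Product-moment correlation over masked pixels; NaN (with a warning)
    when either channel has zero variance in the mask."""
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    if red.shape != green.shape:
        raise ValueError("channel shapes differ")
    if mask is None:
        mask = np.ones(red.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    r = red[mask]
    g = green[mask]
    if r.size < 2 or r.std() == 0 or g.std() == 0:
        logger.warning("degenerate pixel sample: Pearson undefined (NaN)")
        return float("nan")
    return float(np.corrcoef(r, g)[0, 1])


def coloc_image(
    red: ChannelImage | np.ndarray,
    green: ChannelImage | np.ndarray,
    cfg: ColocConfig = ColocConfig(),
) -> ColocResult:
    """Thresholds, both RWC directions and Pearson for one image pair.

    The analysis mask is the union of the two channels' foregrounds (pixels
    above threshold in at least one channel), excluding empty background that
    would inflate rank agreement; set ``mask_mode="image"`` to use every
    pixel.
    """
    r = red.pixels if isinstance(red, ChannelImage) else np.asarray(red, dtype=float)
    g = green.pixels if isinstance(green, ChannelImage) else np.asarray(green, dtype=float)
    if r.shape != g.shape:
        raise ValueError(f"channel shapes differ: {r.shape} vs {g.shape}")
    thr_r, thr_g = coloc_thresholds(r, g, cfg)
    if cfg.mask_mode == "union":
        mask = (r > thr_r) | (g > thr_g)
    else:
        mask = np.ones(r.shape, dtype=bool)
    if not mask.any():
        logger.warning("no foreground pixels: empty colocalization")
        return ColocResult(0.0, 0.0, float("nan"), thr_r, thr_g, 0, 0)
    n_coloc = int(((r > thr_r) & (g > thr_g)).sum())
    return ColocResult(
        rwc_red_green=rwc(r, g, thr_r, thr_g, mask),
        rwc_green_red=rwc(g, r, thr_g, thr_r, mask),
        pearson=pearson(r, g, mask),
        threshold_red=thr_r,
        threshold_green=thr_g,
        n_coloc_pixels=n_coloc,
        n_mask_pixels=int(mask.sum()),
    )
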