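"""Synthetic two-channel slide generator with known ground truth.

Each simulated field of view contains one to a few multiciliated epithelial
cells.  A cell is an elliptical body carrying an apical tuft of elongated
ridge primitives (the cilia bundle), plus a nuclear blob.  The marker channel
(green, acetylated alpha-tubulin) always shows the tuft.  The test channel
(red, antibody under evaluation) shows a mixture controlled by a degradation
fraction ``delta``:

    red = (1 - delta) * tuft + delta * diffuse + background + noise

where ``diffuse`` spreads exactly the tuft's integrated intensity over the
cytoplasm, weighted away from the tuft anchor and modulated by a patchy
texture.  Total expected red photon mass is therefore independent of delta:
degradation moves signal out of the cilium into the cytoplasm without
creating or destroying it, which mimics the loss of epitope-specific ciliary
staining seen on poorly stored slides (weak ciliary signal plus non-specific
diffuse cytoplasmic signal).

Whole studies (donors x storage conditions x antibodies) are generated with
one pseudo-random stream per slide derived from the master seed and the
slide's metadata by a stable hash, so any slide regenerates bit-identically
regardless of generation order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import ImageSet, SlideRecord, write_channel
from .vocab import (
    ANTIBODIES,
    CONDITIONS,
    DEFAULT_PIXEL_SIZE_UM,
    condition_alias,
    normalize_condition,
)

logger = logging.getLogger(__name__)

#: Default rendered field-of-view shape (rows, cols).  Chosen as a scaled-down
#: confocal tile that still holds 1-3 whole cells at the default geometry.
DEFAULT_IMAGE_SHAPE: tuple[int, int] = (256, 256)

#: Fraction of the per-ridge peak amplitude above which a pixel belongs to the
#: ground-truth tuft mask.
TUFT_MASK_LEVEL: float = 0.1


@dataclass(frozen=True)
class Ridge:
    """One elongated cilium primitive: an anti-aliased thick segment with a
    Gaussian cross-profile."""

    origin: tuple[float, float]   # (row, col) px
    length: float                 # px
    width: float                  # Gaussian sigma across the ridge, px
    orientation: float            # rad, image convention (row grows down)
    amplitude: float = 3000.0     # peak intensity, arbitrary confocal units


@dataclass(frozen=True)
class CellSpec:
    """Geometry of one simulated multiciliated cell."""

    body_center: tuple[float, float]
    body_axes: tuple[float, float]          # semi-axes, px
    body_orientation: float                 # rad
    tuft_anchor: tuple[float, float]        # on the body boundary, px
    tuft_ridges: tuple[Ridge, ...]
    nucleus_center: tuple[float, float]
    nucleus_axes: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.body_axes[0] > 0 and self.body_axes[1] > 0):
            raise ValueError("body_axes must be positive")
        if not (self.nucleus_axes[0] > 0 and self.nucleus_axes[1] > 0):
            raise ValueError("nucleus_axes must be positive")
        if not self.tuft_ridges:
            raise ValueError("a cell needs at least one tuft ridge")


@dataclass(frozen=True)
class DegradationModel:
    """Storage-induced degradation of the test-antibody signal.

    delta
        Fraction of ciliary signal relocated to the cytoplasm, in [0, 1].
        0 = intact epitope (red matches the marker), 1 = fully diffused.
    noise_sd
        Additive Gaussian read-noise scale, intensity units.
    background_level
        Flat background offset, intensity units.
    """

    delta: float = 0.0
    noise_sd: float = 40.0
    background_level: float = 150.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must be in [0, 1], got {self.delta}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.background_level < 0:
            raise ValueError("background_level must be non-negative")


@dataclass
class StudyDesign:
    """Full factorial slide-storage study: donors x conditions x antibodies."""

    donors: Sequence[str] = tuple(f"D{i}" for i in range(1, 6))
    conditions: Sequence[str] = CONDITIONS
    antibodies: Sequence[str] = ANTIBODIES
    images_per_slide: int = 22
    cells_per_image: tuple[int, int] = (1, 3)
    delta_map: Mapping[tuple[str, str], float] | None = None
    noise_sd: float = 40.0
    background_level: float = 150.0
    donor_delta_jitter_sd: float = 0.02
    image_shape: tuple[int, int] = DEFAULT_IMAGE_SHAPE
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0

    def __post_init__(self) -> None:
        self.conditions = tuple(normalize_condition(c) for c in self.conditions)
        if self.images_per_slide < 0:
            raise ValueError("images_per_slide must be >= 0")
        lo, hi = self.cells_per_image
        if not (1 <= lo <= hi):
            raise ValueError("cells_per_image must satisfy 1 <= lo <= hi")
        if self.delta_map is None:
            self.delta_map = default_delta_map(self.conditions, self.antibodies)
        for cond in self.conditions:
            for ab in self.antibodies:
                if (cond, ab) not in self.delta_map:
                    raise ValueError(
                        f"delta_map has no entry for condition {cond!r}, "
                        f"antibody {ab!r}"
                    )
                d = self.delta_map[(cond, ab)]
                if not 0.0 <= d <= 1.0:
                    raise ValueError(f"delta for ({cond}, {ab}) outside [0, 1]: {d}")

    @property
    def n_slides(self) -> int:
        return len(self.donors) * len(self.conditions) * len(self.antibodies)


#: Base degradation per storage condition, ordered best to worst.  Free design
#: parameters of the simulator (the study they emulate reports ranks, not
#: degradation fractions): a gentle gradient across frozen/shipped conditions
#: and a steep rise for prolonged room-temperature storage.
CONDITION_BASE_DELTA: dict[str, float] = {
    "-80_28d": 0.08,
    "-20_28d": 0.16,
    "-20/RT/-80": 0.26,
    "-20_8w": 0.34,
    "4/RT/-80": 0.42,
    "RT/RT/-80": 0.60,
    "RT_28d": 0.70,
}

#: Per-antibody sensitivity multipliers, least (RSPH4A) to most (CCDC39)
#: storage-sensitive.  Also free design parameters.
ANTIBODY_SENSITIVITY: dict[str, float] = {
    "RSPH4A": 0.60,
    "DNAH5": 0.70,
    "GAS8": 0.80,
    "RSPH9": 0.90,
    "SPEF2": 1.00,
    "CCDC40": 1.15,
    "DNALI1": 1.25,
    "CCDC39": 1.35,
}


def default_delta_map(
    conditions: Sequence[str] = CONDITIONS,
    antibodies: Sequence[str] = ANTIBODIES,
) -> dict[tuple[str, str], float]:
    """delta(condition, antibody) = clip(base(condition) * sens(antibody)).

    Unknown tokens fall back to the median base (0.3) / neutral sensitivity
    (1.0) so exploratory vocabularies still generate.
    """
    out: dict[tuple[str, str], float] = {}
    for cond in conditions:
        base = CONDITION_BASE_DELTA.get(normalize_condition(cond), 0.3)
        for ab in antibodies:
            sens = ANTIBODY_SENSITIVITY.get(ab, 1.0)
            out[(normalize_condition(cond), ab)] = float(np.clip(base * sens, 0.0, 1.0))
    return out


def slide_seed(master_seed: int, donor: str, condition: str, antibody: str) -> int:
    """Stable per-slide seed below 2**31, independent of generation order."""
    key = f"{master_seed}|{donor}|{normalize_condition(condition)}|{antibody}"
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Geometry sampling
# ---------------------------------------------------------------------------

def sample_cell(
    rng: np.random.Generator,
    shape: tuple[int, int] = DEFAULT_IMAGE_SHAPE,
    existing_centers: Sequence[tuple[float, float]] = (),
) -> CellSpec:
    """Draw a random cell whose full geometry (body + tuft) fits the grid.

    Bodies are kept nearly round (axis ratio <= ~1.3) so that degraded,
    cytoplasm-filling red objects are clearly less eccentric than the
    elongated ciliary tufts.  Rejection sampling avoids overlapping bodies;
    raises after a bounded number of attempts if the field is too crowded.
    """
    n_rows, n_cols = shape
    max_len = 32.0
    for _ in range(200):
        a = rng.uniform(28.0, 38.0)            # semi-axis, px
        b = a * rng.uniform(0.78, 1.0)
        margin = a + max_len + 14.0
        if 2 * margin >= min(n_rows, n_cols):
            raise ValueError(
                f"cell geometry (extent ~{2 * margin:.0f} px) does not fit a "
                f"{n_rows}x{n_cols} grid"
            )
        cy = rng.uniform(margin, n_rows - margin)
        cx = rng.uniform(margin, n_cols - margin)
        if any((cy - ey) ** 2 + (cx - ex) ** 2 < (2.1 * a) ** 2
               for ey, ex in existing_centers):
            continue
        theta_body = rng.uniform(0, 2 * math.pi)
        # apical anchor on the boundary
        phi = rng.uniform(0, 2 * math.pi)
        ar = a * math.cos(phi)
        br = b * math.sin(phi)
        anchor = (
            cy + ar * math.cos(theta_body) - br * math.sin(theta_body),
            cx + ar * math.sin(theta_body) + br * math.cos(theta_body),
        )
        # outward normal direction at the anchor (approximate via center ray)
        out_dir = math.atan2(anchor[0] - cy, anchor[1] - cx)
        n_ridges = int(rng.integers(5, 10))
        ridges = []
        for _ in range(n_ridges):
            jitter = np.clip(rng.normal(0.0, 2.5, size=2), -6.0, 6.0)
            ridges.append(
                Ridge(
                    origin=(anchor[0] + jitter[0], anchor[1] + jitter[1]),
                    length=float(rng.uniform(18.0, max_len)),
                    width=float(rng.uniform(1.2, 2.0)),
                    orientation=float(out_dir + rng.uniform(-0.3, 0.3)),
                    amplitude=float(rng.uniform(2400.0, 3200.0)),
                )
            )
        # nucleus sits inside the body, biased away from the tuft side
        nuc_off = rng.uniform(0.15, 0.35) * a
        nucleus_center = (
            cy - nuc_off * math.sin(out_dir),
            cx - nuc_off * math.cos(out_dir),
        )
        nucleus_axes = (0.38 * a, 0.38 * b)
        return CellSpec(
            body_center=(cy, cx),
            body_axes=(a, b),
            body_orientation=theta_body,
            tuft_anchor=anchor,
            tuft_ridges=tuple(ridges),
            nucleus_center=nucleus_center,
            nucleus_axes=nucleus_axes,
        )
    raise RuntimeError("could not place a non-overlapping cell in 200 attempts")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    orientation: float,
) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dy = rows - center[0]
    dx = cols - center[1]
    c, s = math.cos(orientation), math.sin(orientation)
    u = dy * c + dx * s
    v = -dy * s + dx * c
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _render_ridge(shape: tuple[int, int], ridge: Ridge) -> np.ndarray:
    """Intensity field of a single ridge, evaluated on its bounding box only."""
    oy, ox = ridge.origin
    ey = oy + ridge.length * math.sin(ridge.orientation)
    ex = ox + ridge.length * math.cos(ridge.orientation)
    pad = 4.0 * ridge.width + 1.0
    r0 = max(0, int(math.floor(min(oy, ey) - pad)))
    r1 = min(shape[0], int(math.ceil(max(oy, ey) + pad)) + 1)
    c0 = max(0, int(math.floor(min(ox, ex) - pad)))
    c1 = min(shape[1], int(math.ceil(max(ox, ex) + pad)) + 1)
    out = np.zeros(shape)
    if r0 >= r1 or c0 >= c1:
        return out
    rows, cols = np.mgrid[r0:r1, c0:c1].astype(float)
    # distance from each pixel center to the segment
    vy, vx = ey - oy, ex - ox
    seg_len2 = vy * vy + vx * vx
    t = ((rows - oy) * vy + (cols - ox) * vx) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    d2 = (rows - (oy + t * vy)) ** 2 + (cols - (ox + t * vx)) ** 2
    out[r0:r1, c0:c1] = ridge.amplitude * np.exp(-d2 / (2.0 * ridge.width**2))
    return out


def render_cell(
    spec: CellSpec,
    deg: DegradationModel,
    rng: np.random.Generator,
    shape: tuple[int, int] = DEFAULT_IMAGE_SHAPE,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Render one cell into (green, red, blue) float grids plus truth masks.

    green = tuft + background + noise;
    red   = (1-delta) * tuft + delta * diffuse + background + noise, with the
    diffuse field normalized so its integrated intensity equals the tuft's;
    blue  = nucleus blob (no degradation applied).

    The diffuse field is weighted by distance from the tuft anchor (epitope
    signal retracts into the cell interior) and modulated by a smooth random
    texture, producing the patchy cytoplasmic staining of degraded slides.
    Raises ValueError if any ridge or the body extends beyond the grid.
    """
    _check_geometry(spec, shape)

    tuft = np.zeros(shape)
    for ridge in spec.tuft_ridges:
        tuft += _render_ridge(shape, ridge)
    peak = max(r.amplitude for r in spec.tuft_ridges)
    tuft_mask = tuft > TUFT_MASK_LEVEL * peak

    body = _ellipse_mask(shape, spec.body_center, spec.body_axes, spec.body_orientation)
    nucleus = _ellipse_mask(shape, spec.nucleus_center, spec.nucleus_axes,
                            spec.body_orientation)
    cytoplasm = body & ~nucleus & ~tuft_mask

    # diffuse field: mass-preserving relocation of the tuft signal
    diffuse = np.zeros(shape)
    n_cyto = int(cytoplasm.sum())
    if n_cyto > 0:
        rows, cols = np.nonzero(cytoplasm)
        d_anchor = np.hypot(rows - spec.tuft_anchor[0], cols - spec.tuft_anchor[1])
        w = 0.4 + 0.6 * d_anchor / max(d_anchor.max(), 1.0)
        texture = _patchy_texture(shape, rng)[rows, cols]
        w = w * texture
        w *= tuft.sum() / w.sum()
        diffuse[rows, cols] = w

    noise_g = rng.normal(0.0, deg.noise_sd, size=shape) if deg.noise_sd else 0.0
    noise_r = rng.normal(0.0, deg.noise_sd, size=shape) if deg.noise_sd else 0.0
    green = tuft + deg.background_level + noise_g
    red = ((1.0 - deg.delta) * tuft + deg.delta * diffuse
           + deg.background_level + noise_r)
    blue = _nucleus_signal(shape, spec) + deg.background_level

    truth = {
        "tuft": tuft_mask,
        "cytoplasm": cytoplasm,
        "nucleus": nucleus,
        "body": body,
    }
    return green, red, blue, truth


def _patchy_texture(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Smooth positive random field with unit mean, used to make the diffuse
    cytoplasmic signal blotchy rather than flat."""
    g = gaussian_filter(rng.standard_normal(shape), sigma=3.0)
    g = g / max(g.std(), 1e-12)
    return np.clip(1.0 + 0.55 * g, 0.1, None)


def _nucleus_signal(shape: tuple[int, int], spec: CellSpec) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dy = rows - spec.nucleus_center[0]
    dx = cols - spec.nucleus_center[1]
    c, s = math.cos(spec.body_orientation), math.sin(spec.body_orientation)
    u = dy * c + dx * s
    v = -dy * s + dx * c
    r2 = (u / spec.nucleus_axes[0]) ** 2 + (v / spec.nucleus_axes[1]) ** 2
    return 2000.0 * np.exp(-r2 / 0.6)


def _check_geometry(spec: CellSpec, shape: tuple[int, int]) -> None:
    pts = [spec.body_center, spec.tuft_anchor, spec.nucleus_center]
    extents = [max(spec.body_axes), 0.0, max(spec.nucleus_axes)]
    for ridge in spec.tuft_ridges:
        oy, ox = ridge.origin
        pts.append((oy + ridge.length * math.sin(ridge.orientation),
                    ox + ridge.length * math.cos(ridge.orientation)))
        extents.append(3.0 * ridge.width)
        pts.append(ridge.origin)
        extents.append(3.0 * ridge.width)
    for (y, x), ext in zip(pts, extents):
        if not (ext <= y <= shape[0] - 1 - ext and ext <= x <= shape[1] - 1 - ext):
            raise ValueError(
                f"cell geometry outside the {shape[0]}x{shape[1]} grid: point "
                f"({y:.1f}, {x:.1f}) with extent {ext:.1f} px (cell at "
                f"{spec.body_center})"
            )


def render_field(
    rng: np.random.Generator,
    deg: DegradationModel,
    n_cells: int,
    shape: tuple[int, int] = DEFAULT_IMAGE_SHAPE,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Render one field of view with ``n_cells`` non-overlapping cells.

    Signals add; truth masks are unions over cells, plus ``n_cells`` actually
    placed (crowded fields may hold fewer).
    """
    green = np.zeros(shape)
    red = np.zeros(shape)
    blue = np.zeros(shape)
    truth = {k: np.zeros(shape, dtype=bool) for k in ("tuft", "cytoplasm", "nucleus", "body")}
    centers: list[tuple[float, float]] = []
    placed = 0
    cell_deg = DegradationModel(deg.delta, 0.0, 0.0)  # noise/bg added once, below
    for _ in range(n_cells):
        try:
            spec = sample_cell(rng, shape, centers)
        except RuntimeError:
            break
        g, r, b, t = render_cell(spec, cell_deg, rng, shape)
        green += g
        red += r
        blue += b
        for k in truth:
            truth[k] |= t[k]
        centers.append(spec.body_center)
        placed += 1
    green += deg.background_level
    red += deg.background_level
    blue += deg.background_level
    if deg.noise_sd:
        green += rng.normal(0.0, deg.noise_sd, size=shape)
        red += rng.normal(0.0, deg.noise_sd, size=shape)
        blue += rng.normal(0.0, deg.noise_sd, size=shape)
    truth["n_cells"] = placed  # type: ignore[assignment]
    return green, red, blue, truth


# ---------------------------------------------------------------------------
# Slide / study generation
# ---------------------------------------------------------------------------

def generate_slide(
    entry: tuple[str, str, str],
    deg: DegradationModel,
    images_per_slide: int,
    seed: int,
    out_dir: str | Path,
    cells_per_image: tuple[int, int] = (1, 3),
    image_shape: tuple[int, int] = DEFAULT_IMAGE_SHAPE,
    swap_channels: bool = False,
    overwrite: bool = False,
) -> SlideRecord:
    """Write one slide's field-of-view TIFF triplets and return its record.

    ``swap_channels`` writes the marker signal into the red-named file and the
    test signal into the green-named file (a fluorochrome colour switch); the
    rendered arrays themselves are unchanged, so analyses configured with the
    matching role map must give identical results.
    """
    donor, condition, antibody = entry
    condition = normalize_condition(condition)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    alias = condition_alias(condition)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    record = SlideRecord(donor, condition, antibody, delta=deg.delta, seed=seed)
    for i in range(images_per_slide):
        n_cells = int(rng.integers(cells_per_image[0], cells_per_image[1] + 1))
        green, red, blue, _ = render_field(rng, deg, n_cells, image_shape)
        if swap_channels:
            green, red = red, green
        image_id = f"img{i:03d}"
        paths: dict[str, Path] = {}
        for color, pixels in (("red", red), ("green", green), ("blue", blue)):
            path = out_dir / f"{donor}__{alias}__{antibody}__{image_id}__{color}.tif"
            if path.exists() and not overwrite:
                raise FileExistsError(
                    f"{path} already exists (pass overwrite=True to replace)"
                )
            write_channel(path, pixels)
            paths[color] = path
        record.images.append(ImageSet(image_id=image_id, paths=paths))
    return record


def generate_study(
    design: StudyDesign,
    out_dir: str | Path,
    swap_channels: bool = False,
    overwrite: bool = False,
) -> dict:
    """Generate a full study directory plus a JSON manifest.

    One slide per donor x condition x antibody; each slide's random stream is
    derived from (master seed, metadata) so regeneration is bit-identical and
    order-independent.  Returns the manifest dict (also written to
    ``manifest.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    assert design.delta_map is not None
    slides = []
    for donor in design.donors:
        for condition in design.conditions:
            for antibody in design.antibodies:
                sseed = slide_seed(design.seed, donor, condition, antibody)
                base_delta = design.delta_map[(condition, antibody)]
                jitter_rng = np.random.default_rng(np.random.SeedSequence(sseed))
                delta = float(np.clip(
                    base_delta + jitter_rng.normal(0.0, design.donor_delta_jitter_sd),
                    0.0, 1.0,
                ))
                deg = DegradationModel(delta, design.noise_sd, design.background_level)
                record = generate_slide(
                    (donor, condition, antibody), deg,
                    design.images_per_slide, sseed, out_dir,
                    cells_per_image=design.cells_per_image,
                    image_shape=design.image_shape,
                    swap_channels=swap_channels,
                    overwrite=overwrite,
                )
                slides.append({
                    "donor": donor,
                    "condition": condition,
                    "condition_alias": condition_alias(condition),
                    "antibody": antibody,
                    "delta": delta,
                    "base_delta": base_delta,
                    "seed": sseed,
                    "n_images": len(record.images),
                })
    manifest = {
        "pixel_size_um": design.pixel_size_um,
        "seed": design.seed,
        "image_shape": list(design.image_shape),
        "noise_sd": design.noise_sd,
        "background_level": design.background_level,
        "swap_channels": swap_channels,
        "n_slides": len(slides),
        "slides": slides,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
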