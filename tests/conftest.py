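"""Shared fixtures: geometric masks, rendered cells, and tiny studies."""

from __future__ import annotations

import numpy as np
import pytest

from ciliaquant.synthetic import (
    DegradationModel,
    StudyDesign,
    generate_study,
    render_field,
    sample_cell,
)


def disc_mask(radius: int, pad: int = 4) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[0:n, 0:n]
    c = radius + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def line_mask(length: int, pad: int = 2) -> np.ndarray:
    mask = np.zeros((2 * pad + 1, length + 2 * pad), dtype=bool)
    mask[pad, pad : pad + length] = True
    return mask


def ellipse_mask(a: float, b: float, pad: int = 4) -> np.ndarray:
    n = 2 * int(max(a, b) + pad) + 1
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    return ((yy - c) / a) ** 2 + ((xx - c) / b) ** 2 <= 1.0


def annulus_mask(outer: int, inner: int, pad: int = 4) -> np.ndarray:
    n = 2 * (outer + pad) + 1
    c = outer + pad
    yy, xx = np.mgrid[0:n, 0:n]
    r2 = (yy - c) ** 2 + (xx - c) ** 2
    return (r2 <= outer**2) & (r2 > inner**2)


def random_blob(seed: int, n: int = 40) -> np.ndarray:
    """Connected random blob: dilation-grown from a seed pixel."""
    from scipy.ndimage import binary_dilation

    rng = np.random.default_rng(seed)
    mask = np.zeros((n, n), dtype=bool)
    mask[n // 2, n // 2] = True
    for _ in range(6):
        grown = binary_dilation(mask)
        frontier = grown & ~mask
        keep = rng.random(int(frontier.sum())) < 0.7
        idx = np.argwhere(frontier)[keep]
        mask[idx[:, 0], idx[:, 1]] = True
    return mask


FIXTURE_MASKS = {
    "disc20": disc_mask(20),
    "line40": line_mask(40),
    "line100": line_mask(100),
    "ellipse20x10": ellipse_mask(20, 10),
    "annulus20_15": annulus_mask(20, 15),
    "blob1": random_blob(1),
    "blob2": random_blob(2),
    "two_px": np.array([[True, True]]),
}


# ---------------------------------------------------------------------------
# Brute-force oracles: explicit pixel sums, no shared code with the package
# ---------------------------------------------------------------------------

def oracle_eccentricity(mask: np.ndarray) -> float:
    ys, xs = np.nonzero(mask)
    ys = ys.astype(float); xs = xs.astype(float)
    my, mx = ys.mean(), xs.mean()
    cov = np.array([
        [np.mean((ys - my) ** 2), np.mean((ys - my) * (xs - mx))],
        [np.mean((ys - my) * (xs - mx)), np.mean((xs - mx) ** 2)],
    ])
    lam2, lam1 = np.linalg.eigvalsh(cov)
    if lam1 <= 0:
        return 0.0
    return float(np.sqrt(1.0 - max(lam2, 0.0) / lam1))


def oracle_compactness(mask: np.ndarray) -> float:
    ys, xs = np.nonzero(mask)
    ys = ys.astype(float); xs = xs.astype(float)
    my, mx = ys.mean(), xs.mean()
    msd = sum((y - my) ** 2 + (x - mx) ** 2 for y, x in zip(ys, xs)) / len(ys)
    return float(2.0 * np.pi * msd / len(ys))


def oracle_mass_displacement(mask: np.ndarray, intensity: np.ndarray) -> float:
    ys, xs = np.nonzero(mask)
    w = intensity[mask].astype(float)
    total = w.sum()
    if total == 0:
        return 0.0
    wy = sum(y * wi for y, wi in zip(ys, w)) / total
    wx = sum(x * wi for x, wi in zip(xs, w)) / total
    return float(np.hypot(ys.mean() - wy, xs.mean() - wx))


# ---------------------------------------------------------------------------
# Rendering fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def cell_spec():
    return sample_cell(np.random.default_rng(5))


@pytest.fixture(scope="session")
def noise_free_field():
    """(green, red, blue, truth) of a 3-cell field at delta 0.3, no noise."""
    rng = np.random.default_rng(3)
    return render_field(rng, DegradationModel(0.3, 0.0, 150.0), 3)


@pytest.fixture(scope="session")
def tiny_study_dir(tmp_path_factory):
    """2 donors x 2 conditions x 2 antibodies, 2 images/slide."""
    out = tmp_path_factory.mktemp("tiny_study")
    design = StudyDesign(
        donors=("D1", "D2"),
        conditions=("-80_28d", "RT_28d"),
        antibodies=("RSPH4A", "CCDC39"),
        images_per_slide=2,
        seed=11,
    )
    generate_study(design, out)
    return out
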