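"""Shape and intensity descriptors against brute-force pixel-moment oracles."""

import numpy as np
import pytest

from ciliaquant import (
    ChannelImage,
    compactness,
    eccentricity,
    mass_displacement,
    measure_objects,
    segment_channel,
)
from ciliaquant.segmentation import LabeledObjects

from conftest import (
    FIXTURE_MASKS,
    annulus_mask,
    disc_mask,
    ellipse_mask,
    line_mask,
    oracle_compactness,
    oracle_eccentricity,
    oracle_mass_displacement,
)


@pytest.mark.parametrize("name", sorted(FIXTURE_MASKS))
def test_shape_features_match_pixel_moment_oracles(name):
    """Eccentricity and compactness agree with independent pixel-sum oracles
    to 1e-9 on every fixture mask."""
    mask = FIXTURE_MASKS[name]
    assert eccentricity(mask) == pytest.approx(oracle_eccentricity(mask), abs=1e-9)
    assert compactness(mask) == pytest.approx(oracle_compactness(mask), abs=1e-9)


@pytest.mark.parametrize("name", sorted(FIXTURE_MASKS))
def test_mass_displacement_matches_weighted_mean_oracle(name):
    mask = FIXTURE_MASKS[name]
    rng = np.random.default_rng(hash(name) % 2**31)
    intensity = rng.uniform(0.1, 10.0, size=mask.shape)
    assert mass_displacement(mask, intensity) == pytest.approx(
        oracle_mass_displacement(mask, intensity), abs=1e-9
    )


def test_eccentricity_limits():
    """A disc is nearly circular, a 1-px-wide line is nearly degenerate, and a
    rasterized 20/10 ellipse approaches sqrt(1 - (b/a)^2) = 0.866."""
    assert eccentricity(disc_mask(20)) <= 0.1
    assert eccentricity(line_mask(40)) >= 0.99
    assert eccentricity(ellipse_mask(20, 10)) == pytest.approx(
        np.sqrt(1 - 0.25), abs=0.02
    )


def test_eccentricity_rotation_invariant():
    base = ellipse_mask(18, 7)
    rotated = base.T  # 90-degree rotation
    assert eccentricity(rotated) == pytest.approx(eccentricity(base), abs=1e-12)


def test_eccentricity_single_pixel_convention():
    assert eccentricity(np.array([[True]])) == 0.0


def test_compactness_reference_shapes():
    """Disc -> ~1 (radial-variance normalization), 1x100 line -> ~pi*L/6,
    annulus -> above 1 (hole pushes mass outward)."""
    assert compactness(disc_mask(20)) == pytest.approx(1.0, abs=0.05)
    assert compactness(line_mask(100)) == pytest.approx(np.pi * 100 / 6, abs=2.0)
    assert compactness(annulus_mask(20, 15)) > 1.0


def test_mass_displacement_uniform_and_symmetric_are_zero():
    mask = disc_mask(10)
    assert mass_displacement(mask, np.full(mask.shape, 7.0)) == pytest.approx(0.0, abs=1e-12)
    # mirror-symmetric intensity pattern
    n = mask.shape[0]
    yy, xx = np.mgrid[0:n, 0:n]
    sym = np.abs(xx - n // 2).astype(float) + 1.0
    assert mass_displacement(mask, sym) == pytest.approx(0.0, abs=1e-9)


def test_mass_displacement_two_pixel_hand_example():
    """Intensities {1, 3} at columns {0, 1}: weighted column 0.75 vs
    geometric 0.5 -> displacement 0.25 px."""
    mask = np.array([[True, True]])
    intensity = np.array([[1.0, 3.0]])
    assert mass_displacement(mask, intensity) == pytest.approx(0.25, abs=1e-12)


def test_mass_displacement_all_zero_convention():
    mask = np.array([[True, True]])
    assert mass_displacement(mask, np.zeros((1, 2))) == 0.0
    with pytest.raises(ValueError):
        mass_displacement(mask, np.array([[-1.0, 1.0]]))


def test_features_translation_invariant():
    rng = np.random.default_rng(9)
    mask = np.zeros((60, 60), dtype=bool)
    mask[10:24, 12:20] = rng.random((14, 8)) < 0.8
    mask[15, 15] = True
    intensity = np.zeros((60, 60))
    intensity[mask] = rng.uniform(1, 5, int(mask.sum()))
    shifted_mask = np.roll(np.roll(mask, 17, axis=0), -5, axis=1)
    shifted_int = np.roll(np.roll(intensity, 17, axis=0), -5, axis=1)
    assert eccentricity(shifted_mask) == pytest.approx(eccentricity(mask), abs=1e-12)
    assert compactness(shifted_mask) == pytest.approx(compactness(mask), abs=1e-12)
    assert mass_displacement(shifted_mask, shifted_int) == pytest.approx(
        mass_displacement(mask, intensity), abs=1e-12
    )


def test_mass_displacement_invariant_to_intensity_rescale_not_shift():
    mask = disc_mask(8)
    rng = np.random.default_rng(2)
    intensity = rng.uniform(0.5, 4.0, size=mask.shape)
    base = mass_displacement(mask, intensity)
    assert mass_displacement(mask, 3.5 * intensity) == pytest.approx(base, abs=1e-12)
    shifted = mass_displacement(mask, intensity + 100.0)
    assert shifted < base  # constant pedestal drags the weighted centroid inward


def test_measure_objects_records_and_unit_conversion():
    """area_um2 squares the linear pixel size: 100 px at 0.1136 um/px is
    100 * 0.1136^2 = 1.290 um^2; integrated = mean x area."""
    label_map = np.zeros((20, 20), dtype=int)
    label_map[2:12, 3:13] = 1  # 100 px
    objs = LabeledObjects(label_map)
    img = ChannelImage(np.full((20, 20), 5.0), role="test", pixel_size_um=0.1136)
    feats = measure_objects(objs, img)
    assert len(feats) == 1
    f = feats[0]
    assert f.area_px == 100
    assert f.area_um2 == pytest.approx(100 * 0.1136**2, abs=1e-12)
    assert f.area_um2 == pytest.approx(1.290, abs=5e-4)
    assert f.integrated_intensity == pytest.approx(f.mean_intensity * f.area_px,
                                                   rel=1e-12)


def test_measure_objects_empty_and_mismatch():
    objs = LabeledObjects(np.zeros((5, 5), dtype=int))
    assert measure_objects(objs, np.zeros((5, 5))) == []
    with pytest.raises(ValueError):
        measure_objects(objs, np.zeros((6, 5)))


@pytest.mark.parametrize("seed", [5, 8, 13])
def test_mass_displacement_rises_from_intact_to_degraded(seed):
    """With noise off, relocating ciliary signal into the cytoplasm pulls
    the intensity-weighted centroid away from the geometric centre of the
    main segmented red object: displacement at delta 0.25 exceeds delta 0.
    (Once the object support saturates the whole cell at high delta, the
    displacement of the nearly uniform object shrinks again, so the
    comparison targets the detectable mixture regime.)"""
    from ciliaquant.synthetic import DegradationModel, render_cell, sample_cell

    spec = sample_cell(np.random.default_rng(seed))
    values = []
    for delta in (0.0, 0.25):
        rng = np.random.default_rng(42)
        _, red, _, _ = render_cell(spec, DegradationModel(delta, 0.0, 150.0), rng)
        objs = segment_channel(red)
        feats = measure_objects(objs, red)
        main = max(feats, key=lambda f: f.area_px)
        values.append(main.mass_displacement_px)
    assert values[1] > values[0]
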