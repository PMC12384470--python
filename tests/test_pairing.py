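"""Overlap-based red-green object relation and the unique-pair filter."""

import math

import numpy as np
import pytest

from ciliaquant import (
    centroid_distance,
    filter_unique_pairs,
    measure_objects,
    pairing_rate,
    pairing_summary,
    relate_objects,
    segment_channel,
)
from ciliaquant.pairing import PairRecord
from ciliaquant.segmentation import LabeledObjects


def _labels(arr):
    return LabeledObjects(np.asarray(arr, dtype=int))


def test_red_inside_green_pairs_with_full_overlap():
    red = np.zeros((10, 10), dtype=int)
    red[4:6, 4:6] = 1
    green = np.zeros((10, 10), dtype=int)
    green[2:8, 2:8] = 1
    pairs = relate_objects(_labels(red), _labels(green))
    assert len(pairs) == 1
    p = pairs[0]
    assert p.paired and p.green_id == 1 and p.overlap_px == 4
    assert p.green_multiplicity == 1


def test_red_without_green_overlap_is_unpaired():
    red = np.zeros((10, 10), dtype=int)
    red[0:2, 0:2] = 1
    green = np.zeros((10, 10), dtype=int)
    green[6:9, 6:9] = 1
    pairs = relate_objects(_labels(red), _labels(green))
    assert len(pairs) == 1 and not pairs[0].paired
    assert pairs[0].overlap_px == 0


def test_max_overlap_wins():
    """A red object overlapping green A by 30 px and green B by 10 px is
    assigned to A (checked against a brute-force overlap count)."""
    green = np.zeros((10, 10), dtype=int)
    green[0:4, 0:10] = 1   # A: rows 0-3
    green[6:10, 0:10] = 2  # B: rows 6-9
    red = np.zeros((10, 10), dtype=int)
    red[1:9, 0:5] = 1      # overlaps A rows 1-3 (15px), B rows 6-8 (15px)? adjust
    red[1:4, 0:10] = 1     # top overlap -> 30 px with A
    red[6:8, 0:5] = 1      # bottom overlap -> 10 px with B
    overlap_a = int(((red == 1) & (green == 1)).sum())
    overlap_b = int(((red == 1) & (green == 2)).sum())
    assert overlap_a > overlap_b
    pairs = relate_objects(_labels(red), _labels(green))
    assert pairs[0].green_id == 1 and pairs[0].overlap_px == overlap_a


def test_tie_breaks_to_lower_green_id_and_order_independent():
    green = np.zeros((8, 8), dtype=int)
    green[0:2, 0:4] = 1
    green[4:6, 0:4] = 2
    red = np.zeros((8, 8), dtype=int)
    red[1:5, 0:4] = 1  # 4 px with green 1 (row 1), 4 px with green 2 (row 4)
    pairs = relate_objects(_labels(red), _labels(green))
    assert pairs[0].green_id == 1 and pairs[0].overlap_px == 4
    # exact ties resolve by id, so relabelling still yields the lower id
    green_swapped = np.where(green == 1, 2, np.where(green == 2, 1, 0))
    pairs_swapped = relate_objects(_labels(red), _labels(green_swapped))
    assert pairs_swapped[0].green_id == 1
    assert pairs_swapped[0].overlap_px == pairs[0].overlap_px
    # without a tie the assignment follows the object, not the label
    red2 = red.copy()
    red2[1, 2:4] = 0           # now 2 px with green 1, 4 px with green 2
    winner = relate_objects(_labels(red2), _labels(green))[0]
    assert winner.green_id == 2
    swapped_winner = relate_objects(_labels(red2), _labels(green_swapped))[0]
    assert swapped_winner.green_id == 1  # same object, new label


def test_every_paired_red_shares_a_pixel(noise_free_field):
    green, red, _, _ = noise_free_field
    sr, sg = segment_channel(red), segment_channel(green)
    pairs = relate_objects(sr, sg)
    for p in pairs:
        if p.paired:
            overlap = int((sr.object_mask(p.red_id) & sg.object_mask(p.green_id)).sum())
            assert overlap == p.overlap_px >= 1


def test_centroid_distance_examples():
    """Identical objects -> 0; centroids at (0,0) and (3,4) -> 5 px; 10 px at
    0.1136 um/px -> 1.136 um."""
    a = np.zeros((20, 20), dtype=int); a[0, 0] = 1
    b = np.zeros((20, 20), dtype=int); b[3, 4] = 1
    fa = {1: measure_objects(_labels(a), np.ones((20, 20)))[0]}
    fb = {1: measure_objects(_labels(b), np.ones((20, 20)))[0]}
    pair = PairRecord(red_id=1, green_id=1, overlap_px=1)
    same = centroid_distance(pair, fa, fa, 0.1136)
    assert same.distance_px == pytest.approx(0.0, abs=1e-12)
    p345 = centroid_distance(pair, fa, fb, 0.1136)
    assert p345.distance_px == pytest.approx(5.0, abs=1e-12)
    c = np.zeros((20, 20), dtype=int); c[0, 10] = 1
    fc = {1: measure_objects(_labels(c), np.ones((20, 20)))[0]}
    p10 = centroid_distance(pair, fa, fc, 0.1136)
    assert p10.distance_um == pytest.approx(1.136, abs=1e-12)
    unpaired = centroid_distance(PairRecord(red_id=1, green_id=None, overlap_px=0),
                                 fa, fb, 0.1136)
    assert math.isnan(unpaired.distance_px)


def test_filter_unique_pairs_enumerated_fixture():
    """Greens with 0, 1 and 2 red children: only the single-child pair
    survives; unpaired records are removed."""
    green = np.zeros((12, 12), dtype=int)
    green[0:2, 0:6] = 1    # will get 2 red children
    green[5:7, 0:6] = 2    # will get 1 red child
    green[10:12, 0:6] = 3  # no children
    red = np.zeros((12, 12), dtype=int)
    red[0, 0:3] = 1
    red[1, 3:6] = 2
    red[5:7, 0:3] = 3
    red[9, 9:12] = 4       # unpaired
    pairs = relate_objects(_labels(red), _labels(green))
    survivors = filter_unique_pairs(pairs)
    assert [(p.red_id, p.green_id) for p in survivors] == [(3, 2)]
    # both children of the doubly-claimed green are gone
    assert all(p.green_id != 1 for p in survivors)


def test_pairing_rate_edge_cases():
    assert pairing_rate(0, 0) is None
    assert pairing_rate(10, 10) == 100.0
    assert pairing_rate(10, 0) == 0.0
    with pytest.raises(ValueError):
        pairing_rate(5, 6)


def test_all_paired_on_intact_noise_free_render():
    """delta = 0, noise off: every red object coincides with a green tuft."""
    from ciliaquant.synthetic import DegradationModel, render_field

    rng = np.random.default_rng(3)
    green, red, _, _ = render_field(rng, DegradationModel(0.0, 0.0, 150.0), 3)
    pairs = relate_objects(segment_channel(red), segment_channel(green))
    n_total, n_paired, pct = pairing_summary(pairs)
    assert n_total >= 1 and pct == 100.0
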