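"""Overlap-based relation of test-channel (red) objects to marker-channel
(green) objects.

Each red object is assigned to the green object with which it shares the most
pixels (ties broken toward the lower green id, logged); red objects touching
no green pixel stay unpaired.  ``green_multiplicity`` counts how many red
children a green object has, which feeds the unique-pair filter: downstream
object statistics are restricted to green objects paired with exactly one red
object, so that red and green measurements describe the same cilium.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np

from .features import ObjectFeatures
from .segmentation import LabeledObjects
from .vocab import DEFAULT_PIXEL_SIZE_UM

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairRecord:
    red_id: int
    green_id: int | None           # None = unpaired
    overlap_px: int
    distance_px: float = math.nan
    distance_um: float = math.nan
    green_multiplicity: int = 0

    @property
    def paired(self) -> bool:
        return self.green_id is not None


def relate_objects(red: LabeledObjects, green: LabeledObjects) -> list[PairRecord]:
    """Assign every red object to its max-overlap green parent.

    Deterministic and independent of object enumeration order; overlap ties
    resolve to the lower green id and are logged.
    """
    if red.label_map.shape != green.label_map.shape:
        raise ValueError("label maps must share one shape")
    n_red = red.n_objects
    n_green = green.n_objects
    records: list[PairRecord] = []
    if n_red == 0:
        return records

    # joint histogram of (red label, green label) over pixels in any red object
    rl = red.label_map.ravel()
    gl = green.label_map.ravel()
    sel = rl > 0
    joint = np.zeros((n_red + 1, n_green + 1), dtype=np.int64)
    np.add.at(joint, (rl[sel], gl[sel]), 1)

    assignments: dict[int, int] = {}
    for rid in range(1, n_red + 1):
        overlaps = joint[rid, 1:]
        best = int(overlaps.max()) if n_green else 0
        if best == 0:
            records.append(PairRecord(red_id=rid, green_id=None, overlap_px=0))
            continue
        candidates = np.flatnonzero(overlaps == best)
        if candidates.size > 1:
            logger.info("red %d overlaps green %s equally (%d px); taking lowest id",
                        rid, (candidates + 1).tolist(), best)
        gid = int(candidates[0]) + 1
        assignments[rid] = gid
        records.append(PairRecord(red_id=rid, green_id=gid, overlap_px=best))

    multiplicity = Counter(assignments.values())
    return [
        replace(rec, green_multiplicity=multiplicity[rec.green_id])
        if rec.paired else rec
        for rec in records
    ]


def centroid_distance(
    pair: PairRecord,
    red_feats: dict[int, ObjectFeatures],
    green_feats: dict[int, ObjectFeatures],
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> PairRecord:
    """Fill in the Euclidean distance between the pair's geometric centroids.

    Distances use unweighted centroids; the um value applies the linear pixel
    size once.  Unpaired records keep NaN distances.
    """
    if not pair.paired:
        return pair
    rc = red_feats[pair.red_id].centroid
    gc = green_feats[pair.green_id].centroid  # type: ignore[index]
    d_px = math.hypot(rc[0] - gc[0], rc[1] - gc[1])
    return replace(pair, distance_px=d_px, distance_um=d_px * pixel_size_um)


def filter_unique_pairs(pairs: list[PairRecord]) -> list[PairRecord]:
    """Keep only pairs whose green object has exactly one red child.

    Unpaired records and every child of a multiply-claimed green object are
    removed, leaving one-to-one cilium matches.
    """
    return [p for p in pairs if p.paired and p.green_multiplicity == 1]


def pairing_rate(n_red_total: int, n_paired: int) -> float | None:
    """Percent of red objects with a green partner, to the nearest percent.

    Returns None when there are no red objects (rate undefined).
    """
    if n_red_total == 0:
        return None
    if not 0 <= n_paired <= n_red_total:
        raise ValueError("need 0 <= n_paired <= n_red_total")
    return float(round(100.0 * n_paired / n_red_total))


def pairing_summary(pairs: list[PairRecord]) -> tuple[int, int, float | None]:
    """(n_red_total, n_paired, percent_paired) for a list of pair records."""
    n_total = len(pairs)
    n_paired = sum(1 for p in pairs if p.paired)
    return n_total, n_paired, pairing_rate(n_total, n_paired)
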