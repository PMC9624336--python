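"""Dice-based agreement between segmentation masks.

Whole-mask Dice quantifies global overlap between two binary masks;
object matching pairs labeled objects between two segmentations by
descending pixel overlap (greedy, each object used at most once) and
reports a per-object Dice, with unmatched objects carrying Dice 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ObjectMatch:
    label_a: int | None
    label_b: int | None
    overlap_px: int
    dice: float


def dice(mask_a, mask_b) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|) of two binary masks.

    1 means identical segmentation; 0 means no overlap. Two empty masks
    agree perfectly on absence and score 1.
    """
    a = np.asarray(getattr(mask_a, "pixels", mask_a)).astype(bool)
    b = np.asarray(getattr(mask_b, "pixels", mask_b)).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


def match_objects(labels_a, labels_b) -> list[ObjectMatch]:
    """Pair objects of two label images by greedy descending overlap.

    Every (a, b) label pair with nonzero pixel overlap is a candidate;
    candidates are taken in order of decreasing overlap (ties broken by
    label ids for determinism), each label used at most once. Matched
    pairs carry the Dice of their two object masks; unmatched objects
    are reported with Dice 0.
    """
    la = np.asarray(labels_a)
    lb = np.asarray(labels_b)
    if la.shape != lb.shape:
        raise ValueError("label images must share a shape")

    ids_a = [int(v) for v in np.unique(la) if v > 0]
    ids_b = [int(v) for v in np.unique(lb) if v > 0]
    areas_a = {i: int((la == i).sum()) for i in ids_a}
    areas_b = {i: int((lb == i).sum()) for i in ids_b}

    both = (la > 0) & (lb > 0)
    pairs: dict[tuple[int, int], int] = {}
    if both.any():
        pa = la[both]
        pb = lb[both]
        keys, counts = np.unique(np.stack([pa, pb]), axis=1, return_counts=True)
        for (i, j), c in zip(keys.T, counts):
            pairs[(int(i), int(j))] = int(c)

    order = sorted(pairs.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[ObjectMatch] = []
    for (i, j), overlap in order:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        d = 2.0 * overlap / (areas_a[i] + areas_b[j])
        matches.append(ObjectMatch(i, j, overlap, float(d)))

    for i in ids_a:
        if i not in used_a:
            matches.append(ObjectMatch(i, None, 0, 0.0))
    for j in ids_b:
        if j not in used_b:
            matches.append(ObjectMatch(None, j, 0, 0.0))
    return matches


def matches_to_table(matches: list[ObjectMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"label_a": m.label_a, "label_b": m.label_b, "overlap_px": m.overlap_px, "dice": m.dice}
            for m in matches
        ],
        columns=["label_a", "label_b", "overlap_px", "dice"],
    )
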