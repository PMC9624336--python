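"""Classical nucleus detection on 2D z-projections.

The pipeline mirrors the semi-automatic macro workflow: median filter the
projection, binarize with a minimum cross-entropy threshold, fill holes,
drop regions below a minimum area, and optionally split touching nuclei
with a distance-transform marker watershed. Interactive curation is
replaced by file-based edit lists (removals + added polygons).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .imgio import Image2D, ZStack, median_filter2d

# 4-connectivity for nucleus components: avoids diagonal bridges
# between adjacent nuclei.
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class RoiSet:
    """Labeled nucleus regions on a 2D projection.

    ``label_image`` holds 0 for background and k > 0 for nucleus k, with
    labels consecutive from 1. ``provenance`` maps each label to "auto"
    (detected) or "added" (curation).
    """

    label_image: np.ndarray
    provenance: dict[int, str] = field(default_factory=dict)
    min_area: int = 0

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        labels = self.labels
        if labels and labels != list(range(1, len(labels) + 1)):
            raise ValueError("labels must be consecutive positive integers starting at 1")
        for lab in labels:
            self.provenance.setdefault(lab, "auto")

    @property
    def labels(self) -> list[int]:
        vals = np.unique(self.label_image)
        return [int(v) for v in vals if v > 0]

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def mask(self, label: int) -> np.ndarray:
        if label not in self.labels:
            raise KeyError(f"label {label} not present in RoiSet")
        return self.label_image == label


@dataclass
class CurationEdit:
    """A file-based replacement for interactive ROI curation.

    ``removals`` lists label ids to delete; ``additions`` lists polygons,
    each a sequence of (y, x) vertices, rasterized as new nuclei.
    """

    removals: list[int] = field(default_factory=list)
    additions: list[list[tuple[float, float]]] = field(default_factory=list)

    @classmethod
    def from_json(cls, path) -> "CurationEdit":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            removals=[int(r) for r in data.get("removals", [])],
            additions=[[(float(y), float(x)) for y, x in poly] for poly in data.get("additions", [])],
        )


def min_cross_entropy_threshold(image) -> float:
    """Minimum cross-entropy (Li & Lee) threshold of an image.

    Scans every candidate threshold t and returns the one minimizing the
    cross-entropy between the image and its two-level reconstruction by
    the class means of {g < t} and {g >= t}:

        eta(t) = -m_low(t) * log(mu_low(t)) - m_high(t) * log(mu_high(t))

    where m is the summed intensity and mu the mean intensity of a class
    (a class with zero summed intensity contributes nothing). For integer
    images the candidate grid is every integer level in range (all 256
    levels for 8-bit); for float images, the distinct values present.
    Ties are broken toward the lower threshold. Foreground is defined as
    pixels >= the returned threshold.
    """
    pixels = np.asarray(getattr(image, "pixels", image)).ravel()
    if pixels.size == 0:
        raise ValueError("empty image")
    if np.unique(pixels).size < 2:
        raise ValueError("degenerate histogram: image has a single intensity value")

    if np.issubdtype(pixels.dtype, np.integer):
        lo = 0 if pixels.dtype == np.uint8 else int(pixels.min())
        hi = 255 if pixels.dtype == np.uint8 else int(pixels.max())
        levels = np.arange(lo, hi + 1, dtype=np.float64)
        counts, _ = np.histogram(pixels, bins=np.arange(lo, hi + 2) - 0.5)
        candidates = levels
    else:
        levels, counts = np.unique(pixels, return_counts=True)
        levels = levels.astype(np.float64)
        candidates = levels

    counts = counts.astype(np.float64)
    mass = counts * levels                      # summed intensity per level
    cum_n = np.cumsum(counts)
    cum_m = np.cumsum(mass)
    total_n, total_m = cum_n[-1], cum_m[-1]

    # class {g < t}: everything strictly below each candidate
    idx = np.searchsorted(levels, candidates, side="left")
    n_low = np.where(idx > 0, cum_n[np.maximum(idx - 1, 0)], 0.0)
    m_low = np.where(idx > 0, cum_m[np.maximum(idx - 1, 0)], 0.0)
    n_high = total_n - n_low
    m_high = total_m - m_low

    mu_low = np.where(n_low > 0, m_low / np.maximum(n_low, 1), 0.0)
    mu_high = np.where(n_high > 0, m_high / np.maximum(n_high, 1), 0.0)
    # a class with zero summed intensity contributes 0 (0 * log 0 convention)
    log_low = np.zeros_like(mu_low)
    log_high = np.zeros_like(mu_high)
    np.log(mu_low, out=log_low, where=mu_low > 0)
    np.log(mu_high, out=log_high, where=mu_high > 0)
    objective = -m_low * log_low - m_high * log_high
    best = int(np.argmin(objective))            # argmin takes the first: lower threshold wins ties
    return float(candidates[best])


def detect_nuclei(
    projection: Image2D,
    median_radius: int = 2,
    min_area: int = 500,
    split_touching: bool = True,
    fill_holes: bool = True,
) -> RoiSet:
    """Detect nuclei in a 2D projection by global thresholding.

    Median-filters the projection, thresholds with
    :func:`min_cross_entropy_threshold`, fills holes, removes regions
    smaller than ``min_area`` pixels and, when ``split_touching``,
    separates merged nuclei with a distance-transform marker watershed.
    All resulting labels are tagged "auto".
    """
    filtered = median_filter2d(projection, median_radius)
    t = min_cross_entropy_threshold(filtered)
    binary = filtered.pixels >= t
    if fill_holes:
        binary = ndi.binary_fill_holes(binary)

    if split_touching:
        labeled = _split_touching(binary, min_area)
    else:
        labeled, _ = ndi.label(binary, structure=_STRUCT4)

    labeled = _filter_small(labeled, min_area)
    labeled = _renumber(labeled)
    prov = {lab: "auto" for lab in range(1, labeled.max() + 1)}
    return RoiSet(labeled, prov, min_area=min_area)


def _split_touching(binary: np.ndarray, min_area: int) -> np.ndarray:
    """Marker watershed on the Euclidean distance transform.

    Markers are local maxima of the distance transform separated by at
    least 0.5 * sqrt(min_area) pixels, a scale tied to the smallest
    nucleus we are willing to keep.
    """
    if not binary.any():
        return np.zeros(binary.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(binary)
    min_sep = max(1, int(round(0.5 * np.sqrt(max(min_area, 1)))))
    peaks = peak_local_max(distance, min_distance=min_sep, labels=binary, exclude_border=False)
    markers = np.zeros(binary.shape, dtype=np.int32)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    if markers.max() == 0:
        lab, _ = ndi.label(binary, structure=_STRUCT4)
        return lab
    return watershed(-distance, markers, mask=binary, connectivity=1)


def _filter_small(labeled: np.ndarray, min_area: int) -> np.ndarray:
    if labeled.max() == 0:
        return labeled
    areas = np.bincount(labeled.ravel())
    kill = np.flatnonzero(areas < min_area)
    out = labeled.copy()
    out[np.isin(out, kill[kill > 0])] = 0
    return out


def _renumber(labeled: np.ndarray) -> np.ndarray:
    """Relabel to consecutive 1..n preserving label order."""
    vals = np.unique(labeled)
    vals = vals[vals > 0]
    lut = np.zeros(int(labeled.max()) + 1, dtype=np.int32)
    for new, old in enumerate(vals, start=1):
        lut[old] = new
    return lut[labeled]


def apply_curation(rois: RoiSet, edit: CurationEdit) -> RoiSet:
    """Apply a curation edit: remove labeled nuclei, add polygon nuclei.

    Removed labels are zeroed; added polygons are rasterized as new
    labels tagged "added". Labels are renumbered consecutively, existing
    (surviving) nuclei first in their original order, then additions in
    list order.
    """
    labels = rois.labels
    for rid in edit.removals:
        if rid not in labels:
            raise KeyError(f"removal id {rid} not present in RoiSet")

    out = rois.label_image.copy()
    for rid in edit.removals:
        out[out == rid] = 0

    survivors = [lab for lab in labels if lab not in set(edit.removals)]
    new_image = np.zeros_like(out, dtype=np.int32)
    prov: dict[int, str] = {}
    next_label = 1
    for lab in survivors:
        new_image[out == lab] = next_label
        prov[next_label] = rois.provenance.get(lab, "auto")
        next_label += 1

    for poly in edit.additions:
        ys = [p[0] for p in poly]
        xs = [p[1] for p in poly]
        rr, cc = draw_polygon(ys, xs, shape=new_image.shape)
        if rr.size == 0:
            raise ValueError("added polygon rasterizes to zero pixels")
        if (new_image[rr, cc] > 0).any():
            raise ValueError("added polygon overlaps an existing nucleus")
        new_image[rr, cc] = next_label
        prov[next_label] = "added"
        next_label += 1

    return RoiSet(new_image, prov, min_area=rois.min_area)


def crop_nucleus(stack: ZStack, rois: RoiSet, label: int, margin_frac: float = 0.0):
    """Crop the stack around one nucleus ROI.

    The region's bounding box is expanded by ``margin_frac`` of its
    height/width on each side and clipped to the image bounds; every z
    slice is retained. Returns ``(substack, mask_crop)`` where
    ``mask_crop`` is the nucleus mask over the cropped window.
    """
    mask = rois.mask(label)
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    my = int(round(margin_frac * (y1 - y0)))
    mx = int(round(margin_frac * (x1 - x0)))
    H, W = mask.shape
    y0, y1 = max(0, y0 - my), min(H, y1 + my)
    x0, x1 = max(0, x0 - mx), min(W, x1 + mx)
    sub = ZStack(stack.voxels[:, y0:y1, x0:x1].copy(), stack.voxel_size)
    dz, dy, dx = stack.voxel_size
    crop_mask = Image2D(mask[y0:y1, x0:x1].copy(), (dy, dx))
    return sub, crop_mask, (y0, x0, y1, x1)
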