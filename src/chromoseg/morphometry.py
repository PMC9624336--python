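"""Per-nucleus heterochromatin morphometrics.

Quantities measured per nucleus on a 2D projection:

- nucleus area (µm² when the pixel size is known, else px²)
- CC count: number of chromocenters
- RAF: relative CC area fraction, area of each CC / nucleus area
- HF:  heterochromatin fraction, sum of CC areas / nucleus area
- RHI: relative heterochromatin intensity, mean CC intensity / mean
  nucleus intensity (the nucleus mean includes CC pixels)
- RHF: relative heterochromatin fraction, HF × RHI — the proportion of
  stained DNA residing in chromocenters.

A nucleus with no chromocenters reports HF = RHI = RHF = 0 (flagged by
cc_count = 0) so downstream statistics never drop nuclei silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imgio import Image2D


@dataclass
class TriLevelMask:
    """Annotation image over {0 background, 128 nucleus, 255 chromocenter}."""

    pixels: np.ndarray
    pixel_size: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if not np.isin(self.pixels, (0, 128, 255)).all():
            raise ValueError("tri-level mask values must be in {0, 128, 255}")

    @property
    def nucleus_mask(self) -> np.ndarray:
        return self.pixels >= 128

    @property
    def cc_mask(self) -> np.ndarray:
        return self.pixels == 255


@dataclass
class MorphometricRecord:
    nucleus_id: int
    nucleus_area: float
    units: str
    cc_count: int
    raf: list[float] = field(default_factory=list)
    hf: float = 0.0
    rhi: float = 0.0
    rhf: float = 0.0


def compose_trilevel(nucleus_mask, cc_labels, pixel_size=(1.0, 1.0)) -> TriLevelMask:
    """Compose a tri-level mask from a nucleus mask and CC labels.

    Every chromocenter pixel must lie inside the nucleus mask.
    """
    nuc = np.asarray(getattr(nucleus_mask, "pixels", nucleus_mask)).astype(bool)
    cc = np.asarray(cc_labels) > 0
    if nuc.shape != cc.shape:
        raise ValueError("nucleus mask and chromocenter labels must share a shape")
    if (cc & ~nuc).any():
        raise ValueError("chromocenter pixel outside nucleus")
    out = np.zeros(nuc.shape, dtype=np.uint8)
    out[nuc] = 128
    out[cc] = 255
    return TriLevelMask(out, tuple(pixel_size))


def measure_nucleus(
    nucleus_mask, cc_labels, intensity, pixel_size=(1.0, 1.0), nucleus_id: int = 1
) -> MorphometricRecord:
    """Measure one nucleus.

    ``intensity`` is the image measurements are taken on (conventionally
    the max z-projection of the raw stack). Areas are physical when
    ``pixel_size`` differs from (1, 1); RAF/HF/RHI/RHF are dimensionless
    ratios and independent of units.
    """
    nuc = np.asarray(getattr(nucleus_mask, "pixels", nucleus_mask)).astype(bool)
    if not nuc.any():
        raise ValueError("empty nucleus mask")
    cc_labels = np.asarray(cc_labels)
    img = np.asarray(getattr(intensity, "pixels", intensity)).astype(np.float64)
    if nuc.shape != cc_labels.shape or nuc.shape != img.shape:
        raise ValueError("shape mismatch between mask, labels and intensity")

    dy, dx = pixel_size
    px_area = dy * dx
    units = "um2" if (dy, dx) != (1.0, 1.0) else "px2"

    nucleus_px = int(nuc.sum())
    nucleus_area = nucleus_px * px_area

    labels = np.unique(cc_labels[nuc & (cc_labels > 0)])
    raf = []
    cc_px_total = 0
    for lab in labels:
        area_px = int(((cc_labels == lab) & nuc).sum())
        cc_px_total += area_px
        raf.append(area_px / nucleus_px)

    if labels.size == 0:
        return MorphometricRecord(nucleus_id, nucleus_area, units, 0, [], 0.0, 0.0, 0.0)

    hf = cc_px_total / nucleus_px
    cc_mask = (cc_labels > 0) & nuc
    rhi = img[cc_mask].mean() / img[nuc].mean()
    rhf = hf * rhi
    return MorphometricRecord(
        nucleus_id, nucleus_area, units, int(labels.size), raf, float(hf), float(rhi), float(rhf)
    )


def measure_batch(rois_or_trilevel, cc_labels=None, intensity=None, pixel_size=(1.0, 1.0)):
    """Measure every nucleus in a labeled ROI set or tri-level mask.

    Accepts either ``(TriLevelMask, intensity)`` — nuclei are the
    connected components of the 128∪255 region and chromocenters the
    255 components — or ``(RoiSet-like label image, cc label image,
    intensity)``. Returns ``(records DataFrame, per-CC RAF DataFrame)``
    with rows ordered by nucleus label.
    """
    from scipy import ndimage as ndi

    if isinstance(rois_or_trilevel, TriLevelMask):
        tri = rois_or_trilevel
        nuc_labels, _ = ndi.label(tri.nucleus_mask, structure=np.array(
            [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
        cc_lab_img, _ = ndi.label(tri.cc_mask, structure=np.ones((3, 3), dtype=bool))
        pixel_size = tri.pixel_size
    else:
        label_image = getattr(rois_or_trilevel, "label_image", rois_or_trilevel)
        nuc_labels = np.asarray(label_image)
        cc_lab_img = np.asarray(cc_labels)
    if intensity is None:
        raise ValueError("an intensity image is required")

    records = []
    raf_rows = []
    for lab in [int(v) for v in np.unique(nuc_labels) if v > 0]:
        nuc = nuc_labels == lab
        rec = measure_nucleus(nuc, np.where(nuc, cc_lab_img, 0), intensity, pixel_size, lab)
        records.append(rec)
        for i, r in enumerate(rec.raf, start=1):
            raf_rows.append({"nucleus_id": lab, "cc_index": i, "raf": r})

    table = pd.DataFrame(
        [
            {
                "nucleus_id": r.nucleus_id,
                "nucleus_area": r.nucleus_area,
                "units": r.units,
                "cc_count": r.cc_count,
                "hf": r.hf,
                "rhi": r.rhi,
                "rhf": r.rhf,
            }
            for r in records
        ],
        columns=["nucleus_id", "nucleus_area", "units", "cc_count", "hf", "rhi", "rhf"],
    )
    raf_table = pd.DataFrame(raf_rows, columns=["nucleus_id", "cc_index", "raf"])
    return table, raf_table
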