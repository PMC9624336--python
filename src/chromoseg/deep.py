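"""Three-stage U-Net cascade for nucleus and chromocenter segmentation.

Stage 1 (region proposal) predicts a coarse nucleus-presence heatmap on
the downscaled full image; its thresholded components become bounding
boxes, each intended to contain a single nucleus. Stage 2 segments the
nucleus inside each box fragment; stage 3 segments chromocenters inside
the nucleus. Fragment predictions are mapped back to original
coordinates, overlapping fragments merged by pixelwise maximum
probability, and the result composed into a tri-level mask.

Heatmaps are per-pixel object probabilities in [0, 1]; binarization uses
a default threshold of 0.5 so no human decision enters the cut, with the
preset couples (nucleus, chromocenter) = (0.5, 0.5), (0.5, 0.25) and
(0.8, 0.2) exposed for fine-tuning chromocenter sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize, rotate

from .imgio import Image2D
from .morphometry import TriLevelMask, compose_trilevel
from .unet import UNet

THRESHOLD_PRESETS = {
    "default": (0.5, 0.5),
    "sensitive_cc": (0.5, 0.25),
    "strict": (0.8, 0.2),
}


@dataclass
class FragmentSet:
    """Image fragments cut around proposed nuclei.

    ``boxes`` are (y0, x0, y1, x1) half-open pixel coordinates in the
    source image, margin included and clipped to bounds; ``fragments``
    are the corresponding crops resized to the segmentation model's
    input size and normalized to [0, 1].
    """

    fragments: list[np.ndarray] = field(default_factory=list)
    boxes: list[tuple[int, int, int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fragments)


def normalize01(image: np.ndarray) -> np.ndarray:
    """Per-image min-max normalization to [0, 1] (constant image -> 0)."""
    img = np.asarray(image, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def augment_pair(image, mask, multiplicity: int = 1, seed: int = 0, ops=None):
    """Generate augmented copies of an (image, mask) training pair.

    Each copy applies a seeded random subset of: horizontal/vertical
    flips, 90-degree rotations, a small free rotation (±15 degrees),
    intensity scaling, gamma, and additive Gaussian noise. Geometric
    transforms are applied identically to image and mask; the mask is
    interpolated nearest-neighbour so it stays binary. The first pair
    returned is always the untouched original.
    """
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    all_ops = ("flip", "rot90", "rotate", "intensity", "noise")
    if ops is None:
        ops = all_ops
    img = np.asarray(image, dtype=np.float64)
    msk = np.asarray(mask).astype(bool)
    rng = np.random.default_rng(seed)
    out = [(img.copy(), msk.copy())]
    for _ in range(multiplicity - 1):
        ai, am = img.copy(), msk.copy()
        if "flip" in ops:
            if rng.random() < 0.5:
                ai, am = ai[::-1], am[::-1]
            if rng.random() < 0.5:
                ai, am = ai[:, ::-1], am[:, ::-1]
        if "rot90" in ops:
            k = int(rng.integers(0, 4))
            ai, am = np.rot90(ai, k), np.rot90(am, k)
        if "rotate" in ops and rng.random() < 0.5:
            angle = float(rng.uniform(-15, 15))
            ai = rotate(ai, angle, order=1, mode="reflect", preserve_range=True)
            am = rotate(am.astype(np.float64), angle, order=0, mode="constant",
                        preserve_range=True) > 0.5
        if "intensity" in ops:
            ai = ai * float(rng.uniform(0.8, 1.2))
            gamma = float(rng.uniform(0.8, 1.25))
            top = ai.max()
            if top > 0:
                ai = top * (ai / top) ** gamma
        if "noise" in ops:
            ai = ai + rng.normal(0, 0.02 * max(ai.max(), 1e-9), ai.shape)
        out.append((np.ascontiguousarray(ai), np.ascontiguousarray(am)))
    return out


def _resize_image(img: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    return resize(img, size, order=1, mode="reflect", anti_aliasing=True, preserve_range=True)


def _resize_mask(msk: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    return resize(msk.astype(np.float64), size, order=0, mode="constant",
                  anti_aliasing=False, preserve_range=True) > 0.5


def heatmap_predict(model: UNet, image: np.ndarray) -> np.ndarray:
    """Full-image heatmap: normalize, resize to the model input, predict,
    resize probabilities back to the source shape."""
    src = np.asarray(getattr(image, "pixels", image))
    size = model.config.input_size
    x = _resize_image(normalize01(src), size)
    probs = model.predict_probs(x[None])[0]
    return np.clip(_resize_image(probs, src.shape), 0.0, 1.0)


def propose_regions(image, rp_model: UNet, threshold: float = 0.5,
                    margin_frac: float = 0.15,
                    fragment_size: tuple[int, int] = (64, 64)) -> FragmentSet:
    """Propose single-nucleus fragments from the region-proposal heatmap.

    The heatmap is binarized at ``threshold``; each connected component
    yields a bounding box expanded by ``margin_frac`` per side and
    clipped to the image. Fragments are the source-image crops resized
    to ``fragment_size`` and normalized. An empty proposal set is valid.
    """
    src = np.asarray(getattr(image, "pixels", image))
    heat = heatmap_predict(rp_model, src)
    binary = heat >= threshold
    labeled, n = ndi.label(binary)
    fs = FragmentSet()
    H, W = src.shape
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labeled == lab)
        y0, y1 = ys.min(), ys.max() + 1
        x0, x1 = xs.min(), xs.max() + 1
        my = int(round(margin_frac * (y1 - y0)))
        mx = int(round(margin_frac * (x1 - x0)))
        y0, y1 = max(0, y0 - my), min(H, y1 + my)
        x0, x1 = max(0, x0 - mx), min(W, x1 + mx)
        frag = _resize_image(normalize01(src[y0:y1, x0:x1]), fragment_size)
        fs.fragments.append(frag)
        fs.boxes.append((int(y0), int(x0), int(y1), int(x1)))
    return fs


def predict_trilevel(image, rp_model: UNet, nuc_model: UNet, cc_model: UNet,
                     thresholds: tuple[float, float] = (0.5, 0.5),
                     rp_threshold: float = 0.5, margin_frac: float = 0.15,
                     pixel_size=(1.0, 1.0)):
    """Run the full cascade on one image.

    Returns ``(TriLevelMask, heatmaps)`` where ``heatmaps`` holds the
    full-image region-proposal, nucleus and chromocenter probability
    maps (overlapping fragments merged by pixelwise max). Chromocenter
    pixels are restricted to the nucleus mask, so the tri-level
    containment invariant holds by construction. Lowering a threshold
    can only grow the corresponding mask.
    """
    if nuc_model.config.input_size != cc_model.config.input_size:
        raise ValueError("nucleus and chromocenter models must share an input size")
    t_nuc, t_cc = thresholds
    src = np.asarray(getattr(image, "pixels", image))
    H, W = src.shape

    fs = propose_regions(image, rp_model, rp_threshold, margin_frac,
                         fragment_size=nuc_model.config.input_size)
    rp_heat = heatmap_predict(rp_model, src)
    nuc_prob = np.zeros((H, W), dtype=np.float64)
    cc_prob = np.zeros((H, W), dtype=np.float64)
    for frag, (y0, x0, y1, x1) in zip(fs.fragments, fs.boxes):
        np_frag = nuc_model.predict_probs(frag[None])[0]
        cc_frag = cc_model.predict_probs(frag[None])[0]
        box_shape = (y1 - y0, x1 - x0)
        np_full = np.clip(_resize_image(np_frag, box_shape), 0, 1)
        cc_full = np.clip(_resize_image(cc_frag, box_shape), 0, 1)
        nuc_prob[y0:y1, x0:x1] = np.maximum(nuc_prob[y0:y1, x0:x1], np_full)
        cc_prob[y0:y1, x0:x1] = np.maximum(cc_prob[y0:y1, x0:x1], cc_full)

    nuc_mask = nuc_prob >= t_nuc
    cc_mask = (cc_prob >= t_cc) & nuc_mask
    cc_labels, _ = ndi.label(cc_mask)
    tri = compose_trilevel(nuc_mask, cc_labels, pixel_size)
    heatmaps = {"region_proposal": rp_heat, "nucleus": nuc_prob, "chromocenter": cc_prob}
    return tri, heatmaps
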