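"""Seeded generator of DAPI-like synthetic z-stacks with ground truth.

Scenes emulate fields of DAPI-stained Arabidopsis interphase nuclei:
elliptical nuclei with a smooth nucleoplasm texture containing bright
chromocenter foci, occasional touching nucleus pairs, small non-nucleus
debris, and Gaussian + Poisson acquisition noise added last. Ground
truth (tri-level mask and per-nucleus morphometrics) is computed on the
noiseless rendering, so it is exact.

Phenotype presets capture the qualitative contrasts of interest:

- ``light``: 8-10 conspicuous foci per nucleus at high contrast;
- ``dark``: fewer (4-8), fainter foci in larger nuclei — the
  low-contrast regime where segmentation is hard;
- ``ddm1``: small, faint, dispersed foci mimicking the relaxed
  heterochromatin of the *ddm1* mutant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imgio import ZStack, z_project
from .morphometry import TriLevelMask, compose_trilevel, measure_batch

PRESETS = {
    "light": dict(cc_count_range=(8, 10), cc_contrast=2.5,
                  nucleus_radius_range=(18, 26), cc_radius_range=(2.0, 3.5),
                  target_rhf_range=(0.15, 0.18)),
    "dark": dict(cc_count_range=(4, 8), cc_contrast=1.4,
                 nucleus_radius_range=(22, 30), cc_radius_range=(2.0, 3.5),
                 target_rhf_range=(0.08, 0.11)),
    "ddm1": dict(cc_count_range=(4, 8), cc_contrast=1.6,
                 nucleus_radius_range=(16, 22), cc_radius_range=(1.2, 2.2),
                 target_rhf_range=(0.05, 0.08)),
}


@dataclass
class SceneConfig:
    """Parameters of one synthetic field.

    Intensities are on an 8-bit scale (background ~6, nucleoplasm ~70).
    ``cc_contrast`` is the ratio of chromocenter to nucleoplasm mean
    intensity in the rendered projection; ``noise`` is (gaussian_sd,
    poisson_scale) with poisson_scale 0 disabling shot noise.
    ``target_rhf_range``, when set, rescales chromocenter radii so the
    analytic RHF of each nucleus falls near a value drawn from that
    range.
    """

    shape: tuple[int, int] = (256, 256)
    n_slices: int = 7
    n_nuclei: int = 3
    nucleus_radius_range: tuple[float, float] = (18, 26)
    cc_count_range: tuple[int, int] = (8, 10)
    cc_radius_range: tuple[float, float] = (2.0, 3.5)
    cc_contrast: float = 2.5
    target_rhf_range: tuple[float, float] | None = None
    noise: tuple[float, float] = (2.0, 0.5)
    touching_prob: float = 0.2
    debris_prob: float = 0.3
    min_gap: float = 4.0
    phenotype: str = "custom"
    background: float = 6.0
    nucleoplasm: float = 70.0
    voxel_size: tuple[float, float, float] = (0.4, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        for rng_pair in (self.nucleus_radius_range, self.cc_count_range, self.cc_radius_range):
            if rng_pair[0] > rng_pair[1]:
                raise ValueError(f"range {rng_pair} is not well ordered")
        if not (0 <= self.touching_prob <= 1 and 0 <= self.debris_prob <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.phenotype == "light" and self.cc_contrast <= 1:
            raise ValueError("light preset requires cc_contrast > 1")


def preset_config(phenotype: str, seed: int = 0, **overrides) -> SceneConfig:
    """Build a SceneConfig for a named phenotype preset."""
    if phenotype not in PRESETS:
        raise ValueError(f"unknown preset {phenotype!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[phenotype])
    kwargs.update(overrides)
    return SceneConfig(phenotype=phenotype, seed=seed, **kwargs)


@dataclass
class GroundTruth:
    """Exact pre-noise annotation of a generated scene."""

    trilevel: TriLevelMask
    records: pd.DataFrame
    raf_table: pd.DataFrame
    nucleus_labels: np.ndarray
    cc_labels: np.ndarray
    nucleus_centroids: list[tuple[float, float]]
    cc_centroids: list[tuple[float, float]]
    noiseless_projection: np.ndarray


def _place_nuclei(cfg: SceneConfig, rng: np.random.Generator):
    """Sample non-overlapping nucleus centers and radii; with probability
    touching_prob a nucleus is placed touching the previous one."""
    H, W = cfg.shape
    rlo, rhi = cfg.nucleus_radius_range
    placed = []  # (cy, cx, ry, rx)
    attempts = 0
    while len(placed) < cfg.n_nuclei:
        attempts += 1
        if attempts > 2000:
            raise ValueError("infeasible geometry: too many nuclei for the field")
        ry = rng.uniform(rlo, rhi)
        rx = rng.uniform(rlo, rhi)
        r = max(ry, rx)
        if placed and rng.random() < cfg.touching_prob:
            pcy, pcx, pry, prx = placed[-1]
            ang = rng.uniform(0, 2 * np.pi)
            dist = 0.95 * (max(pry, prx) + r)
            cy, cx = pcy + dist * np.sin(ang), pcx + dist * np.cos(ang)
            min_gap = -0.1 * r  # allowed to touch the previous nucleus
        else:
            cy = rng.uniform(r + 2, H - r - 2)
            cx = rng.uniform(r + 2, W - r - 2)
            min_gap = cfg.min_gap
        if not (r + 1 <= cy <= H - r - 1 and r + 1 <= cx <= W - r - 1):
            continue
        ok = True
        for i, (ocy, ocx, ory, orx) in enumerate(placed):
            gap = np.hypot(cy - ocy, cx - ocx) - (max(ory, orx) + r)
            limit = min_gap if i == len(placed) - 1 else cfg.min_gap
            if gap < limit:
                ok = False
                break
        if ok:
            placed.append((cy, cx, ry, rx))
    return placed


def generate_scene(config: SceneConfig):
    """Render one scene; returns ``(ZStack, GroundTruth)``.

    The same config (including seed) yields bit-identical output.
    Ground truth is computed on the noiseless maximum projection before
    Gaussian and Poisson noise are applied.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.shape
    Z = cfg.n_slices
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)

    nuclei = _place_nuclei(cfg, rng)
    nucleus_labels = np.zeros((H, W), dtype=np.int32)
    cc_labels = np.zeros((H, W), dtype=np.int32)
    clean = np.full((Z, H, W), cfg.background, dtype=np.float64)

    zc_all = (Z - 1) / 2.0
    sz = max(Z / 3.0, 1.0)
    z_profile = np.exp(-((np.arange(Z) - zc_all) ** 2) / (2 * sz**2))

    nucleus_centroids = []
    cc_centroids = []
    cc_next = 1
    for lab, (cy, cx, ry, rx) in enumerate(nuclei, start=1):
        ellipse = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        # later nuclei do not overwrite earlier ones where they touch
        ellipse &= nucleus_labels == 0
        nucleus_labels[ellipse] = lab
        nucleus_centroids.append((cy, cx))

        texture = ndi.gaussian_filter(rng.standard_normal((H, W)), 6.0)
        texture = 1.0 + 0.08 * texture / max(np.abs(texture).max(), 1e-9)
        base = cfg.nucleoplasm * texture

        n_cc = int(rng.integers(cfg.cc_count_range[0], cfg.cc_count_range[1] + 1))
        radii = rng.uniform(cfg.cc_radius_range[0], cfg.cc_radius_range[1], size=n_cc)
        if cfg.target_rhf_range is not None and n_cc > 0:
            # RHF = HF * RHI with RHI ~ c / (1 + HF (c - 1)) at contrast c
            # (the nucleus mean includes the bright CC pixels); solving
            # HF * RHI = R gives HF = R / (c - R (c - 1)).
            target_rhf = rng.uniform(*cfg.target_rhf_range)
            c = cfg.cc_contrast
            target_hf = min(target_rhf / (c - target_rhf * (c - 1.0)), 0.5)
            hf_now = np.sum(np.pi * radii**2) / (np.pi * ry * rx)
            if hf_now > 0:
                radii = radii * np.sqrt(target_hf / hf_now)

        centers = []
        cc_tries = 0
        while len(centers) < n_cc and cc_tries < 500:
            cc_tries += 1
            r = radii[len(centers)]
            u, v = rng.uniform(-0.75, 0.75, size=2)
            py, px = cy + u * ry, cx + v * rx
            if ((py - cy) / (ry - r - 1.5)) ** 2 + ((px - cx) / (rx - r - 1.5)) ** 2 > 1:
                continue
            if any(np.hypot(py - oy, px - ox) < r + orr + 1.0 for oy, ox, orr in centers):
                continue
            centers.append((py, px, r))

        cc_field = np.zeros((H, W), dtype=np.float64)
        for py, px, r in centers:
            d = np.hypot(yy - py, xx - px)
            disk = (d <= r) & ellipse
            if not disk.any():
                continue
            # soft-edged plateau: flat core, Gaussian rolloff just outside
            profile = np.where(d <= r, 1.0, np.exp(-((d - r) ** 2) / (2 * 0.8**2)))
            cc_field = np.maximum(cc_field, profile)
            cc_labels[disk] = cc_next
            cc_centroids.append((py, px))
            cc_next += 1

        amp = (cfg.cc_contrast - 1.0) * cfg.nucleoplasm
        plane = np.where(ellipse, base, 0.0) + np.where(ellipse, amp * cc_field, 0.0)
        for z in range(Z):
            clean[z][ellipse] = cfg.background + (plane[ellipse] - cfg.background) * z_profile[z]

    # debris outside nuclei: small bright blobs mimicking plastids/dust
    if rng.random() < cfg.debris_prob:
        for _ in range(int(rng.integers(1, 4))):
            for _try in range(100):
                dy_, dx_ = rng.uniform(5, H - 5), rng.uniform(5, W - 5)
                r = rng.uniform(1.5, 4.0)
                d = np.hypot(yy - dy_, xx - dx_)
                blob = d <= r + 3
                if (nucleus_labels[blob] == 0).all():
                    z0 = int(rng.integers(0, Z))
                    clean[z0] += cfg.nucleoplasm * np.exp(-(d**2) / (2 * r**2))
                    break

    clean = np.clip(clean, 0, 255)
    noiseless_proj = clean.max(axis=0)

    trilevel = compose_trilevel(nucleus_labels > 0, cc_labels, cfg.voxel_size[1:])
    records, raf_table = measure_batch(
        nucleus_labels, cc_labels, noiseless_proj, cfg.voxel_size[1:]
    )

    noisy = clean.copy()
    g_sd, p_scale = cfg.noise
    if p_scale > 0:
        noisy = rng.poisson(noisy * p_scale).astype(np.float64) / p_scale
    if g_sd > 0:
        noisy = noisy + rng.normal(0, g_sd, noisy.shape)
    stack = ZStack(np.clip(np.round(noisy), 0, 255).astype(np.uint8), cfg.voxel_size)

    gt = GroundTruth(trilevel, records, raf_table, nucleus_labels, cc_labels,
                     nucleus_centroids, cc_centroids, noiseless_proj)
    return stack, gt


def generate_training_set(config: SceneConfig, n_scenes: int, out_dir):
    """Write ``n_scenes`` image/mask pairs plus a ground-truth manifest.

    Scene i uses seed ``config.seed + i``. Files are
    ``scene_###.tif`` / ``scene_###_mask.tif``; the manifest CSV holds
    one row per nucleus with its configured-phenotype morphometrics.
    """
    import pathlib

    from .imgio import write_trilevel_mask, write_zstack

    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_scenes):
        cfg = replace(config, seed=config.seed + i)
        stack, gt = generate_scene(cfg)
        img_name = f"scene_{i:03d}.tif"
        mask_name = f"scene_{i:03d}_mask.tif"
        write_zstack(stack, out / img_name)
        write_trilevel_mask(gt.trilevel.pixels, out / mask_name)
        for _, rec in gt.records.iterrows():
            rows.append({"image": img_name, "mask": mask_name, "seed": cfg.seed,
                         "phenotype": cfg.phenotype, **rec.to_dict()})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def fragments_from_scene(stack: ZStack, gt: GroundTruth, size=(64, 64), margin_frac=0.15):
    """Cut per-nucleus training fragments from a scene.

    Returns a list of dicts with the normalized image fragment, the
    nucleus and chromocenter masks resized to ``size``, and the
    nucleus's ground-truth record.
    """
    from .deep import _resize_image, _resize_mask, normalize01

    proj = z_project(stack, "max").pixels
    H, W = proj.shape
    out = []
    for lab in [int(v) for v in np.unique(gt.nucleus_labels) if v > 0]:
        nuc = gt.nucleus_labels == lab
        ys, xs = np.nonzero(nuc)
        y0, y1 = ys.min(), ys.max() + 1
        x0, x1 = xs.min(), xs.max() + 1
        my = int(round(margin_frac * (y1 - y0)))
        mx = int(round(margin_frac * (x1 - x0)))
        y0, y1 = max(0, y0 - my), min(H, y1 + my)
        x0, x1 = max(0, x0 - mx), min(W, x1 + mx)
        img = _resize_image(normalize01(proj[y0:y1, x0:x1]), size)
        nmask = _resize_mask(nuc[y0:y1, x0:x1], size)
        cmask = _resize_mask((gt.cc_labels > 0)[y0:y1, x0:x1] & nuc[y0:y1, x0:x1], size)
        rec = gt.records[gt.records.nucleus_id == lab].iloc[0].to_dict()
        out.append({"image": img, "nucleus_mask": nmask, "cc_mask": cmask,
                    "record": rec, "box": (int(y0), int(x0), int(y1), int(x1))})
    return out
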