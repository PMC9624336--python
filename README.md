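# chromoseg

Batch segmentation and heterochromatin morphometrics for DAPI-stained
confocal z-stacks of plant interphase nuclei.

In *Arabidopsis*, constitutive heterochromatin coalesces into a handful
of densely stained foci — chromocenters (CC) — whose number, size and
intensity respond to development, light regime and chromatin mutations
such as *ddm1*. Quantifying them from confocal stacks normally involves
manual or semi-interactive segmentation, which is slow and carries
substantial inter-user variability. `chromoseg` provides two scriptable
pipelines over the same inputs and outputs:

- **classical**: nucleus detection on a median-filtered z-projection by
  minimum cross-entropy (Li) thresholding with a distance-transform
  watershed for touching nuclei, then per-nucleus chromocenter
  segmentation on the z-projected largest eigenvalue of the 3D structure
  tensor with a parameterized (non-interactive) H-watershed;
- **learned**: a cascade of three small U-Nets — region proposal →
  nucleus segmentation → chromocenter segmentation — producing per-pixel
  probability heatmaps thresholded at 0.5 by default.

Both pipelines emit tri-level annotation masks (0 background / 128
nucleus / 255 chromocenter) and per-nucleus morphometrics:

- RAF (relative CC area fraction) = area of one CC / nucleus area
- HF (heterochromatin fraction) = Σ CC areas / nucleus area
- RHI (relative heterochromatin intensity) = mean CC intensity / mean
  nucleus intensity
- RHF (relative heterochromatin fraction) = HF × RHI, the proportion of
  stained DNA residing in chromocenters

A seeded synthetic-scene generator (`chromoseg.synthim`) renders
DAPI-like fields — elliptical nuclei with bright foci at presettable
contrast ("light", "dark", "ddm1" phenotypes), touching pairs, debris,
Gaussian + Poisson noise — with exact pre-noise ground truth, so every
stage is testable without microscope data.

## Worked example

```python
import chromoseg as cs

# a synthetic "light"-phenotype field of 3 nuclei with ground truth
stack, gt = cs.generate_scene(cs.preset_config("light", seed=3))

proj = cs.z_project(stack, "max")
rois = cs.detect_nuclei(proj)                     # classical detection
cc = cs.segment_chromocenters(
    stack, rois,
    cs.HWatershedParams(h_rel=0.10, peak_flooding=30),
    sigma_grad=1.0, sigma_int=1.0)
table, raf = cs.measure_batch(rois.label_image, cc, proj.pixels.astype(float))
print(table[["nucleus_id", "cc_count", "hf", "rhi", "rhf"]])
print("nucleus Dice vs ground truth:",
      cs.dice(rois.label_image > 0, gt.nucleus_labels > 0))
```

prints

```
   nucleus_id  cc_count        hf       rhi       rhf
0           1        10  0.154941  1.383405  0.214346
1           2        12  0.182180  1.363129  0.248335
2           3         8  0.183691  1.350062  0.247994
nucleus Dice vs ground truth: 0.999864406779661
```

Each row is one nucleus: 8–12 detected chromocenters covering 15–18% of
the nucleus area at roughly 1.4× the mean nuclear intensity, hence an
RHF around 0.2 — the detected foci hold about a fifth of the stained
DNA. The structure-tensor feature responds to the edges of foci, so the
classical segmentation draws slightly generous chromocenter outlines
and its HF runs above the generating ground truth (≈0.08 here); the
contrast between conditions is what carries the biology: the dark
preset yields RHF near 0.10 under the same settings, and the two
distributions separate at p < 0.01 (Mann–Whitney) with 30 nuclei per
group.

The same measurements run from the shell:

```bash
chromoseg simulate --preset light --n-scenes 5 --seed 7 --out data/
chromoseg detect --input data/scene_000.tif --out rois.tif
chromoseg chromocenters --input data/scene_000.tif --rois rois.tif \
    --h 0.1rel --peak-flooding 30 --out cc.tif
chromoseg measure --input data/scene_000.tif --rois rois.tif --cc cc.tif --out morpho.csv
chromoseg train --stage nucleus --images data/ --out nucleus.npz
chromoseg compare --a rois.tif --b data/scene_000_mask.tif --per-object --out dice.csv
```

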