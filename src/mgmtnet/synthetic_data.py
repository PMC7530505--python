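"""Brain-phantom generator with the statistical structure the pipeline assumes.

Each phantom is a 2D slice: an elliptical "brain" of smoothly varying
tissue intensity on an exactly-zero background, with a hyperintense tumor
(union of 1-3 random ellipses).  Three properties mirror the real-data
regime the pipeline is built for:

* **non-standard intensity scales** — every scan gets its own
  multiplicative/additive intensity drift, so the tissue peak lands at a
  different grey value per scan (the two-peak density with a drifting
  tissue peak that intensity standardization must undo);
* **hyperintense tumors** on brain-like background, with additive noise on
  the foreground only (background stays exactly zero, preserving the
  valued-voxel semantics of the normalization steps);
* **a class-linked morphological signal** — phantoms labelled methylated
  carry a central hypointense necrosis core covering a set fraction of the
  tumor, echoing the reported association between MGMT promoter
  methylation and more tumor necrosis.  The signal is morphological rather
  than textural so a two-convolution classifier can plausibly learn it at
  small sample sizes; no biological fidelity is claimed.

The generator is deterministic given its seed and writes the same
manifest CSV the data model consumes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data_model import (METHYLATED, UNMETHYLATED, CaseRecord,
                         DatasetManifest)

__all__ = ["PhantomConfig", "generate_phantom", "generate_case_arrays",
           "generate_dataset", "load_slice", "PNG_SCALE"]

# fixed quantization for 16-bit PNG output: intensity * PNG_SCALE
PNG_SCALE = 1000.0


@dataclass
class PhantomConfig:
    image_size: int = 96
    n_cases: int = 40
    slices_per_case: int = 3
    tumor_area_range: tuple[int, int] = (60, 500)
    tumor_contrast: float = 1.0
    necrosis_fraction: float = 0.3
    necrosis_contrast: float = 0.45
    intensity_scale_range: tuple[float, float] = (0.7, 1.3)
    intensity_offset_range: tuple[float, float] = (0.0, 0.3)
    noise_sd: float = 0.15
    p_methylated: float = 0.5
    modality: str = "FLAIR"
    seed: int = 0

    def __post_init__(self):
        if self.tumor_area_range[0] >= self.tumor_area_range[1]:
            raise ValueError("tumor_area_range must be ordered")
        if not 0 < self.necrosis_fraction < 1:
            raise ValueError("necrosis_fraction must be in (0, 1)")
        if not 0 <= self.p_methylated <= 1:
            raise ValueError("p_methylated must be in [0, 1]")
        if self.intensity_scale_range[0] > self.intensity_scale_range[1]:
            raise ValueError("intensity_scale_range must be ordered")


def _ellipse_mask(size: int, cy: float, cx: float, ay: float, ax: float,
                  theta: float = 0.0) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    y = yy - cy
    x = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * x + st * y
    v = -st * x + ct * y
    return (u / ax) ** 2 + (v / ay) ** 2 <= 1.0


def _brain_mask(size: int, rng: np.random.Generator) -> np.ndarray:
    ay = size * rng.uniform(0.36, 0.42)
    ax = size * rng.uniform(0.32, 0.38)
    return _ellipse_mask(size, size / 2, size / 2, ay, ax,
                         rng.uniform(-0.2, 0.2))


def generate_phantom(rng: np.random.Generator, config: PhantomConfig,
                     label: str):
    """One (image, mask, label) triple.

    Tissue baseline 1.0 with a smooth spatial field; tumor pixels at
    +tumor_contrast; for methylated labels a central core of
    necrosis_fraction of the tumor area is lowered by necrosis_contrast.
    The whole foreground is then scaled/offset by the per-scan drift and
    perturbed with Gaussian noise.
    """
    s = config.image_size
    brain = _brain_mask(s, rng)
    # smooth tissue texture around baseline 1.0
    field = ndimage.gaussian_filter(rng.standard_normal((s, s)), sigma=6.0)
    field = field / (np.abs(field).max() + 1e-12)
    tissue = 1.0 + 0.12 * field

    tumor = _place_tumor(s, brain, rng, config)
    img = np.zeros((s, s), dtype=float)
    img[brain] = tissue[brain]
    img[tumor] = tissue[tumor] + config.tumor_contrast

    if label == METHYLATED:
        core = _necrosis_core(tumor, config.necrosis_fraction)
        img[core] -= config.necrosis_contrast

    scale = rng.uniform(*config.intensity_scale_range)
    offset = rng.uniform(*config.intensity_offset_range)
    img[brain] = img[brain] * scale + offset
    img[brain] += rng.normal(0.0, config.noise_sd, size=int(brain.sum()))
    # foreground must stay strictly positive (background is exactly 0)
    img[brain] = np.maximum(img[brain], 0.02)
    return img.astype(np.float32), tumor.astype(np.uint8), label


def _place_tumor(s: int, brain: np.ndarray, rng: np.random.Generator,
                 config: PhantomConfig, max_tries: int = 50) -> np.ndarray:
    lo, hi = config.tumor_area_range
    inner = ndimage.binary_erosion(brain, iterations=max(2, s // 16))
    ys, xs = np.nonzero(inner)
    if ys.size == 0:
        raise RuntimeError("brain region too small to host a tumor")
    for _ in range(max_tries):
        j = rng.integers(ys.size)
        cy, cx = float(ys[j]), float(xs[j])
        tumor = np.zeros((s, s), dtype=bool)
        for k in range(rng.integers(1, 4)):
            ay = rng.uniform(3.5, 10.0)
            ax = rng.uniform(3.5, 10.0)
            dy = cy + (rng.uniform(-ay, ay) if k else 0.0)
            dx = cx + (rng.uniform(-ax, ax) if k else 0.0)
            tumor |= _ellipse_mask(s, dy, dx, ay, ax, rng.uniform(0, np.pi))
        tumor &= brain
        if lo <= tumor.sum() <= hi:
            return tumor
    raise RuntimeError(f"could not place a tumor of area in [{lo}, {hi}] "
                       f"after {max_tries} tries")


def _necrosis_core(tumor: np.ndarray, fraction: float) -> np.ndarray:
    ys, xs = np.nonzero(tumor)
    cy, cx = ys.mean(), xs.mean()
    d = (ys - cy) ** 2 + (xs - cx) ** 2
    k = max(1, int(round(fraction * ys.size)))
    order = np.argsort(d)[:k]
    core = np.zeros_like(tumor)
    core[ys[order], xs[order]] = True
    return core


def generate_case_arrays(config: PhantomConfig):
    """In-memory dataset: (images, masks, labels, case_ids), grouped so
    that all slices of a case share its label."""
    rng = np.random.default_rng(config.seed)
    images, masks, labels, case_ids = [], [], [], []
    for i in range(config.n_cases):
        label = (METHYLATED if rng.random() < config.p_methylated
                 else UNMETHYLATED)
        for _ in range(config.slices_per_case):
            img, msk, _ = generate_phantom(rng, config, label)
            images.append(img)
            masks.append(msk)
            labels.append(label)
            case_ids.append(f"case_{i:03d}")
    return images, masks, labels, case_ids


def generate_dataset(config: PhantomConfig, out_dir) -> DatasetManifest:
    """Write PNG slices/masks plus the manifest CSV; returns the manifest.

    Images are stored as 16-bit PNG with fixed quantization (intensity *
    1000), masks as 8-bit binary PNG.
    """
    import imageio.v3 as iio

    os.makedirs(out_dir, exist_ok=True)
    images, masks, labels, case_ids = generate_case_arrays(config)
    refs: dict[str, dict] = {}
    for idx, (img, msk, lab, cid) in enumerate(
            zip(images, masks, labels, case_ids)):
        sl = f"{cid}_slice{idx % config.slices_per_case}"
        img_path = os.path.join(out_dir, f"{sl}.png")
        msk_path = os.path.join(out_dir, f"{sl}_mask.png")
        iio.imwrite(img_path, np.round(img * PNG_SCALE).astype(np.uint16))
        iio.imwrite(msk_path, (msk * 255).astype(np.uint8))
        entry = refs.setdefault(cid, {"label": lab, "slices": [], "masks": []})
        entry["slices"].append(img_path)
        entry["masks"].append(msk_path)
    manifest = DatasetManifest(
        cases=[CaseRecord(case_id=cid, modality=config.modality,
                          slice_refs=e["slices"], mask_refs=e["masks"],
                          label=e["label"])
               for cid, e in refs.items()],
        modality=config.modality)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"))
    return manifest


def load_slice(path: str) -> np.ndarray:
    """Read a phantom PNG back to float intensities (inverse quantization);
    also accepts NIfTI files (first axis = slices collapsed by indexing)."""
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        arr = np.asanyarray(nib.load(path).dataobj, dtype=float)
        return arr[..., 0] if arr.ndim == 3 else arr
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.dtype == np.uint16:
        return arr.astype(float) / PNG_SCALE
    return arr.astype(float)
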