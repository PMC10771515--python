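"""Layered image preprocessing and augmentation.

Mammography: CLAHE contrast enhancement then wavelet-coefficient
compression.  Histology: Reinhard-style color normalization (channel
statistics matched in a perceptual Lab-type space) then median denoise and
min-max contrast stretch.  Augmentation tops classes up with flips and
rotations while recording per-sample provenance.

All operations preserve batch shape and the [0, 1] value range and never
alter labels.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage
from skimage import color, exposure

from .datatypes import ImageBatch

__all__ = [
    "clahe",
    "wavelet_compress",
    "reinhard_normalize",
    "lab_stats",
    "denoise_enhance",
    "augment_balance",
]

_STD_FLOOR = 1e-6


def clahe(batch: ImageBatch, clip_limit: float = 0.01,
          tile_grid: tuple = (8, 8)) -> ImageBatch:
    """Contrast-limited adaptive histogram equalization (grayscale only)."""
    if batch.pixels.shape[-1] != 1:
        raise ValueError("CLAHE is applied to single-channel (mammography) batches only")
    h, w = batch.pixels.shape[1:3]
    kernel = (max(1, h // tile_grid[0]), max(1, w // tile_grid[1]))
    out = np.stack([
        exposure.equalize_adapthist(img[..., 0], kernel_size=kernel,
                                    clip_limit=clip_limit)[..., None]
        for img in batch.pixels
    ])
    return ImageBatch(np.clip(out, 0, 1), list(batch.labels), batch.modality,
                      list(batch.provenance))


def wavelet_compress(batch: ImageBatch, wavelet: str = "db2", level: int = 2,
                     keep_fraction: float = 0.1) -> ImageBatch:
    """Zero the smallest-magnitude detail coefficients, then reconstruct.

    keep_fraction is the fraction of detail coefficients retained (by
    global magnitude rank, per image and channel); approximation
    coefficients are always kept, so keep_fraction=1 is a lossless
    round-trip.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must lie in (0, 1]")
    h, w = batch.pixels.shape[1:3]
    max_level = pywt.dwtn_max_level((h, w), wavelet)
    if level > max_level:
        raise ValueError(f"level {level} exceeds decomposable depth {max_level} "
                         f"for {h}x{w} images with {wavelet!r}")
    out = np.empty_like(batch.pixels)
    for i, img in enumerate(batch.pixels):
        for c in range(img.shape[-1]):
            coeffs = pywt.wavedec2(img[..., c], wavelet, level=level)
            if keep_fraction < 1.0:
                details = np.concatenate([np.abs(a).ravel()
                                          for lvl in coeffs[1:] for a in lvl])
                thresh = np.quantile(details, 1.0 - keep_fraction)
                coeffs = [coeffs[0]] + [
                    tuple(np.where(np.abs(a) >= thresh, a, 0.0) for a in lvl)
                    for lvl in coeffs[1:]
                ]
            rec = pywt.waverec2(coeffs, wavelet)[:h, :w]
            out[i, ..., c] = np.clip(rec, 0.0, 1.0)
    return ImageBatch(out, list(batch.labels), batch.modality, list(batch.provenance))


def lab_stats(batch: ImageBatch):
    """Per-channel (mean, std) of the batch in Lab space — reference stats."""
    lab = color.rgb2lab(batch.pixels)
    flat = lab.reshape(-1, 3)
    return flat.mean(axis=0), flat.std(axis=0)


def reinhard_normalize(batch: ImageBatch, reference_mean, reference_std) -> ImageBatch:
    """Match each image's Lab channel statistics to a reference.

    The classic color-transfer recipe for stain standardization: convert to
    a perceptual Lab-type space, shift/scale each channel to the reference
    mean and std, convert back, clip to [0, 1].  Degenerate (constant)
    channels get a std floor instead of dividing by zero.
    """
    if batch.pixels.shape[-1] != 3:
        raise ValueError("Reinhard normalization needs RGB (histology) batches")
    ref_mean = np.asarray(reference_mean, dtype=float)
    ref_std = np.asarray(reference_std, dtype=float)
    out = np.empty_like(batch.pixels)
    for i, img in enumerate(batch.pixels):
        lab = color.rgb2lab(img)
        mean = lab.reshape(-1, 3).mean(axis=0)
        std = np.maximum(lab.reshape(-1, 3).std(axis=0), _STD_FLOOR)
        lab = (lab - mean) / std * ref_std + ref_mean
        out[i] = np.clip(color.lab2rgb(lab), 0.0, 1.0)
    return ImageBatch(out, list(batch.labels), batch.modality, list(batch.provenance))


def denoise_enhance(batch: ImageBatch, median_size: int = 3) -> ImageBatch:
    """Median-filter denoise plus per-image min-max contrast stretch."""
    out = np.empty_like(batch.pixels)
    for i, img in enumerate(batch.pixels):
        for c in range(img.shape[-1]):
            f = ndimage.median_filter(img[..., c], size=median_size)
            lo, hi = f.min(), f.max()
            out[i, ..., c] = (f - lo) / (hi - lo) if hi - lo > 1e-12 else f
    return ImageBatch(np.clip(out, 0, 1), list(batch.labels), batch.modality,
                      list(batch.provenance))


_TRANSFORMS = ("hflip", "vflip", "rot90", "rot180", "rot270")


def _apply_transform(img, name, rng, small_angle):
    if name == "hflip":
        return img[:, ::-1]
    if name == "vflip":
        return img[::-1]
    if name.startswith("rot"):
        return np.rot90(img, k=int(name[3:]) // 90)
    if name == "small_angle":
        angle = rng.uniform(-small_angle, small_angle)
        return np.clip(ndimage.rotate(img, angle, reshape=False, mode="reflect"), 0, 1)
    raise ValueError(name)


def augment_balance(batch: ImageBatch, target_per_class: int, seed: int,
                    small_angle: float = 0.0) -> ImageBatch:
    """Top every class up to target_per_class with flips/rotations.

    Originals are retained; each appended sample records its source index
    and transform in the provenance list.  small_angle > 0 additionally
    enables ±small_angle degree rotations with reflect padding.
    """
    labels = np.asarray(batch.labels)
    counts = batch.class_counts
    for cls, cnt in counts.items():
        if cnt == 0:
            raise ValueError(f"class {cls!r} is empty")
        if cnt > target_per_class:
            raise ValueError(
                f"target_per_class={target_per_class} below current count {cnt} "
                f"of class {cls!r}")
    rng = np.random.default_rng(seed)
    transforms = _TRANSFORMS + (("small_angle",) if small_angle > 0 else ())
    pixels = [batch.pixels]
    new_labels = list(batch.labels)
    provenance = list(batch.provenance)
    for cls in sorted(counts):
        need = target_per_class - counts[cls]
        src_idx = np.flatnonzero(labels == cls)
        for _ in range(need):
            src = int(rng.choice(src_idx))
            name = str(rng.choice(transforms))
            img = _apply_transform(batch.pixels[src], name, rng, small_angle)
            pixels.append(img[None])
            new_labels.append(cls)
            provenance.append(f"{name}(src={src})")
    return ImageBatch(np.concatenate(pixels), new_labels, batch.modality, provenance)
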