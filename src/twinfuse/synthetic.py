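"""Synthetic multimodal image sets, feature matrices, and the packaged
probability-table fixture.

The image generators plant class-discriminative structure (blobs, speckle,
tints, textures) so every downstream stage — preprocessing, CNN training,
feature selection, fusion — is exercisable at desk scale without any
external mammography or histopathology download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import FeatureMatrix, ImageBatch
from .fusion import ProbabilityRecord

__all__ = [
    "SyntheticImageSpec",
    "gen_mammo_like",
    "gen_histo_like",
    "gen_feature_matrix",
    "table4_fixture",
    "TABLE4_MAMMO_PREDICTED",
    "TABLE4_HISTO_PREDICTED",
]

# Default per-class motif parameters.  Mammography-like classes: 'N' plain,
# 'BM'/'M' soft bright blobs (mass-like; 'M' stronger), 'BC'/'CALC'
# high-frequency bright speckle (calcification-like).  Histology-like
# classes: an RGB tint plus a spatial texture frequency (stain variation).
_MAMMO_MOTIFS = {
    "N": {"blobs": 0, "blob_amp": 0.0, "speckle": 0, "speckle_amp": 0.0},
    "BM": {"blobs": 2, "blob_amp": 0.35, "speckle": 0, "speckle_amp": 0.0},
    "M": {"blobs": 4, "blob_amp": 0.55, "speckle": 0, "speckle_amp": 0.0},
    "BC": {"blobs": 0, "blob_amp": 0.0, "speckle": 25, "speckle_amp": 0.5},
    "CALC": {"blobs": 0, "blob_amp": 0.0, "speckle": 60, "speckle_amp": 0.7},
}
_HISTO_MOTIFS = {
    "N": {"tint": (0.85, 0.75, 0.85), "freq": 2.0},
    "B": {"tint": (0.80, 0.55, 0.75), "freq": 5.0},
    "M": {"tint": (0.60, 0.35, 0.65), "freq": 10.0},
    "A": {"tint": (0.78, 0.60, 0.78), "freq": 4.0},
    "DC": {"tint": (0.55, 0.30, 0.60), "freq": 12.0},
}


@dataclass
class SyntheticImageSpec:
    """Recipe for one synthetic image set; the seed fully determines output."""

    n_per_class: int = 10
    classes: tuple = ("N", "M")
    size: tuple = (32, 32)
    channels: int = 1
    noise_sd: float = 0.05
    seed: int = 0
    motifs: dict = field(default_factory=dict)

    def motif_for(self, cls: str, table: dict) -> dict:
        if cls in self.motifs:
            return self.motifs[cls]
        if cls not in table:
            raise KeyError(
                f"unknown class {cls!r}; known: {sorted(table)} (or supply spec.motifs)"
            )
        return table[cls]


def _soft_blob(h, w, cy, cx, radius, amp):
    yy, xx = np.mgrid[0:h, 0:w]
    return amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * radius**2)))


def gen_mammo_like(spec: SyntheticImageSpec) -> ImageBatch:
    """Grayscale images: background gradient + noise + class motifs."""
    if spec.channels != 1:
        raise ValueError("mammography-like images are single channel")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    grad = np.linspace(0.15, 0.45, h)[:, None] * np.ones((1, w))
    images, labels = [], []
    for cls in spec.classes:
        m = spec.motif_for(cls, _MAMMO_MOTIFS)
        for _ in range(spec.n_per_class):
            img = grad + rng.normal(0.0, spec.noise_sd, size=(h, w))
            for _ in range(m["blobs"]):
                cy, cx = rng.uniform(0.2, 0.8, 2) * (h, w)
                radius = rng.uniform(0.08, 0.18) * min(h, w)
                img += _soft_blob(h, w, cy, cx, radius, m["blob_amp"])
            if m["speckle"]:
                ys = rng.integers(0, h, m["speckle"])
                xs = rng.integers(0, w, m["speckle"])
                img[ys, xs] += m["speckle_amp"]
            images.append(np.clip(img, 0.0, 1.0))
            labels.append(cls)
    pixels = np.stack(images)[..., None]
    return ImageBatch(pixels=pixels, labels=labels, modality="mammography")


def gen_histo_like(spec: SyntheticImageSpec) -> ImageBatch:
    """RGB texture patches with class-controlled tint and spatial frequency."""
    if spec.channels != 3:
        raise ValueError("histology-like images have 3 channels")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    yy, xx = np.mgrid[0:h, 0:w] / max(h, w)
    images, labels = [], []
    for cls in spec.classes:
        m = spec.motif_for(cls, _HISTO_MOTIFS)
        tint = np.asarray(m["tint"])
        for _ in range(spec.n_per_class):
            phase = rng.uniform(0, 2 * np.pi, 2)
            texture = 0.5 + 0.25 * (
                np.sin(2 * np.pi * m["freq"] * yy + phase[0])
                * np.cos(2 * np.pi * m["freq"] * xx + phase[1])
            )
            img = texture[..., None] * tint[None, None, :]
            img = img + rng.normal(0.0, spec.noise_sd, size=(h, w, 3))
            images.append(np.clip(img, 0.0, 1.0))
            labels.append(cls)
    return ImageBatch(pixels=np.stack(images), labels=labels, modality="histology")


def gen_feature_matrix(n: int, dim: int, informative, effect: float = 3.0,
                       seed: int = 0):
    """Two-class Gaussian feature matrix with a known informative subset.

    Informative columns are shifted by ±effect/2 between the classes;
    all other columns are pure N(0, 1) noise.  Returns (FeatureMatrix,
    labels, oracle_mask) where oracle_mask marks the informative columns.
    """
    informative = sorted(set(int(i) for i in informative))
    if not informative:
        raise ValueError("informative column set must be non-empty")
    if informative[0] < 0 or informative[-1] >= dim:
        raise ValueError(f"informative indices must lie in [0, {dim})")
    rng = np.random.default_rng(seed)
    y = np.array([0] * (n // 2) + [1] * (n - n // 2))
    rng.shuffle(y)
    X = rng.normal(0.0, 1.0, size=(n, dim))
    shift = effect / 2.0
    for j in informative:
        X[:, j] += np.where(y == 1, shift, -shift)
    mask = np.zeros(dim, dtype=int)
    mask[informative] = 1
    fm = FeatureMatrix(X=X, sample_ids=[f"s{i}" for i in range(n)],
                       labels=y.tolist())
    return fm, y, mask


# The 20-row printed probability table: histology actual/predicted are
# constant; the mammography predicted column varies per row.
TABLE4_HISTO_PREDICTED = 0.954039
TABLE4_MAMMO_PREDICTED = (
    0.826078, 0.826073, 0.811109, 0.755488, 0.671327,
    0.742093, 0.793881, 0.756792, 0.751871, 0.711373,
    0.803643, 0.799792, 0.654440, 0.826077, 0.822246,
    0.789946, 0.826076, 0.722376, 0.567527, 0.757711,
)


def table4_fixture():
    """The packaged 20-sample probability-table fixture.

    Histology rows: actual probability 1.0, predicted 0.954039, malignant
    (coarse M) throughout.  Mammography rows: actual 1.0, predicted as
    printed, normal (coarse N) throughout.  The source table prints only
    coarse labels; the fine labels here ('DC' for histology, 'N' for
    mammography) are synthetic stand-ins — any malignant histology fine
    class remaps identically, so downstream fusion is unaffected.

    Returns (hist_records, mammo_records), 20 ProbabilityRecords each.
    """
    hist, mammo = [], []
    for i, mp in enumerate(TABLE4_MAMMO_PREDICTED, start=1):
        sid = f"S{i:02d}"
        hist.append(ProbabilityRecord(
            sample_id=sid, modality="histology",
            actual_prob=1.0, predicted_prob=TABLE4_HISTO_PREDICTED,
            fine_true="DC", fine_pred="DC"))
        mammo.append(ProbabilityRecord(
            sample_id=sid, modality="mammography",
            actual_prob=1.0, predicted_prob=mp,
            fine_true="N", fine_pred="N"))
    return hist, mammo
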