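"""Shared in-memory containers for the twinfuse pipeline.

Images travel as :class:`ImageBatch` (channels-last float arrays in [0, 1]),
extracted CNN features as :class:`FeatureMatrix` (one row per image).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODALITIES = ("histology", "mammography")


@dataclass
class ImageBatch:
    """A labelled batch of images.

    pixels : (n, H, W, C) float array with values in [0, 1].
    labels : per-image fine class labels.
    modality : "histology" (C == 3) or "mammography" (C == 1).
    provenance : per-image origin tag, e.g. "original" or "hflip(src=3)".
    """

    pixels: np.ndarray
    labels: list
    modality: str
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 4:
            raise ValueError(f"pixels must be (n, H, W, C); got shape {self.pixels.shape}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}; got {self.modality!r}")
        expected_c = 3 if self.modality == "histology" else 1
        if self.pixels.shape[-1] != expected_c:
            raise ValueError(
                f"{self.modality} batches need {expected_c} channel(s); got {self.pixels.shape[-1]}"
            )
        if len(self.labels) != len(self.pixels):
            raise ValueError("labels and pixels disagree on batch size")
        if self.pixels.size and (self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9):
            raise ValueError("pixel values must lie in [0, 1]")
        if not self.provenance:
            self.provenance = ["original"] * len(self.pixels)

    def __len__(self):
        return len(self.pixels)

    @property
    def class_counts(self) -> dict:
        vals, counts = np.unique(np.asarray(self.labels), return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass
class FeatureMatrix:
    """Samples x features real matrix with aligned ids and fine labels."""

    X: np.ndarray
    sample_ids: list
    labels: list

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, dim)")
        n = self.X.shape[0]
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("sample_ids/labels must align with rows of X")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains NaN/inf")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]
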