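"""Plain-text serialization: feature matrices (CSV/NPZ), binary masks
(0/1 lines or JSON), and probability tables (CSV)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix
from .fusion import ProbabilityRecord

__all__ = [
    "read_image_batch", "write_image_batch",
    "read_feature_csv", "write_feature_csv",
    "read_feature_npz", "write_feature_npz",
    "read_mask", "write_mask",
    "records_to_frame", "frame_to_records",
    "read_probability_csv", "write_probability_csv",
]

PROB_COLUMNS = ["sample_id", "modality", "actual_prob", "predicted_prob",
                "fine_true", "fine_pred"]


def read_image_batch(directory, modality: str):
    """Load a PNG/TIFF image set described by <directory>/manifest.csv
    (columns: file, label) into an ImageBatch with [0, 1] pixels."""
    from PIL import Image

    from .datatypes import ImageBatch

    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    arrs, labels = [], []
    for _, row in manifest.iterrows():
        img = np.asarray(Image.open(directory / row["file"]), dtype=float) / 255.0
        if img.ndim == 2:
            img = img[..., None]
        arrs.append(img)
        labels.append(row["label"])
    return ImageBatch(np.stack(arrs), labels, modality)


def write_image_batch(batch, directory) -> None:
    """Write a batch as PNGs plus a manifest.csv (inverse of read_image_batch)."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, lab) in enumerate(zip(batch.pixels, batch.labels)):
        arr = (np.clip(img, 0, 1) * 255).astype(np.uint8)
        name = f"{batch.modality}_{i:04d}.png"
        Image.fromarray(arr[..., 0] if arr.shape[-1] == 1 else arr).save(directory / name)
        rows.append({"file": name, "label": lab})
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)


def read_feature_csv(path, labels_col: str | None = None) -> FeatureMatrix:
    """CSV layout: header row, first column sample id, last column label
    (or the one named by labels_col)."""
    df = pd.read_csv(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    df = df.iloc[:, 1:]
    labels_col = labels_col or df.columns[-1]
    labels = df[labels_col].tolist()
    X = df.drop(columns=[labels_col]).to_numpy(dtype=float)
    return FeatureMatrix(X=X, sample_ids=ids, labels=labels)


def write_feature_csv(fm: FeatureMatrix, path) -> None:
    df = pd.DataFrame(fm.X, columns=[f"f{j}" for j in range(fm.dim)])
    df.insert(0, "sample_id", fm.sample_ids)
    df["label"] = fm.labels
    df.to_csv(path, index=False)


def read_feature_npz(path) -> FeatureMatrix:
    with np.load(path, allow_pickle=True) as z:
        X, y = z["X"], z["y"]
    return FeatureMatrix(X=X, sample_ids=[f"s{i}" for i in range(len(X))],
                         labels=list(y))


def write_feature_npz(fm: FeatureMatrix, path) -> None:
    np.savez(path, X=fm.X, y=np.asarray(fm.labels))


def read_mask(path) -> np.ndarray:
    text = Path(path).read_text().strip()
    if text.startswith("{"):
        return np.asarray(json.loads(text)["mask"], dtype=int)
    return np.asarray([int(line) for line in text.splitlines() if line.strip()],
                      dtype=int)


def write_mask(mask, path, fitness: float | None = None) -> None:
    path = Path(path)
    mask = [int(b) for b in mask]
    if path.suffix == ".json":
        payload = {"mask": mask}
        if fitness is not None:
            payload["fitness"] = fitness
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        path.write_text("\n".join(str(b) for b in mask) + "\n")


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id, "modality": r.modality,
            "actual_prob": r.actual_prob, "predicted_prob": r.predicted_prob,
            "fine_true": r.fine_true, "fine_pred": r.fine_pred,
            "coarse_true": r.coarse_true, "coarse_pred": r.coarse_pred,
            "fused_prob": r.fused_prob,
        })
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list:
    missing = [c for c in PROB_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probability table missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(ProbabilityRecord(
            sample_id=str(row["sample_id"]), modality=row["modality"],
            actual_prob=float(row["actual_prob"]),
            predicted_prob=float(row["predicted_prob"]),
            fine_true=row["fine_true"], fine_pred=row["fine_pred"],
            coarse_true=row.get("coarse_true", "") or "",
            coarse_pred=row.get("coarse_pred", "") or ""))
    return records


def read_probability_csv(path) -> list:
    return frame_to_records(pd.read_csv(path))


def write_probability_csv(records, path) -> None:
    records_to_frame(records).to_csv(path, index=False)
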