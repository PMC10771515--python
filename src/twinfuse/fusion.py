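"""Class-label remapping and probability-map fusion.

The two modalities classify into different fine label spaces (12 histology
classes, 5 mammography classes).  Fusion first remaps both into the shared
coarse {N, B, M} regime (normal / benign / malignant), then combines
per-modality probabilities into a single multimodal decision, optionally
running BEOSA over the 6-bit probability-map selection space.

Fusion probability rules are pluggable; the defaults are

* per-modality: (actual + predicted) / 2
* multimodal:   hist_predicted / 2 + mammo_predicted / 4

which reproduce the packaged probability-table fixture row for row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import beosa

__all__ = [
    "LabelMap",
    "MAMMO_LABEL_MAP",
    "HISTO_LABEL_MAP",
    "ProbabilityRecord",
    "FusionItem",
    "remap_label",
    "remap_probabilities",
    "modality_fused_probability",
    "multimodal_fused_probability",
    "fused_label",
    "build_fusion_space",
    "fusion_fitness",
    "optimize_fusion",
]

COARSE_CLASSES = ("N", "B", "M")
EN_DASH = "–"


@dataclass(frozen=True)
class LabelMap:
    """Partition of a fine label space into the coarse {N, B, M} classes."""

    coarse_to_fine: dict

    def __post_init__(self):
        if set(self.coarse_to_fine) != set(COARSE_CLASSES):
            raise ValueError(f"coarse classes must be exactly {COARSE_CLASSES}")
        seen = {}
        for coarse, fines in self.coarse_to_fine.items():
            for f in fines:
                if f in seen:
                    raise ValueError(f"fine label {f!r} in both {seen[f]!r} and {coarse!r}")
                seen[f] = coarse

    @property
    def fine_to_coarse(self) -> dict:
        return {f: c for c, fines in self.coarse_to_fine.items() for f in fines}

    @property
    def fine_classes(self) -> list:
        return [f for c in COARSE_CLASSES for f in self.coarse_to_fine[c]]


MAMMO_LABEL_MAP = LabelMap({"N": ["N"], "B": ["BC", "BM"], "M": ["CALC", "M"]})
HISTO_LABEL_MAP = LabelMap({
    "N": ["N"],
    "B": ["B", "A", "F", "PT", "TA"],
    "M": ["IS", "IV", "DC", "LC", "MC", "PC"],
})

_DEFAULT_MAPS = {"mammography": MAMMO_LABEL_MAP, "histology": HISTO_LABEL_MAP}


def remap_label(fine: str, label_map: LabelMap) -> str:
    """Coarse owner of a fine class label."""
    lookup = label_map.fine_to_coarse
    if fine not in lookup:
        raise KeyError(f"unknown fine label {fine!r}; valid: {sorted(lookup)}")
    return lookup[fine]


def remap_probabilities(fine_probs, label_map: LabelMap) -> np.ndarray:
    """Aggregate a fine-class probability vector into [P(N), P(B), P(M)].

    Coarse probability is the sum over member fine classes (conserves total
    mass exactly).  fine_probs must follow label_map.fine_classes order.
    """
    fine_probs = np.asarray(fine_probs, dtype=float)
    order = label_map.fine_classes
    if fine_probs.size != len(order):
        raise ValueError(f"expected {len(order)} fine probabilities, got {fine_probs.size}")
    if abs(fine_probs.sum() - 1.0) > 1e-9:
        raise ValueError("fine probabilities must sum to 1")
    out, k = [], 0
    for c in COARSE_CLASSES:
        n = len(label_map.coarse_to_fine[c])
        out.append(fine_probs[k:k + n].sum())
        k += n
    return np.asarray(out)


def _check_prob(p, name):
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1]; got {p}")


def modality_fused_probability(actual_prob: float, predicted_prob: float) -> float:
    """Single-modality fused probability: the actual/predicted mean."""
    _check_prob(actual_prob, "actual_prob")
    _check_prob(predicted_prob, "predicted_prob")
    return (actual_prob + predicted_prob) / 2.0


def multimodal_fused_probability(hist_pred: float, mammo_pred: float) -> float:
    """Multimodal fused probability hist_pred/2 + mammo_pred/4.

    Histology carries twice the mammography weight; the rule reproduces the
    packaged fixture's fused column and its printed average.
    """
    _check_prob(hist_pred, "hist_pred")
    _check_prob(mammo_pred, "mammo_pred")
    return hist_pred / 2.0 + mammo_pred / 4.0


def fused_label(coarse_hist: str, coarse_mammo: str) -> str:
    """'<hist>–<mammo>' (en dash), collapsing agreement to a single label."""
    for lab in (coarse_hist, coarse_mammo):
        if lab not in COARSE_CLASSES:
            raise ValueError(f"coarse label must be in {COARSE_CLASSES}; got {lab!r}")
    if coarse_hist == coarse_mammo:
        return coarse_hist
    return f"{coarse_hist}{EN_DASH}{coarse_mammo}"


@dataclass
class ProbabilityRecord:
    """Per-sample classifier output for one modality.

    actual_prob is the probability assigned to the true fine label,
    predicted_prob the maximum predicted probability.  Coarse labels are
    derived from the modality's label map unless supplied.  coarse_probs,
    when present, is the full remapped [N, B, M] vector.
    """

    sample_id: str
    modality: str
    actual_prob: float
    predicted_prob: float
    fine_true: str
    fine_pred: str
    coarse_true: str = ""
    coarse_pred: str = ""
    coarse_probs: np.ndarray | None = None
    fused_prob: float = float("nan")

    def __post_init__(self):
        _check_prob(self.actual_prob, "actual_prob")
        _check_prob(self.predicted_prob, "predicted_prob")
        label_map = _DEFAULT_MAPS.get(self.modality)
        if label_map is not None:
            lut = label_map.fine_to_coarse
            if not self.coarse_true:
                self.coarse_true = lut.get(self.fine_true, "")
            if not self.coarse_pred:
                self.coarse_pred = lut.get(self.fine_pred, "")
        if self.coarse_probs is not None:
            self.coarse_probs = np.asarray(self.coarse_probs, dtype=float)


def _coarse_vector(rec: ProbabilityRecord) -> np.ndarray:
    """Record's coarse 3-vector; synthesized when only scalars are known.

    The synthesized vector places predicted_prob on the predicted coarse
    class and splits the remaining mass uniformly over the other two.
    """
    if rec.coarse_probs is not None:
        return rec.coarse_probs
    vec = np.full(3, (1.0 - rec.predicted_prob) / 2.0)
    vec[COARSE_CLASSES.index(rec.coarse_pred)] = rec.predicted_prob
    return vec


@dataclass
class FusionItem:
    """One element of the fusion search space.

    probs holds the histology coarse 3-vector followed by the mammography
    coarse 3-vector; pos is the 6-bit selection, initialized all ones.
    """

    index: int
    probs: np.ndarray
    pos: np.ndarray = field(default_factory=lambda: np.ones(6, dtype=int))
    fit: float = float("nan")
    hist_record: ProbabilityRecord | None = None
    mammo_record: ProbabilityRecord | None = None

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.pos = np.asarray(self.pos, dtype=int)
        if self.probs.size != 6 or self.pos.size != 6:
            raise ValueError("FusionItem needs 6 probabilities and a 6-bit pos")


def build_fusion_space(hist_records, mammo_records, mode: str = "cartesian") -> list:
    """Assemble FusionItems from two record lists.

    mode 'cartesian' pairs every histology record with every mammography
    record (N×M items); 'matched' restricts to pairs sharing coarse_true;
    'paired' zips the lists row by row.
    """
    if not hist_records or not mammo_records:
        raise ValueError("both record lists must be non-empty")
    if mode == "paired":
        if len(hist_records) != len(mammo_records):
            raise ValueError("'paired' mode needs equal-length record lists")
        pairs = list(zip(hist_records, mammo_records))
    else:
        pairs = [(h, m) for h in hist_records for m in mammo_records]
        if mode == "matched":
            pairs = [(h, m) for h, m in pairs if h.coarse_true == m.coarse_true]
        elif mode != "cartesian":
            raise ValueError(f"unknown mode {mode!r}")
    items = []
    for idx, (h, m) in enumerate(pairs):
        probs = np.concatenate([_coarse_vector(h), _coarse_vector(m)])
        items.append(FusionItem(index=idx, probs=probs, hist_record=h, mammo_record=m))
    return items


def fusion_fitness(item: FusionItem) -> float:
    """fit = 2 − (selected histology mass + selected mammography mass).

    Minimized at 0 when both normalized 3-vectors are fully selected; 2 at
    the empty selection.  Adding a bit with positive probability never
    increases the fitness.
    """
    sel = item.pos != 0
    return 2.0 - (item.probs[:3][sel[:3]].sum() + item.probs[3:][sel[3:]].sum())


def optimize_fusion(space, config: beosa.BeosaConfig | None = None,
                    multimodal_rule=multimodal_fused_probability):
    """BEOSA over each item's 6-bit probability-map selection.

    Returns (optimized items, report DataFrame).  The report lists, per
    item, the two predicted coarse labels, the fused label, and the fused
    multimodal probability.
    """
    if not space:
        raise ValueError("fusion space is empty")
    if config is None:
        config = beosa.BeosaConfig(pop_size=8, max_iter=15, seed=0)
    optimized, rows = [], []
    for k, item in enumerate(space):
        cfg = replace(config, seed=(config.seed + 7919 * k) % (2**31))
        res = beosa.optimize(
            dim=6,
            fitness_fn=lambda pos, it=item: fusion_fitness(replace(it, pos=pos)),
            config=cfg,
        )
        new_item = replace(item, pos=res.best.pos.copy(), fit=res.best.fitness)
        optimized.append(new_item)
        h, m = item.hist_record, item.mammo_record
        lab = fused_label(h.coarse_pred, m.coarse_pred)
        rows.append({
            "index": item.index,
            "hist_id": h.sample_id, "mammo_id": m.sample_id,
            "hist_coarse_pred": h.coarse_pred, "mammo_coarse_pred": m.coarse_pred,
            "fused_label": lab,
            "fused_prob": multimodal_rule(h.predicted_prob, m.predicted_prob),
            "fit": new_item.fit,
        })
    return optimized, pd.DataFrame(rows)
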