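"""End-to-end orchestration: preprocess → extract → select → classify →
fuse, with a serializable configuration so any run can be reproduced
bit-for-bit from its persisted config file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beosa, fusion, io, preprocessing, stats, synthetic
from .datatypes import ImageBatch
from .extractors import TrainConfig, build_extractor, extract_features, mini_spec, train

logger = logging.getLogger("twinfuse")

__all__ = ["PipelineConfig", "run_unimodal", "run_multimodal"]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run.

    Extractor geometry defaults to the desk-scale mini spec; the full-size
    specs are available through extractors.mammo_spec / histo_spec.
    """

    modality: str = "mammography"
    seed: int = 0
    # synthetic data (used when no images are supplied)
    classes: tuple = ("N", "M")
    n_per_class: int = 60
    image_size: tuple = (32, 32)
    noise_sd: float = 0.05
    # preprocessing toggles
    use_clahe: bool = True
    use_wavelet: bool = True
    wavelet_keep: float = 0.5
    use_reinhard: bool = True
    use_denoise: bool = True
    # extractor / training (desk-scale defaults; reference values in Table-2
    # style full specs are lr 1e-6 etc., unusable in a handful of epochs)
    blocks: tuple = (8, 16)
    dense_units: int = 32
    pool_stride: int = 2
    learning_rate: float = 1e-3
    epochs: int = 12
    batch_size: int = 32
    splits: tuple = (0.75, 0.15, 0.10)
    # feature selection
    select_pop: int = 20
    select_iters: int = 30
    transfer: str = "S"
    # fusion
    fusion_mode: str = "paired"
    optimize_fusion: bool = False

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("classes", "image_size", "blocks", "splits"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _synthesize(config: PipelineConfig) -> ImageBatch:
    spec = synthetic.SyntheticImageSpec(
        n_per_class=config.n_per_class, classes=tuple(config.classes),
        size=tuple(config.image_size), noise_sd=config.noise_sd,
        channels=1 if config.modality == "mammography" else 3,
        seed=config.seed)
    if config.modality == "mammography":
        return synthetic.gen_mammo_like(spec)
    return synthetic.gen_histo_like(spec)


def _preprocess(batch: ImageBatch, config: PipelineConfig) -> ImageBatch:
    if batch.modality == "mammography":
        if config.use_clahe:
            batch = preprocessing.clahe(batch)
        if config.use_wavelet:
            batch = preprocessing.wavelet_compress(
                batch, keep_fraction=config.wavelet_keep)
    else:
        if config.use_reinhard:
            mean, std = preprocessing.lab_stats(batch)
            batch = preprocessing.reinhard_normalize(batch, mean, std)
        if config.use_denoise:
            batch = preprocessing.denoise_enhance(batch)
    return batch


def run_unimodal(config: PipelineConfig, images: ImageBatch | None = None,
                 outdir=None):
    """Single-modality pipeline: preprocess, train the extractor, select
    features with BEOSA, score classifiers, and emit the probability table.

    Returns a dict with the trained model, mask, probability records, score
    table and per-stage artifacts; everything is also written under outdir
    (resolved config included) when given.
    """
    artifacts = {}
    stage = "synthesize"
    try:
        if images is None:
            images = _synthesize(config)
        stage = "preprocess"
        logger.info("preprocess: %d images (%s)", len(images), images.modality)
        batch = _preprocess(images, config)

        stage = "train"
        spec = mini_spec(channels=batch.pixels.shape[-1],
                         n_classes=len(set(batch.labels)),
                         input_shape=(*config.image_size, batch.pixels.shape[-1]),
                         blocks=tuple(config.blocks),
                         dense_units=config.dense_units,
                         pool_stride=config.pool_stride)
        tcfg = TrainConfig(learning_rate=config.learning_rate,
                           epochs=config.epochs, batch_size=config.batch_size,
                           splits=tuple(config.splits), seed=config.seed)
        model = build_extractor(spec, seed=config.seed)
        model, history = train(model, batch, cfg=tcfg)
        logger.info("train: final acc %.3f", history["acc"][-1] if history["acc"] else float("nan"))

        stage = "extract"
        feats = extract_features(model, batch)

        stage = "select"
        y = np.asarray(batch.labels)
        from .extractors import stratified_split
        train_idx, _, test_idx = stratified_split(y, tuple(config.splits), config.seed)
        bcfg = beosa.BeosaConfig(pop_size=config.select_pop,
                                 max_iter=config.select_iters,
                                 transfer=config.transfer, seed=config.seed)
        res = beosa.optimize(
            dim=feats.dim,
            fitness_fn=lambda m: beosa.feature_fitness(
                m, feats.X[train_idx], y[train_idx], seed=config.seed),
            config=bcfg)
        mask = res.best.pos
        logger.info("select: %d/%d features, fitness %.4f",
                    int(mask.sum()), feats.dim, res.best.fitness)

        stage = "classify"
        Xm = beosa.apply_mask(feats, mask)
        score_table = stats.classify_and_score(Xm, y, seed=config.seed,
                                               splits=tuple(config.splits))
        stage = "probabilities"
        probs = model.predict_proba(batch.pixels[test_idx])
        classes = model.classes_
        fmap = fusion._DEFAULT_MAPS[batch.modality].fine_to_coarse
        records = []
        for row, i in zip(probs, test_idx):
            true_lab = batch.labels[i]
            pred_lab = classes[int(row.argmax())]
            records.append(fusion.ProbabilityRecord(
                sample_id=f"img{i}", modality=batch.modality,
                actual_prob=float(row[classes.index(true_lab)]),
                predicted_prob=float(row.max()),
                fine_true=true_lab, fine_pred=pred_lab,
                coarse_true=fmap.get(true_lab, true_lab),
                coarse_pred=fmap.get(pred_lab, pred_lab),
            ))
        artifacts.update(model=model, history=history, mask=mask,
                         optimize_result=res, features=feats,
                         score_table=score_table, records=records,
                         test_idx=test_idx)
    except Exception:
        logger.exception("unimodal pipeline failed at stage %r", stage)
        if outdir is not None:
            _persist_unimodal(artifacts, config, outdir)
        raise
    if outdir is not None:
        _persist_unimodal(artifacts, config, outdir)
    return artifacts


def _persist_unimodal(artifacts, config, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    if "mask" in artifacts:
        io.write_mask(artifacts["mask"], outdir / "mask.json",
                      fitness=float(artifacts["optimize_result"].best.fitness))
    if "score_table" in artifacts:
        artifacts["score_table"].to_csv(outdir / "scores.csv")
    if "records" in artifacts:
        io.write_probability_csv(artifacts["records"], outdir / "probs.csv")
    if "history" in artifacts:
        (outdir / "history.json").write_text(
            json.dumps(artifacts["history"], indent=1))


def run_multimodal(config: PipelineConfig, hist_records, mammo_records,
                   outdir=None):
    """Fuse two modality probability tables into the multimodal report.

    hist_records / mammo_records may be record lists, DataFrames, or CSV
    paths.  Returns a dict with the fused report DataFrame and the summary
    statistics (per-modality fused mean/variance, Welch t, F test).
    """

    def _load(obj):
        if isinstance(obj, (str, Path)):
            return io.read_probability_csv(obj)
        if isinstance(obj, pd.DataFrame):
            return io.frame_to_records(obj)
        return list(obj)

    hist = _load(hist_records)
    mammo = _load(mammo_records)
    for r in hist + mammo:
        r.fused_prob = fusion.modality_fused_probability(r.actual_prob,
                                                         r.predicted_prob)
    space = fusion.build_fusion_space(hist, mammo, mode=config.fusion_mode)
    if config.optimize_fusion:
        bcfg = beosa.BeosaConfig(pop_size=8, max_iter=15, seed=config.seed)
        items, report = fusion.optimize_fusion(space, bcfg)
    else:
        items = space
        rows = []
        for item in space:
            h, m = item.hist_record, item.mammo_record
            rows.append({
                "index": item.index, "hist_id": h.sample_id, "mammo_id": m.sample_id,
                "hist_coarse_pred": h.coarse_pred, "mammo_coarse_pred": m.coarse_pred,
                "fused_label": fusion.fused_label(h.coarse_pred, m.coarse_pred),
                "fused_prob": fusion.multimodal_fused_probability(
                    h.predicted_prob, m.predicted_prob),
                "fit": fusion.fusion_fitness(item),
            })
        report = pd.DataFrame(rows)

    hist_col = np.asarray([r.fused_prob for r in hist])
    mammo_col = np.asarray([r.fused_prob for r in mammo])
    welch = stats.welch_t_test(mammo_col, hist_col)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        ftest = stats.f_test_variances(mammo_col, hist_col)
    summary = {
        "hist_fused_mean": float(hist_col.mean()),
        "hist_fused_variance": stats.sample_variance(hist_col),
        "mammo_fused_mean": float(mammo_col.mean()),
        "mammo_fused_variance": stats.sample_variance(mammo_col),
        "multimodal_fused_mean": float(report["fused_prob"].mean()),
        "welch_t": welch.t, "welch_df": welch.df, "welch_p_two": welch.p_two,
        "f_stat": ftest.F,
    }
    out = {"report": report, "summary": summary, "items": items,
           "hist_records": hist, "mammo_records": mammo}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        report.to_csv(outdir / "fused.csv", index=False)
        (outdir / "summary.json").write_text(json.dumps(
            {k: (v if np.isfinite(v) else str(v)) for k, v in summary.items()},
            indent=1))
    return out
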