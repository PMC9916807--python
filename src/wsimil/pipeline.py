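"""End-to-end pipeline: simulate toy slides, segment/tile, extract, train,
evaluate, and render a heatmap, with reproducibility metadata on every
artifact."""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

from .bags import FeatureBag, save_bag
from .config import RunConfig, config_hash
from .features import default_desk_encoder, extract_features
from .heatmap import HeatmapSpec, render_heatmap, write_heatmap_outputs
from .model import init_params, forward
from .simulate import render_toy_slide, simulate_toy_cohort
from .slide import ArraySlide, segment_foreground, tile
from .train import evaluate, stratified_split, train

__all__ = ["run_pipeline"]


def _stage(name):
    """Wrap stage failures so the failing stage is named."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full chain on a synthetic toy cohort; return the metrics.

    Artifacts (slide TIFF-free at desk scale: slides stay in memory; bags,
    checkpoint, logs, metrics and heatmap go to disk) are stamped with the
    config hash and seed.  Rerunning the same config reproduces the metrics
    JSON byte-for-byte.
    """
    cfg.validate()
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config_hash(cfg), "seed": cfg.seed}

    with _stage("simulate"):
        cohort = simulate_toy_cohort(
            n_slides=cfg.simulate.n_slides,
            prevalence=cfg.simulate.prevalence,
            width=cfg.simulate.width,
            height=cfg.simulate.height,
            seed=cfg.seed,
        )

    encoder = default_desk_encoder(seed=cfg.encoder.seed, output_dim=cfg.encoder.output_dim)
    bags: list[FeatureBag] = []
    tilesets = {}
    slides = {}
    with _stage("segment-tile-extract"):
        for s, (spec, label) in enumerate(cohort):
            img, _ = render_toy_slide(spec)
            slide = ArraySlide(img, slide_id=f"toy_{s:04d}")
            mask, ds = segment_foreground(slide)
            ts = tile(slide.dimensions, mask,
                      patch_size=cfg.slide_pipeline.patch_size,
                      min_foreground_fraction=cfg.slide_pipeline.min_foreground_fraction,
                      mask_downsample=ds, slide_id=slide.slide_id)
            if len(ts) == 0:
                warnings.warn(f"slide {slide.slide_id} has no foreground tiles; skipped")
                continue
            bag = extract_features(slide, ts, encoder, label=label)
            bags.append(bag)
            tilesets[bag.slide_id] = ts
            slides[bag.slide_id] = slide
            save_bag(bag, out / "bags" / f"{bag.slide_id}.h5")
            (out / "tiles").mkdir(parents=True, exist_ok=True)
            (out / "tiles" / f"{bag.slide_id}.json").write_text(ts.to_json())

    with _stage("split"):
        labels = [b.label for b in bags]
        tr, va, te = stratified_split(labels, cfg.split.fractions, seed=cfg.seed)
        overlap = (set(tr) & set(va)) | (set(tr) & set(te)) | (set(va) & set(te))
        if overlap:
            raise ValueError(f"split overlap at indices {sorted(overlap)}")
        if not tr or not va or not te:
            raise ValueError("each split must be nonempty; increase n_slides")
        split_rows = [
            (bags[i].slide_id, part)
            for part, idxs in zip(("train", "val", "test"), (tr, va, te))
            for i in idxs
        ]
        with open(out / "split.csv", "w") as fh:
            fh.write("slide_id,split\n")
            fh.writelines(f"{sid},{part}\n" for sid, part in split_rows)

    with _stage("train"):
        d = cfg.encoder.output_dim
        from .model import PROFILES

        _, h1, h2 = PROFILES[cfg.model.profile]
        params0 = init_params((d, h1, h2), n_classes=cfg.model.n_classes,
                              seed=cfg.model.seed, dropout_p=cfg.model.dropout_p)
        result = train([bags[i] for i in tr], [bags[i] for i in va],
                       params0, cfg.loss, cfg.training)
        from .model import save_checkpoint

        save_checkpoint(result.best_params, out / "checkpoint.npz", meta=stamp)
        with open(out / "training_log.csv", "w") as fh:
            fh.write("epoch,train_loss,val_loss\n")
            fh.writelines(
                f"{r['epoch']},{r['train_loss']:.6f},{r['val_loss']:.6f}\n" for r in result.log
            )

    with _stage("evaluate"):
        report, preds, cm = evaluate(result.best_params, [bags[i] for i in te])
        metrics = {
            **stamp,
            "n_train": len(tr), "n_val": len(va), "n_test": len(te),
            "best_epoch": result.best_epoch,
            "best_val_loss": round(result.best_val_loss, 6),
            "confusion": {"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn},
            "metrics": {k: (None if np.isnan(v) else round(v, 6))
                        for k, v in report.as_dict().items()},
        }
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
        with open(out / "predictions.csv", "w") as fh:
            fh.write("slide_id,prob_neg,prob_pos,pred,label\n")
            fh.writelines(
                f"{p['slide_id']},{p['probs'][0]:.6f},{p['probs'][1]:.6f},"
                f"{p['pred']},{p['label']}\n" for p in preds
            )

    with _stage("heatmap"):
        first = bags[te[0]]
        fwd = forward(first, result.best_params)
        spec = HeatmapSpec(class_index=cfg.heatmap.class_index,
                           colormap=cfg.heatmap.colormap,
                           alpha_blend=cfg.heatmap.alpha_blend,
                           downsample=cfg.heatmap.downsample)
        img, norm = render_heatmap(slides[first.slide_id], tilesets[first.slide_id],
                                   fwd.a[spec.class_index], spec)
        write_heatmap_outputs(img, tilesets[first.slide_id], fwd.a[spec.class_index],
                              norm, out / "heatmap.png", out / "heatmap.csv")

    return metrics
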