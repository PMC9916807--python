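"""Render an attention heatmap over a toy slide with a trained pipeline.

Runs the full chain on a small toy cohort (simulate -> segment/tile ->
extract -> train -> evaluate -> heatmap) and reports where the artifacts
land.
"""

from wsimil.config import load_config
from wsimil.pipeline import run_pipeline

cfg = load_config(data={
    "seed": 0,
    "simulate": {"n_slides": 40, "prevalence": 0.5, "width": 512, "height": 512},
    "slide_pipeline": {"min_foreground_fraction": 0.2},
    "encoder": {"output_dim": 64},
    "model": {"profile": "small"},
    "training": {"max_epochs": 80},
    "loss": {"k_sample": 2},
    "heatmap": {"downsample": 2},
})
metrics = run_pipeline(cfg, out_dir="scratch/heatmap_demo")

print(f"config hash: {metrics['config_hash']}  seed: {metrics['seed']}")
print(f"split: {metrics['n_train']} train / {metrics['n_val']} val / {metrics['n_test']} test")
print(f"test metrics: {metrics['metrics']}")
print("artifacts in scratch/heatmap_demo/: bags/, tiles/, checkpoint.npz,")
print("  training_log.csv, metrics.json, predictions.csv, heatmap.png, heatmap.csv")
# heatmap.png overlays per-patch attention (red = strongly attended,
# blue = weakly attended) on the rendered slide; heatmap.csv lists the raw
# and min-max-normalized attention per patch.
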