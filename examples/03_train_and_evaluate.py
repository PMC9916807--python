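"""Train the attention-MIL model on separable synthetic bags and evaluate.

Study conditions: 350 bags (prevalence 0.5), witness rate 0.1, 3-sigma
separation between signal and background instance means, split 200 train /
50 validation / 100 test.  Takes ~30 s on one CPU with the small profile.
"""

import numpy as np
from sklearn.metrics import roc_auc_score

import wsimil as w
from wsimil.losses import LossConfig
from wsimil.train import TrainConfig

spec = w.BagSimSpec(n_bags=350, prevalence=0.5, witness_rate=0.1, dim=16,
                    mu_background=0.0, mu_signal=3.0, sigma=1.0, seed=11)
data = w.simulate_bags(spec)
bags, flags = data.bags, data.instance_flags

result = w.train(bags[:200], bags[200:250], w.init_params("small", seed=0),
                 LossConfig(), TrainConfig(seed=0, max_epochs=60))
report, preds, cm = w.evaluate(result.best_params, bags[250:])

aucs = [roc_auc_score(f, w.forward(b, result.best_params).a[1])
        for b, f in zip(bags[250:], flags[250:]) if b.label == 1]

print(f"best epoch: {result.best_epoch}  val loss: {result.best_val_loss:.4f}")
print(f"test accuracy: {report.accuracy:.3f}  mean SS: {report.mean_ss:.3f}")
print(f"confusion: tp={cm.tp} tn={cm.tn} fp={cm.fp} fn={cm.fn}")
print(f"attention-vs-signal AUROC (positive bags): {np.mean(aucs):.3f}")
# Accuracy near 1.0 shows slide labels are recovered from bag-level
# supervision alone; AUROC >= 0.9 shows the attention concentrates on the
# hidden signal instances no instance label ever identified.
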