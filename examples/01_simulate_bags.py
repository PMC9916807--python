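"""Simulate a weakly labeled MIL bag dataset and inspect its ground truth.

Each bag stands for one slide: a matrix of patch embeddings plus a single
slide-level label.  Positive bags hide a minority of mean-shifted "signal"
instances; negative bags contain background only.
"""

import numpy as np

import wsimil as w

spec = w.BagSimSpec(n_bags=100, prevalence=0.82, witness_rate=0.1,
                    dim=64, mu_signal=2.0, seed=0)
data = w.simulate_bags(spec)

labels = [b.label for b in data.bags]
sizes = [b.n_instances for b in data.bags]
witness = [f.mean() for b, f in zip(data.bags, data.instance_flags) if b.label == 1]

print(f"bags: {len(data)}  positive: {sum(labels)}  negative: {len(labels) - sum(labels)}")
print(f"bag sizes: {min(sizes)}-{max(sizes)} instances")
print(f"mean witness rate in positive bags: {np.mean(witness):.3f}")
# With prevalence 0.82 the dataset mirrors a strongly imbalanced cohort
# (82 positive / 18 negative slides); the witness rate ~0.1 means only about
# one patch in ten of a positive slide carries the class signal.
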