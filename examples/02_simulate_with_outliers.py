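"""Generate synthetic RNA-seq data with known truth and outliers.

The default design: 10,000 NB-distributed features, 3 replicates per
condition, 10% DE features (half up-regulated) with fold changes
~ N(3, 0.5^2). Mechanism S then plants one multiplicative outlier
(factor ~ U(1.5, 10)) in each randomly selected feature.
"""

import numpy as np

from destab import SimulationConfig, inject_outliers, simulate_dataset

cfg = SimulationConfig(seed=7)
cm, design, truth, _ = simulate_dataset(cfg)
print(f"counts: {cm.n_features} x {cm.n_samples}")
print(f"DE features: {int(truth.is_de.sum())} ({int(truth.is_up.sum())} up-regulated)")
print(f"fold-change range among DE: {truth.true_fc[truth.is_de].min():.2f}"
      f" .. {truth.true_fc[truth.is_de].max():.2f}")

rng = np.random.default_rng(7)
noisy, mask = inject_outliers(cm, "S", 0.1, (1.5, 10.0), truth, rng)
n_out = int(mask.sum())
print(f"\nmechanism S at prob 0.1: {n_out} outlier cells "
      f"({mask.any(axis=1).sum()} features touched, expected ~1000)")
bumped = noisy.counts[mask] / np.maximum(cm.counts[mask], 1)
print(f"median inflation factor of outlier cells: {np.median(bumped):.2f}")
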