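"""Fit per-class NB distributions by moments and augment a training table.

Moment fitting equates the class/OTU sample mean and variance with the Gamma
moments (mu = r*theta, sigma^2 = r*theta^2) and solves for shape r and scale
theta; sampling the fitted distributions produces new raw-count rows that are
appended to the training set with their class labels.
"""

import numpy as np

import metann as m

table = m.simulate_dataset(m.SimulationConfig(
    n_classes=3, samples_per_class=40, n_otus=20,
    block_sizes=(10, 10), block_dispersions=(0.5, 5.0), seed=11,
))

labels = table.label_vector()
one_class = table.counts[labels == "class_0"]
fit = m.fit_nb_moments(one_class)
print(f"class_0 fit: {int((~fit.degenerate).sum())} NB OTUs, "
      f"{int(fit.degenerate.sum())} degenerate (zero/under-dispersed)")
j = int(np.flatnonzero(~fit.degenerate)[0])
print(f"example OTU {j}: mean {fit.mean[j]:.1f}, "
      f"r={fit.r[j]:.2f}, theta={fit.theta[j]:.2f} "
      f"(r*theta = {fit.r[j] * fit.theta[j]:.1f} reproduces the mean)")

augmented = m.augment_training_set(table, "match", np.random.default_rng(0))
print(f"augmented: {table.n_samples} -> {augmented.n_samples} samples "
      f"(one synthetic row per real training row)")
regen = augmented.counts[table.n_samples:][:40]
print(f"augmented class means track real ones: "
      f"max relative gap "
      f"{np.max(np.abs(regen.mean(0) - one_class.mean(0)) / (one_class.mean(0) + 1)):.2f}")
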