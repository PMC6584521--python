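"""Train the restricted MLP and the taxonomy-ordered 1D CNN on features.

Raw counts are prevalence-filtered, converted to relative abundances and
min-max rescaled to [0,1]; the MLP then trains for a fixed 100 epochs (Adam,
learning rate 0.001) with dropout at the input layer, the CNN for 200 epochs
with dropout after its first convolution.
"""

import numpy as np

import metann as m

table = m.simulate_dataset(m.SimulationConfig(
    n_classes=4, samples_per_class=30, n_otus=40,
    block_sizes=(20, 20), block_dispersions=(0.5, 5.0),
    error_spec=m.ErrorSpec(0.2, 0.2, 0.1), seed=3,
))
table = m.filter_low_prevalence(table, 0.10)
abund = m.to_relative_abundance(table)
abund = m.apply_rescaler(abund, m.fit_rescaler(abund))
y = table.label_vector()

mlp = m.train_mlp(abund, y, m.MLPSpec(hidden_sizes=(64, 32), input_dropout_q=0.5),
                  np.random.default_rng(1))
acc = (m.nn_models.predict(mlp, abund) == y).mean()
print(f"MLP: loss {mlp.loss_trace[0]:.3f} -> {mlp.loss_trace[-1]:.3f} over "
      f"{len(mlp.loss_trace)} epochs; training accuracy {acc:.2f}")

ordering = m.phylo_sort(table.otu_ids, table.taxonomy)  # identity w/o taxonomy
cnn = m.train_cnn(abund, y, ordering, m.CNNSpec(dropout_q=0.5),
                  np.random.default_rng(2))
acc = (m.nn_models.predict(cnn, abund) == y).mean()
flat = cnn.layers[-1].W.shape[0]
print(f"CNN: {flat} flattened features (~P/4 per channel x 8 channels); "
      f"training accuracy {acc:.2f}")
# probabilities come from a softmax output layer, so each row sums to 1
probs = m.predict_proba(mlp, abund)
print(f"first sample class probabilities: {np.round(probs[0], 3)}")
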