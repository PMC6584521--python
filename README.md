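# metann

Negative-binomial data augmentation, synthetic-data simulation and a
cross-validated benchmarking harness for classifying host phenotypes from
microbial (16S OTU) count tables.

Microbiome classification datasets are small (hundreds of samples) and wide
(hundreds to thousands of OTUs), so expressive classifiers over-fit badly.
`metann` attacks this with three pieces:

1. **A Gamma-Poisson (negative binomial) model of counts.** For each class
   and OTU, a count *v* follows
   NB(v; r, p) = Γ(r+v)/(v!·Γ(r)) · pᵛ(1−p)ʳ, constructed hierarchically as
   λ ~ Gamma(shape r, scale θ), v ~ Poisson(λ), with p = θ/(1+θ). Shape *r*
   controls overdispersion (Poisson as r → ∞; heavy zero inflation for small
   r). Parameters are fitted by the method of moments, μ̂ = rθ and σ̂² = rθ²,
   giving θ̂ = σ̂²/μ̂ and r̂ = μ̂²/σ̂² (a corrected convention using the NB
   marginal variance rθ(1+θ) is switchable).
2. **Training-set augmentation.** Per cross-validation split, the NB model is
   fitted to the *training fold only* and sampled to double the training set
   with labeled synthetic count rows, which then flow through the same
   normalization as real counts.
3. **Restricted neural classifiers plus a classical suite.** A 2–3 hidden
   layer MLP with input dropout (rate q, default 0.5) and a taxonomy-ordered
   1D CNN (two conv/pool stages, 8 channels, kernel 3), both trained with Adam
   at fixed epoch budgets (100/200) on a softmax cross-entropy objective —
   implemented in numpy inside the package — benchmarked against one-vs-rest
   SVM, L1/L2 logistic regression, gradient boosting, random forest and
   multinomial naive Bayes.

A simulator generates labeled synthetic count tables from per-class NB
profiles and corrupts them with three measurement-error channels (spurious
non-zeros, dropout to zero, count fluctuation) at configurable probabilities
(e₁, e₂, e₃), so classifier robustness can be measured under controlled noise.

## Worked example

```python
import metann as m

table = m.simulate_dataset(m.SimulationConfig(
    n_classes=3, samples_per_class=30, n_otus=30,
    block_sizes=(10, 10, 10), block_dispersions=(0.1, 1.0, 10.0),
    error_spec=m.ErrorSpec(0.3, 0.3, 0.2), seed=5,
))
models = {
    "mnb": m.BaselineSpec("mnb"),
    "rf":  m.BaselineSpec("rf", grid={}),
    "mlp": m.MLPSpec((64, 32), input_dropout_q=0.5),
}
report = m.cross_validate(
    table, models,
    m.RunConfig(seed=5, n_folds=3, n_runs=1, augment=True),
)
print(report.summary.round(3).to_string())
print(report.gain_percent)
```

prints

```
     f1_macro_mean  f1_macro_sd  f1_micro_mean  f1_micro_sd  auc_mean  auc_sd
mnb          0.955        0.042          0.956        0.042     0.991   0.007
rf           0.955        0.017          0.956        0.016     0.984   0.014
mlp          0.978        0.016          0.978        0.016     0.996   0.004
{'f1_macro': 2, 'f1_micro': 2}
```

Each row is a model's mean (and SD) over fold×run cells of F1-macro
(unweighted mean of per-class F1), F1-micro (pooled accuracy) and
micro-averaged one-vs-rest ROC AUC on held-out folds. The last line is the
performance gain: the best neural model's F1 relative to the best classical
model's, in integer percent — here the dropout-regularized, NB-augmented MLP
beats the best baseline by 2%.

The `examples/` directory has one narrative script per capability
(simulation, NB fitting/augmentation, neural training, benchmarking), and the
same operations are scriptable via a thin CLI:

```sh
metann simulate --seed 7 --out counts.tsv --labels labels.tsv
metann augment --in counts.tsv --labels labels.tsv --match --seed 7 --out aug.tsv
metann benchmark --counts counts.tsv --labels labels.tsv --config run.yaml --out report.json
```

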