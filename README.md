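# mammober

Breast-lesion image classification with a small CNN whose **structure and
training hyperparameters are tuned by the Advanced Al-Biruni Earth Radius
(ABER) metaheuristic**, together with the statistics used to compare
competing models. The package is aimed at researchers studying
nature-inspired hyperparameter optimization for medical-image classifiers:
it provides every stage of the study as an importable, seeded, testable
component, exercised end-to-end on synthetic mammogram-like images so no
clinical data are required.

## What is inside

| stage | module | summary |
| --- | --- | --- |
| synthetic data | `mammober.synthetic` | two-class lesion images (smooth mass vs spiculated mass + calcifications), PNG/CSV on disk |
| augmentation | `mammober.augment` | exact flips and 90° rotations; ×4 (default) or ×9 enlargement |
| feature extraction | `mammober.features` | frozen random-conv backbone (adapter hook for pretrained encoders) |
| search space | `mammober.space` | 11 hyperparameters (Filters/Ksize ×3, dense width, activation, learning rate, batch size, dropout); unit-hypercube decoding |
| optimizer | `mammober.ber` | ABER: BER steps + dynamic 70%→30% groups, elitism, leader probe with k = 1 + 2t²/T², stagnation mutation; classic-BER mode; random-search baseline |
| classifier | `mammober.cnn` | numpy CNN (3 conv blocks → dense → dropout → softmax) trained by SGD; cross-validated fitness with caching |
| metrics | `mammober.metrics` | accuracy, sensitivity, specificity, precision, NPV, F-score from TP/FP/TN/FN |
| statistics | `mammober.stats` | descriptives, one-way ANOVA (raw or from printed summaries), exact Wilcoxon signed-rank (full 2ⁿ null for n ≤ 25) |
| orchestration | `mammober.pipeline`, `mammober.cli` | leakage-free 70:30 protocol, replicated model comparison, `mammober` CLI |

The core step formulas: exploration
`P ← P + c⊙(P−1)⊙(2r₂−1)` with `c = min(|h·cos x/(1−cos x)|, 1)·r₁`;
exploitation `P ← r₁⊙P₁ + z·r₂⊙(P₂−P₃) + (1−z)·r₃⊙(P*−P₁)`; leader probe
`P′ = r₁⊙(P* + k)`, `k = 1 + 2t²/T²`; mutation
`P ← k + (P₁+P₂+P₃)·e^{−zk}`. Fitness is `1 − CV accuracy`, minimized.
See `docs/methods.md` for assumptions, parameter meanings and limitations.

## Worked example

```python
from mammober import desk_scale, run_pipeline

manifest = run_pipeline(desk_scale(seed=11, out_dir="runs/demo"))
print(manifest["best_config"])
print(manifest["heldout_metrics"])
```

A run of `examples/tune_cnn_on_synthetic_data.py` (the same pipeline at a
~1-minute budget) printed:

```
best configuration found:
{
  "filters_1": 96,  "ksize_1": 4,
  "filters_2": 64,  "ksize_2": 4,
  "filters_3": 128, "ksize_3": 5,
  "full_hidden1": 100, "activation": "lrelu",
  "learning_rate": 0.03, "batch_size": 64, "dropout": 0.3
}
cross-validated accuracy during search: 0.985
held-out metrics (malignant = positive class):
  accuracy     0.933
  sensitivity  0.875
  specificity  1.000
  precision    1.000
  npv          0.875
  f_score      0.933
```

Reading: ABER searched the 11-parameter grid by cross-validation inside
the 70% training split and settled on a leaky-ReLU network at learning
rate 0.03; scored once on the untouched 30%, it classified 93.3% of images
correctly, caught 87.5% of malignant lesions (sensitivity) and raised no
false alarms on benign ones (specificity 1.0).

Other examples, one per capability, live in `examples/`:
`generate_and_inspect_data.py`, `augmentation_factors.py`,
`optimize_sphere.py`, `model_comparison_stats.py`.

The same stages are available from the shell:

```bash
mammober generate-data --n-per-class 50 --seed 1 --out data/
mammober run-all --seed 1 --out runs/demo
mammober compare-stats --in results.csv --out stats/
```

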