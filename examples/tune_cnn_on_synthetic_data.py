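"""Full pipeline at a small budget: generate, augment, extract, tune, score.

Prints the decoded best CNN configuration found by ABER and the held-out
metrics. The held-out 30% never enters the search; the fitness is k-fold
cross-validated accuracy inside the 70% training split.
"""

import json
from dataclasses import replace

from mammober import OptimizerConfig, desk_scale, run_pipeline

cfg = desk_scale(seed=11, out_dir="scratch/example_pipeline")
# shrink the search further so this example finishes in ~1 minute
cfg = replace(cfg, optimizer=OptimizerConfig(
    population_size=6, max_iterations=6, n_runs=1, seed=11))
manifest = run_pipeline(cfg)

print("best configuration found:")
print(json.dumps(manifest["best_config"], indent=2))
print(f"cross-validated accuracy during search: "
      f"{manifest['best_cv_accuracy']:.3f}")
print("held-out metrics (malignant = positive class):")
for name, value in manifest["heldout_metrics"].items():
    print(f"  {name:12s} {value:.3f}")
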