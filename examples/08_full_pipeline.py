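"""Run the full grading pipeline on a small synthetic cohort.

Generates 64 labeled images (8 balanced joint grades), preprocesses,
trains and applies the segmenter, extracts features, selects the
informative subset, trains the swarm-optimized classifier and evaluates on
the held-out split.  Scaled down from the default 200-sample study so the
example finishes in a couple of minutes; with so little training data the
accuracy sits well below the ~0.7 of the full-size study, but still far
above chance.
"""

import json

from retinograde import PipelineConfig, run_pipeline
from retinograde.rfselect import RegularizationConfig

config = PipelineConfig(
    n_samples=64,
    swarm_steps=2000,
    selection=RegularizationConfig(n_tree=100, gamma=0.5, threshold=0.01),
    seed=1,
)
report = run_pipeline(config)

print("selected features:", report["stages"]["select"]["top"])
ev = report["stages"]["evaluate"]
print(json.dumps({k: round(ev[k], 3) for k in
                  ("accuracy", "sensitivity", "specificity", "precision", "f1")}, indent=2))
print(f"held-out samples: {ev['n_test']}   total runtime: {report['seconds_total']}s")
# Accuracy clears the 0.125 chance level of the 8-grade task by a wide
# margin even at this reduced cohort size; the selected features are
# dominated by the lesion-load and exudate-distance summaries the grading
# rules rely on.
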