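"""End-to-end configured run writing report artifacts.

Runs the demo-scale pipeline (5 questionnaires x 8 items, 3 datasets of
n = 500, combination arm at k_max = 3) and prints the summary winners.
"""

import json
from pathlib import Path

import factorverse as fv

cfg = fv.RunConfig(
    n_questionnaires=5, items_per_questionnaire=[8] * 5, n_factors=3,
    n_datasets=3, n_per_dataset=500, arms=["combination"],
    k_max={"factor_number": 3, "combination": 3, "rotation": 3},
    directions={"model_based_planning": ["most_negative"],
                "mean_confidence": ["most_positive"]},
)
out = fv.run_pipeline(cfg, output_dir=Path("scratch") / "demo_run")
summary = json.loads((out / "summary.json").read_text())
print(f"artifacts in {out} (config hash {summary['config_hash']})")
for key, win in summary["winners"].items():
    print(f"  {key}: {win['candidate_id']} "
          f"(weighted f2 = {win['f2_weighted']:+.4f}, "
          f"beats {win['percentile_beaten']:.1f}% of candidates)")
print(f"  PLS vs benchmark f2 gain: {summary['pls']['f2_gain']:+.4f}")
print("each winner is the dimension with the strongest weighted effect in "
      "its direction; reruns with the same config are byte-identical")
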