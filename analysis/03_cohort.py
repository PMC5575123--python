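#!/usr/bin/env python
"""Build the study samples: base restrictions, 2006 drop, focal Sections,
and the 200 m interior-buffer subsample; compute the exposure cutoffs on
the all-births sample and the per-measure high-exposure indicators.

Writes samples.csv, cutoffs.json and exclusions.log under results/study/
and prints the sample sizes and nesting.
"""

import json

from analysis_config import CONFIG, OUT
from pestnatal.pipeline import run_pipeline


def main() -> None:
    run_pipeline(CONFIG, OUT, stages=["cohort"])
    tally = json.loads((OUT / "exclusions.log").read_text())
    cuts = json.loads((OUT / "cutoffs.json").read_text())
    n = tally["n"]
    print("exclusions:", tally["base_restrictions"])
    print("samples:", n)
    print(f"focal / full = {n['focal'] / n['full_estimation']:.3f}")
    q = cuts["gestational_total_quantiles"]
    print(f"cutoffs (kg): q75={q['q75_kg']:.0f} q95={q['q95_kg']:.0f} "
          f"q99={q['q99_kg']:.0f}")


if __name__ == "__main__":
    main()
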