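#!/usr/bin/env python
"""Monte Carlo validation of the estimator on the synthetic design.

Three studies, each rebuilt from scratch: (1) recovery of an injected
preterm effect of 0.0075 on the gestational high-exposure indicator;
(2) size of the post-birth (trimester 4) placebo when only gestational
exposure matters; (3) oracle equivalence of the within-FE estimator and
CR1 sandwich against explicit-dummy OLS.  Replicate counts are kept small
here for a quick narrative run; scripts/acceptance.py runs the full 200.

Writes results/validation.json.
"""

import json
from pathlib import Path

from pestnatal.experiments import (
    fe_oracle_check,
    placebo_experiment,
    recovery_experiment,
    recovery_summary,
)

N_REPS = 50


def main() -> None:
    reps = recovery_experiment(n_reps=N_REPS, base_seed=1, effect=0.0075)
    s = recovery_summary(reps)
    print(f"recovery: mean theta = {s['mean_theta']:.5f} "
          f"(truth 0.0075, bias {s['bias']:+.5f} ~ "
          f"{s['bias'] / s['mc_se']:.1f} MC SEs), coverage {s['coverage']:.2f}")

    pl = placebo_experiment(n_reps=N_REPS, base_seed=2, effect=0.0075)
    print(f"placebo: trimester-4 rejection rate {pl['reject'].mean():.3f} "
          f"at alpha = 0.05")

    oracle = fe_oracle_check(n_instances=20, seed=3)
    print(f"oracle: max |coef dev| = {oracle['max_abs_coef_dev']:.2e}, "
          f"max rel SE dev = {oracle['max_rel_se_dev']:.2e}")

    out = Path("results/validation.json")
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps({"recovery": s,
                               "placebo_rejection": float(pl["reject"].mean()),
                               "oracle": oracle}, indent=2))


if __name__ == "__main__":
    main()
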