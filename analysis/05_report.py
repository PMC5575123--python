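#!/usr/bin/env python
"""Convert battery coefficients to interpretable effect sizes.

Linear-probability coefficients are scaled by the focal-sample outcome rate
(x100 -> percent change); log-outcome coefficients convert to percent
(100*theta) and to grams or hours via the focal-sample mean.  Flags
significance at 0.05/0.01 and under a Bonferroni correction for 25
comparisons (5 outcomes x up to 5 exposure terms).

Writes effects.csv and summary.md under results/study/.
"""

import pandas as pd

from analysis_config import CONFIG, OUT
from pestnatal.pipeline import run_pipeline
from pestnatal.report import bonferroni_alpha


def main() -> None:
    run_pipeline(CONFIG, OUT, stages=["report"])
    eff = pd.read_csv(OUT / "effects.csv")
    ok = eff[eff["status"] == "ok"]
    print(f"alpha (Bonferroni, 25 comparisons): {bonferroni_alpha(0.05, 5, 5)}")
    print(f"{int(ok['bonferroni_significant'].sum())} coefficients survive the "
          f"Bonferroni correction")
    show = ok[ok["sample"] == "focal"].head(12).copy()
    show["stars"] = show["stars"].fillna("")
    print(show[["model_id", "term", "coef", "pct_change", "unit_change",
                "stars"]].to_string(index=False))


if __name__ == "__main__":
    main()
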