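#!/usr/bin/env python
"""Attach per-birth exposure vectors: gestational, trimester 0-4, toxicity
and application-method aggregates.

Reads the simulated tables from results/study/, writes exposures.csv, and
prints the additivity check (trimesters, toxicity groups and methods each
sum exactly to the gestational total).
"""

import numpy as np
import pandas as pd

from analysis_config import CONFIG, OUT
from pestnatal.pipeline import run_pipeline


def main() -> None:
    run_pipeline(CONFIG, OUT, stages=["expose"])
    expo = pd.read_csv(OUT / "exposures.csv")
    tri = expo[["tri1_kg", "tri2_kg", "tri3_kg"]].sum(axis=1)
    tox = expo[["tox12_kg", "tox34_kg"]].sum(axis=1)
    print(f"{len(expo)} exposure vectors")
    print("max |tri1+tri2+tri3 - total| =", np.abs(tri - expo["total_kg"]).max())
    print("max |tox12+tox34 - total|   =", np.abs(tox - expo["total_kg"]).max())
    print(f"share with any post-birth (trimester 4) exposure: "
          f"{(expo['tri4_kg'] > 0).mean():.2f}")


if __name__ == "__main__":
    main()
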