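"""Shared configuration for the numbered analysis drivers.

One simulated study: a 3x3-Township grid (324 Sections), births 1997-2011
at 2000 per year with 2006 lacking the tobacco field, applications
1996-2012.  All drivers read and write results/study/.
"""

from pathlib import Path

from pestnatal.pipeline import PipelineConfig
from pestnatal.synth import GridSpec, SimConfig

OUT = Path("results/study")

CONFIG = PipelineConfig(
    grid=GridSpec(3, 3),
    sim=SimConfig(seed=1234, years=(1997, 2011), n_births_per_year=2000),
)
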