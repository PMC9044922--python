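"""Bundled example data.

``load_wheat_heat_qpcr`` returns the published mean fold-change / Log2FC
table for 18 differentially expressed wheat AP2/ERF genes measured by
RT-qPCR in two heat-tolerant and two heat-susceptible genotypes after a
3-day 35 °C seedling heat treatment (beta-actin reference, 25 °C control).
The ``published_trait`` and ``published_group`` columns carry the authors'
trait categorization and regulation-pattern grouping, so the package's
threshold rules can be checked against the published calls.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd


def load_wheat_heat_qpcr() -> pd.DataFrame:
    text = (
        resources.files("gfam.data").joinpath("wheat_heat_qpcr_log2fc.tsv").read_text()
    )
    return pd.read_csv(StringIO(text), sep="\t")
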