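"""Packaged reference data: the published 24-species survey numbers.

The survey's per-species table (total vs membrane protein counts, plus
its LHCA/innovation columns) and its headline totals are shipped as
plain data so that the statistics derived from them — integer membrane
percentages, the membrane-vs-total Spearman correlation, functional
class shares — can be recomputed by this package's own routines.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

_DATA = resources.files("holomem") / "data"


def survey_species_table() -> pd.DataFrame:
    """Per-species totals of the published survey, indexed by species."""
    with resources.as_file(_DATA / "survey_species_totals.tsv") as path:
        df = pd.read_csv(path, sep="\t", index_col="species")
    return df


def survey_reported_totals() -> dict:
    """Headline dataset-wide counts reported by the published survey."""
    with resources.as_file(_DATA / "survey_reported_totals.json") as path:
        data = json.loads(path.read_text())
    data.pop("comment", None)
    return data
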