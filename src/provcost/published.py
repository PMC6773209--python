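"""Published national/regional reference cost summary.

``data/table1_reference.csv`` is a transcription of the published national
and three-region summary of the detailed reference method (overall, urban
and rural cost per procedure, 2018 US$, one-decimal presentation values).
It ships with the package so dispersion-ratio summaries can be reproduced
without any external data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .types import CostTable

#: Procedure settings for the published summary rows: screening, diagnosis
#: and LEEP are outpatient; CKC and staged cancer treatment are inpatient.
PUBLISHED_PROCEDURE_SETTINGS: dict[str, str] = {
    "via": "outpatient", "via_vili": "outpatient",
    "carehpv_self": "outpatient", "carehpv_clinician": "outpatient",
    "hc2_self": "outpatient", "hc2_clinician": "outpatient",
    "colposcopy": "outpatient", "biopsy": "outpatient", "ecc": "outpatient",
    "leep": "outpatient",
    "ckc": "inpatient",
    "figo1": "inpatient", "figo2": "inpatient",
    "figo3": "inpatient", "figo4": "inpatient",
}


def load_published_summary() -> CostTable:
    """The transcribed published national/regional cost summary as a
    :class:`CostTable` (values as printed, i.e. rounded to one decimal)."""
    with resources.files("provcost.data").joinpath("table1_reference.csv").open(
            "r", encoding="utf-8") as fh:
        frame = pd.read_csv(fh)
    return CostTable(frame)
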