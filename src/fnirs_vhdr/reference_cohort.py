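"""Published demographic/clinical reference tables for the two cohorts.

The 12-subject fASD group (ages in years, clinical scores; missing cells as
None, printed as "n.a." on disk) and the 13 control ages.  These are the
printed study inputs used for the demographic summaries and as a realistic
fixture for the clinical-table reader.
"""

from __future__ import annotations

import pandas as pd

#: fASD group: subject_id, age, ADOS_TOT, ADOS_comp, AQ_tot, nv_IQ, VABS_tot
FASD_ROWS = [
    ("B1", 4, 16, 7, 53, 96, 63),
    ("B2", 5, None, None, 56, 78, 74),
    ("B3", 6, 14, 5, 38, 98, 80),
    ("B4", 4, 9, 5, None, 125, 96),
    ("B5", 3, 14, 5, 48, 106, 93),
    ("B6", 6, 12, 7, 58, 108, 81),
    ("B7", 5, 9, 6, 96, 87, 87),
    ("B8", 6, 11, 6, 106, 117, 85),
    ("B9", 5, 9, 5, 53, 102, 85),
    ("B10", 4, 15, 5, 47, 98, None),
    ("B11", 3, 8, 4, 33, 119, 102),
    ("B12", 3, 11, 5, 95, 110, 77),
]

FASD_COLUMNS = ["subject_id", "age", "ADOS_TOT", "ADOS_comp", "AQ_tot", "nv_IQ", "VABS_tot"]

#: control group ages (years), subjects A1..A13
TD_AGES = [4, 5, 6, 5, 4, 6, 3, 4, 6, 6, 4, 6, 3]


def fasd_clinical_table() -> pd.DataFrame:
    """The fASD demographic/clinical table as a DataFrame (NaN = missing)."""
    return pd.DataFrame(FASD_ROWS, columns=FASD_COLUMNS).astype(
        {c: float for c in FASD_COLUMNS if c != "subject_id"}
    )


def fasd_ages() -> list[int]:
    return [row[1] for row in FASD_ROWS]
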