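import numpy as np
import pandas as pd
import pytest

from panelkink import InstrumentTable, PanelDataset


def make_panel(records: list[dict], covariate_names=("x1",)) -> PanelDataset:
    """Build a small panel from dicts, filling label columns with defaults."""
    df = pd.DataFrame(records)
    for col, default in [("gender", "female"), ("skill", "low"),
                         ("employment_status", "employee"), ("pregnant", False)]:
        if col not in df.columns:
            df[col] = default
    return PanelDataset(df, list(covariate_names))


@pytest.fixture
def toy_panel():
    """Three balanced individuals with hand-written values (one covariate)."""
    recs = []
    values = {  # id -> (hours, bmi, x1) per period
        "a": [(31.0, 24.0, 1.0), (35.0, 26.5, 2.0)],
        "b": [(40.0, 30.0, 0.0), (38.0, 31.0, 0.0)],
        "c": [(20.0, 22.0, 3.0), (20.0, 22.0, 3.0)],
    }
    for pid, rows in values.items():
        for period, (h, q, x) in enumerate(rows, start=1):
            recs.append(dict(id=pid, period=period, hours=h, bmi=q, x1=x))
    return make_panel(recs)


@pytest.fixture
def toy_instruments():
    return InstrumentTable(pd.DataFrame({
        "id": ["a", "b", "c"],
        "birth_weight": [3.2, 3.5, 3.0],
        "bmi_age10": [16.0, 18.0, 15.5],
        "mother_bmi": [23.0, 25.0, 22.0],
        "father_bmi": [24.0, 26.0, 23.5],
    }))
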