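import pandas as pd
import pytest

from vegrisk import read_mrl_table, read_records


@pytest.fixture(scope="session")
def mixed_rows_frame() -> pd.DataFrame:
    """10-row inspection table with 2 malformed rows (hand-countable)."""
    cols = ["province", "vegetable", "year", "batch_id", "pesticide",
            "concentration", "unit"]
    rows = [
        ("Jiangsu", "celery", 2021, "b1", "chlorpyrifos", "0.05", "mg/kg"),
        ("Jiangsu", "celery", 2021, "b1", "imidacloprid", "500", "µg/kg"),
        ("Jiangsu", "leek", 2022, "b2", "procymidone", "0.6", "mg/kg"),
        ("Shandong", "tomato", 2021, "b3", "", "", ""),          # no detection
        ("Shandong", "tomato", 2021, "b4", "imidacloprid", "", "mg/kg"),  # missing conc
        ("Shandong", "tomato", 2022, "b5", "imidacloprid", "2", "ppm"),
        ("Yunnan", "ginger", 2023, "b6", "clothianidin", "0.1", "oz/lb"),  # bad unit
        ("Yunnan", "ginger", 2023, "b6", "carbendazim", "0.2", "mg/kg"),
        ("Chongqing", "chili", 2021, "b7", "acetamiprid", "0.3", "mg/kg"),  # alias
        ("Hubei", "cowpea", 2023, "b8", "carbendazim", "0.4", "mg/kg"),
    ]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture(scope="session")
def small_mrl_table():
    df = pd.DataFrame(
        [
            ("celery", "imidacloprid", "0.5", 0),
            ("celery", "chlorpyrifos", "", 1),
            ("leek", "procymidone", "0.2", 0),
            ("tomato", "imidacloprid", "1.0", 0),
            ("ginger", "carbendazim", "0.5", 0),
            ("ginger", "clothianidin", "0.2", 0),
            ("pepper", "acetamiprid", "1.0", 0),
            ("cowpea", "carbendazim", "0.5", 0),
        ],
        columns=["vegetable", "pesticide", "mrl_mg_per_kg", "banned"],
    )
    return read_mrl_table(df)


@pytest.fixture(scope="session")
def mixed_records(mixed_rows_frame):
    records, report = read_records(mixed_rows_frame)
    return records, report
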