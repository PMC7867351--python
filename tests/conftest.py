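import json

import pytest

from soilmatch import ReferenceDatabase, SoilRecord

# Published example database: four rows of the input-data table.
TABLE2_ROWS = [
    {"RA": 108.79, "T2": 90.78, "T3": 78.55, "D250": 0.25, "Humus": 0.38,
     "pH": 8.0, "Clay": 6.7, "Sand": 90.4, "Sample Name": "sand"},
    {"RA": 101.09, "T2": 102.81, "T3": 86.81, "D250": 0.16, "Humus": 0.33,
     "pH": 7.9, "Clay": 5.9, "Sand": 85.4, "Sample Name": "sand"},
    {"RA": 101.09, "T2": 98.46, "T3": 71.99, "D250": 0.25, "Humus": 0.31,
     "pH": 8.0, "Clay": 6.3, "Sand": 88.7, "Sample Name": "sand"},
    {"RA": 104.95, "T2": 101.59, "T3": 71.93, "D250": 0.48, "Humus": 0.55,
     "pH": 5.3, "Clay": 8.5, "Sand": 81.7, "Sample Name": "light loam"},
]

FEATURE_KEYS = ("RA", "T2", "T3", "D250", "Humus", "pH", "Clay", "Sand")


def row_vector(row):
    return tuple(row[k] for k in FEATURE_KEYS)


@pytest.fixture
def table2_rows():
    return [dict(r) for r in TABLE2_ROWS]


@pytest.fixture
def table2_db():
    records = tuple(
        SoilRecord(
            ra=r["RA"], t2=r["T2"], t3=r["T3"], d250=r["D250"], humus=r["Humus"],
            ph=r["pH"], clay=r["Clay"], sand=r["Sand"], name=r["Sample Name"],
        )
        for r in TABLE2_ROWS
    )
    return ReferenceDatabase(records=records, source="fixture")


@pytest.fixture
def table2_json(tmp_path, table2_rows):
    path = tmp_path / "refs.json"
    path.write_text(json.dumps(table2_rows), encoding="utf-8")
    return path
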